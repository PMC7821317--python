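"""Sex-specific distributions of individual condition.

Condition is a dimensionless measure of individual quality drawn from a
normal distribution with mean 1; the mean is fixed because condition is
relative within each sex.  Environmental stress is modeled as an increase
in the standard deviation of the condition distribution — stress reveals
cryptic variation among individuals — and the SD can be set independently
for each sex, which is what makes sex-limited stress scenarios possible.

Draws are truncated below at zero (negative draws are set to 0) because
condition enters contest success as ``c**g`` and fecundity linearly, both
of which require nonnegative condition.  At the SD ranges of interest
(sigma <= 0.5) the truncated mass is tiny, so the sample mean stays within
sampling error of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

SCENARIO_LABELS = ("none", "both", "female_only", "male_only")


@dataclass(frozen=True)
class StressScenario:
    """Which sex(es) receive stress, and the condition SD per sex.

    Parameters
    ----------
    label : str
        One of ``none``, ``both``, ``female_only``, ``male_only``.  The
        label is metadata describing which sigma varies in a sweep; the
        distributions are determined entirely by ``sigma_f``/``sigma_m``.
    sigma_f, sigma_m : float
        Standard deviation of female / male condition, >= 0.
    """

    label: str
    sigma_f: float
    sigma_m: float

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(
                f"unknown scenario label {self.label!r}; expected one of {SCENARIO_LABELS}"
            )
        if not (np.isfinite(self.sigma_f) and self.sigma_f >= 0):
            raise ValueError(f"sigma_f must be finite and >= 0, got {self.sigma_f}")
        if not (np.isfinite(self.sigma_m) and self.sigma_m >= 0):
            raise ValueError(f"sigma_m must be finite and >= 0, got {self.sigma_m}")


@dataclass
class Population:
    """Condition values for one simulated population, equal counts per sex."""

    female_conditions: np.ndarray
    male_conditions: np.ndarray
    seed: int
    scenario: StressScenario | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.female_conditions = np.asarray(self.female_conditions, dtype=float)
        self.male_conditions = np.asarray(self.male_conditions, dtype=float)
        if self.female_conditions.shape != self.male_conditions.shape:
            raise ValueError("female and male condition vectors must have equal length")
        for name, v in (
            ("female", self.female_conditions),
            ("male", self.male_conditions),
        ):
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} conditions must be finite and >= 0")

    @property
    def n_per_sex(self) -> int:
        return self.female_conditions.size

    def to_tsv(self, path) -> None:
        """Write the population as a two-column TSV (sex, condition)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "sex": ["F"] * self.n_per_sex + ["M"] * self.n_per_sex,
                "condition": np.concatenate(
                    [self.female_conditions, self.male_conditions]
                ),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def draw_conditions(n: int, sigma: float, seed) -> np.ndarray:
    """Draw ``n`` condition values from Normal(1, sigma), truncated at 0.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  A given
    (n, sigma, seed) triple always yields a bitwise-identical vector.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError(f"sigma must be finite and >= 0, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = rng.normal(loc=1.0, scale=sigma, size=n) if sigma > 0 else np.ones(n)
    np.maximum(c, 0.0, out=c)
    return c


def make_population(n_per_sex: int, scenario: StressScenario, seed: int) -> Population:
    """Draw a population of ``n_per_sex`` females and males under a scenario.

    ``n_per_sex`` must be even so the population partitions into mating
    groups of two individuals per sex.  Independent per-sex random
    sub-streams are derived from ``seed``, so the male draw does not
    depend on the female one.
    """
    if not isinstance(n_per_sex, (int, np.integer)) or n_per_sex < 2 or n_per_sex % 2:
        raise ValueError(f"n_per_sex must be a positive even integer, got {n_per_sex!r}")
    seq = np.random.SeedSequence(seed)
    f_ss, m_ss = seq.spawn(2)
    females = draw_conditions(n_per_sex, scenario.sigma_f, np.random.default_rng(f_ss))
    males = draw_conditions(n_per_sex, scenario.sigma_m, np.random.default_rng(m_ss))
    return Population(females, males, seed=int(seed), scenario=scenario)


def scenario_from_config(path) -> tuple[StressScenario, dict]:
    """Read a scenario from a YAML config file.

    Expected keys: label, sigma_f, sigma_m and optionally n_per_sex, seed.
    Returns the scenario plus the full parsed mapping (for extras).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"scenario config {path} must be a mapping")
    missing = {"label", "sigma_f", "sigma_m"} - cfg.keys()
    if missing:
        raise ValueError(f"scenario config missing keys: {sorted(missing)}")
    scen = StressScenario(
        label=cfg["label"],
        sigma_f=float(cfg["sigma_f"]),
        sigma_m=float(cfg["sigma_m"]),
    )
    return scen, cfg
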