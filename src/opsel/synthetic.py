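"""Synthetic fitness-assay tables with known ground truth.

Emulates the structure of the empirical dataset: three treatments
(CT control, HT heterogeneous bean quality, AT delayed oviposition), two
focal sexes, sample sizes near the study's (CT 102/102, HT 105/87,
AT 101/97 males/females; 594 assays total), an assay-date random effect,
overdispersed adult-offspring counts with sex-by-treatment-specific mean
and target variance of relative fitness, and per-assay offspring weights.

Counts are negative-binomial.  For a group with mean count ``mu``, target
opportunity for selection ``I`` (total variance of relative fitness) and
between-date SD ``tau`` on the relative-fitness scale, the NB shape ``k``
is solved from the law of total variance so the marginal Var/mean^2 hits
the target:

    I = 1/mu + (1 + tau^2)/k + tau^2   =>   k = (1 + tau^2) / (I - 1/mu - tau^2)

Targets below the Poisson-plus-date floor ``1/mu + tau^2`` are infeasible
for this count family and rejected explicitly rather than silently
substituted.  The date effect is a multiplicative mean-1 lognormal factor
on the group mean, shared by all assays of a date within a sex-treatment
group.  An optional per-treatment ceiling (maximum count) produces
negative skew, mimicking a performance ceiling.

Default group means encode the study conditions: CT mean 40 offspring,
HT 14% lower, AT 36% lower; male relative-fitness variance twice the
female one in every treatment (log ratio ln 2), with a stronger male bias
in HT and both sexes' variances elevated in AT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from opsel.condition import StressScenario, draw_conditions
from opsel.pipeline import AssayRecord, TREATMENTS
from opsel.reproduction import MatingGroup, ReproductionParams, group_reproduction

#: study-scale group sizes, (sex, treatment) -> n
DEFAULT_N = {
    ("M", "CT"): 102, ("F", "CT"): 102,
    ("M", "HT"): 105, ("F", "HT"): 87,
    ("M", "AT"): 101, ("F", "AT"): 97,
}
#: mean adult offspring per treatment: CT 40, HT -14%, AT -36%
DEFAULT_MEANS = {"CT": 40.0, "HT": 34.4, "AT": 25.6}
#: target I (total variance of relative fitness) per (sex, treatment);
#: male variance is twice the female one in each treatment, the male bias
#: strongest in HT and both variances elevated in AT
DEFAULT_TARGET_I = {
    ("F", "CT"): 0.30, ("M", "CT"): 0.60,
    ("F", "HT"): 0.15, ("M", "HT"): 0.45,
    ("F", "AT"): 0.45, ("M", "AT"): 0.90,
}
#: mean individual offspring weight (mg): elevated in AT
DEFAULT_INDIV_WEIGHT = {"CT": 4.0, "HT": 4.0, "AT": 5.2}


class InfeasibleTargetError(ValueError):
    """Target I unreachable for the negative-binomial count family."""


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of one synthetic assay table.

    ``n``, ``mean_count`` and ``target_I`` are keyed by (sex, treatment)
    or treatment as in the module defaults.  ``date_sd`` is the
    between-date SD on the relative-fitness scale; ``ceiling`` optionally
    maps a treatment to a maximum count (negative-skew device).
    """

    n: dict = field(default_factory=lambda: dict(DEFAULT_N))
    mean_count: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    target_I: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_I))
    indiv_weight: dict = field(default_factory=lambda: dict(DEFAULT_INDIV_WEIGHT))
    weight_cv: float = 0.08
    n_dates: int = 10
    date_sd: float = 0.15
    ceiling: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.n.items():
            if n < 2:
                raise ValueError(f"group {key}: n must be >= 2, got {n}")
        for key, m in self.mean_count.items():
            if m <= 0:
                raise ValueError(f"treatment {key}: mean count must be > 0, got {m}")
        for key, i in self.target_I.items():
            if i < 0:
                raise ValueError(f"group {key}: target I must be >= 0, got {i}")
        if self.n_dates < 1:
            raise ValueError("n_dates must be >= 1")
        if self.date_sd < 0:
            raise ValueError("date_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = {f"{s}:{t}": v for (s, t), v in self.n.items()}
        d["target_I"] = {f"{s}:{t}": v for (s, t), v in self.target_I.items()}
        return d


def nb_shape_for_target(mu: float, target_I: float, tau: float = 0.0) -> float:
    """Solve the NB shape k so that marginal Var/mean^2 equals target_I.

    Raises :class:`InfeasibleTargetError` when the target lies at or
    below the Poisson-plus-date floor ``1/mu + tau^2``.
    """
    floor = 1.0 / mu + tau**2
    if target_I <= floor:
        raise InfeasibleTargetError(
            f"target I = {target_I} is infeasible for a negative-binomial count "
            f"with mean {mu} and date SD {tau}: the floor is 1/mu + tau^2 = "
            f"{floor:.4f}; use a smaller date SD, a larger target, or a "
            "binomial/under-dispersed count family"
        )
    return (1.0 + tau**2) / (target_I - floor)


def _lognormal_date_factors(n_dates: int, tau: float, rng) -> np.ndarray:
    """Mean-1 multiplicative date effects with SD tau."""
    if tau == 0:
        return np.ones(n_dates)
    s2 = np.log1p(tau**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=n_dates)


def generate_assays(config: GeneratorConfig | None = None):
    """Generate a synthetic assay table plus its ground-truth record.

    Returns ``(records, truth)`` where ``records`` is a list of
    :class:`~opsel.pipeline.AssayRecord` and ``truth`` holds the exact
    group targets (mean, I, V_m/V_f per treatment, date-effect SD) the
    table was generated from.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    treatments = sorted({t for (_, t) in config.n}, key=TREATMENTS.index)
    records: list[AssayRecord] = []
    date_labels = [f"d{j + 1:02d}" for j in range(config.n_dates)]
    for (sex, trt), n in config.n.items():
        mu = config.mean_count[trt] if trt in config.mean_count else config.mean_count[(sex, trt)]
        target = config.target_I[(sex, trt)]
        k = nb_shape_for_target(mu, target, config.date_sd)
        factors = _lognormal_date_factors(config.n_dates, config.date_sd, rng)
        dates = rng.integers(0, config.n_dates, size=n)
        mu_i = mu * factors[dates]
        # NB with mean m and shape k: numpy parameterization n=k, p=k/(k+m)
        counts = rng.negative_binomial(k, k / (k + mu_i))
        cap = config.ceiling.get(trt)
        if cap is not None:
            counts = np.minimum(counts, int(cap))
        w_mean = config.indiv_weight[trt]
        indiv_w = rng.normal(w_mean, config.weight_cv * w_mean, size=n).clip(min=0.1)
        total_w = counts * indiv_w
        for i in range(n):
            records.append(
                AssayRecord(
                    focal_sex=sex,
                    treatment=trt,
                    assay_date=date_labels[dates[i]],
                    offspring_count=int(counts[i]),
                    total_offspring_weight=float(total_w[i]),
                )
            )
    truth = {
        "target_I": {f"{s}:{t}": v for (s, t), v in config.target_I.items()},
        "mean_count": dict(config.mean_count),
        "log_variance_ratio": {
            t: float(np.log(config.target_I[("M", t)] / config.target_I[("F", t)]))
            for t in treatments
            if ("M", t) in config.target_I and ("F", t) in config.target_I
        },
        "date_sd": config.date_sd,
        "n_dates": config.n_dates,
        "indiv_weight": dict(config.indiv_weight),
        "seed": config.seed,
    }
    return records, truth


def generate_from_mechanism(
    scenario_map: dict[str, StressScenario],
    params: ReproductionParams | None = None,
    n_per_group: dict | None = None,
    base_mean: float = 40.0,
    seed: int = 0,
):
    """Generate an assay table by running the mating-group mechanism.

    Each assay simulates one 2+2 mating group under the treatment's
    stress scenario; the focal individual's group fitness (relative
    scale, mean ~ 1) is converted to an integer offspring count by a
    Poisson draw with mean ``base_mean * fitness``.  Under zero stress
    every fitness is 1, so counts are Poisson(base_mean) and the
    realized I sits at the Poisson floor 1/base_mean.

    Returns ``(records, truth)`` where truth holds the realized
    (pre-Poisson) relative-fitness I per group.
    """
    if params is None:
        params = ReproductionParams()
    if n_per_group is None:
        n_per_group = dict(DEFAULT_N)
    rng = np.random.default_rng(seed)
    records: list[AssayRecord] = []
    realized: dict[str, float] = {}
    for (sex, trt), n in n_per_group.items():
        scen = scenario_map[trt]
        cf = draw_conditions(2 * n, scen.sigma_f, rng)
        cm = draw_conditions(2 * n, scen.sigma_m, rng)
        w = np.empty(n)
        for i in range(n):
            g = MatingGroup(
                cf1=cf[2 * i], cf2=cf[2 * i + 1], cm1=cm[2 * i], cm2=cm[2 * i + 1]
            )
            fit = group_reproduction(g, params)
            w[i] = fit.wf1 if sex == "F" else fit.wm1
        mean_w = w.mean()
        if mean_w <= 0:
            raise ValueError(f"group ({sex}, {trt}): degenerate zero mean fitness")
        realized[f"{sex}:{trt}"] = float(w.var(ddof=1) / mean_w**2)
        counts = rng.poisson(base_mean * w / mean_w)
        dates = rng.integers(0, 10, size=n)
        for i in range(n):
            records.append(
                AssayRecord(
                    focal_sex=sex,
                    treatment=trt,
                    assay_date=f"d{dates[i] + 1:02d}",
                    offspring_count=int(counts[i]),
                )
            )
    truth = {"realized_I": realized, "base_mean": base_mean, "seed": seed}
    return records, truth


def records_to_frame(records) -> pd.DataFrame:
    """Assay records as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "focal_sex": [r.focal_sex for r in records],
            "treatment": [r.treatment for r in records],
            "assay_date": [r.assay_date for r in records],
            "offspring_count": [r.offspring_count for r in records],
            "total_offspring_weight": [r.total_offspring_weight for r in records],
        }
    )
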