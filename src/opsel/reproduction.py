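"""Fitness assignment within four-individual mating groups.

Reproduction happens in groups of two females and two males, mirroring the
competitive fitness-assay design.  In the baseline model a female produces
eggs in linear proportion to her condition (Eggs = c_f), sperm is never
limiting so her fitness equals her fecundity, and the two males split the
total realized fecundity of both females through a contest success
function: the focal male wins a share

    c_m1**g / (c_m1**g + c_m2**g)

where ``g`` (default 2, intense male-male competition) tunes how strongly
condition decides the contest.  Because male fitness is a partition of
realized female fitness, total male fitness always equals total female
fitness — a conservation law that holds in every variant.

Four optional variants relax the baseline assumptions:

* ``female_competition`` — females likewise contest the pooled fecundity
  with intensity ``g_f`` (``g_f = 1`` reproduces the baseline exactly,
  since linear fecundity already splits the pool in proportion to
  condition).
* ``sperm_limitation`` — the fraction of eggs fertilized saturates with
  mean male condition: ``min(1, mc * cbar_m)``.
* ``male_harm`` — fecundity is reduced multiplicatively by mean male
  condition: ``cf * max(0, 1 - harm * cbar_m)``.
* ``nuptial_gift`` — fecundity is raised multiplicatively:
  ``cf * (1 + gift * cbar_m)``.

The harm/gift/sperm functional forms are the simplest modifiers consistent
with their qualitative descriptions; all coefficients at zero (and the
saturation cap) recover the baseline exactly, which is the tested contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class ReproductionParams:
    """Parameters of the mating-group fitness model.

    g_m : intensity of male-male competition (>= 0); default 2.
    g_f : intensity of female-female competition (used only when
        ``female_competition`` is on).
    mc : male contribution-to-fertility parameter (> 0 when
        ``sperm_limitation`` is on).
    harm, gift : coefficients of the male-harm / nuptial-gift fecundity
        modifiers (>= 0; active only when the matching flag is on).
    """

    g_m: float = 2.0
    g_f: float = 1.0
    mc: float = 1.0
    harm: float = 0.0
    gift: float = 0.0
    female_competition: bool = False
    sperm_limitation: bool = False
    male_harm: bool = False
    nuptial_gift: bool = False

    def __post_init__(self) -> None:
        for name in ("g_m", "g_f", "mc", "harm", "gift"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.g_m < 0 or self.g_f < 0:
            raise ValueError("competition intensities g_m, g_f must be >= 0")
        if self.harm < 0 or self.gift < 0:
            raise ValueError("harm and gift coefficients must be >= 0")
        if self.sperm_limitation and self.mc <= 0:
            raise ValueError("mc must be > 0 when sperm_limitation is on")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReproductionParams":
        return cls(**d)


@dataclass(frozen=True)
class MatingGroup:
    """Conditions of the two females and two males in one mating group."""

    cf1: float
    cf2: float
    cm1: float
    cm2: float

    def __post_init__(self) -> None:
        for name in ("cf1", "cf2", "cm1", "cm2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class GroupFitness:
    """Fitness outcome of one mating group, in fertilized-egg equivalents.

    Invariant: ``wm1 + wm2 == wf1 + wf2`` — males partition realized
    female fitness.
    """

    wf1: float
    wf2: float
    wm1: float
    wm2: float


def contest_share(c_focal: float, c_rival: float, g: float) -> float:
    """Share of a contested resource won by the focal individual.

    ``c_focal**g / (c_focal**g + c_rival**g)``, with the conventions
    ``c**0 == 1`` (so g=0 always yields 0.5) and share = 0.5 when both
    conditions are 0 (the limit along the diagonal).
    """
    if not (np.isfinite(c_focal) and np.isfinite(c_rival) and np.isfinite(g)):
        raise ValueError("contest_share arguments must be finite")
    if c_focal < 0 or c_rival < 0:
        raise ValueError("conditions must be >= 0")
    if g < 0:
        raise ValueError("competition intensity g must be >= 0")
    if g == 0:
        return 0.5
    if c_focal == 0 and c_rival == 0:
        return 0.5
    # Work on the log scale to survive large g (winner-take-all limit)
    # without overflow of c**g.
    if c_focal == 0:
        return 0.0
    if c_rival == 0:
        return 1.0
    # share = 1 / (1 + (c_rival/c_focal)**g)
    ratio_pow = np.exp(g * (np.log(c_rival) - np.log(c_focal)))
    return float(1.0 / (1.0 + ratio_pow))


def _mean_male_condition(cm1: float, cm2: float) -> float:
    return 0.5 * (cm1 + cm2)


def female_fecundity(
    cf: float, male_context: tuple[float, float], params: ReproductionParams
) -> float:
    """Number of fertile eggs a female produces.

    Baseline: exactly ``cf``.  The nuptial-gift and male-harm variants
    modify fecundity multiplicatively through the mean condition of the
    two males in the group.
    """
    if not np.isfinite(cf) or cf < 0:
        raise ValueError(f"female condition must be finite and >= 0, got {cf}")
    cm1, cm2 = male_context
    if cm1 < 0 or cm2 < 0 or not (np.isfinite(cm1) and np.isfinite(cm2)):
        raise ValueError("male conditions must be finite and >= 0")
    eggs = float(cf)
    cbar_m = _mean_male_condition(cm1, cm2)
    if params.nuptial_gift:
        eggs *= 1.0 + params.gift * cbar_m
    if params.male_harm:
        eggs *= max(0.0, 1.0 - params.harm * cbar_m)
    if not np.isfinite(eggs):
        raise ValueError("fecundity is not finite under the given parameters")
    return eggs


def fertilized_fraction(cm1: float, cm2: float, params: ReproductionParams) -> float:
    """Proportion of a female's eggs that get fertilized.

    Baseline assumes sperm is never limiting, so the fraction is exactly
    1.  Under sperm limitation the fraction is ``min(1, mc * cbar_m)``, a
    saturating function of mean male condition.
    """
    if cm1 < 0 or cm2 < 0 or not (np.isfinite(cm1) and np.isfinite(cm2)):
        raise ValueError("male conditions must be finite and >= 0")
    if not params.sperm_limitation:
        return 1.0
    return min(1.0, params.mc * _mean_male_condition(cm1, cm2))


def group_reproduction(group: MatingGroup, params: ReproductionParams) -> GroupFitness:
    """Resolve reproduction in one 2+2 mating group.

    Female fitness is fecundity times the fertilized fraction; with
    female competition on, the two fecundities are pooled and split by a
    contest with intensity ``g_f``.  The two males then split total
    female fitness by a contest with intensity ``g_m``.
    """
    frac = fertilized_fraction(group.cm1, group.cm2, params)
    males = (group.cm1, group.cm2)
    f1 = female_fecundity(group.cf1, males, params)
    f2 = female_fecundity(group.cf2, males, params)
    if params.female_competition:
        pool = f1 + f2
        s1 = contest_share(group.cf1, group.cf2, params.g_f)
        wf1 = pool * s1 * frac
        wf2 = pool * (1.0 - s1) * frac
    else:
        wf1 = f1 * frac
        wf2 = f2 * frac
    total = wf1 + wf2
    sm1 = contest_share(group.cm1, group.cm2, params.g_m)
    wm1 = total * sm1
    wm2 = total * (1.0 - sm1)
    return GroupFitness(wf1=wf1, wf2=wf2, wm1=wm1, wm2=wm2)
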