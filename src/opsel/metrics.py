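"""Crow's opportunity for selection and related fitness-variance statistics.

The opportunity for selection I = sigma_w^2 / wbar^2 is the variance in
relative fitness and bounds the strength of selection on any trait.  After
mean standardization (dividing fitness by its mean so the mean is 1), I is
simply the variance of the standardized values.  The sample variance uses
the unbiased n-1 denominator throughout; at the sample sizes of interest
(n ~ 100) the choice matters at the ~1% level and is documented so tests
can be exact.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when a fitness vector cannot support the requested statistic."""


def _as_fitness(w, min_n: int = 2) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        w = w.ravel()
    if w.size < min_n:
        raise DegenerateInputError(f"need at least {min_n} fitness values, got {w.size}")
    if not np.all(np.isfinite(w)):
        raise DegenerateInputError("fitness values must be finite")
    return w


def mean_standardize(w) -> np.ndarray:
    """Divide a fitness vector by its mean so the result has mean 1.

    Raises :class:`DegenerateInputError` if the mean is not strictly
    positive (e.g. all-zero fitness), since relative fitness is then
    undefined.
    """
    w = _as_fitness(w)
    m = w.mean()
    if m <= 0:
        raise DegenerateInputError(
            f"cannot mean-standardize: mean fitness is {m} (must be > 0)"
        )
    return w / m


def opportunity_for_selection(w) -> float:
    """Crow's index I = var(w) / mean(w)^2 (sample variance, n-1).

    Scale-invariant: I(k*w) == I(w) for any k > 0.
    """
    w = _as_fitness(w)
    m = w.mean()
    if m <= 0:
        raise DegenerateInputError(
            f"cannot compute opportunity for selection: mean fitness is {m}"
        )
    return float(w.var(ddof=1) / m**2)


def log_variance_ratio(w_m, w_f) -> float:
    """Natural log of V_m / V_f on mean-standardized fitness.

    Positive values indicate a male-biased opportunity for selection.
    Invariant to separate rescaling of either sex's fitness vector;
    antisymmetric under swapping the sexes.
    """
    v_m = opportunity_for_selection(w_m)
    v_f = opportunity_for_selection(w_f)
    if v_f == 0:
        raise DegenerateInputError("female variance is zero: log ratio is infinite")
    if v_m == 0:
        raise DegenerateInputError("male variance is zero: log ratio is -infinite")
    return float(np.log(v_m / v_f))


def skewness(w) -> float:
    """Adjusted Fisher-Pearson standardized third moment of a fitness vector.

    The bias-corrected estimator (the default in major statistics
    software); zero for symmetric samples.
    """
    w = _as_fitness(w, min_n=3)
    if w.var(ddof=0) == 0:
        raise DegenerateInputError("zero variance: skewness undefined")
    return float(stats.skew(w, bias=False))
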