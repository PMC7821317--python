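"""Estimation pipeline for competitive fitness-assay tables.

Input is one row per assay: the focal individual's sex (F/M), the
treatment (CT = control, HT = heterogeneous bean quality, AT = delayed
oviposition / ageing), the assay date, the number of adult offspring
(the fitness measure) and optionally the total offspring weight in mg.

The pipeline estimates, per sex-by-treatment group:

* mean fitness with bootstrap CIs and percent change relative to CT;
* the total variance of relative (mean-standardized) fitness, decomposed
  into between-date and within-date components by a one-way
  random-effects method-of-moments (ANOVA) estimator with assay date as
  the grouping factor — this is the opportunity for selection I;
* the log ratio log(V_m/V_f) per treatment with bootstrap CIs, and
  pairwise treatment contrasts of the log ratio with Bonferroni-adjusted
  bootstrap p-values;
* offspring-weight summaries and the skewness of raw fitness per
  treatment (sexes pooled).

Uncertainty is by nonparametric bootstrap over individuals, stratified
by assay date within each sex-by-treatment group, with percentile
intervals (default B = 2000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from opsel.metrics import (
    DegenerateInputError,
    mean_standardize,
    skewness as _skewness,
)

SEXES = ("F", "M")
TREATMENTS = ("CT", "HT", "AT")
REQUIRED_COLUMNS = ("focal_sex", "treatment", "assay_date", "offspring_count")
OPTIONAL_COLUMNS = ("total_offspring_weight",)


class ValidationError(ValueError):
    """Raised when an assay table fails validation; lists offending rows."""


@dataclass(frozen=True)
class AssayRecord:
    """One fitness assay: a focal individual's lifetime offspring count."""

    focal_sex: str
    treatment: str
    assay_date: str
    offspring_count: int
    total_offspring_weight: float | None = None

    def __post_init__(self) -> None:
        if self.focal_sex not in SEXES:
            raise ValidationError(f"focal_sex must be one of {SEXES}, got {self.focal_sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        c = self.offspring_count
        if not isinstance(c, (int, np.integer)) or isinstance(c, bool) or c < 0:
            raise ValidationError(f"offspring_count must be an integer >= 0, got {c!r}")
        w = self.total_offspring_weight
        if w is not None and (not np.isfinite(w) or w < 0):
            raise ValidationError(
                f"total_offspring_weight must be finite and >= 0, got {w!r}"
            )

    @property
    def individual_offspring_weight(self) -> float | None:
        """Mean weight per offspring; undefined when the count is zero."""
        if self.total_offspring_weight is None or self.offspring_count == 0:
            return None
        return self.total_offspring_weight / self.offspring_count


@dataclass
class VarianceDecomposition:
    """Variance of relative fitness split into date components.

    ``total = between_date + within_date`` (method of moments, the
    between component floored at 0).
    """

    sex: str
    treatment: str
    total: float
    between_date: float
    within_date: float
    n: int


@dataclass
class OpportunityEstimate:
    """Opportunity for selection for one sex-by-treatment group."""

    sex: str
    treatment: str
    I: float
    variance_rel: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


def _to_frame(records) -> pd.DataFrame:
    """Normalize a list of AssayRecord or a DataFrame to a validated frame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        df = pd.DataFrame(
            {
                "focal_sex": [r.focal_sex for r in records],
                "treatment": [r.treatment for r in records],
                "assay_date": [r.assay_date for r in records],
                "offspring_count": [r.offspring_count for r in records],
                "total_offspring_weight": [r.total_offspring_weight for r in records],
            }
        )
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    if "total_offspring_weight" not in df.columns:
        df["total_offspring_weight"] = np.nan
    return df


def load_assays(path, sep: str | None = None) -> list[AssayRecord]:
    """Read and validate a CSV/TSV fitness-assay table.

    The delimiter is sniffed from the extension unless ``sep`` is given.
    Malformed rows are reported together with their (1-based, header
    excluded) line numbers.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns: {sorted(missing)}")
    records: list[AssayRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            raw_count = row["offspring_count"]
            count = float(raw_count)
            if not count.is_integer():
                raise ValidationError(f"offspring_count {raw_count!r} is not an integer")
            w = row.get("total_offspring_weight")
            weight = None if w is None or (isinstance(w, float) and np.isnan(w)) or w == "" else float(w)
            records.append(
                AssayRecord(
                    focal_sex=str(row["focal_sex"]).strip(),
                    treatment=str(row["treatment"]).strip(),
                    assay_date=str(row["assay_date"]).strip(),
                    offspring_count=int(count),
                    total_offspring_weight=weight,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    return records


def _bootstrap_ci(
    values: np.ndarray,
    stat,
    rng: np.random.Generator,
    n_boot: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    n = values.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = stat(values[rng.integers(0, n, size=n)])
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def group_mean_fitness(
    records, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Mean offspring count per sex x treatment with bootstrap 95% CIs.

    Also reports, per treatment (sexes pooled), the percent change in
    mean fitness relative to the CT reference:
    ``100 * (1 - mean_T / mean_CT)``.
    """
    df = _to_frame(records)
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, trt), sub in df.groupby(["focal_sex", "treatment"], sort=False):
        counts = sub["offspring_count"].to_numpy(dtype=float)
        if counts.size < 2:
            raise ValidationError(f"group ({sex}, {trt}) has fewer than 2 records")
        lo, hi = _bootstrap_ci(counts, np.mean, rng, n_boot)
        rows.append(
            {
                "focal_sex": sex,
                "treatment": trt,
                "n": counts.size,
                "mean_fitness": counts.mean(),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    out = pd.DataFrame(rows)
    pooled = df.groupby("treatment")["offspring_count"].mean()
    if "CT" not in pooled.index:
        raise ValidationError("missing CT reference treatment for percent change")
    out["percent_change_vs_CT"] = [
        100.0 * (1.0 - pooled[t] / pooled["CT"]) for t in out["treatment"]
    ]
    return out


def _anova_components(w: np.ndarray, idx: np.ndarray) -> tuple[float, float, bool]:
    """Method-of-moments one-way random-effects split of var(w) by ``idx``.

    Returns (between, within, separable).  ``within = MS_within`` (pooled
    within-level variance); ``between = max(0, (MS_between - MS_within) /
    n0)`` with the standard unbalanced-design coefficient
    ``n0 = (N - sum n_i^2 / N) / (a - 1)``.  When fewer than two levels
    have >= 2 observations the components are not separable and the
    sample variance is returned as within-only.
    """
    n = w.size
    sizes = np.bincount(idx)
    sizes = sizes[sizes > 0]
    a = sizes.size
    if a < 2 or np.sum(sizes >= 2) < 2:
        return 0.0, float(w.var(ddof=1)), False
    sums = np.bincount(idx, weights=w)
    counts_per = np.bincount(idx).astype(float)
    nz = counts_per > 0
    level_means = np.zeros_like(sums)
    level_means[nz] = sums[nz] / counts_per[nz]
    grand = w.mean()
    ss_between = float(np.sum(counts_per[nz] * (level_means[nz] - grand) ** 2))
    ss_within = float(np.sum((w - level_means[idx]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n - a)
    n0 = (n - np.sum(counts_per[nz] ** 2) / n) / (a - 1)
    between = max(0.0, (ms_between - ms_within) / n0)
    return between, ms_within, True


def decompose_variance(records, sex: str, treatment: str) -> VarianceDecomposition:
    """One-way random-effects variance decomposition for one group.

    Fitness is mean-standardized within the group, then split into
    between-date and within-date components with the ANOVA
    (method-of-moments) estimator for unbalanced designs.  With a single
    usable date the between component is 0 and total is the sample
    variance.
    """
    df = _to_frame(records)
    sub = df[(df["focal_sex"] == sex) & (df["treatment"] == treatment)]
    if len(sub) < 2:
        raise ValidationError(f"group ({sex}, {treatment}) has fewer than 2 records")
    w = mean_standardize(sub["offspring_count"].to_numpy(dtype=float))
    _, idx = np.unique(sub["assay_date"].to_numpy(), return_inverse=True)
    between, within, separable = _anova_components(w, idx)
    if not separable:
        warnings.warn(
            f"group ({sex}, {treatment}): fewer than 2 dates with >= 2 records; "
            "reporting within-date variance only (between-date component = 0)",
            stacklevel=2,
        )
    return VarianceDecomposition(
        sex=sex,
        treatment=treatment,
        total=between + within,
        between_date=between,
        within_date=within,
        n=w.size,
    )


def _total_variance_rel(counts: np.ndarray, idx: np.ndarray) -> float:
    """Total (between + within date) variance of relative fitness."""
    m = counts.mean()
    if m <= 0:
        raise DegenerateInputError("mean fitness is not positive")
    w = counts / m
    between, within, _ = _anova_components(w, idx)
    return between + within


def _group_total_variance(counts: np.ndarray, dates: np.ndarray) -> float:
    _, idx = np.unique(dates, return_inverse=True)
    return _total_variance_rel(np.asarray(counts, dtype=float), idx)


def _stratified_resample(
    idx_by_date: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    parts = [d[rng.integers(0, d.size, size=d.size)] for d in idx_by_date]
    return np.concatenate(parts)


def estimate_opportunity(
    records, n_boot: int = 2000, seed: int = 0
) -> list[OpportunityEstimate]:
    """Opportunity for selection per sex x treatment with bootstrap CIs.

    I is the total variance of relative fitness from
    :func:`decompose_variance`; the CI is a percentile interval from a
    nonparametric bootstrap over individuals, stratified by assay date.
    """
    df = _to_frame(records)
    rng = np.random.default_rng(seed)
    out: list[OpportunityEstimate] = []
    for (sex, trt), sub in df.groupby(["focal_sex", "treatment"], sort=False):
        counts = sub["offspring_count"].to_numpy(dtype=float)
        dates = sub["assay_date"].to_numpy()
        if np.all(counts == counts[0]):
            out.append(
                OpportunityEstimate(
                    sex=sex, treatment=trt, I=0.0, variance_rel=0.0, n=counts.size,
                    ci_low=0.0, ci_high=0.0,
                )
            )
            continue
        _, idx = np.unique(dates, return_inverse=True)
        point = _total_variance_rel(counts, idx)
        idx_by_date = [np.flatnonzero(dates == d) for d in np.unique(dates)]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = _stratified_resample(idx_by_date, rng)
            try:
                boots[b] = _total_variance_rel(counts[take], idx[take])
            except DegenerateInputError:
                boots[b] = 0.0
        lo, hi = np.quantile(boots, [0.025, 0.975])
        out.append(
            OpportunityEstimate(
                sex=sex,
                treatment=trt,
                I=point,
                variance_rel=point,
                n=counts.size,
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return out


def compare_sex_bias(
    records, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Per-treatment log(V_m/V_f) with bootstrap CIs and treatment contrasts.

    V is the total variance of relative fitness (date-stratified, method
    of moments).  The bootstrap resamples individuals within each sex x
    treatment group, stratified by date.  Pairwise treatment contrasts of
    the log ratio get two-sided bootstrap exceedance p-values, multiplied
    by the number of contrasts (Bonferroni) and capped at 1.
    """
    df = _to_frame(records)
    rng = np.random.default_rng(seed)
    treatments = [t for t in TREATMENTS if t in set(df["treatment"])]
    point: dict[str, float] = {}
    boot: dict[str, np.ndarray] = {}
    per_treatment = {}
    for trt in treatments:
        sub_m = df[(df["treatment"] == trt) & (df["focal_sex"] == "M")]
        sub_f = df[(df["treatment"] == trt) & (df["focal_sex"] == "F")]
        if len(sub_m) < 2 or len(sub_f) < 2:
            raise ValidationError(f"treatment {trt} needs both sexes with >= 2 records")
        cm, dm = sub_m["offspring_count"].to_numpy(float), sub_m["assay_date"].to_numpy()
        cf, dfa = sub_f["offspring_count"].to_numpy(float), sub_f["assay_date"].to_numpy()
        _, idx_m = np.unique(dm, return_inverse=True)
        _, idx_f = np.unique(dfa, return_inverse=True)
        v_m = _total_variance_rel(cm, idx_m)
        v_f = _total_variance_rel(cf, idx_f)
        if v_m == 0 or v_f == 0:
            raise DegenerateInputError(
                f"zero variance in treatment {trt}: log ratio undefined"
            )
        point[trt] = float(np.log(v_m / v_f))
        im = [np.flatnonzero(dm == d) for d in np.unique(dm)]
        if_ = [np.flatnonzero(dfa == d) for d in np.unique(dfa)]
        draws = np.empty(n_boot)
        for b in range(n_boot):
            tm = _stratified_resample(im, rng)
            tf = _stratified_resample(if_, rng)
            vm_b = _total_variance_rel(cm[tm], idx_m[tm])
            vf_b = _total_variance_rel(cf[tf], idx_f[tf])
            draws[b] = np.log(vm_b / vf_b) if vm_b > 0 and vf_b > 0 else np.nan
        draws = draws[np.isfinite(draws)]
        boot[trt] = draws
        lo, hi = np.quantile(draws, [0.025, 0.975])
        per_treatment[trt] = {
            "log_ratio": point[trt],
            "ci_low": float(lo),
            "ci_high": float(hi),
        }
    contrasts = {}
    pairs = [(a, b) for i, a in enumerate(treatments) for b in treatments[i + 1 :]]
    n_contrasts = len(pairs)
    for a, b in pairs:
        m = min(boot[a].size, boot[b].size)
        diff = boot[a][:m] - boot[b][:m]
        # two-sided bootstrap exceedance of zero
        p_one = min(np.mean(diff <= 0), np.mean(diff >= 0))
        p = min(1.0, 2.0 * p_one * n_contrasts)
        contrasts[f"{a}-{b}"] = {
            "delta_log_ratio": point[a] - point[b],
            "p_bonferroni": float(p),
        }
    return {"per_treatment": per_treatment, "contrasts": contrasts}


def offspring_weight_summary(
    records, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Per-treatment mean total and individual offspring weight with CIs.

    Individual weight (total weight / count) is undefined for zero-count
    assays, which are excluded from that mean.  Returns an empty frame if
    no weights are present.
    """
    df = _to_frame(records)
    has_w = df["total_offspring_weight"].notna()
    if not has_w.any():
        return pd.DataFrame(
            columns=[
                "treatment", "n", "mean_total_weight", "total_ci_low",
                "total_ci_high", "mean_individual_weight", "indiv_ci_low",
                "indiv_ci_high",
            ]
        )
    rng = np.random.default_rng(seed)
    rows = []
    for trt, sub in df[has_w].groupby("treatment", sort=False):
        tw = sub["total_offspring_weight"].to_numpy(dtype=float)
        t_lo, t_hi = _bootstrap_ci(tw, np.mean, rng, n_boot)
        nz = sub[sub["offspring_count"] > 0]
        iw = (
            nz["total_offspring_weight"].to_numpy(dtype=float)
            / nz["offspring_count"].to_numpy(dtype=float)
        )
        if iw.size:
            i_lo, i_hi = _bootstrap_ci(iw, np.mean, rng, n_boot)
            i_mean = iw.mean()
        else:
            i_lo = i_hi = i_mean = np.nan
        rows.append(
            {
                "treatment": trt,
                "n": tw.size,
                "mean_total_weight": tw.mean(),
                "total_ci_low": t_lo,
                "total_ci_high": t_hi,
                "mean_individual_weight": i_mean,
                "indiv_ci_low": i_lo,
                "indiv_ci_high": i_hi,
            }
        )
    return pd.DataFrame(rows)


def skewness_by_treatment(records) -> dict[str, float]:
    """Skewness of raw offspring counts per treatment, sexes pooled."""
    df = _to_frame(records)
    return {
        trt: _skewness(sub["offspring_count"].to_numpy(dtype=float))
        for trt, sub in df.groupby("treatment", sort=False)
    }


def analyze(records, n_boot: int = 2000, seed: int = 0) -> dict:
    """Full report: means, weights, I per group, sex bias, skewness."""
    means = group_mean_fitness(records, n_boot=n_boot, seed=seed)
    opp = estimate_opportunity(records, n_boot=n_boot, seed=seed + 1)
    bias = compare_sex_bias(records, n_boot=n_boot, seed=seed + 2)
    weights = offspring_weight_summary(records, n_boot=n_boot, seed=seed + 3)
    return {
        "group_mean_fitness": means.to_dict(orient="records"),
        "opportunity": [vars(e) for e in opp],
        "sex_bias": bias,
        "offspring_weight": weights.to_dict(orient="records"),
        "skewness": skewness_by_treatment(records),
    }
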