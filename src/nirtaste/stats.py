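"""Harvest-stage statistics: one-way ANOVA with a linear-trend contrast,
Tukey HSD / LSD pairwise comparisons, Levene's test and two-sample t-tests.

These mirror the classical analysis battery applied to fruit chemistry
across ripening stages: ANOVA (with the polynomial linear term separated
out) to test for a stage effect, post-hoc pairwise mean comparisons, and
Levene + pooled/Welch t-tests to compare destructive reference values with
non-destructive predictions.  Tail probabilities come from scipy's F, t and
studentized-range distributions; all sums of squares are computed from the
textbook definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "AnovaTable",
    "PairwiseComparison",
    "TTestResult",
    "one_way_anova",
    "tukey_lsd",
    "levene",
    "two_sample_t",
    "groups_from_summary",
]


def groups_from_summary(
    means: Sequence[float], ns: Sequence[int], ss_within: float
) -> list[np.ndarray]:
    """Deterministic group vectors with exactly the given means and SS_within.

    Useful for re-running ANOVA/post-hoc machinery on published summary
    tables (group means plus the within-group sum of squares) when the raw
    data are not available.  Each group is an alternating +/- pattern scaled
    so the within-group sums of squares split equally across groups.
    """
    if len(means) != len(ns) or not len(means):
        raise ConfigError("means and ns must have equal, non-zero length")
    if ss_within < 0:
        raise ConfigError("ss_within must be non-negative")
    k = len(means)
    groups = []
    for mean, n in zip(means, ns):
        if n < 2:
            raise ConfigError("each group needs n >= 2")
        pattern = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
        if n % 2 == 1:
            pattern[-1] = 0.0  # keep the pattern mean exactly zero
        scale = np.sqrt((ss_within / k) / float(np.sum(pattern**2)))
        groups.append(mean + scale * pattern)
    return groups


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f: float
    p: float
    ss_contrast: float | None = None
    f_contrast: float | None = None
    p_contrast: float | None = None
    ss_deviation: float | None = None
    f_deviation: float | None = None
    p_deviation: float | None = None


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: int
    group_j: int
    mean_difference: float
    std_error: float
    p_tukey: float
    p_lsd: float


@dataclass(frozen=True)
class TTestResult:
    levene_f: float
    levene_p: float
    t: float
    df: float
    p: float
    mean_difference: float
    se_difference: float
    ci_lower: float
    ci_upper: float
    equal_var: bool


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    out = []
    for g, values in enumerate(groups):
        v = np.asarray(values, dtype=float).ravel()
        if v.size < 2:
            raise ConfigError(f"group {g} has fewer than 2 values")
        out.append(v)
    return out


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaTable:
    """Classical one-way ANOVA decomposition with a linear-term contrast.

    The linear polynomial contrast uses equally spaced coefficients
    (-1, 0, 1); it is defined here for exactly three groups, the design it
    decomposes (deviation = between - contrast, on 1 df each).
    """
    gs = _check_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    all_values = np.concatenate(gs)
    grand = all_values.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in gs))
    ss_total = float(np.sum((all_values - grand) ** 2))
    df_between, df_within = k - 1, all_values.size - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise DegenerateInputError("zero within-group variance; F undefined")
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))

    contrast_fields: dict = {}
    if k == 3:
        c = np.array([-1.0, 0.0, 1.0])
        estimate = float(np.sum(c * means))
        ss_contrast = estimate**2 / float(np.sum(c**2 / ns))
        ss_deviation = ss_between - ss_contrast
        f_c = ss_contrast / ms_within
        f_d = (ss_deviation / (df_between - 1)) / ms_within
        contrast_fields = dict(
            ss_contrast=ss_contrast,
            f_contrast=f_c,
            p_contrast=float(sps.f.sf(f_c, 1, df_within)),
            ss_deviation=ss_deviation,
            f_deviation=f_d,
            p_deviation=float(sps.f.sf(f_d, df_between - 1, df_within)),
        )
    elif k > 3:
        raise NotImplementedError("linear contrast implemented for exactly 3 groups")

    return AnovaTable(
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        df_between=df_between, df_within=df_within, df_total=all_values.size - 1,
        ms_between=ms_between, ms_within=ms_within, f=f, p=p, **contrast_fields,
    )


def tukey_lsd(groups: Sequence[np.ndarray], alpha: float = 0.05) -> list[PairwiseComparison]:
    """All ordered pairwise comparisons with Tukey-HSD and LSD p-values.

    SE of a difference is sqrt(MSw (1/ni + 1/nj)); the Tukey p comes from
    the studentized range distribution q(k, df_within) via the
    Tukey-Kramer statistic, the LSD p from the t distribution on df_within.
    """
    gs = _check_groups(groups)
    table = one_way_anova(gs)
    k = len(gs)
    out = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            ni, nj = gs[i].size, gs[j].size
            diff = float(gs[i].mean() - gs[j].mean())
            se = float(np.sqrt(table.ms_within * (1.0 / ni + 1.0 / nj)))
            q = abs(diff) / np.sqrt(table.ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
            p_tukey = float(np.clip(sps.studentized_range.sf(q, k, table.df_within), 0, 1))
            t = diff / se
            p_lsd = float(2.0 * sps.t.sf(abs(t), table.df_within))
            out.append(
                PairwiseComparison(
                    group_i=i + 1, group_j=j + 1, mean_difference=diff,
                    std_error=se, p_tukey=p_tukey, p_lsd=p_lsd,
                )
            )
    return out


def levene(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Levene's test (mean-centred variant) for equality of two variances."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 values")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    if np.ptp(za) == 0 and np.ptp(zb) == 0:
        if za.mean() == zb.mean():
            return 0.0, 1.0
        raise DegenerateInputError("degenerate absolute deviations; Levene undefined")
    table = one_way_anova([za, zb])
    return table.f, table.p


def two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test with 95% CI, pooled or Welch, plus Levene's preamble."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigError("each sample needs at least 2 values")
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if equal_var:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if pooled == 0:
            raise DegenerateInputError("zero pooled variance; t undefined")
        se = float(np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)))
        df = float(n1 + n2 - 2)
    else:
        if v1 == 0 and v2 == 0:
            raise DegenerateInputError("zero variances; t undefined")
        se = float(np.sqrt(v1 / n1 + v2 / n2))
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    lf, lp = levene(a, b)
    return TTestResult(
        levene_f=lf, levene_p=lp, t=float(t), df=float(df), p=p,
        mean_difference=diff, se_difference=se,
        ci_lower=diff - tcrit * se, ci_upper=diff + tcrit * se,
        equal_var=equal_var,
    )
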