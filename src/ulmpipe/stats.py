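"""Statistical battery over per-animal metric tables, from first principles.

One-way ANOVA is available both on raw group values and on printed summary
statistics (n, mean, SD), which are algebraically equivalent; two-way ANOVA
uses sequential (Type I) sums of squares in the order the terms are listed.
Multiplicity is controlled with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats


@dataclass
class GroupSummary:
    """Printed-style summary of one group: n, mean, sample SD (n-1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class StatResult:
    """One test: statistic name/value, degrees of freedom, raw/adjusted p."""

    name: str
    value: float
    df: tuple
    p_raw: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.name == "F" and self.value < 0:
            raise ValueError("F must be >= 0")


def summarize(values: np.ndarray, label: str = "") -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(label, len(values), float(values.mean()),
                        float(values.std(ddof=1)))


def average_replicates(df: pd.DataFrame, by: str | list[str] = "animal_id",
                       value_cols: list[str] | None = None) -> pd.DataFrame:
    """Unweighted mean over repeated measurements (planes/sections) per animal."""
    by = [by] if isinstance(by, str) else list(by)
    if value_cols is None:
        value_cols = [c for c in df.columns
                      if c not in by and pd.api.types.is_numeric_dtype(df[c])]
    keep = [c for c in df.columns if c not in value_cols and c not in by]
    agg = {c: "mean" for c in value_cols}
    agg.update({c: "first" for c in keep})
    return df.groupby(by, as_index=False).agg(agg)


def anova_oneway(groups: list[np.ndarray]) -> StatResult:
    """Standard between/within one-way ANOVA on raw values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(g) for g in groups])
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return StatResult("F", float(f), (df1, df2), p)


def anova_oneway_summary(summaries: list[GroupSummary]) -> StatResult:
    """One-way ANOVA from (n, mean, sd) triples.

    SS_between = sum n_i (m_i - grand_mean)^2;
    SS_within  = sum (n_i - 1) sd_i^2.  Exactly equivalent to
    :func:`anova_oneway` on the underlying raw data.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in summaries], dtype=float)
    means = np.array([g.mean for g in summaries])
    sds = np.array([g.sd for g in summaries])
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df1 = len(summaries) - 1
    df2 = int(ns.sum()) - len(summaries)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return StatResult("F", float(f), (df1, df2), p)


def _design(levels: pd.Series) -> np.ndarray:
    """Full-rank treatment-coded dummy block for one factor."""
    cats = pd.Categorical(levels)
    dummies = pd.get_dummies(cats, drop_first=True).to_numpy(float)
    return dummies


def anova_twoway(df: pd.DataFrame, response: str, factor_a: str,
                 factor_b: str) -> dict[str, StatResult]:
    """Two-way ANOVA with sequential (Type I) SS, term order (B, A, AxB).

    ``factor_a`` is the primary factor (e.g. genotype) and ``factor_b`` the
    blocking factor (e.g. rostro-caudal position), matching the reporting
    order position / genotype / interaction.  Requires every cell of the
    design to be populated.
    """
    y = df[response].to_numpy(float)
    n = len(y)
    cells = df.groupby([factor_a, factor_b]).size()
    na = df[factor_a].nunique()
    nb = df[factor_b].nunique()
    if len(cells) < na * nb:
        raise ValueError("empty cells in the two-way design")

    xb = _design(df[factor_b])
    xa = _design(df[factor_a])
    xab = np.concatenate([(xa[:, i:i + 1] * xb) for i in range(xa.shape[1])], axis=1) \
        if xa.shape[1] and xb.shape[1] else np.empty((n, 0))
    intercept = np.ones((n, 1))

    def rss(X):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X0 = intercept
    X1 = np.hstack([X0, xb])
    X2 = np.hstack([X1, xa])
    X3 = np.hstack([X2, xab])
    rss0, rss1, rss2, rss3 = rss(X0), rss(X1), rss(X2), rss(X3)
    df_b, df_a, df_ab = nb - 1, na - 1, (na - 1) * (nb - 1)
    df_err = n - na * nb
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss3 / df_err

    def term(name, ss, dft):
        f = (ss / dft) / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        f = max(f, 0.0)
        p = float(scipy.stats.f.sf(f, dft, df_err))
        return StatResult("F", float(f), (dft, df_err), p)

    return {
        factor_b: term(factor_b, rss0 - rss1, df_b),
        factor_a: term(factor_a, rss1 - rss2, df_a),
        "interaction": term("interaction", rss2 - rss3, df_ab),
    }


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p values")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    D = sup |ECDF_a - ECDF_b|; p from the asymptotic Kolmogorov distribution
    with effective n = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / na
    cdf_b = np.searchsorted(b, grid, side="right") / nb
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = na * nb / (na + nb)
    p = float(np.clip(scipy.special.kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    return StatResult("D", d, (na, nb), p)


def pearson(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance input")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = float(2.0 * scipy.stats.t.sf(abs(t), n - 2))
    return StatResult("r", r, (n - 2,), p)
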