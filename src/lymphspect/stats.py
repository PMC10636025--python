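"""Nonparametric statistical battery for staging/quantification cohorts.

Covers the tests a lymphedema imaging cohort analysis leans on: paired
marginal homogeneity (McNemar, and its Bowker generalization for K>2
stages), Kruskal-Wallis with Dunn-Bonferroni post-hoc pairs,
Mann-Whitney, Spearman rank correlation, the linear-by-linear
(Mantel-Haenszel) trend test for ordered contingency tables, weighted
Cohen's kappa with the conventional agreement bands, and
Shapiro-Wilk-gated numeric summaries (mean+-SD vs median(IQR)).

Standard tests delegate to scipy/statsmodels; the Bowker zero-pair
convention, Dunn post-hoc, trend test and weighted kappa are implemented
here (mid-ranks for ties throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .core import ContingencyTable

__all__ = [
    "TestResult",
    "KappaResult",
    "NumericSummary",
    "mcnemar",
    "kruskal_wallis",
    "dunn_bonferroni",
    "mann_whitney",
    "spearman",
    "linear_by_linear",
    "weighted_kappa",
    "kappa_band",
    "bonferroni_adjust",
    "summarize_numeric",
    "KAPPA_BANDS",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, optional df and post-hoc table."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return np.asarray(table.counts, float)
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"expected a square count table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def mcnemar(table, exact: bool | None = None, correction: bool = True) -> TestResult:
    """Marginal homogeneity of a paired square table.

    2x2 tables use the classic McNemar test (exact binomial when the
    discordant count b+c < 25 unless overridden); K>2 tables use the
    McNemar-Bowker symmetry generalization, with symmetric pairs whose
    combined count is zero skipped and the degrees of freedom reduced
    accordingly.
    """
    t = _as_counts(table)
    k = t.shape[0]
    if k == 2:
        b, c = t[0, 1], t[1, 0]
        if exact is None:
            exact = (b + c) < 25
        res = _sm_mcnemar(t, exact=exact, correction=correction)
        method = "McNemar (exact binomial)" if exact else "McNemar (chi-squared)"
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method=method, df=None if exact else 1.0)
    stat = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            denom = t[i, j] + t[j, i]
            if denom > 0:
                stat += (t[i, j] - t[j, i]) ** 2 / denom
                df += 1
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=float(stat), p_value=p,
                      method="McNemar-Bowker symmetry", df=float(df))


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return arrs


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H over >= 2 nonempty groups.

    Identical constant groups (all ties) return H = 0, p = 1.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0,
                          method="Kruskal-Wallis", df=float(len(arrs) - 1))
    h, p = sps.kruskal(*arrs)
    return TestResult(statistic=float(h), p_value=float(p),
                      method="Kruskal-Wallis", df=float(len(arrs) - 1))


def dunn_bonferroni(groups, labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled mid-ranks, Bonferroni-adjusted
    over all k(k-1)/2 pairs.  Returns one row per pair with the z value,
    raw and adjusted two-sided p (adjusted p = min(1, m * raw p))."""
    arrs = _check_groups(groups)
    k = len(arrs)
    labels = labels if labels is not None else [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match the number of groups")
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    mean_ranks, sizes = [], []
    start = 0
    for g in arrs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            rows.append({
                "group_a": labels[i], "group_b": labels[j], "z": float(z),
                "p_raw": p_raw, "p_bonferroni": bonferroni_adjust(p_raw, m),
            })
    return pd.DataFrame(rows)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p); never below the raw p."""
    return float(min(1.0, m * p))


def mann_whitney(a, b, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U with mid-rank tie handling."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="Mann-Whitney U")


def spearman(x, y) -> TestResult:
    """Two-sided Spearman rank correlation (statistic is rho)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p),
                      method="Spearman rank correlation")


def linear_by_linear(table, row_scores=None, col_scores=None) -> TestResult:
    """Mantel-Haenszel linear-by-linear association trend test.

    M^2 = (N - 1) * r^2 where r is the Pearson correlation of the row and
    column scores weighted by the cell counts (default integer scores);
    p from chi-squared with 1 df.
    """
    t = np.asarray(table.counts if isinstance(table, ContingencyTable) else table, float)
    if t.ndim != 2:
        raise ValueError(f"expected a 2-D count table, got ndim={t.ndim}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n_rows, n_cols = t.shape
    u = np.asarray(row_scores if row_scores is not None else np.arange(n_rows), float)
    v = np.asarray(col_scores if col_scores is not None else np.arange(n_cols), float)
    if u.size != n_rows or v.size != n_cols:
        raise ValueError("score vectors must match the table dimensions")
    n = t.sum()
    if n < 2:
        raise ValueError(f"need a grand total >= 2, got {n:g}")
    pu = t.sum(axis=1) / n
    pv = t.sum(axis=0) / n
    mu_u, mu_v = pu @ u, pv @ v
    cov = float(np.einsum("ij,i,j->", t / n, u - mu_u, v - mu_v))
    var_u = float(pu @ (u - mu_u) ** 2)
    var_v = float(pv @ (v - mu_v) ** 2)
    r = cov / np.sqrt(var_u * var_v) if var_u > 0 and var_v > 0 else 0.0
    m2 = (n - 1.0) * r * r
    return TestResult(statistic=float(m2), p_value=float(sps.chi2.sf(m2, 1)),
                      method="linear-by-linear association", df=1.0)


# ---------------------------------------------------------------------------
# weighted kappa and agreement bands
# ---------------------------------------------------------------------------

#: (upper edge inclusive, label); kappa above 0.80 is almost perfect
KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Agreement label for a kappa value; band edges sit at the printed
    two-decimal cuts (0.20 -> poor, 0.21 -> fair, ...); negative values
    are poor."""
    for edge, label in KAPPA_BANDS:
        if kappa <= edge + 1e-12:
            return label
    return "almost perfect"


@dataclass
class KappaResult:
    """Weighted kappa with its weighting scheme and agreement band."""

    kappa: float
    scheme: str
    band: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.kappa <= 1.0 + 1e-9:
            raise ValueError(f"kappa {self.kappa} outside [-1, 1]")


def weighted_kappa(ratings_a, ratings_b, scheme: str = "linear",
                   categories: list | None = None) -> KappaResult:
    """Weighted Cohen's kappa between two equal-length ordinal rating
    vectors: kappa = 1 - sum(w * O) / sum(w * E) with linear (default) or
    quadratic disagreement weights over the shared ordered category set."""
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError(f"rating vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("rating vectors are empty")
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"scheme must be 'linear' or 'quadratic', got {scheme!r}")
    if categories is None:
        if not set(a) & set(b):
            raise ValueError("raters share no categories; pass an explicit category set")
        categories = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(categories)}
    try:
        ia = np.array([idx[x] for x in a])
        ib = np.array([idx[x] for x in b])
    except KeyError as exc:
        raise ValueError(f"rating {exc.args[0]!r} not in the category set") from exc
    k = len(categories)
    observed = np.zeros((k, k))
    np.add.at(observed, (ia, ib), 1.0)
    observed /= observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    d = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :]).astype(float)
    if k > 1:
        d /= k - 1
    w = d if scheme == "linear" else d ** 2
    denom = float((w * expected).sum())
    kappa = 1.0 if denom == 0 else 1.0 - float((w * observed).sum()) / denom
    return KappaResult(kappa=float(kappa), scheme=scheme, band=kappa_band(kappa))


# ---------------------------------------------------------------------------
# normality-gated numeric summaries
# ---------------------------------------------------------------------------

@dataclass
class NumericSummary:
    """Both summary forms are always retained; the Shapiro-Wilk gate at
    alpha = 0.05 only selects which one to display."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    shapiro_p: float | None
    display: str  # "mean_sd" or "median_iqr"
    flags: tuple[str, ...] = ()

    def render(self) -> str:
        if self.display == "mean_sd":
            return f"{self.mean:.2f} +/- {self.sd:.2f}"
        return f"{self.median:.2f} ({self.q1:.2f}, {self.q3:.2f})"


def summarize_numeric(values, alpha: float = 0.05) -> NumericSummary:
    """Mean+-SD when Shapiro-Wilk accepts normality at ``alpha``, else
    median (IQR).  Samples with n < 3 skip the gate (flagged); constant
    vectors are degenerate (flagged, median form)."""
    v = np.asarray(values, float).ravel()
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        raise ValueError("no values to summarize")
    mean, sd = float(v.mean()), float(v.std(ddof=1)) if n > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    flags: list[str] = []
    if n < 3:
        return NumericSummary(n=n, mean=mean, sd=sd, median=med, q1=q1, q3=q3,
                              shapiro_p=None, display="median_iqr",
                              flags=("too_few_for_normality_gate",))
    if np.all(v == v[0]):
        return NumericSummary(n=n, mean=mean, sd=0.0, median=med, q1=q1, q3=q3,
                              shapiro_p=None, display="median_iqr",
                              flags=("degenerate_constant",))
    _, p = sps.shapiro(v)
    display = "mean_sd" if p >= alpha else "median_iqr"
    return NumericSummary(n=n, mean=mean, sd=sd, median=med, q1=q1, q3=q3,
                          shapiro_p=float(p), display=display, flags=tuple(flags))
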