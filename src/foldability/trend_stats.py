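"""Trend statistics for trait-versus-age timelines.

The analyses here answer one question in several ways: did a trait (SMCO,
tightness, chain length) drift up or down over evolutionary time?

* :func:`loess_fit` — Cleveland's locally weighted polynomial regression
  (tricube weights, default degree 2, span 0.7) with a pointwise 95% band
  and the endpoint difference ``delta = fitted(youngest) - fitted(oldest)``.
* :func:`trend_significance` — an approximate F-test of the smoother against
  the intercept-only model, using trace-based effective degrees of freedom.
* :func:`segmented_linear` — two independent OLS lines on either side of a
  fixed breakpoint (no continuity constraint).
* :func:`binned_length_analysis` — the trend test repeated inside exact
  chain-length bins, with each bin categorised positive / negative /
  insignificant by the sign of delta and the F-test.
* :func:`class_analysis` — the binned analysis per SCOP fold class plus
  pairwise Wilcoxon rank-sum comparisons of class SMCO distributions.
* :func:`resample_sem` — bootstrap standard errors for any reported
  percentage.
* :func:`screen_fast_folders` — families whose mean SMCO falls at or below
  a threshold (candidate ultra-fast, "downhill" folders).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import DomainCatalog

__all__ = [
    "TrendConfig",
    "TrendFit",
    "SegmentFit",
    "SegmentedFit",
    "BinSummary",
    "ClassSummary",
    "FastFolderScreen",
    "DOWNHILL_FOLDER_FAMILIES",
    "FOLD_CLASSES",
    "loess_fit",
    "trend_significance",
    "segmented_linear",
    "binned_length_analysis",
    "class_analysis",
    "resample_sem",
    "screen_fast_folders",
]

#: SCOP families containing experimentally identified downhill folders.
DOWNHILL_FOLDER_FAMILIES = ("a.35.1.2", "a.4.1.1", "a.8.1.2", "b.72.1.1", "d.100.1.1")

#: The four analysed SCOP fold classes.
FOLD_CLASSES = ("a", "b", "c", "d")

# exact (two-delta) degrees of freedom require O(n^2) memory / O(n^3) time;
# above this size the one-delta approximation is used instead
_EXACT_DF_MAX_N = 3200


@dataclass(frozen=True)
class TrendConfig:
    """Knobs of the trend analyses.

    span / degree
        LOESS neighbourhood fraction and local polynomial degree.
    alpha_sig
        Significance level for categorising endpoint differences.
    breakpoint
        Epoch boundary in Gya separating early from late evolution.
    n_resample / seed
        Bootstrap repetitions and RNG seed for SEM estimation.
    min_bin_n
        Sparse exact-length bins are pooled with neighbours until they hold
        at least this many domains.
    bin_method
        Per-bin trend model: ``loess`` (default) or ``poly`` (one global
        quadratic per bin).
    bh_correct
        Apply Benjamini-Hochberg across length bins (off by default: shares
        are reported from raw per-bin significance).
    """

    span: float = 0.7
    degree: int = 2
    alpha_sig: float = 0.05
    breakpoint: float = 1.5
    n_resample: int = 100
    seed: int = 0
    min_bin_n: int = 10
    bin_method: str = "loess"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if not 0 < self.alpha_sig < 1:
            raise ValueError("alpha_sig must lie in (0, 1)")
        if self.bin_method not in ("loess", "poly"):
            raise ValueError(f"unknown bin_method {self.bin_method!r}")

    def fingerprint(self) -> str:
        return (
            f"span={self.span:g};degree={self.degree};alpha={self.alpha_sig:g};"
            f"break={self.breakpoint:g};resample={self.n_resample};seed={self.seed};"
            f"min_bin_n={self.min_bin_n};bin_method={self.bin_method}"
        )


@dataclass
class TrendFit:
    """A fitted smooth trend with endpoint difference and significance."""

    x: np.ndarray
    fitted: np.ndarray
    ci95: np.ndarray  # (n, 2) lower/upper
    delta: float  # fitted(min x) - fitted(max x): youngest minus oldest age
    p_value: float
    edf: float  # effective degrees of freedom (trace of the smoother)


# ---------------------------------------------------------------------------
# LOESS core


def _loess_smoother(x: np.ndarray, span: float, degree: int):
    """Hat-matrix rows of the loess smoother evaluated at each x.

    Returns (fitted_rows L, nu1, nu2, row_norms2).  Neighbourhoods hold
    ``q = floor(span * n)`` points (the convention of Cleveland's original
    implementation); tricube weights are taken on distances scaled by the
    q-th nearest distance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    q = int(np.floor(span * n + 1e-9))
    if q < degree + 2:
        raise ValueError(
            f"span {span} too small for degree {degree} at n={n} "
            f"(needs floor(span*n) >= {degree + 2})"
        )
    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dq = d[idx[-1]]
        if dq == 0:  # >= q replicates of x[i]: uniform weights over them
            w = np.ones(q)
        else:
            u = d[idx] / dq
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        WX = w[:, None] * X
        A = X.T @ WX
        e1 = np.zeros(degree + 1)
        e1[0] = 1.0
        try:
            beta_row = np.linalg.solve(A, e1)
        except np.linalg.LinAlgError:
            beta_row = np.linalg.pinv(A)[0]
        L[i, idx] = beta_row @ WX.T
    nu1 = float(np.trace(L))
    row_norms2 = np.einsum("ij,ij->i", L, L)
    nu2 = float(row_norms2.sum())
    return L, nu1, nu2, row_norms2


def _loess_pvalue(y: np.ndarray, L: np.ndarray, nu1: float, nu2: float) -> tuple[float, float, float]:
    """F-test of the loess fit against the intercept-only model.

    Trace-based effective degrees of freedom; for moderate n the exact
    two-delta form of Cleveland & Devlin is used, above ``_EXACT_DF_MAX_N``
    the one-delta approximation.  Returns (p, sigma2, t_df).
    """
    n = y.size
    fitted = L @ y
    rss1 = float(np.sum((y - fitted) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    delta1 = n - 2.0 * nu1 + nu2  # tr[(I-L)'(I-L)]
    if rss0 <= 0:
        return 1.0, 0.0, max(delta1, 1.0)
    if delta1 <= 0:
        return 1.0, rss1 / max(n - nu1, 1.0), 1.0
    if rss1 <= 1e-12 * rss0:  # (near-)perfect fit, e.g. heavily tied data
        return 0.0, 0.0, max(delta1, 1.0)
    if n <= _EXACT_DF_MAX_N:
        A1 = np.eye(n) - L
        A1 = A1.T @ A1
        A0 = np.eye(n) - 1.0 / n  # (I - J/n), symmetric idempotent
        diff = A0 - A1
        lam1 = float(np.trace(diff))
        lam2 = float(np.sum(diff * diff.T))
        delta2 = float(np.sum(A1 * A1.T))
        df_num = lam1**2 / lam2 if lam2 > 0 else max(nu1 - 1.0, 1.0)
        df_den = delta1**2 / delta2 if delta2 > 0 else delta1
        f_stat = ((rss0 - rss1) / lam1) / (rss1 / delta1) if lam1 > 0 else 0.0
    else:
        lam1 = nu1 - 1.0
        df_num = max(lam1, 1.0)
        df_den = delta1
        f_stat = ((rss0 - rss1) / df_num) / (rss1 / delta1)
    p = float(stats.f.sf(max(f_stat, 0.0), df_num, df_den))
    return p, rss1 / delta1, df_den


def loess_fit(x, y, cfg: TrendConfig | None = None) -> TrendFit:
    """Locally weighted polynomial regression evaluated at each data point.

    ``delta`` is the fitted value at the smallest x minus the fitted value
    at the largest x — with x in Gya this is trait(youngest) minus
    trait(oldest), the endpoint change over the window.
    """
    cfg = cfg or TrendConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < max(10, 5 * cfg.degree):
        raise ValueError(f"need at least {max(10, 5 * cfg.degree)} points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical")
    L, nu1, nu2, row_norms2 = _loess_smoother(x, cfg.span, cfg.degree)
    fitted = L @ y
    p_value, sigma2, t_df = _loess_pvalue(y, L, nu1, nu2)
    se = np.sqrt(np.maximum(sigma2, 0.0) * row_norms2)
    tq = stats.t.ppf(0.975, max(t_df, 1.0))
    ci95 = np.column_stack([fitted - tq * se, fitted + tq * se])
    delta = float(fitted[np.argmin(x)] - fitted[np.argmax(x)])
    return TrendFit(x=x, fitted=fitted, ci95=ci95, delta=delta, p_value=p_value, edf=nu1)


def trend_significance(x, y, cfg: TrendConfig | None = None, method: str = "loess") -> float:
    """P-value of the fitted trend against the flat (intercept-only) model.

    ``method='loess'`` uses the trace-based F-test of the loess smoother;
    ``method='linear'`` is the classical OLS slope F-test (identical to the
    squared slope t-test).  Constant y returns p = 1.
    """
    cfg = cfg or TrendConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return 1.0
    if method == "linear":
        res = stats.linregress(x, y)
        return float(res.pvalue)
    if method != "loess":
        raise ValueError(f"unknown method {method!r}")
    L, nu1, nu2, _ = _loess_smoother(x, cfg.span, cfg.degree)
    p, _, _ = _loess_pvalue(y, L, nu1, nu2)
    return p


# ---------------------------------------------------------------------------
# Segmented regression


@dataclass(frozen=True)
class SegmentFit:
    slope: float
    intercept: float
    p_slope: float
    stderr: float
    n: int


@dataclass(frozen=True)
class SegmentedFit:
    """Two independent OLS lines split at a fixed breakpoint (on x)."""

    breakpoint: float
    above: SegmentFit | None  # x >= breakpoint
    below: SegmentFit | None  # x < breakpoint


def _ols_segment(x: np.ndarray, y: np.ndarray) -> SegmentFit | None:
    if x.size < 3 or np.ptp(x) == 0:
        return None
    res = stats.linregress(x, y)
    return SegmentFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )


def segmented_linear(x, y, breakpoint: float) -> SegmentedFit:
    """Fit independent OLS lines on ``{x >= breakpoint}`` and ``{x < breakpoint}``.

    No continuity is imposed at the breakpoint; a side with fewer than 3
    points (or no x spread) is reported absent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hi = x >= breakpoint
    return SegmentedFit(
        breakpoint=float(breakpoint),
        above=_ols_segment(x[hi], y[hi]),
        below=_ols_segment(x[~hi], y[~hi]),
    )


# ---------------------------------------------------------------------------
# Binned length analysis


@dataclass
class BinSummary:
    """Per-length-bin endpoint changes and the aggregate category shares.

    ``table`` columns: bin (label), lengths (tuple), n, delta, p_value,
    category.  ``percentages`` maps positive/negative/insignificant to the
    domain-abundance-weighted share (summing to 100).
    """

    epoch: tuple[float, float]
    table: pd.DataFrame
    percentages: dict[str, float]
    n_domains: int
    sem: dict[str, float] = field(default_factory=dict)


def _pool_lengths(counts: pd.Series, min_n: int) -> list[list[int]]:
    """Merge adjacent exact lengths (ascending) until each pool holds >= min_n.

    A trailing short pool is merged backwards into its neighbour.
    """
    pools: list[list[int]] = []
    current: list[int] = []
    total = 0
    for length, n in counts.sort_index().items():
        current.append(int(length))
        total += int(n)
        if total >= min_n:
            pools.append(current)
            current, total = [], 0
    if current:
        if pools:
            pools[-1].extend(current)
        else:
            pools.append(current)
    return pools


def _bin_trend(ages: np.ndarray, values: np.ndarray, cfg: TrendConfig) -> tuple[float, float]:
    """Endpoint delta and p-value of the trait trend within one bin."""
    if np.ptp(ages) == 0 or np.ptp(values) == 0:
        return 0.0, 1.0
    if cfg.bin_method == "poly":
        deg = cfg.degree
        coefs = np.polyfit(ages, values, deg)
        fitted = np.polyval(coefs, ages)
        delta = float(np.polyval(coefs, ages.min()) - np.polyval(coefs, ages.max()))
        rss1 = float(np.sum((values - fitted) ** 2))
        rss0 = float(np.sum((values - values.mean()) ** 2))
        df_num, df_den = deg, ages.size - deg - 1
        if df_den <= 0 or rss1 == 0:
            return delta, 0.0 if rss0 > rss1 else 1.0
        f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        return delta, float(stats.f.sf(max(f_stat, 0.0), df_num, df_den))
    fit = loess_fit(ages, values, cfg)
    return fit.delta, fit.p_value


_CATEGORIES = ("positive", "negative", "insignificant")


def binned_length_analysis(
    catalog: DomainCatalog | pd.DataFrame,
    epoch: tuple[float, float],
    cfg: TrendConfig | None = None,
    trait: str = "smco",
) -> BinSummary:
    """Endpoint trait change per exact chain length within an age epoch.

    Domains with age in ``[epoch[0], epoch[1]]`` are grouped by exact chain
    length; sparse lengths are pooled with ascending neighbours until each
    bin holds at least ``cfg.min_bin_n`` domains.  Each bin's trait-vs-age
    trend yields an endpoint difference (youngest minus oldest) and an
    F-test p-value; bins are categorised positive / negative when the trend
    is significant at ``cfg.alpha_sig``, else insignificant.  The aggregate
    category shares are weighted by domain abundance.
    """
    cfg = cfg or TrendConfig()
    df = catalog.domains if isinstance(catalog, DomainCatalog) else catalog
    lo, hi = min(epoch), max(epoch)
    sub = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if sub.empty:
        raise ValueError(f"no domains with age in [{lo}, {hi}]")
    pools = _pool_lengths(sub["length"].value_counts(), cfg.min_bin_n)

    min_fit_n = max(10, 5 * cfg.degree)
    rows = []
    for lengths in pools:
        grp = sub[sub["length"].isin(lengths)]
        label = (
            str(lengths[0]) if len(lengths) == 1 else f"{lengths[0]}-{lengths[-1]}"
        )
        ages = grp["age"].to_numpy(dtype=float)
        vals = grp[trait].to_numpy(dtype=float)
        if ages.size < min_fit_n:
            delta, p = 0.0, 1.0
        else:
            delta, p = _bin_trend(ages, vals, cfg)
        rows.append(
            {"bin": label, "lengths": tuple(lengths), "n": int(ages.size),
             "delta": delta, "p_value": p}
        )
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy()
    if cfg.bh_correct:
        pvals = stats.false_discovery_control(pvals, method="bh")
        table["p_adjusted"] = pvals
    category = np.where(
        pvals >= cfg.alpha_sig,
        "insignificant",
        np.where(table["delta"] > 0, "positive", "negative"),
    )
    # a significant bin with exactly zero delta carries no direction
    category[(pvals < cfg.alpha_sig) & (table["delta"] == 0)] = "insignificant"
    table["category"] = category

    n_total = int(table["n"].sum())
    percentages = {
        cat: float(100.0 * table.loc[table["category"] == cat, "n"].sum() / n_total)
        for cat in _CATEGORIES
    }
    return BinSummary(epoch=(lo, hi), table=table, percentages=percentages, n_domains=n_total)


# ---------------------------------------------------------------------------
# Fold-class analysis


@dataclass
class ClassSummary:
    """Binned analysis per SCOP fold class and pairwise class comparisons."""

    per_class: dict[str, dict[str, BinSummary]]
    pairwise_p: dict[tuple[str, str], float]
    excluded: dict[str, int]


def class_analysis(
    catalog: DomainCatalog | pd.DataFrame,
    cfg: TrendConfig | None = None,
    origin_age: float = 3.8,
    min_class_n: int = 30,
) -> ClassSummary:
    """Run the binned length analysis per fold class and epoch.

    Epochs are ``early`` (breakpoint..origin_age) and ``late``
    (0..breakpoint).  Classes outside the four analysed ones, or with fewer
    than ``min_class_n`` domains, are excluded and counted.  Pairwise
    two-sided Wilcoxon rank-sum tests compare the domain SMCO distributions
    of the included classes.
    """
    cfg = cfg or TrendConfig()
    df = catalog.domains if isinstance(catalog, DomainCatalog) else catalog
    epochs = {"early": (cfg.breakpoint, origin_age), "late": (0.0, cfg.breakpoint)}
    per_class: dict[str, dict[str, BinSummary]] = {}
    excluded: dict[str, int] = {}
    for letter, grp in df.groupby("class_letter"):
        if letter not in FOLD_CLASSES or len(grp) < min_class_n:
            excluded[str(letter)] = int(len(grp))
            continue
        per_class[str(letter)] = {}
        for name, epoch in epochs.items():
            try:
                per_class[str(letter)][name] = binned_length_analysis(grp, epoch, cfg)
            except ValueError:
                continue  # class empty in this epoch
    included = sorted(per_class)
    pairwise_p: dict[tuple[str, str], float] = {}
    for i, c1 in enumerate(included):
        for c2 in included[i + 1 :]:
            x1 = df.loc[df["class_letter"] == c1, "smco"].to_numpy()
            x2 = df.loc[df["class_letter"] == c2, "smco"].to_numpy()
            res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
            pairwise_p[(c1, c2)] = float(res.pvalue)
    return ClassSummary(per_class=per_class, pairwise_p=pairwise_p, excluded=excluded)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small samples)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Resampling


def resample_sem(
    catalog: DomainCatalog | pd.DataFrame,
    analysis: Callable[[pd.DataFrame], dict[str, float]],
    n_resample: int = 100,
    seed: int = 0,
    method: str = "bootstrap",
    subsample_frac: float = 0.8,
) -> tuple[dict[str, float], int]:
    """Standard errors of analysis percentages under data resampling.

    Each replicate draws domains with replacement (``bootstrap``, default)
    or a ``subsample_frac`` fraction without replacement (``subsample``),
    reruns ``analysis`` on the replicate, and collects its named values.
    The reported SEM of each value is the standard deviation over replicate
    values (ddof=1) — the spread of the replicate means themselves, not
    divided again by sqrt(n).  Failed replicates are dropped and counted.

    Returns (sem per key, number of dropped replicates).
    """
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    if method not in ("bootstrap", "subsample"):
        raise ValueError(f"unknown resampling method {method!r}")
    df = catalog.domains if isinstance(catalog, DomainCatalog) else catalog
    rng = np.random.default_rng(seed)
    n = len(df)
    collected: dict[str, list[float]] = {}
    dropped = 0
    for _ in range(n_resample):
        if method == "bootstrap":
            idx = rng.integers(0, n, size=n)
        else:
            k = max(int(round(subsample_frac * n)), 1)
            idx = rng.choice(n, size=k, replace=False)
        replicate = df.iloc[idx].reset_index(drop=True)
        try:
            values = analysis(replicate)
        except Exception:
            dropped += 1
            continue
        for key, val in values.items():
            collected.setdefault(key, []).append(float(val))
    if dropped:
        warnings.warn(f"{dropped} resampling replicates failed", stacklevel=2)
    sems = {
        key: float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        for key, vals in collected.items()
    }
    return sems, dropped


# ---------------------------------------------------------------------------
# Fast-folder screen


@dataclass
class FastFolderScreen:
    """Families whose mean SMCO is at or below the screen threshold."""

    threshold: float
    families: pd.DataFrame  # family, smco, age, is_known_downhill
    fraction: float  # of all families in the catalog
    n_families_total: int


def screen_fast_folders(
    catalog: DomainCatalog,
    smco_threshold: float = 1.5,
    downhill_families: tuple[str, ...] = DOWNHILL_FOLDER_FAMILIES,
) -> FastFolderScreen:
    """Select families with mean SMCO <= threshold — candidate fast folders.

    The threshold defaults to 1.5, below the SMCO of families containing
    experimentally identified downhill folders; those known families are
    flagged alongside the screen output.
    """
    fm = catalog.family_means
    hits = fm[fm["smco"] <= smco_threshold].copy()
    hits["is_known_downhill"] = hits["family"].isin(downhill_families)
    cols = ["family", "n_domains", "smco", "age", "is_known_downhill"]
    hits = hits[[c for c in cols if c in hits.columns]].reset_index(drop=True)
    total = len(fm)
    fraction = float(len(hits) / total) if total else 0.0
    return FastFolderScreen(
        threshold=float(smco_threshold),
        families=hits,
        fraction=fraction,
        n_families_total=total,
    )
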