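"""Statistical primitives shared by every pipeline stage.

The conventions fixed here (and relied on by the screens downstream):

* Mann-Whitney U uses mid-ranks for ties; the p-value is exact (full
  enumeration) for small tie-free samples and otherwise a normal
  approximation with tie and continuity corrections.
* The common-language effect size F equals U/(n1*n2), i.e. the AUROC of
  one group against the other.
* Odds-ratio confidence intervals use the Woolf log method; tables with a
  zero cell get the Haldane-Anscombe +0.5 correction (flagged).
* Two-sided Fisher p-values order tables by hypergeometric probability
  mass, the convention of mainstream statistics libraries.
* Benjamini-Hochberg q-values are the step-up adjusted p-values.
* Percentile ranks are mid-rank based: 100*(rank - 0.5)/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "mann_whitney_u",
    "common_language_f",
    "odds_ratio_ci",
    "fisher_exact",
    "bh_fdr",
    "bh_reject",
    "spearman_rho",
    "bootstrap_spearman_ci",
    "percentile_rank",
]

# Largest n1*n2 for which the tie-free Mann-Whitney p-value is computed by
# exact enumeration rather than the corrected normal approximation.
EXACT_MWU_MAX_PRODUCT = 400


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows {factor true, factor false} x columns {highlighted, not}.

    ``a`` counts factor-true highlighted genes, ``b`` factor-true
    non-highlighted, ``c`` factor-false highlighted, ``d`` factor-false
    non-highlighted.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) <= 0:
            raise ValueError("contingency table must have positive total")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``effect`` is the odds ratio for contingency tests, the common-language
    F for rank tests, or the correlation for Spearman. ``flags`` records
    corrections or degeneracies (e.g. ``haldane_correction``,
    ``undefined_effect``, ``constant_input``).
    """

    statistic: float
    p_value: float
    effect: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"group '{name}' is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group '{name}' contains non-finite values")
    return arr


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    The statistic is U for ``x`` (number of (x, y) pairs with x > y plus
    half the tied pairs).  Small tie-free samples (n1*n2 <= 400) use exact
    enumeration; everything else the tie- and continuity-corrected normal
    approximation.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and xa.size * ya.size <= EXACT_MWU_MAX_PRODUCT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method,
                           use_continuity=True)
    p = min(float(res.pvalue), 1.0)
    f = float(res.statistic) / (xa.size * ya.size)
    return TestResult(statistic=float(res.statistic), p_value=p, effect=f,
                      flags=(method,))


def common_language_f(x_high: Sequence[float], x_rest: Sequence[float]) -> float:
    """Common-language effect size F = P(X_high > X_rest) + 0.5 P(tie).

    Equals the AUROC of ``x_high`` against ``x_rest`` and U/(n1*n2).
    """
    xa = _as_float_array(x_high, "x_high")
    ya = _as_float_array(x_rest, "x_rest")
    # U via rank sums: identical to pairwise counting with mid-rank ties.
    ranks = sps.rankdata(np.concatenate([xa, ya]))
    u = ranks[: xa.size].sum() - xa.size * (xa.size + 1) / 2.0
    return float(u) / (xa.size * ya.size)


def odds_ratio_ci(t: ContingencyTable, alpha: float = 0.05) -> TestResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log confidence interval.

    Tables containing a zero cell get 0.5 added to every cell for both the
    point estimate and the interval (Haldane-Anscombe), flagged
    ``haldane_correction``.  An all-zero row or column leaves the effect
    undefined (NaN, flagged ``undefined_effect``).
    """
    a, b, c, d = (float(v) for v in t.counts)
    flags: list[str] = []
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return TestResult(statistic=np.nan, p_value=np.nan, effect=np.nan,
                          flags=("undefined_effect",))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("haldane_correction")
    orv = (a * d) / (b * c)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orv) - z * se))
    hi = float(np.exp(np.log(orv) + z * se))
    return TestResult(statistic=float(np.log(orv)), p_value=np.nan,
                      effect=float(orv), ci_low=lo, ci_high=hi,
                      flags=tuple(flags))


def fisher_exact(t: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test by probability-mass ordering."""
    res = sps.fisher_exact(t.as_array(), alternative="two-sided")
    orv = float(res.statistic) if np.isfinite(res.statistic) else np.nan
    return TestResult(statistic=orv, p_value=min(float(res.pvalue), 1.0),
                      effect=orv)


def _validate_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = _validate_pvalues(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bh_reject(p_values: Sequence[float], q_star: float = 0.05) -> np.ndarray:
    """Boolean rejection mask at FDR threshold ``q_star`` (q <= q_star)."""
    q = bh_fdr(p_values)
    return q <= q_star


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return TestResult(statistic=np.nan, p_value=np.nan, effect=np.nan,
                          flags=("constant_input",))
    res = sps.spearmanr(xa, ya)
    return TestResult(statistic=float(res.statistic),
                      p_value=min(float(res.pvalue), 1.0),
                      effect=float(res.statistic))


def _rowwise_pearson(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_spearman_ci(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the Spearman correlation of ``pairs``.

    Resamples the pairs with replacement ``n_boot`` times. Degenerate
    resamples (either margin constant) are redrawn; the redraw count is
    logged. Identical seed gives an identical interval.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("pairs must be an (n, 2) array with n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = arr.shape[0]
    x, y = arr[:, 0], arr[:, 1]
    idx = rng.integers(0, n, size=(n_boot, n))
    xr = sps.rankdata(x[idx], axis=1)
    yr = sps.rankdata(y[idx], axis=1)
    rho = _rowwise_pearson(xr, yr)
    n_redraw = 0
    for _ in range(1000):
        bad = ~np.isfinite(rho)
        if not bad.any():
            break
        n_redraw += int(bad.sum())
        idx = rng.integers(0, n, size=(int(bad.sum()), n))
        rho[bad] = _rowwise_pearson(sps.rankdata(x[idx], axis=1),
                                    sps.rankdata(y[idx], axis=1))
    else:
        # every datum identical: the correlation itself is undefined
        raise ValueError("resamples are persistently degenerate (constant data)")
    if n_redraw:
        logger.info("bootstrap_spearman_ci: redrew %d degenerate resamples", n_redraw)
    lo, hi = np.percentile(rho, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def percentile_rank(
    counts: Mapping[int, float], reference: Iterable[int]
) -> dict[int, float]:
    """Mid-rank percentile of each reference gene's count, in [0, 100].

    percentile = 100 * (midrank - 0.5) / n over the reference set. Genes
    absent from ``counts`` are treated as count 0 (logged).
    """
    ref = list(reference)
    if not ref:
        raise ValueError("reference gene set is empty")
    missing = [g for g in ref if g not in counts]
    if missing:
        logger.info("percentile_rank: %d reference genes missing from counts, "
                    "treated as 0", len(missing))
    values = np.array([float(counts.get(g, 0)) for g in ref])
    ranks = sps.rankdata(values)  # mid-ranks
    pct = 100.0 * (ranks - 0.5) / len(ref)
    return dict(zip(ref, pct.tolist()))
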