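"""Built-in differential-abundance tests (DATs) behind one pluggable contract.

Every test consumes a two-condition :class:`CountMatrix` plus per-sample
normalization factors and produces a :class:`DATResult` with per-entity
p-values, BH q-values and a log2 fold-change estimate.  External tools can
be registered under the same contract with :func:`register_dat`.

The workhorse is the negative-binomial exact test: for entity counts that
are iid NB with common dispersion phi within each condition, the sum for
condition 1 given the grand total s follows a beta-binomial distribution
BetaBinomial(s, n1/phi, n2/phi); the test sums the conditional tail
probabilities and doubles the smaller tail.  At phi = 0 this reduces to
the exact binomial test on the pooled split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .generators import CountMatrix, DispersionModel, estimate_dispersion
from .normalization import NormalizationFactors, get_factors
from .profiles import filter_low_counts

__all__ = [
    "DATResult",
    "nb_exact_test",
    "nb_exact_pvalue",
    "wilcoxon_test",
    "welch_t_test",
    "welch_t",
    "fisher_exact_pooled",
    "bh_adjust",
    "run_dat",
    "register_dat",
    "registered_dats",
]

# totals above this use the large-sample Beta limit of the beta-binomial tail
_EXACT_LIMIT = 10_000


@dataclass
class DATResult:
    """Per-entity output of one differential-abundance test."""

    entity_ids: list[str]
    pvalue: np.ndarray
    qvalue: np.ndarray
    log2fc: np.ndarray
    statistic: np.ndarray
    test_name: str
    normalization_used: str = "none"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "entity_id": self.entity_ids,
                "log2fc": self.log2fc,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "qvalue": self.qvalue,
                "test_name": self.test_name,
                "normalization": self.normalization_used,
            }
        )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _normalized(counts: CountMatrix, factors: NormalizationFactors | None) -> np.ndarray:
    c = counts.counts.astype(float)
    if factors is None:
        return c
    f = np.asarray(factors.factors, dtype=float)
    if f.size != counts.n_samples:
        raise ValueError("factor vector length must match the number of samples")
    return c / f[None, :]


def _split(counts: CountMatrix, factors) -> tuple[np.ndarray, np.ndarray]:
    norm = _normalized(counts, factors)
    g1 = norm[:, counts.condition == 1]
    g2 = norm[:, counts.condition == 2]
    if g1.shape[1] == 0 or g2.shape[1] == 0:
        raise ValueError("both conditions must be present")
    return g1, g2


def _log2fc(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    return np.log2((g2.mean(axis=1) + 0.5) / (g1.mean(axis=1) + 0.5))


def _finish(counts, pvals, log2fc, stat, name, factors) -> DATResult:
    pvals = np.clip(np.asarray(pvals, dtype=float), 0.0, 1.0)
    return DATResult(
        entity_ids=list(counts.entity_ids),
        pvalue=pvals,
        qvalue=bh_adjust(pvals),
        log2fc=np.asarray(log2fc, dtype=float),
        statistic=np.asarray(stat, dtype=float),
        test_name=name,
        normalization_used=factors.method if factors is not None else "none",
    )


def nb_exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional NB p-value for one entity.

    Conditions on the total s = s1 + s2; under the null the condition-1 sum
    is BetaBinomial(s, n1/phi, n2/phi) (Binomial(s, n1/(n1+n2)) at phi=0).
    The p-value doubles the smaller tail, capped at 1.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    if phi <= 1e-10:
        dist = stats.binom(s, n1 / (n1 + n2))
        lower = dist.cdf(s1)
        upper = dist.sf(s1 - 1)
        return min(1.0, 2.0 * min(lower, upper))
    a, b = n1 / phi, n2 / phi
    if s <= _EXACT_LIMIT:
        k = np.arange(s + 1)
        logpmf = (
            gammaln(k + a)
            - gammaln(k + 1)
            + gammaln(s - k + b)
            - gammaln(s - k + 1)
        )
        logpmf -= logpmf.max()
        pmf = np.exp(logpmf)
        pmf /= pmf.sum()
        lower = pmf[: s1 + 1].sum()
        upper = pmf[s1:].sum()
    else:
        # s -> inf: the condition-1 proportion converges to Beta(a, b)
        lower = stats.beta.cdf((s1 + 0.5) / s, a, b)
        upper = stats.beta.sf((s1 - 0.5) / s, a, b)
    return min(1.0, 2.0 * min(lower, upper))


def nb_exact_test(
    counts: CountMatrix,
    factors: NormalizationFactors | None = None,
    dispersion: DispersionModel | float | np.ndarray | None = None,
    shrink_weight: float = 0.5,
) -> DATResult:
    """Exact conditional NB test on per-condition sums of normalized pseudo-counts.

    ``dispersion`` may be a scalar, a per-entity vector, a fitted
    :class:`DispersionModel` (per-entity values shrunk toward the
    mean-dispersion trend with weight ``shrink_weight`` on the raw value),
    or None, in which case dispersion is estimated from ``counts``.
    """
    g1, g2 = _split(counts, factors)
    n1, n2 = g1.shape[1], g2.shape[1]
    if dispersion is None:
        if max(n1, n2) < 2:
            raise ValueError("dispersion not estimable from single replicates; supply it")
        dispersion = estimate_dispersion(counts)
    if isinstance(dispersion, DispersionModel):
        phi = dispersion.shrunk(shrink_weight)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (counts.n_entities,))
    s1 = np.round(g1.sum(axis=1)).astype(np.int64)
    s2 = np.round(g2.sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [nb_exact_pvalue(int(a), int(b), n1, n2, float(f)) for a, b, f in zip(s1, s2, phi)]
    )
    lfc = np.log2((s2 / n2 + 0.5) / (s1 / n1 + 0.5))
    return _finish(counts, pvals, lfc, lfc, "nb_exact", factors)


def wilcoxon_test(
    counts: CountMatrix, factors: NormalizationFactors | None = None
) -> DATResult:
    """Two-sided rank-sum test per entity on normalized counts.

    Uses the exact null distribution when both groups have <= 10 samples
    and no ties, and the tie-corrected normal approximation otherwise.
    """
    g1, g2 = _split(counts, factors)
    n1, n2 = g1.shape[1], g2.shape[1]
    if min(n1, n2) < 3:
        raise ValueError("wilcoxon_test needs >= 3 samples per condition")
    pvals = np.empty(counts.n_entities)
    stat = np.empty(counts.n_entities)
    for i in range(counts.n_entities):
        x, y = g1[i], g2[i]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            pvals[i], stat[i] = 1.0, n1 * n2 / 2.0
            continue
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(n1, n2) <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(y, x, alternative="two-sided", method=method)
        pvals[i], stat[i] = res.pvalue, res.statistic
    return _finish(counts, pvals, _log2fc(g1, g2), stat, "wilcoxon", factors)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t on raw values: (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = x.size, y.size
    if v1 == 0 and v2 == 0:
        return (0.0, float(n1 + n2 - 2), 1.0) if x.mean() == y.mean() else (np.inf, float(n1 + n2 - 2), 0.0)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_test(
    counts: CountMatrix, factors: NormalizationFactors | None = None
) -> DATResult:
    """Welch t-test per entity on log2(normalized count + 1)."""
    g1, g2 = _split(counts, factors)
    if min(g1.shape[1], g2.shape[1]) < 2:
        raise ValueError("welch_t_test needs >= 2 samples per condition")
    l1, l2 = np.log2(g1 + 1.0), np.log2(g2 + 1.0)
    pvals = np.empty(counts.n_entities)
    stat = np.empty(counts.n_entities)
    zero_var_diff = 0
    for i in range(counts.n_entities):
        t, _, p = welch_t(l1[i], l2[i])
        stat[i], pvals[i] = -t, p  # sign follows condition2 - condition1
        if not np.isfinite(t):
            zero_var_diff += 1
    if zero_var_diff:
        warnings.warn(f"{zero_var_diff} entities had zero variance with unequal means (p -> 0)")
    stat = np.where(np.isfinite(stat), stat, np.sign(stat) * 1e12)
    return _finish(counts, pvals, _log2fc(g1, g2), stat, "welch_t", factors)


def fisher_exact_pooled(
    counts: CountMatrix, factors: NormalizationFactors | None = None,
    overflow_margin: float = 1e8,
) -> DATResult:
    """Fisher's exact test per entity on pooled condition counts.

    Builds the 2x2 table (entity vs all-other counts, per condition) from
    factor-adjusted counts rounded to integers; intended for small-count
    settings where replicate-level tests lose power.  Tables with margins
    beyond ``overflow_margin`` fall back to a chi-square approximation.
    """
    g1, g2 = _split(counts, factors)
    s1 = np.round(g1.sum(axis=1)).astype(np.int64)
    s2 = np.round(g2.sum(axis=1)).astype(np.int64)
    t1, t2 = int(s1.sum()), int(s2.sum())
    pvals = np.empty(counts.n_entities)
    fell_back = 0
    for i in range(counts.n_entities):
        table = np.array([[s1[i], t1 - s1[i]], [s2[i], t2 - s2[i]]])
        if table.max() > overflow_margin:
            fell_back += 1
            chi2, p, *_ = stats.chi2_contingency(np.maximum(table, 0), correction=True)
            pvals[i] = p
        else:
            pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    if fell_back:
        warnings.warn(f"chi-square fallback used for {fell_back} large tables")
    lfc = _log2fc(g1, g2)
    return _finish(counts, pvals, lfc, lfc, "fisher", factors)


_REGISTRY: dict[str, callable] = {}


def register_dat(name: str, func) -> None:
    """Register a test callable ``func(counts, factors, **options) -> DATResult``."""
    if name in _REGISTRY:
        raise ValueError(f"a DAT named {name!r} is already registered")
    _REGISTRY[name] = func


def registered_dats() -> list[str]:
    return sorted(_REGISTRY)


for _name, _func in (
    ("nb_exact", nb_exact_test),
    ("wilcoxon", wilcoxon_test),
    ("welch_t", welch_t_test),
    ("fisher", fisher_exact_pooled),
):
    register_dat(_name, _func)


def run_dat(
    name: str,
    counts: CountMatrix,
    normalization: str = "mode",
    min_count: int = 10,
    **options,
) -> DATResult:
    """Filter low-count entities, normalize, and run the named test."""
    if name not in _REGISTRY:
        raise ValueError(f"unknown DAT {name!r}; registered: {registered_dats()}")
    filtered = filter_low_counts(counts, min_count=min_count)
    factors = get_factors(filtered, normalization)
    return _REGISTRY[name](filtered, factors, **options)
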