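"""Per-sample normalization factors for count matrices.

The novel method here is mode normalization: the distribution of
un-normalized fold-changes (UFCs, ratios of average counts between the two
conditions) is smoothed by kernel density estimation, and the mode
presumed to hold the non-differentially-abundant entities fixes the
between-condition scale.  Classical baselines (total-count, upper-quartile,
median-of-ratios) and a ground-truth oracle (sum of counts over truly null
entities) are provided for comparison.

All factor vectors are reported with geometric mean 1; normalized counts
are ``counts / factor`` per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generators import CountMatrix

__all__ = [
    "NormalizationFactors",
    "UFCDistribution",
    "compute_ufc",
    "mode_normalize",
    "totalcount_normalize",
    "upperquartile_normalize",
    "medianratio_normalize",
    "oracle_nonda_normalize",
    "get_factors",
    "condition_factor_ratio",
]


@dataclass
class NormalizationFactors:
    """Per-sample positive scale factors (geometric mean 1) plus diagnostics."""

    factors: np.ndarray
    method: str
    sample_ids: list[str]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("factors must be strictly positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        self.factors = self.factors / gm


@dataclass
class UFCDistribution:
    """Log2 un-normalized fold-changes and (optionally) their smoothed density."""

    log_ufc: np.ndarray
    entity_ids: list[str]
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    maxima: np.ndarray | None = None
    bandwidth: float | None = None


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _require_two_conditions(counts: CountMatrix) -> None:
    if set(counts.conditions) != {1, 2}:
        raise ValueError("exactly two conditions (1 and 2) are required")


def compute_ufc(counts: CountMatrix) -> UFCDistribution:
    """Per-entity log2 ratio of average counts, condition 2 over condition 1.

    When either condition mean is zero, a 0.5 pseudocount is added to both
    means for that entity so the ratio stays finite.
    """
    _require_two_conditions(counts)
    m1 = counts.condition_counts(1).mean(axis=1)
    m2 = counts.condition_counts(2).mean(axis=1)
    zero = (m1 == 0) | (m2 == 0)
    m1 = np.where(zero, m1 + 0.5, m1)
    m2 = np.where(zero, m2 + 0.5, m2)
    return UFCDistribution(log_ufc=np.log2(m2 / m1), entity_ids=list(counts.entity_ids))


def _kde_grid(x: np.ndarray, bw: float, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    return grid, dens


def _local_maxima(density: np.ndarray, min_prominence_frac: float = 0.1) -> np.ndarray:
    """Indices of local density maxima with non-negligible topographic prominence.

    Genuine modes of the UFC distribution are separated by deep valleys;
    two other kinds of local maximum are artifacts and must not count —
    isolated extreme fold-changes (tiny spikes far in the tails) and
    low-prominence ripples on the shoulder of a wide cluster, which at
    small bandwidths masquerade as the expected up/null/down triple.  A
    prominence of at least ``min_prominence_frac`` of the global maximum
    screens out both.  Plateau maxima collapse to their midpoint.
    """
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(density, prominence=min_prominence_frac * density.max())
    return peaks.astype(int)


def _peak_fwhm(grid: np.ndarray, density: np.ndarray, peak: int) -> float:
    half = density[peak] / 2.0
    left = peak
    while left > 0 and density[left] > half:
        left -= 1
    right = peak
    while right < density.size - 1 and density[right] > half:
        right += 1
    return float(grid[right] - grid[left])


def mode_normalize(counts: CountMatrix, bw_start: float = 0.5, bw_step: float = 0.02,
                   bw_floor: float = 0.02, n_around: int = 10) -> NormalizationFactors:
    """Mode normalization from the smoothed UFC distribution.

    The log2 UFC density is estimated with a Gaussian kernel, annealing the
    bandwidth downward from ``bw_start`` in steps of ``bw_step`` until the
    number of local maxima is as close to 3 as possible (up, unchanged and
    down entities).  With one or three modes the middle mode is taken as
    the null cluster; with two modes the narrowest peak (full width at half
    maximum) is taken and a bimodal warning flag is raised.  The
    between-condition factor ratio is the geometric mean of the raw
    condition mean-count ratios of the 10 entities whose UFC lies closest
    to the chosen mode; within a condition, samples are scaled by their
    library size relative to the condition's geometric-mean depth.
    """
    _require_two_conditions(counts)
    if counts.n_entities < 20:
        raise ValueError("too few entities for density estimation (need >= 20)")
    ufc = compute_ufc(counts)
    x = ufc.log_ufc

    # Anneal the bandwidth downward over the whole schedule and group
    # bandwidths into contiguous runs with a constant number of maxima.  A
    # mode count is only trusted when it persists for at least
    # ``min_run`` consecutive bandwidth steps: at small bandwidths real
    # clusters fragment, and a count of exactly 3 that appears for a
    # single step is an artifact, not structure.  Among trusted runs the
    # one with count closest to 3 wins (ties favouring larger bandwidths);
    # within the winning run the smallest bandwidth is used, since sharper
    # peaks reduce the pull of neighbouring clusters on the null mode.
    bandwidths = np.arange(bw_start, bw_floor - 1e-12, -bw_step)
    n_by_bw = []
    for bw in bandwidths:
        grid, dens = _kde_grid(x, bw)
        n_by_bw.append(_local_maxima(dens).size)
    runs = []  # (n_modes, first_index, last_index)
    start = 0
    for i in range(1, len(n_by_bw) + 1):
        if i == len(n_by_bw) or n_by_bw[i] != n_by_bw[start]:
            runs.append((n_by_bw[start], start, i - 1))
            start = i
    longest = max(r[2] - r[1] + 1 for r in runs)
    min_run = max(3, -(-longest // 3))  # at least a third of the longest run
    trusted = [r for r in runs if r[2] - r[1] + 1 >= min_run]
    pool = trusted if trusted else runs
    n_best, first, last = min(pool, key=lambda r: (abs(r[0] - 3), r[1]))
    bw = float(bandwidths[last])
    grid, dens = _kde_grid(x, bw)
    maxima = _local_maxima(dens)
    bw_wide = float(bandwidths[first])

    n_modes = int(maxima.size)
    bimodal = False
    if n_modes == 0:  # monotone density edge case: fall back to the global max
        maxima = np.array([int(np.argmax(dens))])
        n_modes = 1
    if n_modes % 2 == 1:
        peak = maxima[n_modes // 2]
    else:
        # Peak widths are compared at the run's *largest* bandwidth: at
        # cluster scale the null peak (replicate noise only) is never wider
        # than a DA peak (noise plus fold-change spread), whereas at sharp
        # bandwidths a tight-fold-change DA cluster can look narrower.
        grid_w, dens_w = _kde_grid(x, bw_wide)
        widths = []
        for p in maxima:
            p_w = int(np.argmin(np.abs(grid_w - grid[p])))
            widths.append(_peak_fwhm(grid_w, dens_w, p_w))
        peak = maxima[int(np.argmin(widths))]
        bimodal = True
    mode_loc = float(grid[peak])

    if maxima.size >= 2:
        # Refine the location to the median UFC of the valley-bounded
        # segment around the chosen peak.  The raw density apex is pulled
        # toward the heavier neighbouring DA cluster by its overlapping
        # tail; the segment median is robust to that shoulder
        # contamination.  With a single mode there are no valleys to bound
        # the segment, so the apex is kept.
        order = np.sort(maxima)
        pos = int(np.searchsorted(order, peak))
        if pos == 0:
            lo = grid[0]
        else:
            left = order[pos - 1]
            lo = grid[left + int(np.argmin(dens[left : peak + 1]))]
        if pos == order.size - 1:
            hi = grid[-1]
        else:
            right = order[pos + 1]
            hi = grid[peak + int(np.argmin(dens[peak : right + 1]))]
        segment = x[(x >= lo) & (x <= hi)]
        if segment.size:
            mode_loc = float(np.median(segment))

    nearest = np.argsort(np.abs(x - mode_loc))[: min(n_around, x.size)]
    ratio = float(2.0 ** np.mean(x[nearest]))  # condition2 / condition1 scale

    ufc.grid, ufc.density, ufc.maxima, ufc.bandwidth = grid, dens, grid[maxima], bw

    depths = counts.counts.sum(axis=0).astype(float)
    factors = np.empty(counts.n_samples)
    for cond, cond_ratio in ((1, ratio**-0.5), (2, ratio**0.5)):
        cols = counts.condition_columns(cond)
        base = _geomean(depths[cols])
        factors[cols] = depths[cols] / base * cond_ratio
    return NormalizationFactors(
        factors=factors,
        method="mode",
        sample_ids=list(counts.sample_ids),
        flags={
            "bimodal_warning": bimodal,
            "bandwidth_used": float(bw),
            "n_modes": n_modes,
            "mode_location": mode_loc,
            "condition_ratio": ratio,
        },
    )


def totalcount_normalize(counts: CountMatrix) -> NormalizationFactors:
    """Factors proportional to library size (total count per sample)."""
    sums = counts.counts.sum(axis=0).astype(float)
    if np.any(sums == 0):
        raise ValueError("cannot total-count normalize a sample with zero counts")
    return NormalizationFactors(sums, "totalcount", list(counts.sample_ids))


def upperquartile_normalize(counts: CountMatrix) -> NormalizationFactors:
    """Factors proportional to the 75th percentile of each sample's nonzero counts."""
    factors = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        col = counts.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.sample_ids[j]!r} has no nonzero counts")
        factors[j] = np.percentile(nz, 75)
    return NormalizationFactors(factors, "upperquartile", list(counts.sample_ids))


def medianratio_normalize(counts: CountMatrix) -> NormalizationFactors:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only entities with positive counts in every sample enter the reference,
    mirroring the size-factor construction used by median-normalization
    methods.
    """
    c = counts.counts.astype(float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no entity is positive in all samples")
    sub = c[allpos]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return NormalizationFactors(factors, "medianratio", list(counts.sample_ids))


def oracle_nonda_normalize(counts: CountMatrix) -> NormalizationFactors:
    """Ideal-performance factors: per-sample sums over truly null entities.

    Requires simulation ground truth; used as the reference when measuring
    normalization accuracy.
    """
    if counts.truth is None:
        raise ValueError("oracle normalization requires attached ground truth")
    null = counts.truth.da_label == "null"
    sums = counts.counts[null].sum(axis=0).astype(float)
    if np.any(sums == 0):
        raise ValueError("a sample has zero counts over null entities")
    return NormalizationFactors(sums, "oracle", list(counts.sample_ids))


_METHODS = {
    "mode": mode_normalize,
    "totalcount": totalcount_normalize,
    "upperquartile": upperquartile_normalize,
    "medianratio": medianratio_normalize,
    "oracle": oracle_nonda_normalize,
}


def get_factors(counts: CountMatrix, method: str = "mode") -> NormalizationFactors:
    """Compute factors by method name; ``'none'`` returns unit factors."""
    if method == "none":
        return NormalizationFactors(np.ones(counts.n_samples), "none", list(counts.sample_ids))
    try:
        return _METHODS[method](counts)
    except KeyError:
        raise ValueError(f"unknown normalization {method!r}; known: {sorted(_METHODS)} or 'none'")


def condition_factor_ratio(nf: NormalizationFactors, condition: np.ndarray) -> float:
    """Geometric-mean factor of condition 2 over condition 1."""
    condition = np.asarray(condition)
    f = nf.factors
    return _geomean(f[condition == 2]) / _geomean(f[condition == 1])
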