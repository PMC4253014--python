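"""Replicate count simulation under the Multinomial, NB and Full models.

All three models share the same ground truth (a :class:`PerturbedPair`) and
the same depth convention: ``ND`` is the average number of data-points per
entity, so a sample's total count is drawn around ``ND * EC``.

* Multinomial — one multinomial draw per replicate from the condition's
  mean abundance vector; no replicate-level variability.
* NB — each entity/replicate count is an independent negative-binomial
  draw with variance mu + phi * mu^2.
* Full — negative-binomial draws first set a latent per-replicate mean for
  each entity; the latent vector is renormalized to frequencies and a
  single multinomial draw imposes the sample's total, coupling entities
  the way a sequencing run does.

Per-entity dispersions are sampled once per dataset from a Gamma
distribution with mean ``SV`` (emulating dispersion heterogeneity across
genes), or held at the common value ``SV`` in scalar mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import PerturbedPair

__all__ = [
    "SimConfig",
    "CountMatrix",
    "DispersionModel",
    "simulate",
    "simulate_full",
    "simulate_nb",
    "simulate_multinomial",
    "inject_outliers",
    "estimate_dispersion",
    "concat_conditions",
]


@dataclass
class SimConfig:
    """Simulation settings.

    NR: replicates per condition.  ND: mean data-points per entity (a
    sample's total count is ~ Uniform(0.9, 1.1) * ND * EC).  SM: simulation
    model, one of ``multinomial``, ``nb``, ``full``.  SV: dispersion phi
    (scalar, or a per-entity vector); with ``dispersion_mode='gamma'`` a
    scalar SV is the mean of a Gamma(shape, SV/shape) per-entity dispersion
    draw, with ``'common'`` every entity uses SV exactly.
    """

    NR: int = 3
    ND: float = 500.0
    SM: str = "full"
    SV: float | np.ndarray = 0.5
    gamma_shape: float = 1.0
    dispersion_mode: str = "gamma"
    outlier_fraction: float = 0.0
    outlier_factor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.NR < 1:
            raise ValueError("NR must be >= 1")
        if self.ND <= 0:
            raise ValueError("ND must be > 0")
        self.SM = self.SM.lower()
        if self.SM not in {"multinomial", "nb", "full"}:
            raise ValueError(f"unknown simulation model {self.SM!r}")
        if np.any(np.asarray(self.SV) < 0):
            raise ValueError("SV must be non-negative")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.dispersion_mode not in {"gamma", "common"}:
            raise ValueError("dispersion_mode must be 'gamma' or 'common'")


@dataclass
class CountMatrix:
    """Integer entities x samples count table with per-sample condition labels."""

    counts: np.ndarray
    entity_ids: list[str]
    sample_ids: list[str]
    condition: np.ndarray
    truth: PerturbedPair | None = None
    outlier_cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (entities x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.condition = np.asarray(self.condition, dtype=int)
        if self.condition.size != self.counts.shape[1]:
            raise ValueError("condition labels must match the number of samples")
        if len(self.entity_ids) != self.counts.shape[0]:
            raise ValueError("entity_ids must match the number of rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids must match the number of columns")

    @property
    def n_entities(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.condition)

    def condition_columns(self, cond: int) -> np.ndarray:
        return np.flatnonzero(self.condition == cond)

    def condition_counts(self, cond: int) -> np.ndarray:
        return self.counts[:, self.condition == cond]

    def subset_entities(self, mask_or_idx: np.ndarray) -> "CountMatrix":
        idx = (
            np.flatnonzero(mask_or_idx)
            if np.asarray(mask_or_idx).dtype == bool
            else np.asarray(mask_or_idx)
        )
        truth = self.truth.subset(idx) if self.truth is not None else None
        return CountMatrix(
            counts=self.counts[idx],
            entity_ids=[self.entity_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            condition=self.condition.copy(),
            truth=truth,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.entity_ids, columns=self.sample_ids)


@dataclass
class DispersionModel:
    """Per-entity NB dispersions with a mean-dispersion trend.

    ``trend(mean)`` interpolates the locally averaged dispersion at a given
    normalized mean count; ``common_phi`` is a trimmed-mean summary used
    when a single dispersion is wanted.
    """

    per_entity_phi: np.ndarray
    means: np.ndarray
    trend_means: np.ndarray
    trend_phi: np.ndarray
    common_phi: float

    def trend(self, mean: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(mean, dtype=float), self.trend_means, self.trend_phi)

    def shrunk(self, weight: float = 0.5) -> np.ndarray:
        """Per-entity dispersion shrunk toward the trend (weight on the raw value)."""
        return weight * self.per_entity_phi + (1 - weight) * self.trend(self.means)


def _entity_dispersions(cfg: SimConfig, ec: int, rng: np.random.Generator) -> np.ndarray:
    sv = np.asarray(cfg.SV, dtype=float)
    if sv.ndim == 1:
        if sv.size != ec:
            raise ValueError("per-entity SV vector length must equal EC")
        return sv
    if cfg.dispersion_mode == "common" or sv == 0:
        return np.full(ec, float(sv))
    return rng.gamma(cfg.gamma_shape, float(sv) / cfg.gamma_shape, size=ec)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and dispersion (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _totals(rng: np.random.Generator, cfg: SimConfig, ec: int, n: int) -> np.ndarray:
    lo, hi = 0.9 * cfg.ND * ec, 1.1 * cfg.ND * ec
    return np.round(rng.uniform(lo, hi, size=n)).astype(np.int64)


def _sample_ids(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"C1R{r + 1}" for r in range(cfg.NR)] + [f"C2R{r + 1}" for r in range(cfg.NR)]
    cond = np.array([1] * cfg.NR + [2] * cfg.NR)
    return ids, cond


def simulate_multinomial(pair: PerturbedPair, cfg: SimConfig) -> CountMatrix:
    """One multinomial draw per replicate from the condition mean profile."""
    rng = np.random.default_rng(cfg.seed)
    ec = pair.EC
    ids, cond = _sample_ids(cfg)
    cols = []
    for mean in (pair.mean1, pair.mean2):
        totals = _totals(rng, cfg, ec, cfg.NR)
        for t in totals:
            cols.append(rng.multinomial(t, mean))
    return _finish(np.column_stack(cols), pair, cfg, ids, cond, rng)


def simulate_nb(pair: PerturbedPair, cfg: SimConfig) -> CountMatrix:
    """Independent NB counts per entity and replicate (no multinomial coupling)."""
    rng = np.random.default_rng(cfg.seed)
    ec = pair.EC
    phi = _entity_dispersions(cfg, ec, rng)
    ids, cond = _sample_ids(cfg)
    cols = []
    for mean in (pair.mean1, pair.mean2):
        mu = mean * cfg.ND * ec
        for _ in range(cfg.NR):
            cols.append(_nb_draw(rng, mu, phi))
    return _finish(np.column_stack(cols), pair, cfg, ids, cond, rng)


def _latent_means(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Biological replicate means: the Gamma mixing component of the NB.

    A count that is NB(mu, phi) is Poisson with a Gamma(1/phi, phi*mu)
    random mean; the Gamma part is the replicate-to-replicate (biological)
    variability, while the Poisson/multinomial part is counting noise that
    the subsequent multinomial draw supplies.  At phi = 0 the latent mean
    is mu itself, so the model degenerates to a pure multinomial.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = mean.copy()
    mix = phi > 1e-12
    if mix.any():
        shape = 1.0 / phi[mix]
        out[mix] = rng.gamma(shape, phi[mix] * mean[mix])
    return out


def simulate_full(pair: PerturbedPair, cfg: SimConfig) -> CountMatrix:
    """Gamma-distributed latent replicate means renormalized, then multinomial sampling.

    Marginally each count is approximately NB(abundance * depth, phi) while
    entities within a sample are coupled through the fixed total, the way a
    sequencing run couples them.  The multinomial model is recovered
    exactly at SV = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    ec = pair.EC
    phi = _entity_dispersions(cfg, ec, rng)
    ids, cond = _sample_ids(cfg)
    cols = []
    for mean in (pair.mean1, pair.mean2):
        mu = mean * cfg.ND * ec
        totals = _totals(rng, cfg, ec, cfg.NR)
        for t in totals:
            latent = _latent_means(rng, mu, phi)
            attempts = 0
            while latent.sum() == 0:
                attempts += 1
                if attempts > 10:
                    raise RuntimeError("latent frequencies degenerate after 10 attempts")
                warnings.warn("all-zero latent replicate; resampling")
                latent = _latent_means(rng, mu, phi)
            freq = latent / latent.sum()
            cols.append(rng.multinomial(t, freq))
    return _finish(np.column_stack(cols), pair, cfg, ids, cond, rng)


def _finish(counts, pair, cfg, ids, cond, rng) -> CountMatrix:
    cm = CountMatrix(counts=counts, entity_ids=list(pair.entity_ids),
                     sample_ids=ids, condition=cond, truth=pair)
    if cfg.outlier_fraction > 0:
        cm = inject_outliers(cm, cfg.outlier_fraction, cfg.outlier_factor,
                             seed=int(rng.integers(2**31 - 1)))
    return cm


_DISPATCH = {"multinomial": simulate_multinomial, "nb": simulate_nb, "full": simulate_full}


def simulate(pair: PerturbedPair, cfg: SimConfig) -> CountMatrix:
    """Dispatch to the model named by ``cfg.SM``."""
    return _DISPATCH[cfg.SM](pair, cfg)


def inject_outliers(
    counts: CountMatrix, fraction: float = 0.15, factor: float = 100.0, seed: int = 0
) -> CountMatrix:
    """Scale a random subset of entities up or down in one random sample each.

    Emulates the single-sample aberrations frequently seen in real count
    data: for each selected entity one sample's count is multiplied or
    divided (fair coin) by ``factor`` and rounded half-up.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if factor <= 0:
        raise ValueError("factor must be > 0")
    rng = np.random.default_rng(seed)
    new = counts.counts.copy()
    n_pick = int(round(fraction * counts.n_entities))
    picked = rng.choice(counts.n_entities, size=n_pick, replace=False)
    cells = []
    for i in picked:
        j = int(rng.integers(counts.n_samples))
        scale = factor if rng.random() < 0.5 else 1.0 / factor
        new[i, j] = max(0, int(np.floor(new[i, j] * scale + 0.5)))
        cells.append((int(i), j))
    return CountMatrix(
        counts=new,
        entity_ids=list(counts.entity_ids),
        sample_ids=list(counts.sample_ids),
        condition=counts.condition.copy(),
        truth=counts.truth,
        outlier_cells=cells,
    )


def estimate_dispersion(counts: CountMatrix, trim: float = 0.1, window: int = 51) -> DispersionModel:
    """Method-of-moments NB dispersion estimation from replicated counts.

    Within each condition with >= 2 replicates, columns are first scaled to
    a common depth (total-count normalization); per-entity dispersion is
    phi = max(0, (s^2 - m) / m^2) pooled across conditions by weighting
    with the within-condition degrees of freedom.  A running mean over
    mean-ranked entities gives the mean-dispersion trend, and the common
    dispersion is a trimmed mean of per-entity values.
    """
    groups = []
    for cond in counts.conditions:
        block = counts.condition_counts(cond).astype(float)
        if block.shape[1] >= 2:
            depth = block.sum(axis=0)
            block = block * (depth.mean() / np.where(depth == 0, 1, depth))
            groups.append(block)
    if not groups:
        raise ValueError("dispersion not estimable from single replicates; supply SV")
    num = np.zeros(counts.n_entities)
    den = 0.0
    mean_acc = np.zeros(counts.n_entities)
    for block in groups:
        m = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        w = block.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += w * np.maximum(phi, 0.0)
        mean_acc += w * m
        den += w
    phi_hat = num / den
    means = mean_acc / den

    order = np.argsort(means)
    win = min(window, phi_hat.size)
    kernel = np.ones(win) / win
    padded = np.pad(phi_hat[order], (win // 2, win - 1 - win // 2), mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    trend_means = means[order]
    # enforce strictly increasing x for interpolation
    uniq, first = np.unique(trend_means, return_index=True)
    trend_means, smooth = uniq, smooth[first]

    informative = means >= 1
    vals = np.sort(phi_hat[informative]) if informative.any() else np.sort(phi_hat)
    k = int(trim * vals.size)
    common = float(vals[k : vals.size - k].mean()) if vals.size > 2 * k else float(vals.mean())
    return DispersionModel(
        per_entity_phi=phi_hat,
        means=means,
        trend_means=trend_means,
        trend_phi=smooth,
        common_phi=common,
    )


def concat_conditions(cm1: CountMatrix, cm2: CountMatrix) -> CountMatrix:
    """Join two single-condition matrices over a shared entity set as conditions 1 and 2."""
    if cm1.entity_ids != cm2.entity_ids:
        raise ValueError("count matrices must share an identical entity set")
    return CountMatrix(
        counts=np.column_stack([cm1.counts, cm2.counts]),
        entity_ids=list(cm1.entity_ids),
        sample_ids=[f"A.{s}" for s in cm1.sample_ids] + [f"B.{s}" for s in cm2.sample_ids],
        condition=np.array([1] * cm1.n_samples + [2] * cm2.n_samples),
        truth=cm1.truth,
    )
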