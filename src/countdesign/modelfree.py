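"""Model-free count simulation by subsampling a replicate-rich pilot dataset.

When no parametric model (Poisson, NB) fits the replicate variability of a
platform — single-cell RNA-seq being the canonical case — counts can
instead be resampled from a pilot dataset with many replicates.  For each
target entity the pilot entity with the closest average count donates
replicate values (scaled to the target mean); when the pilot has too few
replicates, values are drawn from a pool of entities with similar average
counts, which preserves the mean-variability relationship of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .generators import CountMatrix

__all__ = ["PilotLibrary", "modelfree_simulate", "validate_grouping"]


@dataclass
class PilotLibrary:
    """A pilot count matrix with entity means and mean-similarity groups.

    Entities are bucketed into ``n_groups`` equal-occupancy bins on log
    average count; bins drive the group-level sampling path.
    """

    counts: CountMatrix
    n_groups: int = 20
    entity_means: np.ndarray = field(init=False)
    group_of: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.counts.n_samples < 2:
            raise ValueError("pilot data needs >= 2 replicates")
        self.entity_means = self.counts.counts.mean(axis=1)
        logm = np.log1p(self.entity_means)
        ranks = stats.rankdata(logm, method="ordinal") - 1
        n_groups = min(self.n_groups, self.counts.n_entities)
        self.group_of = (ranks * n_groups // self.counts.n_entities).astype(int)

    @property
    def n_replicates(self) -> int:
        return self.counts.n_samples


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round so that the expectation is preserved: floor + Bernoulli(frac)."""
    floor = np.floor(x)
    return (floor + (rng.random(x.shape) < (x - floor))).astype(np.int64)


def modelfree_simulate(
    pilot: PilotLibrary,
    target_means: np.ndarray,
    NR: int,
    n_sims: int = 1,
    seed: int = 0,
    rescale_ND: float | None = None,
) -> CountMatrix | list[CountMatrix]:
    """Simulate NR-replicate counts matching target means from pilot variability.

    For each target entity, the pilot entity with the closest average count
    is matched.  If the pilot holds at least ``NR * n_sims`` replicates the
    values are drawn without replacement from that entity's own counts;
    otherwise each replicate value is drawn from the matched entity's
    mean-group pool (scaled by the target mean over the donor entity's
    mean).  Scaled values are stochastically rounded so expectations are
    unbiased.  With ``rescale_ND`` set, each sample is renormalized and
    redrawn from a multinomial at total ~ Uniform(0.9, 1.1) * rescale_ND *
    EC, restoring a fixed sequencing depth.

    Returns one CountMatrix when ``n_sims`` is 1, else a list.  Each matrix
    carries ``provenance`` (source entity index of every cell) in
    ``outlier_cells``-style metadata via the ``provenance`` attribute.
    """
    if NR < 1:
        raise ValueError("NR must be >= 1")
    target_means = np.asarray(target_means, dtype=float)
    if np.any(target_means <= 0):
        raise ValueError("target means must be positive")
    rng = np.random.default_rng(seed)
    ec = target_means.size
    matched = np.array(
        [int(np.argmin(np.abs(pilot.entity_means - t))) for t in target_means]
    )
    direct = pilot.n_replicates >= NR * n_sims
    sims = []
    for _ in range(n_sims):
        out = np.empty((ec, NR), dtype=np.int64)
        provenance = np.empty((ec, NR), dtype=np.int64)
        for i in range(ec):
            src = matched[i]
            if direct:
                cols = rng.choice(pilot.n_replicates, size=NR, replace=False)
                vals = pilot.counts.counts[src, cols].astype(float)
                donors = np.full(NR, src)
            else:
                pool = np.flatnonzero(pilot.group_of == pilot.group_of[src])
                donors = rng.choice(pool, size=NR, replace=True)
                cols = rng.integers(pilot.n_replicates, size=NR)
                vals = pilot.counts.counts[donors, cols].astype(float)
            donor_means = np.maximum(pilot.entity_means[donors], 1e-9)
            scaled = vals * (target_means[i] / donor_means)
            out[i] = _stochastic_round(scaled, rng)
            provenance[i] = donors
        cm = CountMatrix(
            counts=out,
            entity_ids=[f"E{i:06d}" for i in range(ec)],
            sample_ids=[f"S{r + 1}" for r in range(NR)],
            condition=np.ones(NR, dtype=int),
        )
        cm.provenance = provenance
        if rescale_ND is not None:
            total_target = rescale_ND * ec
            freq = out / np.maximum(out.sum(axis=0, keepdims=True), 1)
            redrawn = np.column_stack(
                [
                    rng.multinomial(
                        int(round(rng.uniform(0.9, 1.1) * total_target)), freq[:, j]
                    )
                    for j in range(NR)
                ]
            )
            cm = CountMatrix(
                counts=redrawn,
                entity_ids=cm.entity_ids,
                sample_ids=cm.sample_ids,
                condition=cm.condition,
            )
            cm.provenance = provenance
        sims.append(cm)
    return sims[0] if n_sims == 1 else sims


def validate_grouping(
    pilot: PilotLibrary, k_neighbors: int = 10, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Check that entities resemble their nearest mean-neighbours in variability.

    For each entity, its counts scaled by the entity mean are compared
    (two-sample Kolmogorov-Smirnov) against the pooled mean-scaled counts
    of the ``k_neighbors`` entities with closest average count; an entity
    is 'similar' when the KS test does not reject at ``alpha``.  Returns
    (fraction similar under nearest-neighbour grouping, fraction similar
    under random grouping) — the first should far exceed the second when
    grouping by average count is meaningful.
    """
    if pilot.n_replicates < 10:
        raise ValueError("validate_grouping needs >= 10 pilot replicates")
    rng = np.random.default_rng(seed)
    ec = pilot.counts.n_entities
    means = np.maximum(pilot.entity_means, 1e-9)
    scaled = pilot.counts.counts / means[:, None]
    order = np.argsort(means)
    rank_of = np.empty(ec, dtype=int)
    rank_of[order] = np.arange(ec)

    def similar_fraction(neighbor_picker) -> float:
        hits = 0
        for i in range(ec):
            nbrs = neighbor_picker(i)
            pooled = scaled[nbrs].ravel()
            if np.all(scaled[i] == scaled[i][0]) and np.all(pooled == scaled[i][0]):
                hits += 1
                continue
            p = stats.ks_2samp(scaled[i], pooled).pvalue
            hits += p >= alpha
        return hits / ec

    def nearest(i: int) -> np.ndarray:
        r = rank_of[i]
        lo = max(0, min(r - k_neighbors // 2, ec - k_neighbors - 1))
        window = [order[j] for j in range(lo, min(ec, lo + k_neighbors + 1)) if order[j] != i]
        return np.array(window[:k_neighbors])

    def random_pick(i: int) -> np.ndarray:
        pool = np.delete(np.arange(ec), i)
        return rng.choice(pool, size=k_neighbors, replace=False)

    return similar_fraction(nearest), similar_fraction(random_pick)
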