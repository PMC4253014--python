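"""Abundance profiles and ground-truth perturbations.

An abundance profile is the vector of relative abundances of the counted
entities (genes, transcripts, taxa) in the reference condition.  A
perturbation turns one profile into a pair of condition profiles with known
differentially abundant (DA) entities and fold-changes, which downstream
modules use as simulation ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbundanceProfile",
    "PerturbationSpec",
    "PerturbedPair",
    "make_powerlaw_profile",
    "profile_from_counts",
    "resample_profile",
    "apply_perturbation",
    "learn_perturbation_from_data",
    "filter_low_counts",
]

@dataclass
class AbundanceProfile:
    """Relative abundances over a fixed set of entities.

    Abundances are strictly positive and sum to one; ``EC`` is the entity
    count.  ``meta`` carries provenance (for example, the source stratum of
    each entity after stratified resampling).
    """

    abundances: np.ndarray
    entity_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size < 1:
            raise ValueError("abundances must be a non-empty 1-D vector")
        if not self.entity_ids:
            self.entity_ids = [f"E{i:06d}" for i in range(self.abundances.size)]
        if len(self.entity_ids) != self.abundances.size:
            raise ValueError("entity_ids length must match abundances")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be strictly positive")
        if abs(self.abundances.sum() - 1.0) > 1e-6:
            raise ValueError("abundances must sum to 1")
        # snap to exact normalization within tolerance
        self.abundances = self.abundances / self.abundances.sum()

    @property
    def EC(self) -> int:
        return int(self.abundances.size)


@dataclass
class PerturbationSpec:
    """How to perturb a profile: which fraction of entities change and by how much.

    ``fc_dist`` is one of ``uniform``, ``lognormal``, ``normal`` or
    ``empirical``.  Drawn fold-changes are constrained to be > 1 before a
    direction (up or down) is applied; an empirical list keeps the observed
    directions and its length fixes the number of perturbed entities.
    """

    pda_up: float = 0.0
    pda_down: float = 0.0
    fc_dist: str = "uniform"
    fc_params: tuple | list = (3.0, 5.0)

    def __post_init__(self) -> None:
        if self.pda_up < 0 or self.pda_down < 0 or self.pda_up + self.pda_down > 1:
            raise ValueError("pda_up + pda_down must lie in [0, 1]")
        self.fc_dist = self.fc_dist.lower()
        if self.fc_dist not in {"uniform", "lognormal", "normal", "empirical"}:
            raise ValueError(f"unknown fold-change distribution {self.fc_dist!r}")

    def draw_foldchanges(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` fold-changes > 1 (rejection sampling for unbounded dists)."""
        if self.fc_dist == "empirical":
            fc = np.asarray(self.fc_params, dtype=float)
            return fc[: n] if n <= fc.size else fc
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = n - filled
            if self.fc_dist == "uniform":
                a, b = self.fc_params
                draw = rng.uniform(a, b, size=m)
            elif self.fc_dist == "lognormal":
                mu, sigma = self.fc_params
                draw = rng.lognormal(mu, sigma, size=m)
            else:  # normal
                mu, sigma = self.fc_params
                draw = rng.normal(mu, sigma, size=m)
            draw = draw[draw > 1.0]
            out[filled : filled + draw.size] = draw
            filled += draw.size
        return out


@dataclass
class PerturbedPair:
    """Paired condition profiles plus ground truth.

    ``fc[i]`` is the true fold-change mean2/mean1 of entity ``i`` before the
    per-condition renormalization (1 for null entities); ``da_label`` is one
    of ``up``, ``down``, ``null``.
    """

    mean1: np.ndarray
    mean2: np.ndarray
    da_label: np.ndarray
    fc: np.ndarray
    entity_ids: list[str]

    @property
    def EC(self) -> int:
        return int(self.mean1.size)

    @property
    def is_da(self) -> np.ndarray:
        return self.da_label != "null"

    def subset(self, idx: np.ndarray) -> "PerturbedPair":
        m1 = self.mean1[idx]
        m2 = self.mean2[idx]
        return PerturbedPair(
            mean1=m1 / m1.sum(),
            mean2=m2 / m2.sum(),
            da_label=self.da_label[idx],
            fc=self.fc[idx],
            entity_ids=[self.entity_ids[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.entity_ids[i] for i in idx],
        )


def make_powerlaw_profile(
    EC: int, exponent: float = 1.0, seed: int = 0
) -> AbundanceProfile:
    """Power-law rank-frequency profile: abundance of rank r proportional to r^-exponent.

    Relative abundances in counting experiments typically follow a power
    law; this generator stands in for profiles learnt from pilot data.  The
    seed shuffles which entity index receives which rank, leaving the
    rank-frequency shape untouched.
    """
    if EC < 1:
        raise ValueError("EC must be >= 1")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    ranks = np.arange(1, EC + 1, dtype=float)
    ab = ranks ** (-exponent)
    rng = np.random.default_rng(seed)
    ab = rng.permutation(ab)
    return AbundanceProfile(ab / ab.sum())


def profile_from_counts(counts: np.ndarray, entity_ids: list[str] | None = None) -> AbundanceProfile:
    """Average frequency profile from an entities x samples count table.

    Counts are aggregated across samples; zero-total entities receive a 0.5
    pseudocount so the profile stays strictly positive.
    """
    totals = np.asarray(counts, dtype=float).sum(axis=1)
    totals = np.where(totals <= 0, 0.5, totals)
    return AbundanceProfile(totals / totals.sum(), entity_ids=list(entity_ids or []))


def _strata(order: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split entity indices (descending abundance) into top 10% / middle 80% / bottom 10%."""
    ec = order.size
    n_top = max(1, int(round(0.1 * ec)))
    n_bot = max(1, int(round(0.1 * ec)))
    top = order[:n_top]
    bot = order[ec - n_bot :]
    mid = order[n_top : ec - n_bot]
    return top, mid, bot


def resample_profile(
    profile: AbundanceProfile, target_EC: int, seed: int = 0
) -> AbundanceProfile:
    """Resample a profile to a different entity count, preserving dynamic range.

    Entities are ordered by relative abundance and drawn independently from
    the top 10%, middle 80% and bottom 10% strata (10% / 80% / 10% of the
    target count respectively), without replacement when subsampling and
    with replacement when over-sampling a stratum.
    """
    if target_EC < 10:
        raise ValueError("target_EC must be >= 10")
    rng = np.random.default_rng(seed)
    # descending abundance; ties broken by entity index for determinism
    order = np.lexsort((np.arange(profile.EC), -profile.abundances))
    top, mid, bot = _strata(order)
    n_top = max(1, int(round(0.1 * target_EC)))
    n_bot = max(1, int(round(0.1 * target_EC)))
    n_mid = target_EC - n_top - n_bot
    picks, strata = [], []
    for pool, n, name in ((top, n_top, "top"), (mid, n_mid, "middle"), (bot, n_bot, "bottom")):
        replace = n > pool.size
        picks.append(rng.choice(pool, size=n, replace=replace))
        strata.extend([name] * n)
    idx = np.concatenate(picks)
    ab = profile.abundances[idx]
    ids = [f"{profile.entity_ids[i]}.r{k}" for k, i in enumerate(idx)]
    return AbundanceProfile(
        ab / ab.sum(),
        entity_ids=ids,
        meta={"source_index": idx, "source_stratum": np.array(strata)},
    )


def apply_perturbation(
    profile: AbundanceProfile, spec: PerturbationSpec, seed: int = 0
) -> PerturbedPair:
    """Create the two condition profiles by perturbing a random entity subset.

    Each perturbed entity's abundance x is split symmetrically so that the
    geometric mean of the two condition means stays at x and their ratio is
    the drawn fold-change: condition 2 gets x*sqrt(f), condition 1 gets
    x/sqrt(f) for an up entity (f inverted for a down entity).  Both
    condition vectors are then renormalized independently.
    """
    ec = profile.EC
    rng = np.random.default_rng(seed)
    if spec.fc_dist == "empirical":
        fc_list = np.asarray(spec.fc_params, dtype=float)
        n_pert = min(fc_list.size, ec)
        chosen = rng.choice(ec, size=n_pert, replace=False)
        fc_vals = fc_list[:n_pert]
        labels_pert = np.where(fc_vals > 1.0, "up", "down")
        fc_applied = fc_vals
    else:
        n_up = int(round(spec.pda_up * ec))
        n_dn = int(round(spec.pda_down * ec))
        chosen = rng.choice(ec, size=n_up + n_dn, replace=False)
        raw = spec.draw_foldchanges(n_up + n_dn, rng)
        labels_pert = np.array(["up"] * n_up + ["down"] * n_dn)
        fc_applied = np.where(labels_pert == "up", raw, 1.0 / raw)

    labels = np.full(ec, "null", dtype=object)
    fc = np.ones(ec)
    labels[chosen] = labels_pert
    fc[chosen] = fc_applied

    root = np.sqrt(fc)
    mean1 = profile.abundances / root
    mean2 = profile.abundances * root
    return PerturbedPair(
        mean1=mean1 / mean1.sum(),
        mean2=mean2 / mean2.sum(),
        da_label=np.asarray(labels, dtype=object),
        fc=fc,
        entity_ids=list(profile.entity_ids),
    )


def filter_low_counts(counts, min_count: int = 10):
    """Drop entities whose count is below ``min_count`` in every sample.

    An entity survives if at least one sample reaches the threshold.  The
    relative order of survivors is preserved; attached ground truth is
    subset accordingly.
    """
    from .generators import CountMatrix  # local import to avoid a cycle

    if not isinstance(counts, CountMatrix):
        raise TypeError("filter_low_counts expects a CountMatrix")
    keep = (counts.counts >= min_count).any(axis=1)
    if not keep.any():
        warnings.warn("all entities filtered out; returning an empty matrix")
    return counts.subset_entities(keep)


def _expected_true_positives(qvalues: np.ndarray) -> int:
    """Expected number of truly DA entities: max over ranks k of k*(1 - q_(k))."""
    q = np.sort(qvalues)
    k = np.arange(1, q.size + 1)
    if q.size == 0:
        return 0
    return int(round(np.max(k * (1.0 - q))))


def learn_perturbation_from_data(
    counts1,
    counts2,
    fdr_cutoff: float = 0.05,
    min_count: int = 10,
    seed: int = 0,
) -> PerturbationSpec:
    """Learn an empirical perturbation profile from pilot data.

    Runs the built-in negative-binomial exact test (after mode
    normalization) on the two pilot condition matrices, keeps the observed
    fold-changes of entities passing the FDR cutoff, and augments the list
    with randomly selected failing entities with fold-change > 1.5 (either
    direction) until the list length matches the expected number of truly
    DA entities estimated from the q-value profile.
    """
    from .dat import nb_exact_test
    from .generators import concat_conditions
    from .normalization import mode_normalize

    cm = concat_conditions(counts1, counts2)
    cm = filter_low_counts(cm, min_count=min_count)
    if cm.n_entities == 0:
        warnings.warn("no entities survive the count filter; empty perturbation")
        return PerturbationSpec(fc_dist="empirical", fc_params=[])
    factors = mode_normalize(cm)
    res = nb_exact_test(cm, factors=factors)
    fc = np.power(2.0, res.log2fc)
    passing = res.qvalue <= fdr_cutoff
    d_hat = _expected_true_positives(res.qvalue)
    d_hat = max(d_hat, int(passing.sum()))
    fc_list = list(fc[passing])
    pool = np.flatnonzero(~passing & ((fc > 1.5) | (fc < 1.0 / 1.5)))
    rng = np.random.default_rng(seed)
    need = d_hat - len(fc_list)
    if need > 0 and pool.size:
        extra = rng.choice(pool, size=min(need, pool.size), replace=False)
        fc_list.extend(fc[extra])
    if not fc_list:
        warnings.warn("no differential signal detected; empty perturbation spec")
    return PerturbationSpec(fc_dist="empirical", fc_params=fc_list)
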