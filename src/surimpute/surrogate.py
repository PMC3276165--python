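"""Surrogate-family template selection.

Within a limited genomic region, the reference haplotypes with the fewest
allele differences to a study haplotype are enriched for close genealogical
neighbours.  Ranking candidates by Hamming distance at overlapping typed
SNPs and keeping the nearest k (or k_hap) yields a small custom template
panel per study haplotype; haplotypes tied exactly at the cutoff distance
are resolved by a uniform random draw so that exactly the requested number
of states is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import HaplotypePanel

__all__ = [
    "TemplateSelection",
    "hamming_distance",
    "hamming_distances",
    "select_k_nearest",
    "phasing_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class TemplateSelection:
    """Chosen template haplotype indices and their Hamming distances."""

    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.int64)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must be parallel arrays")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")


def hamming_distance(hap_a, hap_b, mask=None) -> int:
    """Allele differences between two haplotypes at masked (overlap) sites."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    diff = a != b
    if mask is not None:
        diff = diff & np.asarray(mask, dtype=bool)
    return int(diff.sum())


def hamming_distances(query, panel, mask=None) -> np.ndarray:
    """Hamming distance from one query haplotype to every panel haplotype.

    ``panel`` is a HaplotypePanel or a (sites x haplotypes) 0/1 matrix
    restricted to the comparison sites.
    """
    A = panel.alleles if isinstance(panel, HaplotypePanel) else np.asarray(panel)
    q = np.asarray(query).reshape(-1)
    if A.shape[0] != q.shape[0]:
        raise ValueError(f"length mismatch: query {q.shape[0]} vs panel {A.shape[0]}")
    diff = A != q[:, None]
    if mask is not None:
        diff = diff & np.asarray(mask, dtype=bool)[:, None]
    return diff.sum(axis=0).astype(np.int64)


def select_from_distances(distances: np.ndarray, count: int,
                          rng: np.random.Generator) -> TemplateSelection:
    """Pick ``count`` indices with the smallest distances, randomizing ties.

    Every haplotype strictly below the count-th order statistic is always
    included; the remaining slots are filled by a uniform draw from the
    haplotypes exactly at the boundary distance.
    """
    distances = np.asarray(distances, dtype=np.int64)
    n = distances.shape[0]
    if count >= n:
        if count > n:
            logger.warning("requested %d templates but only %d available; clamped",
                           count, n)
        idx = np.arange(n)
        return TemplateSelection(indices=idx, distances=distances)
    cutoff = np.partition(distances, count - 1)[count - 1]
    below = np.flatnonzero(distances < cutoff)
    boundary = np.flatnonzero(distances == cutoff)
    n_from_boundary = count - below.size
    chosen_boundary = rng.choice(boundary, size=n_from_boundary, replace=False)
    idx = np.concatenate([below, np.sort(chosen_boundary)])
    return TemplateSelection(indices=idx, distances=distances[idx])


def select_k_nearest(query, panel, count: int, rng: np.random.Generator,
                     mask=None) -> TemplateSelection:
    """The ``count`` Hamming-nearest panel haplotypes to a query haplotype."""
    if count < 1:
        raise ValueError("count must be positive")
    d = hamming_distances(query, panel, mask=mask)
    return select_from_distances(d, count, rng)


def phasing_candidates(individual: int, study_haps: np.ndarray,
                       reference: HaplotypePanel | np.ndarray, k: int,
                       rng: np.random.Generator, mask=None
                       ) -> TemplateSelection:
    """Template set for one individual's phasing update.

    The candidate pool is all reference haplotypes plus the other study
    individuals' current sampled haplotypes (never the pair being updated).
    For each of the individual's two haplotypes the k/2 nearest candidates
    are taken (boundary ties randomized); the union is topped up from the
    pooled ranking if deduplication leaves fewer than k templates.

    Parameters
    ----------
    individual : index of the individual being updated.
    study_haps : (sites x 2*n_individuals) matrix of current sampled
        haplotypes, columns 2i and 2i+1 belonging to individual i.
    reference : reference haplotypes at the same (typed) sites.

    Returns
    -------
    TemplateSelection with indices into the pooled matrix
    [reference | study_haps-minus-own-pair]; use :func:`candidate_pool` to
    materialize the same pool.
    """
    pool = candidate_pool(individual, study_haps, reference)
    n_pool = pool.shape[1]
    if n_pool <= k:
        d = hamming_distances(study_haps[:, 2 * individual], pool, mask=mask)
        return TemplateSelection(indices=np.arange(n_pool), distances=d)

    half = max(1, k // 2)
    chosen: list[np.ndarray] = []
    dists = []
    for h in (0, 1):
        q = study_haps[:, 2 * individual + h]
        d = hamming_distances(q, pool, mask=mask)
        dists.append(d)
        sel = select_from_distances(d, half, rng)
        chosen.append(sel.indices)
    idx = np.unique(np.concatenate(chosen))
    if idx.size < k:
        # top up from the pooled ranking (min distance over the two queries)
        dmin = np.minimum(dists[0], dists[1])
        dmin_rest = dmin.copy()
        dmin_rest[idx] = np.iinfo(np.int64).max
        extra = select_from_distances(dmin_rest, k - idx.size, rng).indices
        idx = np.unique(np.concatenate([idx, extra]))
    dmin = np.minimum(dists[0], dists[1])
    return TemplateSelection(indices=idx, distances=dmin[idx])


def candidate_pool(individual: int, study_haps: np.ndarray,
                   reference: HaplotypePanel | np.ndarray) -> np.ndarray:
    """Pooled (sites x candidates) matrix: reference then other study haps."""
    R = reference.alleles if isinstance(reference, HaplotypePanel) else np.asarray(reference)
    n_cols = study_haps.shape[1]
    keep = [c for c in range(n_cols) if c not in (2 * individual, 2 * individual + 1)]
    return np.concatenate([R, study_haps[:, keep]], axis=1)
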