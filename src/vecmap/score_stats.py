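"""Alignment significance and retrieval evaluation.

The raw DOT score grows with map size, so database rankings use a
Z-score: the refined best score is standardized against the distribution
of per-rotation best scores from the coarse scan.  Because symmetric
particles (e.g. icosahedral capsids) put a secondary mode into that
distribution, the scores are first clustered by single linkage with a
cutoff of 20% of the score range and only the largest cluster defines
the mean and standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import RigidTransform, search
from .map_io import AtomicModel

__all__ = ["ScoreDistribution", "RetrievalRanking", "zscore",
           "single_linkage_1d", "database_search", "tier_fractions",
           "alcps", "rmsd_of_transform"]

#: single-linkage cutoff as a fraction of (max - min) of the scores
CLUSTER_CUTOFF_FRACTION = 0.2


@dataclass
class ScoreDistribution:
    """Per-rotation best scores from a coarse scan, plus the refined best."""

    per_rotation_best: np.ndarray
    refined_best: float

    def __post_init__(self) -> None:
        self.per_rotation_best = np.asarray(self.per_rotation_best,
                                            dtype=np.float64).reshape(-1)
        if self.refined_best < self.per_rotation_best.max() - 1e-6:
            raise ValueError("refined best cannot fall below the coarse best")


@dataclass
class RetrievalRanking:
    """Z-score ranking of database targets against one query map."""

    query_id: str
    entries: list = field(default_factory=list)   # (target_id, zscore), sorted
    class_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        zs = [z for _, z in self.entries]
        if any(later > earlier + 1e-9 for later, earlier in zip(zs[1:], zs)):
            raise ValueError("entries must be sorted by non-increasing Z-score")


def single_linkage_1d(values: np.ndarray, cutoff: float) -> list[np.ndarray]:
    """Single-linkage clusters of scalars: sorted runs split at gaps > cutoff.

    Equivalent to cutting the single-linkage dendrogram on the line at the
    given height, in O(n log n).  Clusters are returned in ascending order
    of their members.
    """
    values = np.sort(np.asarray(values, dtype=np.float64))
    if len(values) == 0:
        return []
    splits = np.where(np.diff(values) > cutoff)[0] + 1
    return np.split(values, splits)


def zscore(dist: ScoreDistribution) -> float:
    """Clustered Z-score of the refined best score.

    Single-linkage clusters of the per-rotation best scores are formed
    with a cutoff of 20% of (max - min); the mean and (population)
    standard deviation of the largest cluster standardize the refined
    best score.  When cluster sizes tie, the cluster with the smaller
    minimum is used (the conservative null).  Raises on fewer than three
    rotations or zero variance.
    """
    scores = dist.per_rotation_best
    if len(scores) < 3:
        raise ValueError("need at least three per-rotation scores")
    cutoff = CLUSTER_CUTOFF_FRACTION * (scores.max() - scores.min())
    clusters = single_linkage_1d(scores, cutoff)
    # ascending order => first maximal cluster has the smallest minimum
    largest = max(clusters, key=len)
    sd = float(largest.std())
    if sd <= 0:
        raise ValueError("zero variance in the score distribution; Z undefined")
    return (dist.refined_best - float(largest.mean())) / sd


def database_search(query, targets: dict, query_id: str = "query",
                    class_labels: dict | None = None, **search_params
                    ) -> RetrievalRanking:
    """Rank database maps against a query by the Z-score of the best score.

    Parameters
    ----------
    query
        Preprocessed query map (``DensityGrid`` or ``VectorField``).
    targets
        Mapping of target id to preprocessed map; all maps must share the
        query's preprocessing parameters.
    class_labels
        Optional mapping of map id to class label for tier evaluation.
    search_params
        Forwarded to :func:`vecmap.align.search` (interval, score, ...).

    Ties in Z-score break deterministically by target id.
    """
    if not targets:
        raise ValueError("empty target list")
    scored = []
    for target_id in sorted(targets):
        _, dist = search(targets[target_id], query, full_output=True,
                         **search_params)
        scored.append((target_id, zscore(dist)))
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RetrievalRanking(query_id=query_id, entries=scored,
                            class_labels=dict(class_labels or {}))


def tier_fractions(ranking: RetrievalRanking) -> tuple[int, float, float]:
    """Top-hit flag and first/second-tier retrieval fractions.

    With m same-class targets in the ranked list (the query itself
    excluded), the first tier is the fraction of them found within the
    top m ranks and the second tier within the top 2m.  Returns
    ``(0, 0.0, 0.0)`` when no same-class target is present.
    """
    labels = ranking.class_labels
    if ranking.query_id not in labels:
        raise ValueError("query class label unknown")
    qclass = labels[ranking.query_id]
    same = [i for i, (tid, _) in enumerate(ranking.entries)
            if labels.get(tid) == qclass]
    m = len(same)
    if m == 0:
        return 0, 0.0, 0.0
    top_hit = int(len(ranking.entries) > 0 and
                  labels.get(ranking.entries[0][0]) == qclass)
    first = sum(1 for i in same if i < m) / m
    second = sum(1 for i in same if i < 2 * m) / m
    return top_hit, first, second


def alcps(r: float, theta: float) -> float:
    """Arc-length-based pose deviation: 2 pi r theta / 360.

    ``r`` is the translational offset (Angstrom) and ``theta`` the
    rotation angle (degrees) from the reference superposition.
    """
    if r < 0:
        raise ValueError("translation offset must be non-negative")
    if not (0 <= theta <= 360):
        raise ValueError("rotation angle must be in [0, 360] degrees")
    return 2.0 * math.pi * r * theta / 360.0


def rmsd_of_transform(model: AtomicModel, found: RigidTransform,
                      reference) -> float:
    """RMSD between a model placed by two rigid transforms.

    Both transforms are applied to every atom; the root-mean-square
    coordinate deviation is returned, minimized over the supplied
    reference transform(s) (a list accommodates symmetry-equivalent
    references).  No re-superposition is performed.
    """
    refs = reference if isinstance(reference, (list, tuple)) else [reference]
    if not refs:
        raise ValueError("at least one reference transform required")
    p_found = found.apply(model.positions)
    best = math.inf
    for ref_t in refs:
        d = p_found - ref_t.apply(model.positions)
        best = min(best, math.sqrt(float(np.mean(np.sum(d * d, axis=1)))))
    return best
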