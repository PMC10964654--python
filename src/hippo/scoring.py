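"""Scoring poses with a histogram set and evaluating enrichment.

The score of a pose is linear in its contacts: every bead-bead distance
falling in a refined range of pair (i, j) contributes that range's
log-odds value, summed over the per-stratum parts of the histogram and
over all pairs,

    S_pose = sum_i sum_j R_ij . H_ij^T

with R_ij the per-range contact counts of the pose.  Pools are ranked by
descending score; enrichment is measured as the fraction of all
near-native poses captured in the top fraction of the ranking.  A single
potential is successful on a case when it captures at least 60% of the
near-natives within the top 5%; a collection of potentials is applied by
pooling each member's top-ranked poses into a consensus selection (TopC)
of 20% of the pool, and is successful/very successful when TopC holds at
least 60%/80% of the near-natives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ScoringError
from .pose_pool import LABEL_NEAR, PosePool
from .potential import HistogramSet

logger = logging.getLogger(__name__)

SUCCESS_CUT = 0.60
VERY_SUCCESS_CUT = 0.80


@dataclass
class ScoredPool:
    """A ranked pool: ``order[r]`` is the pool index of the rank-r pose."""

    case_id: str
    scores: np.ndarray  # aligned with the pool's pose order
    order: np.ndarray  # pose indices sorted best-first

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ScoringError("non-finite pose scores")
        if sorted(self.order) != list(range(len(self.scores))):
            raise ScoringError("order is not a permutation of the pool")

    def top(self, fraction: float) -> np.ndarray:
        return self.order[: int(len(self.order) * fraction)]


@dataclass
class EnrichmentReport:
    """Near-native capture of a top-fraction selection."""

    fraction_selected: float
    n_selected: int
    n_near_native: int
    n_captured: int
    near_native_capture: float
    enrichment_factor: float
    success: bool
    very_success: bool


@dataclass
class TopC:
    """Consensus selection pooled from several rankings."""

    selected: np.ndarray  # pose indices, best contributing rank first
    member: np.ndarray  # which ranking contributed each pose
    member_rank: np.ndarray  # the contributing (best) rank of each pose
    n_total: int


def _check_types(receptor, fragment_types, h: HistogramSet) -> None:
    n_i, n_j = h.table_shape
    if receptor.type_indices.max(initial=0) > n_i or int(
        np.max(fragment_types, initial=0)
    ) > n_j:
        raise ScoringError(
            "bead type index exceeds the potential's typing table shape; "
            "receptor/fragment were coarse-grained with a different table"
        )


def score_pose(
    receptor,
    fragment_coords: np.ndarray,
    fragment_types: np.ndarray,
    h: HistogramSet,
) -> float:
    """Score one pose by direct per-pair accumulation.

    Reference implementation: loops over the pairs of the histogram set
    and bins the pose's distances into each pair's refined edges, per
    stratum part.  Pairs absent from H contribute nothing.
    """
    _check_types(receptor, fragment_types, h)
    from scipy.spatial.distance import cdist

    d = cdist(receptor.coords, np.asarray(fragment_coords, dtype=float))
    i_types = receptor.type_indices
    j_types = np.asarray(fragment_types)
    score = 0.0
    for (i, j), hist in h.histograms.items():
        sub = d[np.ix_(i_types == i, j_types == j)]
        if sub.size == 0:
            continue
        flat = sub.ravel()
        for part in hist.parts:
            if part is None:
                continue
            score += float(part.value_at(flat).sum())
    return score


def _value_table(pool: PosePool, h: HistogramSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-bead-pair, per-base-bin score contributions (strata pre-summed).

    Refined ranges are coarsenings of the base range set, so the summed
    per-stratum potential can be expanded onto the base bins once and
    looked up per contact.
    """
    n_bins = len(h.ranges)
    base_edges = h.ranges.edge_array
    mids = np.empty(n_bins)
    mids[:-1] = (base_edges[:-2] + base_edges[1:-1]) / 2
    mids[0] = base_edges[1] / 2
    mids[-1] = base_edges[-2] + 1.0  # representative point inside the overflow bin
    i_types = pool.receptor.type_indices
    j_types = pool.fragment_types
    pair_key = (i_types[:, None] * 1000 + j_types[None, :]).ravel()
    uniq_keys, slot = np.unique(pair_key, return_inverse=True)
    table = np.zeros((len(uniq_keys), n_bins))
    for row, key in enumerate(uniq_keys):
        pair = (int(key // 1000), int(key % 1000))
        hist = h.histograms.get(pair)
        if hist is None:
            continue
        for part in hist.parts:
            if part is not None:
                table[row] += part.value_at(mids)
    return table, slot


def score_pool(pool: PosePool, h: HistogramSet, chunk: int = 1024) -> np.ndarray:
    """Vectorised scores for every pose of a pool (same result as score_pose)."""
    _check_types(pool.receptor, pool.fragment_types, h)
    table, slot = _value_table(pool, h)
    n_bins = len(h.ranges)
    edge = h.ranges.edge_array
    flat_table = table.ravel()
    rec_coords = pool.receptor.coords
    scores = np.empty(len(pool))
    coords = pool.coords
    for start in range(0, len(pool), chunk):
        block = coords[start : start + chunk]
        diff = block[:, None, :, :] - rec_coords[None, :, None, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))  # (P, n_rec, n_frag)
        bins = np.clip(np.searchsorted(edge, d, side="left") - 1, 0, n_bins - 1)
        idx = slot[None, :] * n_bins + bins.reshape(len(block), -1)
        scores[start : start + len(block)] = flat_table[idx].sum(axis=1)
    return scores


def rank_pool(pool: PosePool, h: HistogramSet) -> ScoredPool:
    """Stable descending sort by score; ties broken by original rank, then pose id."""
    scores = score_pool(pool, h)
    ranks = pool.ranks.astype(float)
    ranks[ranks < 0] = np.inf  # unranked poses last among ties
    pose_pos = np.arange(len(pool))
    order = np.lexsort((pose_pos, ranks, -scores))
    return ScoredPool(case_id=pool.case_id, scores=scores, order=order)


def evaluate_selection(
    selected: ScoredPool | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    fraction: float,
    n_total: int | None = None,
) -> EnrichmentReport:
    """Near-native capture of the top ``fraction`` of a ranking.

    ``selected`` may be a ScoredPool (the top slice is taken here) or an
    explicit array of selected pose indices (e.g. a TopC selection, with
    ``n_total`` giving the pool size).
    """
    labels = np.asarray(labels)
    near = labels == LABEL_NEAR
    n_near = int(near.sum())
    if n_near == 0:
        raise ScoringError("pool has no near-native pose (sampling problem)")
    if isinstance(selected, ScoredPool):
        n_total = len(selected.scores)
        chosen = selected.order[: int(n_total * fraction)]
    else:
        chosen = np.asarray(selected)
        if n_total is None:
            raise ScoringError("n_total required with an explicit selection")
    n_captured = int(near[chosen].sum())
    capture = n_captured / n_near
    return EnrichmentReport(
        fraction_selected=fraction,
        n_selected=len(chosen),
        n_near_native=n_near,
        n_captured=n_captured,
        near_native_capture=capture,
        enrichment_factor=capture / fraction if fraction > 0 else np.nan,
        success=capture >= SUCCESS_CUT,
        very_success=capture >= VERY_SUCCESS_CUT,
    )


def pool_topC(
    rankings: Sequence[ScoredPool | np.ndarray],
    target_fraction: float = 0.20,
) -> TopC:
    """Pool several rankings into a consensus selection of unique poses.

    The rankings are merged round-robin in rank order (rank 0 of every
    ranking, then rank 1, ...); a pose already selected by an earlier
    ranking keeps its first (best) contributing rank.  Exactly
    ``floor(target_fraction * N)`` unique poses are returned.
    """
    if len(rankings) != 4:
        logger.warning("pooling %d rankings (reference protocol uses 4)", len(rankings))
    orders = [
        r.order if isinstance(r, ScoredPool) else np.asarray(r) for r in rankings
    ]
    n = len(orders[0])
    for o in orders:
        if len(o) != n:
            raise ScoringError("rankings cover different pose universes")
    n_select = int(n * target_fraction)
    interleaved = np.stack(orders, axis=1).ravel()  # rank-major round-robin
    _, first_idx = np.unique(interleaved, return_index=True)
    first_idx.sort()
    first_idx = first_idx[:n_select]
    return TopC(
        selected=interleaved[first_idx],
        member=(first_idx % len(orders)).astype(np.int64),
        member_rank=(first_idx // len(orders)).astype(np.int64),
        n_total=n,
    )


def evaluate_collection(
    pool: PosePool,
    collection: Sequence[HistogramSet],
    target_fraction: float = 0.20,
) -> tuple[EnrichmentReport, TopC]:
    """Rank a pool with every member potential, pool into TopC, and evaluate."""
    rankings = [rank_pool(pool, h) for h in collection]
    topc = pool_topC(rankings, target_fraction=target_fraction)
    report = evaluate_selection(
        topc.selected, pool.labels, fraction=target_fraction, n_total=topc.n_total
    )
    return report, topc


@dataclass
class ComplexSummary:
    """Best-fragment capture per complex and threshold pass rates."""

    best_capture: dict[str, float]
    fraction_success: float
    fraction_very_success: float


def per_complex_best(
    reports: Mapping[str, EnrichmentReport | float],
    complex_of: Mapping[str, str] | None = None,
) -> ComplexSummary:
    """Group case reports by complex and take the best capture per complex.

    ``complex_of`` maps case id to complex id; by default the case id's
    prefix before the first '-' is used.
    """
    best: dict[str, float] = {}
    for case_id, rep in reports.items():
        capture = rep.near_native_capture if isinstance(rep, EnrichmentReport) else float(rep)
        cx = complex_of[case_id] if complex_of else case_id.split("-")[0]
        best[cx] = max(best.get(cx, 0.0), capture)
    values = np.array(list(best.values()))
    return ComplexSummary(
        best_capture=best,
        fraction_success=float(np.mean(values >= SUCCESS_CUT)),
        fraction_very_success=float(np.mean(values >= VERY_SUCCESS_CUT)),
    )
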