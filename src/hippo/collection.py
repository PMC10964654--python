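"""Building a consensus collection of potentials and homology-aware splits.

A single contact potential rarely covers the diversity of protein-ssRNA
binding modes, so one potential is derived per training case, every case
is cross-scored with every candidate, and the N candidates (default 4)
whose successes jointly cover the most cases form the collection; cases
covered by no member are outliers.  Training/test splits are built
leave-homology-out: a random seed complex plus every complex whose
protein sequence similarity exceeds the threshold (default 40%) form a
test set, the remainder the training set, iterating until every complex
has served in a test set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import HippoError, PotentialError
from .pose_pool import PosePool
from .potential import HistogramSet, RangeSet, RankStrata, derive_histogram_set
from .scoring import SUCCESS_CUT, evaluate_selection, rank_pool

logger = logging.getLogger(__name__)

#: largest number of candidate subsets enumerated exhaustively
EXHAUSTIVE_LIMIT = 1_000_000


@dataclass
class SuccessMatrix:
    """Rows: candidate potentials; columns: cases; entry = candidate succeeds on case."""

    candidate_ids: list[str]
    case_ids: list[str]
    capture: np.ndarray  # (n_candidates, n_cases) float
    success: np.ndarray  # boolean, same shape
    fraction: float = 0.05
    success_cut: float = SUCCESS_CUT

    def __post_init__(self) -> None:
        expected = (len(self.candidate_ids), len(self.case_ids))
        if self.capture.shape != expected or self.success.shape != expected:
            raise HippoError("success-matrix shape mismatch")


@dataclass
class Collection:
    """The selected member potentials plus the coverage they achieve."""

    members: list[HistogramSet]
    member_ids: list[str]
    covered_cases: list[str]
    outliers: list[str]
    method: str = "exhaustive"  # or "greedy"


@dataclass
class HomologySplit:
    """Series of (training ids, test ids) pairs from a leave-homology-out sweep."""

    pairs: list[tuple[list[str], list[str]]]
    threshold: float
    degenerate: list[int] = field(default_factory=list)  # pairs with empty training


def build_success_matrix(
    cases: Sequence[PosePool],
    fraction: float = 0.05,
    success_cut: float = SUCCESS_CUT,
    ranges: RangeSet | None = None,
    strata: RankStrata | None = None,
    min_near: int = 100,
    candidates: Mapping[str, HistogramSet] | None = None,
) -> tuple[SuccessMatrix, dict[str, HistogramSet]]:
    """Derive one candidate potential per case and cross-score all cases.

    Entry (h, c) holds the fraction of case c's near-natives that the
    candidate derived from case h places in its top ``fraction``; the
    boolean matrix thresholds it at ``success_cut``.  Degenerate candidates
    yield an all-False row.  Pre-derived ``candidates`` may be supplied.
    """
    if candidates is None:
        candidates = {}
        for case in cases:
            try:
                candidates[case.case_id] = derive_histogram_set(
                    case, ranges=ranges, strata=strata, min_near=min_near
                )
            except PotentialError as exc:
                logger.warning("candidate for %s unusable: %s", case.case_id, exc)
    candidate_ids = list(candidates)
    capture = np.zeros((len(candidate_ids), len(cases)))
    for col, case in enumerate(cases):
        for row, cid in enumerate(candidate_ids):
            scored = rank_pool(case, candidates[cid])
            rep = evaluate_selection(scored, case.labels, fraction=fraction)
            capture[row, col] = rep.near_native_capture
    matrix = SuccessMatrix(
        candidate_ids=candidate_ids,
        case_ids=[c.case_id for c in cases],
        capture=capture,
        success=capture >= success_cut,
        fraction=fraction,
        success_cut=success_cut,
    )
    return matrix, candidates


def _coverage(success: np.ndarray, rows: Sequence[int]) -> int:
    return int(np.any(success[list(rows)], axis=0).sum())


def select_collection(
    matrix: SuccessMatrix,
    n: int = 4,
    candidates: Mapping[str, HistogramSet] | None = None,
) -> Collection:
    """Pick the n candidates whose successes cover the most cases.

    All C(M, n) subsets are enumerated when that count stays within
    EXHAUSTIVE_LIMIT; otherwise greedy max-coverage is used (flagged in the
    result).  Coverage ties break by larger summed capture over covered
    cases, then by lexicographic candidate ids.
    """
    m = len(matrix.candidate_ids)
    if m == 0:
        raise HippoError("empty success matrix")
    n = min(n, m)
    success = matrix.success

    def tie_key(rows: tuple[int, ...]):
        covered = np.any(success[list(rows)], axis=0)
        gain = float(matrix.capture[list(rows)][:, covered].max(axis=0).sum()) if covered.any() else 0.0
        ids = tuple(sorted(matrix.candidate_ids[r] for r in rows))
        return (-int(covered.sum()), -gain, ids)

    if math.comb(m, n) <= EXHAUSTIVE_LIMIT:
        best = min(itertools.combinations(range(m), n), key=tie_key)
        method = "exhaustive"
    else:
        chosen: list[int] = []
        covered = np.zeros(len(matrix.case_ids), dtype=bool)
        for _ in range(n):
            remaining = [r for r in range(m) if r not in chosen]
            best_row = min(
                remaining,
                key=lambda r: (
                    -int((success[r] & ~covered).sum()),
                    -float(matrix.capture[r][success[r] & ~covered].sum()),
                    matrix.candidate_ids[r],
                ),
            )
            chosen.append(best_row)
            covered |= success[best_row]
        best = tuple(chosen)
        method = "greedy"
        logger.warning("select_collection fell back to greedy max-coverage")

    covered = np.any(success[list(best)], axis=0)
    member_ids = [matrix.candidate_ids[r] for r in best]
    members = [candidates[cid] for cid in member_ids] if candidates else []
    return Collection(
        members=members,
        member_ids=member_ids,
        covered_cases=[c for c, ok in zip(matrix.case_ids, covered) if ok],
        outliers=[c for c, ok in zip(matrix.case_ids, covered) if not ok],
        method=method,
    )


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns / alignment length."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def leave_homology_out_split(
    complexes: Mapping[str, str],
    similarity_fn: Callable[[str, str], float] = sequence_identity,
    threshold: float = 0.40,
    seed: int = 0,
) -> HomologySplit:
    """Iteratively carve test sets of mutually homologous complexes.

    Each iteration draws a random complex never used in a previous test
    set; that complex plus every complex with similarity above the
    threshold forms a test set, all other complexes the training set.
    Iteration stops when every complex has appeared in a test set.  Pairs
    whose training side comes out empty are flagged degenerate.
    """
    ids = list(complexes)
    rng = np.random.default_rng(seed)
    n = len(ids)
    sim = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            s = similarity_fn(complexes[ids[a]], complexes[ids[b]])
            sim[a, b] = sim[b, a] = s
    tested = np.zeros(n, dtype=bool)
    pairs: list[tuple[list[str], list[str]]] = []
    degenerate: list[int] = []
    while not tested.all():
        candidates = np.nonzero(~tested)[0]
        pick = int(rng.choice(candidates))
        test_mask = sim[pick] > threshold
        test_mask[pick] = True
        test = [ids[k] for k in np.nonzero(test_mask)[0]]
        train = [ids[k] for k in np.nonzero(~test_mask)[0]]
        if not train:
            degenerate.append(len(pairs))
            logger.warning("split %d: empty training set (one homology cluster)", len(pairs))
        pairs.append((train, test))
        tested |= test_mask
    return HomologySplit(pairs=pairs, threshold=threshold, degenerate=degenerate)
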