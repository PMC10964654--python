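"""Distance arrays and the log-odds contact potential.

For each bead-type pair (i, j), the distances between every protein bead
of type i and RNA bead of type j are counted over a labelled decoy pool,
separately for near-native and non-native poses (intermediates are
ignored) and separately for three rank-based sub-pools.  Distances are
binned into 27 right-closed ranges: (0, 2], 0.25-A steps over (2, 7],
1.5-A steps over (7, 14.5], and an overflow range (14.5, inf).

Bins whose near-native count falls below the pair's signal threshold
w_ij = A_ij / 60 (A_ij = total near-native count) are merged downwards
with their successors until the merged count reaches the threshold; a
trailing remainder that cannot reach it is folded back into the previous
refined bin.  The potential value of each refined bin x is the centred
log odds ratio

    H_ij[x] = ln d*_x1 - ln d*_x2 - (ln A_ij - ln B_ij)

with d*_x1 / d*_x2 the refined near-/non-native counts and B_ij the
total non-native count.  A zero non-native count is replaced by a
pseudocount of 1 before taking the logarithm.  The histogram set H maps
every (i, j) pair present in the pool to its per-stratum potential.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import PoolError, PotentialError
from .pose_pool import LABEL_NEAR, LABEL_NON, PosePool, filter_sampling_problem

logger = logging.getLogger(__name__)

NEAR_COL = 0
NON_COL = 1

#: divisor of the near-native total that defines the per-pair signal threshold
SIGNAL_DIVISOR = 60.0


@dataclass(frozen=True)
class RangeSet:
    """Ordered right-closed distance bins (a, b] partitioning (0, inf)."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise PotentialError("edges must be strictly increasing")
        if e[0] != 0.0 or not math.isinf(e[-1]):
            raise PotentialError("edges must start at 0 and end at inf")

    def __len__(self) -> int:
        return len(self.edges) - 1

    @property
    def edge_array(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=float)

    def bin_of(self, distances) -> np.ndarray:
        """Bin index for each distance; bins are right-closed, d=0 maps to bin 0."""
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.edge_array, d, side="left") - 1
        return np.clip(idx, 0, len(self) - 1)

    def interval(self, k: int) -> tuple[float, float]:
        return (self.edges[k], self.edges[k + 1])


def make_range_set(
    fine_step: float = 0.25,
    coarse_step: float = 1.5,
    fine_interval: tuple[float, float] = (2.0, 7.0),
    coarse_interval: tuple[float, float] = (7.0, 14.5),
) -> RangeSet:
    """Two-resolution discretisation plus underflow and overflow bins.

    Defaults give 27 bins: (0, 2], twenty 0.25-A bins over (2, 7], five
    1.5-A bins over (7, 14.5], and (14.5, inf).
    """
    if fine_interval[0] <= 0 or fine_interval[1] != coarse_interval[0]:
        raise PotentialError("fine and coarse intervals must be contiguous and positive")
    edges = [0.0]
    for (lo, hi), step in ((fine_interval, fine_step), (coarse_interval, coarse_step)):
        n = (hi - lo) / step
        if abs(n - round(n)) > 1e-9:
            raise PotentialError(f"step {step} does not divide interval ({lo}, {hi}]")
        edges.extend(lo + step * k for k in range(int(round(n))))
    edges.append(coarse_interval[1])
    edges.append(math.inf)
    return RangeSet(tuple(edges))


@dataclass(frozen=True)
class RankStrata:
    """Half-open rank intervals [b0, b1), [b1, b2), ... covering the pool."""

    bounds: tuple[int, ...] = (0, 100_000, 1_000_000, 10_000_000)

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds)
        if len(b) < 2 or np.any(np.diff(b) <= 0) or b[0] != 0:
            raise PotentialError(f"invalid strata bounds {self.bounds}")

    @property
    def n_strata(self) -> int:
        return len(self.bounds) - 1

    def stratum_of(self, ranks) -> np.ndarray:
        r = np.asarray(ranks)
        if np.any(r < 0) or np.any(r >= self.bounds[-1]):
            raise PotentialError("rank outside the strata cover")
        return np.searchsorted(np.asarray(self.bounds), r, side="right") - 1

    @classmethod
    def scaled(cls, pool_size: int, n_strata: int = 3) -> "RankStrata":
        """Strata proportional to the reference 1% / 9% / 90% split of a
        10^7-pose pool, scaled down to ``pool_size`` ranks."""
        if pool_size < n_strata:
            return cls(tuple(range(pool_size + 1)) if pool_size else (0, 1))
        bounds = [0]
        for frac in (0.01, 0.1):
            b = max(bounds[-1] + 1, int(round(pool_size * frac)))
            bounds.append(b)
        bounds.append(max(bounds[-1] + 1, pool_size))
        return cls(tuple(bounds[: n_strata + 1]))


@dataclass
class DistanceArray:
    """Per-(i, j) binned distance counts, near vs non-native, per stratum."""

    pair: tuple[int, int]
    ranges: RangeSet
    strata: RankStrata
    counts: np.ndarray  # (n_strata, n_bins, 2) integer counts

    def __post_init__(self) -> None:
        expected = (self.strata.n_strata, len(self.ranges), 2)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != expected:
            raise PotentialError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise PotentialError("negative counts")

    @property
    def A(self) -> np.ndarray:
        """Total near-native count per stratum."""
        return self.counts[:, :, NEAR_COL].sum(axis=1)

    @property
    def B(self) -> np.ndarray:
        """Total non-native count per stratum."""
        return self.counts[:, :, NON_COL].sum(axis=1)

    @property
    def w(self) -> np.ndarray:
        """Per-stratum signal threshold A / 60."""
        return self.A / SIGNAL_DIVISOR


@dataclass
class RefinedPart:
    """One stratum of a refined distance array."""

    edges: np.ndarray  # merged bin edges, length q + 1
    counts: np.ndarray  # (q, 2)
    A: int
    B: int
    w: float
    usable: bool = True


@dataclass
class RefinedDistanceArray:
    pair: tuple[int, int]
    parts: list[RefinedPart]

    @property
    def usable(self) -> bool:
        return any(p.usable for p in self.parts)


@dataclass
class HistogramPart:
    edges: np.ndarray  # length q + 1
    values: np.ndarray  # length q
    A: int
    B: int
    w: float

    def value_at(self, distances) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, d, side="left") - 1, 0, len(self.values) - 1)
        return self.values[idx]


@dataclass
class Histogram:
    """Per-pair log-odds potential; one part per rank stratum (None if unusable)."""

    pair: tuple[int, int]
    parts: list[HistogramPart | None]


class HistogramSet:
    """The scoring parameter set H: (i, j) -> Histogram for all observed pairs."""

    def __init__(
        self,
        case_id: str,
        ranges: RangeSet,
        strata: RankStrata,
        histograms: Mapping[tuple[int, int], Histogram],
        table_shape: tuple[int, int] = (31, 17),
    ) -> None:
        if not histograms:
            raise PotentialError("empty histogram set")
        self.case_id = case_id
        self.ranges = ranges
        self.strata = strata
        self.histograms = dict(histograms)
        self.table_shape = tuple(table_shape)

    def __len__(self) -> int:
        return len(self.histograms)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.histograms

    def __getitem__(self, pair) -> Histogram:
        return self.histograms[tuple(pair)]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.histograms)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def _edges(e: np.ndarray) -> list:
            return [None if math.isinf(x) else float(x) for x in e]

        return {
            "case_id": self.case_id,
            "table_shape": list(self.table_shape),
            "ranges": _edges(self.ranges.edge_array),
            "strata": list(self.strata.bounds),
            "pairs": [
                {
                    "i": i,
                    "j": j,
                    "parts": [
                        None
                        if p is None
                        else {
                            "edges": _edges(p.edges),
                            "values": [float(v) for v in p.values],
                            "A": int(p.A),
                            "B": int(p.B),
                            "w": float(p.w),
                        }
                        for p in h.parts
                    ],
                }
                for (i, j), h in sorted(self.histograms.items())
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "HistogramSet":
        def _edges(seq) -> np.ndarray:
            return np.array([math.inf if x is None else x for x in seq], dtype=float)

        histograms = {}
        for entry in raw["pairs"]:
            pair = (int(entry["i"]), int(entry["j"]))
            parts: list[HistogramPart | None] = []
            for p in entry["parts"]:
                if p is None:
                    parts.append(None)
                else:
                    parts.append(
                        HistogramPart(
                            edges=_edges(p["edges"]),
                            values=np.array(p["values"], dtype=float),
                            A=int(p["A"]),
                            B=int(p["B"]),
                            w=float(p["w"]),
                        )
                    )
            histograms[pair] = Histogram(pair, parts)
        return cls(
            case_id=raw["case_id"],
            ranges=RangeSet(tuple(_edges(raw["ranges"]))),
            strata=RankStrata(tuple(int(b) for b in raw["strata"])),
            histograms=histograms,
            table_shape=tuple(raw.get("table_shape", (31, 17))),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "HistogramSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# building

def _pool_count_tensor(
    pool: PosePool, ranges: RangeSet, strata: RankStrata, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Count all typed bead-pair distances of a labelled, ranked pool.

    Returns (pairs, counts, pair_slot) where ``pairs`` is the (n_pairs, 2)
    array of observed (i, j) combinations, ``counts`` has shape
    (n_pairs, n_strata, n_bins, 2) and ``pair_slot`` maps each flattened
    receptor x fragment bead pair to its row in ``pairs``.
    """
    labels = pool.labels
    use = (labels == LABEL_NEAR) | (labels == LABEL_NON)
    if not np.any(use):
        raise PotentialError(f"case {pool.case_id}: no near-/non-native pose")
    ranks = pool.ranks
    if np.any(ranks[use] < 0):
        raise PoolError(f"case {pool.case_id}: pool must be ranked")
    cols = np.where(labels == LABEL_NEAR, NEAR_COL, NON_COL)
    stratum = strata.stratum_of(np.where(use, ranks, 0))

    rec = pool.receptor
    i_types = rec.type_indices
    j_types = pool.fragment_types
    # enumerate observed (i, j) combinations and map every bead pair to a slot
    pair_key = (i_types[:, None] * 1000 + j_types[None, :]).ravel()
    uniq_keys, pair_slot = np.unique(pair_key, return_inverse=True)
    pairs = np.stack([uniq_keys // 1000, uniq_keys % 1000], axis=1)
    n_pairs, n_bins, n_strata = len(uniq_keys), len(ranges), strata.n_strata

    counts = np.zeros((n_strata, 2, n_pairs * n_bins), dtype=np.int64)
    idx_use = np.nonzero(use)[0]
    all_coords = pool.coords
    rec_coords = rec.coords
    edge = ranges.edge_array
    for start in range(0, len(idx_use), chunk):
        sel = idx_use[start : start + chunk]
        block = all_coords[sel]  # (P, n_frag, 3)
        diff = block[:, None, :, :] - rec_coords[None, :, None, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))  # (P, n_rec, n_frag)
        bins = np.clip(np.searchsorted(edge, d, side="left") - 1, 0, n_bins - 1)
        flat = pair_slot[None, :] * n_bins + bins.reshape(len(sel), -1)
        for s in range(n_strata):
            for c in (NEAR_COL, NON_COL):
                mask = (stratum[sel] == s) & (cols[sel] == c)
                if np.any(mask):
                    counts[s, c] += np.bincount(
                        flat[mask].ravel(), minlength=n_pairs * n_bins
                    )
    counts = counts.reshape(n_strata, 2, n_pairs, n_bins)
    counts = np.transpose(counts, (2, 0, 3, 1))  # (n_pairs, n_strata, n_bins, 2)
    return pairs, counts, pair_slot


def build_distance_array(
    pool: PosePool,
    pair: tuple[int, int],
    ranges: RangeSet | None = None,
    strata: RankStrata | None = None,
) -> DistanceArray:
    """Distance array for a single (i, j) pair, counted over the whole pool."""
    ranges = ranges or make_range_set()
    strata = strata or RankStrata.scaled(len(pool))
    pairs, counts, _ = _pool_count_tensor(pool, ranges, strata)
    match = np.nonzero((pairs[:, 0] == pair[0]) & (pairs[:, 1] == pair[1]))[0]
    if len(match):
        c = counts[match[0]]
    else:
        c = np.zeros((strata.n_strata, len(ranges), 2), dtype=np.int64)
    return DistanceArray(pair=tuple(pair), ranges=ranges, strata=strata, counts=c)


def _refine_part(
    counts: np.ndarray, edges: np.ndarray, w: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge bins downwards until every near-native count reaches ``w``.

    Scans top-down accumulating rows; a row whose near-native count already
    meets the threshold flushes immediately, so well-populated rows pass
    through unchanged.  A trailing remainder below the threshold is folded
    back into the last flushed row (extending its upper edge), which keeps
    the merge loop terminating while conserving both column sums.
    """
    out_rows: list[np.ndarray] = []
    out_edges: list[float] = [edges[0]]
    acc = np.zeros(2, dtype=np.int64)
    for k in range(len(counts)):
        acc = acc + counts[k]
        if acc[NEAR_COL] >= w:
            out_rows.append(acc)
            out_edges.append(edges[k + 1])
            acc = np.zeros(2, dtype=np.int64)
    if not out_rows:
        # total below threshold: impossible for w = A/60 unless A == 0
        raise PotentialError("refinement produced no rows")
    if np.any(acc != 0) or out_edges[-1] != edges[-1]:
        out_rows[-1] = out_rows[-1] + acc
        out_edges[-1] = edges[-1]
    return np.stack(out_rows), np.array(out_edges, dtype=float)


def refine_distance_array(d: DistanceArray) -> RefinedDistanceArray:
    """Refine every stratum of a distance array against its threshold w = A/60."""
    parts: list[RefinedPart] = []
    edges = d.ranges.edge_array
    for s in range(d.strata.n_strata):
        counts = d.counts[s]
        A = int(counts[:, NEAR_COL].sum())
        B = int(counts[:, NON_COL].sum())
        w = A / SIGNAL_DIVISOR
        if A == 0:
            # degenerate: no near-native signal in this stratum
            parts.append(
                RefinedPart(
                    edges=np.array([edges[0], edges[-1]]),
                    counts=counts.sum(axis=0, keepdims=True),
                    A=A,
                    B=B,
                    w=w,
                    usable=False,
                )
            )
            continue
        rows, merged_edges = _refine_part(counts, edges, w)
        parts.append(RefinedPart(edges=merged_edges, counts=rows, A=A, B=B, w=w))
    return RefinedDistanceArray(pair=d.pair, parts=parts)


def derive_histogram(refined: RefinedDistanceArray) -> Histogram:
    """Centred log-odds values for every usable stratum part.

    A part also needs non-native mass (B > 0); zero non-native counts in
    individual refined rows are replaced by a pseudocount of 1.
    """
    parts: list[HistogramPart | None] = []
    for p in refined.parts:
        if not p.usable or p.A == 0 or p.B == 0:
            parts.append(None)
            continue
        d1 = p.counts[:, NEAR_COL].astype(float)
        d2 = np.maximum(p.counts[:, NON_COL].astype(float), 1.0)
        values = np.log(d1) - np.log(d2) - (math.log(p.A) - math.log(p.B))
        if not np.all(np.isfinite(values)):
            raise PotentialError(f"non-finite histogram values for pair {refined.pair}")
        parts.append(
            HistogramPart(edges=p.edges, values=values, A=p.A, B=p.B, w=p.w)
        )
    return Histogram(pair=refined.pair, parts=parts)


def derive_histogram_set(
    pool: PosePool,
    ranges: RangeSet | None = None,
    strata: RankStrata | None = None,
    min_near: int = 100,
    allow_small: bool = False,
    table_shape: tuple[int, int] = (31, 17),
) -> HistogramSet:
    """Build, refine and convert a distance array for every observed pair.

    Pools failing the sampling filter (fewer than ``min_near`` near-natives)
    are rejected unless ``allow_small``.  Pairs without a single usable
    stratum part are omitted with a log entry.
    """
    if not allow_small and not filter_sampling_problem(pool, min_near=min_near):
        raise PotentialError(
            f"case {pool.case_id}: sampling problem "
            f"({pool.n_label(LABEL_NEAR)} < {min_near} near-natives)"
        )
    ranges = ranges or make_range_set()
    strata = strata or RankStrata.scaled(len(pool))
    pairs, counts, _ = _pool_count_tensor(pool, ranges, strata)
    histograms: dict[tuple[int, int], Histogram] = {}
    for row, c in zip(pairs, counts):
        pair = (int(row[0]), int(row[1]))
        da = DistanceArray(pair=pair, ranges=ranges, strata=strata, counts=c)
        refined = refine_distance_array(da)
        hist = derive_histogram(refined)
        if all(part is None for part in hist.parts):
            logger.info("case %s: pair %s unusable, omitted", pool.case_id, pair)
            continue
        histograms[pair] = hist
    if not histograms:
        raise PotentialError(f"case {pool.case_id}: no usable pair")
    return HistogramSet(
        case_id=pool.case_id,
        ranges=ranges,
        strata=strata,
        histograms=histograms,
        table_shape=table_shape,
    )
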