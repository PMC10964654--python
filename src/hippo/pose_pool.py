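"""Decoy pools: labelled docking poses for one receptor-fragment case.

A pose is one placement of the RNA fragment's beads on the fixed, rigid
receptor.  Poses are labelled from their ligand RMSD (LRMSD) to the bound
native fragment, computed in the receptor frame without superposition:
near-native below 5 A, non-native above 7 A, intermediate in between.
Cases whose pool holds fewer than 100 near-natives suffer from the
sampling problem and are excluded from potential training.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cg_model import CGStructure
from .errors import PoolError

LABEL_NEAR = "near_native"
LABEL_NON = "non_native"
LABEL_INTERMEDIATE = "intermediate"
LABEL_UNLABELLED = "unlabelled"
LABELS = (LABEL_NEAR, LABEL_NON, LABEL_INTERMEDIATE, LABEL_UNLABELLED)


@dataclass(frozen=True)
class LabelThresholds:
    """LRMSD cutoffs: near-native strictly below near_max, non-native strictly above non_min."""

    near_max: float = 5.0
    non_min: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.near_max <= self.non_min:
            raise PoolError(f"invalid thresholds {self}")


@dataclass
class Pose:
    pose_id: str
    coords: np.ndarray  # (n_beads, 3), Angstrom
    asf_rank: int | None = None
    lrmsd: float | None = None
    label: str = LABEL_UNLABELLED

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PoolError(f"pose {self.pose_id}: coords must be (n, 3)")
        if self.label not in LABELS:
            raise PoolError(f"pose {self.pose_id}: unknown label {self.label!r}")
        if self.asf_rank is not None and self.asf_rank < 0:
            raise PoolError(f"pose {self.pose_id}: negative rank")


@dataclass
class PosePool:
    """All candidate poses of one receptor-fragment docking case."""

    case_id: str
    receptor: CGStructure
    fragment_types: np.ndarray  # bead type indices (j) shared by all poses
    poses: list[Pose] = field(default_factory=list)
    native: np.ndarray | None = None
    complex_id: str | None = None
    fragment_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise PoolError("case_id must be non-empty")
        self.fragment_types = np.asarray(self.fragment_types, dtype=np.int64)
        n = len(self.fragment_types)
        for p in self.poses:
            if p.coords.shape[0] != n:
                raise PoolError(
                    f"pose {p.pose_id}: {p.coords.shape[0]} beads, template has {n}"
                )
        if self.native is not None:
            self.native = np.asarray(self.native, dtype=float)
            if self.native.shape != (n, 3):
                raise PoolError("native coords do not match the fragment template")
        ranks = [p.asf_rank for p in self.poses if p.asf_rank is not None]
        if len(ranks) != len(set(ranks)):
            raise PoolError("duplicate asf_rank within pool")
        if self.complex_id is None:
            self.complex_id = self.case_id.split("-")[0]

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.poses])

    @property
    def ranks(self) -> np.ndarray:
        return np.array(
            [-1 if p.asf_rank is None else p.asf_rank for p in self.poses],
            dtype=np.int64,
        )

    @property
    def coords(self) -> np.ndarray:
        """Stacked pose coordinates, shape (n_poses, n_beads, 3)."""
        return np.stack([p.coords for p in self.poses])

    def n_label(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def fragment_structure(self, coords: np.ndarray, id: str = "") -> CGStructure:
        labels = self.fragment_labels or [""] * len(self.fragment_types)
        return CGStructure.from_arrays("rna", self.fragment_types, coords, id=id, labels=labels)


def lrmsd(pose_coords: np.ndarray, native_coords: np.ndarray) -> float:
    """Ligand RMSD in the fixed receptor frame (no superposition)."""
    a = np.asarray(pose_coords, dtype=float)
    b = np.asarray(native_coords, dtype=float)
    if a.shape != b.shape:
        raise PoolError(f"bead count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def label_for(value: float, thresholds: LabelThresholds = LabelThresholds()) -> str:
    if value < thresholds.near_max:
        return LABEL_NEAR
    if value > thresholds.non_min:
        return LABEL_NON
    return LABEL_INTERMEDIATE


def label_pose(pose: Pose, thresholds: LabelThresholds = LabelThresholds()) -> Pose:
    """Return a relabelled copy; the pose must carry an LRMSD."""
    if pose.lrmsd is None:
        raise PoolError(f"pose {pose.pose_id} has no LRMSD; cannot label")
    return replace(pose, label=label_for(pose.lrmsd, thresholds))


def label_pool(
    pool: PosePool, thresholds: LabelThresholds = LabelThresholds()
) -> PosePool:
    """Compute LRMSD against the pool's native and label every pose."""
    if pool.native is None:
        raise PoolError(f"case {pool.case_id} has no native; cannot label")
    poses = []
    for p in pool.poses:
        value = lrmsd(p.coords, pool.native)
        poses.append(replace(p, lrmsd=value, label=label_for(value, thresholds)))
    return replace(pool, poses=poses)


def dedup_pool(pool: PosePool, rmsd_cut: float = 0.2) -> PosePool:
    """Drop redundant poses (pairwise unfitted RMSD < rmsd_cut).

    Greedy scan in rank order (unranked poses last, in input order), so the
    better-ranked representative of a redundant group survives.  Retained
    poses come back in scan order.
    """
    order = sorted(
        range(len(pool.poses)),
        key=lambda k: (
            pool.poses[k].asf_rank is None,
            pool.poses[k].asf_rank if pool.poses[k].asf_rank is not None else k,
            k,
        ),
    )
    kept_idx: list[int] = []
    kept_coords: list[np.ndarray] = []
    n_beads = len(pool.fragment_types)
    for k in order:
        c = pool.poses[k].coords
        redundant = False
        if kept_coords:
            stack = np.stack(kept_coords)
            d = np.sqrt(np.mean(np.sum((stack - c) ** 2, axis=-1), axis=-1))
            redundant = bool(np.any(d < rmsd_cut))
        if not redundant:
            kept_idx.append(k)
            kept_coords.append(c)
    return replace(pool, poses=[pool.poses[k] for k in kept_idx])


def filter_sampling_problem(pool: PosePool, min_near: int = 100) -> bool:
    """True iff the case is usable: at least ``min_near`` near-native poses."""
    return pool.n_label(LABEL_NEAR) >= min_near


def contact_fingerprint(
    receptor: CGStructure,
    fragment: CGStructure | np.ndarray,
    ranges=None,
    cutoff: float = 6.0,
    fragment_types: np.ndarray | None = None,
) -> Counter:
    """Multiset of (i, j, distance-bin) contacts within ``cutoff``.

    Used for the contact-level redundancy check between cases: two cases
    whose native fingerprints are very similar describe the same binding
    geometry.  Distances are binned with the potential module's range set.
    """
    from .potential import make_range_set

    if ranges is None:
        ranges = make_range_set()
    if isinstance(fragment, CGStructure):
        coords = fragment.coords
        j_types = fragment.type_indices
    else:
        coords = np.asarray(fragment, dtype=float)
        if fragment_types is None:
            raise PoolError("fragment_types required with raw coordinates")
        j_types = np.asarray(fragment_types, dtype=np.int64)
    d = cdist(receptor.coords, coords)
    ii, jj = np.nonzero(d <= cutoff)
    bins = ranges.bin_of(d[ii, jj])
    return Counter(
        (int(receptor.type_indices[a]), int(j_types[b]), int(k))
        for a, b, k in zip(ii, jj, bins)
    )


def multiset_jaccard(a: Counter, b: Counter) -> float:
    """sum(min)/sum(max) over the union of keys; 1.0 for two empty multisets."""
    keys = set(a) | set(b)
    if not keys:
        return 1.0
    inter = sum(min(a[k], b[k]) for k in keys)
    union = sum(max(a[k], b[k]) for k in keys)
    return inter / union


def redundancy_filter(
    cases: Sequence[PosePool],
    similarity_cut: float = 0.8,
    cutoff: float = 6.0,
    ranges=None,
) -> list[PosePool]:
    """Greedy retention of contact-level non-redundant cases.

    Cases are scanned in input order; a case is dropped when the multiset
    Jaccard similarity of its native contact fingerprint to any retained
    case reaches ``similarity_cut``.
    """
    kept: list[PosePool] = []
    kept_fp: list[Counter] = []
    for case in cases:
        if case.native is None:
            raise PoolError(f"case {case.case_id} has no native fingerprintable pose")
        fp = contact_fingerprint(
            case.receptor, case.native, ranges=ranges, cutoff=cutoff,
            fragment_types=case.fragment_types,
        )
        if all(multiset_jaccard(fp, other) < similarity_cut for other in kept_fp):
            kept.append(case)
            kept_fp.append(fp)
    return kept


# ---------------------------------------------------------------------------
# pool I/O: TSV of poses + JSON sidecar with receptor/fragment metadata

def _sidecar_path(tsv_path) -> Path:
    return Path(tsv_path).with_suffix(".json")


def write_pool(pool: PosePool, tsv_path) -> None:
    """Write poses as TSV and case metadata as a JSON sidecar."""
    n = len(pool.fragment_types)
    cols: dict[str, list] = {
        "pose_id": [p.pose_id for p in pool.poses],
        "asf_rank": [("" if p.asf_rank is None else p.asf_rank) for p in pool.poses],
        "lrmsd": [("" if p.lrmsd is None else p.lrmsd) for p in pool.poses],
        "label": [p.label for p in pool.poses],
    }
    coords = pool.coords if pool.poses else np.zeros((0, n, 3))
    for b in range(n):
        for a, axis in enumerate("xyz"):
            cols[f"{axis}{b + 1}"] = coords[:, b, a]
    pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False)
    meta = {
        "case_id": pool.case_id,
        "complex_id": pool.complex_id,
        "fragment_types": [int(t) for t in pool.fragment_types],
        "fragment_labels": pool.fragment_labels,
        "native": None if pool.native is None else pool.native.tolist(),
        "receptor": pool.receptor.to_frame().to_dict(orient="list"),
    }
    _sidecar_path(tsv_path).write_text(json.dumps(meta))


def read_pool(tsv_path) -> PosePool:
    meta = json.loads(_sidecar_path(tsv_path).read_text())
    receptor = CGStructure.from_frame(
        pd.DataFrame(meta["receptor"]), id=meta["case_id"]
    )
    frame = pd.read_csv(tsv_path, sep="\t")
    n = len(meta["fragment_types"])
    coord_cols = [f"{axis}{b + 1}" for b in range(n) for axis in "xyz"]
    coords = frame[coord_cols].to_numpy(dtype=float).reshape(len(frame), n, 3)
    poses = []
    for k, row in enumerate(frame.itertuples(index=False)):
        rank = row.asf_rank
        rmsd = row.lrmsd
        poses.append(
            Pose(
                pose_id=str(row.pose_id),
                coords=coords[k],
                asf_rank=None if pd.isna(rank) else int(rank),
                lrmsd=None if pd.isna(rmsd) else float(rmsd),
                label=row.label if isinstance(row.label, str) else LABEL_UNLABELLED,
            )
        )
    return PosePool(
        case_id=meta["case_id"],
        receptor=receptor,
        fragment_types=np.array(meta["fragment_types"], dtype=np.int64),
        poses=poses,
        native=None if meta["native"] is None else np.array(meta["native"]),
        complex_id=meta.get("complex_id"),
        fragment_labels=meta.get("fragment_labels"),
    )
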