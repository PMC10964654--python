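"""Coarse-grained bead model of protein and RNA structures.

Proteins are reduced to at most 31 bead types (2 backbone beads per
residue plus 0-2 side-chain beads), RNA to at most 17 bead types
(1 phosphate + 2 sugar + 3-4 base beads per nucleotide), giving up to
31 x 17 = 527 cross-side bead-type pairs.  Protein bead types are
indexed by ``i``, RNA bead types by ``j``.  The atom->bead assignment
is configuration: a :class:`TypingTable` maps each residue name to its
atom groups, and each bead sits at the unweighted geometric centre of
the group's heavy atoms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .errors import StructureError, TypingTableError, UnknownResidueError

logger = logging.getLogger(__name__)

SIDE_PROTEIN = "protein"
SIDE_RNA = "rna"

#: hard bounds on the number of distinct bead types per side
MAX_TYPES = {SIDE_PROTEIN: 31, SIDE_RNA: 17}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class BeadType:
    """A typed pseudo-atom class: protein index i in 1..31, RNA index j in 1..17."""

    side: str
    index: int
    label: str

    def __post_init__(self) -> None:
        if self.side not in MAX_TYPES:
            raise TypingTableError(f"unknown side {self.side!r}")
        if not 1 <= self.index <= MAX_TYPES[self.side]:
            raise TypingTableError(
                f"{self.side} bead index {self.index} outside 1..{MAX_TYPES[self.side]}"
            )


@dataclass(frozen=True)
class Bead:
    """One pseudo-atom: a bead type plus a position in Angstrom."""

    bead_type: BeadType
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.position) != 3 or not all(math.isfinite(c) for c in self.position):
            raise StructureError(f"non-finite bead position {self.position}")


class CGStructure:
    """An ordered list of beads on one side (protein receptor or RNA fragment)."""

    def __init__(self, side: str, beads: Sequence[Bead], id: str = "") -> None:
        beads = list(beads)
        if not beads:
            raise StructureError("empty coarse-grained structure")
        if side not in MAX_TYPES:
            raise StructureError(f"unknown side {side!r}")
        for b in beads:
            if b.bead_type.side != side:
                raise StructureError(
                    f"bead of side {b.bead_type.side!r} in a {side!r} structure"
                )
        self.side = side
        self.id = id
        self.beads = beads
        self.coords = np.array([b.position for b in beads], dtype=float)
        self.type_indices = np.array([b.bead_type.index for b in beads], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.beads)

    def __repr__(self) -> str:
        return f"CGStructure({self.side!r}, {len(self)} beads, id={self.id!r})"

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: bead_index, side, type_index, x, y, z (plus label)."""
        return pd.DataFrame(
            {
                "bead_index": np.arange(len(self)),
                "side": self.side,
                "type_index": self.type_indices,
                "label": [b.bead_type.label for b in self.beads],
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id: str = "") -> "CGStructure":
        side = str(frame["side"].iloc[0])
        labels = frame["label"] if "label" in frame else [""] * len(frame)
        beads = [
            Bead(
                BeadType(side, int(t), str(lab)),
                (float(x), float(y), float(z)),
            )
            for t, lab, x, y, z in zip(
                frame["type_index"], labels, frame["x"], frame["y"], frame["z"]
            )
        ]
        return cls(side, beads, id=id)

    @classmethod
    def from_arrays(
        cls,
        side: str,
        type_indices: Iterable[int],
        coords: np.ndarray,
        id: str = "",
        labels: Sequence[str] | None = None,
    ) -> "CGStructure":
        coords = np.asarray(coords, dtype=float)
        type_indices = list(type_indices)
        if labels is None:
            labels = [""] * len(type_indices)
        beads = [
            Bead(BeadType(side, int(t), lab), tuple(map(float, xyz)))
            for t, lab, xyz in zip(type_indices, labels, coords)
        ]
        return cls(side, beads, id=id)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "CGStructure":
        """Same bead typing, new coordinates (e.g. another pose of a fragment)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError("coordinate shape mismatch")
        beads = [
            Bead(b.bead_type, tuple(map(float, xyz)))
            for b, xyz in zip(self.beads, coords)
        ]
        return CGStructure(self.side, beads, id=self.id if id is None else id)


@dataclass(frozen=True)
class BeadGroup:
    """One atom group of a residue and the bead type it maps to."""

    bead_type: BeadType
    atoms: tuple[str, ...]


class TypingTable:
    """Residue-wise atom->bead mapping for both sides.

    ``protein_backbone`` and ``rna_backbone`` are shared by every residue
    of their side; ``protein_side`` / ``rna_base`` add the residue-specific
    beads.  The table is closed-world: residues it does not list cannot be
    coarse-grained.
    """

    def __init__(
        self,
        protein_backbone: Sequence[BeadGroup],
        protein_side: dict[str, Sequence[BeadGroup]],
        rna_backbone: Sequence[BeadGroup],
        rna_base: dict[str, Sequence[BeadGroup]],
    ) -> None:
        self.protein_backbone = tuple(protein_backbone)
        self.protein_side = {k: tuple(v) for k, v in protein_side.items()}
        self.rna_backbone = tuple(rna_backbone)
        self.rna_base = {k: tuple(v) for k, v in rna_base.items()}
        self._validate()

    def _validate(self) -> None:
        if len(self.protein_backbone) != 2:
            raise TypingTableError("protein residues need exactly 2 backbone beads")
        for res, groups in self.protein_side.items():
            if not 0 <= len(groups) <= 2:
                raise TypingTableError(f"{res}: side-chain beads must number 0-2")
        if len(self.rna_backbone) != 3:
            raise TypingTableError(
                "RNA nucleotides need 1 phosphate + 2 sugar backbone beads"
            )
        for res, groups in self.rna_base.items():
            if not 3 <= len(groups) <= 4:
                raise TypingTableError(f"{res}: base beads must number 3-4")
        # distinct (side, index) pairs must stay within the declared bounds;
        # BeadType already enforces the per-index range
        for side, n_max, indices in (
            (SIDE_PROTEIN, MAX_TYPES[SIDE_PROTEIN], self._indices(SIDE_PROTEIN)),
            (SIDE_RNA, MAX_TYPES[SIDE_RNA], self._indices(SIDE_RNA)),
        ):
            if len(indices) > n_max:
                raise TypingTableError(f"{side}: {len(indices)} types exceed {n_max}")
        # a given (side, index) must always carry the same label
        seen: dict[tuple[str, int], str] = {}
        for g in self._all_groups():
            key = (g.bead_type.side, g.bead_type.index)
            if seen.setdefault(key, g.bead_type.label) != g.bead_type.label:
                raise TypingTableError(f"conflicting labels for bead type {key}")

    def _all_groups(self) -> Iterable[BeadGroup]:
        yield from self.protein_backbone
        for groups in self.protein_side.values():
            yield from groups
        yield from self.rna_backbone
        for groups in self.rna_base.values():
            yield from groups

    def _indices(self, side: str) -> set[int]:
        return {
            g.bead_type.index for g in self._all_groups() if g.bead_type.side == side
        }

    @property
    def n_protein_types(self) -> int:
        return len(self._indices(SIDE_PROTEIN))

    @property
    def n_rna_types(self) -> int:
        return len(self._indices(SIDE_RNA))

    @property
    def shape(self) -> tuple[int, int]:
        """(number of protein types, number of RNA types)."""
        return (self.n_protein_types, self.n_rna_types)

    def residue_groups(self, resname: str, side: str) -> tuple[BeadGroup, ...]:
        """All bead groups (backbone + residue-specific) of one residue."""
        resname = resname.strip().upper()
        if side == SIDE_PROTEIN:
            if resname not in self.protein_side:
                raise UnknownResidueError(f"protein residue {resname!r} not in table")
            return self.protein_backbone + self.protein_side[resname]
        if side == SIDE_RNA:
            if resname not in self.rna_base:
                raise UnknownResidueError(f"RNA residue {resname!r} not in table")
            return self.rna_backbone + self.rna_base[resname]
        raise TypingTableError(f"unknown side {side!r}")

    def fragment_template(self, sequence: str) -> tuple[list[int], list[str]]:
        """Bead type indices and labels for an RNA fragment sequence, 5'->3'."""
        indices: list[int] = []
        labels: list[str] = []
        for nt in sequence:
            for g in self.residue_groups(nt, SIDE_RNA):
                indices.append(g.bead_type.index)
                labels.append(g.bead_type.label)
        return indices, labels


def _parse_groups(side: str, raw: Sequence[dict]) -> list[BeadGroup]:
    groups = []
    for entry in raw:
        try:
            bt = BeadType(side, int(entry["index"]), str(entry["label"]))
            atoms = tuple(str(a) for a in entry["atoms"])
        except (KeyError, TypeError, ValueError) as exc:
            raise TypingTableError(f"malformed bead group {entry!r}") from exc
        if not atoms:
            raise TypingTableError(f"bead group {entry!r} lists no atoms")
        groups.append(BeadGroup(bt, atoms))
    return groups


def load_typing_table(path) -> TypingTable:
    """Load and validate a YAML typing table."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _table_from_dict(raw)


def _table_from_dict(raw: dict) -> TypingTable:
    try:
        prot = raw["protein"]
        rna = raw["rna"]
        return TypingTable(
            protein_backbone=_parse_groups(SIDE_PROTEIN, prot["backbone"]),
            protein_side={
                res: _parse_groups(SIDE_PROTEIN, groups or [])
                for res, groups in prot["side_chains"].items()
            },
            rna_backbone=_parse_groups(SIDE_RNA, rna["backbone"]),
            rna_base={
                res: _parse_groups(SIDE_RNA, groups or [])
                for res, groups in rna["bases"].items()
            },
        )
    except (KeyError, TypeError) as exc:
        raise TypingTableError(f"malformed typing-table document: {exc}") from exc


def default_typing_table() -> TypingTable:
    """The shipped default table (31 protein types, 17 RNA types)."""
    ref = resources.files("hippo.data") / "default_beads.yaml"
    return _table_from_dict(yaml.safe_load(ref.read_text()))


def max_pair_count(table: TypingTable) -> int:
    """Number of possible cross-side bead-type pairs (i, j)."""
    return table.n_protein_types * table.n_rna_types


def coarse_grain(
    source,
    table: TypingTable,
    side: str,
    *,
    id: str | None = None,
    skip_unknown: bool = False,
) -> CGStructure:
    """Reduce an all-atom structure to beads.

    ``source`` may be a PDB/mmCIF path or a ``gemmi.Structure``; model 1 is
    used for multi-model (NMR) entries.  Each bead is the unweighted
    geometric centre of its group's atoms; groups with some atoms missing
    are built from the present ones (with a warning), groups with no atom
    present are skipped.  Unknown residues raise
    :class:`~hippo.errors.UnknownResidueError` unless ``skip_unknown``.
    """
    import gemmi

    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        structure = gemmi.read_structure(str(source))
        structure.setup_entities()
    else:
        structure = source
    if isinstance(structure, gemmi.Structure):
        if len(structure) == 0:
            raise StructureError("structure has no models")
        model = structure[0]
        struct_name = structure.name
    else:
        model = structure
        struct_name = getattr(structure, "name", "")

    beads: list[Bead] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            if resname in _WATER_NAMES:
                continue
            try:
                groups = table.residue_groups(resname, side)
            except UnknownResidueError:
                if skip_unknown:
                    continue
                raise
            atom_pos = {}
            for atom in residue:
                # first altloc wins
                atom_pos.setdefault(atom.name, (atom.pos.x, atom.pos.y, atom.pos.z))
            for group in groups:
                present = [atom_pos[a] for a in group.atoms if a in atom_pos]
                if not present:
                    logger.warning(
                        "%s %s: no atoms of group %s present, bead skipped",
                        chain.name,
                        residue.name,
                        group.bead_type.label,
                    )
                    continue
                if len(present) < len(group.atoms):
                    logger.warning(
                        "%s %s: group %s built from %d/%d atoms",
                        chain.name,
                        residue.name,
                        group.bead_type.label,
                        len(present),
                        len(group.atoms),
                    )
                centre = tuple(np.mean(np.array(present, dtype=float), axis=0))
                beads.append(Bead(group.bead_type, centre))
    if not beads:
        raise StructureError("no residue of the structure is mappable by the table")
    return CGStructure(side, beads, id=id if id is not None else struct_name)


def cross_distances(
    receptor: CGStructure, fragment_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Typed all-pairs distances between a receptor and fragment coordinates.

    Returns flat arrays ``(i_types, j_types, distances)`` of length
    ``len(receptor) * n_fragment_beads``; the fragment bead typing must be
    attached by the caller (see :func:`pair_distances` for the structured
    variant).
    """
    fragment_coords = np.asarray(fragment_coords, dtype=float)
    d = cdist(receptor.coords, fragment_coords)
    ni, nj = d.shape
    i_types = np.repeat(receptor.type_indices, nj)
    j_index = np.tile(np.arange(nj), ni)
    return i_types, j_index, d.ravel()


def pair_distances(
    receptor: CGStructure,
    fragment_pose: CGStructure,
    max_distance: float = math.inf,
) -> list[tuple[int, int, float]]:
    """All cross-side (i, j, distance) records with distance <= max_distance."""
    if receptor.side != SIDE_PROTEIN:
        raise StructureError("receptor must be protein-side")
    if fragment_pose.side != SIDE_RNA:
        raise StructureError("fragment pose must be RNA-side")
    d = cdist(receptor.coords, fragment_pose.coords)
    ii, jj = np.nonzero(d <= max_distance)
    return [
        (int(receptor.type_indices[a]), int(fragment_pose.type_indices[b]), float(d[a, b]))
        for a, b in zip(ii, jj)
    ]
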