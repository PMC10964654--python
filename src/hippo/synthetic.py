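"""Synthetic labelled decoy pools with planted contact-distance signal.

The generator emulates the statistical structure the potential assumes,
without any docking engine: a quasi-spherical receptor bead cloud, a
planted native fragment placement whose chosen (protein type i, RNA type
j) contacts sit at a preferred distance, near-native poses scattered
within the near-native LRMSD threshold of that native with their planted
contact distances drawn from N(mu, sigma), and non-native poses whose
beads are drawn independently from a broad shell around the receptor so
their contact distances form a featureless background.  Optionally a
fraction of the non-natives is placed at decoy binding sites (the
planted sites of other binding modes), emulating poses docked at the
wrong surface patch; this is what makes potentials trained on different
modes disagree, and hence what a consensus collection exists to fix.
Ranks are a noisy function of LRMSD (weak rank-label correlation,
mimicking an imperfect original scoring) and span all rank strata.

With an empty signal list the generator emits a null-control pool: all
poses are drawn from the background distribution and labels are assigned
at random, so any structure in a derived potential is sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cg_model import CGStructure, TypingTable, default_typing_table
from .errors import GeneratorError
from .pose_pool import (
    LABEL_NEAR,
    LABEL_NON,
    LABEL_INTERMEDIATE,
    LabelThresholds,
    Pose,
    PosePool,
    label_for,
    lrmsd,
)

_MAX_TRIES = 200


@dataclass(frozen=True)
class PlantedSignal:
    """A preferred contact: fragment beads of type j near receptor beads of type i."""

    protein_type: int
    rna_type: int
    mu: float = 3.5  # preferred contact distance, Angstrom
    sigma: float = 0.4  # spread of the planted distance
    strength: int = 3  # planted contacts per near-native pose

    def __post_init__(self) -> None:
        if not 2.0 < self.mu < 14.5:
            raise GeneratorError(f"planted distance {self.mu} outside (2, 14.5)")
        if self.sigma <= 0 or self.strength <= 0:
            raise GeneratorError("sigma and strength must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic case.

    Defaults give a 6000-pose pool with 300 near-natives (near-natives
    are a small minority, as in real decoy pools), a 120-bead receptor
    of radius 18 A cycling through all 31 protein types, a trinucleotide
    fragment, and one planted arginine-guanidinium/phosphate contact at
    3.5 +/- 0.4 A, three per near-native pose.

    ``receptor_seed`` and ``site_seed`` default to ``seed``; giving
    several cases the same receptor seed puts them on one receptor, and
    the site seed pins the binding-site choice so that cases of one
    binding mode share their native geometry.  ``decoy_signals`` (with
    aligned ``decoy_site_seeds``) place a ``decoy_fraction`` of the
    non-natives near other planted sites instead of in the background.
    """

    seed: int
    n_near: int = 300
    n_non: int = 5700
    n_intermediate: int = 0
    receptor_size: int = 120
    receptor_radius: float = 18.0
    fragment_sequence: str = "GCA"
    signal: tuple[PlantedSignal, ...] = (PlantedSignal(23, 1),)
    background_shell: tuple[float, float] = (-3.0, 9.0)  # radii relative to receptor
    near_noise: float = 0.8  # per-bead placement noise of near-natives, Angstrom
    rank_lrmsd_weight: float = 0.3  # rank/LRMSD correlation of the emulated scoring
    thresholds: LabelThresholds = field(default_factory=LabelThresholds)
    receptor_seed: int | None = None
    site_seed: int | None = None
    decoy_signals: tuple[tuple[PlantedSignal, ...], ...] = ()
    decoy_site_seeds: tuple[int, ...] = ()
    decoy_fraction: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_near, self.n_non, self.n_intermediate) < 0:
            raise GeneratorError("pose counts must be >= 0")
        if self.receptor_size <= 0:
            raise GeneratorError("receptor size must be positive")
        if self.decoy_signals and len(self.decoy_site_seeds) != len(self.decoy_signals):
            raise GeneratorError("decoy_site_seeds must align with decoy_signals")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise GeneratorError("decoy_fraction must be within [0, 1]")

    @property
    def n_poses(self) -> int:
        return self.n_near + self.n_non + self.n_intermediate


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_receptor(
    config: GeneratorConfig,
    seed: int | None = None,
    table: TypingTable | None = None,
) -> CGStructure:
    """Reproducible quasi-spherical protein bead cloud.

    Beads sit on a Fibonacci lattice over the sphere of the configured
    radius with a small radial jitter; bead types cycle through the
    table's protein types so every type is represented.
    """
    table = table or default_typing_table()
    if seed is None:
        seed = config.receptor_seed if config.receptor_seed is not None else config.seed
    rng = np.random.default_rng(seed)
    n = config.receptor_size
    k = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * k / golden
    z = 1 - (2 * k + 1) / n
    r_xy = np.sqrt(1 - z**2)
    directions = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    radii = config.receptor_radius + rng.normal(0.0, 0.5, size=n)
    coords = directions * radii[:, None]
    types = (k % table.n_protein_types) + 1
    return CGStructure.from_arrays("protein", types, coords, id="synthetic-receptor")


def _plant_native(
    signals: Sequence[PlantedSignal],
    receptor: CGStructure,
    frag_types: np.ndarray,
    radius: float,
    site_rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, PlantedSignal]]]:
    """Native fragment coordinates plus (fragment bead, anchor, signal) pairings.

    The binding site is the surface patch around a randomly chosen bead of
    the first signal's protein type; planted fragment beads sit exactly at
    their preferred distance from the nearest anchors, the remaining beads
    form a blob held outside the planted-contact range of every receptor
    bead so that no unplanned pair gets closer than the planted ones.
    """
    first = signals[0]
    site_pool = np.nonzero(receptor.type_indices == first.protein_type)[0]
    if len(site_pool) == 0:
        raise GeneratorError(f"receptor lacks protein type {first.protein_type}")
    site_dir = _unit(receptor.coords[site_rng.choice(site_pool)])
    site_point = site_dir * radius

    pairings: list[tuple[int, int, PlantedSignal]] = []
    native = np.zeros((len(frag_types), 3))
    placed = np.zeros(len(frag_types), dtype=bool)
    for signal in signals:
        if signal.mu > 2 * radius:
            raise GeneratorError(f"planted distance {signal.mu} beyond receptor reach")
        j_beads = np.nonzero(frag_types == signal.rna_type)[0]
        i_beads = np.nonzero(receptor.type_indices == signal.protein_type)[0]
        if len(j_beads) == 0:
            raise GeneratorError(f"fragment has no bead of RNA type {signal.rna_type}")
        n_planted = min(signal.strength, len(j_beads))
        if len(i_beads) < n_planted:
            raise GeneratorError("not enough receptor beads to realise the signal")
        order = np.argsort(np.linalg.norm(receptor.coords[i_beads] - site_point, axis=1))
        anchors = i_beads[order[:n_planted]]
        for f_bead, anchor in zip(j_beads[:n_planted], anchors):
            native[f_bead] = receptor.coords[anchor] + _unit(receptor.coords[anchor]) * signal.mu
            placed[f_bead] = True
            pairings.append((int(f_bead), int(anchor), signal))
    # remaining beads: loose blob outside the planted-contact range
    clearance = max(s.mu for s in signals) + 1.5
    base = native[placed].mean(axis=0) if placed.any() else site_point
    blob_centre = _unit(base) * (radius + clearance)
    for b in np.nonzero(~placed)[0]:
        pos = blob_centre + site_rng.normal(0.0, 1.2, size=3)
        for _ in range(10):
            if cdist(pos[None], receptor.coords).min() >= clearance:
                break
            pos = pos + _unit(pos) * 1.0
        native[b] = pos
    return native, pairings


def _background_pose(
    config: GeneratorConfig, n_beads: int, rng: np.random.Generator
) -> np.ndarray:
    lo = config.receptor_radius + config.background_shell[0]
    hi = config.receptor_radius + config.background_shell[1]
    directions = rng.normal(size=(n_beads, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return directions * rng.uniform(lo, hi, size=(n_beads, 1))


def _near_style_pose(
    config: GeneratorConfig,
    native: np.ndarray,
    pairings: Sequence[tuple[int, int, PlantedSignal]],
    receptor: CGStructure,
    rng: np.random.Generator,
) -> np.ndarray:
    """Native plus placement noise; planted contacts resampled from N(mu, sigma)."""
    pose = native + rng.normal(0.0, config.near_noise, size=native.shape)
    for f_bead, anchor, signal in pairings:
        d = max(0.5, rng.normal(signal.mu, signal.sigma))
        direction = _unit(
            (native[f_bead] - receptor.coords[anchor]) + rng.normal(0.0, 0.12, size=3)
        )
        pose[f_bead] = receptor.coords[anchor] + direction * d
    return pose


def _near_native_pose(config, native, pairings, receptor, rng) -> np.ndarray:
    for _ in range(_MAX_TRIES):
        pose = _near_style_pose(config, native, pairings, receptor, rng)
        if lrmsd(pose, native) < config.thresholds.near_max:
            return pose
    raise GeneratorError("could not place a near-native pose; lower near_noise")


def _intermediate_pose(
    config: GeneratorConfig, native: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    t = config.thresholds
    for _ in range(_MAX_TRIES):
        offset = rng.normal(size=3)
        offset = _unit(offset) * rng.uniform(t.near_max + 0.3, t.non_min - 0.3)
        pose = native + offset + rng.normal(0.0, 0.3, size=native.shape)
        if t.near_max <= lrmsd(pose, native) <= t.non_min:
            return pose
    raise GeneratorError("could not place an intermediate pose")


def _assign_ranks(
    config: GeneratorConfig, lrmsds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Ranks weakly correlated with LRMSD (better rank ~ lower LRMSD)."""
    n = len(lrmsds)
    z = np.empty(n)
    z[np.argsort(lrmsds, kind="stable")] = np.linspace(-1.7, 1.7, n)  # normal-ish scores
    rho = config.rank_lrmsd_weight
    key = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(key, kind="stable")] = np.arange(n)
    return ranks


def generate_pool(
    config: GeneratorConfig, table: TypingTable | None = None
) -> PosePool:
    """Generate a labelled, ranked synthetic pool for one case.

    Poses are ordered by rank; labels are re-derived from each pose's
    actual LRMSD against the planted native, so label-geometry
    consistency holds by construction.  With ``config.signal == ()`` a
    null-control pool is produced instead (background poses, random
    labels, no native, no LRMSD).
    """
    table = table or default_typing_table()
    rng = np.random.default_rng(config.seed)
    receptor = generate_receptor(config, table=table)
    frag_indices, frag_labels = table.fragment_template(config.fragment_sequence)
    frag_types = np.asarray(frag_indices, dtype=np.int64)
    n = config.n_poses
    if n == 0:
        raise GeneratorError("empty pool requested")

    if not config.signal:
        return _null_pool(config, receptor, frag_types, frag_labels, rng)

    site_seed = config.site_seed if config.site_seed is not None else config.seed
    native, pairings = _plant_native(
        config.signal, receptor, frag_types, config.receptor_radius,
        np.random.default_rng(site_seed),
    )
    decoys = [
        _plant_native(
            tuple(sigs), receptor, frag_types, config.receptor_radius,
            np.random.default_rng(ss),
        )
        for sigs, ss in zip(config.decoy_signals, config.decoy_site_seeds)
    ]

    coords = np.empty((n, len(frag_types), 3))
    n_decoy = int(round(config.n_non * config.decoy_fraction)) if decoys else 0
    intended = (
        [LABEL_NEAR] * config.n_near
        + ["decoy"] * n_decoy
        + [LABEL_NON] * (config.n_non - n_decoy)
        + [LABEL_INTERMEDIATE] * config.n_intermediate
    )
    t = config.thresholds
    for k, lab in enumerate(intended):
        if lab == LABEL_NEAR:
            coords[k] = _near_native_pose(config, native, pairings, receptor, rng)
        elif lab == "decoy":
            d_native, d_pairings = decoys[k % len(decoys)]
            for _ in range(_MAX_TRIES):
                pose = _near_style_pose(config, d_native, d_pairings, receptor, rng)
                if lrmsd(pose, native) > t.non_min:
                    break
            else:
                raise GeneratorError("decoy site overlaps the native site")
            coords[k] = pose
        elif lab == LABEL_INTERMEDIATE:
            coords[k] = _intermediate_pose(config, native, rng)
        else:
            for _ in range(_MAX_TRIES):
                pose = _background_pose(config, len(frag_types), rng)
                if lrmsd(pose, native) > t.non_min:
                    break
            else:
                raise GeneratorError("could not place a non-native pose")
            coords[k] = pose

    lrmsds = np.array([lrmsd(coords[k], native) for k in range(n)])
    ranks = _assign_ranks(config, lrmsds, rng)
    order = np.argsort(ranks)
    case_id = f"SYN{config.seed}-{config.fragment_sequence}"
    poses = [
        Pose(
            pose_id=f"{case_id}:{int(ranks[k])}",
            coords=coords[k],
            asf_rank=int(ranks[k]),
            lrmsd=float(lrmsds[k]),
            label=label_for(lrmsds[k], t),
        )
        for k in order
    ]
    return PosePool(
        case_id=case_id,
        receptor=receptor,
        fragment_types=frag_types,
        poses=poses,
        native=native,
        fragment_labels=frag_labels,
    )


def _null_pool(
    config: GeneratorConfig,
    receptor: CGStructure,
    frag_types: np.ndarray,
    frag_labels: list[str],
    rng: np.random.Generator,
) -> PosePool:
    n = config.n_poses
    coords = np.stack([_background_pose(config, len(frag_types), rng) for _ in range(n)])
    labels = np.array(
        [LABEL_NEAR] * config.n_near
        + [LABEL_NON] * config.n_non
        + [LABEL_INTERMEDIATE] * config.n_intermediate
    )
    rng.shuffle(labels)
    ranks = rng.permutation(n)
    order = np.argsort(ranks)
    case_id = f"NULL{config.seed}-{config.fragment_sequence}"
    poses = [
        Pose(
            pose_id=f"{case_id}:{int(ranks[k])}",
            coords=coords[k],
            asf_rank=int(ranks[k]),
            lrmsd=None,
            label=str(labels[k]),
        )
        for k in order
    ]
    return PosePool(
        case_id=case_id,
        receptor=receptor,
        fragment_types=frag_types,
        poses=poses,
        native=None,
        fragment_labels=frag_labels,
    )


#: two stock binding modes used by the case-family generator: an
#: arginine-guanidinium/phosphate salt-bridge-like contact and a
#: tryptophan-ring/sugar stacking-like contact at a longer distance.
DEFAULT_MODES: tuple[tuple[PlantedSignal, ...], ...] = (
    (PlantedSignal(23, 1, mu=3.5, sigma=0.4, strength=3),),
    (PlantedSignal(31, 3, mu=5.5, sigma=0.5, strength=3),),
)


def generate_case_family(
    k_cases: int,
    modes: Sequence[tuple[PlantedSignal, ...]] = DEFAULT_MODES,
    seed: int = 0,
    base_config: GeneratorConfig | None = None,
    cases_per_complex: int = 1,
    table: TypingTable | None = None,
) -> list[PosePool]:
    """Cases partitioned round-robin across binding modes.

    All cases share one receptor; cases of the same mode share their
    planted signal and binding site (fresh placement noise per case),
    and every case's non-natives include decoy poses at the other modes'
    sites, so a potential trained on one mode penalises the geometry of
    the others.  ``cases_per_complex`` groups consecutive cases of a
    mode under a common complex id.
    """
    if k_cases and not modes:
        raise GeneratorError("at least one binding mode required")
    base = base_config or GeneratorConfig(seed=seed)
    site_seed_of = lambda m: (seed * 131 + m) % (2**31)  # noqa: E731
    pools: list[PosePool] = []
    per_mode_count = [0] * max(len(modes), 1)
    for c in range(k_cases):
        m = c % len(modes)
        others = [o for o in range(len(modes)) if o != m]
        cfg = replace(
            base,
            signal=tuple(modes[m]),
            seed=(seed + 104_729 * (c + 1)) % (2**31),
            receptor_seed=seed,
            site_seed=site_seed_of(m),
            decoy_signals=tuple(tuple(modes[o]) for o in others),
            decoy_site_seeds=tuple(site_seed_of(o) for o in others),
        )
        pool = generate_pool(cfg, table=table)
        idx = per_mode_count[m]
        per_mode_count[m] += 1
        pool.case_id = f"M{m}F{idx}-{base.fragment_sequence}"
        pool.complex_id = f"M{m}X{idx // cases_per_complex}"
        for p in pool.poses:
            p.pose_id = f"{pool.case_id}:{p.asf_rank}"
        pools.append(pool)
    return pools
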