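"""Synthetic conformer ensembles: the stand-in for MD trajectories.

The sampler draws each snapshot's backbone torsions independently from a
rotational-isomeric-state (RIS) mixture: the O-C-C-O ("CC") dihedrals
populate gauche+ / gauche- / trans states centred at +|g|, -|g| and 180°
(|g| from the GeometrySpec) with configurable weights and Gaussian jitter;
the flanking OC torsions are predominantly trans.  Snapshots are
independent equilibrium draws, not a correlated dynamics chain — the
downstream analysis averages over an equilibrated window, so only the
stationary distribution matters.  Self-overlapping chains (any nonbonded
atom pair closer than a hard-clash cutoff) are rejected and resampled.

``hydrate_fixture`` and ``hydrate_by_exposure`` add explicit waters:
the former plants waters at exact canonical H-bond geometries (ground
truth for detector tests), the latter emulates a hydration shell by
planting one donor water at every solvent-exposed PEG oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import Conformer, DihedralAssignment, place_chain
from .geometry import GeometrySpec
from .topology import PEGTopology, build_topology

#: default hard-clash cutoff between nonbonded atoms, Å
CLASH_CUTOFF = 1.5

# rigid water geometry used for planted/decoy waters
WATER_OH = 0.9572
WATER_HOH = 104.52


@dataclass(frozen=True)
class RISWeights:
    """Statistical weights of the CC-dihedral rotational isomeric states.

    Defaults (0.35, 0.35, 0.30) with 12° jitter and 0.9 OC-trans
    probability reflect the gauche preference and the equal g+/g- split
    observed for PEG in water; they are a qualitative emulation — no
    printed gauche fraction exists to anchor them quantitatively.
    """

    p_gauche_plus: float = 0.35
    p_gauche_minus: float = 0.35
    p_trans: float = 0.30
    sigma_jitter: float = 12.0
    oc_trans_prob: float = 0.9

    def __post_init__(self) -> None:
        p = (self.p_gauche_plus, self.p_gauche_minus, self.p_trans)
        if any(v < 0 for v in p):
            raise ValueError("state probabilities must be >= 0")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"state probabilities must sum to 1, got {sum(p)}")
        if self.sigma_jitter < 0:
            raise ValueError("sigma_jitter must be >= 0")
        if not 0.0 <= self.oc_trans_prob <= 1.0:
            raise ValueError("oc_trans_prob must be in [0, 1]")

    @classmethod
    def symmetric(cls, sigma_jitter: float = 12.0) -> "RISWeights":
        """Equal-weight three-state mixture (ideal-chain reference)."""
        return cls(1 / 3, 1 / 3, 1 / 3, sigma_jitter=sigma_jitter)


@dataclass
class Trajectory:
    """Ordered conformer ensemble with snapshot times (ps)."""

    topology: PEGTopology
    snapshots: list[Conformer]
    times: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.snapshots):
            raise ValueError("times and snapshots must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("snapshot times must be strictly increasing")
        for c in self.snapshots:
            if c.topology.n_subunits != self.topology.n_subunits:
                raise ValueError("all snapshots must share the trajectory topology")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)


def _wrap_degrees(a: np.ndarray) -> np.ndarray:
    """Map angles to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return np.where(a == -180.0, 180.0, a)


def _nonbonded_clash(conformer: Conformer, cutoff: float) -> bool:
    tree = cKDTree(conformer.coords)
    pairs = tree.query_pairs(cutoff)
    if not pairs:
        return False
    bonded = {tuple(sorted(b)) for b in conformer.topology.bonds}
    return any(tuple(sorted(p)) not in bonded for p in pairs)


def sample_assignment(
    n: int, weights: RISWeights, geometry: GeometrySpec, rng: np.random.Generator
) -> DihedralAssignment:
    """Draw one RIS torsion assignment (no excluded-volume filtering)."""
    g = abs(geometry.cc_dihedral_gauche)
    centers = np.array([g, -g, 180.0])
    states = rng.choice(3, size=n, p=[weights.p_gauche_plus, weights.p_gauche_minus, weights.p_trans])
    cc = centers[states]
    oc_trans = rng.random(max(2 * n - 2, 0)) < weights.oc_trans_prob
    oc_sign = np.where(rng.random(oc_trans.shape) < 0.5, 1.0, -1.0)
    oc = np.where(oc_trans, 180.0, oc_sign * g)
    if weights.sigma_jitter > 0:
        cc = cc + rng.normal(0.0, weights.sigma_jitter, size=cc.shape)
        oc = oc + rng.normal(0.0, weights.sigma_jitter, size=oc.shape)
    return DihedralAssignment(_wrap_degrees(cc), _wrap_degrees(oc))


def sample_trajectory(
    n: int,
    n_snapshots: int,
    weights: RISWeights | None = None,
    geometry: GeometrySpec | None = None,
    seed: int = 0,
    snapshot_interval_ps: float = 5.0,
    clash_cutoff: float = CLASH_CUTOFF,
) -> Trajectory:
    """Sample an ensemble of self-avoiding RIS conformers.

    Each snapshot is an independent draw; conformers with any nonbonded
    atom pair closer than ``clash_cutoff`` are rejected and redrawn.
    Reproducible given ``seed``.  Aborts with a diagnostic if the
    rejection rate exceeds 99%.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    weights = weights or RISWeights()
    geometry = geometry or GeometrySpec.crystal()
    topo = build_topology(n)
    rng = np.random.default_rng(seed)

    snapshots: list[Conformer] = []
    attempts = 0
    while len(snapshots) < n_snapshots:
        attempts += 1
        conf = place_chain(topo, geometry, sample_assignment(n, weights, geometry, rng))
        if not _nonbonded_clash(conf, clash_cutoff):
            snapshots.append(conf)
        if attempts >= 200 and len(snapshots) < 0.01 * attempts:
            raise RuntimeError(
                f"RIS sampling rejection rate above 99% "
                f"({len(snapshots)}/{attempts} accepted, n={n}); "
                f"weights or clash cutoff are physically implausible"
            )
    times = snapshot_interval_ps * np.arange(n_snapshots)
    return Trajectory(topology=topo, snapshots=snapshots, times=times, seed=seed)


# ----------------------------------------------------------------------
# hydration fixtures


def _water_at(
    o_pos: np.ndarray, donate_towards: np.ndarray | None, axis: np.ndarray, rng
) -> np.ndarray:
    """Build one rigid water at ``o_pos``.

    If ``donate_towards`` is given, one O-H bond points exactly at that
    acceptor position (linear D-H···A geometry) and the second hydrogen
    follows from the H-O-H angle.  Otherwise both hydrogens are placed
    perpendicular to ``axis`` so the water neither donates along nor
    against it.
    """
    if donate_towards is not None:
        d1 = donate_towards - o_pos
        d1 /= np.linalg.norm(d1)
        perp = _any_perpendicular(d1, rng)
        ang = np.radians(WATER_HOH)
        d2 = np.cos(ang) * d1 + np.sin(ang) * perp
    else:
        p1 = _any_perpendicular(axis, rng)
        p2 = np.cross(axis / np.linalg.norm(axis), p1)
        half = np.radians(WATER_HOH) / 2.0
        # both O-H bonds orthogonal to the H-bond axis (in the plane normal
        # to it), so neither points at the partner
        d1 = np.cos(half) * p1 + np.sin(half) * p2
        d2 = np.cos(half) * p1 - np.sin(half) * p2
    return np.stack([o_pos, o_pos + WATER_OH * d1, o_pos + WATER_OH * d2])


def _any_perpendicular(v: np.ndarray, rng) -> np.ndarray:
    v = v / np.linalg.norm(v)
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        norm = np.linalg.norm(p)
        if norm > 1e-6:
            return p / norm


def _forms_unplanned_bond(
    water: np.ndarray,
    topo: PEGTopology,
    coords: np.ndarray,
    planted: tuple[int, str] | None,
    dist_margin: float = 3.7,
    angle_margin: float = 120.0,
) -> bool:
    """True if this water could register any H-bond with the PEG other
    than the planted one, judged with safety margins beyond the default
    detection criteria (3.5 Å / 135°)."""
    from .builder import bond_angle  # local import to keep module load light

    o_w = water[0]
    partner, role = planted if planted is not None else (None, None)
    for o_j in topo.oxygen_indices:
        d = np.linalg.norm(coords[o_j] - o_w)
        if d > dist_margin:
            continue
        # water donating to PEG oxygen o_j?
        for h in water[1:]:
            pts = np.array([o_w, h, coords[o_j]])
            if bond_angle(pts, 0, 1, 2) >= angle_margin:
                if not (o_j == partner and role == "acceptor"):
                    return True
        # PEG hydroxyl donating to this water?
        if topo.atoms[o_j].group == "OH":
            (h_j,) = topo.attached_hydrogens(o_j)
            pts = np.array([coords[o_j], coords[h_j], o_w])
            if bond_angle(pts, 0, 1, 2) >= angle_margin:
                if not (o_j == partner and role == "donor"):
                    return True
    return False


def hydrate_fixture(
    conformer: Conformer,
    planted_bonds: list[tuple[int, str]],
    decoy_waters: int = 0,
    seed: int = 0,
    oo_distance: float = 2.8,
    decoy_min_distance: float = 5.0,
    max_attempts: int = 10_000,
) -> Conformer:
    """Plant waters at exact H-bond geometries plus far-away decoys.

    ``planted_bonds`` lists (peg_atom_index, role) pairs where ``role``
    describes the PEG side: ``"donor"`` means the PEG hydroxyl donates its
    H to the water (the index must be a hydroxyl O or its H);
    ``"acceptor"`` means the water donates to a PEG oxygen.  Planted
    waters sit at O···O = ``oo_distance`` with a linear (180°) D-H···A
    angle; placements and orientations are rejection-sampled until the
    water can register no bond besides the planted one under the default
    detection criteria (with safety margins).  Decoys are placed
    uniformly at more than ``decoy_min_distance`` from every PEG atom and
    every other water.  Waters already present on ``conformer`` are kept.
    """
    topo = conformer.topology
    coords = conformer.coords
    rng = np.random.default_rng(seed)
    waters: list[np.ndarray] = list(conformer.waters) if conformer.waters is not None else []

    heavy = np.array([a.element != "H" for a in topo.atoms])

    def sterically_ok(o_pos: np.ndarray) -> bool:
        d = np.linalg.norm(coords - o_pos, axis=1)
        # H-bonded hydrogens legitimately sit ~1.8 Å from the water oxygen,
        # so hydrogens only get a hard-clash clearance
        if np.any(d[heavy] < 2.2) or np.any(d[~heavy] < 1.6):
            return False
        return all(np.linalg.norm(w[0] - o_pos) >= 2.6 for w in waters)

    for peg_idx, role in planted_bonds:
        atom = topo.atoms[peg_idx]
        if role == "donor":
            if atom.element == "H" and atom.group == "OH":
                h_idx = peg_idx
                o_idx = next(
                    o for o in topo.hydroxyl_oxygens
                    if h_idx in topo.attached_hydrogens(o)
                )
            elif atom.element == "O" and atom.group == "OH":
                o_idx = peg_idx
                (h_idx,) = topo.attached_hydrogens(o_idx)
            else:
                raise ValueError(
                    f"atom {peg_idx} ({atom.element}/{atom.group}) cannot donate: "
                    "PEG donors are hydroxyl O-H groups"
                )
            # acceptor water along the extended O-H bond: D-H···A exactly 180°
            axis = coords[h_idx] - coords[o_idx]
            axis /= np.linalg.norm(axis)
            o_pos = coords[o_idx] + oo_distance * axis
            placed = False
            for _ in range(max_attempts):
                w = _water_at(o_pos, None, axis, rng)
                if sterically_ok(o_pos) and not _forms_unplanned_bond(
                    w, topo, coords, (o_idx, "donor")
                ):
                    waters.append(w)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"cannot plant a clean donor bond at atom {peg_idx}: "
                    "the hydroxyl direction is blocked"
                )
        elif role == "acceptor":
            if atom.element != "O":
                raise ValueError(
                    f"atom {peg_idx} ({atom.element}) cannot accept: not an oxygen"
                )
            placed = False
            for _ in range(max_attempts):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                o_pos = coords[peg_idx] + oo_distance * direction
                if not sterically_ok(o_pos):
                    continue
                w = _water_at(o_pos, coords[peg_idx], direction, rng)
                if not _forms_unplanned_bond(w, topo, coords, (peg_idx, "acceptor")):
                    waters.append(w)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"no clean water placement found around atom {peg_idx} "
                    f"in {max_attempts} attempts"
                )
        else:
            raise ValueError(f"unknown role {role!r}: use 'donor' or 'acceptor'")

    # decoys: uniform in the bounding box inflated by 2*decoy_min_distance
    lo = coords.min(axis=0) - 2.0 * decoy_min_distance
    hi = coords.max(axis=0) + 2.0 * decoy_min_distance
    for _ in range(decoy_waters):
        placed = False
        for _ in range(max_attempts):
            o_pos = rng.uniform(lo, hi)
            if np.any(np.linalg.norm(coords - o_pos, axis=1) < decoy_min_distance):
                continue
            if any(
                np.linalg.norm(w[0] - o_pos) < decoy_min_distance for w in waters
            ):
                continue
            axis = rng.normal(size=3)
            waters.append(_water_at(o_pos, None, axis / np.linalg.norm(axis), rng))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"no valid decoy position found in {max_attempts} attempts"
            )

    water_arr = np.stack(waters) if waters else None
    return conformer.with_waters(water_arr)


def hydrate_by_exposure(
    conformer: Conformer,
    surface_config=None,
    min_exposure: float = 1.0,
    seed: int = 0,
) -> Conformer:
    """Emulate a hydration shell: one donor water per exposed PEG oxygen.

    Every PEG oxygen whose per-atom solvent-accessible surface exceeds
    ``min_exposure`` (Å²) receives a water donating to it; additionally
    each exposed terminal hydroxyl donates to a water of its own.  Sites
    whose surroundings leave no clean placement direction are skipped —
    consistent with their being sterically shielded from the solvent.
    """
    from .surface import SurfaceConfig, sasa

    surface_config = surface_config or SurfaceConfig()
    per_atom, _ = sasa(conformer, surface_config)
    topo = conformer.topology
    planted: list[tuple[int, str]] = []
    for o in topo.oxygen_indices:
        if per_atom[o] > min_exposure:
            planted.append((o, "acceptor"))
    for o in topo.hydroxyl_oxygens:
        (h,) = topo.attached_hydrogens(o)
        if per_atom[h] > min_exposure:
            planted.append((o, "donor"))

    hydrated = conformer.with_waters(None)
    for i, site in enumerate(planted):
        try:
            hydrated = hydrate_fixture(
                hydrated, [site], decoy_waters=0, seed=seed + i, max_attempts=200
            )
        except RuntimeError:
            continue  # shielded site
    return hydrated


def hydrate_trajectory(
    trajectory: Trajectory,
    surface_config=None,
    min_exposure: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Apply :func:`hydrate_by_exposure` to every snapshot."""
    snaps = [
        hydrate_by_exposure(c, surface_config, min_exposure, seed=seed + 1000 * i)
        for i, c in enumerate(trajectory.snapshots)
    ]
    return Trajectory(trajectory.topology, snaps, trajectory.times.copy(), trajectory.seed)
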