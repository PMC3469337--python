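"""Cartesian chain construction from internal coordinates.

``place_chain`` extends a PEG chain atom by atom using the natural
extension reference frame (NeRF): each backbone atom is placed from its
three predecessors by a bond length, a bond angle and a torsion.  The
first three backbone atoms are placed canonically (origin, +x axis,
xy-plane with positive y) so construction is fully deterministic.
Torsions follow the IUPAC sign convention: looking from atom 2 to atom 3,
a positive torsion rotates the 3->4 bond clockwise relative to the
1->2 bond.  Measuring any internal coordinate used in construction on the
built chain reproduces the input value to numerical precision.

Hydrogens are placed deterministically after the backbone: the two CH2
hydrogens sit symmetrically about the plane of the carbon and its two
heavy neighbours (along the bisector of the X-C-Y angle, opened to the
H-C-H angle in the perpendicular direction); the hydroxyl hydrogens are
placed anti to the backbone by default (H-O-C-C torsion in the
GeometrySpec).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometrySpec
from .topology import PEGTopology, build_topology


# ----------------------------------------------------------------------
# elementary measurements

def bond_length(p: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(p[j] - p[i]))


def bond_angle(p: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = p[i] - p[j]
    v = p[k] - p[j]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate geometry: zero-length bond in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(p: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i-j-k-l in degrees, in (-180, 180], IUPAC convention."""
    b0 = p[j] - p[i]
    b1 = p[k] - p[j]
    b2 = p[l] - p[k]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise ValueError("degenerate geometry: zero-length central bond in torsion")
    m = np.cross(n1, b1 / nb1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """Place atom d from predecessors a, b, c.

    r is the c-d bond length (Å), theta the b-c-d angle (degrees), phi the
    a-b-c-d torsion (degrees).  Raises if a, b, c are collinear (the local
    frame is undefined).
    """
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = c - b
    nbc = np.linalg.norm(bc)
    bc = bc / nbc
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10 * max(1.0, np.linalg.norm(b - a)):
        raise ValueError("collinear predecessor triple: torsion frame undefined")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), -r * np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ----------------------------------------------------------------------
# data containers

@dataclass
class DihedralAssignment:
    """Backbone torsion targets for one conformer.

    ``cc_dihedrals`` holds the n O-C-C-O torsions (one per subunit, chain
    order); ``oc_dihedrals`` the 2n-2 C-C-O-C / C-O-C-C torsions flanking
    them, also in chain order.  Degrees, in (-180, 180].
    """

    cc_dihedrals: np.ndarray
    oc_dihedrals: np.ndarray

    def __post_init__(self) -> None:
        self.cc_dihedrals = np.asarray(self.cc_dihedrals, dtype=float)
        self.oc_dihedrals = np.asarray(self.oc_dihedrals, dtype=float)

    @classmethod
    def uniform(cls, n: int, cc: float, oc: float) -> "DihedralAssignment":
        return cls(np.full(n, float(cc)), np.full(max(2 * n - 2, 0), float(oc)))

    def validate_against(self, topology: PEGTopology) -> None:
        n = topology.n_subunits
        if len(self.cc_dihedrals) != n:
            raise ValueError(
                f"expected {n} CC dihedrals, got {len(self.cc_dihedrals)}"
            )
        if len(self.oc_dihedrals) != max(2 * n - 2, 0):
            raise ValueError(
                f"expected {max(2 * n - 2, 0)} OC dihedrals, got {len(self.oc_dihedrals)}"
            )


@dataclass
class Conformer:
    """One set of 3D coordinates (Å) for a PEG topology.

    ``waters`` is an optional (m, 3, 3) array of water molecules, each a
    (O, H1, H2) coordinate triple; waters are not part of the PEG surface
    or R_g but participate in H-bond detection and (optionally) surface
    occlusion.
    """

    topology: PEGTopology
    coords: np.ndarray
    waters: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if self.waters is not None:
            self.waters = np.asarray(self.waters, dtype=float)
            if self.waters.ndim != 3 or self.waters.shape[1:] != (3, 3):
                raise ValueError("waters must have shape (m, 3, 3)")

    @property
    def n_waters(self) -> int:
        return 0 if self.waters is None else len(self.waters)

    def with_waters(self, waters: np.ndarray | None) -> "Conformer":
        return Conformer(self.topology, self.coords.copy(), waters)

    def end_to_end_distance(self) -> float:
        """Distance between the two terminal hydroxyl oxygens, Å."""
        b = self.topology.backbone
        return bond_length(self.coords, b[0], b[-1])


# ----------------------------------------------------------------------
# chain construction

def place_chain(
    topology: PEGTopology,
    geometry: GeometrySpec,
    assignment: DihedralAssignment,
) -> Conformer:
    """Build Cartesian coordinates from internal coordinates.

    Backbone atoms are placed sequentially; the bond length / bond angle
    per position follows from the O-C-C-O-C-C... pattern (OC and CC bond
    lengths; COC, OCC and CCO angles), the torsion from ``assignment``.
    """
    assignment.validate_against(topology)
    n = topology.n_subunits
    b = topology.backbone
    coords = np.zeros((topology.n_atoms, 3))

    # canonical first three backbone atoms: O0 at origin, Ca1 on +x,
    # Cb1 in the xy-plane with positive y
    occ = np.radians(geometry.occ_angle)
    coords[b[0]] = (0.0, 0.0, 0.0)
    coords[b[1]] = (geometry.oc_length, 0.0, 0.0)
    coords[b[2]] = coords[b[1]] + geometry.cc_length * np.array(
        [-np.cos(occ), np.sin(occ), 0.0]
    )

    oc_iter = iter(assignment.oc_dihedrals)
    for i in range(3, len(b)):
        pos = i % 3
        if pos == 0:  # oxygen placed from Ca-Cb: CC torsion of subunit i//3
            r, theta = geometry.oc_length, geometry.cco_angle
            phi = assignment.cc_dihedrals[i // 3 - 1]
        elif pos == 1:  # Ca placed from Cb-O
            r, theta = geometry.oc_length, geometry.coc_angle
            phi = next(oc_iter)
        else:  # Cb placed from O-Ca
            r, theta = geometry.cc_length, geometry.occ_angle
            phi = next(oc_iter)
        coords[b[i]] = place_atom(
            coords[b[i - 3]], coords[b[i - 2]], coords[b[i - 1]], r, theta, phi
        )

    _place_ch2_hydrogens(topology, geometry, coords)
    _place_hydroxyl_hydrogens(topology, geometry, coords)
    return Conformer(topology, coords)


def _place_ch2_hydrogens(
    topology: PEGTopology, geometry: GeometrySpec, coords: np.ndarray
) -> None:
    # symmetric placement: H directions = cos(hch/2) * (anti-bisector of the
    # two heavy-neighbour bonds) +/- sin(hch/2) * (normal of the X-C-Y plane)
    half = np.radians(geometry.hch_angle) / 2.0
    b = topology.backbone
    pos_in_backbone = {idx: i for i, idx in enumerate(b)}
    for c in topology.carbon_indices:
        i = pos_in_backbone[c]
        u = coords[b[i - 1]] - coords[c]
        v = coords[b[i + 1]] - coords[c]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        bis = -(u + v)
        bis /= np.linalg.norm(bis)
        nrm = np.cross(u, v)
        nrm /= np.linalg.norm(nrm)
        h1, h2 = topology.attached_hydrogens(c)
        coords[h1] = coords[c] + geometry.ch_length * (
            np.cos(half) * bis + np.sin(half) * nrm
        )
        coords[h2] = coords[c] + geometry.ch_length * (
            np.cos(half) * bis - np.sin(half) * nrm
        )


def _place_hydroxyl_hydrogens(
    topology: PEGTopology, geometry: GeometrySpec, coords: np.ndarray
) -> None:
    b = topology.backbone
    for o_idx, frame in (
        (b[0], (b[2], b[1], b[0])),
        (b[-1], (b[-3], b[-2], b[-1])),
    ):
        (h,) = topology.attached_hydrogens(o_idx)
        coords[h] = place_atom(
            coords[frame[0]],
            coords[frame[1]],
            coords[frame[2]],
            geometry.oh_length,
            geometry.coh_angle,
            geometry.hoc_torsion,
        )


def build_ideal_helix(n: int, geometry: GeometrySpec | None = None) -> Conformer:
    """The ideal all-gauche helix: every O-C-C-O torsion at the gauche
    reference value (uniform sign), every OC torsion at the trans value.

    For n >= 5 the helicality of the result is 1.0 (all CC dihedrals in a
    single same-signed gauche run); for n < 4 the run-length rule cannot
    be met and helicality is 0 by definition.
    """
    if n < 2:
        raise ValueError(f"ideal helix needs n >= 2, got {n}")
    geometry = geometry or GeometrySpec.crystal()
    topo = build_topology(n)
    assignment = DihedralAssignment.uniform(
        n, geometry.cc_dihedral_gauche, geometry.oc_dihedral_trans
    )
    return place_chain(topo, geometry, assignment)


def build_ideal_linear(n: int, geometry: GeometrySpec | None = None) -> Conformer:
    """The fully extended chain: every backbone torsion at 180°."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    geometry = geometry or GeometrySpec.crystal()
    topo = build_topology(n)
    assignment = DihedralAssignment.uniform(n, 180.0, 180.0)
    return place_chain(topo, geometry, assignment)
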