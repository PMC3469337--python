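"""Geometric PEG-water hydrogen-bond detection.

A donor-H / acceptor pair is a hydrogen bond iff the donor-oxygen to
acceptor-oxygen distance is at most ``max_da_distance`` and the
donor-H···acceptor angle is at least ``min_dha_angle``.  The criterion is
purely geometric (defaults 3.5 Å / 135°, standard practice for water);
there is no energy model.  Only PEG-water bonds are counted: PEG ether
and hydroxyl oxygens accept, PEG hydroxyl O-H groups donate, water does
both; water-water and intramolecular PEG-PEG pairs are ignored.
Bookkeeping is PEG-sided: "donated" means the PEG provides the hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .builder import Conformer, bond_angle
from .sampling import Trajectory


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # donor O to acceptor O, Å
    min_dha_angle: float = 135.0  # donor-H···acceptor, degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("min_dha_angle must lie in (0, 180]")


class HBond(NamedTuple):
    donor: tuple[str, int]  # ("peg", atom index) or ("water", water index)
    acceptor: tuple[str, int]
    distance: float  # donor O ··· acceptor O, Å
    angle: float  # donor-H···acceptor, degrees


@dataclass
class HBondSummary:
    total: int
    donated: int  # PEG provides the H
    accepted: int  # PEG accepts from water
    per_subunit: float

    def __post_init__(self) -> None:
        if self.donated + self.accepted != self.total:
            raise ValueError("donated + accepted must equal total")


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    return bond_angle(np.array([d, h, a]), 0, 1, 2)


def detect_hbonds(
    conformer: Conformer, criteria: HBondCriteria | None = None
) -> tuple[list[HBond], HBondSummary]:
    """Enumerate PEG-water hydrogen bonds in one conformer."""
    criteria = criteria or HBondCriteria()
    if conformer.waters is None or len(conformer.waters) == 0:
        raise ValueError("conformer carries no waters; nothing to detect")
    topo = conformer.topology
    coords = conformer.coords
    waters = conformer.waters
    if waters.shape[1] != 3:
        raise ValueError("each water needs an O and two H positions")

    peg_acceptors = topo.oxygen_indices
    peg_donors = []  # (O index, H index) of hydroxyls
    for o in topo.hydroxyl_oxygens:
        hs = topo.attached_hydrogens(o)
        if not hs:
            raise ValueError(f"hydroxyl oxygen {o} is missing its hydrogen")
        peg_donors.extend((o, h) for h in hs)

    bonds: list[HBond] = []
    w_o = waters[:, 0]

    # water donates to PEG oxygen
    for wi, water in enumerate(waters):
        for o_j in peg_acceptors:
            dist = float(np.linalg.norm(water[0] - coords[o_j]))
            if dist > criteria.max_da_distance:
                continue
            for h in water[1:]:
                ang = _dha_angle(water[0], h, coords[o_j])
                if ang >= criteria.min_dha_angle:
                    bonds.append(HBond(("water", wi), ("peg", o_j), dist, ang))

    # PEG hydroxyl donates to water oxygen
    for o_i, h_i in peg_donors:
        dists = np.linalg.norm(w_o - coords[o_i], axis=1)
        for wi in np.flatnonzero(dists <= criteria.max_da_distance):
            ang = _dha_angle(coords[o_i], coords[h_i], w_o[wi])
            if ang >= criteria.min_dha_angle:
                bonds.append(HBond(("peg", o_i), ("water", int(wi)), float(dists[wi]), ang))

    donated = sum(1 for b in bonds if b.donor[0] == "peg")
    accepted = sum(1 for b in bonds if b.acceptor[0] == "peg")
    summary = HBondSummary(
        total=len(bonds),
        donated=donated,
        accepted=accepted,
        per_subunit=len(bonds) / topo.n_subunits,
    )
    return bonds, summary


def hbonds_per_subunit(
    trajectory: Trajectory,
    criteria: HBondCriteria | None = None,
    window: slice | None = None,
) -> float:
    """Ensemble mean of (total PEG-water H-bonds)/(n subunits)."""
    snaps = trajectory.snapshots[window] if window is not None else trajectory.snapshots
    if not snaps:
        raise ValueError("empty trajectory window")
    if all(c.waters is None or len(c.waters) == 0 for c in snaps):
        raise ValueError("dry trajectory: no snapshot carries waters")
    vals = []
    for c in snaps:
        if c.waters is None or len(c.waters) == 0:
            vals.append(0.0)
        else:
            _, summary = detect_hbonds(c, criteria)
            vals.append(summary.per_subunit)
    return float(np.mean(vals))
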