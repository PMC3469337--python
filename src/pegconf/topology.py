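"""Molecular topology of a PEG chain HO-(CH2-CH2-O)n-H.

The topology fixes the atom ordering used everywhere else in the package:
atoms are listed along the chain, each heavy atom followed by its
hydrogens::

    O0 H | Ca H H  Cb H H  O1 | Ca H H  Cb H H  O2 | ... | On H

which gives ``7 n + 3`` atoms for ``n`` subunits (2n C, n+1 O, 4n+2 H).
Group labels follow the surface-chemistry convention: each CH2 carbon and
its hydrogens are ``CH``; ether oxygens are ``O``; the two terminal
oxygens and their (hydroxyl) hydrogens are ``OH``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

ATOMIC_MASS = {"C": 12.011, "O": 15.999, "H": 1.008}

#: molar mass of one ethylene-oxide repeat / of water, Da
SUBUNIT_MASS = 2 * ATOMIC_MASS["C"] + ATOMIC_MASS["O"] + 4 * ATOMIC_MASS["H"]
END_MASS = ATOMIC_MASS["O"] + 2 * ATOMIC_MASS["H"]


class Atom(NamedTuple):
    element: str  # C, O or H
    group: str  # CH, O or OH
    subunit: int  # 1-based repeat index the atom belongs to


def peg_molecular_weight(n: int) -> float:
    """Molar mass of HO-(CH2CH2O)n-H in Da (= 44.053 n + 18.015)."""
    return SUBUNIT_MASS * n + END_MASS


@dataclass(frozen=True)
class PEGTopology:
    """Atom/bond graph of an n-subunit PEG chain.

    Besides the raw atom and bond lists the topology precomputes the index
    tuples needed for geometric measurement: backbone indices, torsion
    quadruples (split into the n O-C-C-O "CC dihedrals" and the 2n-2
    C-C-O-C / C-O-C-C "OC dihedrals"), bond-angle triples per type and
    bond pairs per type.
    """

    n_subunits: int
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int], ...]
    backbone: tuple[int, ...] = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[a.element] for a in self.atoms])

    @property
    def molecular_weight(self) -> float:
        return float(self.masses.sum())

    # ------------------------------------------------------------------
    # index helpers (chain order throughout)

    @property
    def cc_torsion_quads(self) -> list[tuple[int, int, int, int]]:
        """O-C-C-O quadruples, one per subunit."""
        b = self.backbone
        return [tuple(b[3 * k : 3 * k + 4]) for k in range(self.n_subunits)]

    @property
    def oc_torsion_quads(self) -> list[tuple[int, int, int, int]]:
        """C-C-O-C and C-O-C-C quadruples adjacent to the O-C-C-O torsions."""
        b = self.backbone
        quads = []
        for i in range(4, len(b)):
            if i % 3 != 0:  # i % 3 == 0 are the O-C-C-O torsions
                quads.append(tuple(b[i - 3 : i + 1]))
        return quads

    def angle_triples(self, kind: str) -> list[tuple[int, int, int]]:
        """Bond-angle triples of one type: 'coc', 'occ', 'cco' or 'hch'.

        OCC is the angle at the first carbon of a subunit (O->Ca->Cb along
        the chain), CCO the angle at the second (Ca->Cb->O); both are
        carbon-centred O/C angles distinguished by chain direction, as in
        the crystallographic bookkeeping.
        """
        b = self.backbone
        if kind == "coc":
            return [(b[i - 1], b[i], b[i + 1]) for i in range(1, len(b) - 1) if i % 3 == 0]
        if kind == "occ":
            return [(b[i - 1], b[i], b[i + 1]) for i in range(1, len(b) - 1) if i % 3 == 1]
        if kind == "cco":
            return [(b[i - 1], b[i], b[i + 1]) for i in range(1, len(b) - 1) if i % 3 == 2]
        if kind == "hch":
            triples = []
            for c in self.carbon_indices:
                hs = self.attached_hydrogens(c)
                triples.append((hs[0], c, hs[1]))
            return triples
        raise ValueError(f"unknown angle kind {kind!r}")

    def bond_pairs(self, kind: str) -> list[tuple[int, int]]:
        """Bond pairs of one type: 'oc', 'cc', 'ch' or 'oh'."""
        want = {"oc": {"O", "C"}, "cc": {"C"}, "ch": {"C", "H"}, "oh": {"O", "H"}}
        try:
            elems = want[kind]
        except KeyError:
            raise ValueError(f"unknown bond kind {kind!r}") from None
        out = []
        for i, j in self.bonds:
            if {self.atoms[i].element, self.atoms[j].element} == elems:
                out.append((i, j))
        return out

    @property
    def carbon_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element == "C"]

    @property
    def oxygen_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element == "O"]

    @property
    def hydroxyl_oxygens(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element == "O" and a.group == "OH"]

    @property
    def ether_oxygens(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element == "O" and a.group == "O"]

    def attached_hydrogens(self, index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == index and self.atoms[j].element == "H":
                out.append(j)
            elif j == index and self.atoms[i].element == "H":
                out.append(i)
        return out


def build_topology(n: int) -> PEGTopology:
    """Build the topology of HO-(CH2CH2O)n-H.

    Parameters
    ----------
    n
        Number of ethylene-oxide repeats; must be a positive integer.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError(f"n must be an integer, got {type(n).__name__}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    backbone: list[int] = []

    def add(element: str, group: str, subunit: int, bond_to: int | None = None) -> int:
        atoms.append(Atom(element, group, subunit))
        idx = len(atoms) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    o_prev = add("O", "OH", 1)  # terminal hydroxyl oxygen
    backbone.append(o_prev)
    add("H", "OH", 1, bond_to=o_prev)
    for k in range(1, n + 1):
        ca = add("C", "CH", k, bond_to=o_prev)
        backbone.append(ca)
        add("H", "CH", k, bond_to=ca)
        add("H", "CH", k, bond_to=ca)
        cb = add("C", "CH", k, bond_to=ca)
        backbone.append(cb)
        add("H", "CH", k, bond_to=cb)
        add("H", "CH", k, bond_to=cb)
        o_group = "OH" if k == n else "O"
        o_prev = add("O", o_group, k, bond_to=cb)
        backbone.append(o_prev)
    add("H", "OH", n, bond_to=o_prev)  # terminal hydroxyl hydrogen

    return PEGTopology(
        n_subunits=int(n),
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        backbone=tuple(backbone),
    )
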