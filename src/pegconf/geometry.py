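"""Internal-coordinate parameter sets for PEG chain construction.

A :class:`GeometrySpec` holds the bond lengths, bond angles and reference
torsion values used to build PEG conformers.  The default parameter set is
the crystallographic one (high-resolution PEG crystal structure); every
field can be overridden, and a spec can be read from / written to a plain
``key = value`` config file (units: Å and degrees throughout).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GeometrySpec:
    """Internal-coordinate parameters of a PEG chain.

    Lengths in Å, angles and torsions in degrees.  Torsions follow the
    IUPAC sign convention (clockwise positive viewed from atom 1 towards
    atom 4); values lie in (−180, 180].

    The defaults are the crystal-structure values; the C–H and O–H
    geometries are not part of that record, so standard sp3 values are
    used (C–H 1.09 Å, O–H 0.96 Å, C–O–H 108.5°).
    """

    oc_length: float = 1.43
    cc_length: float = 1.48
    ch_length: float = 1.09
    oh_length: float = 0.96
    hch_angle: float = 109.01
    cco_angle: float = 109.96
    coc_angle: float = 115.64
    occ_angle: float = 109.49
    coh_angle: float = 108.5
    cc_dihedral_gauche: float = -74.95
    oc_dihedral_trans: float = 177.41
    # torsion used to place the hydroxyl hydrogens (H-O-C-C), anti by default
    hoc_torsion: float = 180.0

    def __post_init__(self) -> None:
        for name in ("oc_length", "cc_length", "ch_length", "oh_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("hch_angle", "cco_angle", "coc_angle", "occ_angle", "coh_angle"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must lie in (0, 180), got {v}")
        for name in ("cc_dihedral_gauche", "oc_dihedral_trans", "hoc_torsion"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} must lie in (-180, 180], got {v}")

    @classmethod
    def crystal(cls) -> "GeometrySpec":
        """The crystal-structure parameter set (the class defaults)."""
        return cls()

    def replace(self, **changes) -> "GeometrySpec":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometrySpec":
        """Read a spec from a ``key = value`` config file.

        Unknown keys raise; missing keys keep their defaults.  Lines that
        are blank or start with ``#`` are ignored.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        values: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown geometry parameter {key!r}")
            try:
                values[key] = float(val.strip())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric value {val!r}") from exc
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [
            "# PEG internal-coordinate parameters (lengths in Angstrom, angles in degrees)"
        ]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")
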