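"""Per-conformer geometric measurement and ensemble statistics.

This module measures what the analysis of a trajectory snapshot needs:
all typed bond lengths, bond angles and backbone torsions; the
gauche/trans classification of the O-C-C-O ("CC") dihedrals; the
helicality statistic (fraction of CC dihedrals in runs of >= 4
consecutive same-signed gauche states); the radius of gyration; the
equilibration window of a time series; and ensemble averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .builder import Conformer, bond_angle, bond_length, dihedral_angle

GAUCHE_PLUS = "g+"
GAUCHE_MINUS = "g-"
TRANS = "trans"
OTHER = "other"


@dataclass(frozen=True)
class ClassifierConfig:
    """Torsion-state bands (degrees) and the helical run length.

    The gauche band is 50-100° in magnitude, signed by handedness; the
    trans band 150-180° in magnitude (symmetric width to the gauche band;
    the trans boundaries are a package convention, not a crystallographic
    one).  Band boundaries are inclusive.  A CC dihedral is helical iff it
    belongs to a run of at least ``min_run`` consecutive dihedrals of the
    same signed gauche state.
    """

    gauche_lo: float = 50.0
    gauche_hi: float = 100.0
    trans_lo: float = 150.0
    min_run: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.gauche_lo < self.gauche_hi < 180.0:
            raise ValueError("need 0 < gauche_lo < gauche_hi < 180")
        if not self.gauche_hi <= self.trans_lo <= 180.0:
            raise ValueError("trans_lo must lie between gauche_hi and 180")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")


@dataclass
class GeometryMeasurements:
    """All typed internal coordinates of one conformer (degrees / Å)."""

    cc_dihedrals: np.ndarray
    oc_dihedrals: np.ndarray
    coc_angles: np.ndarray
    occ_angles: np.ndarray
    cco_angles: np.ndarray
    hch_angles: np.ndarray
    oc_lengths: np.ndarray
    cc_lengths: np.ndarray
    ch_lengths: np.ndarray


@dataclass
class ConformerMetrics:
    """Secondary/tertiary-structure summary of one conformer."""

    helicality: float
    gauche_fraction: float
    g_plus_fraction: float
    g_minus_fraction: float
    rg: float


def measure_geometry(conformer: Conformer) -> GeometryMeasurements:
    """Enumerate every typed bond, angle and backbone torsion."""
    topo = conformer.topology
    p = conformer.coords

    def lengths(kind: str) -> np.ndarray:
        vals = np.array([bond_length(p, i, j) for i, j in topo.bond_pairs(kind)])
        if vals.size and np.any(vals < 1e-8):
            raise ValueError("degenerate geometry: zero-length bond")
        return vals

    return GeometryMeasurements(
        cc_dihedrals=np.array([dihedral_angle(p, *q) for q in topo.cc_torsion_quads]),
        oc_dihedrals=np.array([dihedral_angle(p, *q) for q in topo.oc_torsion_quads]),
        coc_angles=np.array([bond_angle(p, *t) for t in topo.angle_triples("coc")]),
        occ_angles=np.array([bond_angle(p, *t) for t in topo.angle_triples("occ")]),
        cco_angles=np.array([bond_angle(p, *t) for t in topo.angle_triples("cco")]),
        hch_angles=np.array([bond_angle(p, *t) for t in topo.angle_triples("hch")]),
        oc_lengths=lengths("oc"),
        cc_lengths=lengths("cc"),
        ch_lengths=lengths("ch"),
    )


def classify_dihedrals(
    cc_dihedrals: Sequence[float], config: ClassifierConfig | None = None
) -> list[str]:
    """Classify signed CC dihedrals into g+ / g- / trans / other.

    g+ iff value in [gauche_lo, gauche_hi]; g- iff in the mirrored band;
    trans iff |value| in [trans_lo, 180]; anything else is "other".
    """
    config = config or ClassifierConfig()
    out = []
    for v in np.asarray(cc_dihedrals, dtype=float):
        if config.gauche_lo <= v <= config.gauche_hi:
            out.append(GAUCHE_PLUS)
        elif -config.gauche_hi <= v <= -config.gauche_lo:
            out.append(GAUCHE_MINUS)
        elif config.trans_lo <= abs(v) <= 180.0:
            out.append(TRANS)
        else:
            out.append(OTHER)
    return out


def helicality(states: Sequence[str], config: ClassifierConfig | None = None) -> float:
    """Fraction of CC dihedrals inside same-signed gauche runs of length
    >= min_run.

    Runs must be of ONE signed gauche state (helices require uniform
    handedness); a g+ run abutting a g- run does not merge.  Returns 0 for
    sequences shorter than min_run.
    """
    config = config or ClassifierConfig()
    states = list(states)
    total = len(states)
    if total < config.min_run:
        return 0.0
    helical = 0
    i = 0
    while i < total:
        if states[i] in (GAUCHE_PLUS, GAUCHE_MINUS):
            j = i
            while j < total and states[j] == states[i]:
                j += 1
            if j - i >= config.min_run:
                helical += j - i
            i = j
        else:
            i += 1
    return helical / total


def conformer_metrics(
    conformer: Conformer,
    config: ClassifierConfig | None = None,
    mass_weighted: bool = True,
) -> ConformerMetrics:
    config = config or ClassifierConfig()
    cc = np.array(
        [dihedral_angle(conformer.coords, *q) for q in conformer.topology.cc_torsion_quads]
    )
    states = classify_dihedrals(cc, config)
    n = len(states)
    gp = states.count(GAUCHE_PLUS) / n
    gm = states.count(GAUCHE_MINUS) / n
    return ConformerMetrics(
        helicality=helicality(states, config),
        gauche_fraction=gp + gm,
        g_plus_fraction=gp,
        g_minus_fraction=gm,
        rg=radius_of_gyration(conformer, mass_weighted=mass_weighted),
    )


def rg_of_points(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted RMS distance of a point set from its weighted centroid."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("radius of gyration needs >= 2 points")
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, dtype=float)
    center = np.average(coords, axis=0, weights=w)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def radius_of_gyration(conformer: Conformer, mass_weighted: bool = True) -> float:
    """RMS distance of the PEG atoms from their centroid, Å.

    Mass-weighted by default (``mass_weighted=False`` switches to the
    geometric definition for sensitivity checks); waters are excluded.
    """
    return rg_of_points(
        conformer.coords,
        conformer.topology.masses if mass_weighted else None,
    )


class EquilibriumWindow(NamedTuple):
    start: int  # first snapshot index of the stationary window
    stationary: bool  # False if no stationary suffix was found


def equilibrium_window(
    series: Sequence[float],
    block_size: int = 10,
    alpha: float = 0.05,
) -> EquilibriumWindow:
    """Find the earliest snapshot from which a series shows no time trend.

    The series is block-averaged (blocks of ``block_size`` snapshots) and
    scanned from the start: the window beginning at each successive block
    is kept as soon as the OLS slope of block mean vs block index is not
    significantly different from zero (two-sided t-test at ``alpha``).
    Returns index 0 for an already-stationary series; if no suffix with at
    least three blocks is stationary, returns the whole series flagged
    ``stationary=False``.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 10:
        raise ValueError("equilibrium detection needs >= 10 snapshots")
    n_blocks = len(y) // block_size
    blocks = y[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    x = np.arange(n_blocks, dtype=float)
    for start in range(0, n_blocks - 2):
        yb = blocks[start:]
        if np.allclose(yb, yb[0]):
            return EquilibriumWindow(start * block_size, True)
        res = stats.linregress(x[start:], yb)
        if res.pvalue > alpha:
            return EquilibriumWindow(start * block_size, True)
    return EquilibriumWindow(0, False)


class EnsembleAverage(NamedTuple):
    mean: float
    sd: float
    cv: float


def ensemble_average(
    trajectory,
    metric: Callable[[Conformer], float] | Sequence[float] | np.ndarray,
    window: slice | None = None,
) -> EnsembleAverage:
    """Mean, SD and CV of a per-snapshot metric over a window.

    ``metric`` is either a callable evaluated on each snapshot or a
    precomputed per-snapshot sequence.  ``window`` is a slice into the
    snapshot axis (default: all snapshots).  SD is the sample SD over the
    window (ddof=1; 0 for a single snapshot); CV = SD/mean (nan for zero
    mean).
    """
    if callable(metric):
        values = np.array([metric(c) for c in trajectory.snapshots])
    else:
        values = np.asarray(metric, dtype=float)
    if window is not None:
        values = values[window]
    if values.size == 0:
        raise ValueError("empty ensemble window")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    cv = sd / mean if mean != 0.0 else float("nan")
    return EnsembleAverage(mean, sd, cv)
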