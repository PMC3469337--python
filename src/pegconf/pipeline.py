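"""The end-to-end analysis pipeline.

``run_pipeline`` binds the stages together: for every requested chain
length it generates (or loads) a conformer ensemble, measures secondary
and tertiary structure, surface and (optionally) H-bond descriptors,
averages them over the equilibrated window, and fits the R_g-MW scaling
law; ideal helical/linear reference curves and binodal / polarity
correlations are produced when requested.  Every run writes tidy CSV
tables plus a provenance manifest (config, seed, package version) and is
bit-identical when rerun with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .builder import build_ideal_helix, build_ideal_linear
from .fits import (
    BinodalDataset,
    PolarityDataset,
    et30_slope,
    fit_scaling,
    linear_fit,
    min_peg_for_phase,
    relative_molar_fraction,
)
from .geometry import GeometrySpec
from .hbonds import HBondCriteria, detect_hbonds
from .measure import (
    ClassifierConfig,
    conformer_metrics,
    ensemble_average,
    equilibrium_window,
)
from .sampling import RISWeights, hydrate_by_exposure, sample_trajectory
from .surface import SurfaceConfig, hydrophobic_fraction, sasa
from .topology import peg_molecular_weight


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    subunits: tuple[int, ...] = (6, 11, 16, 26, 41, 61, 81)
    n_snapshots: int = 100
    seed: int = 0
    weights: RISWeights = field(default_factory=RISWeights)
    geometry: GeometrySpec = field(default_factory=GeometrySpec.crystal)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    output_dir: Path = Path("pegconf_results")
    ideal_structures: bool = True  # emit the helical/linear reference curves
    with_hbonds: bool = False  # hydrate snapshots and count H-bonds (slower)
    surface_every: int = 10  # surface descriptors on every k-th snapshot
    binodal_csv: Path | None = None
    polarity_csv: Path | None = None

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.surface_every < 1:
            raise ValueError("surface_every must be >= 1")
        if not self.subunits:
            raise ValueError("need at least one subunit count")


@dataclass
class PipelineResult:
    ensemble_table: pd.DataFrame
    scaling_fit: object
    ideal_table: pd.DataFrame | None = None
    binodal_fit: object | None = None
    polarity_slopes: dict | None = None


def _log(msg: str) -> None:
    print(f"[pegconf] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    # fail early on missing input tables
    for label, path in (("binodal", config.binodal_csv), ("polarity", config.polarity_csv)):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{label} CSV not found: {path}")

    tidy_rows = []
    ensemble_rows = []
    for n in config.subunits:
        _log(f"sampling n={n}: {config.n_snapshots} snapshots")
        traj = sample_trajectory(
            n,
            config.n_snapshots,
            weights=config.weights,
            geometry=config.geometry,
            seed=config.seed + n,
        )
        metrics = [conformer_metrics(c, config.classifier) for c in traj.snapshots]
        rg = np.array([m.rg for m in metrics])
        window = equilibrium_window(rg) if len(rg) >= 10 else None
        win = slice(window.start, None) if window is not None else slice(None)

        surf_fracs = []
        hb_per_subunit = []
        for i in range(0, traj.n_snapshots, config.surface_every):
            snap = traj.snapshots[i]
            _, report = sasa(snap, config.surface)
            surf_fracs.append(hydrophobic_fraction(report))
            if config.with_hbonds:
                hydrated = hydrate_by_exposure(
                    snap, config.surface, seed=config.seed + 7919 * i
                )
                if hydrated.n_waters:
                    _, summary = detect_hbonds(hydrated, config.hbond_criteria)
                    hb_per_subunit.append(summary.per_subunit)
                else:
                    hb_per_subunit.append(0.0)

        for i, m in enumerate(metrics):
            for name, value in (
                ("helicality", m.helicality),
                ("gauche_fraction", m.gauche_fraction),
                ("rg", m.rg),
            ):
                tidy_rows.append(
                    {"n_subunits": n, "snapshot": i, "time_ps": traj.times[i],
                     "metric": name, "value": value}
                )

        rg_stats = ensemble_average(traj, rg, win)
        row = {
            "n_subunits": n,
            "molecular_weight": peg_molecular_weight(n),
            "rg_mean": rg_stats.mean,
            "rg_sd": rg_stats.sd,
            "rg_cv": rg_stats.cv,
            "helicality_mean": float(np.mean([m.helicality for m in metrics])),
            "gauche_fraction_mean": float(np.mean([m.gauche_fraction for m in metrics])),
            "hydrophobic_fraction_mean": float(np.mean(surf_fracs)),
            "equilibrium_start": 0 if window is None else window.start,
        }
        if config.with_hbonds:
            row["hbonds_per_subunit_mean"] = float(np.mean(hb_per_subunit))
        ensemble_rows.append(row)

    tidy = pd.DataFrame(tidy_rows)
    ensemble = pd.DataFrame(ensemble_rows)
    tidy.to_csv(out / "snapshot_metrics.csv", index=False)
    ensemble.to_csv(out / "ensemble_metrics.csv", index=False)

    scaling = None
    if len(ensemble) >= 3:
        scaling = fit_scaling(
            ensemble[["molecular_weight", "rg_mean"]].to_numpy(),
            method="lar",
            seed=config.seed,
        )
        (out / "scaling_fit.txt").write_text(scaling.summary())
        _log(scaling.summary().strip())
    else:
        _log("fewer than 3 chain lengths: skipping the scaling fit")

    ideal_table = None
    if config.ideal_structures:
        ideal_table = ideal_reference_curves(
            range(min(config.subunits), max(config.subunits) + 1),
            config.geometry,
            config.surface,
        )
        ideal_table.to_csv(out / "ideal_reference_curves.csv", index=False)

    binodal_fit = None
    if config.binodal_csv is not None:
        binodal_fit = correlate_binodal(
            BinodalDataset.from_csv(config.binodal_csv), ensemble, out
        )

    polarity_slopes = None
    if config.polarity_csv is not None:
        polarity_slopes = polarity_analysis(
            PolarityDataset.from_csv(config.polarity_csv), out
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        ensemble_table=ensemble,
        scaling_fit=scaling,
        ideal_table=ideal_table,
        binodal_fit=binodal_fit,
        polarity_slopes=polarity_slopes,
    )


def ideal_reference_curves(ns, geometry=None, surface_config=None) -> pd.DataFrame:
    """Hydrophobic fraction of the ideal helical and linear chains per n."""
    geometry = geometry or GeometrySpec.crystal()
    surface_config = surface_config or SurfaceConfig()
    rows = []
    for n in ns:
        for shape, builder in (("helical", build_ideal_helix), ("linear", build_ideal_linear)):
            conf = builder(n, geometry)
            _, report = sasa(conf, surface_config)
            rows.append(
                {
                    "n_subunits": n,
                    "structure": shape,
                    "hydrophobic_fraction": hydrophobic_fraction(report),
                    "sas_total": report.sas_total,
                }
            )
    return pd.DataFrame(rows)


def correlate_binodal(binodal: BinodalDataset, ensemble: pd.DataFrame, out: Path):
    """Correlate minimum PEG %w/w for phase formation with the simulated
    hydrophobic fraction, per PO4 level (matching curves by PEG MW to the
    nearest simulated chain length)."""
    fits = {}
    rows = []
    mws = ensemble["molecular_weight"].to_numpy()
    levels = sorted(
        set.intersection(
            *[set(np.round(c[:, 0], 6)) for c in binodal.curves.values()]
        )
    ) or None
    if levels is None:
        raise ValueError("binodal curves share no common PO4 levels")
    for level in levels:
        xs, ys = [], []
        for mw, _pts in sorted(binodal.curves.items()):
            nearest = int(np.argmin(np.abs(mws - mw)))
            frac = ensemble["hydrophobic_fraction_mean"].iloc[nearest]
            peg_needed = min_peg_for_phase(binodal, mw, level)
            xs.append(frac)
            ys.append(peg_needed)
            rows.append(
                {"po4_pct": level, "peg_mw": mw, "hydrophobic_fraction": frac,
                 "min_peg_pct": peg_needed}
            )
        if len(xs) >= 3:
            fits[level] = linear_fit(xs, ys)
    pd.DataFrame(rows).to_csv(out / "binodal_correlation.csv", index=False)
    with open(out / "binodal_fits.txt", "w") as fh:
        for level, fit in fits.items():
            fh.write(f"PO4 {level}%: {fit.summary()}")
    return fits


def polarity_analysis(dataset: PolarityDataset, out: Path) -> dict:
    """ET(30) slopes of the linear region per PEG MW, on relative fractions."""
    corrected = relative_molar_fraction(dataset)
    slopes = {}
    for mw, pts in sorted(corrected.items()):
        try:
            slopes[mw] = et30_slope(pts)
        except ValueError as exc:
            _log(f"polarity series MW {mw}: {exc}")
    rows = [
        {"peg_mw": mw, "slope": fit.slope, "intercept": fit.intercept,
         "r_squared": fit.r_squared}
        for mw, fit in slopes.items()
    ]
    pd.DataFrame(rows).to_csv(out / "polarity_slopes.csv", index=False)
    return slopes


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return convert(config)
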