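# pegconf

Construction and conformational analysis of polyethylene glycol (PEG)
chains in the size range used in protein purification (~300–3500 Da,
n = 6–81 ethylene-oxide repeats).

PEG is the workhorse of aqueous two-phase extraction, precipitation and
PEGylation, yet how chain length shapes its surface chemistry and solvent
interaction is not obvious from the formula HO–(CH₂CH₂O)ₙ–H. This package
provides the desk-side half of that investigation:

* **Reference structures from internal coordinates.** Chains are built
  atom-by-atom with the natural extension reference frame (NeRF) from a
  crystallographic parameter set (O–C 1.43 Å, C–C 1.48 Å, C–O–C 115.64°,
  O–C–C–O gauche torsion −74.95°, C–O–C–C trans torsion 177.41°, …),
  giving the ideal all-gauche **helix** and the fully extended (all-trans)
  **linear** chain at any n.
* **Synthetic conformer ensembles.** A rotational-isomeric-state (RIS)
  sampler draws each snapshot's O–C–C–O torsions from a
  gauche⁺/gauche⁻/trans mixture with Gaussian jitter, rejecting
  self-overlapping chains — a statistical stand-in for solution MD
  trajectories.
* **Descriptors.** Per-snapshot internal coordinates; gauche/trans state
  classification (|φ| ∈ [50°, 100°] gauche, signed by handedness);
  **helicality** (the fraction of O–C–C–O torsions inside runs of ≥ 4
  consecutive same-handed gauche states); radius of gyration R_g;
  Shrake–Rupley solvent-accessible surface decomposed into CH / ether-O /
  hydroxyl groups with the **surface hydrophobic fraction**
  SAS(CH)/SAS(total); voxel-counted solvent-accessible volume (1.4 Å
  probe); geometric PEG–water hydrogen-bond detection (O···O ≤ 3.5 Å,
  D–H···A ≥ 135°).
* **Fits.** The Flory scaling law R_g ∝ MW^ν on log–log axes by ordinary
  or least-average-residual (L1) regression with a bootstrap 95% CI
  (ν = 0.5 is the ideal-chain reference); linear descriptor correlations;
  binodal interpolation (minimum PEG %w/w for two-phase formation at a
  given phosphate level); ET(30) polarity calibration and linear-region
  slopes on relative molar fractions.

## Worked example

Crystal-parameter round trip — build the ideal helix and re-measure it:

```python
>>> from pegconf import GeometrySpec, build_ideal_helix, measure_geometry
>>> meas = measure_geometry(build_ideal_helix(12, GeometrySpec.crystal()))
>>> float(meas.coc_angles.mean()), float(meas.cc_dihedrals[0])
(115.64, -74.95)
```

A small pipeline run — four chain lengths, 40 snapshots each, with the
bundled **synthetic, illustrative** binodal and polarity tables (see
`examples/`; these are generated curves for demonstrating the I/O and
fitting machinery, not measurements):

```python
from pathlib import Path
from pegconf import RunConfig, run_pipeline

result = run_pipeline(RunConfig(
    subunits=(6, 11, 16, 26), n_snapshots=40, seed=7,
    output_dir=Path("demo"),
    binodal_csv=Path("examples/synthetic_binodal.csv"),
    polarity_csv=Path("examples/synthetic_polarity_et30.csv"),
))
print(result.ensemble_table[["n_subunits", "rg_mean",
                             "hydrophobic_fraction_mean"]].round(3))
print(result.scaling_fit.summary())
```

prints (seed 7):

```
   n_subunits  rg_mean  hydrophobic_fraction_mean
0           6    4.925                      0.768
1          11    8.057                      0.818
2          16    9.480                      0.849
3          26   13.306                      0.867
Power-law fit Rg = c * MW^v   [LAR, 4 points]
  exponent v : 0.7019  (95% CI 0.4475 .. 0.8534)
  prefactor c: 0.0938 Å
```

The hydrophobic fraction rises with chain length (the hydrophilic OH end
groups get "diluted"), mean R_g grows with molecular weight, and the
scaling exponent carries a wide CI at only four short chain lengths.
Polarity slopes from the synthetic ET(30) table come out around −6 to
−12 kcal/mol per relative molar fraction, steeper (more hydrophobic) for
heavier PEG.

The same stages are scriptable from the shell:

```bash
pegconf build -n 20 --shape helical -o helix20.pdb
pegconf sample -n 11 --snapshots 100 --seed 3 --format xyz -o traj.xyz
pegconf analyze traj.xyz -o metrics.csv
pegconf run --subunits 6,11,16,26 --snapshots 40 -o results/
```

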