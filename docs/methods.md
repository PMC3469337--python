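# Methods

This note records the models, conventions and numerical choices behind
`pegconf`, and what its synthetic ensembles do and do not emulate.

## Chain model and construction

A PEG of n subunits is HO–(CH₂CH₂O)ₙ–H: 2n carbons, n+1 oxygens, 4n+2
hydrogens (7n+3 atoms), molar mass 44.053 n + 18.015 Da. Atoms are
ordered along the chain; the two terminal oxygens with their hydrogens
form the OH group, every CH₂ carbon with its hydrogens the CH group, the
remaining oxygens the ether-O group. This grouping drives the surface
decomposition and the H-bond donor/acceptor roles.

Cartesian coordinates are generated from internal coordinates with the
natural extension reference frame (NeRF): each backbone atom is placed
from its three predecessors by bond length, bond angle and torsion. The
first three backbone atoms are fixed canonically (origin, +x axis,
xy-plane, positive y), so construction is deterministic; torsions follow
the IUPAC sign convention, verified by round-trip tests at 10⁻⁶
precision. The two CH₂ hydrogens are placed symmetrically about the
plane of the carbon and its two heavy neighbours, opened to the H–C–H
angle perpendicular to that plane — re-measuring the H–C–H angle returns
the input exactly. Hydroxyl hydrogens sit anti to the backbone
(H–O–C–C = 180°) by default.

The default `GeometrySpec` is a crystallographic parameter set (O–C
1.43 Å, C–C 1.48 Å, H–C–H 109.01°, C–C–O 109.96°, C–O–C 115.64°,
O–C–C 109.49°, gauche O–C–C–O −74.95°, trans C–O–C–C 177.41°). The
crystal record carries no C–H or O–H geometry, so standard sp³ values
are used (C–H 1.09 Å, O–H 0.96 Å, C–O–H 108.5°); all fields are
configurable and can be read from a plain `key = value` file. The ideal
**helix** sets every O–C–C–O torsion to the gauche value with uniform
handedness and every flanking torsion to the trans value; the ideal
**linear** chain sets every torsion to 180°.

## Synthetic ensembles (what they emulate, what they do not)

The RIS sampler draws each snapshot's O–C–C–O ("CC") torsions
independently from a three-state mixture centred at +|g|, −|g| and 180°
with Gaussian jitter, and the flanking ("OC") torsions from a
trans-dominant two-sided mixture. Defaults: CC weights
(0.35, 0.35, 0.30), jitter 12°, OC trans probability 0.9 — a qualitative
emulation of the solution-phase gauche preference and the equal
gauche⁺/gauche⁻ split; no printed gauche fraction exists to anchor them
more tightly. Conformers with any nonbonded atom pair closer than 1.5 Å
are rejected and redrawn (abort with a diagnostic above 99% rejection);
snapshots are stamped 5 ps apart.

Deliberate simplifications: snapshots are independent equilibrium draws,
not a correlated dynamics chain — only the stationary distribution is
represented, so time-correlation quantities are out of reach. There is
no force field, no water dynamics, no thermodynamic weighting beyond the
state probabilities, and the 1.5 Å cutoff is a minimal plausibility
filter, not an excluded-volume model. Consequently, passing tests
demonstrate correct *measurement and statistics* on ensembles with a
controlled torsion distribution; they do not validate solution
thermodynamics.

One consequence is worth stating plainly because the package computes it
honestly: over n = 6–81 the fitted scaling exponent of these ensembles
is ~0.57 without clash rejection and ~0.65 with it, not the asymptotic
ideal-chain 0.5. Two real effects are responsible. First, a chain with
fixed bond angles and 90% trans OC torsions has a stiffness crossover:
the local log–log slope of R_g vs MW falls towards 0.5 from above and is
still ≈ 0.54 at the large-n end of this range. Second, the hard-clash
filter rejects mostly long-range self-contacts (at n = 81 about 99% of
clashing pairs are more than six bonds apart, with a ~7% acceptance
rate), i.e. it acts as genuine excluded volume and pushes the exponent
further up. The sampler itself is certified against an exact
enumeration oracle (all discrete torsion-state combinations of a
two-subunit chain, weighted by their mixture probabilities), so this
deviation is a property of the model conditions, not an implementation
artefact.

### Hydration

`hydrate_fixture` plants waters at canonical H-bond geometry (O···O
2.8 Å, linear D–H···A) with rejection-sampled directions that provably
form no second bond under the default criteria, plus decoy waters at
> 5 Å from everything — ground truth for detector tests.
`hydrate_by_exposure` emulates a hydration shell: one donating water per
PEG oxygen whose per-atom SAS exceeds 1 Å², plus a water accepting from
each exposed hydroxyl. This makes the H-bond count respond to burial and
end-group dilution, which is the mechanism behind the decreasing
H-bonds-per-subunit vs hydrophobic-fraction relation; absolute counts
depend on the exposure threshold and are not calibrated to any
experiment.

## Descriptors

* **State classification.** gauche⁺ iff φ ∈ [50°, 100°], gauche⁻ in the
  mirrored band, trans iff |φ| ∈ [150°, 180°], else "other". The trans
  band is a package convention chosen symmetric in width to the gauche
  band; band edges are inclusive. "Other" never counts toward gauche
  fraction or helicality.
* **Helicality.** Fraction of CC torsions belonging to maximal runs of
  ≥ 4 consecutive *same-signed* gauche states (helices need uniform
  handedness; mixed-sign runs do not qualify). Sequences shorter than 4
  score 0. Verified against exhaustive window enumeration for all state
  strings up to length 12.
* **R_g.** Mass-weighted RMS distance from the mass-weighted centroid,
  waters excluded; a flag switches to the geometric (unweighted) form
  for sensitivity checks.
* **SASA.** Shrake–Rupley with Fibonacci (golden-spiral) test points
  (default 960 per atom) for determinism, probe 1.4 Å, Bondi radii
  (C 1.70, O 1.52, H 1.20 Å). Group sums reproduce the total exactly by
  construction. Waters can occlude the PEG surface but never contribute
  surface.
* **SAV.** Voxel counting on a 0.4 Å grid over the union of
  probe-inflated spheres; accuracy target 2% (halving the spacing moves
  a chain's volume by < 1%). The grid spacing must stay below the probe
  radius.
* **H-bonds.** Pure geometry: donor-O to acceptor-O ≤ 3.5 Å and
  D–H···A ≥ 135°, both configurable. PEG ether and hydroxyl oxygens
  accept; PEG hydroxyl O–H donates; water does both. Only PEG–water
  bonds are counted ("donated" = PEG provides the H). No energy model is
  attached to a bond: counts are the only statistic carried.

Numerical caveat: descriptors built from lab-frame point or voxel
sampling (SASA, SAV) are exactly invariant under translation but only
invariant under rotation to sampling tolerance (≈ 0.1% at the defaults;
tests allow 0.5% / 1%). Torsions, R_g and H-bond counts are invariant to
machine precision.

## Equilibration and averaging

A per-snapshot series is block-averaged (blocks of 10) and scanned from
the start; the window is accepted at the first block whose remaining
OLS slope is statistically indistinguishable from zero (two-sided
t-test, α = 0.05). A series with no stationary suffix is returned whole
with a `stationary=False` flag. Ensemble averages report mean, sample
SD (ddof = 1) and CV over the chosen window.

## Fits

* **Scaling law.** Straight line on log R_g vs log MW. The robust
  variant minimises the mean absolute residual (least-average-residual,
  LAR) by iteratively reweighted least squares (50 iterations, damping
  10⁻⁸ on the residual magnitudes); on noise-free data it coincides with
  OLS to 10⁻⁹. The 95% CI is a seeded percentile bootstrap over the
  points (1000 resamples; degenerate resamples with a single distinct
  abscissa are redrawn, and the interval is widened minimally if needed
  to contain the point estimate).
* **Linear correlations.** OLS with R² the squared Pearson correlation;
  zero variance in x is an error.
* **Binodal interpolation.** Piecewise-linear interpolation of PEG %w/w
  at a queried PO₄ %w/w; extrapolation outside the measured range is
  refused rather than guessed.
* **Relative molar fraction.** Fractions of a PEG of mass MW are
  multiplied by round(MW / 200), so k reference-mass molecules compare
  against one k-fold heavier molecule.
* **ET(30).** Wavelength→ET(30) calibration is a least-squares
  quadratic. The "linear region" of a polarity series is the longest
  low-fraction prefix of ≥ 4 points whose OLS fit reaches R² ≥ 0.98
  (both thresholds configurable); its slope is the polarity measure. The
  rule is a package convention — any reasonable selector would do, and
  the parameters are exposed for exactly that reason.

## Problem sizes and determinism

Default analyses use n ∈ {6, 11, 16, 26, 41, 61, 81}; the scaling-law
computation uses 500 snapshots per chain length, smaller demonstrations
10–100. Every stochastic stage takes an explicit integer seed and is
bit-reproducible; pipeline runs write a manifest (config, seed, package
version) sufficient to regenerate any table.

## Known limitations

* No force-field energies, charges, minimisation or dynamics; dihedral
  and system energy traces are out of scope by design.
* Absolute SASA values depend on the radius set and point density;
  only trends, fractions and decompositions are comparable across
  implementations.
* The RIS ensembles do not reproduce the chain-length dependence of the
  gauche fraction or helicality seen in solution (state weights are
  length-independent by construction).
* Binodal and polarity example tables shipped under `examples/` are
  synthetic and illustrative, not measurements.
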