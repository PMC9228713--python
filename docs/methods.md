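# Methods

## Spectral preprocessing

A peak table holds one row per recorded TOF-SIMS spectrum with metadata
(`sample_id`, `group` ∈ {bare, fc_ref, fab2_ref, igg}, `substrate`); a
sample is the set of rows sharing a `sample_id` (in practice several
non-overlapping analysis areas of one surface). Preprocessing restricts
to a curated fragment list, divides each row by its summed intensity over
the selected peaks, and mean-centres. Normalising to the *selected* sum
(rather than total ion count) removes acquisition-to-acquisition yield
variation and puts every spectrum on the simplex; it also means a bare
region's contribution to the selected channels competes with protein
signal row by row.

The shipped 36-fragment library covers standard immonium and related
ions for all twenty amino acids. Domain-enrichment classes mark the
fragments that discriminate the exposed domains — Fc: proline, arginine,
histidine, phenylalanine fragments; F(ab')₂: serine, alanine, leucine,
threonine fragments — plus two substrate channels (CH₄N⁺, shared with
amino-silane; C₂H₅S⁺, overlapping SiO₂H⁺). Any real study should
override the library with its own validated peak list; the class
assignments, not the exact mass list, are what the downstream logic
uses.

## PCA model

PCA is fitted by eigendecomposition of the sample covariance (divisor
n−1) of the centred matrix; component signs are fixed by making the
largest-magnitude loading entry positive, so fits are bit-reproducible.
Up to min(8, rank bound) components are retained by default. Component
*roles* are identified from training labels, never by index: the
coverage component maximises the standardised mean separation (pooled
SD) between bare and protein-bearing spectra; the orientation component
is the best remaining separator of the Fc and F(ab')₂ references, with
its sign chosen so the Fc-reference mean is positive. Ties break to the
lower index. On typical data coverage lands on the first component and
orientation on a later, small-variance one, but nothing downstream
assumes that.

Covariance (not correlation) PCA is used: after sum-normalisation the
channels share a scale, and standardising would up-weight noise-dominated
minor peaks.

## Coverage correction of orientation scores

A spectrum of a partially covered surface is, under the linear-mixing
assumption, a convex blend x = w·protein + (1−w)·substrate of the
pure-protein and bare compositions, where w is the protein share of the
selected-channel intensity. Every linear functional — in particular a PC
score — is then diluted by w, so at low coverage the orientation score
of a flat-on layer is dragged toward the bare-substrate level. Left
uncorrected this (a) biases the two-point f_Fc calibration, because the
flat-on anchor sits at a systematically diluted level while the vertical
regime is measured at full coverage, and (b) can make the within-regime
score trend larger than the between-regime steps, defeating
segmentation when f_Fc increases monotonically with Γ.

The pipeline therefore estimates w per sample from its coverage-PC
score placed affinely between the bare reference and the saturated
reference layers, and deprojects:

    s_protein = s_bare + (s − s_bare) / w .

The correction is exact for the linear mixing model at zero noise. It
amplifies noise by 1/w, so shares are clipped below `min_protein_share`
(default 0.05); samples near that clip are essentially bare and their
corrected scores should not be trusted. Raw scores are kept in the
report alongside the corrected ones.

## Regime segmentation

Per-sample mean orientation scores (means over a sample's replicate
spectra; samples are the independent units, replicate spectra are
technical replicates) are ordered by Γ and split into three contiguous
groups by exhaustive search over ordered breakpoint pairs, each group
≥ 2 samples, maximising the one-way ANOVA F. The F statistic uses
hand-assembled sums of squares with (k−1, N−k) degrees of freedom; a
perfect step (zero within-group variance, unequal means) maps to
F = +∞, p = 0 rather than NaN. Boundaries are reported as midpoints
between the adjacent Γ values across each break.

The split is *accepted* only if the omnibus p < α (default 0.05) and
the Welch tests of the two regime transitions (flat-on|side-on,
side-on|vertical) pass a Bonferroni-corrected α/2. The flat-on|vertical
contrast is computed and reported but deliberately not gated: a mixed
head-on/tail-on vertical layer can expose exactly the flat-on
composition, so those two levels may legitimately coincide and a
three-regime structure is still established by its two transitions.
When the gate fails, a "no significant segmentation" result is returned
(the max-F boundaries remain available as a diagnostic).

## Calibration and unmixing

Scores are assumed affine in the areal Fc exposure f_Fc. The flat-on
and side-on group means of the corrected scores are anchored to
f_Fc = 0.28 and 0.34 (molecular-dynamics values for those orientations),
fixing slope and intercept exactly. Calibrated f_Fc outside [0, 1] is
reported with a diagnostic, never clamped — it signals miscalibration.

The vertical regime is modelled as a two-endmember mixture of head-on
(f_Fc = h) and tail-on (f_Fc = t) molecules; the head-on fraction is
p = (f − t)/(h − t). Default endmembers (h, t) = (0.5, 0.0): with these
the lever rule reproduces a 1:1 proportion at f_Fc = 0.25 exactly, and
4:3 / 3:1 proportions at f_Fc ≈ 0.29 / 0.375, consistent to rounding
with the published per-chemistry values. The three published
(proportion, f_Fc) pairs are not jointly consistent with any single
t ≥ 0 lever rule (unconstrained least squares drives t slightly
negative), so exact joint reproduction is not forced; a constrained
`fit_endmembers` (t ≥ 0) is provided for user-supplied pairs, and
per-pair residuals are left to the user to inspect.

## Ellipsometry conversion

Γ = d·C with C = (L(n_p) − L(n_a))/(r − v̄·L(n_a)) in g/cm³ and the unit
identity 1 nm·g/cm³ = 1 mg/m². Defaults: n_p = 1.53, ambient air
n_a = 1.00 (dried layers), specific refractivity r = 0.254 cm³/g and
partial specific volume v̄ = 0.73 cm³/g — standard globular-protein
values, giving C ≈ 1.216, i.e. a 1 nm dry layer ≈ 1.22 mg/m². All four
constants are explicit config so any published variant of the conversion
can be matched exactly. Fitting raw ellipsometric spectra is out of
scope; the package consumes fitted thicknesses.

## Packing model

Γ_ind = (M/N_A)/A with M = 150 kDa and default footprints A = 125 nm²
(flat-on) and 72 nm² (side-on), chosen to be consistent with published
critical densities ≈1.1 and ≈1.9 mg/m² at Φ∞ = 0.55; both are config
entries. Critical density Γ_c = Γ_ind·Φ∞. Candidate packing fractions:
Φ∞ = 0.55 (random) and 0.91 (hexagonal close packing, π/(2√3) ≈ 0.9069).

The RSA jamming coverage is estimated by direct Monte Carlo: unit-
diameter disks proposed uniformly in a periodic square box (side in
diameters), accepted when no accepted centre is within one diameter
(cell-list neighbour search), stopping after a fixed number of
consecutive rejections. The stopping rule under-approaches the true
disk-RSA jamming limit (≈0.547): with a 30-diameter box and a 5·10⁵
consecutive-rejection cap the per-seed estimates sit a little above
0.53, and this bias is intentional and documented rather than
extrapolated away. Identical (box, cap, seed) give identical placements.
Disks are the minimal isotropic model; anisotropic (Y-shaped) particles
are out of scope.

## Synthetic-data generator

The generator emulates the structure the analysis assumes:

* **Signatures.** Protein signatures start uniform over the non-substrate
  fragments; Fc-class peaks are scaled by the enrichment strength
  (default 2) and Fab-class peaks by its inverse (and vice versa), then
  renormalised. The substrate signature concentrates 80 % of its mass on
  the substrate channels. Enrichment strength 1 collapses Fc and Fab to
  the same signature.
* **Coverage mixing.** θ = min(Γ/Γ_ml, 1) with monolayer saturation
  Γ_ml = 2.2 mg/m², so the substrate contribution vanishes at the
  vertical-regime onset. Expected spectrum =
  θ·[f·Fc + (1−f)·Fab] + (1−θ)·`substrate_yield`·substrate, renormalised;
  `substrate_yield` (default 1.0, i.e. the plain area-weighted blend)
  expresses that a bare surface may yield less intensity within an
  amino-acid peak list than a protein layer.
* **Regimes.** f_Fc = 0.28 below the first threshold, 0.34 between the
  thresholds, and the forward lever-rule value above. Default thresholds
  0.8/2.2 mg/m² (physisorption); the chemisorption series uses 1.2/2.2.
  Default head-on fractions by chemistry: 4/7 (APTES), 1/2 (NHS-silane),
  3/4 (APTES/GA) — the published proportions 4:3, 1:1, 3:1.
* **Noise.** Independent multiplicative lognormal noise per channel with
  unit mean, CV 0.05 by default and a hard ceiling of 0.10 (the
  instrument's stated fluctuation bound for normalised amino-acid
  signals), followed by renormalisation. Thicknesses get additive
  Gaussian noise, SD 0.05 nm per sample (a per-sample value is already
  an average of several ellipsometry spots).
* **Study layout.** Default grid: 20 Γ values spanning 0.2–3.5 mg/m²
  (series start at finite coverage; the bare surface enters as a
  reference class, not as a Γ = 0 sample), 10 replicate spectra per
  sample, plus bare, pure-Fc and pure-F(ab')₂ reference samples at
  saturation. A Langmuir isotherm Γ(c) = Γ_max·Kc/(1+Kc) with
  K = 0.01 mL/µg, Γ_max = 3.5 mg/m² emulates the concentration→density
  map (its exact form in a real study is empirical).

What the generator does **not** emulate: SIMS fragmentation physics and
matrix effects, detector dead time and Poisson counting, topography,
partially Fc-contaminated reference layers (references are generated as
pure endmembers), within-regime orientational heterogeneity, and
adsorption kinetics. Passing recovery tests therefore demonstrates that
the inference chain is correct and well-conditioned under its own
assumptions — not that those assumptions hold for any particular
instrument or surface chemistry.

## Problem sizes and tolerances

Recovery tests use the default study (20 samples × 10 replicates + 3
reference samples, 36 channels) over 20 generator seeds; transition
densities must land within ±0.2 mg/m² (one grid step ≈ 0.17) in ≥ 18 of
20 seeds, and head-on fractions within ±0.1. The RSA benchmark uses a
30-diameter box, 5·10⁵-rejection cap and 5 seeds. PCA orthonormality and
variance conservation are asserted at 1e−8, simplex closure at 1e−12,
exact algebraic identities (calibration anchors, lever-rule inverses,
Cuypers round trip) at 1e−12 relative or tighter.

## Known limitations

* The coverage correction assumes linear mixing and a coverage axis that
  is informative for the protein share; strongly nonlinear matrix
  effects would violate both.
* The two-point calibration propagates any error in the assumed MD
  anchor values 0.28/0.34 directly into f_Fc and hence into the head-on
  fraction.
* Endmember exposures (h, t) are config, not estimated from the data;
  the lever rule cannot distinguish mixtures whose f_Fc coincide.
* Segmentation assumes exactly three contiguous regimes; it does not
  select the number of regimes.
* The consecutive-rejection RSA estimator underestimates the jamming
  limit by construction; it is a benchmark, not a precision estimate.
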