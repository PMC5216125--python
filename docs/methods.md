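# Methods

## The scientific setting

Microsporidian mitosomes are strongly reduced mitochondria: small
double-membrane organelles without cristae or a genome.  Whether the core
iron–sulfur cluster (ISC) assembly proteins of *Trachipleistophora hominis*
reside in the mitosomal matrix is a quantitative question about immunogold
electron microscopy: gold particles marking each ISC protein are dots on
thin (~80 nm) cryo-sections, and "matrix localization" means their
distances to the inner membrane are distributed differently from chance.
This package implements that analysis — stereological labelling densities,
signed distance distributions against a matched random-point null, and the
accompanying spectroscopic quantifications (CD-monitored cluster-synthesis
rates, Fe/S stoichiometry, EPR g-tensor fitting) — as a tested library
over coordinate tables rather than raw micrographs.

## Geometry model

A mitosome section is idealised as two concentric, co-oriented ellipses.
The outer ellipse is the organelle boundary; the **inner aspect of the
inner membrane** — the reference boundary for all distances — is the outer
ellipse shrunk radially by `membrane_inset`.  The inset defaults to
**15 nm** (two ~7 nm membranes plus a thin intermembrane space); the
source measurements never state this offset, so it is configurable.
How membranes were delineated on the original micrographs (manual tracing
versus a fitted ellipse) is unknown; the ellipse is our idealisation, and
distances are measured in the section plane (sections are thin relative to
organelle size, so no 3-D correction is attempted).

Signed distance to the inner aspect is positive toward the matrix and
negative outside.  The nearest point on an ellipse is found from the
stationarity condition in the profile frame, solved by 90 bisection steps
plus Newton polishing (relative error ~1e-10, verified against a dense
boundary-scan oracle); points on the major axis inside the evolute are
handled by the closed-form branch.  Gold positions are particle centres;
the 10 nm marker diameter is metadata only.  No correction is made for the
antibody/protein-A linkage offset (~10–20 nm), which blurs but does not
bias distances on average.

## Synthetic fields

The study's coordinates were never deposited, so a seeded generator
emulates the sampling universe:

* **Axis diameters.**  Minor diameters on [47, 119] nm, major on
  [78, 267] nm, with target means 80 and 127 nm.  A triangular law cannot
  reach a mean of 127 nm on [78, 267] (its minimum possible mean is
  141 nm), so both axes use scaled Beta(2, β) laws with β solved from the
  mean position in the range (minor β ≈ 2.36, major β ≈ 5.71); where a
  draw gives major < minor the major axis is redrawn, which lifts the
  realised major mean by a few nm.
* **Layout.**  Each field is a circular cell profile (radius 900 nm)
  containing a circular nucleus (radius 280 nm); mitosome centres are
  uniform over the cytoplasm with non-overlap enforced on bounding
  circles; placement failure after bounded retries raises.
* **Gold placement laws** (a test harness, not a biological claim — the
  true spatial law of labelling is unknown): `matrix_uniform` (uniform
  inside the inner aspect), `membrane_proximal` (matrix points thinned to
  density ∝ exp(−d/λ), λ default 10 nm, by rejection sampling bounded at
  10⁷ proposals), `profile_uniform`, and `cytosol_uniform`.  Default
  per-protein counts are the published distance-analysis counts
  (ThIsu1 79, ThNfs1 66, ThYah1 37, ThYfh1 63, ThIsd11 50; 295 pooled).
* **Null points.**  One uniform random point per gold particle, over the
  *same* profile, up to the closed outer boundary — the matched design
  ("equal number of random points over the corresponding profiles").
  Random points cover the whole profile rather than the matrix only
  because the original design places them "over the profiles"; a
  matrix-only variant is available via `matrix_uniform`.

What the generator does **not** emulate: real section-thickness and
projection effects, membrane tracing noise, antibody linkage displacement,
non-elliptical profiles, and sporulating-cell morphology.  Green tests
therefore certify the estimators and tests on data whose ground truth is
known, not the biological conclusion itself.

## Stereology

Classical point counting: a square lattice with offset uniform in
[0, spacing)² is overlaid per micrograph (re-randomised per micrograph,
translation only — translation alone already makes the estimator unbiased,
`E[hits]·a² = area`), and compartment area is `hits · a²`.  Spacings
default to the study's 15.5 nm (mitosome) and 206.1 nm
(cytoplasm/nucleus).  Lattice points exactly on a boundary count as inside
(closed regions); for polygon masks this biases the estimate high by the
boundary's measure-zero set only.  Densities are gold counts per µm²
(1 µm² = 10⁶ nm²), summarised across experiments as mean ± s.e.m.
(sample sd/√N; N = 3 in the emulated design); N = 1 groups are flagged
rather than given a fake s.e.m.

## Membrane-distance statistics

For each label, gold distances are compared with the matched random
sample by:

* **Band fraction** — the proportion of distances in [0, band] with band
  defaulting to 20 nm; "outside" pools d < 0 and d > band, matching the
  binary inside/outside headline split.
* **Binning** — default edges −40 … +60 nm in 10-nm steps (the original
  "distance groups" are unpublished); left-closed/right-open bins, last
  bin closed, values on an internal edge go up, out-of-range values land
  in flagged underflow/overflow bins.
* **Tests** — all two-sided.  KS: exact p when n_a+n_b ≤ 16, asymptotic
  Kolmogorov otherwise.  Mann–Whitney: exact when min(n) ≤ 8 without
  ties, else normal approximation with tie and continuity corrections.
  Chi-squared: goodness-of-fit of binned gold counts against the random
  sample's proportions after merging adjacent bins (smaller neighbour
  first) until every expected count ≥ 5, df = bins − 1; a 2×k homogeneity
  variant is available behind a flag since the original formulation is
  ambiguous.  Per-protein comparisons are reported uncorrected for
  multiplicity (as in the source design); Bonferroni is optional.

**Known calibration limit:** at equal sample sizes the KS statistic is
discrete (multiples of 1/n).  At n = 50/50 the achievable test sizes
bracketing α = 0.05 are 0.0638 (D ≥ 13/50) and 0.0339 (D ≥ 14/50), so the
realised size at nominal 0.05 is ≈ 0.034–0.038 for *any* correctly
computed non-randomised KS p-value.  The Mann–Whitney test, whose null
distribution is much finer, realises ≈ 0.048.

With the default `membrane_proximal` law (λ = 10 nm) and the published
counts, the pooled 20-nm band fraction of the synthetic demo comes out
around 0.95–0.99 against ~0.4 for the random null — the same qualitative
regime as the published 86.8 % / 13.2 % split (mitosome inner aspects are
only ~15–40 nm in semi-minor axis, so a 10-nm exponential packs nearly
everything into the band) — but this is a property of the chosen
generator settings, not a reproduction of the original data.

## Kinetics and stoichiometry

Initial rates are ordinary least squares of ellipticity (mdeg, 431 nm)
against time over the first **4.5 min** (boundary inclusive; the source
does not say), with a free intercept — iron-free background reactions are
expressed through `relative_rate` (percent of the standard reaction)
rather than subtracted.  Times are seconds internally, slopes mdeg/min.
The synthetic trace is a saturating rise A(1−e^(−kt)) plus Gaussian noise;
for k·window → 0 the fitted slope tends to A·k.  Stoichiometry is atom
bookkeeping ([2Fe–2S] → 2+2, [4Fe–4S] → 4+4): two [4Fe–4S] clusters per
Cfd1–Nbp35 heterodimer give the expected 8 Fe / 8 S benchmark for the
measured 9.5 Fe / 8.6 S; `occupancy_from_cd` scales a reference occupancy
(one [2Fe–2S] per Isu1 dimer) by CD intensity ratio.

## EPR simulation and g fitting

Rhombic S = 1/2 powder spectra: g_eff(n) = √(Σ g_i² n_i²), resonance at
B = hν/(g_eff µ_B) (CODATA h and µ_B), orientation average over one octant
on a deterministic midpoint grid in (cos θ, φ) (default 10⁴ orientations,
4096 field points over 300–380 mT).  Each orientation contributes a
Gaussian first-derivative line whose variance interpolates the per-axis
widths by squared direction cosines, weighted 1/g_eff; implementation
accumulates resonance fields into a stick histogram, groups orientations
into ≤ 16 linewidth classes and convolves each class with its analytic
kernel (identical to per-orientation summation up to grid resolution, and
fast enough to sit inside a least-squares fit).  Doubling the orientation
count changes the default spectrum by < 0.5 % RMS.  Modulation amplitude,
microwave power, temperature and g-strain are instrument conditions
outside the model; since the original fitting routine's lineshape is
unpublished, round-trip tolerances are defined against this simulator's
own forward model.

Fitting: landmark initialisation (first significant positive lobe → low
field edge/largest g; steepest central zero crossing → middle g; last
significant trough → high-field edge/smallest g), then Nelder–Mead over
(g₁, g₂, g₃, log widths) with the amplitude profiled out analytically,
5 jittered restarts from a fixed seed, simplex re-starts from each
converged point (a collapsed simplex otherwise stalls short of the
minimum), and a final constrained isotropic refinement kept only when it
fits at least as well (resolving the near-isotropic degeneracy where tiny
splittings trade against widths).  Noiseless rhombic round trips recover
each g to ~1e-6; with 1 % added noise recovery stays within ±0.01.

## Determinism and problem sizes

Every stochastic component takes a seed; the pipeline derives stage seeds
from one global seed via `numpy.random.SeedSequence.spawn`, and identical
config + seed produce byte-identical outputs (the run manifest hashes
config, inputs and seed, excluding the timestamp).  Default problem sizes
were chosen so each analysis is statistically meaningful yet runs
interactively on one core: 3 fields × 8 profiles and 295 gold points in
the demo pipeline; 10⁴ grid offsets for unbiasedness checks; 10⁴ null
replicates for test calibration; 500 replicates for the power study;
10⁴ orientations for powder spectra.

## Known limitations

* The ellipse idealisation and the fixed 15-nm inset are assumptions, not
  measurements; real inner-aspect tracing would shift all signed distances
  by the tracing error.
* The chi-squared merging rule and bin edges are our choices; the original
  "distance groups" are unknown, so per-bin numbers are not comparable to
  the source figures, only the test logic is.
* `membrane_proximal` is phenomenological; no spatial point-process model
  (e.g. Ripley's K) is fitted.
* The EPR model omits g-strain and Lorentzian admixture; fitted widths are
  not interpretable instrument parameters.
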