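# Methods

## The docking model

The docking procedure treats both partners as rigid bodies and searches a
one-parameter pose space. The physical picture: a short TM helix bundle
carries a lateral groove where its long homolog has a filler helix; a
receptor presents a protruding outer helix (M4). Superposing the filler
onto M4 fixes five of the six rigid degrees of freedom; the remaining one —
the spin of the bundle about the shared helix axis — is resolved by
minimising steric clashes against the rest of the receptor. No translation
search accompanies the rotation (an optional ±3 Å axial-offset scan exists
behind a flag but is off by default); no energies, flexibility or membrane
restraints are modelled. Side chains play no role: poses are computed on
backbone/reduced representations (`strip_side_chains` keeps N, CA, C, O,
CB), so downstream side-chain rebuilding is explicitly out of scope.

Numerical choices:

* **Superposition** — Kabsch via SVD; the smallest singular direction is
  sign-corrected so the rotation is always proper (no reflections).
  Collinear point sets are rejected. When filler and target traces differ
  in length both are centre-trimmed to the shorter, aligned N→C, since no
  residue-level mapping exists between non-homologous helices.
* **Clash criterion** — an inter-body heavy-atom pair strictly closer than
  2.5 Å. The cutoff is configurable; 2.5 Å flags severe overlap on reduced
  models without penalising packing contacts (which sit at ~2.6–3.5 Å in
  the fixtures). Whether the original procedure used a pair count, an
  overlap volume, or visual inspection is unknowable; the pair count is
  this package's choice. The scan counts neighbours within the cutoff ball;
  exact boundary equality is a measure-zero event for scanned poses.
* **Scan** — angles 0, 1°, …, 359°; ties broken toward the smallest angle
  for determinism. The groove is declared occluded when the *minimum* clash
  count over the scan exceeds a ceiling (default 25); a groove-bearing
  query reaches 0 at its mating angle while a groove-filled one never
  drops below ~65 on the default fixtures.
* **Helix axis** — the axis direction is the normal of the plane spanned by
  the trace's second differences, which are exactly radial for a regular
  helix; plain PCA of the trace tilts by ~5×10⁻³ rad at 24 residues
  because the helical phase coverage is asymmetric. The on-axis point is
  the centre of the circle described by the radial components (linear Kåsa
  fit). Both are exact on ideal helices.

## Interface scoring

SASA is Shrake–Rupley with a deterministic golden-section spiral of 960
points per atom (no random seed needed; doubling the point count moves
areas by < 1 % on the fixtures, and the spiral's orientation dependence is
~0.2 %). Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å, probe 1.4 Å. Reduced
Cα/Cβ models inflate CA to 2.4 Å to mimic residue bulk; the pseudo-Cβ is
treated as carbon. Buried area is the SASA lost on complex formation
summed over both partners; per-partner splits come from per-atom
differences, and a negative total within quadrature noise is clamped to
zero with a warning. The figure the docked synthetic complex produces
(~1.7 × 10³ Å²) is of the same order as published buried areas for
TM–TM complexes of this size, but no quantitative comparison is possible:
the coordinates behind published values were never deposited.

## Synthetic structures

All helices are ideal: rise 1.5 Å/residue, twist 100°/residue, Cα radius
2.3 Å, a pseudo-Cβ 1.5 Å further out along the radial direction, 24
residues (36 Å span) unless noted. Bundles place helices on a 12-position
ring (spacing 10.5 Å, radius ≈ 20.3 Å) with alternating up/down axes;
omitting one position leaves the lateral groove. The long homolog adds the
filler at the groove position plus two peripheral helices outside the ring;
long and short share coordinates exactly, so the query→template mapping in
the dock is an identity test case while remaining a genuine Kabsch fit.

The receptor fixture has four subunits with exact four-fold symmetry about
the pore axis. Per subunit: a thin Cα-only pore helix (M2, radius 5.1 Å,
18 residues), two mid-radius helices (M1/M3), and the outermost M4
(radius 22.5 Å, residues numbered 813–836 to match the registered GluN1-M4
landmark). Two design constants deserve explanation:

* **M4 phase = −90°.** With this phase the Kabsch superposition of the
  filler onto M4 lands the bundle exactly in its outward mating
  orientation, so scan angle 0 coincides with the planted-angle origin and
  recovered angles are directly comparable to planted ones.
* **Guard offsets.** M1 and M3 sit at hand-computed offsets from their own
  M4 (−6.57, −7.52) and (−6.13, +7.66) Å such that, across the symmetry,
  each M4 is flanked by the neighbouring subunits' guards at ~10.3 Å from
  the docked bundle's groove-wall helices. At the mating orientation the
  closest wall–guard atoms clear the 2.5 Å cutoff by < 0.1 Å; a 1°
  mis-rotation (≈ 0.16 Å of travel at that radius) already produces
  clashes. This pinches the zero-clash window to ±1° and makes the scan
  minimum unique at the planted angle. The two offsets differ because
  helix handedness breaks mirror symmetry. These constants were frozen
  from a one-time geometric design computation; they encode the fixture's
  stated property (unique recovery) and correspond to no empirical value.

`plant_complex` keeps the target M4 fixed and rotates the probe bundle
*and* the receptor's remaining helices in tandem about the M4 axis. This
is deliberate: rotating the probe alone would make most of [0, 360°)
physically inadmissible (the probe would sweep through the receptor core),
whereas the tandem rotation makes every planted angle admissible with the
clash-scan minimum at exactly that angle — which is what a recovery test
needs. The returned ground-truth transform applies to the bundle alone and
reproduces the planted scene exactly.

What these fixtures do *not* emulate: real helices are neither straight
nor ideally wound, side chains pack the interface, membranes restrain tilt,
and experimental structures carry coordinate error. Passing recovery tests
therefore demonstrates the correctness of the search and scoring machinery,
not the accuracy of any particular biological pose.

## Synthetic assays

**Co-localization images.** Per cell: `puncta_count` (40) point sources
per channel on a 128×128 px frame, a fraction ρ of them at shared
positions with shared amplitudes, the rest independent; amplitudes are
log-normal (σ = 0.25) around 3000 counts, blurred with a Gaussian PSF
(σ = 1.5 px), giving peak signal ≈ 10× the flat background of 20 counts;
Poisson photon noise by default (Gaussian read noise and noise-free modes
available). The mask defaults to the whole frame. Real images additionally
carry cell-shaped intensity envelopes, uneven illumination and correlated
background structure, none of which are modelled — which is precisely why
the ρ = 0 calibration below is the stringent case.

**Thresholded PCC.** The threshold line is fit by ordinary least squares
of ch2 on ch1, following the original auto-threshold recipe. Orthogonal
(total least squares) regression is available as an option but is *not*
the default: on uncorrelated channels the TLS slope is unbounded (observed
|slope| up to ~18 on ρ = 0 fixtures), which drags the thresholds to
arbitrary places and biases the statistic to ≈ −0.16; the OLS slope tends
to 0 for uncorrelated data and calibrates the ρ = 0 mean to ≈ −0.06. The
walk decrements t1 from max(ch1) in (max−min)/256 steps with
t2 = slope·t1 + intercept and stops at the largest t1 whose below-both
pixels have r ≤ 0 (the ≤ makes the stop deterministic on flat regions);
if the walk exhausts — perfectly correlated channels — thresholds land at
the minimum. The reported coefficient uses pixels above threshold in
*either* channel (the complement of the below-both region); the stricter
both-above rule is a flag, noting that it degenerates to an empty pixel
set on fully uncorrelated images. A small negative residual bias at ρ = 0
(≈ −0.06 to −0.09 across seeds) is intrinsic to restricting Pearson's r to
bright-in-either pixels of disjoint signals.

**BiFC tables.** Per cell, background ~ 100 counts with multiplicative
normal noise of CV `noise_cv`; Cy3 = `cy3_fold`×background (default 6, so
cells gate in) and Venus = `reporter_fold`×background, each with their own
noise draw. Classification is strict: intensity must *exceed* 3.5× the
cell's own background; equality is negative, since the source rule speaks
only of > 3.5× and < 3.5× and leaves equality unassigned. Normalization
divides Venus by the mean Venus of Cy3-positive control cells, so the
control group's mean is 1 by construction and the statistic is a fold.

## Statistics

Kruskal–Wallis uses midranks with the tie correction
H′ = H / (1 − Σ(t³−t)/(N³−N)) and a χ²(k−1) reference (delegated to
scipy; validated against the direct rank formula and, at n ≤ 8, against
full enumeration of the permutation distribution). Dunn's pairwise z uses
pooled midranks with the same tie term,
z = (R̄ᵢ−R̄ⱼ)/√{[N(N+1)/12 − T/(12(N−1))](1/nᵢ+1/nⱼ)}, two-sided normal
p-values, Bonferroni-adjusted over all pairs by default (none/Holm
available; the adjustment is recorded in the output because the original
analyses used an unnamed graphics-package default). Welch's one-way ANOVA
is computed from the closed formula with Welch–Satterthwaite degrees of
freedom; the two-group case reduces exactly to the squared Welch t, and an
independent library implementation serves as a cross-check in the tests.
p-values are floored at the smallest positive double rather than printed
as 0. Mean ± s.e.m. uses the n−1 sample standard deviation, with s.e.m.
defined as 0 for a single observation (logged).

## Alignment statistics

Global alignment under affine gaps (open 12, extend 2: a gap of length L
costs 12 + 2(L−1)), BLOSUM62 with 'X' scoring 0 against everything, end
gaps penalized — the classic protein settings of the named EMBOSS tool,
which publishes no parameters in the source text. The dynamic program is
delegated to Biopython's PairwiseAligner; tie-breaking among co-optimal
alignments follows its deterministic first-traceback order, which replaces
the hand-specified match-over-gap preference while keeping the observable
contract (optimal score, deterministic output). Percent identity counts
identical columns and percent similarity counts positively-scoring columns,
both over the full alignment length including gap columns, so the two
percentages share a denominator. The exhaustive-enumeration oracle in the
tests confirms optimality for short sequences; the published identity/
similarity pairs for the real M4 segments are not recomputable here
because the sequences live behind accession fetches and supplementary
boundaries (see the acceptance notes).

## Problem sizes

The shipped analyses use: 20 planted scenes for docking recovery (24-residue
helices, ≈ 530 query and ≈ 650 receptor heavy atoms, 360 scan angles);
960 sphere points for production SASA and 480 for the in-run docked-complex
area; 30 cells per condition and a five-point ρ grid for co-localization;
2,000 simulated null datasets for each type-I calibration; 30 cells per
group for BiFC recovery. These sizes were chosen so the whole acceptance
computation completes in well under a minute while keeping every Monte-Carlo
band at least three standard errors wide.

## Known limitations

Rigid bodies and a single rotational degree of freedom; no pose refinement;
reduced-atom clash and area computations (absolute areas depend on the
radii convention); flat-background image model; per-cell scalar intensities
for BiFC (no segmentation); quadratic-memory alignment (fine at peptide
lengths); PDB input only (no mmCIF, assemblies, insertion codes, or
occupancy handling).
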