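# Methods

This note documents the models, numerical choices and limitations of
`rimspec`. The package emulates a 7 T MRSI analysis of iron-containing MS
lesions; since the underlying patient data are not redistributable, a
synthetic cohort generator plays the role of the scanner and the
segmentation readers, and the published group statistics are treated as
the generator's population parameters.

## The synthetic cohort

**Anatomy.** Each subject is a concentric-compartment "brain" on an
isotropic 0.8 mm grid (default 96³): a WM core (label 1), a 3.2 mm GM rind
(2), a 2.4 mm CSF shell (3), background 0. Lesions are spheres with radii
drawn uniformly from 2.8–4.5 mm (volumes ≈ 92–382 mm³), rejection-sampled
to be pairwise disjoint with a one-voxel gap and at least one voxel inside
WM. The radius range is chosen so that (a) the morphological SWI signatures
of the four iron types are resolvable at 0.8 mm (a 1-voxel rim shell on a
smaller sphere is most of the sphere), and (b) the volumes span both the
>20 mm³ ROI inclusion filter and the 100–400 mm³ layer-eligibility window.
No claim of anatomical realism is made — every downstream operator consumes
only masks and voxel values, so compartment geometry is the minimal
structure that exercises the GM/CSF-distance and intrusion-exclusion rules.

**Iron-type prevalences.** Types are drawn i.i.d. with probabilities
412/487, 31/487, 8/487, 36/487 (non-iron, area, transition, rim — the
published segmented counts). Cohort-level analyses can instead fix the
published *included* group sizes exactly (174/13/7/26), which is what the
acceptance checks do, because those are the groups whose statistics are
being recovered.

**Ratio maps.** For each of the four ratios (mIns/tNAA, mIns/tCr, tNAA/tCr,
tCho/tCr), tissue voxels take the NAWM mean plus two noise terms:

* a smooth zero-mean Gaussian random field (4 mm correlation length,
  amplitude = the published NAWM SD) emulating regional NAWM heterogeneity —
  this is what gives NAWM reference ROIs a realistic across-ROI scatter;
* i.i.d. voxel noise (per-ratio SD, defaults 0.05–0.15) emulating
  quantification noise.

Lesion voxels take `p_l · g_l(d)`, where `d` is the voxel's depth below the
lesion surface in units of the layer thickness (one voxel step) and `g_l`
is a piecewise-linear radial profile anchored at the published normalized
layer values: the L0 anchor at depth 0.5, the L−3 anchor at depth 2.5,
clamped outside. Per lesion and ratio the two anchors are drawn Normal
around the published layer means with the published layer SDs (truncated at
0.05), so the across-lesion profile scatter matches the layer tables; the
published tables only distinguish "non-iron" vs "iron" profiles, so area
and transition lesions reuse the iron anchors.

The level `p_l` has two calibration modes, because the published
whole-lesion means and the published periphery-normalized profiles are
mutually inconsistent in a single scalar field (a rim lesion's mIns/tNAA
mean of 1.53 against a NAWM of 0.53 implies lesion/periphery ≈ 2.9, while
the normalized core profile says 1.40 — in the real data the normalization
reference is the lesion's own partial-volumed periphery, not bulk NAWM):

* `group_mean` (default): `p_l` is calibrated per lesion so the
  volume-weighted mean over the lesion's voxels equals the lesion's true
  mean — the published group mean times a unit-mean lognormal factor whose
  CV matches the published SD/mean of that group and ratio. With all SDs
  zero the calibration is exact to machine precision, which the tests
  assert at 1e-9. Used for ROI group statistics.
* `periphery`: `p_l` is the NAWM mean, so lesion values continue the local
  periphery level and the periphery-normalized layer profile reproduces the
  anchors. Used for layer-analysis cohorts.

The two variance sources (multiplicative lognormal across lesions, additive
Gaussian within lesions) are kept separate: the first controls group SDs
and keeps values positive; the second averages out in ROI means.

**Susceptibility volume.** Background 100 a.u., additive Gaussian noise
(SD 2), hypointensity depth Δ = 40: rim lesions lose Δ on their 1-voxel
outer shell only (mask minus one 6-connected erosion); area lesions lose Δ
everywhere; transition lesions lose `Δ·max(0, 1 − d/(0.45·R))` — a graded
drop fading to zero at 45% relative depth, the package's reading of a type
"in transition between area and rim". Non-iron lesions are untouched. All
iron-type hypointensities span ≥3 contiguous axial slices by construction
(lesion diameters ≥ 5.6 mm at 0.8 mm slices).

**Longitudinal series.** Three co-registered epochs (Year −1, Year 0,
Year 1) share one grid. Newly emerging lesions (default 27, iron with
probability 16/27, iron newcomers given a rim SWI signature) are absent
from the Year −1 label volume, but their future footprint carries the
published per-epoch means (times a lognormal across-lesion factor per
epoch) at every epoch — at Year −1 this emulates the already-abnormal
pre-lesional NAWM. Pre-existing lesions keep one ground truth across
epochs.

Everything is deterministic given the configuration seed; identical
config + seed reproduces bit-identical volumes.

## The spectral engine

Spectra live in the frequency domain on an ascending ppm axis (default 512
points over 0.2–5.0 ppm; ppm↔Hz via the 297.2 MHz proton frequency at 7 T).
A basis component is a sum of Lorentzian lines (absorption in the real
channel, dispersion in the imaginary channel) normalized to unit maximum of
the real channel. The default basis carries the four quantified
metabolites — tNAA (2.008, 2.49 ppm), tCr (3.027, 3.913), tCho (3.208),
mIns (3.52, 3.615, 4.054) — plus one macromolecular (MM) component; larger
peak tables (e.g. a 17-metabolite simulation) load through the same CSV
path. Rows sharing a name merge into one multi-line component; exact
duplicate (name, ppm) rows are rejected.

**Fitting.** Amplitudes minimize the real-channel sum of squares restricted
to 1.8–4.2 ppm under non-negativity (scipy NNLS). The fit is purely linear:
no lineshape, phase or frequency optimization, because the pipeline's
analysis currency is amplitude ratios, for which the linear model is exact
on the synthetic forward model (noiseless recovery to 1e-8 is a test).
CRLB% of component k is `100·σ̂·sqrt([(BᵀB)⁻¹]_kk)/a_k` with B the
fit-window basis and σ̂ the residual-based noise estimate (dof-corrected);
a zero amplitude reports +inf. Monte-Carlo scatter of the amplitude
estimates matches the reported CRLB within 20% (tested at 200 replicates).

**Quality metrics.** The noise SD for SNR is estimated in the upper 10% of
the ppm axis after projecting out the (small) basis tails that reach into
the window, so it is a pure noise estimate and vanishes on noiseless input
(on which SNR is declared undefined). SNR is the fitted NAA peak height
(amplitude × unit component maximum) over that SD; FWHM is the width of the
fitted NAA component at half maximum, interpolated on the axis and
converted to Hz (≈20 Hz at the default 10 Hz HWHM, matching the published
linewidths).

**Calibration of the default basis and noise.** Two published figures are
treated as study conditions: mean NAA SNR in 11–15 and mean metabolite
CRLBs in 15–26%. At a given SNR the CRLB of a well-separated 5-component
Lorentzian basis would be far below 15% — the published precision reflects
a 17-metabolite basis plus measured background with substantial spectral
overlap. The default MM component therefore consists of moderately broad
humps co-centered on the metabolite lines, with widths and areas calibrated
once (numerically, at design time) so that the per-metabolite CRLB factors
`sqrt([(BᵀB)⁻¹]_kk)` reproduce the published precision range at the default
noise SD of 0.12 (which puts the cohort mean NAA SNR at ≈13). The resulting
normal matrix remains well-conditioned (condition number ≈ 3·10²). On the
default cohort slab the measured values are mean SNR ≈ 13 and mean CRLBs
16–20% per metabolite; both are asserted by tests.

**MRSI stage.** Amplitude volumes are derived from the subject's ratio maps
with tCr as the unit reference; mIns is set to mIns/tNAA × tNAA/tCr so the
fitted mIns/tNAA and tNAA/tCr maps reproduce the generator's maps exactly
(the independently generated mIns/tCr map is then their product — three of
the four ratios can be simultaneously consistent with a single amplitude
assignment, and these are the three the analysis leans on). Amplitudes are
block-averaged onto the MRSI grid (default: one 32×32 slab, 2.4×2.4×8 mm
nominal voxels through the volume center), a spectrum is synthesized and
fitted per voxel with ≥50% brain coverage, and the fitted amplitudes yield
ratio maps plus CRLB/SNR/FWHM maps. On a grid matched to the phantom and at
noise 0 the fitted ratio maps equal the ground-truth maps to 1e-6 (tested).

## ROI pipeline

Tricubic resampling uses a 3D cubic spline (scipy `map_coordinates`,
order 3): exact on an identical grid, constant-preserving, and reproducing
trilinear ramps away from the boundary (the spline prefilter's edge
handling decays geometrically inward, so exactness to 1e-6 holds ≈6 source
voxels from the edge). Out-of-source target voxels are masked.

The lesion size filter is strict (>20 mm³; a lesion of exactly 20 mm³ is
excluded) and idempotent. NAWM reference ROIs are compact blobs of the
nearest achievable voxel count to 37 mm³ (72 voxels at 0.8 mm), grown
around seed points such that every ROI voxel is WM and at Euclidean
distance ≥5 mm (distance transform on the metric grid) from any GM, CSF or
lesion voxel; placement is seeded and returns what fits (with a warning)
when fewer than requested are placeable. ROI means are unweighted over
unmasked voxels; the "0.5 cm" rule is read as Euclidean voxel-to-voxel
distance, the standard choice.

**Iron-type classification.** The published categorization was a
qualitative two-reader call; the package replaces it with explicit,
testable rules. Hypointense voxels lie below (background mean − 3 SD),
with the background estimated from WM at least 2 voxels from any lesion.
A lesion is non-iron unless its hypointensity spans ≥3 contiguous axial
slices ("three contiguous layers" is read as axial slices) and covers ≥5%
of the lesion; otherwise it is area if the hypointense fraction reaches
0.85, rim if hypointensity stays out of the core (core fraction < 0.30,
core = one 6-connected erosion), and transition in between. θ_area = 0.85
(rather than a lower value) is required for the graded transition pattern
to be separable from area across the default radius range; with these
defaults the classifier recovers the generating type with 100% accuracy on
noise-free phantoms and ≥90% under default noise (both tested).

## Layer profiler

With D^k/E^k the k-fold dilation/erosion by the structuring element
(default 6-connected; 18/26 available): L+3 = D³\D², L+2 = D²\D¹,
L+1 = D¹\mask, L0 = mask\E¹, L−1 = E¹\E², L−2 = E²\E³, L−3 = E³ (the full
erosion-3 core, not a one-voxel shell). At 0.8 mm isotropic one layer is
≈0.8 mm thick. For the 6-connected element, k-fold dilation/erosion equals
taxicab-distance bands, which the tests exploit as an independent
distance-transform oracle. Lesion-free GM, CSF and neighboring-lesion
voxels are subtracted from every layer and the removed counts tracked —
conservation (Σ layer counts + exclusions = |D³|) and pairwise disjointness
are exact test assertions. There is no manual-correction step; the
deterministic mask subtraction replaces it.

Eligibility requires an original volume in [100, 400] mm³ and all four
inner layers non-empty after exclusions. Profiles are per-layer unweighted
means, normalized by the L+3 mean (so L+3 ≡ 1 whenever defined; a zero or
undefined L+3 mean is an error, an empty inner layer flags the lesion out
of group statistics for that ratio). Group statistics run on L+3/L0/L−3
only — the pipeline computes all seven layers, but adjacent layers of a
moving-average decomposition are strongly correlated and the published
comparisons use every third layer; the full profile is still emitted.

## Longitudinal tracker

Epochs are assumed co-registered (true for phantoms; a stated requirement
for real data — no registration is implemented). A Year-0 lesion is "new"
if its mask overlaps previous-epoch lesions by <10% (any nonzero overlap on
real data could be registration error). The Year-0 footprint is applied
verbatim at all epochs; footprint immutability and the absence of lesion
labels in the Year −1 footprint are invariants. Iron status is assessed at
Year 0 and collapses {area, transition, rim} → iron. Epoch comparisons run
ANOVA + Tukey across epochs within each grouping (all-new, iron, non-iron)
and iron vs non-iron within each epoch.

## Statistics

Mean ± sample SD (n−1 denominator); one-way ANOVA via the classical
between/within decomposition with p from F(k−1, N−k); Tukey–Kramer HSD with
`q = |mᵢ−mⱼ| / sqrt(MSW/2·(1/nᵢ+1/nⱼ))` against the studentized range with
df = N−k (the Kramer form because the cohort's groups are unbalanced:
174/13/7/26 plus NAWM). NAWM enters the type comparison as a fifth group.
Degenerate inputs are defined, not errors: identical groups give F = 0,
p = 1 and all Tukey p = 1; zero within-variance with distinct means gives
F = ∞, p = 0. No correction is applied across the four ratios or across
layer families beyond Tukey within each family, mirroring the emulated
analysis. The implementation is cross-checked against scipy's `f_oneway`
and `tukey_hsd` and against permutation nulls, its type-I error rate is
calibration-tested (0.05 ± 0.01 over 5000 null simulations), and the k = 2
Tukey p provably equals the two-sided pooled-t p.

Reports are CSVs (group descriptives, ANOVA row, pairwise-p matrix) at full
precision plus a JSON run log (seed, configuration, exclusion counts).

## Problem sizes and determinism

The default end-to-end cohort is 220 lesions over ten 96³ subjects with a
32×32 single-slab MRSI grid — chosen as the smallest configuration that
carries the published group sizes with every stage active; it runs in well
under a minute per cohort on one CPU. The acceptance script pools twelve
seeded replicate cohorts: the rim group mean at n = 26 has a standard error
of ≈0.19 (the published SD is 0.97), so pooling to n = 312 tightens the
recovered estimate without touching the per-lesion model. All randomness
flows from `numpy.random.Generator` seeds; spawned sub-seeds stay below
2³¹.

## What passing tests do and do not show

The generator reproduces the *statistical* structure of the published
cohort — group means/SDs, radial profile anchors, epoch means, prevalences,
SNR/CRLB ranges — on schematic geometry. Passing tests therefore show that
the analysis operators (filters, morphology, normalization, statistics,
fitting) implement their contracts and can recover known population
parameters from data with realistic variance structure. They do not show
robustness to real-data phenomena the generator omits: irregular lesion
shapes and confluent lesions, registration error between epochs and
modalities, spatially varying spectral quality and lipid contamination,
partial-volume effects of an 8 mm MRSI slab (the generator's maps emulate
the *measured*, already partial-volumed maps, so the MRSI stage is
value-preserving rather than degrading), reader variability in lesion
segmentation, and within-patient correlation of lesions (lesions are
treated as independent throughout, as in the emulated analysis).
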