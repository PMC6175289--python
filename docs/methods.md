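# Methods

`lamap` quantifies the tissue composition of fixed human left-atrial
myocardium — total, interstitial and fatty fibrosis, and fat — from three ex
vivo MRI acquisitions, and validates the whole chain on digital phantoms
with known composition. This note records the models, the default
parameters and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions taken where the design was open.

## Signal models

**Saturation-recovery T1.** A fat-saturated RARE stack is acquired at nine
repetition delays, TR ∈ {0.15, 0.25, 0.4, 0.65, 1.0, 1.5, 2.5, 4.0, 6.5} s.
Each voxel is fitted with the three-parameter model

    S(t) = A (1 − B e^(−t/T1)),

where A absorbs proton density, receive gain and echo-train amplitude
effects and B the saturation efficacy. The fit uses variable projection:
for fixed T1 the model is linear in (A, A·B), so the profiled residual is a
1-D function of T1, bracketed on a 64-point logarithmic grid over
[50, 10000] ms and refined by golden-section search. On noiseless data this
recovers generating parameters to better than 1e-6 relative. Voxels whose
peak signal is below 5σ (σ from the Rayleigh background, see below), or
whose fit lands outside A > 0, B ∈ [0.5, 2] or at the T1 search bounds, are
masked out and counted.

*Global-B second pass.* B reflects the preparation and echo train — a
property of the sequence, not of the tissue. Estimating it per voxel costs
accuracy: at SNR 40 the per-voxel Cramér-Rao bound for myocardial T1 is
≈ 71 ms with B free but ≈ 47 ms with B known. The pipeline therefore
re-fits (A, T1) per voxel with B pinned to the median of the first-pass
estimates. Both passes are available (`fit_t1_map(global_b=...)`); the
pipeline default is the two-pass fit.

**Monoexponential transverse decay.** Multi-echo magnitude data are fitted
with S(TE) = S0·e^(−TE/τ). Two objectives are provided: plain least squares
(variable projection + golden section, as above), and a Rician-aware fit
that minimises the misfit of the expected magnitude

    E[M | ν, σ] = σ √(π/2) [(1 + x) I0(x/2) + x I1(x/2)] e^(−x/2),
    x = ν²/(2σ²),  ν = S0 e^(−TE/τ),

evaluated with exponentially scaled Bessel functions (overflow-free at any
SNR; above x = 1e8 the Gaussian-regime form √(ν² + σ²) is used). The
Rician fit runs a vectorised Levenberg–Marquardt on (log S0, log τ) with
the analytic derivative dE/dν, warm-started from the Gaussian fit. It
removes the noise-floor bias: at SNR 5 the Gaussian fit overestimates a
30 ms decay constant by tens of ms, the Rician fit by an order of magnitude
less.

**Noise estimation.** The fluorinert bath is proton-free, so background
magnitudes are Rayleigh; σ is estimated as mean/√(π/2) (or from the second
moment), on a user mask or on the lowest-intensity border-connected region.

**Two-point Dixon.** At 4 T the fat-water shift is ≈ 600 Hz; the gradient
echo at TE = 3.356 ms is (nearly) in phase and 4.194 ms opposed. The fat
fraction is FF = (IP − OP)/(2·IP) after dividing both magnitudes by
e^(−TE/T2*) with a shared T2* (sequential correction with an externally
fitted map). Following the original analysis the decay map fitted on the
MSME data stands in for T2*; the residual mismatch shifts FF by ≲ 0.02,
which the adaptive fat-region threshold absorbs. Magnitude Dixon cannot
distinguish water from fat dominance (W↔F symmetry); fold-over is left
unresolved and the phantom tissues stay water-dominant (see below). Voxels
with corrected IP below 5σ are masked (the formula divides by IP); negative
fractions are clipped to zero and counted.

## Tissue clustering

T1 values of fitted voxels are clustered with a 1-D Gaussian mixture fitted
by EM (own implementation: seeded quantile/k-means initialisation, 10
restarts, per-iteration log-likelihood trace, collapse detection; verified
against scikit-learn on synthetic mixtures). Components get roles purely by
mean-T1 ordering:

* three classes → myocardium < total fibrosis < PFA;
* four classes → fat mixture < myocardium < interstitial fibrosis < PFA;
* two classes on the fat region → fat < fatty fibrosis.

Voxels are hard-assigned by maximum posterior. FWHM per class is
2√(2 ln 2)·σ.

Three robustness measures, all on by default and all of which matter on
realistic data:

1. **Interior fitting.** Mixtures are fitted only on voxels whose largest
   in-plane neighbour |ΔT1| is below 3× the map-wide median of that
   statistic (a self-calibrating scale). Partial-volume voxels on strong
   interfaces — especially the tissue–bath rim, whose apparent T1 sweeps
   continuously from fibrosis-like to bath-like values — otherwise carry
   enough mass to capture a mixture component and break the ordering-based
   role assignment. All voxels are still classified under the fitted model.
2. **Uniform outlier component.** EM carries an optional uniform background
   component over the data range whose weight is learned (the classical
   noise-component robustification); stray values cannot then hijack a
   Gaussian.
3. **Border exclusion.** Tissue voxels adjacent to bath, background or
   unfitted voxels are excluded from fraction numerators and denominators,
   the counterpart of excluding the specimen border (endo-/epicardial rim)
   from histological quantification.

**Pipeline composition.** The four-class mixture is fitted on all interior
T1 values; its PFA class delimits tissue. The Dixon fat region (threshold:
Otsu on the within-tissue FF histogram, floored at 0.05 and rejected when
the candidate region's mean FF is < 1.5× the threshold — the upper noise
tail of a fat-free map fails this) is superimposed; the three-class mixture
is fitted on the fat-eliminated T1 values. This fat elimination is a
deliberate design choice: the three-class model assumes fat contributes no
signal, which is only approximate on rendered data where adipose tissue
keeps its residual water signal at short T1 — with tens of percent of fat
mass at 350 ms, a three-component fit provably merges the myocardium and
fibrosis modes. Inside the fat region a two-class mixture separates fat
from fatty fibrosis (the "T1-fat map" step); a region smaller than 20
voxels, or one whose T1 distribution a single Gaussian explains better by
BIC, reports 0% fatty fibrosis (flagged) instead of an arbitrary split.
Fatty fibrosis is confined to the fat-region interior: on the region's rim
an elevated T1 reflects myocardial partial volume, not septal collagen.

The four-component partition (myocardium, interstitial fibrosis, fat, fatty
fibrosis) sums to 100% of tissue per slice. Interstitial fibrosis inside
the fat region counts as fatty. Total fibrosis is the three-class fibrosis
plus fatty fibrosis. Per-slice percentages are averaged over the central 3
slices for fibrosis quantities and 5 slices for fat; the designated 2D
slice (the histology-matched plane) defaults to the middle slice. The
reclassification rate between the three-class total-fibrosis and
four-class interstitial-fibrosis maps is the percentage of voxels whose
fibrosis membership differs (an any-label mode exists).

## Resolution degradation

`degrade_resolution` block-averages integer factors of the 200 µm grid
(trailing rows/columns dropped and logged) either on the raw series before
fitting (signal domain — the physically faithful partial-volume simulation)
or on the fitted maps (map domain, the default). The percentage of
variation of each component is 100 × (test − reference)/reference against
the 200 µm run; the default ladder is {200, 400, 1000, 2000} µm.

Degraded maps are **classified under the native-resolution mixtures** rather
than re-fitted. Block averaging shrinks the voxel noise by the averaging
factor while partial-volume spread persists, so the degraded histogram has
sharp tissue cores with heavy mixed-voxel halos; an unsupervised (even
warm-started) maximum-likelihood re-fit reproducibly moves the fibrosis
component onto the myocardial halo, inflating fibrosis severalfold instead
of producing the expected loss. Classification under the anchored model
yields the physically expected behaviour: sub-voxel strands and septa
dilute below the class boundaries (fibrosis falls), while lobule borders
bleed outward past the fat-fraction threshold (fat rises). Fresh fitting
remains available by not passing the reference quantification.

## Statistics

Spearman rank correlation (mid-ranks; t-approximation p, exact permutation
p available for n ≤ 9), ordinary least squares with Pearson r, Bland-Altman
bias ± 1.96·sample-SD limits, and the Steiger Z̄* test for two dependent
correlations sharing one variable (Fisher transforms with the
shared-variable covariance term; Hotelling's t behind a flag). Correlation
triples are validated for positive semidefiniteness — note that a pair of
equal correlations r12 = r13 = 0.8 *requires* r23 ≥ 0.28, so the
equal-correlation zero-statistic property only holds on consistent triples.
No multiple-testing correction is applied.

## The digital phantom

Each sample is a myocardial ellipse inside a PFA rim, immersed in a
proton-free fluorinert bath, on a 96×192 grid of 200 µm pixels (1 mm
slices, 5 slices), with microstructure painted on a 10× supersampled grid
(20 µm cells) and block-averaged into acquisition voxels (in-plane partial
volume only; slices are single-label slabs). Rician noise is applied after
block averaging, as two Gaussian channels on the complex signal, with scale
relative to the peak clean signal (SNR 40 ⇒ σ = peak/40).

Microstructure and targets: interstitial fibrosis is painted to an area
target as 60% confluent patches (semi-axes 2.5–4.5 mm — resolved at 2 mm)
plus 40% thin strands (0.4–0.6 mm wide — lost at 2 mm); fat is painted as
lobules (radius 1.0–1.8 mm) crossed by 0.5 mm fatty-fibrosis septa. The mix
of resolved and sub-voxel structure is what produces the moderate
resolution-variation percentages seen on real tissue. Painting stops
mid-structure when a target is met, so area targets are hit to ≈ ±1%.

Tissue parameters (all configurable): T1 962 ms (myocardium) and 1131 ms
(fibrosis) are the reported ex vivo values; fat T1 350 ms, fatty fibrosis
1100 ms, bath 2000 ms, and all T2/T2*/proton-density values are explicit
assumptions — only the ordering fat < myocardium < fibrosis < bath is
load-bearing. Two defaults deserve comment:

* **Bath T1 = 2000 ms.** With a 6.5 s maximum repetition delay, a much
  longer bath T1 is so poorly constrained per voxel (CRLB ≈ 345 ms at
  2800 ms, and skewed) that the maximum-likelihood four-component mixture
  spends two components on the bath and merges myocardium with fibrosis.
  At 2000 ms the bath estimate is tight (≈ 180 ms) and near-Gaussian, and
  the bath remains far above the fibrosis T1, which is all the role
  assignment needs.
* **Intravoxel fat fractions 0.45 (adipose) / 0.30 (fatty fibrosis).**
  Two-point magnitude Dixon is single-valued only in the water-dominant
  regime; the measured ex vivo fat fractions stayed below ~47%, consistent
  with mixed fatty infiltration rather than bulk lipid. Keeping every
  tissue below 0.5 makes the raw fat fraction monotone in fat content.
  Under fat saturation the lipid fraction of every cell is suppressed by a
  residual factor (default 0), so adipose voxels keep a residual-water
  signal at T1 350 ms — which is what the T1-fat clustering observes.

What the phantom does *not* emulate: through-slice partial volume, B0/B1
inhomogeneity and susceptibility (the fluorinert bath exists precisely to
avoid these), coil sensitivity, RARE profile-ordering and echo-train
amplitude effects (absorbed into proton density), multi-peak fat spectra,
motion and flow. Passing tests therefore demonstrate the correctness and
internal consistency of the analysis chain under the stated signal models,
not robustness to scanner artefacts.

## Key limits at the study conditions

At SNR 40 with the nine-TR schedule, per-voxel T1 noise is CRLB-limited
(≈ 47 ms for myocardium after the global-B pass), so the myocardium and
fibrosis modes — 169 ms apart — overlap at roughly 3σ. Fraction accuracy
then rests on the mixture decomposition of overlapping components, not on
clean per-voxel separation; the robustness measures above are what keep
that decomposition anchored. Recovered fractions on the eight-phantom
study stay within ±1.5 percentage points of truth per component; the ±2 pp
figure quoted for well-separated mixtures (component gap ≥ 4σ) is not
attainable for these T1 values at this SNR by any unbiased per-voxel
estimator.

## Problem sizes used

The validation suite runs the full 96×192 matrix: exact-recovery checks on
3 noiseless slices, an eight-phantom recovery study at SNR 40 (seeds 1-8,
5 slices each), the resolution ladder on the seed-1 phantom in both modes,
10⁴ simulated decay curves for the Rician-bias comparison, and two repeated
full runs for bit-level reproducibility.
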