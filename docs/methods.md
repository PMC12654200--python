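# Methods

## Data model and conventions

All stages operate on a `SpectraSet`: absorbance spectra on a shared,
strictly increasing wavenumber grid (cm⁻¹) with donor / replicate / group
metadata. Technical replicates are averaged per donor before any analysis
(`aggregate_replicates`), and all supervised and unsupervised computations
use donor-level spectra only, so technical replication can never leak into
cross-validation. Spectral windows are closed intervals: fingerprint
900–1800 cm⁻¹, Amide I 1600–1700 cm⁻¹, off-band 1800–1900 cm⁻¹ with
2000–2200 cm⁻¹ as fallback. Axis alignment uses linear interpolation
restricted to the common overlap of all axes; no extrapolation, ever.

## Quality control

Four donor-level metrics, all invariant to uniform rescaling of a spectrum
(so pathlength differences cannot masquerade as quality differences):

1. **Amide I SNR** — the rubber-band-corrected maximum in 1600–1700 cm⁻¹
   divided by the sample SD (n−1 denominator) of the corrected absorbance in
   an off-band window. The hull is computed on the full available spectrum
   because it must span both the band and the noise window. If the primary
   off-band window holds fewer than `min_offband_points` (default 10) grid
   points the fallback window is used, then the global SD as a last resort;
   the source actually used is reported alongside the value. An exactly zero
   noise estimate raises rather than returning infinity — it indicates
   degenerate (noise-free synthetic) input.
2. **Spike count** — robust z-scores of the first differences within the
   fingerprint window, z = (d − median d)/(1.4826·MAD d); points with
   |z| > 6 are counted. The 1.4826 factor makes the MAD a consistent SD
   estimator. MAD = 0 returns 0 by convention. Because one single-point
   spike perturbs two successive differences, an optional mode counts
   maximal runs of consecutive flagged points instead of points; the default
   counts points, which also explains why real-data spike counts can reach
   the tens.
3. **Cosine coherence** — each donor's fingerprint spectrum and the cohort's
   pointwise median, both scaled to unit Euclidean norm; the value is their
   dot product.
4. **Baseline area fraction** — trapezoidal area under the rubber-band
   baseline over the fingerprint window as a percentage of the raw area, a
   drift index.

Group comparisons of QC metrics use the exact Mann–Whitney machinery below,
with DCD as the first sample.

## Exact statistics

At five donors per group, large-sample approximations are meaningless, so:

* **Mann–Whitney U** is the pair count Σ[aᵢ > bⱼ] + 0.5·[aᵢ = bⱼ]. The
  two-sided p-value enumerates all C(n₁+n₂, n₁) reassignments of the pooled
  observed values and doubles the smaller tail, clamped at 1; ties are
  handled by the enumeration itself rather than a correction formula.
  Enumeration is limited to pooled n ≤ 20 (184 756 assignments) — beyond
  that the function refuses rather than silently approximating. Note that
  observed-value enumeration of tied data can differ marginally from
  classical tables that assume no ties; on tie-free data it reproduces the
  classical two-sided p exactly (verified against an independent
  implementation for every U at sizes 5/5).
* **Rank-biserial r** = 1 − 2U/(n₁n₂), the standard effect size for U.
* **Fisher's exact test** sums hypergeometric probabilities of all tables
  with the observed margins whose point probability does not exceed the
  observed one (point-probability two-sidedness, 1e-12 slack).
* **Chi-square** is the Pearson statistic without continuity correction,
  referred to χ²₁.

## Preprocessing

* **Rubber-band correction** subtracts the lower convex hull of the
  (ν, A) point set, interpolated between hull vertices (Andrew monotone
  chain). It is idempotent and leaves any convex spectrum at zero.
* **Savitzky–Golay derivatives** use second-order local polynomials over a
  15-point window, scaled by the grid spacing so outputs are true d/dν
  derivatives. The grid must be uniform to 1e-9 relative tolerance. The
  7 edge points per side, where the convolution window is incomplete, are
  dropped rather than padded; windows are therefore extracted with a 7-point
  margin when the surrounding grid allows, so the derivative still covers
  the full analysis region.
* **Vector normalization** divides by the Euclidean norm over the current
  window (region-local, i.e. applied after windowing); a mean-center-first
  variant is available behind a flag. Any pipeline ending in VN is exactly
  invariant to per-spectrum multiplicative scaling.
* The six named pipelines (`bc`, `vn`, `d1`, `d1+vn`, `d2`, `d2+fcbf`)
  apply their steps in order to every row; `d2+fcbf` marks that FCBF runs
  downstream inside the evaluation loop, not as a spectral transform.
  Amide I deconvolution is not implemented: no band-narrowing parameters
  exist to implement it against, and the pipelines run on the Amide I window
  without it.

## FCBF

Features (wavenumbers) are discretized — default a median split, which is
the only discretizer that remains estimable at n = 10; equal-frequency
binning and Fayyad–Irani MDL cuts are available, though at this sample size
the MDL criterion accepts only near-perfect splits. Symmetrical uncertainty
uses base-2 entropies of the empirical joint distribution. Selection ranks
features by SU with the class (ties broken toward the lower wavenumber,
making the procedure fully deterministic), drops SU ≤ δ (default δ = 0),
and then walks the list removing any later feature at least as predictable
from a kept feature as from the class. Selection always runs on donor-level
rows.

Two numerical guards matter at this scale. Band tails are truncated to
exactly zero below e⁻⁵⁰ relative amplitude, and features whose relative
spread is ≤ 1e-9 are binned as constant: otherwise denormal-range tails and
floating-point cancellation residue (spreads ~1e-17 on values ~1e-4) would
impose donor orderings on wavenumbers that carry no physical signal, and a
rank-based statistic happily consumes them.

**Behaviour at n = 10, honestly stated.** SU from a median split of ten
values saturates: any feature that rank-separates the groups reaches
SU = 1.0 exactly, and in leave-one-out folds of nine donors the 5/4 split
cannot match a 4/5 class partition, capping SU at ≈ 0.597 for *any* feature
— genuinely discriminant or not. Rank coincidences are scale-free, so with
hundreds of correlated features some spurious ties are unavoidable in the
fold setting. Consequences: donor-level (n = 10) selection localizes the
injected bands reliably (≈ 97% of synthetic cohorts select only wavenumbers
within ±6 cm⁻¹ of an injected discriminant band), while per-fold selections
on noisy cohorts routinely contain tie-artifact wavenumbers. This is a
property of the method at this sample size, not of the implementation.

## Classification and evaluation

Leave-one-donor-out: per fold, optional FCBF on the nine training donors
(`per_fold`; `global` instead applies one selection computed on all ten,
which mirrors how a single band list can be reported for all folds but is
optimistic), per-fold z-scoring with training means/SDs (SD floor 1e-12),
then an RBF SVM (C = 1, scale gamma) scored by its signed decision value or
Gaussian Naïve Bayes (variance smoothing 1e-9) scored by the positive-class
posterior. Thresholds are fixed (0 / 0.5); n = 10 forbids threshold tuning.
Out-of-fold scores aggregate into a rank AUC (ties 0.5) that is reported
exactly as computed — an inverted score orientation shows up as AUC < 0.5
and is never silently flipped — plus a confusion matrix, accuracy with the
exact Clopper–Pearson interval (Beta-quantile form, closed at 0 and 1), and
sensitivity/specificity with DCD as the default positive class. Everything
is deterministic given the configuration; there are no random restarts.

## Unsupervised structure

Cosine distances (1 − cosine similarity, range [0, 2]) feed a metric MDS
(classical Torgerson initialization, then SMACOF majorization to relative
stress change < 1e-9 or 300 iterations; stress is non-increasing by
construction and the run is deterministic) and Ward clustering via the
Lance–Williams recursion applied to the given distances. Cosine distances
are not Euclidean, so this is Ward's update on non-Euclidean input — kept
deliberately, with this caveat, because it matches how such heatmaps are
produced in practice. 2D-COS treats the sample series as the perturbation
axis; for a cross-sectional cohort this is a *choice*, so the ordering
(default: DBD block, then DCD, by donor id) is explicit, configurable and
recorded — the asynchronous map depends on it. The maps use the m−1
normalization; the alternative 1/m affects scale only.

## Synthetic cohorts

The generator emulates dried-film transmission FTIR of perfusion fluid on
the 400–4000 cm⁻¹ grid at 2 cm⁻¹ spacing: 5 + 5 donors, 3 technical
replicates each (the replicate count is a free choice; the study does not
state one). Per donor it draws discriminant band amplitudes (group mean ×
unit-mean lognormal, CV 3%), a polynomial baseline (SDs 0.002/0.001/0.0005
on a unit coordinate, shifted non-negative plus a 0.01 offset), and a
lognormal pathlength factor (CV 3%); per replicate it adds i.i.d. Gaussian
noise (SD 0.002 absorbance) and Poisson(1) single-point spikes of ±0.05.
The background (a broad pedestal plus eleven shared bands at canonical
biofluid positions) is identical across donors up to the pathlength factor,
so the shared chemistry varies along a single latent axis; the discriminant
bands at 1202, 1342, 1413 and 1673 cm⁻¹ are narrow (FWHM 6 cm⁻¹) with DCD
amplitudes elevated by 0.10 absorbance (50× the noise SD).

These defaults were fixed once, with the recovery analysis above in mind:
a rank-based filter at n = 10 only localizes effects when background donor
orderings are governed by one latent direction with noise well below the
inter-donor gaps, and when the injected bands are narrow enough that their
separable zone stays within a few grid steps of the center. What the
generator deliberately does not emulate: Mie scattering, water-vapor
rotational lines, film-interference fringes, detector drift, or
donor-specific background chemistry. Two visible consequences: the
hull-baseline area fraction is large (the pedestal is counted as baseline),
and the QC metrics themselves separate the groups (the discriminant bands
raise DCD Amide I SNR and their steep flanks add to the spike count) —
unlike the real cohort, where QC was group-balanced. Passing tests on these
cohorts therefore demonstrate correctness of the computations and
recoverability of planted effects, not robustness to real instrumental
artifacts.

Two derived configurations support testing: `null_config` removes all group
effects (classifiers must hover near chance: measured mean LOOCV accuracy
≈ 0.4–0.5 for the d2+FCBF Naïve Bayes cell, and the 24-cell grid exceeds
AUC 0.9 in only a few percent of cohorts), and `separable_config` switches
off noise, spikes, drift and pathlength variation so that only the
discriminant amplitudes vary — on such a cohort feature selection can only
pick discriminant wavenumbers and leave-one-out classification is perfect
(accuracy 1.00, interval 0.69–1.00, AUC 1.00) for every seed, which is the
regime in which a perfect LOOCV row is a meaningful statement rather than a
small-sample accident.

## Problem sizes

The test suite and the acceptance script use the cohort size the study
design fixes (10 donors × 3 replicates, 1801 grid points); the recovery and
null analyses run 50 generator seeds each, and the full evaluation grid is
2 regions × 6 pipelines × 2 models = 24 LOOCV cells per cohort. A complete
acceptance run takes seconds to tens of seconds on one core.

## Known limitations

* Per-fold FCBF at nine donors is tie-degenerate (see above); conclusions
  about *which* wavenumbers drive a fold should use the donor-level
  selection.
* The exact Mann–Whitney enumeration is bounded at pooled n = 20.
* Gaussian Naïve Bayes on continuous features is the standard continuous
  reading of "Naïve Bayes"; software that discretizes features first would
  differ in detail.
* Ward-on-cosine and the 2D-COS sample ordering are pragmatic conventions,
  both flagged where used.
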