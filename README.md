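# ftirfp

Label-free FTIR fingerprinting of kidney-graft preservation fluid, as an
end-to-end, testable pipeline. Static cold-storage effluent carries
biochemical traces of the donor pathway — donation after circulatory death
(DCD) versus donation after brain death (DBD) — and mid-infrared spectra of
the dried fluid integrate the relevant protein, lipid, carbohydrate and
phosphate bands. `ftirfp` implements the full analysis for such a pilot
cohort (n = 10 donors, 5 per group, technical replicates averaged per
donor):

* **Spectral QC** — Amide I signal-to-noise ratio with an off-band noise
  ladder (1800–1900 → 2000–2200 cm⁻¹ → global SD), spike detection via a
  robust z-score on fingerprint first differences (|z| > 6 with
  SD-consistent MAD), cosine similarity of each vector-normalized
  fingerprint spectrum to the cohort median, and the rubber-band baseline
  area as a fraction of raw spectral area.
* **Preprocessing** — rubber-band (lower convex hull) baseline correction,
  Savitzky–Golay first/second derivatives (second-order polynomial,
  15-point window, edge-truncated), vector normalization, and the six named
  pipelines built from them (`bc`, `vn`, `d1`, `d1+vn`, `d2`, `d2+fcbf`).
* **Feature selection** — Fast Correlation-Based Filter written from
  scratch: symmetrical uncertainty SU(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) on
  discretized donor-level features, relevance ranking, and redundancy
  elimination (drop fⱼ when SU(f_keep, fⱼ) ≥ SU(fⱼ, class)).
* **Classification** — leave-one-donor-out cross-validation of an RBF SVM
  and Gaussian Naïve Bayes with per-fold standardization and (optionally)
  per-fold FCBF; rank-based AUC with ties at 0.5, accuracy with the exact
  Clopper–Pearson 95% interval, sensitivity and specificity.
* **Exact small-sample statistics** — Mann–Whitney U with 0.5 per tie and a
  two-sided p-value by full enumeration of group assignments, rank-biserial
  r = 1 − 2U/(n₁n₂), Fisher's exact test (point-probability rule), and the
  2×2 Pearson chi-square.
* **Unsupervised structure** — cosine distance matrices, metric MDS
  (classical scaling + SMACOF), Ward hierarchical clustering, and
  generalized 2D correlation spectroscopy (synchronous ỸᵀỸ/(m−1) and
  asynchronous ỸᵀNỸ/(m−1) maps with the Hilbert–Noda matrix).

The original cohort's spectra are not publicly deposited, so the package
ships a synthetic-cohort generator (`ftirfp.synthetic`) that produces
FTIR-like absorbance spectra on the 400–4000 cm⁻¹ grid at 2 cm⁻¹ spacing
with known ground truth: Gaussian bands with group-dependent intensities
near 1202, 1342, 1413 and 1673 cm⁻¹, a shared biofluid background scaled by
a per-donor pathlength factor, polynomial baseline drift, Gaussian noise and
sparse single-point spike artifacts. Every stage of the pipeline is
validated against that ground truth and against brute-force oracles.

## Worked example

Simulate a cohort, run QC, and evaluate the strongest pipeline:

```bash
ftirfp simulate --out cohort.csv --seed 7
ftirfp qc cohort.csv --out-records qc.csv --out-groups qc_groups.csv
ftirfp classify cohort.csv --region fingerprint --pipeline d2+fcbf --model nb
```

The QC table holds one row per donor:

```
donor_id,group,snr_amide_i,spike_count,cosine_fp,baseline_area_fraction,snr_noise_source
DBD01,DBD,100.1578504351043,5,0.999901978462265,64.2440743426216,offband_primary
DBD02,DBD,98.62500159213012,5,0.9999438067012749,64.05091823478261,offband_primary
...
```

`snr_amide_i` is the baseline-corrected Amide I peak height over the
off-band noise SD (here ≈ 100, noise taken from the primary 1800–1900 cm⁻¹
window); `spike_count` the number of |z| > 6 excursions in the fingerprint
first differences; `cosine_fp` the shape coherence against the cohort median
(1.0 = identical shape); `baseline_area_fraction` the percentage of raw area
attributable to the convex-hull baseline (large here because the synthetic
spectra sit on a broad absorption pedestal).

The `classify` call prints the LOOCV summary for Naïve Bayes on
second-derivative fingerprint spectra with per-fold FCBF:

```
"auc": 0.8, "accuracy": 0.7,
"accuracy_ci": [0.348, 0.933],
"sensitivity": 0.8, "specificity": 0.6
```

AUC is the probability a random DCD donor outscores a random DBD donor
(ties at 0.5); the accuracy interval is the exact binomial (Clopper–Pearson)
95% interval for 7 correct out of 10 donors — at n = 10 it spans 0.35–0.93,
which is why single-pipeline point estimates in such pilots must be read
cautiously. On a cohort with an overwhelming group effect and no nuisance
variation (`ftirfp.synthetic.separable_config`), the same pipeline reaches
accuracy 1.00 with interval (0.69, 1.00) and AUC 1.00.

The full 2-regions × 6-pipelines × 2-models grid, QC tables and exploration
artifacts (cosine distances, MDS coordinates, Ward linkage, 2D-COS maps) are
produced in one run:

```bash
ftirfp report --out-dir run/ --seed 7
```

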