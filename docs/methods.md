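# Methods

## Scientific background

Resting-state BOLD fluctuations carry information in both gray matter (GM)
and white matter (WM). A voxel's **ALFF** (amplitude of low-frequency
fluctuation) summarizes the strength of its spontaneous activity as the mean
spectral amplitude within a low-frequency band. **Functional covariance
connectivity (FCC)** asks a different question than ordinary functional
connectivity: instead of correlating two time series within one subject, it
correlates two voxels' ALFF values *across subjects*,

    r(g, w) = 1/(N-1) * sum_i Z_g,i * Z_w,i,

where Z are across-subject standard scores (sample sd, denominator N−1).
The per-subject product **FCS** = Z_g,i · Z_w,i is subject *i*'s contribution
to that correlation, and it is the quantity compared between groups: if a
GM–WM pair covaries strongly in controls but not in patients, the mean FCS
differs between groups and a two-sample t-test per connection can detect it.

The package implements this analysis end to end for a two-group design
(healthy controls `HC` vs. a patient group `PDH`), together with a synthetic
cohort generator that makes the true covariance structure known.

## Pipeline and parameters

Stage order is fixed: volume drop → tissue masks → signal extraction →
nuisance regression → band-pass filter → spatial smoothing → ALFF →
normalization → FCS → two-stage testing → classification.

| parameter | default | meaning |
|---|---|---|
| `n_drop` | 10 | initial volumes discarded (scanner equilibration) |
| `mask_threshold` | 0.6 | group-mask occupancy; inclusion is **strictly** > 0.6 |
| `gm_band` | 0.01–0.1 Hz | GM band-pass / ALFF band |
| `wm_band` | 0.01–0.15 Hz | WM band-pass / ALFF band (WM signals carry higher-frequency content) |
| `fwhm_mm` | 4 | isotropic Gaussian smoothing FWHM (σ = FWHM/√(8 ln 2)) |
| `alpha_screen` | 5e-6 | stage-1 uncorrected per-connection threshold |
| `fdr_q` | 0.05 | stage-2 Benjamini–Hochberg level |
| `entry_alpha` / `removal_alpha` | 0.05 / 0.10 | stepwise logistic LRT entry/removal |
| `pooling` | pooled | z-scores over both groups jointly (`within_group` available) |
| `t_variant` | student | pooled-variance t (`welch` available) |

Design choices where the protocol was open:

- *Individual masks* assign each voxel to the max-probability tissue, ties
  broken by fixed precedence GM > WM > CSF; voxels with all probabilities
  below 0.1 are background.
- *"Near the boundary"* is operationalized as 6-connectivity adjacency
  between the GM and WM group masks; mixed (overlapping) voxels are removed
  first, then the adjacency layer is removed simultaneously from both sides,
  leaving disjoint, non-adjacent masks.
- *Detrending* is a linear-trend column inside the single nuisance
  regression (intercept + trend + CSF mean + Friston-24 motion expansion,
  27 columns), equivalent to a separate detrend pass by Frisch–Waugh.
- *Filtering* is an ideal rectangular frequency-domain filter: DFT bins with
  frequency outside [f_lo, f_hi] are zeroed (inclusive edges, DC always
  removed). No taper: this matches common resting-state toolchain behavior
  and makes the in-band/out-band contract exact for bin-aligned sinusoids.
- *Smoothing* renormalizes the Gaussian kernel within the tissue mask
  (smooth(data·mask)/smooth(mask)), so out-of-mask values never leak in and
  constants are preserved. The discrete kernel is the sampled Gaussian
  truncated at 4σ (radius `int(4σ + 0.5)`).
- *ALFF* sums the single-sided spectrum only; the recipe's scale convention
  is immaterial because each subject's maps are divided by the mean ALFF
  over the union of the GM and WM group masks (CSF excluded — the pipeline
  retains no other brain voxels).
- *Multiple testing* is per **connection** (GM–WM pair), not per voxel, at
  both stages. Stage 1 is deliberately uncorrected at a very small alpha;
  stage 2 re-tests the ROI-restricted connection set with BH-FDR. Note that
  stage 2 re-uses the same subjects that selected the ROI, so its error
  control is conditional on selection — a property of the protocol itself.
- *Stepwise logistic* is forward selection with likelihood-ratio entry
  (p < 0.05) and removal (p > 0.10), deterministic tie-break on the smaller
  feature index, collinear candidates skipped. Quasi-complete separation
  (|coef| > 15 or deviance → 0) sets a flag; coefficients are reported
  as-is with a warning. The fit is IRLS with convergence at max |score| <
  1e-8 or 100 iterations.
- *ROC* uses the model's predicted probabilities (patients = positive
  class), thresholds swept over unique scores, ties grouped into a single
  step; the trapezoidal AUC therefore equals the Mann–Whitney statistic
  with half credit for ties. AUC is reported as computed (never flipped).

## Synthetic cohort

Each subject lives on a 12³ grid of 4 mm voxels (TR 2.5 s, 139 timepoints,
15 per group by default). Tissue geometry is deterministic: a GM shell of
thickness 2 around a WM core box, with a 2-voxel CSF "ventricle" block at
the centre; the home tissue has probability 0.9, the other two 0.05.

Signals are sums of 8 random sinusoids with frequencies uniform in
0.01–0.1 Hz (unit RMS), so all signal mass is in-band without filtering
artifacts. The planted structure follows a single-factor model: each subject
has one latent value u_s ~ N(0, latent_sd²); a planted GM voxel has band
amplitude 1 + u_s and a planted WM voxel 1 + β·u_s + √(1−β²)·ε with
ε ~ N(0, latent_sd²) and β the group's coupling, giving an across-subject
amplitude correlation of exactly β. Planted voxels keep a fixed waveform
across subjects so their ALFF is proportional to the planted amplitude; all
other brain voxels get fresh independent waveforms of unit amplitude. White
measurement noise (sd `noise_sd` = 0.05, i.e. latent:noise = 5:1) is added
everywhere, CSF voxels share one per-subject nuisance waveform, and motion
traces are Gaussian random walks (step sd 0.02) that carry no injected
artifact — they exist to exercise the Friston-24 regression path.

The default planted topology is a fully coupled 3 GM × 8 WM block with
coupling 0.95 in HC and 0.0 in PDH — a desk-scale analogue of a coherent
GM–WM region whose covariance is reduced in patients (reduction, not sign
reversal, is the default effect direction; both directions are supported).
Planted voxels are drawn from the subset guaranteed to survive group-mask
boundary exclusion.

What the generator does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, scanner drift beyond a linear
trend, spatial normalization error, heavy-tailed latent distributions, and
motion-correlated artifacts. A green test therefore establishes the
correctness and calibration of the statistical machinery on the stated
amplitude-covariance model, not robustness to realistic fMRI artifacts.

## Statistical properties and known limitations

- **Identity check.** For every connection, (1/(N−1))·Σ_s FCS equals the
  Pearson correlation of the two ALFF columns to 1e-8; this is the module's
  core correctness surface and is enforced in tests.
- **Null calibration.** With equal couplings in both groups, the
  per-connection two-sample t at α = 0.01 is calibrated (99% binomial
  interval), and BH at q = 0.05 over an all-null ROI rejects anything in
  ≲ 5% of cohorts. The FCS products are heavy-tailed (variance 1 + r²,
  kurtosis ≫ 0) but symmetric, and the t-test's level is empirically
  accurate at n = 20 per group.
- **Intrinsic power limit of the product statistic.** The variance of
  Z_X·Z_Y comes from the latent randomness itself (Var = 1 + r² for
  bivariate-normal scores), not from measurement noise, so no
  signal-to-noise setting of the generator can shrink it. At couplings
  0.95 vs 0.0 and n = 20/group the per-connection t has mean ≈ 2.5; the
  α = 1e-3 threshold (t ≈ 3.57) is reached for only ~10–15% of planted
  connections, and a single-voxel mean-FCS feature discriminates groups
  only through u_s² (a χ²₁ with heavy mass near zero), capping its AUC
  near ~0.85 at these sample sizes. Detecting such effects reliably at
  desk scale requires either larger cohorts or a correlation-difference
  test (e.g. Fisher z), which the protocol deliberately does not use.
- **Selection circularity.** Because stage 2 re-tests the subjects that
  selected the ROI, chance connections that pass the stage-1 screen tend to
  survive stage-2 FDR; stage-2 q-values should be read as descriptive
  within the selected set, not as unconditional error control.
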