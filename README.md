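# gwfcc — gray–white matter functional covariance connectivity

`gwfcc` implements an ALFF-based **functional covariance connectivity (FCC)**
analysis of resting-state fMRI for two-group designs, aimed at studies that
ask whether the coupling between gray-matter (GM) and white-matter (WM)
spontaneous activity differs between patients and controls (the motivating
use case is Parkinson's disease with hyposmia, `PDH`, vs. healthy controls,
`HC`). Because such analyses are usually locked inside GUI toolchains, the
package also ships a seeded synthetic cohort generator with known ground
truth, so every stage can be tested end to end.

## The statistic

A voxel's **ALFF** is its mean spectral amplitude within a low-frequency
band (0.01–0.1 Hz for GM, 0.01–0.15 Hz for WM), normalized per subject by
the whole-brain mean. FCC correlates two voxels' ALFF values **across
subjects**:

    r(g, w) = 1/(N−1) · Σᵢ Z_g,i · Z_w,i

where Z are across-subject z-scores (sample sd). The per-subject product
**FCS** = Z_g,i · Z_w,i is subject *i*'s contribution to that correlation
and is the unit of analysis: per GM–WM connection, a two-sample t-test
compares FCS between groups. A voxelwise screen (P < 5·10⁻⁶, uncorrected)
defines regions of interest; ROI-restricted connections are re-tested with
Benjamini–Hochberg FDR (q < 0.05); and each ROI voxel's mean FCS against
the other tissue's ROI voxels feeds a forward-stepwise binary logistic
model, scored by ROC/AUC.

Preprocessing covers the in-scope steps on a common 4 mm grid: drop the
first 10 volumes, max-probability individual tissue masks, group masks at
strictly >60% occupancy with GM/WM boundary exclusion, nuisance regression
(intercept, linear trend, CSF mean, Friston-24 motion expansion),
tissue-specific ideal band-pass filtering, and masked 4 mm FWHM Gaussian
smoothing. See `docs/methods.md` for every design decision and limitation.

## Worked example

Run the full pipeline on a simulated default cohort (15+15 subjects, a
3 GM × 8 WM block of connections whose across-subject coupling is 0.95 in
HC and 0.0 in PDH):

```sh
$ printf 'alpha_screen: 0.001\nseed: 4\n' > demo.yaml
$ gwfcc run-all --config demo.yaml --out demo
gwfcc 0.1.0 run (seed 4)
subjects: 30; GM voxels: 568; WM voxels: 56
stage-1 significant connections: 8
ROI: 8 GM x 8 WM voxels
stage-2 significant connections: 8
GM mean-FCS classifier: no predictor entered
WM mean-FCS classifier: no predictor entered
```

The screen found 8 of the ~32,000 connections significant at 1e-3 — about
the chance rate, because with 15 subjects per group the z-score-product
t-test has little power for a coupling difference of 0.95 (the product's
variance comes from the latent covariance itself; see `docs/methods.md`).
At the default screen of 5e-6 the same cohort yields an empty ROI and the
run reports that stage 2 and classification were skipped. This is the
expected desk-scale behavior, not a bug: the published analyses of this
kind operate on ~28,000 × 648 connection matrices from real cohorts.

The library surface lets you target the ground-truth block directly:

```python
import numpy as np
import gwfcc
from gwfcc import fcc, classify as cls
from gwfcc.pipeline import preprocess_cohort

cfg = gwfcc.PipelineConfig(seed=0)
subjects, truth = gwfcc.generate_cohort(gwfcc.SynthConfig(seed=0))
pre = preprocess_cohort(subjects, cfg)
z_gm = fcc.zscore_across_subjects(pre.gm_alff, pre.gm_mask.linear_indices())
z_wm = fcc.zscore_across_subjects(pre.wm_alff, pre.wm_mask.linear_indices())
tensor = fcc.compute_fcs(z_gm, z_wm)
# restrict to the planted GM/WM voxels and classify on mean FCS
gm_true = sorted({c.gm_index for c in truth.planted_connections})
wm_true = sorted({c.wm_index for c in truth.planted_connections})
pos = lambda idx, vox: np.array([list(idx).index(v) for v in vox])
roi = fcc.restrict_fcs(tensor, pos(tensor.gm_voxel_indices, gm_true),
                       pos(tensor.wm_voxel_indices, wm_true))
labels = (pre.groups == "PDH").astype(int)
table = cls.mean_fcs_features(roi, labels, axis="per_gm_voxel")
model = cls.fit_logistic(table, columns=[table.feature_names[0]])
roc = cls.roc_and_auc(model.predict_proba(table), labels)
print(table.values[labels == 0, 0].mean(),  # 0.805  mean FCS in HC
      table.values[labels == 1, 0].mean(),  # 0.005  mean FCS in PDH
      roc.auc)                              # 0.76
```

The planted GM voxel's mean FCS is ≈0.8 in controls (coupling 0.95) and
≈0.0 in patients (coupling 0.0) — the across-subject correlation the
generator planted — and the single-voxel classifier reaches AUC 0.76 on
this seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline run from scratch: it simulates the
default cohort from the given seed, executes preprocessing, ALFF, FCS, the
two-stage tests and (where an ROI exists) classification, and writes the
acceptance JSON to `--out`.

## Layout

- `src/gwfcc/synth.py` — synthetic cohort generator and cohort I/O
- `src/gwfcc/preprocess.py` — masks, nuisance regression, filtering, smoothing
- `src/gwfcc/alff.py` — ALFF maps and whole-brain normalization
- `src/gwfcc/fcc.py` — z-scores, FCS tensor, two-stage tests, BH-FDR
- `src/gwfcc/classify.py` — mean-FCS features, stepwise logistic, ROC/AUC
- `src/gwfcc/pipeline.py`, `cli.py`, `config.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, parameters, limitations
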