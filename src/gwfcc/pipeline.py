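"""End-to-end orchestration: simulate/read -> preprocess -> ALFF -> FCS ->
two-stage tests -> classification, with reproducible on-disk outputs.

The stage order is fixed: drop initial volumes, individual and group tissue
masks with boundary exclusion, tissue signal extraction, nuisance regression
(detrending included), tissue-specific band-pass filtering, masked smoothing,
ALFF with whole-brain normalization, z-score-product FCS, stage-1 screen,
ROI-restricted stage-2 FDR test, and mean-FCS logistic/ROC classification.
All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from . import __version__
from .config import PipelineConfig
from .synth import (
    GroundTruth,
    SubjectRecord,
    SynthConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from . import preprocess as pp
from .alff import compute_alff, normalize_alff
from . import fcc
from . import classify as cls

log = logging.getLogger(__name__)


@dataclass
class PreprocessedCohort:
    """Per-tissue normalized ALFF tables (subjects x voxels) plus bookkeeping."""

    gm_alff: np.ndarray
    wm_alff: np.ndarray
    gm_mask: pp.TissueMask
    wm_mask: pp.TissueMask
    subject_ids: list[str]
    groups: np.ndarray
    affine: np.ndarray
    grid_dims: tuple[int, int, int]


@dataclass
class AnalysisResult:
    """Statistical outputs of the FCS analysis on one cohort."""

    fcs: fcc.FcsTensor
    stage1: fcc.ConnectionTestResult
    roi_gm_positions: np.ndarray
    roi_wm_positions: np.ndarray
    fcs_roi: fcc.FcsTensor | None
    stage2: fcc.ConnectionTestResult | None
    features: dict[str, cls.FeatureTable]
    models: dict[str, cls.LogisticModel]
    rocs: dict[str, cls.RocCurve]


def preprocess_cohort(
    subjects: list[SubjectRecord], config: PipelineConfig
) -> PreprocessedCohort:
    """Run every subject through preprocessing and ALFF on the group masks."""
    tr_s = float(config.synth.get("tr_s", SynthConfig.tr_s))
    dropped = [pp.drop_initial_volumes(rec, config.n_drop) for rec in subjects]
    individual = [pp.build_individual_masks(rec) for rec in dropped]
    gm_group = pp.build_group_mask([m[0] for m in individual], "GM",
                                   threshold=config.mask_threshold)
    wm_group = pp.build_group_mask([m[1] for m in individual], "WM",
                                   threshold=config.mask_threshold)
    gm_mask, wm_mask = pp.exclude_boundary_and_mixed(gm_group, wm_group)

    voxel_size = float(abs(subjects[0].affine[0, 0]))
    gm_rows, wm_rows = [], []
    for rec, masks in zip(dropped, individual):
        csf_sig = pp.extract_tissue_signals(rec, masks[2], tr_s=tr_s)
        csf_mean = csf_sig.timeseries.mean(axis=1)
        design = pp.build_nuisance_design(rec.motion, csf_mean)
        maps = {}
        for mask, band in ((gm_mask, config.gm_band), (wm_mask, config.wm_band)):
            sig = pp.extract_tissue_signals(rec, mask, tr_s=tr_s)
            sig = pp.regress_nuisance(sig, design)
            sig = pp.bandpass_filter(sig, *band)
            vol = pp.signals_to_volume(sig)
            vol = pp.smooth_volumes(vol, config.fwhm_mm, mask, voxel_size)
            sig = pp.volume_to_signals(vol, sig)
            maps[mask.tissue] = compute_alff(sig, subject_id=rec.subject_id)
        gm_map, wm_map = normalize_alff(maps["GM"], maps["WM"], gm_mask, wm_mask)
        gm_rows.append(gm_map.values[gm_mask.data])
        wm_rows.append(wm_map.values[wm_mask.data])

    return PreprocessedCohort(
        gm_alff=np.array(gm_rows),
        wm_alff=np.array(wm_rows),
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        subject_ids=[r.subject_id for r in subjects],
        groups=np.array([r.group for r in subjects]),
        affine=subjects[0].affine.copy(),
        grid_dims=subjects[0].bold.shape[:3],
    )


def analyze_cohort(pre: PreprocessedCohort, config: PipelineConfig) -> AnalysisResult:
    """FCS tensor, two-stage tests and mean-FCS classification."""
    z_gm = fcc.zscore_across_subjects(
        pre.gm_alff, pre.gm_mask.linear_indices(), pooling=config.pooling,
        groups=pre.groups,
    )
    z_wm = fcc.zscore_across_subjects(
        pre.wm_alff, pre.wm_mask.linear_indices(), pooling=config.pooling,
        groups=pre.groups,
    )
    tensor = fcc.compute_fcs(z_gm, z_wm)
    stage1 = fcc.ttest_connections(
        tensor, pre.groups, alpha_screen=config.alpha_screen,
        variant=config.t_variant,
    )
    gm_pos, wm_pos = fcc.extract_roi(stage1)

    fcs_roi = stage2 = None
    features: dict[str, cls.FeatureTable] = {}
    models: dict[str, cls.LogisticModel] = {}
    rocs: dict[str, cls.RocCurve] = {}
    if gm_pos.size and wm_pos.size:
        fcs_roi = fcc.restrict_fcs(tensor, gm_pos, wm_pos)
        stage2 = fcc.stage2_test(
            fcs_roi, pre.groups, q_level=config.fdr_q, variant=config.t_variant
        )
        labels = (pre.groups == "PDH").astype(int)
        for axis in ("per_gm_voxel", "per_wm_voxel"):
            table = cls.mean_fcs_features(fcs_roi, labels, axis=axis)
            model = cls.forward_stepwise(
                table, entry_alpha=config.entry_alpha,
                removal_alpha=config.removal_alpha,
            )
            features[axis] = table
            models[axis] = model
            if model.included_features:
                rocs[axis] = cls.roc_and_auc(model.predict_proba(table), labels)
    else:
        log.info("no stage-1 significant connection; downstream stages skipped")

    return AnalysisResult(
        fcs=tensor, stage1=stage1, roi_gm_positions=gm_pos,
        roi_wm_positions=wm_pos, fcs_roi=fcs_roi, stage2=stage2,
        features=features, models=models, rocs=rocs,
    )


# ---------------------------------------------------------------------------
# on-disk run


def _voxel_index_table(indices: np.ndarray, grid_dims, affine: np.ndarray,
                       tissue: str) -> pd.DataFrame:
    coords = np.column_stack(np.unravel_index(indices, grid_dims))
    mm = nib.affines.apply_affine(affine, coords)
    return pd.DataFrame({
        "tissue": tissue,
        "linear_index": indices,
        "i": coords[:, 0], "j": coords[:, 1], "k": coords[:, 2],
        "x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2],
    })


def _result_frame(res: fcc.ConnectionTestResult) -> pd.DataFrame:
    gm_idx, wm_idx = np.meshgrid(
        res.gm_voxel_indices, res.wm_voxel_indices, indexing="ij"
    )
    frame = pd.DataFrame({
        "gm_index": gm_idx.ravel(),
        "wm_index": wm_idx.ravel(),
        "t": res.t.ravel(),
        "p": res.p.ravel(),
        "q": res.q.ravel() if res.q is not None else np.nan,
        "significant": res.significant.ravel().astype(int),
        "stage": res.stage,
    })
    return frame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    manifest: str | Path | None = None,
) -> Path:
    """Execute the full pipeline; returns the results directory.

    If ``manifest`` is None a synthetic cohort is generated from the config
    seed and written under ``out_dir/cohort``; otherwise subjects are read
    from the manifest.  Every output file is declared (with its SHA-256) in
    ``run_record.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    log.info("run-all parameters: %s", json.dumps(config.to_dict(), sort_keys=True))

    truth: GroundTruth | None = None
    if manifest is None:
        synth_cfg = SynthConfig(seed=config.seed, **config.synth)
        subjects, truth = generate_cohort(synth_cfg)
        write_cohort(subjects, truth, out_dir / "cohort")
    else:
        subjects = read_cohort(manifest)

    pre = preprocess_cohort(subjects, config)
    result = analyze_cohort(pre, config)

    float_fmt = "%.10g"
    written: list[Path] = []

    def _write_tsv(frame: pd.DataFrame, name: str):
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format=float_fmt)
        written.append(path)

    # ALFF tables and voxel index map
    gm_idx = pre.gm_mask.linear_indices()
    wm_idx = pre.wm_mask.linear_indices()
    _write_tsv(
        pd.DataFrame(pre.gm_alff, index=pd.Index(pre.subject_ids, name="subject_id"),
                     columns=gm_idx).reset_index(),
        "alff_gm.tsv",
    )
    _write_tsv(
        pd.DataFrame(pre.wm_alff, index=pd.Index(pre.subject_ids, name="subject_id"),
                     columns=wm_idx).reset_index(),
        "alff_wm.tsv",
    )
    _write_tsv(
        pd.concat([
            _voxel_index_table(gm_idx, pre.grid_dims, pre.affine, "GM"),
            _voxel_index_table(wm_idx, pre.grid_dims, pre.affine, "WM"),
        ]),
        "voxel_index.tsv",
    )

    _write_tsv(_result_frame(result.stage1), "stage1_connections.tsv")

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": len(pre.subject_ids),
        "n_gm_voxels": int(gm_idx.size),
        "n_wm_voxels": int(wm_idx.size),
        "stage1_significant": int(result.stage1.significant.sum()),
        "roi_gm_voxels": int(result.roi_gm_positions.size),
        "roi_wm_voxels": int(result.roi_wm_positions.size),
    }

    if result.stage2 is not None:
        _write_tsv(_result_frame(result.stage2), "stage2_connections.tsv")
        summary["stage2_significant"] = int(result.stage2.significant.sum())
        # per-subject FCS matrices over the ROI
        for s, sid in enumerate(pre.subject_ids):
            frame = pd.DataFrame(
                result.fcs_roi.values[s],
                index=pd.Index(result.fcs_roi.gm_voxel_indices, name="gm_index"),
                columns=result.fcs_roi.wm_voxel_indices,
            ).reset_index()
            _write_tsv(frame, f"fcs_roi_{sid}.tsv")
        for axis in ("per_gm_voxel", "per_wm_voxel"):
            table = result.features[axis]
            model = result.models[axis]
            frame = pd.DataFrame(table.values, columns=table.feature_names)
            frame.insert(0, "subject_id", pre.subject_ids)
            frame.insert(1, "label", table.labels)
            _write_tsv(frame, f"features_{axis}.tsv")
            key = "gm" if axis == "per_gm_voxel" else "wm"
            if model.included_features:
                roc = result.rocs[axis]
                _write_tsv(
                    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                                  "tpr": roc.tpr}),
                    f"roc_{key}.tsv",
                )
                probs = model.predict_proba(table)
                _write_tsv(
                    pd.DataFrame({"subject_id": pre.subject_ids,
                                  "label": table.labels, "probability": probs}),
                    f"probabilities_{key}.tsv",
                )
                summary[key] = {
                    "auc": roc.auc,
                    "n_pos": int(table.labels.sum()),
                    "n_neg": int((1 - table.labels).sum()),
                    "included_features": model.included_features,
                    "separation_flag": model.separation_flag,
                }
            else:
                summary[key] = "no predictor entered"
    else:
        summary["stage2_significant"] = 0
        summary["note"] = "no stage-1 significant connection; stage 2 and classification skipped"

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)

    cohort_files = sorted((out_dir / "cohort").glob("*")) if manifest is None else []
    record = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "manifest": str(manifest) if manifest is not None else "cohort/manifest.tsv",
        "stage_hashes": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(written) + cohort_files
        },
        "started": t_start,
        "finished": time.time(),
    }
    (out_dir / "run_record.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n"
    )
    return out_dir


def report(results_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    results_dir = Path(results_dir)
    summary_path = results_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {results_dir}")
    s = json.loads(summary_path.read_text())
    lines = [
        f"gwfcc {s.get('version', '?')} run (seed {s.get('seed')})",
        f"subjects: {s.get('n_subjects')}; GM voxels: {s.get('n_gm_voxels')}; "
        f"WM voxels: {s.get('n_wm_voxels')}",
        f"stage-1 significant connections: {s.get('stage1_significant')}",
        f"ROI: {s.get('roi_gm_voxels')} GM x {s.get('roi_wm_voxels')} WM voxels",
        f"stage-2 significant connections: {s.get('stage2_significant')}",
    ]
    for key, label in (("gm", "GM mean-FCS classifier"), ("wm", "WM mean-FCS classifier")):
        if key in s:
            v = s[key]
            if isinstance(v, dict):
                lines.append(
                    f"{label}: AUC {v['auc']:.3f} "
                    f"({len(v['included_features'])} feature(s) entered)"
                )
                if v.get("separation_flag"):
                    lines.append(f"  warning: separation detected in the {key} model")
            else:
                lines.append(f"{label}: {v}")
    if "note" in s:
        lines.append(f"note: {s['note']}")
    return "\n".join(lines)
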