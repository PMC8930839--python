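"""Functional covariance connection strength (FCS) and two-stage group testing.

Functional covariance connectivity (FCC) is the Pearson correlation of two
voxels' ALFF values computed ACROSS subjects,

    r = 1/(N-1) * sum_i Z_Xi * Z_Yi,

where Z are across-subject standard scores (sample sd, denominator N-1).
The per-subject product Z_Xi * Z_Yi is that subject's contribution to the
correlation — the functional covariance connection strength (FCS).  Group
differences in FCS are tested per connection with a two-sample t-test: a
voxelwise screen at an uncorrected threshold (default P < 5e-6) defines the
regions of interest, and connections restricted to the ROI are re-tested with
Benjamini-Hochberg FDR control (default q < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, ConfigError, InsufficientDataError

log = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    """Across-subject standard scores of an ALFF table (subjects x voxels)."""

    values: np.ndarray
    voxel_indices: np.ndarray
    pooling: str                       # "pooled" | "within_group"
    dropped_voxels: np.ndarray         # zero-variance voxels removed upstream

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class FcsTensor:
    """Per-subject z-score products: subjects x GM voxels x WM voxels.

    Summing over the pooled subjects recovers (N-1) times the Pearson
    correlation of the two ALFF columns — the module's core identity.
    """

    values: np.ndarray
    gm_voxel_indices: np.ndarray
    wm_voxel_indices: np.ndarray
    pooling: str

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ConnectionTestResult:
    """Per-connection t, p, (stage-2) BH-q and significance flags."""

    t: np.ndarray                     # (n_gm, n_wm)
    p: np.ndarray
    q: np.ndarray | None              # stage-2 only
    significant: np.ndarray           # boolean
    stage: str                        # "screen" | "roi"
    df: int
    gm_voxel_indices: np.ndarray
    wm_voxel_indices: np.ndarray
    degenerate: np.ndarray            # both groups zero-variance -> p forced to 1


def zscore_across_subjects(
    alff_table: np.ndarray,
    voxel_indices: np.ndarray | None = None,
    pooling: str = "pooled",
    groups: np.ndarray | None = None,
) -> ZScoreMatrix:
    """Column-wise standardization over subjects with sample sd (ddof=1).

    ``pooling="pooled"`` standardizes over all subjects together (the default:
    the between-group test on FCS needs both groups on a common scale);
    ``"within_group"`` standardizes each group separately and requires
    ``groups``.  Zero-variance voxels are dropped with a logged warning.
    """
    table = np.asarray(alff_table, dtype=float)
    if voxel_indices is None:
        voxel_indices = np.arange(table.shape[1])
    voxel_indices = np.asarray(voxel_indices)
    if pooling not in ("pooled", "within_group"):
        raise ConfigError(f"unknown pooling {pooling!r}")

    if pooling == "pooled":
        if table.shape[0] < 3:
            raise InsufficientDataError("need >= 3 subjects to standardize")
        sd = table.std(axis=0, ddof=1)
        keep = sd > 0
        z = (table[:, keep] - table[:, keep].mean(axis=0)) / sd[keep]
    else:
        if groups is None:
            raise ConfigError("within_group pooling requires group labels")
        groups = np.asarray(groups)
        z_full = np.empty_like(table)
        keep = np.ones(table.shape[1], dtype=bool)
        for g in np.unique(groups):
            rows = groups == g
            if rows.sum() < 3:
                raise InsufficientDataError(f"group {g!r} has < 3 subjects")
            sub = table[rows]
            sd = sub.std(axis=0, ddof=1)
            keep &= sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                z_full[rows] = (sub - sub.mean(axis=0)) / sd
        z = z_full[:, keep]

    dropped = voxel_indices[~keep]
    if dropped.size:
        msg = f"dropped {dropped.size} zero-variance voxel(s): {dropped.tolist()}"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return ZScoreMatrix(
        values=z,
        voxel_indices=voxel_indices[keep],
        pooling=pooling,
        dropped_voxels=dropped,
    )


def compute_fcs(z_gm: ZScoreMatrix, z_wm: ZScoreMatrix) -> FcsTensor:
    """FCS tensor: values[s, g, w] = Z_gm[s, g] * Z_wm[s, w]."""
    if z_gm.n_subjects != z_wm.n_subjects:
        raise AlignmentError("GM and WM z-score matrices have different subjects")
    if z_gm.pooling != z_wm.pooling:
        raise AlignmentError("GM and WM z-scores use different pooling")
    values = np.einsum("sg,sw->sgw", z_gm.values, z_wm.values)
    return FcsTensor(
        values=values,
        gm_voxel_indices=z_gm.voxel_indices.copy(),
        wm_voxel_indices=z_wm.voxel_indices.copy(),
        pooling=z_gm.pooling,
    )


def _pooled_ttest(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized two-sample t over axis 0; returns (t, p, degenerate, df).

    ``student`` pools variances (the default for equal group sizes); ``welch``
    is available for sensitivity analysis.  Connections where both groups have
    zero variance get t=0, p=1 and a degenerate flag.
    """
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    if variant == "student":
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        df_arr = df
    elif variant == "welch":
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(invalid="ignore", divide="ignore"):
            df_arr = se2 ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = int(np.nanmax(df_arr)) if np.ndim(df_arr) else df_arr
    else:
        raise ConfigError(f"unknown t-test variant {variant!r}")
    degenerate = se == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, 0.0, (m1 - m2) / np.where(degenerate, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df_arr)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate, n1 + n2 - 2


def ttest_connections(
    fcs: FcsTensor,
    groups: np.ndarray,
    alpha_screen: float = 5e-6,
    variant: str = "student",
) -> ConnectionTestResult:
    """Stage-1 voxelwise screen: per-connection two-sided t at ``alpha_screen``.

    The threshold is an uncorrected per-connection level (default 5e-6);
    connections passing it define the regions of interest.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ConfigError(f"need exactly two groups, got {labels.tolist()}")
    in_first = groups == labels[0]
    if in_first.sum() < 2 or (~in_first).sum() < 2:
        raise InsufficientDataError("each group needs >= 2 subjects")
    t, p, degenerate, df = _pooled_ttest(
        fcs.values[in_first], fcs.values[~in_first], variant
    )
    return ConnectionTestResult(
        t=t, p=p, q=None, significant=p < alpha_screen, stage="screen", df=df,
        gm_voxel_indices=fcs.gm_voxel_indices, wm_voxel_indices=fcs.wm_voxel_indices,
        degenerate=degenerate,
    )


def extract_roi(result: ConnectionTestResult) -> tuple[np.ndarray, np.ndarray]:
    """Positional ROI axes: GM/WM positions appearing in >= 1 significant cell.

    Returns positions into the tensor axes (sorted).  An empty pair signals
    "no significant connection"; downstream stages refuse to run on it.
    """
    sig = result.significant
    return np.flatnonzero(sig.any(axis=1)), np.flatnonzero(sig.any(axis=0))


def restrict_fcs(
    fcs: FcsTensor, gm_positions: np.ndarray, wm_positions: np.ndarray
) -> FcsTensor:
    """Restrict the tensor to ROI axes (positions into the current axes)."""
    return FcsTensor(
        values=fcs.values[:, gm_positions][:, :, wm_positions],
        gm_voxel_indices=fcs.gm_voxel_indices[gm_positions],
        wm_voxel_indices=fcs.wm_voxel_indices[wm_positions],
        pooling=fcs.pooling,
    )


def bh_fdr(pvalues: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a flat p-value list.

    Returns (adjusted values, reject flags); adjusted values are the usual
    monotone min-over-tail quantities capped at 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return adjusted, reject


def stage2_test(
    fcs_roi: FcsTensor,
    groups: np.ndarray,
    q_level: float = 0.05,
    variant: str = "student",
) -> ConnectionTestResult:
    """Stage-2 ROI test: per-connection t, then BH-FDR over all ROI connections."""
    if fcs_roi.values.shape[1] == 0 or fcs_roi.values.shape[2] == 0:
        raise InsufficientDataError("empty ROI; stage-2 refuses to run")
    screen = ttest_connections(fcs_roi, groups, alpha_screen=np.inf, variant=variant)
    # extreme t can underflow the two-sided p to exactly 0; clip for the step-up
    q, reject = bh_fdr(np.clip(screen.p.ravel(), 1e-300, 1.0), q_level=q_level)
    shape = screen.p.shape
    return ConnectionTestResult(
        t=screen.t, p=screen.p, q=q.reshape(shape),
        significant=reject.reshape(shape), stage="roi", df=screen.df,
        gm_voxel_indices=fcs_roi.gm_voxel_indices,
        wm_voxel_indices=fcs_roi.wm_voxel_indices,
        degenerate=screen.degenerate,
    )
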