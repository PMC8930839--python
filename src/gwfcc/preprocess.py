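"""Preprocessing of synthetic resting-state runs.

Implements the in-scope steps of a standard resting-state pipeline on a
common grid: initial-volume removal, individual (max-probability) and group
(>60% occupancy) tissue masks with gray/white boundary exclusion, tissue
signal extraction, nuisance regression (intercept + linear trend + CSF mean +
Friston-24 motion expansion), ideal rectangular band-pass filtering with
tissue-specific bands, and masked Gaussian smoothing.

The fixed stage order is: drop -> masks -> extract -> regress (detrending via
the trend column) -> filter -> smooth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, EmptyMaskError, ShapeError
from .synth import SubjectRecord

#: FWHM of a Gaussian with unit sd: sqrt(8 ln 2)
FWHM_PER_SIGMA = 2.3548200450309493

#: truncation radius of the discrete Gaussian kernel, in units of sigma
GAUSSIAN_TRUNCATE = 4.0

TISSUES = ("GM", "WM", "CSF")


@dataclass
class TissueMask:
    """Binary tissue mask, either per subject or group-level."""

    data: np.ndarray              # boolean 3D array
    tissue: str                   # "GM" | "WM" | "CSF"
    source: str                   # "individual" | "group"
    occupancy: np.ndarray | None = None  # group masks: fraction of subjects per voxel

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.tissue not in TISSUES:
            raise ConfigError(f"tissue must be one of {TISSUES}")
        if self.source not in ("individual", "group"):
            raise ConfigError("source must be 'individual' or 'group'")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def linear_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data.ravel())


@dataclass
class TissueSignalSet:
    """Time series of the voxels of one tissue mask, in linear-index order."""

    voxel_indices: np.ndarray     # strictly increasing linear indices
    timeseries: np.ndarray        # (t, n_voxels)
    tissue: str
    tr_s: float
    grid_dims: tuple[int, int, int]
    band_hz: tuple[float, float] | None = None   # set once band-pass filtered

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if np.any(np.diff(self.voxel_indices) <= 0):
            raise ShapeError("voxel_indices must be strictly increasing")
        if self.voxel_indices.size and self.voxel_indices[-1] >= np.prod(self.grid_dims):
            raise ShapeError("voxel index outside grid")
        if self.timeseries.shape[1] != self.voxel_indices.size:
            raise ShapeError("timeseries column count != voxel count")

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]


@dataclass
class NuisanceDesign:
    """t x k design matrix: intercept, linear trend, CSF mean, Friston-24."""

    columns: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        if self.columns.shape[1] != len(self.column_names):
            raise ShapeError("column count != name count")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("design contains non-finite entries")


def drop_initial_volumes(record: SubjectRecord, n_drop: int) -> SubjectRecord:
    """Remove the first ``n_drop`` timepoints from BOLD and motion."""
    if not 0 <= n_drop < record.n_timepoints:
        raise ValueError(
            f"n_drop must be in [0, {record.n_timepoints}), got {n_drop}"
        )
    if n_drop == 0:
        return record
    return dataclasses.replace(
        record,
        bold=record.bold[..., n_drop:],
        motion=record.motion[n_drop:],
    )


def build_individual_masks(
    record: SubjectRecord, background_threshold: float = 0.1
) -> tuple[TissueMask, TissueMask, TissueMask]:
    """Assign each voxel to the maximum-probability tissue.

    Ties break by the fixed precedence GM > WM > CSF; voxels where all three
    probabilities fall below ``background_threshold`` belong to no tissue.
    """
    missing = [t for t in TISSUES if t not in record.tissue_probs]
    if missing:
        raise ValueError(f"missing tissue probability maps: {missing}")
    stack = np.stack([record.tissue_probs[t] for t in TISSUES])  # argmax -> precedence
    winner = np.argmax(stack, axis=0)
    background = np.all(stack < background_threshold, axis=0)
    masks = []
    for code, tissue in enumerate(TISSUES):
        masks.append(
            TissueMask(data=(winner == code) & ~background, tissue=tissue,
                       source="individual")
        )
    return tuple(masks)


def build_group_mask(
    masks: list[TissueMask], tissue: str, threshold: float = 0.6
) -> TissueMask:
    """Voxels present in strictly more than ``threshold`` of individual masks."""
    if not masks:
        raise ValueError("no masks given")
    shapes = {m.data.shape for m in masks}
    if len(shapes) > 1:
        raise ShapeError(f"mixed mask grids: {shapes}")
    for m in masks:
        if m.tissue != tissue or m.source != "individual":
            raise ConfigError("all masks must be individual masks of the requested tissue")
    occupancy = np.mean([m.data for m in masks], axis=0)
    return TissueMask(
        data=occupancy > threshold, tissue=tissue, source="group", occupancy=occupancy
    )


def exclude_boundary_and_mixed(
    gm: TissueMask, wm: TissueMask
) -> tuple[TissueMask, TissueMask]:
    """Remove GM/WM overlap and the 6-adjacent contact layer from both masks.

    Mixed voxels (in both group masks) are removed first; then any GM voxel
    6-adjacent to a remaining WM voxel is dropped and vice versa (computed
    simultaneously, so the result is symmetric).  The returned masks are
    disjoint and non-adjacent.
    """
    if gm.source != "group" or wm.source != "group":
        raise ConfigError("boundary exclusion applies to group masks")
    if gm.data.shape != wm.data.shape:
        raise ShapeError("masks on different grids")
    mixed = gm.data & wm.data
    gm1 = gm.data & ~mixed
    wm1 = wm.data & ~mixed
    six = ndimage.generate_binary_structure(3, 1)
    gm2 = gm1 & ~ndimage.binary_dilation(wm1, structure=six)
    wm2 = wm1 & ~ndimage.binary_dilation(gm1, structure=six)
    return (
        TissueMask(data=gm2, tissue="GM", source="group", occupancy=gm.occupancy),
        TissueMask(data=wm2, tissue="WM", source="group", occupancy=wm.occupancy),
    )


def extract_tissue_signals(
    record: SubjectRecord, mask: TissueMask, tr_s: float = 2.5
) -> TissueSignalSet:
    """Pull out the masked voxels' time series, columns in linear-index order.

    ``tr_s`` is recorded on the output (the sampling interval is not encoded
    in the NIfTI affine).
    """
    if mask.data.shape != record.bold.shape[:3]:
        raise ShapeError("mask grid does not match BOLD grid")
    idx = mask.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError(f"empty {mask.tissue} mask")
    flat = record.bold.reshape(-1, record.n_timepoints)
    return TissueSignalSet(
        voxel_indices=idx,
        timeseries=flat[idx].T.copy(),
        tissue=mask.tissue,
        tr_s=tr_s,
        grid_dims=record.bold.shape[:3],
    )


def expand_friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion: [R(t), R(t-1), R(t)^2, R(t-1)^2], 6 columns each.

    The lagged blocks are zero on their first row.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ShapeError(f"motion must be (t, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ShapeError("need at least 2 timepoints")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion ** 2, lagged ** 2])


def build_nuisance_design(motion: np.ndarray, csf_mean: np.ndarray) -> NuisanceDesign:
    """Assemble intercept + linear trend + CSF mean + Friston-24 (27 columns)."""
    n_t = motion.shape[0]
    if csf_mean.shape != (n_t,):
        raise ShapeError("csf_mean length must match motion rows")
    friston = expand_friston24(motion)
    trend = np.linspace(-1.0, 1.0, n_t)
    columns = np.column_stack([np.ones(n_t), trend, csf_mean, friston])
    names = (
        ["intercept", "linear_trend", "csf_mean"]
        + [f"friston24_{i + 1}" for i in range(24)]
    )
    return NuisanceDesign(columns=columns, column_names=names)


def regress_nuisance(signals: TissueSignalSet, design: NuisanceDesign) -> TissueSignalSet:
    """Least-squares residuals of each voxel series on the nuisance design.

    All-zero design columns (e.g. Friston terms of a motionless run) are
    pruned first; if the pruned design is still rank deficient the offending
    columns are named in the error.
    """
    X = design.columns
    if X.shape[0] != signals.n_timepoints:
        raise ShapeError("design rows != signal timepoints")
    nonzero = np.ptp(X, axis=0) > 0
    nonzero |= np.array([n == "intercept" for n in design.column_names])
    kept = [n for n, keep in zip(design.column_names, nonzero) if keep]
    Xp = X[:, nonzero]
    rank = np.linalg.matrix_rank(Xp)
    if rank < Xp.shape[1]:
        offenders = _dependent_columns(Xp, kept)
        raise np.linalg.LinAlgError(
            f"nuisance design rank deficient; dependent columns: {offenders}"
        )
    beta, *_ = np.linalg.lstsq(Xp, signals.timeseries, rcond=None)
    residuals = signals.timeseries - Xp @ beta
    return dataclasses.replace(signals, timeseries=residuals)


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan naming columns that add no rank."""
    offenders, basis = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
        else:
            offenders.append(name)
    return offenders


def band_mask(n_t: int, tr_s: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Boolean keep-mask over the rFFT bins: f in [f_lo, f_hi], DC excluded."""
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    return (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)


def bandpass_filter(
    signals: TissueSignalSet, f_lo: float, f_hi: float
) -> TissueSignalSet:
    """Ideal rectangular band-pass: zero all Fourier bins outside [f_lo, f_hi].

    Band edges are inclusive; the DC bin is always zeroed.  The band is
    recorded on the returned signal set.
    """
    nyquist = 1.0 / (2.0 * signals.tr_s)
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"f_hi {f_hi} exceeds Nyquist {nyquist}")
    spec = np.fft.rfft(signals.timeseries, axis=0)
    keep = band_mask(signals.n_timepoints, signals.tr_s, f_lo, f_hi)
    spec[~keep] = 0.0
    filtered = np.fft.irfft(spec, n=signals.n_timepoints, axis=0)
    return dataclasses.replace(signals, timeseries=filtered, band_hz=(f_lo, f_hi))


def smooth_volumes(
    data: np.ndarray,
    fwhm_mm: float,
    mask: TissueMask,
    voxel_size_mm: float,
) -> np.ndarray:
    """Masked isotropic Gaussian smoothing with FWHM ``fwhm_mm``.

    The kernel is renormalized within the mask (smooth(data*mask)/smooth(mask))
    so values outside the mask never leak in and constants are preserved.
    Accepts a 3D map or a 4D series (smoothed per volume); fwhm 0 is identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    m = mask.data
    if data.shape[:3] != m.shape:
        raise ShapeError("data grid does not match mask grid")
    out = np.where(m if data.ndim == 3 else m[..., None], data, 0.0)
    if fwhm_mm == 0:
        return out
    sigma_vox = fwhm_mm / (voxel_size_mm * FWHM_PER_SIGMA)
    sigma = (sigma_vox,) * 3 + ((0.0,) if data.ndim == 4 else ())
    num = ndimage.gaussian_filter(out, sigma=sigma, mode="constant",
                                  truncate=GAUSSIAN_TRUNCATE)
    den = ndimage.gaussian_filter(m.astype(float), sigma=sigma_vox,
                                  mode="constant", truncate=GAUSSIAN_TRUNCATE)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / (den if data.ndim == 3 else den[..., None])
    return np.where(m if data.ndim == 3 else m[..., None], smoothed, 0.0)


def signals_to_volume(signals: TissueSignalSet) -> np.ndarray:
    """Place a signal set back on its grid as a (x, y, z, t) array, zeros elsewhere."""
    vol = np.zeros((int(np.prod(signals.grid_dims)), signals.n_timepoints))
    vol[signals.voxel_indices] = signals.timeseries.T
    return vol.reshape(*signals.grid_dims, signals.n_timepoints)


def volume_to_signals(
    volume: np.ndarray, template: TissueSignalSet
) -> TissueSignalSet:
    """Inverse of :func:`signals_to_volume` for the template's voxel set."""
    flat = volume.reshape(-1, volume.shape[3])
    return dataclasses.replace(
        template, timeseries=flat[template.voxel_indices].T.copy()
    )
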