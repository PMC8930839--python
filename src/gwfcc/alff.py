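"""Amplitude of low-frequency fluctuation (ALFF) maps.

ALFF summarizes each voxel's spontaneous BOLD activity as the mean spectral
amplitude within a low-frequency band: the single-sided discrete Fourier
transform of the (already band-pass filtered) series is taken, the square
root of the power spectrum is summed over the in-band positive-frequency
bins, and the sum is divided by the number of timepoints.  Per-subject maps
are then normalized by the whole-brain (GM u WM group mask) mean so that
global amplitude scale cancels across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, ShapeError, StateError
from .preprocess import TissueMask, TissueSignalSet, band_mask


@dataclass
class AlffMap:
    """Per-subject, per-tissue 3D ALFF image; zero outside its tissue mask."""

    values: np.ndarray
    tissue: str
    band_hz: tuple[float, float]
    normalized: bool
    subject_id: str

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ShapeError("ALFF values must be a 3D array")
        if np.any(self.values < 0):
            raise ValueError("ALFF values must be non-negative")


def compute_alff(signals: TissueSignalSet, subject_id: str = "") -> AlffMap:
    """Unnormalized ALFF of each voxel of an already-filtered signal set.

    Per voxel: ALFF = (sum over positive-frequency bins f in the recorded
    band of |F(f)|) / T, with F the length-T DFT.  Only the single-sided
    spectrum is summed; any constant scale convention cancels after
    whole-brain normalization.
    """
    if signals.band_hz is None:
        raise StateError("signals must be band-pass filtered before ALFF")
    t = signals.n_timepoints
    spec = np.abs(np.fft.rfft(signals.timeseries, axis=0))
    keep = band_mask(t, signals.tr_s, *signals.band_hz)
    alff_per_voxel = spec[keep].sum(axis=0) / t
    values = np.zeros(int(np.prod(signals.grid_dims)))
    values[signals.voxel_indices] = alff_per_voxel
    return AlffMap(
        values=values.reshape(signals.grid_dims),
        tissue=signals.tissue,
        band_hz=signals.band_hz,
        normalized=False,
        subject_id=subject_id,
    )


def normalize_alff(
    gm_map: AlffMap,
    wm_map: AlffMap,
    gm_mask: TissueMask,
    wm_mask: TissueMask,
) -> tuple[AlffMap, AlffMap]:
    """Divide both maps by the subject's mean ALFF over GM u WM mask voxels.

    The "whole brain" here is the union of the two group masks — the only
    brain voxels the pipeline retains; the mean of the combined normalized
    values is 1 by construction.
    """
    for m in (gm_map, wm_map):
        if m.normalized:
            raise StateError("maps are already normalized")
    if gm_map.subject_id != wm_map.subject_id:
        raise ValueError("maps belong to different subjects")
    combined = np.concatenate(
        [gm_map.values[gm_mask.data], wm_map.values[wm_mask.data]]
    )
    mean = combined.mean() if combined.size else 0.0
    if mean <= 0:
        raise DegenerateInputError("whole-brain mean ALFF is zero")
    return (
        replace(gm_map, values=gm_map.values / mean, normalized=True),
        replace(wm_map, values=wm_map.values / mean, normalized=True),
    )
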