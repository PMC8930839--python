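"""Seeded synthetic two-group resting-state fMRI cohorts with known gray-white
matter amplitude-covariance structure.

The generator emulates a two-group study (healthy controls ``HC`` and a patient
group ``PDH``) scanned on a common 4 mm grid: each subject gets a 4D BOLD run,
GM/WM/CSF tissue probability maps on a deterministic nested geometry, and a
6-parameter motion trace.  The scientific structure of interest is planted
*across subjects*: a single latent factor ``u_s`` per subject drives the
low-frequency amplitude of selected GM voxels (``a_g = 1 + u_s``) and, with a
group-dependent coupling ``beta``, of selected WM voxels
(``a_w = 1 + beta*u_s + sqrt(1-beta^2)*eps``).  The across-subject Pearson
correlation between the two voxels' band amplitudes is then ``beta`` by
construction, which is exactly the quantity the downstream covariance
connectivity analysis estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

from .errors import ConfigError, ShapeError

log = logging.getLogger(__name__)

GROUPS = ("HC", "PDH")

# tissue label codes in the deterministic geometry
BG, GM, WM, CSF = 0, 1, 2, 3

#: default in-band frequency range of the synthesized signal, Hz
SIGNAL_BAND = (0.01, 0.1)
#: number of sinusoidal components per band-limited waveform
N_COMPONENTS = 8


class PlantedConnection(NamedTuple):
    """A GM-WM voxel pair with group-dependent amplitude coupling."""

    gm_index: int          # linear (C-order) voxel index into the grid
    wm_index: int
    coupling_hc: float     # across-subject amplitude correlation in HC
    coupling_pdh: float    # ... in PDH


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the acquisition the generator emulates: 4 mm isotropic
    voxels, TR 2.5 s, 139 timepoints (of which the first 10 are later
    discarded, leaving an ~8 min run), and 15 subjects per group.
    """

    grid_dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 4.0
    tr_s: float = 2.5
    n_timepoints: int = 139
    n_per_group: int = 15
    planted_connections: tuple[PlantedConnection, ...] | None = None
    latent_sd: float = 0.25
    noise_sd: float = 0.05
    motion_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_dims) != 3 or any(int(d) != d or d <= 0 for d in self.grid_dims):
            raise ConfigError(f"grid_dims must be 3 positive integers, got {self.grid_dims}")
        if min(self.grid_dims) < 12:
            raise ConfigError("grid_dims must be at least 12 per axis for the nested tissue geometry")
        for name in ("voxel_size_mm", "tr_s", "latent_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.motion_sd < 0:
            raise ConfigError("motion_sd must be non-negative")
        if self.n_timepoints < 30:
            raise ConfigError("n_timepoints must be >= 30")
        if self.n_per_group < 4:
            raise ConfigError("n_per_group must be >= 4")
        if self.planted_connections is None:
            object.__setattr__(
                self, "planted_connections", default_planted_block(self.grid_dims)
            )
        else:
            object.__setattr__(
                self,
                "planted_connections",
                tuple(PlantedConnection(*c) for c in self.planted_connections),
            )
        labels = tissue_labels(self.grid_dims)
        flat = labels.ravel()
        seen_wm: dict[int, tuple[float, float]] = {}
        for conn in self.planted_connections:
            if not (0 <= conn.gm_index < flat.size) or flat[conn.gm_index] != GM:
                raise ConfigError(
                    f"planted gm_index {conn.gm_index} is outside the GM label region"
                )
            if not (0 <= conn.wm_index < flat.size) or flat[conn.wm_index] != WM:
                raise ConfigError(
                    f"planted wm_index {conn.wm_index} is outside the WM label region"
                )
            for b in (conn.coupling_hc, conn.coupling_pdh):
                if not -1.0 <= b <= 1.0:
                    raise ConfigError(f"coupling {b} outside [-1, 1]")
            couplings = (conn.coupling_hc, conn.coupling_pdh)
            if seen_wm.setdefault(conn.wm_index, couplings) != couplings:
                raise ConfigError(
                    f"wm_index {conn.wm_index} appears with conflicting couplings"
                )


@dataclass
class SubjectRecord:
    """One subject's raw inputs: BOLD run, tissue probabilities, motion, label."""

    subject_id: str
    group: str
    bold: np.ndarray                      # (x, y, z, t)
    affine: np.ndarray                    # 4x4 voxel -> mm
    tissue_probs: dict[str, np.ndarray]   # {"GM","WM","CSF"} -> 3D in [0, 1]
    motion: np.ndarray                    # (t, 6): 3 translations mm, 3 rotations rad

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.bold.ndim != 4:
            raise ShapeError("bold must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("bold contains non-finite values")
        psum = sum(self.tissue_probs[t] for t in ("GM", "WM", "CSF"))
        if psum.max() > 1 + 1e-6:
            raise ValueError("tissue probabilities sum to > 1 at some voxel")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if self.motion.shape != (self.bold.shape[3], 6):
            raise ShapeError("motion must be (timepoints, 6)")

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[3]


@dataclass
class GroundTruth:
    """What was planted: the connection list and each subject's latent factor."""

    planted_connections: tuple[PlantedConnection, ...]
    subject_ids: list[str]
    u: np.ndarray  # one latent value per subject, in subject_ids order

    def __post_init__(self):
        if len(self.subject_ids) != len(self.u):
            raise ShapeError("one latent value per subject required")


def tissue_labels(grid_dims: Sequence[int]) -> np.ndarray:
    """Deterministic nested tissue geometry: GM shell, WM core box, CSF block.

    Layout per axis of length n: background margin of 1 voxel, a GM shell of
    thickness 2, a WM core filling the rest, and a 2-voxel CSF "ventricle"
    block at the grid centre.  Voxel indices are therefore reproducible across
    runs and configurations with the same grid.
    """
    nx, ny, nz = grid_dims
    labels = np.zeros(grid_dims, dtype=np.int8)
    labels[1:nx - 1, 1:ny - 1, 1:nz - 1] = GM
    labels[3:nx - 3, 3:ny - 3, 3:nz - 3] = WM
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    labels[cx - 1:cx + 1, cy - 1:cy + 1, cz - 1:cz + 1] = CSF
    return labels


def analysis_safe_voxels(grid_dims: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Linear indices of GM/WM voxels that survive boundary exclusion.

    The preprocessing stage removes GM voxels 6-adjacent to WM and vice versa;
    planting effects in the returned voxels guarantees they remain testable.
    """
    labels = tissue_labels(grid_dims)
    gm = labels == GM
    wm = labels == WM
    six = ndimage.generate_binary_structure(3, 1)
    gm_safe = gm & ~ndimage.binary_dilation(wm, structure=six)
    wm_safe = wm & ~ndimage.binary_dilation(gm, structure=six)
    return np.flatnonzero(gm_safe.ravel()), np.flatnonzero(wm_safe.ravel())


def default_planted_block(
    grid_dims: Sequence[int],
    n_gm: int = 3,
    n_wm: int = 8,
    coupling_hc: float = 0.95,
    coupling_pdh: float = 0.0,
) -> tuple[PlantedConnection, ...]:
    """Fully-coupled GM x WM block sharing the per-subject latent factor.

    The default stated world plants a coherent 3 GM x 8 WM block whose
    across-subject amplitude correlation is ``coupling_hc`` in controls and
    ``coupling_pdh`` in patients — a desk-scale analogue of a contiguous
    GM-WM region whose covariance is reduced in the patient group.
    """
    gm_safe, wm_safe = analysis_safe_voxels(grid_dims)
    if len(gm_safe) < n_gm or len(wm_safe) < n_wm:
        raise ConfigError("grid too small for the requested planted block")
    gm_pick = gm_safe[np.linspace(0, len(gm_safe) - 1, n_gm).astype(int)]
    wm_pick = wm_safe[np.linspace(0, len(wm_safe) - 1, n_wm).astype(int)]
    return tuple(
        PlantedConnection(int(g), int(w), coupling_hc, coupling_pdh)
        for g in gm_pick
        for w in wm_pick
    )


def _band_limited(rng: np.random.Generator, n_series: int, t_s: np.ndarray,
                  f_lo: float, f_hi: float) -> np.ndarray:
    """Sum of ``N_COMPONENTS`` random sinusoids per series, ~unit RMS.

    Frequencies are uniform in [f_lo, f_hi] Hz with uniform phases, so all
    signal mass lies in-band without any filtering artifacts.
    """
    freqs = rng.uniform(f_lo, f_hi, size=(n_series, N_COMPONENTS))
    phases = rng.uniform(0, 2 * np.pi, size=(n_series, N_COMPONENTS))
    # each sinusoid has RMS 1/sqrt(2); dividing the sum of 8 by 2 gives RMS ~1
    arg = 2 * np.pi * freqs[:, :, None] * t_s[None, None, :] + phases[:, :, None]
    return np.sin(arg).sum(axis=1) / 2.0


def _default_affine(grid_dims: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_size_mm * (np.asarray(grid_dims) - 1) / 2.0
    return aff


def generate_cohort(config: SynthConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a seeded two-group cohort; deterministic given the config.

    See the module docstring for the amplitude model.  All non-planted brain
    voxels receive independent band-limited signal of unit amplitude; every
    voxel receives white measurement noise of sd ``noise_sd``; CSF voxels share
    one per-subject nuisance waveform; motion traces are Gaussian random walks
    of step sd ``motion_sd``.
    """
    rng = np.random.default_rng(config.seed)
    labels = tissue_labels(config.grid_dims)
    flat_labels = labels.ravel()
    brain_idx = np.flatnonzero((flat_labels == GM) | (flat_labels == WM))
    csf_idx = np.flatnonzero(flat_labels == CSF)
    t_s = np.arange(config.n_timepoints) * config.tr_s
    f_lo, f_hi = SIGNAL_BAND

    conns = config.planted_connections
    planted_gm = sorted({c.gm_index for c in conns})
    planted_wm = sorted({c.wm_index for c in conns})
    wm_coupling = {c.wm_index: (c.coupling_hc, c.coupling_pdh) for c in conns}
    planted_vox = np.array(planted_gm + planted_wm, dtype=int)
    # waveforms of planted voxels are fixed across subjects so that a voxel's
    # band amplitude (hence its ALFF) is proportional to its planted amplitude
    planted_wave = _band_limited(rng, len(planted_vox), t_s, f_lo, f_hi)
    planted_pos = {v: i for i, v in enumerate(planted_vox)}

    n_total = 2 * config.n_per_group
    groups = ["HC"] * config.n_per_group + ["PDH"] * config.n_per_group
    subject_ids = [f"{g}{i + 1:02d}" for g in GROUPS for i in range(config.n_per_group)]
    u = config.latent_sd * rng.standard_normal(n_total)

    tissue_probs = _tissue_probabilities(labels)
    affine = _default_affine(config.grid_dims, config.voxel_size_mm)

    subjects: list[SubjectRecord] = []
    for s in range(n_total):
        sig = _band_limited(rng, len(brain_idx), t_s, f_lo, f_hi)
        amp = np.ones(len(brain_idx))
        pos_in_brain = {v: j for j, v in enumerate(brain_idx)}
        for v in planted_gm:
            amp[pos_in_brain[v]] = 1.0 + u[s]
            sig[pos_in_brain[v]] = planted_wave[planted_pos[v]]
        for v in planted_wm:
            beta = wm_coupling[v][0] if groups[s] == "HC" else wm_coupling[v][1]
            eps = config.latent_sd * rng.standard_normal()
            amp[pos_in_brain[v]] = 1.0 + beta * u[s] + np.sqrt(1.0 - beta ** 2) * eps
            sig[pos_in_brain[v]] = planted_wave[planted_pos[v]]

        flat_bold = rng.normal(
            0.0, config.noise_sd, size=(flat_labels.size, config.n_timepoints)
        )
        flat_bold[brain_idx] += amp[:, None] * sig + 100.0
        # one shared nuisance waveform across the CSF block, distinct from any
        # brain voxel's signal, so the CSF-mean regressor has something to remove
        csf_wave = _band_limited(rng, 1, t_s, 0.005, 0.15)[0]
        flat_bold[csf_idx] += csf_wave[None, :] + 100.0

        motion = np.cumsum(
            config.motion_sd * rng.standard_normal((config.n_timepoints, 6)), axis=0
        )
        subjects.append(
            SubjectRecord(
                subject_id=subject_ids[s],
                group=groups[s],
                bold=flat_bold.reshape(*config.grid_dims, config.n_timepoints),
                affine=affine.copy(),
                tissue_probs={k: v.copy() for k, v in tissue_probs.items()},
                motion=motion,
            )
        )

    truth = GroundTruth(
        planted_connections=conns, subject_ids=subject_ids, u=u.copy()
    )
    return subjects, truth


def _tissue_probabilities(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Home tissue probability 0.9, 0.05 for the other two, background ~0."""
    probs = {}
    for name, code in (("GM", GM), ("WM", WM), ("CSF", CSF)):
        p = np.full(labels.shape, 0.02)
        p[labels != BG] = 0.05
        p[labels == code] = 0.9
        probs[name] = p
    return probs


# ---------------------------------------------------------------------------
# cohort I/O

MANIFEST_COLUMNS = [
    "subject_id", "group", "bold_path", "gm_path", "wm_path", "csf_path", "motion_path",
]


def write_cohort(cohort: list[SubjectRecord], ground_truth: GroundTruth,
                 directory: str | Path) -> Path:
    """Write a cohort to ``directory``; returns the manifest TSV path.

    One NIfTI-1 file per BOLD run and per tissue probability map (float32),
    motion as 6-column whitespace-delimited text, plus ``ground_truth.tsv``
    (planted connections) and ``latent_factors.tsv`` (per-subject u values).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        paths = {}
        bold_img = nib.Nifti1Image(rec.bold.astype(np.float32), rec.affine)
        paths["bold_path"] = f"{rec.subject_id}_bold.nii.gz"
        bold_img.to_filename(directory / paths["bold_path"])
        for tissue in ("GM", "WM", "CSF"):
            img = nib.Nifti1Image(rec.tissue_probs[tissue].astype(np.float32), rec.affine)
            key = f"{tissue.lower()}_path"
            paths[key] = f"{rec.subject_id}_{tissue.lower()}_prob.nii.gz"
            img.to_filename(directory / paths[key])
        paths["motion_path"] = f"{rec.subject_id}_motion.txt"
        np.savetxt(directory / paths["motion_path"], rec.motion, fmt="%.8f")
        rows.append({"subject_id": rec.subject_id, "group": rec.group, **paths})

    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)

    pd.DataFrame(
        ground_truth.planted_connections,
        columns=["gm_index", "wm_index", "coupling_hc", "coupling_pdh"],
    ).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"subject_id": ground_truth.subject_ids, "u": ground_truth.u}
    ).to_csv(directory / "latent_factors.tsv", sep="\t", index=False, float_format="%.10g")
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Read a cohort back from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"manifest missing columns: {missing}")
    records = []
    for row in table.itertuples(index=False):
        for col in MANIFEST_COLUMNS[2:]:
            if not (base / getattr(row, col)).exists():
                raise FileNotFoundError(
                    f"manifest references missing file: {base / getattr(row, col)}"
                )
        bold_img = nib.load(base / row.bold_path)
        probs = {
            tissue: np.asarray(nib.load(base / getattr(row, f"{tissue.lower()}_path")).dataobj,
                               dtype=np.float64)
            for tissue in ("GM", "WM", "CSF")
        }
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                bold=np.asarray(bold_img.dataobj, dtype=np.float64),
                affine=np.asarray(bold_img.affine, dtype=np.float64),
                tissue_probs=probs,
                motion=np.loadtxt(base / row.motion_path, ndmin=2),
            )
        )
    return records
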