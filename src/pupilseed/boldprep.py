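"""Post-registration BOLD denoising.

Operates on 4D BOLD data that is already in a common voxel grid
(slice-timing, realignment and spatial normalisation are upstream
concerns).  Implements the denoising chain used for seed connectivity:

- framewise displacement (FD) from 6 rigid-motion parameters,
- outlier-volume detection (FD > 0.9 mm or global-signal change > 5 SD),
- volume-wise Gaussian spatial smoothing (8 mm FWHM default),
- OLS confound regression (motion, tissue signals, rest-onset ramp,
  one indicator per outlier volume; the global signal is never used),
- hard frequency-domain bandpass, 0.008-0.09 Hz default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
import pandas as pd
from scipy import ndimage

__all__ = [
    "BOLDDataset",
    "OutlierFlags",
    "compute_fd",
    "detect_outliers",
    "spatial_smooth",
    "regress_confounds",
    "bandpass",
    "rest_regressors",
    "preprocess",
    "read_motion_tsv",
    "write_motion_tsv",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BOLDDataset:
    """4D BOLD array with mask, repetition time, rigid-motion parameters
    and voxel-to-mm affine.

    ``data`` is (x, y, z, t); ``motion`` is (t, 6): three translations in
    mm then three rotations in radians.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    motion: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.motion = np.asarray(self.motion, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dims")
        if self.motion.shape != (self.data.shape[3], 6):
            raise ValueError("motion must be (n_volumes, 6)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def in_mask(self) -> np.ndarray:
        """(n_mask_voxels, t) view of the masked time series."""
        return self.data[self.mask]

    # --- NIfTI I/O -------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size, self.tr))
        return img

    @classmethod
    def from_nifti(cls, bold_path, mask_path, motion, tr=None) -> "BOLDDataset":
        img = nib.load(str(bold_path))
        mask = nib.load(str(mask_path)).get_fdata() > 0.5
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            mask=mask,
            tr=tr,
            motion=np.asarray(motion, dtype=float),
            affine=np.asarray(img.affine, dtype=float),
        )


@dataclass
class OutlierFlags:
    """Per-volume outlier flags with the FD and global-signal-change
    series they were derived from."""

    flags: np.ndarray
    fd: np.ndarray
    global_z: np.ndarray
    fd_thresh: float = 0.9
    gs_thresh: float = 5.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.fd = np.asarray(self.fd, dtype=float)
        self.global_z = np.asarray(self.global_z, dtype=float)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def compute_fd(motion: np.ndarray, rotation_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement: sum of absolute frame-to-frame changes in
    the three translations (mm) plus ``rotation_radius`` times the sum of
    absolute rotation changes (rad), i.e. rotations converted to arc
    length on a 50 mm sphere.  fd[0] = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_outliers(
    bold: BOLDDataset, fd_thresh: float = 0.9, gs_thresh: float = 5.0
) -> OutlierFlags:
    """Flag volumes with FD above ``fd_thresh`` mm or a global-signal
    change above ``gs_thresh`` standard deviations.

    The global signal is the mean over the mask per volume; its
    frame-to-frame difference is z-scored by its own SD.
    """
    if not bold.mask.any():
        raise ValueError("mask is empty")
    fd = compute_fd(bold.motion)
    gs = bold.in_mask().mean(axis=0)
    dg = np.diff(gs)
    sd = dg.std()
    gz = np.concatenate([[0.0], dg / sd]) if sd > 0 else np.zeros(bold.n_volumes)
    flags = (fd > fd_thresh) | (np.abs(gz) > gs_thresh)
    return OutlierFlags(flags=flags, fd=fd, global_z=gz,
                        fd_thresh=fd_thresh, gs_thresh=gs_thresh)


def spatial_smooth(bold: BOLDDataset, fwhm: float = 8.0) -> BOLDDataset:
    """Volume-wise separable Gaussian smoothing with the given FWHM in
    mm; a FWHM of 0 is the identity.  Mask, affine and TR are unchanged."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return replace(bold, data=bold.data.copy(), meta=dict(bold.meta))
    sigma_vox = fwhm * FWHM_TO_SIGMA / bold.voxel_size
    # nearest-edge padding keeps constant volumes constant at the borders
    out = ndimage.gaussian_filter(bold.data, sigma=(*sigma_vox, 0.0), mode="nearest")
    return replace(bold, data=out, meta=dict(bold.meta))


def rest_regressors(n_volumes: int, n_initial: int = 10) -> np.ndarray:
    """Session-onset regressors absorbing transient ramping at the start
    of the scan: a 0/1 indicator over the first ``n_initial`` volumes
    plus a linear trend."""
    onset = np.zeros(n_volumes)
    onset[: min(n_initial, n_volumes)] = 1.0
    trend = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack([onset, trend])


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = _qr_pivoted(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def _qr_pivoted(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def regress_confounds(
    bold: BOLDDataset,
    confounds: np.ndarray | None,
    outliers: OutlierFlags | None = None,
    confound_names: list[str] | None = None,
) -> BOLDDataset:
    """Per-voxel OLS residualisation on [intercept | confounds | one
    indicator column per flagged volume].

    The global signal is never added here; callers supply motion, tissue
    and rest regressors explicitly.  Residuals at flagged volumes are
    exactly zero (the indicator absorbs them).
    """
    T = bold.n_volumes
    cols = [np.ones((T, 1))]
    names = ["intercept"]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != T:
            if confounds.shape[1] == T:
                confounds = confounds.T
            else:
                raise ValueError("confound rows must equal n_volumes")
        cols.append(confounds)
        if confound_names is None:
            confound_names = [f"confound_{i}" for i in range(confounds.shape[1])]
        names += list(confound_names)
    if outliers is not None and outliers.n_flagged:
        idx = np.flatnonzero(outliers.flags)
        ind = np.zeros((T, idx.size))
        ind[idx, np.arange(idx.size)] = 1.0
        cols.append(ind)
        names += [f"outlier_{i}" for i in idx]
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _name_collinear(X, names)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    Y = bold.in_mask().T  # (t, v)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = bold.data.copy()
    out[bold.mask] = resid.T
    meta = dict(bold.meta)
    meta["confound_regression"] = {"n_regressors": X.shape[1], "names": names}
    return replace(bold, data=out, meta=meta)


def bandpass(bold: BOLDDataset, low: float = 0.008, high: float = 0.09) -> BOLDDataset:
    """Zero-phase hard bandpass: real-FFT bins with frequency below
    ``low`` or above ``high`` Hz are zeroed per voxel.  The DC bin lies
    below the band, so constant offsets are removed."""
    nyquist = 1.0 / (2.0 * bold.tr)
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz is at or above Nyquist {nyquist:.4f} Hz")
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr)
    keep = (freqs >= low) & (freqs <= high)
    Y = bold.in_mask()
    spec = np.fft.rfft(Y, axis=1)
    spec[:, ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=T, axis=1)
    out = bold.data.copy()
    out[bold.mask] = filtered
    return replace(bold, data=out, meta=dict(bold.meta))


def preprocess(
    bold: BOLDDataset,
    confounds: np.ndarray | None = None,
    confound_names: list[str] | None = None,
    *,
    fwhm: float = 8.0,
    fd_thresh: float = 0.9,
    gs_thresh: float = 5.0,
    low: float = 0.008,
    high: float = 0.09,
    include_motion: bool = True,
    include_rest: bool = True,
) -> tuple[BOLDDataset, OutlierFlags]:
    """Full denoising chain: smooth, detect outliers, regress confounds
    (motion + rest ramp + supplied tissue columns + outlier indicators),
    bandpass.  Returns the cleaned dataset and the outlier flags.
    """
    smoothed = spatial_smooth(bold, fwhm=fwhm)
    flags = detect_outliers(smoothed, fd_thresh=fd_thresh, gs_thresh=gs_thresh)
    cols, names = [], []
    if include_motion:
        motion = bold.motion - bold.motion.mean(axis=0)
        cols.append(motion)
        names += [f"motion_{i}" for i in range(6)]
    if include_rest:
        cols.append(rest_regressors(bold.n_volumes))
        names += ["rest_onset", "trend"]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != bold.n_volumes:
            confounds = confounds.T
        cols.append(confounds)
        if confound_names is None:
            confound_names = [f"tissue_{i}" for i in range(confounds.shape[1])]
        names += list(confound_names)
    design = np.hstack(cols) if cols else None
    if design is not None:
        varying = design.std(axis=0) > 0  # constants belong to the intercept
        design = design[:, varying]
        names = [n for n, v in zip(names, varying) if v]
        if design.shape[1] == 0:
            design = None
    regressed = regress_confounds(smoothed, design, flags, confound_names=names)
    cleaned = bandpass(regressed, low=low, high=high)
    cleaned.meta["preprocess"] = {
        "fwhm": fwhm,
        "fd_thresh": fd_thresh,
        "gs_thresh": gs_thresh,
        "band": [low, high],
        "n_outliers": flags.n_flagged,
    }
    return cleaned, flags


def read_motion_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)


def write_motion_tsv(motion: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(motion)).to_csv(path, sep="\t", index=False, header=False)
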