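"""Subject-level connectivity maps.

Seed-to-voxel maps: Pearson correlation between a seed regressor and
every in-mask voxel time series, Fisher z-transformed for group
statistics.  Local-correlation maps: a regional-homogeneity measure,
the Gaussian-weighted average correlation of each voxel with its
spatial neighbours, used as a control for effects driven by local
coherence rather than seed-mediated connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage

from .boldprep import BOLDDataset, OutlierFlags, FWHM_TO_SIGMA
from .pupil import SeedSeries

__all__ = [
    "ConnectivityMap",
    "LocalCorrMap",
    "seed_to_voxel",
    "fisher_z",
    "local_correlation",
    "gaussian_weight_kernel",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMap:
    """Voxel-wise seed correlation: raw r and Fisher z, NaN outside the
    mask."""

    r: np.ndarray
    z: np.ndarray
    seed_kind: str
    n_timepoints: int
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.r.shape != self.mask.shape or self.z.shape != self.mask.shape:
            raise ValueError("map shape must match mask shape")

    def masked_z(self) -> np.ndarray:
        """1-D vector of z values over the mask."""
        return self.z[self.mask]

    def to_nifti(self, which: str = "z") -> nib.Nifti1Image:
        arr = {"z": self.z, "r": self.r}[which]
        return nib.Nifti1Image(arr.astype(np.float32), self.affine)

    def save(self, path, which: str = "z") -> None:
        nib.save(self.to_nifti(which), str(path))
        sidecar = {
            "seed_kind": self.seed_kind,
            "n_timepoints": int(self.n_timepoints),
            "map": which,
        }
        with open(str(path).split(".nii")[0] + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass
class LocalCorrMap:
    """Gaussian-weighted mean neighbour correlation per voxel, in
    [-1, 1] inside the mask, NaN outside."""

    value: np.ndarray
    kernel_fwhm: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_timepoints: int = 0

    def masked(self) -> np.ndarray:
        return self.value[self.mask]


def fisher_z(r):
    """Fisher z transform, atanh(r), with |r| clipped to 1 - 1e-7 so z
    stays finite at perfect correlation."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| must not exceed 1")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out if out.ndim else float(out)


def seed_to_voxel(
    bold: BOLDDataset,
    seed: SeedSeries,
    flags: OutlierFlags | None = None,
) -> ConnectivityMap:
    """Pearson correlation of the seed with every in-mask voxel series,
    computed over unflagged volumes only, then Fisher z-transformed.

    Constant voxel series get r = 0; their count is reported in
    ``meta["n_constant_voxels"]``.
    """
    if seed.n_volumes != bold.n_volumes:
        raise ValueError("seed length must equal number of volumes")
    keep = np.ones(bold.n_volumes, dtype=bool)
    if flags is not None:
        keep = ~flags.flags
    x = seed.value[keep]
    if x.std() == 0:
        raise ValueError("seed has zero variance over retained volumes")
    xs = (x - x.mean()) / x.std()
    Y = bold.in_mask()[:, keep]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sd = Yc.std(axis=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    r_vec = (Yc / sd_safe[:, None]) @ xs / x.size
    r_vec[constant] = 0.0
    r_vec = np.clip(r_vec, -1.0, 1.0)
    r = np.full(bold.mask.shape, np.nan)
    z = np.full(bold.mask.shape, np.nan)
    r[bold.mask] = r_vec
    z[bold.mask] = np.arctanh(np.clip(r_vec, -R_CLIP, R_CLIP))
    return ConnectivityMap(
        r=r,
        z=z,
        seed_kind=seed.kind,
        n_timepoints=int(x.size),
        mask=bold.mask,
        affine=bold.affine,
        meta={"n_constant_voxels": int(constant.sum())},
    )


def gaussian_weight_kernel(
    kernel_fwhm: float, voxel_size: np.ndarray, radius_factor: float = 3.0
) -> np.ndarray:
    """Explicit truncated Gaussian spatial-weight kernel.

    Weight of a neighbour at voxel offset (di, dj, dk) is
    exp(-d_mm^2 / (2 sigma^2)) with sigma = FWHM / (2 sqrt(2 ln 2)),
    inside a box of ``radius_factor`` sigma per axis; the centre weight
    (self) is included in the array and excluded by the caller.
    """
    axes = _kernel_axes(kernel_fwhm, voxel_size, radius_factor)
    k = np.multiply.outer(np.multiply.outer(axes[0], axes[1]), axes[2])
    return k


def _kernel_axes(kernel_fwhm, voxel_size, radius_factor=3.0):
    """Per-axis 1-D factors of the separable weight kernel."""
    sigma = kernel_fwhm * FWHM_TO_SIGMA
    voxel_size = np.asarray(voxel_size, dtype=float)
    radii = np.maximum(np.ceil(radius_factor * sigma / voxel_size).astype(int), 1)
    return [
        np.exp(-((np.arange(-r, r + 1) * v) ** 2) / (2.0 * sigma ** 2))
        for r, v in zip(radii, voxel_size)
    ]


def _weighted_sum(vol: np.ndarray, axes_kernels) -> np.ndarray:
    """Separable spatial convolution with the weight kernel (zero
    boundary), applied to a 3-D or 4-D (x, y, z[, t]) array."""
    out = vol
    for ax, k in enumerate(axes_kernels):
        out = ndimage.convolve1d(out, k, axis=ax, mode="constant")
    return out


def local_correlation(
    bold: BOLDDataset,
    kernel_fwhm: float = 10.0,
    flags: OutlierFlags | None = None,
) -> LocalCorrMap:
    """Gaussian-weighted average correlation of each in-mask voxel with
    its in-mask neighbours (self excluded), weights from inter-voxel mm
    distance.

    Uses the standardised-series identity: with voxel series z-scored
    over time, sum_u w(v,u) corr(v,u) = (1/T) sum_t s_v(t) (W s_t)(v)
    where W is spatial convolution with the weight kernel.  The self
    term (weight w(0), correlation 1) is subtracted and the result is
    normalised by the total in-mask neighbour weight.
    """
    if kernel_fwhm <= 0:
        raise ValueError("kernel_fwhm must be positive")
    if bold.mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    keep = np.ones(bold.n_volumes, dtype=bool)
    if flags is not None:
        keep = ~flags.flags
    T = int(keep.sum())
    axes_kernels = _kernel_axes(kernel_fwhm, bold.voxel_size)
    w0 = float(np.prod([k[k.size // 2] for k in axes_kernels]))  # self weight

    Y = bold.in_mask()[:, keep]
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    S = (Y - mu) / sd_safe[:, None]  # standardised series, (v, t)

    vol = np.zeros((*bold.mask.shape, T))
    vol[bold.mask] = S
    # weighted neighbour sums per timepoint (zero outside the grid)
    smoothed = _weighted_sum(vol, axes_kernels)
    num = (vol * smoothed).sum(axis=3) / T - w0  # subtract self corr * w0
    wsum = _weighted_sum(bold.mask.astype(float), axes_kernels) - w0
    value = np.full(bold.mask.shape, np.nan)
    ok = bold.mask & (wsum > 1e-12)
    value[ok] = num[ok] / wsum[ok]
    value[bold.mask] = np.clip(value[bold.mask], -1.0, 1.0)
    return LocalCorrMap(
        value=value,
        kernel_fwhm=kernel_fwhm,
        mask=bold.mask,
        affine=bold.affine,
        n_timepoints=T,
    )
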