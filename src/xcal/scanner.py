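"""Dual-resolution scan simulation.

A scanner profile degrades a finely rasterised ground-truth structure into
a calibrated grayscale acquisition: multiply by the tissue mineral density,
blur with an isotropic Gaussian point-spread function, box-average onto the
scanner's voxel grid, and add Gaussian noise.  Two presets emulate the two
HR-pQCT generations: an 82 um first-generation-like grid and a 61 um
second-generation-like grid.  The PSF width defaults to 0.6 x voxel size so
blur scales with resolution; neither device's true PSF or noise spectrum is
modelled — the profiles are qualitative, resolution-dominated stand-ins.

The box resampling emits every fully-covered coarse voxel as the exact
average of the fine signal over its physical box, so gray means are
unbiased and total mineral mass (gray x voxel volume) is conserved up to
the sub-voxel sliver cropped at the far boundary — exactly, when the
extent is a multiple of the coarse voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume, ImageVolume

__all__ = ["ScannerProfile", "simulate_scan", "box_resample", "resample_mask"]


@dataclass
class ScannerProfile:
    """Acquisition model: voxel size, PSF width, noise level, calibration."""

    name: str
    voxel_um: float
    psf_sigma_um: float
    noise_sd_mgHA: float = 0.0
    # linear gray <-> mgHA mapping (slope, intercept); identity by default
    calibration: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if self.psf_sigma_um < 0 or self.noise_sd_mgHA < 0:
            raise ValueError("psf_sigma_um and noise_sd_mgHA must be nonnegative")

    @classmethod
    def xcti_like(cls, noise_sd_mgHA: float = 30.0) -> "ScannerProfile":
        """First-generation-like profile: isotropic 82 um grid."""
        return cls("XCTI_like", 82.0, 0.6 * 82.0, noise_sd_mgHA)

    @classmethod
    def xctii_like(cls, noise_sd_mgHA: float = 20.0) -> "ScannerProfile":
        """Second-generation-like profile: isotropic 61 um grid."""
        return cls("XCTII_like", 61.0, 0.6 * 61.0, noise_sd_mgHA)


def _overlap_matrix(n_in: int, v_in: float, v_out: float) -> np.ndarray:
    """1D box-average operator (n_out x n_in).

    Row j holds the fraction of output box [j*v_out, (j+1)*v_out) covered
    by each input voxel.  Only fully-covered output boxes are emitted
    (n_out = floor(extent / v_out)), so every row sums to exactly 1 and
    each output value is a true average of the input signal over its box;
    a trailing sliver of the input narrower than one output voxel is
    dropped.  When the extents are commensurate the operator conserves
    total mass exactly.
    """
    n_out = int(np.floor(n_in * v_in / v_out + 1e-9))
    if n_out < 1:
        raise ValueError("input extent smaller than one output voxel")
    j = np.arange(n_out)
    i = np.arange(n_in)
    lo = np.maximum(j[:, None] * v_out, i[None, :] * v_in)
    hi = np.minimum((j[:, None] + 1) * v_out, (i[None, :] + 1) * v_in)
    w = np.clip(hi - lo, 0.0, None) / v_out
    return w / w.sum(axis=1, keepdims=True)


def box_resample(data: np.ndarray, voxel_in_um: float, voxel_out_um: float) -> np.ndarray:
    """Resample by exact box averaging onto a coarser (or finer) grid."""
    out = np.asarray(data, dtype=np.float64)
    for axis in range(3):
        w = _overlap_matrix(out.shape[axis], voxel_in_um, voxel_out_um)
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def resample_mask(mask: np.ndarray, voxel_in_um: float, voxel_out_um: float,
                  min_fraction: float = 0.5) -> np.ndarray:
    """Carry a compartment mask across grids: coarse voxel is in-mask when at
    least ``min_fraction`` of its physical box is covered by the fine mask."""
    frac = box_resample(mask.astype(np.float64), voxel_in_um, voxel_out_um)
    return frac >= min_fraction


def simulate_scan(
    truth: BinaryVolume,
    tissue_density_mgHA: float,
    profile: ScannerProfile,
    seed: int | None = 0,
) -> ImageVolume:
    """Image a binary ground-truth structure with a scanner profile.

    The blur uses periodic (wrap) boundary handling — the analytic phantoms
    are periodic by construction when their extent is a multiple of the
    structural pitch — which keeps the pre-noise acquisition exactly
    mass-conserving.  Deterministic for a given seed.
    """
    if truth.voxel_um > profile.voxel_um + 1e-9:
        raise ValueError(
            f"truth grid ({truth.voxel_um} um) must be at least as fine as the "
            f"scanner grid ({profile.voxel_um} um)"
        )
    gray = truth.voxels.astype(np.float64) * float(tissue_density_mgHA)
    if profile.psf_sigma_um > 0:
        gray = ndimage.gaussian_filter(gray, sigma=profile.psf_sigma_um / truth.voxel_um,
                                       mode="wrap")
    gray = box_resample(gray, truth.voxel_um, profile.voxel_um)
    if profile.noise_sd_mgHA > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, profile.noise_sd_mgHA, size=gray.shape)
    return ImageVolume(gray, profile.voxel_um, calibrated=True)
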