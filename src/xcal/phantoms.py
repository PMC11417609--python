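"""Analytic bone phantoms with known ground-truth morphometry.

Each phantom kind is defined analytically (plates, rods, a thresholded
Gaussian random field, or a cortical plate perforated by cylindrical
pores), so its morphometric ground truth — bone volume fraction,
thicknesses, spacings, porosity — is known by construction rather than
measured from the raster.  Rasterisation happens at a user-chosen fine
grid (20 um by default downstream) and the same spec rasterised at two
grids yields the *same* truth fields, which is what makes the phantoms
usable as oracles for the measurement pipeline.

Coordinate convention: axis 0 is the "axial" direction.  Plates are
normal to axis 0; rods and cortical pores run along axis 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom"]

PhantomKind = Literal["plate_lattice", "rod_lattice", "gaussian_field", "cortical_shell"]


@dataclass
class PhantomTruth:
    """Analytic morphometry of a phantom; fields are None where a quantity
    is not analytically defined for the phantom kind."""

    bvtv_true: float | None = None
    tb_th_true_um: float | None = None
    tb_sp_true_um: float | None = None
    tb_n_true_mm: float | None = None
    ct_th_true_um: float | None = None
    ct_po_true: float | None = None
    ct_po_dm_true_um: float | None = None

    def __post_init__(self) -> None:
        for name in ("bvtv_true", "ct_po_true"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("tb_th_true_um", "tb_sp_true_um", "tb_n_true_mm",
                     "ct_th_true_um", "ct_po_dm_true_um"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic structure.

    structure_params by kind:

    - ``plate_lattice``: ``thickness_um``, ``spacing_um`` (centre-to-centre
      pitch of parallel plates normal to axis 0).
    - ``rod_lattice``: ``diameter_um``, ``pitch_um`` (square lattice of rods
      along axis 0).
    - ``gaussian_field``: ``correlation_length_um``, ``solid_fraction``.
    - ``cortical_shell``: ``shell_thickness_um``, ``pore_diameters_um``
      (scalar or sequence, cycled over pores), and either ``n_pores`` or
      ``target_porosity`` (pore count solved from the analytic porosity);
      through-thickness cylindrical pores on a jittered lattice.
    """

    kind: PhantomKind
    extent_mm: tuple[float, float, float]
    structure_params: dict
    tissue_density_mgHA: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("extent must be positive")
        p = self.structure_params
        if self.kind == "plate_lattice":
            if not 0 < p["thickness_um"] < p["spacing_um"]:
                raise ValueError("plate thickness must be positive and < spacing")
        elif self.kind == "rod_lattice":
            if not 0 < p["diameter_um"] < p["pitch_um"]:
                raise ValueError("rod diameter must be positive and < pitch")
        elif self.kind == "gaussian_field":
            if not 0 < p["solid_fraction"] < 1:
                raise ValueError("solid_fraction must lie in (0, 1)")
            if p["correlation_length_um"] <= 0:
                raise ValueError("correlation length must be positive")
        elif self.kind == "cortical_shell":
            if p["shell_thickness_um"] <= 0:
                raise ValueError("shell thickness must be positive")
            if np.any(np.asarray(p["pore_diameters_um"]) <= 0):
                raise ValueError("pore diameters must be positive")
        else:
            raise ValueError(f"unknown phantom kind {self.kind!r}")

    def smallest_feature_um(self) -> float:
        p = self.structure_params
        if self.kind == "plate_lattice":
            return min(p["thickness_um"], p["spacing_um"] - p["thickness_um"])
        if self.kind == "rod_lattice":
            return min(p["diameter_um"], p["pitch_um"] - p["diameter_um"])
        if self.kind == "gaussian_field":
            return p["correlation_length_um"]
        return float(np.min(p["pore_diameters_um"]))


def _grid_coords(n: int, voxel_um: float) -> np.ndarray:
    # voxel-centre physical coordinates in um
    return (np.arange(n) + 0.5) * voxel_um


def generate_phantom(spec: PhantomSpec, voxel_um: float) -> tuple[BinaryVolume, PhantomTruth]:
    """Rasterise ``spec`` on an isotropic grid and return (volume, truth).

    The truth is filled from the analytic definition of the structure,
    never measured from the raster.  A grid too coarse to resolve the
    smallest structural feature (less than two voxels across it) is
    rejected.
    """
    if voxel_um <= 0:
        raise ValueError("voxel_um must be positive")
    feat = spec.smallest_feature_um()
    if voxel_um > feat / 2.0:
        raise ValueError(
            f"unresolvable feature: smallest feature {feat:g} um needs "
            f"voxel <= {feat / 2.0:g} um, got {voxel_um:g} um"
        )
    shape = tuple(max(1, round(e * 1000.0 / voxel_um)) for e in spec.extent_mm)
    builder = {
        "plate_lattice": _plate_lattice,
        "rod_lattice": _rod_lattice,
        "gaussian_field": _gaussian_field,
        "cortical_shell": _cortical_shell,
    }[spec.kind]
    voxels, truth = builder(spec, shape, voxel_um)
    return BinaryVolume(voxels, voxel_um), truth


def _plate_lattice(spec: PhantomSpec, shape, voxel_um):
    th = spec.structure_params["thickness_um"]
    sp = spec.structure_params["spacing_um"]
    z = _grid_coords(shape[0], voxel_um)
    # plates centred at (k + 1/2) * spacing so a volume whose extent is a
    # multiple of the pitch holds whole plates with symmetric margins
    inplate = np.abs((z % sp) - sp / 2.0) <= th / 2.0
    voxels = np.zeros(shape, dtype=bool)
    voxels[inplate, :, :] = True
    truth = PhantomTruth(
        bvtv_true=th / sp,
        tb_th_true_um=th,
        tb_sp_true_um=sp - th,
        tb_n_true_mm=1000.0 / sp,
    )
    return voxels, truth


def _rod_lattice(spec: PhantomSpec, shape, voxel_um):
    d = spec.structure_params["diameter_um"]
    pitch = spec.structure_params["pitch_um"]
    y = _grid_coords(shape[1], voxel_um)
    x = _grid_coords(shape[2], voxel_um)
    # distance to the nearest rod axis of the square lattice
    dy = np.abs((y % pitch) - pitch / 2.0)
    dx = np.abs((x % pitch) - pitch / 2.0)
    r2 = dy[:, None] ** 2 + dx[None, :] ** 2
    inrod = r2 <= (d / 2.0) ** 2
    voxels = np.broadcast_to(inrod[None, :, :], shape).copy()
    truth = PhantomTruth(
        bvtv_true=math.pi * d**2 / (4.0 * pitch**2),
        tb_th_true_um=d,
        tb_n_true_mm=1000.0 / pitch,
    )
    return voxels, truth


def _gaussian_field(spec: PhantomSpec, shape, voxel_um):
    corr = spec.structure_params["correlation_length_um"]
    frac = spec.structure_params["solid_fraction"]
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma_vox = corr / voxel_um
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    thr = np.quantile(fieldv, 1.0 - frac)
    voxels = fieldv >= thr
    truth = PhantomTruth(bvtv_true=frac)
    return voxels, truth


def _cortical_shell(spec: PhantomSpec, shape, voxel_um):
    p = spec.structure_params
    t = p["shell_thickness_um"]
    diam = np.atleast_1d(np.asarray(p["pore_diameters_um"], dtype=float))
    extent_um = tuple(e * 1000.0 for e in spec.extent_mm)
    if t > extent_um[0]:
        raise ValueError("shell thicker than extent along axis 0")
    area_um2 = extent_um[1] * extent_um[2]

    # pores sit on a jittered lattice so they can never merge; the lattice
    # pitch leaves at least one max-diameter clearance between pore walls
    dmax = float(diam.max())
    cell = 2.0 * dmax
    ncy = int(extent_um[1] // cell)
    ncx = int(extent_um[2] // cell)
    n_cells = ncy * ncx
    if "n_pores" in p:
        n_pores = int(p["n_pores"])
    else:
        target = float(p["target_porosity"])
        if not 0.0 <= target < 1.0:
            raise ValueError("target_porosity must lie in [0, 1)")
        # through-pores: porosity = sum(pi d_i^2 / 4) / shell area
        mean_pore_area = float(np.mean(math.pi * diam**2 / 4.0))
        n_pores = round(target * area_um2 / mean_pore_area)
    if n_pores > n_cells:
        raise ValueError(
            f"cannot place {n_pores} non-overlapping pores on a "
            f"{ncy} x {ncx} lattice; enlarge the extent or shrink pores"
        )

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_cells)[:n_pores]
    pore_d = diam[np.arange(n_pores) % diam.size]
    jitter = rng.uniform(-0.5, 0.5, size=(n_pores, 2)) * (cell - dmax - 2 * voxel_um)
    cy = (order // ncx + 0.5) * cell + jitter[:, 0]
    cx = (order % ncx + 0.5) * cell + jitter[:, 1]

    z = _grid_coords(shape[0], voxel_um)
    z0 = (extent_um[0] - t) / 2.0
    inshell = (z >= z0) & (z <= z0 + t)
    voxels = np.zeros(shape, dtype=bool)
    voxels[inshell, :, :] = True

    y = _grid_coords(shape[1], voxel_um)
    x = _grid_coords(shape[2], voxel_um)
    pore2d = np.zeros(shape[1:], dtype=bool)
    for yc, xc, d in zip(cy, cx, pore_d):
        r2 = (y[:, None] - yc) ** 2 + (x[None, :] - xc) ** 2
        pore2d |= r2 <= (d / 2.0) ** 2
    voxels[:, pore2d] = False

    ct_po = float(np.sum(math.pi * pore_d**2 / 4.0) / area_um2) if n_pores else 0.0
    truth = PhantomTruth(
        ct_th_true_um=t,
        ct_po_true=ct_po,
        ct_po_dm_true_um=float(pore_d.mean()) if n_pores else None,
    )
    return voxels, truth


def shell_mask(spec: PhantomSpec, voxel_um: float) -> np.ndarray:
    """Compartment mask for a cortical_shell phantom: the full (unperforated)
    shell slab, emitted analytically rather than by contouring."""
    if spec.kind != "cortical_shell":
        raise ValueError("shell_mask is defined for cortical_shell phantoms")
    shape = tuple(max(1, round(e * 1000.0 / voxel_um)) for e in spec.extent_mm)
    t = spec.structure_params["shell_thickness_um"]
    extent0_um = spec.extent_mm[0] * 1000.0
    z = _grid_coords(shape[0], voxel_um)
    z0 = (extent0_um - t) / 2.0
    mask = np.zeros(shape, dtype=bool)
    mask[(z >= z0) & (z <= z0 + t), :, :] = True
    return mask
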