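"""Digital image-quality phantom: voxelized hot spheres in warm background.

Emulates the NEMA NU-2 image-quality phantom measurement that underlies
recovery-coefficient curves: six hot spheres (inner diameters 10-37 mm, 1 mm
cold walls) in a warm background with a cold cylindrical lung insert, imaged
at finite resolution.  Rendering voxelizes the geometry with sub-voxel
supersampling, blurs with the Gaussian PSF, and optionally adds zero-mean
Gaussian noise (a post-reconstruction noise surrogate).  ``measure_rc``
extracts per-sphere contrast-recovery coefficients exactly as one would from
a scanner image: spherical VOIs matching the inner diameters, background ROIs
placed away from spheres and insert.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .rc_model import PsfModel, SphereGeom
from .units import equivalent_diameter_mm, sphere_volume_ml

NEMA_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class PlacedSphere:
    geom: SphereGeom
    center_mm: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Geometry + imaging parameters of a digital phantom realization.

    Coordinates are in mm with the origin at the grid corner; voxel centers
    sit at ``(i + 0.5) * voxel_mm``.  ``noise_sd`` is the per-voxel Gaussian
    noise standard deviation relative to the background activity.
    """

    shape: tuple[int, int, int] = (200, 200, 120)
    voxel_mm: float = 2.0
    spheres: list[PlacedSphere] = field(default_factory=list)
    background_kbq_ml: float = 4.240
    sphere_kbq_ml: float = 9.284
    lung_insert_radius_mm: float | None = 25.0
    psf: PsfModel = field(default_factory=lambda: PsfModel(fwhm_mm=6.5))
    noise_sd: float = 0.0
    seed: int = 0
    #: sub-voxel sampling per axis for voxelization (1 = voxel-center inclusion)
    supersample: int = 3

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.background_kbq_ml < 0 or self.sphere_kbq_ml < 0:
            raise ValueError("activities must be non-negative")
        ext = self.extent_mm
        for ps in self.spheres:
            r = ps.geom.outer_radius_mm
            for c, e in zip(ps.center_mm, ext):
                if c - r < 0 or c + r > e:
                    raise ValueError(
                        f"sphere at {ps.center_mm} (outer radius {r} mm) exceeds grid extent {ext}"
                    )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_mm for n in self.shape)

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(e / 2.0 for e in self.extent_mm)

    @property
    def sbr(self) -> float:
        return self.sphere_kbq_ml / self.background_kbq_ml


@dataclass
class PhantomImage:
    data: np.ndarray
    spec: PhantomSpec

    def save_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.diag([self.spec.voxel_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), aff), str(path))

    def save_raw(self, path_prefix) -> None:
        """Raw float32 binary + JSON sidecar (shape, voxel size, activities)."""
        self.data.astype(np.float32).tofile(str(path_prefix) + ".raw")
        sidecar = {
            "shape": list(self.spec.shape),
            "voxel_mm": self.spec.voxel_mm,
            "dtype": "float32",
            "background_kbq_ml": self.spec.background_kbq_ml,
            "sphere_kbq_ml": self.spec.sphere_kbq_ml,
        }
        with open(str(path_prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def nema_iq_spec(
    diameters_mm: Sequence[float] = NEMA_DIAMETERS_MM,
    wall_mm: float = 1.0,
    ring_radius_mm: float = 57.2,
    shape: tuple[int, int, int] = (200, 200, 120),
    voxel_mm: float = 2.0,
    background_kbq_ml: float = 4.240,
    sphere_kbq_ml: float = 9.284,
    psf_fwhm_mm: float = 6.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """NEMA-IQ-like layout: spheres coplanar on a ring around a cold lung insert.

    Sphere centers are snapped to the nearest voxel center so that the maximum
    statistic samples the true profile center.
    """
    cx, cy, cz = (n * voxel_mm / 2.0 for n in shape)
    spheres = []
    for k, d in enumerate(diameters_mm):
        ang = 2.0 * math.pi * k / len(diameters_mm)
        raw = (cx + ring_radius_mm * math.cos(ang), cy + ring_radius_mm * math.sin(ang), cz)
        center = tuple(
            (math.floor(c / voxel_mm) + 0.5) * voxel_mm for c in raw
        )
        geom = SphereGeom(
            inner_diameter_mm=d,
            wall_thickness_mm=wall_mm,
            sphere_level=sphere_kbq_ml,
            background_level=background_kbq_ml,
        )
        spheres.append(PlacedSphere(geom=geom, center_mm=center))
    return PhantomSpec(
        shape=shape,
        voxel_mm=voxel_mm,
        spheres=spheres,
        background_kbq_ml=background_kbq_ml,
        sphere_kbq_ml=sphere_kbq_ml,
        lung_insert_radius_mm=25.0,
        psf=PsfModel(fwhm_mm=psf_fwhm_mm),
        noise_sd=noise_sd,
        seed=seed,
    )


def _ball_occupancy(
    shape: tuple[int, int, int], voxel: float, center: tuple[float, float, float],
    radius: float, supersample: int = 3,
    box: tuple[slice, slice, slice] | None = None,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Fractional voxel occupancy of a ball, supersampled within its bounding box."""
    if box is None:
        lo = [max(0, int((c - radius) / voxel) - 1) for c in center]
        hi = [min(n, int((c + radius) / voxel) + 2) for n, c in zip(shape, center)]
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    else:
        sl = box
        lo = [s.start for s in sl]
        hi = [s.stop for s in sl]
    # supersample offsets within a voxel
    off = (np.arange(supersample) + 0.5) / supersample * voxel
    axes = []
    for a, b, c in zip(lo, hi, center):
        base = np.arange(a, b) * voxel
        axes.append((base[:, None] + off[None, :] - c).reshape(-1))
    dx2 = axes[0][:, None, None] ** 2
    dy2 = axes[1][None, :, None] ** 2
    dz2 = axes[2][None, None, :] ** 2
    inside = (dx2 + dy2 + dz2) <= radius**2
    s = supersample
    nx, ny, nz = (b - a for a, b in zip(lo, hi))
    occ = inside.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))
    return sl, occ


def render_phantom(spec: PhantomSpec) -> PhantomImage:
    """Voxelize, blur and (optionally) add noise; deterministic for a given seed."""
    img = np.full(spec.shape, float(spec.background_kbq_ml))

    if spec.lung_insert_radius_mm:
        # cold cylinder along z through the grid center, antialiased radially
        cx, cy, _ = spec.center_mm
        x = (np.arange(spec.shape[0]) + 0.5) * spec.voxel_mm - cx
        y = (np.arange(spec.shape[1]) + 0.5) * spec.voxel_mm - cy
        d = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
        frac = np.clip((spec.lung_insert_radius_mm - d) / spec.voxel_mm + 0.5, 0.0, 1.0)
        img *= (1.0 - frac)[:, :, None]

    for ps in spec.spheres:
        sl, occ_out = _ball_occupancy(
            spec.shape, spec.voxel_mm, ps.center_mm, ps.geom.outer_radius_mm,
            supersample=spec.supersample,
        )
        _, occ_in = _ball_occupancy(
            spec.shape, spec.voxel_mm, ps.center_mm, ps.geom.inner_radius_mm,
            supersample=spec.supersample, box=sl,
        )
        img[sl] = (
            img[sl] * (1.0 - occ_out) + spec.sphere_kbq_ml * occ_in
        )

    sigma_vox = spec.psf.sigma_mm / spec.voxel_mm
    if sigma_vox > 0:
        img = gaussian_filter(img, sigma=sigma_vox, mode="nearest")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd * spec.background_kbq_ml, size=spec.shape)

    return PhantomImage(data=img, spec=spec)


def default_background_rois(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """Centers of 12 background ROIs (37 mm spheres): 6 in the sphere plane at
    ring radius 110 mm offset 30 deg from the spheres, and 3 each at +/-40 mm
    axially; all clear of the spheres and the lung insert."""
    cx, cy, cz = spec.center_mm
    centers = []
    for k in range(6):
        ang = 2.0 * math.pi * (k + 0.5) / 6.0
        centers.append((cx + 110.0 * math.cos(ang), cy + 110.0 * math.sin(ang), cz))
    for k in range(6):
        ang = 2.0 * math.pi * k / 6.0
        dz = 40.0 if k % 2 == 0 else -40.0
        centers.append((cx + 110.0 * math.cos(ang), cy + 110.0 * math.sin(ang), cz + dz))
    return centers


def _voi_values_weights(
    image: PhantomImage, center: tuple[float, float, float], radius: float,
    supersample: int = 3,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    sl, occ = _ball_occupancy(
        image.spec.shape, image.spec.voxel_mm, center, radius, supersample=supersample
    )
    vals = image.data[sl]
    return vals, occ, sl


def measure_rc(
    image: PhantomImage,
    statistic: str = "mean",
    peak_voi_ml: float = 1.0,
    background_roi_centers: Sequence[tuple[float, float, float]] | None = None,
    min_voxels: int = 8,
    supersample: int = 3,
) -> pd.DataFrame:
    """Per-sphere contrast-recovery coefficients from a phantom image.

    For each sphere the statistic ``C`` is evaluated over a spherical VOI
    matching the inner diameter (occupancy-weighted mean; the max is the
    hottest voxel in the VOI; the peak is the occupancy-weighted mean of a
    ``peak_voi_ml`` sphere centered on that hottest voxel).  ``C_B`` is the
    pooled mean over the background ROIs, and

        RC = (C / C_B - 1) / (a_H / a_B - 1).
    """
    spec = image.spec
    if spec.sphere_kbq_ml == spec.background_kbq_ml:
        raise ValueError("sphere and background activities are equal; contrast is undefined")
    if background_roi_centers is None:
        background_roi_centers = default_background_rois(spec)

    bg_vals, bg_wts = [], []
    for c in background_roi_centers:
        vals, occ, _ = _voi_values_weights(image, c, 37.0 / 2.0, supersample)
        bg_vals.append(vals.ravel())
        bg_wts.append(occ.ravel())
    bg_vals = np.concatenate(bg_vals)
    bg_wts = np.concatenate(bg_wts)
    c_b = float(np.average(bg_vals, weights=bg_wts))

    rows = []
    denom = spec.sbr - 1.0
    for ps in spec.spheres:
        r_in = ps.geom.inner_radius_mm
        vals, occ, sl = _voi_values_weights(image, ps.center_mm, r_in, supersample)
        hard = occ > 0.5
        if hard.sum() < min_voxels and statistic == "mean":
            raise ValueError(
                f"sphere VOI ({ps.geom.inner_diameter_mm} mm) resolves only "
                f"{int(hard.sum())} voxels at {spec.voxel_mm} mm; need >= {min_voxels}"
            )
        if statistic == "mean":
            c = float(np.average(vals, weights=occ))
        elif statistic == "max":
            masked = np.where(occ > 0, vals, -np.inf)
            c = float(masked.max())
        elif statistic == "peak":
            masked = np.where(occ > 0, vals, -np.inf)
            idx = np.unravel_index(np.argmax(masked), masked.shape)
            center = tuple(
                (s.start + i + 0.5) * spec.voxel_mm for s, i in zip(sl, idx)
            )
            r_peak = equivalent_diameter_mm(peak_voi_ml) / 2.0
            pvals, pocc, _ = _voi_values_weights(image, center, r_peak, supersample)
            c = float(np.average(pvals, weights=pocc))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.append(
            {
                "statistic": statistic,
                "inner_diameter_mm": ps.geom.inner_diameter_mm,
                "volume_mL": sphere_volume_ml(ps.geom.inner_diameter_mm),
                "rc_measured": (c / c_b - 1.0) / denom,
            }
        )
    return pd.DataFrame(rows).sort_values("volume_mL", ignore_index=True)
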