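"""Synthetic bladder phantoms with known wall thickness and invasion depth.

The study data this package targets (T2-weighted bladder MRI with expert
tumor delineations) are not publicly available, so the pipeline is exercised
on geometric phantoms: an ellipsoidal lumen surrounded by a wall of uniform
thickness, with a spherical-cap tumor that protrudes into the lumen and
excavates the wall to a known invasion depth.  Wall and tumor voxels are
given distinct intensity statistics and spatial-correlation lengths
(Gaussian random fields), so intensity *and* texture carry class signal —
the situation the voxel classifier assumes on real T2W data.

The phantom emulates on T2W contrast: bright urine in the lumen, a
hypointense wall, and an intermediate-intensity tumor.  It does not model MR
physics (coil inhomogeneity, Rician noise) or irregular tumor shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io import Mask, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "sample_training_voxels"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bladder volume.

    All lengths are millimetres.  ``invasion_depth_mm`` is the ground-truth
    depth to which tumor tissue replaces wall tissue (the quantity the depth
    stage must recover); it must satisfy 0 <= depth < wall_thickness_mm.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lumen_radii_mm: tuple[float, float, float] = (17.0, 15.0, 14.0)
    wall_thickness_mm: float = 3.0
    tumor_center_angle: tuple[float, float] = (0.0, 90.0)  # (azimuth, polar) deg
    tumor_radius_mm: float = 8.0
    tumor_protrusion_mm: float = 6.0
    invasion_depth_mm: float = 1.5
    candidate_margin_mm: float = 3.0
    wall_intensity: tuple[float, float] = (100.0, 12.0)
    tumor_intensity: tuple[float, float] = (118.0, 12.0)
    lumen_intensity: tuple[float, float] = (210.0, 6.0)
    exterior_intensity: tuple[float, float] = (45.0, 10.0)
    # spatial correlation length (voxels) of the per-tissue noise field
    texture_params: dict = field(default_factory=lambda: {
        "wall": 0.5, "tumor": 1.8, "lumen": 0.5, "exterior": 0.5})
    partial_volume: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.invasion_depth_mm < self.wall_thickness_mm):
            raise ValueError(
                f"invasion_depth_mm must satisfy 0 <= d < wall_thickness_mm "
                f"({self.invasion_depth_mm} vs {self.wall_thickness_mm})")
        if self.wall_thickness_mm <= 0 or self.tumor_radius_mm <= 0:
            raise ValueError("wall_thickness_mm and tumor_radius_mm must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")


@dataclass
class PhantomTruth:
    """A generated phantom with its ground-truth masks.

    ``inner_mask``/``outer_mask`` are the 1-voxel shells a surface
    segmentation of the *apparent* organ (wall plus attached tumor) would
    produce: the inner shell hugs the tumor where it protrudes into the
    lumen.  ``wall_mask`` is true wall tissue only (tumor excluded);
    ``candidate_mask`` is the mixed tumor+wall region a wall-shape
    abnormality detector would flag.
    """

    volume: Volume
    wall_mask: Mask
    tumor_mask: Mask
    inner_mask: Mask
    outer_mask: Mask
    candidate_mask: Mask
    lumen_mask: Mask
    invasion_depth_mm: float
    spec: PhantomSpec


def _unit_direction(azimuth_deg: float, polar_deg: float) -> np.ndarray:
    az, pol = np.deg2rad(azimuth_deg), np.deg2rad(polar_deg)
    return np.array([np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), np.cos(pol)])


def _correlated_field(shape, corr_len_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with given correlation length."""
    noise = rng.standard_normal(shape)
    if corr_len_vox > 1e-6:
        noise = ndimage.gaussian_filter(noise, corr_len_vox)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a phantom volume plus ground-truth masks.

    Deterministic: identical spec (including seed) gives bit-identical
    output.  The wall under the tumor footprint is thinned by exactly
    ``invasion_depth_mm`` (the excavation front follows an iso-distance
    surface from the lumen), with tumor tissue filling the excavation and
    protruding ``tumor_protrusion_mm`` into the lumen.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0

    idx = np.indices(shape).astype(float)
    pos_mm = (idx - center[:, None, None, None]) * sp[:, None, None, None]

    a, b, c = spec.lumen_radii_mm
    lumen = ((pos_mm[0] / a) ** 2 + (pos_mm[1] / b) ** 2 + (pos_mm[2] / c) ** 2) < 1.0

    # signed-distance bands give a wall of uniform physical thickness
    dist_out = ndimage.distance_transform_edt(~lumen, sampling=sp)
    dist_in = ndimage.distance_transform_edt(lumen, sampling=sp)
    wall_band = (dist_out > 0) & (dist_out <= spec.wall_thickness_mm)

    u = _unit_direction(*spec.tumor_center_angle)
    t_surf = 1.0 / np.sqrt((u[0] / a) ** 2 + (u[1] / b) ** 2 + (u[2] / c) ** 2)
    c_tumor_mm = u * t_surf
    ball = np.sqrt(((pos_mm - c_tumor_mm[:, None, None, None]) ** 2).sum(0)) \
        <= spec.tumor_radius_mm

    tumor = (ball & lumen & (dist_in <= spec.tumor_protrusion_mm))
    if spec.invasion_depth_mm > 0:
        tumor |= ball & wall_band & (dist_out <= spec.invasion_depth_mm)
    if not tumor.any():
        raise ValueError("tumor region is empty; check radius/protrusion")
    wall = wall_band & ~tumor
    lumen_clean = lumen & ~tumor
    organ = wall_band | tumor
    exterior = ~(lumen | wall_band)

    dist_to_tumor = ndimage.distance_transform_edt(~tumor, sampling=sp)
    candidate = organ & (dist_to_tumor <= spec.candidate_margin_mm)

    inner = ndimage.binary_dilation(organ) & lumen_clean
    outer = ndimage.binary_dilation(organ) & exterior
    if not (tumor & ndimage.binary_dilation(inner)).any():
        raise ValueError("tumor does not reach the inner surface")

    rng = np.random.default_rng(spec.seed)
    means = {"lumen": spec.lumen_intensity, "wall": spec.wall_intensity,
             "tumor": spec.tumor_intensity, "exterior": spec.exterior_intensity}
    regions = {"lumen": lumen_clean, "wall": wall, "tumor": tumor,
               "exterior": exterior}

    mean_map = np.zeros(shape)
    for name, mask in regions.items():
        mean_map[mask] = means[name][0]
    if spec.partial_volume:
        # 1-voxel-scale mixing at tissue interfaces ("weak boundary")
        mean_map = ndimage.gaussian_filter(mean_map, 0.6)

    data = mean_map.copy()
    for name, mask in regions.items():
        fld = _correlated_field(shape, spec.texture_params.get(name, 0.5), rng)
        data[mask] += means[name][1] * fld[mask]

    spacing = tuple(sp)
    vol = Volume(data, spacing)
    mk = lambda m: Mask.from_bool(m, vol)
    return PhantomTruth(
        volume=vol, wall_mask=mk(wall), tumor_mask=mk(tumor),
        inner_mask=mk(inner), outer_mask=mk(outer),
        candidate_mask=mk(candidate), lumen_mask=mk(lumen_clean),
        invasion_depth_mm=spec.invasion_depth_mm, spec=spec)


def sample_training_voxels(truth: PhantomTruth, n_per_class: int,
                           margin_mm: float = 1.0, seed: int = 0,
                           near_mm: float = 6.0):
    """Draw balanced tumor/wall voxel samples for classifier training.

    Tumor voxels come from the tumor eroded by ``margin_mm`` (emulating
    contours kept away from the wall interface); wall voxels come from wall
    tissue within ``near_mm`` of the candidate region but at least
    ``margin_mm`` from the tumor.  Returns two (n, 3) integer index arrays.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    sp = truth.volume.spacing
    dist_to_tumor = ndimage.distance_transform_edt(
        ~truth.tumor_mask.bool(), sampling=sp)
    dist_in_tumor = ndimage.distance_transform_edt(
        truth.tumor_mask.bool(), sampling=sp)

    tumor_pool = np.argwhere(dist_in_tumor > margin_mm)
    if len(tumor_pool) == 0:
        raise ValueError("no eligible tumor voxels (margin_mm too large)")
    dist_to_cand = ndimage.distance_transform_edt(
        ~truth.candidate_mask.bool(), sampling=sp)
    wall_pool = np.argwhere(truth.wall_mask.bool()
                            & (dist_to_cand <= near_mm)
                            & (dist_to_tumor >= margin_mm))
    if len(wall_pool) == 0:
        raise ValueError("no eligible wall voxels near the candidate region")
    for name, pool in (("tumor", tumor_pool), ("wall", wall_pool)):
        if n_per_class > len(pool):
            raise ValueError(
                f"requested {n_per_class} {name} voxels but only "
                f"{len(pool)} are eligible")
    rng = np.random.default_rng(seed)
    tumor_idx = tumor_pool[rng.choice(len(tumor_pool), n_per_class, replace=False)]
    wall_idx = wall_pool[rng.choice(len(wall_pool), n_per_class, replace=False)]
    return tumor_idx, wall_idx
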