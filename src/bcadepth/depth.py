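"""Invasion depth from post-excision wall thickness.

After the tumor is segmented it is excised from the wall domain: the lumen
grows into the excavated cavity and the inner surface is recomputed as the
lumen-facing shell of the residual wall.  On the re-solved thickness map,

* ``T_mean`` — mean wall thickness over inner-surface seeds away from the
  candidate region (excluding it avoids bias from the lesion),
* ``T_min``  — minimum residual thickness over seeds within the cancer
  footprint (the inner-surface projection of the excised tumor),
* ``T_ID``   — the invasion depth, ``T_mean - T_min``.

A healthy wall under the lesion (no invasion) gives T_ID near zero; a
thickened residual wall can give a negative T_ID, which is reported
as-is and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Mask
from .thickness import ThicknessMap, WallGeometry, geometry_from_regions

__all__ = ["DepthReport", "excise_cancer", "invasion_depth"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DepthReport:
    t_mean_mm: float
    t_min_mm: float
    t_id_mm: float
    n_seeds_normal: int
    n_seeds_cancer_footprint: int
    excluded_invalid: int
    negative_depth: bool = False

    def __post_init__(self):
        assert self.t_id_mm == self.t_mean_mm - self.t_min_mm


def excise_cancer(geom: WallGeometry, cancer_mask: Mask) -> WallGeometry:
    """Remove cancer voxels from the wall domain and recompute the surfaces.

    The excised cavity joins the lumen, so the new inner surface hugs the
    excavation.  Raises if cancer voxels lie outside the wall domain or if
    the excision breaches the wall (lumen and exterior become connected).
    """
    cancer = cancer_mask.bool()
    wall = geom.wall_mask.bool()
    if (cancer & ~wall).any():
        raise ValueError("cancer mask extends outside the wall domain")
    if not cancer.any():
        return geom

    new_wall = wall & ~cancer
    background = ~new_wall
    labels, n = ndimage.label(background)
    inner_labels = set(np.unique(labels[geom.inner_mask.bool()])) - {0}
    outer_labels = set(np.unique(labels[geom.outer_mask.bool()])) - {0}
    if inner_labels & outer_labels:
        raise ValueError("excision breaches the wall: lumen and exterior "
                         "are connected")
    lumen = np.isin(labels, sorted(inner_labels))

    # an imperfect segmentation can leave small wall fragments floating in
    # the excision cavity; they carry no thickness information, so fold
    # them into the cavity (lumen).  A large disconnected piece means the
    # wall annulus itself was broken, which is a genuine topology error.
    wlabels, wn = ndimage.label(new_wall, structure=_STRUCT26)
    if wn > 1:
        inner_adj = ndimage.binary_dilation(lumen)
        outer_adj = ndimage.binary_dilation(~(new_wall | lumen))
        sizes = ndimage.sum_labels(new_wall, wlabels, index=np.arange(1, wn + 1))
        for lab in range(1, wn + 1):
            comp = wlabels == lab
            if (comp & inner_adj).any() and (comp & outer_adj).any():
                continue
            if sizes[lab - 1] > 0.05 * new_wall.sum():
                raise ValueError(
                    f"excision disconnected a wall piece of "
                    f"{int(sizes[lab - 1])} voxels from the boundary surfaces")
            new_wall &= ~comp
            if (comp & inner_adj).any() or not (comp & outer_adj).any():
                lumen |= comp   # cavity debris joins the lumen
            # exterior-side debris simply leaves the wall domain
    new_geom = geometry_from_regions(new_wall, lumen, geom.wall_mask)
    new_geom.validate_topology()
    return new_geom


def _seed_footprint(seeds: np.ndarray, region: np.ndarray,
                    shape) -> np.ndarray:
    """Boolean per-seed flag: seed adjacent to ``region``, dilated by one
    voxel along the seed shell."""
    near = ndimage.binary_dilation(region, structure=_STRUCT26)
    flag = near[seeds[:, 0], seeds[:, 1], seeds[:, 2]]
    # dilate the flagged seed set by one voxel
    seed_mask = np.zeros(shape, dtype=bool)
    hit = seeds[flag]
    seed_mask[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    seed_mask = ndimage.binary_dilation(seed_mask, structure=_STRUCT26)
    return flag | seed_mask[seeds[:, 0], seeds[:, 1], seeds[:, 2]]


def invasion_depth(tmap: ThicknessMap, candidate_mask: Mask,
                   cancer_mask: Mask, t_min_domain: str = "cancer",
                   t_min_percentile: float | None = None) -> DepthReport:
    """Compute T_mean, T_min and T_ID from a post-excision thickness map.

    ``t_min_domain`` selects whether T_min is taken over the cancer
    footprint (default) or the whole candidate footprint;
    ``t_min_percentile`` optionally replaces the absolute minimum with a
    lower percentile for robustness to single-streamline outliers.
    """
    shape = candidate_mask.data.shape
    cancer = cancer_mask.bool()
    candidate = candidate_mask.bool() | cancer
    seeds = tmap.seeds
    cancer_fp = _seed_footprint(seeds, cancer, shape)
    cand_fp = _seed_footprint(seeds, candidate, shape)

    valid = tmap.valid
    normal = valid & ~cand_fp
    lesion = valid & (cancer_fp if t_min_domain == "cancer" else cand_fp)
    if not lesion.any():
        raise ValueError("no cancer seeds: the cancer footprint does not "
                         "touch the inner surface")
    if not normal.any():
        raise ValueError("no normal-wall seeds outside the candidate region")

    t = tmap.thickness_mm
    t_mean = float(np.mean(t[normal]))
    if t_min_percentile is None:
        t_min = float(np.min(t[lesion]))
    else:
        t_min = float(np.percentile(t[lesion], t_min_percentile))
    t_id = t_mean - t_min
    return DepthReport(
        t_mean_mm=t_mean, t_min_mm=t_min, t_id_mm=t_id,
        n_seeds_normal=int(normal.sum()),
        n_seeds_cancer_footprint=int(lesion.sum()),
        excluded_invalid=int((~valid).sum()),
        negative_depth=bool(t_id < 0))
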