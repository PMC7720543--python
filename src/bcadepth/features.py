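"""Per-voxel feature extraction: 1159 features per voxel.

Each voxel is described by 3 location features (its x, y, z indices) plus,
for each of 17 images (the original volume and 16 wavelet images), 20
intensity features and 48 texture features:

* wavelet images: a 2-level undecimated (stationary) 3D wavelet transform;
  each level contributes its approximation plus 7 detail subbands, all at
  the original shape, giving 16 voxel-aligned images.
* intensity features: the intensities of the voxel and its 6 face
  neighbours, the means of the in-plane 3x3 patches centred at those 7
  voxels, and the 6 centre-minus-neighbour differences.
* texture features: the responses of the 48-filter Leung-Malik bank
  (18 first-derivative + 18 second-derivative oriented Gaussian filters at
  6 orientations x 3 scales, 8 Laplacian-of-Gaussian, 4 Gaussian), applied
  as 2D convolutions on the axial slice with edge replication.

Feature columns have stable names and a fixed order, so matrices extracted
from different volumes are column-compatible for training and prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import fft as sfft
from scipy import ndimage

from .io import Volume

__all__ = ["ImageStack", "LMFilterBank", "FeatureExtractor", "wavelet_stack",
           "build_lm_bank", "intensity_features", "texture_features",
           "extract_features", "N_FEATURES", "SUBBAND_ORDER",
           "INTENSITY_FEATURE_NAMES"]

SUBBAND_ORDER = ("aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd")
_NEIGHBOR_TAGS = ("c", "xm", "xp", "ym", "yp", "zm", "zp")
INTENSITY_FEATURE_NAMES = tuple(
    [f"int_{t}" for t in _NEIGHBOR_TAGS]
    + [f"mean3_{t}" for t in _NEIGHBOR_TAGS]
    + [f"diff_{t}" for t in _NEIGHBOR_TAGS[1:]])
N_FEATURES = 3 + (20 + 48) * 17


@dataclass
class ImageStack:
    """17 same-shape images: the original plus 16 wavelet subbands."""

    images: list
    names: list

    def __post_init__(self):
        if len(self.images) != 17 or len(self.names) != 17:
            raise ValueError("stack must hold exactly 17 images")
        shape = self.images[0].shape
        if any(im.shape != shape for im in self.images):
            raise ValueError("all stack images must share one shape")


@dataclass
class LMFilterBank:
    """The 48 Leung-Malik texture kernels with canonical ordering."""

    kernels: list
    names: list

    def __post_init__(self):
        if len(self.kernels) != 48 or len(self.names) != 48:
            raise ValueError("LM bank must hold exactly 48 kernels")


def wavelet_stack(v: Volume, wavelet: str = "haar", levels: int = 2) -> ImageStack:
    """Decompose a volume into the 17-image stack (original + 16 subbands).

    Uses the undecimated 3D wavelet transform so every subband keeps the
    original shape (features stay voxel-aligned).  Axes are edge-padded to a
    multiple of 2**levels and cropped back after the transform.
    """
    data = np.asarray(v.data, dtype=float)
    wav = pywt.Wavelet(wavelet)
    if min(data.shape) < wav.dec_len:
        raise ValueError(
            f"volume shape {data.shape} smaller than wavelet support {wav.dec_len}")
    mult = 2 ** levels
    pad = [(0, (-n) % mult) for n in data.shape]
    padded = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=levels)
    sl = tuple(slice(0, n) for n in data.shape)
    images = [data]
    names = ["orig"]
    # swtn returns levels deepest-first; emit level 1 then level 2
    for lev, cd in enumerate(reversed(coeffs), start=1):
        for key in SUBBAND_ORDER:
            images.append(cd[key][sl])
            names.append(f"L{lev}_{key}")
    return ImageStack(images, names)


def _gauss1d(x: np.ndarray, sigma: float, order: int) -> np.ndarray:
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    if order == 0:
        return g
    if order == 1:
        return -x / sigma ** 2 * g
    if order == 2:
        return (x ** 2 - sigma ** 2) / sigma ** 4 * g
    raise ValueError(order)


def _oriented_kernel(support: int, sigma: float, theta_deg: float,
                     order: int, elongation: float = 3.0) -> np.ndarray:
    """Derivative-of-Gaussian kernel: envelope sigma*elongation along the
    filter axis, derivative of order ``order`` across it."""
    h = support // 2
    x, y = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    t = np.deg2rad(theta_deg)
    u = np.cos(t) * x + np.sin(t) * y       # along filter
    w = -np.sin(t) * x + np.cos(t) * y      # across filter
    k = _gauss1d(u, elongation * sigma, 0) * _gauss1d(w, sigma, order)
    k = k - k.mean()
    s = np.abs(k).sum()
    return k / s if s > 0 else k


def _log_kernel(support: int, sigma: float) -> np.ndarray:
    h = support // 2
    x, y = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    r2 = x ** 2 + y ** 2
    k = (r2 - 2 * sigma ** 2) / sigma ** 4 * np.exp(-r2 / (2 * sigma ** 2))
    k = k - k.mean()
    return k / np.abs(k).sum()


def _gauss_kernel(support: int, sigma: float) -> np.ndarray:
    h = support // 2
    x, y = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    k = np.exp(-(x ** 2 + y ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def build_lm_bank(scales=None, support: int = 49, sigma0: float = 1.0) -> LMFilterBank:
    """Build the 48-filter Leung-Malik bank.

    ``scales`` are the 3 oriented-filter sigmas (default sigma0*{1, sqrt2,
    2}); the LoG/Gaussian family extends the progression with a fourth
    basic scale 2*sqrt2*sigma0, with LoG additionally at 3x those scales.
    Orientations are 0, 30, ..., 150 degrees.
    """
    if support % 2 != 1:
        raise ValueError(f"support must be odd, got {support}")
    if scales is None:
        scales = tuple(sigma0 * np.sqrt(2.0) ** k for k in range(3))
    scales = tuple(float(s) for s in scales)
    if len(scales) != 3 or len(set(scales)) != 3:
        raise ValueError("exactly 3 distinct scales required")
    basic = scales + (scales[-1] * np.sqrt(2.0),)
    orients = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

    kernels, names = [], []
    for order, tag in ((1, "dgauss1"), (2, "dgauss2")):
        for s_i, sigma in enumerate(scales):
            for theta in orients:
                kernels.append(_oriented_kernel(support, sigma, theta, order))
                names.append(f"{tag}_s{s_i}_o{int(theta)}")
    for s_i, sigma in enumerate(basic):
        kernels.append(_log_kernel(support, sigma))
        names.append(f"log_s{s_i}")
    for s_i, sigma in enumerate(basic):
        kernels.append(_log_kernel(support, 3.0 * sigma))
        names.append(f"log3_s{s_i}")
    for s_i, sigma in enumerate(basic):
        kernels.append(_gauss_kernel(support, sigma))
        names.append(f"gauss_s{s_i}")
    return LMFilterBank(kernels, names)


def _intensity_block(img: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """(n, 20) intensity features; out-of-bounds neighbourhoods use edge
    replication, voxels themselves must lie inside the image."""
    voxels = np.asarray(voxels, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise ValueError("voxels must be an (n, 3) index array")
    if (voxels < 0).any() or (voxels >= np.asarray(img.shape)).any():
        raise IndexError("voxel outside the image")
    pad = np.pad(img, 1, mode="edge")
    # in-plane 3x3 means with edge replication
    means = ndimage.uniform_filter(img.astype(float), size=(3, 3, 1), mode="nearest")
    mpad = np.pad(means, 1, mode="edge")
    x, y, z = voxels.T + 1  # indices into padded arrays
    offs = [(0, 0, 0), (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
            (0, 0, -1), (0, 0, 1)]
    ints = np.stack([pad[x + dx, y + dy, z + dz] for dx, dy, dz in offs], axis=1)
    mns = np.stack([mpad[x + dx, y + dy, z + dz] for dx, dy, dz in offs], axis=1)
    diffs = ints[:, :1] - ints[:, 1:]
    return np.concatenate([ints, mns, diffs], axis=1)


def intensity_features(img: np.ndarray, voxel) -> np.ndarray:
    """The 20 intensity features of one voxel (7 + 7 + 6)."""
    return _intensity_block(np.asarray(img), np.asarray(voxel)[None, :])[0]


class _SliceConvolver:
    """Shared-FFT 2D convolution of axial slices with a kernel set.

    Convolution (kernel flipped) with edge replication: slices are
    edge-padded by the kernel half-support, then linearly convolved via one
    forward FFT per slice and precomputed kernel FFTs.
    """

    def __init__(self, kernels):
        self.kernels = [np.asarray(k, dtype=float) for k in kernels]
        self.half = self.kernels[0].shape[0] // 2
        self._kfft = {}

    def _kernel_ffts(self, fshape):
        if fshape not in self._kfft:
            self._kfft[fshape] = [sfft.rfftn(k, fshape) for k in self.kernels]
        return self._kfft[fshape]

    def responses(self, sl: np.ndarray) -> np.ndarray:
        """(48, nx, ny) responses for one 2D slice."""
        h = self.half
        padded = np.pad(sl.astype(float), h, mode="edge")
        fshape = tuple(sfft.next_fast_len(n + 2 * h) for n in padded.shape)
        sf = sfft.rfftn(padded, fshape)
        out = np.empty((len(self.kernels),) + sl.shape)
        kffts = self._kernel_ffts(fshape)
        for i, kf in enumerate(kffts):
            full = sfft.irfftn(sf * kf, fshape)
            out[i] = full[2 * h:2 * h + sl.shape[0], 2 * h:2 * h + sl.shape[1]]
        return out


def texture_features(img: np.ndarray, bank: LMFilterBank, voxel) -> np.ndarray:
    """The 48 LM-filter responses at one voxel (2D filtering of slice z)."""
    x, y, z = (int(c) for c in voxel)
    img = np.asarray(img)
    if not (0 <= x < img.shape[0] and 0 <= y < img.shape[1]
            and 0 <= z < img.shape[2]):
        raise IndexError("voxel outside the image")
    resp = _SliceConvolver(bank.kernels).responses(img[:, :, z])
    return resp[:, x, y]


class FeatureExtractor:
    """Computes the full 1159-column per-voxel feature matrix.

    Parameters
    ----------
    wavelet, levels : wavelet family and decomposition depth of the
        stationary transform (levels=2 with 8 subbands/level -> 16 images).
    lm_scales, lm_support, sigma0 : Leung-Malik bank geometry, in voxel
        units of the image grid.
    """

    def __init__(self, wavelet: str = "haar", levels: int = 2,
                 lm_scales=None, lm_support: int = 49, sigma0: float = 1.0):
        self.wavelet = wavelet
        self.levels = levels
        self.bank = build_lm_bank(lm_scales, lm_support, sigma0)
        self._conv = _SliceConvolver(self.bank.kernels)

    def column_names(self, stack_names=None):
        if stack_names is None:
            stack_names = ["orig"] + [f"L{lev}_{k}" for lev in (1, 2)
                                      for k in SUBBAND_ORDER]
        cols = ["loc_x", "loc_y", "loc_z"]
        for im in stack_names:
            cols += [f"{im}|{f}" for f in INTENSITY_FEATURE_NAMES]
            cols += [f"{im}|{f}" for f in self.bank.names]
        return cols

    def extract(self, v: Volume, voxels) -> pd.DataFrame:
        """Feature matrix for the given (n, 3) voxel index list."""
        voxels = np.asarray(voxels, dtype=int)
        if voxels.size == 0:
            raise ValueError("empty voxel list")
        if voxels.ndim != 2 or voxels.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) index array")
        stack = wavelet_stack(v, self.wavelet, self.levels)
        n = len(voxels)
        out = np.empty((n, N_FEATURES))
        out[:, :3] = voxels
        col = 3
        z_vals = np.unique(voxels[:, 2])
        for img in stack.images:
            out[:, col:col + 20] = _intensity_block(img, voxels)
            tex = np.empty((n, 48))
            for z in z_vals:
                rows = np.flatnonzero(voxels[:, 2] == z)
                resp = self._conv.responses(img[:, :, z])
                tex[rows] = resp[:, voxels[rows, 0], voxels[rows, 1]].T
            out[:, col + 20:col + 68] = tex
            col += 68
        cols = self.column_names(stack.names)
        index = pd.MultiIndex.from_arrays(voxels.T, names=["x", "y", "z"])
        return pd.DataFrame(out, columns=cols, index=index)


def extract_features(v: Volume, voxels, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`FeatureExtractor`."""
    return FeatureExtractor(**kwargs).extract(v, voxels)
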