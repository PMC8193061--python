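"""Texture features for grayscale images: wavelet subband statistics + GLCM.

The front end turns a single-channel raster into a fixed-length vector of
540 texture descriptors under the default configuration:

* 40 wavelet features — a 3-level 2-D ``db4`` decomposition yields 10
  subbands (1 approximation + 3 detail orientations x 3 levels); each
  subband contributes its coefficient mean, standard deviation, energy
  (sum of squares) and energy entropy.
* 500 co-occurrence features — gray-level co-occurrence matrices (GLCM)
  computed for 5 pixel distances {1..5} x 4 angles {0, 45, 90, 135 deg},
  each at 5 quantization settings {8, 16, 32, 64, 128 gray levels}; every
  (distance, angle, levels) combination contributes the 5 Haralick-style
  descriptors contrast, correlation, energy, homogeneity and entropy
  (5 x 4 x 5 x 5 = 500).

The exact split is a documented convention of this package; any alternative
composition is expressible through :class:`FeatureConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from skimage.feature import graycomatrix, graycoprops

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "wavelet_subband_stats",
    "glcm_stats",
    "extract_features",
    "standardize_features",
]

_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass(frozen=True)
class FeatureConfig:
    wavelet_name: str = "db4"
    decomposition_levels: int = 3
    glcm_distances: tuple = (1, 2, 3, 4, 5)
    glcm_angles_deg: tuple = (0.0, 45.0, 90.0, 135.0)
    glcm_levels: tuple = (8, 16, 32, 64, 128)
    glcm_props: tuple = _GLCM_PROPS

    @property
    def n_wavelet_features(self) -> int:
        return (3 * self.decomposition_levels + 1) * 4

    @property
    def n_glcm_features(self) -> int:
        return (
            len(self.glcm_distances)
            * len(self.glcm_angles_deg)
            * len(self.glcm_levels)
            * len(self.glcm_props)
        )

    @property
    def n_features(self) -> int:
        return self.n_wavelet_features + self.n_glcm_features


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a single-channel 2-D array")
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise ValueError("image must be at least 32 x 32")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if img.min() < 0:
        raise ValueError("image must be nonnegative")
    return img


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a discrete distribution; 0 log 0 = 0."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def wavelet_subband_stats(img: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Per-subband {mean, sd, energy, energy entropy} of a multilevel 2-D
    wavelet decomposition, ordered coarsest first."""
    img = _validate_image(img)
    min_side = min(img.shape)
    if min_side < 2**cfg.decomposition_levels:
        raise ValueError(
            f"image too small for {cfg.decomposition_levels}-level decomposition"
        )
    coeffs = pywt.wavedec2(img, cfg.wavelet_name, level=cfg.decomposition_levels)
    subbands = [coeffs[0]]
    for detail in coeffs[1:]:
        subbands.extend(detail)
    feats = []
    for band in subbands:
        band = np.asarray(band, dtype=float).ravel()
        energy = float(band @ band)
        p = band**2 / energy if energy > 0 else np.zeros_like(band)
        feats.extend([float(band.mean()), float(band.std()), energy, _entropy(p)])
    return np.asarray(feats)


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of the observed intensity range into ``levels``
    gray levels; a constant image maps to level 0 everywhere."""
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_stats(img: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Haralick-style descriptors of symmetric, normalized co-occurrence
    matrices over every (distance, angle, quantization) combination."""
    img = _validate_image(img)
    if any(lv < 2 for lv in cfg.glcm_levels):
        raise ValueError("glcm levels must be >= 2")
    angles = [np.deg2rad(a) for a in cfg.glcm_angles_deg]
    feats = []
    for levels in cfg.glcm_levels:
        q = _quantize(img, levels)
        constant = q.max() == q.min()
        glcm = graycomatrix(
            q, distances=cfg.glcm_distances, angles=angles, levels=levels,
            symmetric=True, normed=True,
        )
        prop_cache = {}
        for prop in cfg.glcm_props:
            if prop == "entropy":
                continue
            prop_cache[prop] = graycoprops(glcm, prop)
        for di in range(len(cfg.glcm_distances)):
            for ai in range(len(angles)):
                P = glcm[:, :, di, ai]
                for prop in cfg.glcm_props:
                    if prop == "entropy":
                        feats.append(_entropy(P.ravel()))
                    elif prop == "correlation" and constant:
                        # undefined on a zero-variance image; reported as 0
                        logger.debug("GLCM correlation undefined for constant image; set to 0")
                        feats.append(0.0)
                    else:
                        feats.append(float(prop_cache[prop][di, ai]))
    return np.asarray(feats)


def extract_features(img: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Concatenated [wavelet, GLCM] texture vector; 540 values by default."""
    v = np.concatenate([wavelet_subband_stats(img, cfg), glcm_stats(img, cfg)])
    assert v.shape[0] == cfg.n_features
    return v


def standardize_features(
    table: np.ndarray, mean: np.ndarray = None, sd: np.ndarray = None
) -> tuple:
    """Zero-mean unit-variance scaling across a training set.

    ``table`` is feature-by-sample.  Returns ``(scaled, mean, sd)``;
    zero-variance features are left centered but unscaled.  Pass the
    returned ``mean``/``sd`` to apply a training-set scaling to new data.
    """
    table = np.asarray(table, dtype=float)
    if mean is None:
        mean = table.mean(axis=1)
        sd = table.std(axis=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (table - mean[:, None]) / sd_safe[:, None], mean, sd
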