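"""GLCM texture and texture-derivative analysis of parametric maps.

First pass: grey-level co-occurrence matrices of quantized QUS parametric
maps yield four Haralick features — contrast (CON), correlation (COR),
homogeneity (HOM) and energy (ENE).  Sliding-window evaluation of those
features produces texture maps; a second GLCM pass over each texture map
yields the "texture derivative" features (16 per parametric map: 4 second-
pass features of each of 4 first-pass maps).

Feature dialects (these differ across libraries, so they are pinned here):
HOM is the inverse difference moment with |i−j| in the denominator,
``sum P / (1 + |i-j|)``; ENE is the angular second moment ``sum P**2`` (not
its square root); COR is defined as 0 for degenerate (zero-variance)
matrices.  GLCMs are symmetric, averaged over the configured angles, and
normalized to sum 1.  Pixels outside a map's validity mask never contribute
to pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .maps import ParametricMap

__all__ = [
    "GLCMConfig",
    "TextureFeatures",
    "TEXTURE_FEATURE_NAMES",
    "quantize",
    "glcm",
    "glcm_features",
    "texture_map",
    "texture_derivative",
]

TEXTURE_FEATURE_NAMES = ("CON", "COR", "HOM", "ENE")


@dataclass(frozen=True)
class GLCMConfig:
    """Haralick-standard defaults: 16 levels, distance 1, four angles,
    symmetric counting.  ``quantization_range`` fixes the bin span per
    parameter; None means data-driven min/max of the valid pixels."""

    grey_levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    quantization_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.grey_levels < 2:
            raise ValueError("grey_levels must be at least 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1 pixel")


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    homogeneity: float
    energy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "CON": self.contrast,
            "COR": self.correlation,
            "HOM": self.homogeneity,
            "ENE": self.energy,
        }


def quantize(
    values: np.ndarray,
    config: GLCMConfig,
    validity_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear binning of valid pixels into ``grey_levels`` bins.

    Returns ``(levels, valid)``.  Binning spans ``quantization_range`` when
    configured, else the data min/max; the top bin is right-closed so the
    range maximum lands in bin ``grey_levels - 1``.  A degenerate range
    (max == min) maps every pixel to bin 0.  Invalid pixels get level 0 but
    stay flagged invalid and are excluded from pair counting downstream.
    """
    values = np.asarray(values, dtype=float)
    if validity_mask is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(validity_mask, dtype=bool) & np.isfinite(values)
    if not valid.any():
        raise ValueError("no valid pixels to quantize")
    if config.quantization_range is not None:
        lo, hi = config.quantization_range
    else:
        lo, hi = float(values[valid].min()), float(values[valid].max())
    levels = np.zeros(values.shape, dtype=np.uint16)
    if hi > lo:
        scaled = (values - lo) / (hi - lo) * config.grey_levels
        levels[valid] = np.clip(
            np.floor(scaled[valid]).astype(int), 0, config.grey_levels - 1
        ).astype(np.uint16)
    return levels, valid


def glcm(
    levels: np.ndarray,
    config: GLCMConfig,
    validity_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized co-occurrence matrix averaged over distances and angles.

    Invalid pixels are excluded by recoding them to a sentinel level and
    striking the sentinel's row and column before normalization.
    """
    levels = np.asarray(levels)
    if validity_mask is None:
        valid = np.ones(levels.shape, dtype=bool)
    else:
        valid = np.asarray(validity_mask, dtype=bool)
    if levels.max(initial=0) >= config.grey_levels:
        raise ValueError("image contains levels outside the configured range")
    L = config.grey_levels
    coded = np.where(valid, levels, L).astype(np.uint16)
    angles = [np.deg2rad(a) for a in config.angles_deg]
    counts = graycomatrix(
        coded,
        distances=list(config.distances),
        angles=angles,
        levels=L + 1,
        symmetric=config.symmetric,
        normed=False,
    ).astype(float)
    counts = counts[:L, :L, :, :]  # drop sentinel pairs
    total = counts.sum(axis=(0, 1), keepdims=True)
    if not (total > 0).all():
        raise ValueError("no valid pixel pairs at the configured offsets")
    return (counts / total).mean(axis=(2, 3))


def glcm_features(P: np.ndarray) -> TextureFeatures:
    """Contrast, correlation, homogeneity and energy of a normalized GLCM."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(np.sum((i - j) ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    energy = float(np.sum(P**2))
    mu_i = float(np.sum(i * P))
    mu_j = float(np.sum(j * P))
    var_i = float(np.sum((i - mu_i) ** 2 * P))
    var_j = float(np.sum((j - mu_j) ** 2 * P))
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j)
        )
    return TextureFeatures(contrast, correlation, homogeneity, energy)


def region_texture(pmap: ParametricMap, config: GLCMConfig) -> TextureFeatures:
    """Whole-region texture: one GLCM over the map's valid pixels."""
    levels, valid = quantize(pmap.values, config, pmap.validity_mask)
    return glcm_features(glcm(levels, config, valid))


def texture_map(
    pmap: ParametricMap,
    config: GLCMConfig,
    texture_window: int = 5,
    step: int = 1,
) -> dict[str, ParametricMap]:
    """Sliding-window texture maps (CON/COR/HOM/ENE) of a parametric map.

    Quantization happens once over the whole map (so windows share a level
    scale); each window needs at least 70% valid pixels and one valid pair
    to contribute.  Output dimensions follow
    ``floor((extent - window) / step) + 1``.
    """
    if texture_window < 3:
        raise ValueError("texture_window must be at least 3 map pixels")
    nz, nx = pmap.values.shape
    if texture_window > nz or texture_window > nx:
        raise ValueError("texture window larger than the parametric map")
    levels, valid = quantize(pmap.values, config, pmap.validity_mask)

    z_starts = np.arange(0, nz - texture_window + 1, step)
    x_starts = np.arange(0, nx - texture_window + 1, step)
    shape = (len(z_starts), len(x_starts))
    out = {name: np.full(shape, np.nan) for name in TEXTURE_FEATURE_NAMES}
    out_valid = np.zeros(shape, dtype=bool)
    min_valid = 0.7 * texture_window**2
    for a, z0 in enumerate(z_starts):
        for b, x0 in enumerate(x_starts):
            w_valid = valid[z0 : z0 + texture_window, x0 : x0 + texture_window]
            if w_valid.sum() < min_valid:
                continue
            w_levels = levels[z0 : z0 + texture_window, x0 : x0 + texture_window]
            try:
                feats = glcm_features(glcm(w_levels, config, w_valid))
            except ValueError:  # no valid pair at the offset
                continue
            for name, value in feats.as_dict().items():
                out[name][a, b] = value
            out_valid[a, b] = True
    if not out_valid.any():
        raise ValueError("no texture window with enough valid pixels")

    centres_z = pmap.centres_z[z_starts + texture_window // 2]
    centres_x = pmap.centres_x[x_starts + texture_window // 2]
    return {
        name: ParametricMap(
            values=out[name],
            validity_mask=out_valid,
            centres_z=centres_z,
            centres_x=centres_x,
            window_size=texture_window * pmap.step,
            step=step * pmap.step,
            parameter_name=f"{pmap.parameter_name}-{name}",
            region=pmap.region,
        )
        for name in TEXTURE_FEATURE_NAMES
    }


def texture_derivative(
    texture_maps: dict[str, ParametricMap],
    config: GLCMConfig | None = None,
) -> dict[str, float]:
    """Second-pass GLCM features of each texture map.

    Returns 16 values named ``<param>-<firstpass>-<secondpass>`` (e.g.
    ``MBF-CON-ENE``).  Second-pass quantization is always data-driven
    min/max of the texture map — first-pass parameter ranges do not apply.
    """
    if config is None:
        config = GLCMConfig()
    second = GLCMConfig(
        grey_levels=config.grey_levels,
        distances=config.distances,
        angles_deg=config.angles_deg,
        symmetric=config.symmetric,
        quantization_range=None,
    )
    out: dict[str, float] = {}
    for first_name, tmap in texture_maps.items():
        feats = region_texture(tmap, second)
        for second_name, value in feats.as_dict().items():
            out[f"{tmap.parameter_name}-{second_name}"] = value
    return out
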