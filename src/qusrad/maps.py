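"""Sliding-window parametric maps of the five QUS parameters.

A window grid is tiled over the frame with step = window * (1 - overlap);
a window contributes one map pixel iff at least 70% of its RF pixels lie
inside the region mask.  Per-window values come from reference-phantom
normalized spectra: MBF/SS/SI from the linear spectral fit, ASD/AAC from the
backscatter-coefficient inversion.  The map grid is the window-centre
lattice (coordinates in mm), not the RF grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AcquisitionConfig, PhantomFrame, make_margin_mask
from .spectral import (
    DEFAULT_BAND,
    estimate_bsc,
    fit_asd_aac,
    linear_spectral_fit,
    normalize_spectrum,
    power_spectrum,
)

__all__ = ["ParametricMap", "QUS_PARAMETERS", "compute_qus_maps", "sliding_window_map", "map_pair"]

QUS_PARAMETERS = ("MBF", "SS", "SI", "ASD", "AAC")

#: display/quantization ranges used for clinical-style map rendering
#: (dB, dB/cm^3, um); SS/SI have no conventional fixed range
PARAMETER_DISPLAY_RANGES = {
    "MBF": (-9.6, 35.9),
    "AAC": (20.4, 179.6),
    "ASD": (85.0, 198.0),
}

#: minimum fraction of a window inside the region mask for it to contribute
WINDOW_INSIDE_FRACTION = 0.7


@dataclass
class ParametricMap:
    """Masked 2-D map of one QUS parameter over a region.

    ``values`` is indexed (axial window × lateral window); entries are
    meaningful only where ``validity_mask`` is true.  ``centres_z`` /
    ``centres_x`` give window-centre coordinates in mm.
    """

    values: np.ndarray
    validity_mask: np.ndarray
    centres_z: np.ndarray
    centres_x: np.ndarray
    window_size: float
    step: float
    parameter_name: str
    region: str

    def __post_init__(self) -> None:
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask shapes differ")
        if self.validity_mask.any() and not np.all(
            np.isfinite(self.values[self.validity_mask])
        ):
            raise ValueError("non-finite values inside the validity mask")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.validity_mask]


def _window_grid(
    config: AcquisitionConfig, window_mm: float, overlap: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    step_mm = window_mm * (1.0 - overlap)
    wz = int(round(window_mm / config.axial_spacing))
    wx = max(2, int(round(window_mm / config.lateral_spacing)))
    sz = max(1, int(round(step_mm / config.axial_spacing)))
    sx = max(1, int(round(step_mm / config.lateral_spacing)))
    z_starts = np.arange(0, config.n_axial - wz + 1, sz)
    x_starts = np.arange(0, config.line_count - wx + 1, sx)
    return z_starts, x_starts, wz, wx


def compute_qus_maps(
    frame: PhantomFrame,
    region_mask: np.ndarray,
    reference: PhantomFrame,
    window_size: float = 2.0,
    overlap: float = 0.8,
    band: tuple[float, float] | None = None,
    region: str = "core",
    min_inside: float = WINDOW_INSIDE_FRACTION,
) -> dict[str, ParametricMap]:
    """All five parametric maps over one region in a single window sweep.

    The reference spectrum for each window depth is the periodogram averaged
    over the reference frame's full lateral aperture at the same axial rows
    (lower variance than matching the sample's window width).
    """
    config = frame.config
    if band is None:
        band = (config.band_low, config.band_high)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != frame.rf.shape:
        raise ValueError("region mask must live on the RF grid")
    if "reference" in reference.truth:
        ref_params = reference.truth["reference"]
    else:
        ref_params = reference.truth["background"]

    z_starts, x_starts, wz, wx = _window_grid(config, window_size, overlap)
    if len(z_starts) == 0 or len(x_starts) == 0:
        raise ValueError(
            f"window of {window_size} mm does not fit inside the frame; "
            "use a smaller window"
        )
    n_inside = np.zeros((len(z_starts), len(x_starts)), dtype=int)
    for i, z0 in enumerate(z_starts):
        for j, x0 in enumerate(x_starts):
            n_inside[i, j] = region_mask[z0 : z0 + wz, x0 : x0 + wx].sum()
    valid = n_inside >= min_inside * wz * wx
    if not valid.any():
        raise ValueError(
            f"region holds no {window_size} mm window at >= {min_inside:.0%} "
            "coverage; use a smaller window"
        )

    values = {p: np.full(valid.shape, np.nan) for p in QUS_PARAMETERS}
    ref_cache: dict[int, object] = {}
    for i, z0 in enumerate(z_starts):
        if not valid[i].any():
            continue
        if z0 not in ref_cache:
            ref_cache[z0] = power_spectrum(reference.rf[z0 : z0 + wz, :], config)
        ref_spec = ref_cache[z0]
        for j, x0 in enumerate(x_starts):
            if not valid[i, j]:
                continue
            spec = power_spectrum(frame.rf[z0 : z0 + wz, x0 : x0 + wx], config)
            fit = linear_spectral_fit(normalize_spectrum(spec, ref_spec), band)
            values["MBF"][i, j] = fit.MBF
            values["SS"][i, j] = fit.SS
            values["SI"][i, j] = fit.SI
            bsc = estimate_bsc(spec, ref_spec, ref_params, config)
            est = fit_asd_aac(bsc, band, config.speed_of_sound)
            values["ASD"][i, j] = est.ASD
            values["AAC"][i, j] = est.AAC

    centres_z = (z_starts + wz / 2.0) * config.axial_spacing
    centres_x = (x_starts + wx / 2.0) * config.lateral_spacing
    step = window_size * (1.0 - overlap)
    return {
        p: ParametricMap(
            values=values[p],
            validity_mask=valid,
            centres_z=centres_z,
            centres_x=centres_x,
            window_size=window_size,
            step=step,
            parameter_name=p,
            region=region,
        )
        for p in QUS_PARAMETERS
    }


def sliding_window_map(
    frame: PhantomFrame,
    region_mask: np.ndarray,
    parameter: str,
    reference: PhantomFrame,
    window_size: float = 2.0,
    overlap: float = 0.8,
    **kwargs,
) -> ParametricMap:
    """One parametric map; thin wrapper over :func:`compute_qus_maps`."""
    if parameter not in QUS_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; choose from {QUS_PARAMETERS}")
    return compute_qus_maps(
        frame, region_mask, reference, window_size=window_size, overlap=overlap, **kwargs
    )[parameter]


def map_pair(
    frame: PhantomFrame,
    core_mask: np.ndarray,
    reference: PhantomFrame,
    margin_width: float = 5.0,
    window_size: float = 2.0,
    overlap: float = 0.8,
    band: tuple[float, float] | None = None,
) -> dict[str, dict[str, ParametricMap]]:
    """Five-parameter maps for the tumour core and its surrounding margin.

    The margin is the band of tissue within ``margin_width`` mm outside the
    core boundary (5 mm default).  Returns ``{'core': {...}, 'margin':
    {...}}`` with one map per QUS parameter in each region; the two regions'
    valid windows are disjoint by the inclusion rule applied to disjoint
    masks.
    """
    config = frame.config
    core_mask = np.asarray(core_mask, dtype=bool)
    margin_mask = make_margin_mask(
        core_mask, margin_width, (config.axial_spacing, config.lateral_spacing)
    )
    core_maps = compute_qus_maps(
        frame, core_mask, reference, window_size, overlap, band, region="core"
    )
    margin_maps = compute_qus_maps(
        frame, margin_mask, reference, window_size, overlap, band, region="margin"
    )
    return {"core": core_maps, "margin": margin_maps}
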