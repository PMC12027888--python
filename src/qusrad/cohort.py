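"""Synthetic patient cohorts with a known response effect.

Each synthetic "patient" is one simulated RF frame: an elliptical tumour
core inside background tissue, plus a matched uniform reference phantom.
Responders and non-responders differ only in the core-versus-margin
acoustic-concentration contrast — responders carry a strong core AAC excess
over background, non-responders essentially none — while every other
microstructural parameter varies patient-to-patient identically in both
groups.  The full feature pipeline (maps → texture → derivatives →
201-feature registry) is then run per patient, so classifier tests exercise
the same code path as real data would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import MolecularSubtype, assemble_features, default_registry
from .maps import map_pair
from .model import encode_subtypes
from .phantom import AcquisitionConfig, TissueClassParams, generate_phantom, generate_reference
from .spectral import estimate_attenuation, normalize_spectrum, power_spectrum
from .texture import GLCMConfig

__all__ = ["CohortConfig", "simulate_patient", "generate_cohort", "cohort_table"]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Responders get a core AAC ``responder_contrast_db`` above background
    (non-responders ``nonresponder_contrast_db``); background AAC and both
    regions' scatterer diameters vary between patients.  Frame geometry is
    sized so a 5 mm margin around the core fits the field of view.
    """

    responder_contrast_db: float = 15.0
    nonresponder_contrast_db: float = 2.0
    contrast_sd_db: float = 2.0
    background_aac_db: float = 55.0
    background_aac_sd_db: float = 3.0
    asd_mean_um: float = 140.0
    asd_sd_um: float = 12.0
    core_radius_mm: float = 3.5
    margin_width_mm: float = 5.0
    frame_extent_mm: float = 20.0
    line_count: int = 80
    window_mm: float = 2.0
    overlap: float = 0.5
    snr_db: float = 30.0
    responder_fraction: float = 0.5


def _acquisition(config: CohortConfig) -> AcquisitionConfig:
    return AcquisitionConfig(
        axial_extent=config.frame_extent_mm,
        lateral_extent=config.frame_extent_mm,
        line_count=config.line_count,
    )


def simulate_patient(
    responder: bool,
    seed: int,
    config: CohortConfig | None = None,
    registry: list[tuple[str, str]] | None = None,
):
    """Simulate one patient frame and extract its feature vector."""
    if config is None:
        config = CohortConfig()
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(seed)
    acq = _acquisition(config)

    bg_aac = rng.normal(config.background_aac_db, config.background_aac_sd_db)
    contrast = rng.normal(
        config.responder_contrast_db if responder else config.nonresponder_contrast_db,
        config.contrast_sd_db,
    )
    core_asd = float(np.clip(rng.normal(config.asd_mean_um, config.asd_sd_um), 60, 350))
    bg_asd = float(np.clip(rng.normal(config.asd_mean_um, config.asd_sd_um), 60, 350))

    core = TissueClassParams(
        effective_scatterer_diameter=core_asd, acoustic_concentration=bg_aac + contrast
    )
    background = TissueClassParams(
        effective_scatterer_diameter=bg_asd, acoustic_concentration=bg_aac
    )
    ref_params = TissueClassParams(
        effective_scatterer_diameter=100.0, acoustic_concentration=50.0
    )

    centre = config.frame_extent_mm / 2.0
    geometry = (centre, centre, config.core_radius_mm, config.core_radius_mm)
    frame = generate_phantom(
        acq, core, background, geometry, seed=seed, snr_db=config.snr_db
    )
    reference = generate_reference(acq, ref_params, seed=seed + 1_000_003)

    maps = map_pair(
        frame,
        frame.core_mask,
        reference,
        margin_width=config.margin_width_mm,
        window_size=config.window_mm,
        overlap=config.overlap,
    )

    # whole-frame spectral-difference attenuation over three depth windows
    wlen = int(3.0 / acq.axial_spacing)
    specs, depths = [], []
    for z0 in np.linspace(0, acq.n_axial - wlen, 3).astype(int):
        sw = power_spectrum(frame.rf[z0 : z0 + wlen, :], acq)
        rw = power_spectrum(reference.rf[z0 : z0 + wlen, :], acq)
        specs.append(normalize_spectrum(sw, rw))
        depths.append((z0 + wlen / 2.0) * acq.axial_spacing / 10.0)
    attenuation = estimate_attenuation(specs, np.array(depths))

    subtype = list(MolecularSubtype)[int(rng.integers(0, 4))]
    return assemble_features(
        maps["core"],
        maps["margin"],
        attenuation,
        subtype=subtype,
        registry=registry,
        glcm_config=GLCMConfig(),
        tumour_id=f"synthetic-{seed}",
    )


def generate_cohort(
    n: int,
    seed: int,
    config: CohortConfig | None = None,
    registry: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table and labels for ``n`` synthetic patients.

    Returns ``(X, y)``: X holds the registry features plus one-hot subtype
    columns; y is 'R'/'NR'.  Class assignment is deterministic in (n, seed).
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    n_resp = int(round(n * config.responder_fraction))
    labels = np.array(["R"] * n_resp + ["NR"] * (n - n_resp))
    rng.shuffle(labels)
    patient_seeds = rng.integers(0, 2**31 - 1, size=n)

    rows, subtypes, ids = [], [], []
    for label, pseed in zip(labels, patient_seeds):
        fv = simulate_patient(label == "R", int(pseed), config, registry)
        rows.append(fv.to_series())
        subtypes.append(fv.subtype)
        ids.append(fv.tumour_id)
    X = pd.DataFrame(rows, index=ids)
    X = pd.concat([X, encode_subtypes(pd.Series(subtypes, index=ids))], axis=1)
    y = pd.Series(labels, index=ids, name="response")
    return X, y


def cohort_table(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Feature table with the response column appended (CSV-ready)."""
    out = X.copy()
    out["response"] = y
    return out
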