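import numpy as np
import pytest

from qusrad.maps import map_pair
from qusrad.phantom import AcquisitionConfig, TissueClassParams, generate_phantom, generate_reference
from qusrad.validation import load_cohort


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Small frame used by most simulation tests (14 x 14 mm, 56 lines)."""
    return AcquisitionConfig(axial_extent=14.0, lateral_extent=14.0, line_count=56)


@pytest.fixture(scope="session")
def contrast_frame(acq):
    """Phantom with a strong core AAC excess and its reference."""
    core = TissueClassParams(effective_scatterer_diameter=150.0, acoustic_concentration=70.0)
    background = TissueClassParams(effective_scatterer_diameter=120.0, acoustic_concentration=52.0)
    ref = TissueClassParams(effective_scatterer_diameter=100.0, acoustic_concentration=50.0)
    frame = generate_phantom(acq, core, background, (7.0, 7.0, 3.0, 3.0), seed=7)
    reference = generate_reference(acq, ref, seed=11)
    return frame, reference


@pytest.fixture(scope="session")
def contrast_maps(contrast_frame):
    frame, reference = contrast_frame
    return map_pair(
        frame, frame.core_mask, reference, margin_width=3.0, window_size=2.0, overlap=0.5
    )


@pytest.fixture(scope="session")
def cohort_df():
    return load_cohort()


def brute_force_glcm(levels, valid, grey_levels, distances, angles_deg, symmetric):
    """Independent pair-enumeration GLCM oracle (matches the offset
    convention of the implementation: displacement (d·sin θ, d·cos θ))."""
    levels = np.asarray(levels)
    valid = np.asarray(valid, dtype=bool)
    nz, nx = levels.shape
    mats = []
    for d in distances:
        for ang in angles_deg:
            theta = np.deg2rad(ang)
            dr = int(round(d * np.sin(theta)))
            dc = int(round(d * np.cos(theta)))
            P = np.zeros((grey_levels, grey_levels))
            for r in range(nz):
                for c in range(nx):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < nz and 0 <= c2 < nx):
                        continue
                    if not (valid[r, c] and valid[r2, c2]):
                        continue
                    P[levels[r, c], levels[r2, c2]] += 1
            if symmetric:
                P = P + P.T
            total = P.sum()
            if total == 0:
                return None
            mats.append(P / total)
    return np.mean(mats, axis=0)
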