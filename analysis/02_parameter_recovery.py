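"""Recover scatterer size and concentration from simulated phantoms.

For phantoms with known effective scatterer diameter (ASD) and acoustic
concentration (AAC), runs the full sliding-window estimation pipeline
(reference-phantom normalization, backscatter-coefficient inversion) and
tabulates the recovery error over seeds.  Writes
results/parameter_recovery.csv.
"""

import os

import numpy as np
import pandas as pd

from qusrad.maps import compute_qus_maps
from qusrad.phantom import AcquisitionConfig, TissueClassParams, generate_reference

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

acq = AcquisitionConfig(axial_extent=14.0, lateral_extent=14.0, line_count=56)
ref_params = TissueClassParams(effective_scatterer_diameter=100.0, acoustic_concentration=50.0)

rows = []
for asd_true, aac_true in [(100.0, 55.0), (150.0, 60.0), (180.0, 65.0)]:
    truth = TissueClassParams(
        effective_scatterer_diameter=asd_true, acoustic_concentration=aac_true
    )
    for seed in range(10):
        frame = generate_reference(acq, truth, seed=seed)
        reference = generate_reference(acq, ref_params, seed=seed + 10_000)
        maps = compute_qus_maps(
            frame, np.ones_like(frame.rf, dtype=bool), reference,
            window_size=2.0, overlap=0.5,
        )
        rows.append(
            {
                "asd_true_um": asd_true,
                "aac_true_db": aac_true,
                "seed": seed,
                "asd_est_um": float(np.mean(maps["ASD"].valid_values)),
                "aac_est_db": float(np.mean(maps["AAC"].valid_values)),
                "mbf_db": float(np.mean(maps["MBF"].valid_values)),
                "ss_db_mhz": float(np.mean(maps["SS"].valid_values)),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(os.path.join(OUT, "parameter_recovery.csv"), index=False)

summary = table.groupby("asd_true_um").agg(
    asd_mean=("asd_est_um", "mean"), aac_mean=("aac_est_db", "mean"),
    aac_true=("aac_true_db", "first"), ss_mean=("ss_db_mhz", "mean"),
)
print(summary.round(2))
for asd_true, row in summary.iterrows():
    err = abs(row["asd_mean"] - asd_true) / asd_true * 100
    print(f"ASD {asd_true:.0f} um -> {row['asd_mean']:.1f} um ({err:.1f}% error); "
          f"AAC {row['aac_true']:.0f} dB -> {row['aac_mean']:.1f} dB")
print("note the spectral slope steepens (more negative) as the true scatterer size grows")
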