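"""Published benchmark resolution measurements.

Radial (RR) and tangential (TR) FWHM of eight coplanar point sources at
radii 2-9 cm from isocenter, measured on a clinical SPECT/CT system
(5/8 inch NaI(Tl) detector, low-energy high-resolution collimator, 99mTc)
reconstructed with 3D OSEM at 10 iterations x 18 subsets and 1.8 mm voxels,
for the three activity distributions: sources in air, in a cold (inactive
water) background, and in a warm (low-activity water) background.

These numbers are scanner- and vendor-algorithm-specific; the package uses
them as a benchmark table for its trend statistics, not as simulation
targets.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ResolutionRecord

_ROWS = [
    # radius_cm, air RR, air TR, cold RR, cold TR, warm RR, warm TR  (mm)
    (2, 5.69, 6.42, 6.28, 6.17, 17.72, 14.94),
    (3, 4.83, 5.82, 5.18, 5.10, 16.14, 15.32),
    (4, 5.07, 6.17, 5.45, 5.35, 15.14, 12.60),
    (5, 4.65, 5.92, 5.74, 5.08, 12.74, 10.07),
    (6, 4.97, 5.57, 4.94, 4.83, 12.03, 9.17),
    (7, 4.90, 5.29, 4.85, 3.98, 11.70, 8.41),
    (8, 4.26, 5.03, 4.96, 4.40, 11.85, 8.33),
    (9, 4.52, 5.38, 4.38, 3.76, 8.10, 7.71),
]


def benchmark_resolution_table() -> pd.DataFrame:
    """The benchmark RR/TR table as a tidy DataFrame (radius in cm, mm FWHM)."""
    return pd.DataFrame(
        _ROWS,
        columns=["radius_cm", "air_rr_mm", "air_tr_mm", "cold_rr_mm",
                 "cold_tr_mm", "warm_rr_mm", "warm_tr_mm"],
    )


def benchmark_records(medium: str) -> list[ResolutionRecord]:
    """Benchmark rows as ResolutionRecords for one medium (air/cold/warm)."""
    if medium not in ("air", "cold", "warm"):
        raise ValueError(f"unknown medium {medium!r}")
    df = benchmark_resolution_table()
    return [
        ResolutionRecord(radius_cm=row["radius_cm"],
                         rr_mm=row[f"{medium}_rr_mm"],
                         tr_mm=row[f"{medium}_tr_mm"])
        for _, row in df.iterrows()
    ]
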