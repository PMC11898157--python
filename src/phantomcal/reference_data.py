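"""Published reference measurements for the five-insert polymer phantom.

These are the validation inputs for the density-calibration workflow: the
certified mass and the two independent volume measurements (laser scan and CT
scan) of each polymer insert, plus the mean femur densities from the published
12-scan factorial sensitivity study of scanner settings.  They are inputs, not
fitted values — everything derived from them (densities, σ, 6σ) is recomputed
at run time.
"""

from __future__ import annotations

# (material, manufacturer density g/cc, mass g, laser-scan volume mm³, CT-scan volume mm³)
INSERT_MEASUREMENTS: list[tuple[str, float, float, float, float]] = [
    ("Nylon", 1.14, 10.25, 8925.62, 8863.84),
    ("PEEK", 1.32, 10.87, 8265.49, 8286.66),
    ("Acetal", 1.42, 11.98, 8444.13, 8391.10),
    ("PPS", 1.64, 14.12, 8593.82, 8808.03),
    ("PTFE", 2.18, 18.21, 8414.74, 8546.67),
]

#: Certified insert densities (g/cc) used for calibration: the mean of the
#: laser-scan and CT-scan mass/volume densities, rounded to 2 dp for display.
#: Unrounded values are recomputed from INSERT_MEASUREMENTS where needed.
CERTIFIED_DENSITIES_GCC: dict[str, float] = {
    "Nylon": 1.15,
    "PEEK": 1.31,
    "Acetal": 1.42,
    "PPS": 1.62,
    "PTFE": 2.15,
}

# Full-factorial sensitivity study: voltage (kV) x exposure (ms) x filter,
# voltage slowest, filter fastest, and the published mean mapped femur density
# (g/cc) for each of the 12 scans.
FACTORIAL_LEVELS = {
    "voltage_kv": [100.0, 110.0],
    "exposure_ms": [80.0, 100.0],
    "filter": ["no", "0.25 mm Cu", "0.25 mm Sn"],
}

FACTORIAL_MEAN_DENSITIES_GCC: list[tuple[int, float, float, str, float]] = [
    (1, 100.0, 80.0, "no", 1.528),
    (2, 100.0, 80.0, "0.25 mm Cu", 1.530),
    (3, 100.0, 80.0, "0.25 mm Sn", 1.525),
    (4, 100.0, 100.0, "no", 1.526),
    (5, 100.0, 100.0, "0.25 mm Cu", 1.567),
    (6, 100.0, 100.0, "0.25 mm Sn", 1.580),
    (7, 110.0, 80.0, "no", 1.570),
    (8, 110.0, 80.0, "0.25 mm Cu", 1.577),
    (9, 110.0, 80.0, "0.25 mm Sn", 1.562),
    (10, 110.0, 100.0, "no", 1.570),
    (11, 110.0, 100.0, "0.25 mm Cu", 1.560),
    (12, 110.0, 100.0, "0.25 mm Sn", 1.569),
]
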