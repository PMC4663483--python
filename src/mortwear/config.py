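"""Default configuration constants.

Calibration constants for the synthetic seasonal-diet model and the default
training recipe live here, not in code: the simulator's defaults are chosen
so that simulated scenario sub-samples land in the same (SD, CV) envelope as
the published reference samples (SD roughly 0.8–7 scratches/0.16 mm^2,
CV roughly 0.08–0.36).
"""

from __future__ import annotations

#: Synthetic seasonal-diet model defaults.  Baseline and amplitude are in
#: scratches per 0.16 mm^2; the annual peak sits in late spring (day 135),
#: between the spring maximum seen in caribou and the summer maximum seen in
#: mule deer.  The peak/trough ratio (~2.4x) and the within-date individual
#: spread (~1.3) reproduce the dispersion of the published day-resolution and
#: year-long samples.
DEFAULT_SEASONAL_MODEL = {
    "baseline": 14.0,
    "amplitude": 5.5,
    "peak_day": 135,
    "individual_sd": 1.3,
    "hemisphere": "north",
}

#: Minimum sub-sample size for a (SD, CV) point to enter a training set.
DEFAULT_MIN_SIZE = 15

#: Probability masses of the default mixture isolines.
DEFAULT_ISOLINE_MASSES = (0.68, 0.95, 0.995)

#: Default evaluation grid over the SD-CV plane.  Covers every published
#: sample coordinate with a margin (including a small negative margin: the
#: Gaussian model assigns negligible mass to negative SD/CV, and integrals
#: run over the full grid).
DEFAULT_GRID = {
    "x_min": -1.5,
    "x_max": 10.0,
    "y_min": -0.10,
    "y_max": 0.60,
    "nx": 500,
    "ny": 500,
}

#: Operationalisation of "evenly distributed" death dates for scenario A/B
#: sub-samples: no inter-death gap longer than max_gap_frac of the window,
#: and no single 1/n_bins-window bin holding more than max_bin_frac of the
#: deaths.
EVENNESS = {"max_gap_frac": 1.0 / 3.0, "n_bins": 6, "max_bin_frac": 0.5}

#: Default warm-season proportion grid for scenario-C sub-sample assembly
#: (nine values covering the spectrum of two-event imbalances).
C_PROPORTIONS = tuple(round(0.1 * i, 1) for i in range(1, 10))

#: Default training recipe: death-date windows (start day-of-year, length in
#: days) for each scenario.  A: one mid-season month and one full season per
#: season; B: four-month to year-long windows at staggered phases; C: two
#: short events in opposite seasons (warm window first), combined over the
#: proportion grid.
TRAINING_WINDOWS_A = (
    (15, 30), (335, 90),   # winter
    (105, 30), (60, 90),   # spring
    (196, 30), (152, 90),  # summer
    (288, 30), (244, 90),  # autumn
)
TRAINING_WINDOWS_B = (
    (1, 365),
    (32, 180),
    (121, 270),
    (182, 150),
    (244, 330),
    (305, 210),
    (60, 365),
    (288, 240),
)
TRAINING_WINDOWS_C = {
    "warm": (121, 30),   # mid-spring short event (near the seasonal peak)
    "cold": (303, 30),   # mid-autumn short event (near the seasonal trough)
}

#: Individuals per simulated training sub-sample (>= DEFAULT_MIN_SIZE).
TRAINING_N_PER_SUBSAMPLE = 30

#: Within-date individual heterogeneity cycled across training sub-samples.
#: Real populations differ in individual spread (the two day-resolution
#: reference samples alone span SD 0.8–1.1, season-scale ones reach ~2.2);
#: cycling these values makes each scenario class reflect between-population
#: differences, not a single idealised herd.
TRAINING_INDIVIDUAL_SDS = (0.9, 1.3, 1.7, 2.1)
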