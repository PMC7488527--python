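"""Published reference values for stagewise *C. maculatus* development.

Machine-readable copies of the study's printed result tables: median stage
transition times and stage durations at five constant temperature regimes,
median stage durations with quartiles for the individually followed
stages, and the per-stage linear thermal-response coefficients with the
derived lower temperature thresholds.

The five chambers were set to 20, 23, 26, 29 and 32 °C; the realized
temperatures differed slightly between the embryonic/early-larval runs
(the "pre/post dorsal closure" blocks of the destructive experiment) and
the within-seed experiment, so actual temperatures are carried per block.

Rate-unit convention: the destructive (embryonic and early larval) stage
coefficients are on a per-hour scale, the within-seed stage coefficients
on a per-day scale; every coefficient row carries an explicit unit tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Chamber set points used as regime labels throughout.
SET_POINTS = (20, 23, 26, 29, 32)

#: Realized chamber temperatures (°C) per experimental block.
ACTUAL_TEMPS = {
    "pre_dorsal_closure": (19.8, 22.7, 25.6, 28.6, 31.7),
    "post_dorsal_closure": (19.7, 22.6, 25.6, 28.8, 31.6),
    "within_seed": (20.0, 23.0, 25.9, 28.9, 31.8),
}

#: Block assignment per destructive stage (which realized temperatures apply).
STAGE_BLOCK = {
    "early_cleavages": "pre_dorsal_closure",
    "late_cleavages": "pre_dorsal_closure",
    "germ_band_extension": "pre_dorsal_closure",
    "germ_band_retraction": "pre_dorsal_closure",
    "dorsal_closure": "pre_dorsal_closure",
    "final_morphogenesis": "post_dorsal_closure",
    "sclerotization": "post_dorsal_closure",
    "hatching": "post_dorsal_closure",
    "boring": "post_dorsal_closure",
    "larva": "within_seed",
    "pupa": "within_seed",
    "teneral": "within_seed",
}

# Median transition times (h from oviposition) at the five regimes,
# estimated by logistic regression on the destructive samples.
_TRANSITIONS_H = {
    "early_cleavages": (14.10, 10.25, 6.28, 5.17, 4.11),
    "late_cleavages": (34.37, 24.21, 18.52, 14.15, 12.42),
    "germ_band_extension": (54.63, 39.16, 28.03, 21.09, 17.52),
    "germ_band_retraction": (107.90, 75.33, 57.06, 41.63, 34.51),
    "dorsal_closure": (167.85, 115.20, 85.78, 64.89, 54.66),
    "final_morphogenesis": (211.32, 134.54, 105.34, 80.57, 68.81),
    "sclerotization": (235.74, 157.76, 118.68, 89.66, 78.59),
    "hatching": (269.90, 177.72, 130.58, 99.12, 87.09),
    "boring": (351.53, 229.27, 172.34, 129.15, 112.20),
}

# Stage durations (h) as printed: consecutive differences of the above.
_DURATIONS_H = {
    "early_cleavages": (14.10, 10.25, 6.28, 5.17, 4.11),
    "late_cleavages": (20.27, 13.96, 12.24, 8.98, 8.32),
    "germ_band_extension": (20.26, 14.95, 9.51, 6.94, 5.10),
    "germ_band_retraction": (53.27, 36.18, 29.03, 20.54, 16.99),
    "dorsal_closure": (59.95, 39.87, 28.73, 23.26, 20.15),
    "final_morphogenesis": (43.47, 19.34, 19.56, 15.69, 14.15),
    "sclerotization": (24.42, 23.22, 13.33, 9.08, 9.78),
    "hatching": (34.15, 19.96, 11.91, 9.47, 8.50),
    "boring": (81.63, 51.55, 41.76, 30.03, 25.12),
}

# Within-seed stages: median (lower quartile, upper quartile) durations, days.
_STAGE_SUMMARIES_D = {
    "larva": (
        (38.9, 35.0, 49.8),
        (22.6, 21.0, 24.2),
        (17.1, 15.9, 18.9),
        (14.0, 11.8, 15.0),
        (12.9, 11.0, 13.8),
    ),
    "pupa": (
        (10.3, 9.8, 10.8),
        (6.9, 6.0, 7.0),
        (5.9, 5.0, 6.2),
        (5.0, 4.2, 5.3),
        (4.1, 3.9, 5.0),
    ),
    "teneral": (
        (6.8, 6.0, 7.1),
        (4.5, 4.0, 5.0),
        (3.0, 3.0, 4.0),
        (3.1, 2.0, 5.0),
        (4.0, 2.9, 5.0),
    ),
}

# Linear thermal-response coefficients R = a + b·T with SEs and the derived
# lower temperature threshold (LTT = −a/b) with its reported SE.
# rate_units: scale of R ("per_hour" for destructive stages, "per_day" for
# within-seed stages; "total_embryonic" spans oviposition→hatching).
_COEFFICIENTS = [
    # stage, a, se_a, b, se_b, ltt, se_ltt, rate_units
    ("early_cleavages", -0.2269, 0.02268, 0.01479, 0.00087, 15.3, 2.2, "per_hour"),
    ("late_cleavages", -0.0692, 0.01565, 0.00608, 0.00060, 11.4, 2.6, "per_hour"),
    ("germ_band_extension", -0.2075, 0.02759, 0.01245, 0.00106, 16.7, 2.3, "per_hour"),
    ("germ_band_retraction", -0.0495, 0.00561, 0.00340, 0.00022, 14.6, 2.2, "per_hour"),
    ("dorsal_closure", -0.0382, 0.00336, 0.00281, 0.00013, 13.6, 2.2, "per_hour"),
    ("hatching", -0.1220, 0.01736, 0.00776, 0.00067, 15.7, 2.3, "per_hour"),
    ("total_embryonic", -0.0095, 0.00080, 0.00067, 0.00003, 14.2, 2.2, "per_hour"),
    ("boring", -0.0335, 0.00288, 0.00231, 0.00011, 14.5, 2.2, "per_hour"),
    ("larva", -0.0793, 0.00199, 0.00527, 0.00009, 15.1, 0.4, "per_day"),
    ("pupa", -0.1607, 0.00478, 0.01295, 0.00023, 12.4, 0.6, "per_day"),
]

# Provisional quadratic thermal responses R = c2·T² + c1·T + c0 for the two
# markedly nonlinear periods (per-day rates).
QUADRATIC_COEFFICIENTS = {
    # dorsal closure → end of sclerotization, pooled rates
    "sclerotization_composite": (-0.00009, 0.0073, -0.0918),
    "teneral": (-0.0021, 0.1219, -1.443),
}


def reference_transition_times() -> pd.DataFrame:
    """Median transition times (h), stages × set-point regimes."""
    return pd.DataFrame.from_dict(
        _TRANSITIONS_H, orient="index", columns=list(SET_POINTS)
    ).rename_axis("stage")


def reference_durations() -> pd.DataFrame:
    """Printed stage durations (h), stages × set-point regimes."""
    return pd.DataFrame.from_dict(
        _DURATIONS_H, orient="index", columns=list(SET_POINTS)
    ).rename_axis("stage")


def reference_stage_summaries() -> pd.DataFrame:
    """Within-seed stage medians and quartiles (days), long format."""
    rows = []
    for stage, cells in _STAGE_SUMMARIES_D.items():
        for temp, (med, lq, uq) in zip(ACTUAL_TEMPS["within_seed"], cells):
            rows.append(
                {"stage": stage, "temp_c": temp, "median_d": med,
                 "q1_d": lq, "q3_d": uq}
            )
    return pd.DataFrame(rows)


def reference_coefficients() -> pd.DataFrame:
    """Linear thermal-response coefficients and lower thresholds per stage."""
    return pd.DataFrame(
        _COEFFICIENTS,
        columns=["stage", "a", "se_a", "b", "se_b", "ltt_c", "se_ltt_c",
                 "rate_units"],
    ).set_index("stage")


def actual_temperatures(stage: str) -> tuple[float, ...]:
    """Realized chamber temperatures (°C) for a stage's experimental block."""
    return ACTUAL_TEMPS[STAGE_BLOCK[stage]]


@dataclass(frozen=True)
class FixtureTables:
    """Bundle of the packaged reference tables."""

    transitions_h: pd.DataFrame
    durations_h: pd.DataFrame
    stage_summaries_d: pd.DataFrame
    coefficients: pd.DataFrame
    actual_temps: dict[str, tuple[float, ...]]
    quadratic: dict[str, tuple[float, float, float]]


def make_fixture_tables() -> FixtureTables:
    """Return every packaged reference table as one bundle."""
    return FixtureTables(
        transitions_h=reference_transition_times(),
        durations_h=reference_durations(),
        stage_summaries_d=reference_stage_summaries(),
        coefficients=reference_coefficients(),
        actual_temps=dict(ACTUAL_TEMPS),
        quadratic=dict(QUADRATIC_COEFFICIENTS),
    )
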