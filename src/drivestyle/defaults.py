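"""Default calibration profiles for the three driving-style groups.

These are the group-level summary statistics (mean +/- between-task SD)
of the simulated-driving study this package models: seven behavioural
driving variables per style group, and per-channel EEG power spectral
density levels (dB, 10*log10 of one-sided PSD in a.u.^2/Hz) in the three
analysis bands (0.5-7, 7-21, 21-30 Hz). The synthetic-data generator
uses them as its targets, so the statistical structure of generated
datasets matches the study's reported group profiles.
"""

from __future__ import annotations

from .montage import CHANNELS

#: Driving variables in canonical column order.
DRIVING_VARIABLES: tuple[str, ...] = (
    "velocity_kmh",
    "total_time_s",
    "n_lane_excursions",
    "n_collisions",
    "ang_vel_rad_s",
    "ang_acc_rad_s2",
    "rot_angle_deg",
)

#: Variables that are event counts (clipped at zero and rounded).
COUNT_VARIABLES: frozenset[str] = frozenset({"n_lane_excursions", "n_collisions"})

STYLES: tuple[str, ...] = ("Aggressive", "Moderate", "Conservative")

#: Group sizes (tasks per style) in the default 75-task study design.
GROUP_N_TASKS: dict[str, int] = {"Aggressive": 19, "Moderate": 25, "Conservative": 31}

#: (mean, SD) per driving variable per style group.
DRIVING_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Aggressive": {
        "velocity_kmh": (68.2, 4.1),
        "total_time_s": (430.3, 18.6),
        "n_lane_excursions": (10.0, 4.4),
        "n_collisions": (4.6, 1.9),
        "ang_vel_rad_s": (1.96, 0.38),
        "ang_acc_rad_s2": (1001.1, 167.5),
        "rot_angle_deg": (48.8, 12.6),
    },
    "Moderate": {
        "velocity_kmh": (62.2, 3.3),
        "total_time_s": (428.3, 15.2),
        "n_lane_excursions": (4.8, 3.0),
        "n_collisions": (2.8, 1.5),
        "ang_vel_rad_s": (1.49, 0.18),
        "ang_acc_rad_s2": (697.6, 148.7),
        "rot_angle_deg": (32.2, 5.7),
    },
    "Conservative": {
        "velocity_kmh": (51.4, 2.1),
        "total_time_s": (499.5, 9.6),
        "n_lane_excursions": (1.8, 2.1),
        "n_collisions": (0.7, 0.9),
        "ang_vel_rad_s": (1.15, 0.19),
        "ang_acc_rad_s2": (413.5, 118.8),
        "rot_angle_deg": (26.2, 2.5),
    },
}

#: Analysis-band edges in Hz (low inclusive, high exclusive).
ANALYSIS_BAND_EDGES: dict[str, tuple[float, float]] = {
    "band1": (0.5, 7.0),
    "band2": (7.0, 21.0),
    "band3": (21.0, 30.0),
}

# Per-channel (mean dB, between-task SD dB) for the three analysis bands,
# per style group. Row order follows the canonical montage order.
# fmt: off
_EEG_PSD_ROWS: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]]] = {
    # channel: {style: ((band1 mean, sd), (band2 mean, sd), (band3 mean, sd))}
    "Fz":  {"Aggressive": ((-60.7, 2.1), (-68.5, 0.5), (-70.8, 0.1)),
            "Moderate":   ((-62.6, 1.4), (-68.6, 0.2), (-70.7, 0.2)),
            "Conservative": ((-58.1, 4.1), (-68.2, 0.6), (-70.5, 0.5))},
    "F8":  {"Aggressive": ((-59.4, 2.3), (-68.4, 0.5), (-70.7, 0.1)),
            "Moderate":   ((-59.1, 3.1), (-68.3, 0.7), (-70.6, 0.2)),
            "Conservative": ((-61.6, 1.8), (-68.3, 0.5), (-70.6, 0.4))},
    "Cz":  {"Aggressive": ((-56.9, 4.0), (-67.0, 1.1), (-69.9, 0.2)),
            "Moderate":   ((-61.8, 1.5), (-67.4, 0.2), (-69.8, 0.2)),
            "Conservative": ((-62.6, 1.3), (-65.8, 1.8), (-69.3, 1.0))},
    "Pz":  {"Aggressive": ((-59.5, 2.7), (-67.9, 1.3), (-70.4, 0.7)),
            "Moderate":   ((-61.2, 2.5), (-65.3, 3.0), (-70.6, 1.2)),
            "Conservative": ((-57.6, 4.1), (-60.8, 3.5), (-70.3, 1.5))},
    "T6":  {"Aggressive": ((-56.3, 4.1), (-68.7, 1.0), (-71.7, 0.9)),
            "Moderate":   ((-58.7, 3.1), (-68.6, 0.2), (-71.4, 0.3)),
            "Conservative": ((-59.7, 2.8), (-68.3, 0.6), (-71.3, 0.6))},
    "T5":  {"Aggressive": ((-51.9, 5.7), (-67.5, 1.0), (-70.8, 0.5)),
            "Moderate":   ((-54.4, 4.7), (-67.6, 0.6), (-70.7, 0.4)),
            "Conservative": ((-58.3, 2.4), (-67.7, 0.8), (-70.9, 0.6))},
    "C4":  {"Aggressive": ((-53.3, 4.8), (-68.2, 0.9), (-71.2, 0.5)),
            "Moderate":   ((-56.8, 3.9), (-65.9, 3.1), (-70.9, 1.1)),
            "Conservative": ((-54.0, 5.1), (-67.4, 1.9), (-71.1, 0.8))},
    "C3":  {"Aggressive": ((-60.1, 2.7), (-68.2, 2.0), (-71.5, 0.5)),
            "Moderate":   ((-62.9, 1.5), (-68.6, 0.3), (-71.6, 0.1)),
            "Conservative": ((-63.2, 1.1), (-67.5, 1.7), (-71.3, 0.6))},
    "T4":  {"Aggressive": ((-54.9, 3.9), (-67.8, 1.3), (-71.2, 0.2)),
            "Moderate":   ((-55.6, 4.2), (-68.0, 1.1), (-70.9, 0.6)),
            "Conservative": ((-61.4, 1.7), (-68.2, 0.5), (-71.0, 0.7))},
    "T3":  {"Aggressive": ((-54.4, 4.7), (-67.8, 0.6), (-69.0, 0.4)),
            "Moderate":   ((-55.9, 3.3), (-66.2, 2.0), (-66.8, 3.4)),
            "Conservative": ((-60.7, 2.3), (-67.7, 1.4), (-68.8, 1.9))},
    "O2":  {"Aggressive": ((-59.8, 2.3), (-68.1, 0.5), (-71.1, 0.1)),
            "Moderate":   ((-61.9, 1.6), (-68.1, 0.2), (-71.0, 0.2)),
            "Conservative": ((-61.9, 1.7), (-68.0, 0.4), (-70.9, 0.5))},
    "O1":  {"Aggressive": ((-57.8, 2.7), (-63.5, 3.7), (-71.2, 0.8)),
            "Moderate":   ((-59.2, 1.8), (-68.2, 0.3), (-71.2, 0.3)),
            "Conservative": ((-58.5, 3.0), (-62.4, 3.3), (-70.6, 1.3))},
    "P4":  {"Aggressive": ((-59.0, 3.3), (-69.3, 0.5), (-72.0, 0.1)),
            "Moderate":   ((-62.4, 1.9), (-69.0, 1.2), (-71.7, 1.0)),
            "Conservative": ((-63.2, 1.4), (-66.8, 2.7), (-71.5, 1.0))},
    "P3":  {"Aggressive": ((-61.4, 2.9), (-69.2, 2.9), (-74.9, 0.6)),
            "Moderate":   ((-63.9, 1.8), (-71.9, 0.4), (-74.9, 0.4)),
            "Conservative": ((-63.7, 2.3), (-68.1, 3.4), (-74.4, 1.3))},
    "Fp2": {"Aggressive": ((-58.0, 2.6), (-65.4, 3.0), (-71.0, 0.7)),
            "Moderate":   ((-60.0, 2.6), (-65.2, 3.2), (-70.7, 0.7)),
            "Conservative": ((-60.3, 2.2), (-66.2, 2.6), (-70.8, 0.8))},
    "Fp1": {"Aggressive": ((-57.0, 2.5), (-68.3, 0.4), (-71.4, 0.1)),
            "Moderate":   ((-60.5, 2.1), (-68.4, 0.2), (-71.4, 0.1)),
            "Conservative": ((-61.4, 1.2), (-68.2, 0.5), (-71.3, 0.4))},
}
# fmt: on


def eeg_band_levels(style: str) -> "tuple[list[list[float]], list[list[float]]]":
    """(means, sds): 16 x 3 nested lists of band PSD levels in dB for *style*.

    Rows follow the canonical channel order, columns the analysis bands
    band1/band2/band3.
    """
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}")
    means, sds = [], []
    for ch in CHANNELS:
        rows = _EEG_PSD_ROWS[ch][style]
        means.append([m for m, _ in rows])
        sds.append([s for _, s in rows])
    return means, sds
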