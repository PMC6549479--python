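"""16-channel 10-20 montage used throughout the package.

The channel set is the 16-electrode subset (no F3/F4/F7, no mastoids)
recorded by the simulated-driving acquisition setup this package models.
Channel order below is the canonical order; every reader normalises to it.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "Fz", "Cz", "Pz", "T6", "T5", "C4", "C3", "F8",
    "T4", "T3", "O2", "O1", "P4", "P3", "Fp1", "Fp2",
)

N_CHANNELS = len(CHANNELS)

# Two nearest in-set neighbours per channel, used for bad-channel
# replacement (mean of the two neighbours). Where the geometric
# neighbour (F7, F3, F4, A1/A2 ...) is absent from the set, the nearest
# present electrode substitutes; the table is symmetric where the
# geometry allows.
NEIGHBOURS: dict[str, tuple[str, str]] = {
    "Fp1": ("Fp2", "Fz"),
    "Fp2": ("Fp1", "F8"),
    "Fz":  ("Fp1", "Cz"),
    "F8":  ("Fp2", "T4"),
    "Cz":  ("Fz", "Pz"),
    "C3":  ("T3", "Cz"),
    "C4":  ("T4", "Cz"),
    "T3":  ("C3", "T5"),
    "T4":  ("C4", "T6"),
    "T5":  ("T3", "O1"),
    "T6":  ("T4", "O2"),
    "Pz":  ("P3", "P4"),
    "P3":  ("C3", "O1"),
    "P4":  ("C4", "O2"),
    "O1":  ("P3", "O2"),
    "O2":  ("P4", "O1"),
}

# Approximate 2-D scalp layout (head radius 1, nose up) for reporting.
LAYOUT_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "Fz": (0.0, 0.50), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.38, -0.54), "Pz": (0.0, -0.50),
    "P4": (0.38, -0.54), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# Frontal topography template for ocular-component detection: blinks
# project most strongly onto the prefrontal pair and fade with distance.
FRONTAL_PATTERN: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "Fz": 0.45, "F8": 0.45,
    "C3": 0.12, "C4": 0.12, "Cz": 0.15, "T3": 0.10, "T4": 0.10,
    "T5": 0.03, "T6": 0.03, "P3": 0.03, "P4": 0.03, "Pz": 0.03,
    "O1": 0.01, "O2": 0.01,
}


def channel_index(name: str) -> int:
    """Position of *name* in the canonical channel order."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; montage has {CHANNELS}") from None
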