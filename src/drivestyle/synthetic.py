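"""Synthetic driving-task tables and multichannel EEG recordings.

The generator emulates the statistical structure the analysis pipeline
assumes: three driving-style groups whose seven behavioural variables
follow the calibrated group means/SDs, and 16-channel EEG whose Welch
band PSD levels (dB) match per-channel, per-band targets, including a
narrowband "bump" component near 15 Hz in the Conservative group.
Ocular, drift and mains-line artifacts can be injected with a
ground-truth log for testing the preprocessing chain.

EEG synthesis works in the spectral domain: per channel, white Gaussian
noise is shaped by a target one-sided PSD curve assembled from
band-limited masks with raised-cosine crossfades (0.5 Hz transition)
at the band boundaries. Because the crossfades and the bump perturb the
in-band average density, the per-band component amplitudes are solved
from a small linear system so that the bin-averaged density over each
analysis band equals its target exactly; the Welch estimator then
recovers the targets up to estimator noise (well under 1 dB when
averaged over seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .defaults import (
    ANALYSIS_BAND_EDGES,
    COUNT_VARIABLES,
    DRIVING_VARIABLES,
    GROUP_N_TASKS,
    STYLES,
)
from .montage import CHANNELS, FRONTAL_PATTERN, N_CHANNELS
from .recording import EEGRecording

#: dB sentinel meaning "no power in this band".
NO_POWER = -np.inf

_TRANSITION_HZ = 0.5  # raised-cosine crossfade width at band edges
_CAL_BIN_HZ = 0.5     # bin grid of the default 2-s Welch estimator


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DrivingGroupSpec:
    """Mean/SD of the seven driving variables for one style group."""

    style: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    n_tasks: int

    def __post_init__(self) -> None:
        missing = set(DRIVING_VARIABLES) - set(self.means) | set(DRIVING_VARIABLES) - set(self.sds)
        if missing:
            raise ValueError(f"driving spec missing variables: {sorted(missing)}")
        for var in DRIVING_VARIABLES:
            if self.sds[var] < 0:
                raise ValueError(f"negative SD for variable {var!r}")
            if var in COUNT_VARIABLES and self.means[var] < 0:
                raise ValueError(f"count variable {var!r} has negative mean")
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")

    @classmethod
    def from_defaults(cls, style: str, n_tasks: int | None = None) -> "DrivingGroupSpec":
        stats = defaults.DRIVING_GROUP_STATS[style]
        return cls(
            style=style,
            means={v: stats[v][0] for v in DRIVING_VARIABLES},
            sds={v: stats[v][1] for v in DRIVING_VARIABLES},
            n_tasks=GROUP_N_TASKS[style] if n_tasks is None else n_tasks,
        )


@dataclass(frozen=True)
class BumpSpec:
    """Narrowband spectral bump: raised-cosine component of half-width
    ``bandwidth`` Hz around ``center`` Hz, ``rel_level_db`` above the
    hosting band's base density at its peak."""

    center_hz: float = 15.0
    bandwidth_hz: float = 2.0
    rel_level_db: float = 4.0

    def __post_init__(self) -> None:
        if not (0.5 < self.center_hz < 30.0):
            raise ValueError("bump center must lie inside 0.5-30 Hz")
        if self.bandwidth_hz <= 0:
            raise ValueError("bump bandwidth must be positive")


@dataclass(frozen=True)
class ArtifactConfig:
    """Rates/amplitudes of injected artifacts; zero rates disable each."""

    blink_rate_per_min: float = 0.0
    blink_amplitude: float = 0.02
    blink_duration_s: float = 0.3
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.2
    line_amplitude: float = 0.0
    line_freq_hz: float = 50.0

    @property
    def is_null(self) -> bool:
        return (
            self.blink_rate_per_min == 0
            and self.drift_amplitude == 0
            and self.line_amplitude == 0
        )


#: Default artifact contamination for generated study datasets.
DEFAULT_ARTIFACTS = ArtifactConfig(
    blink_rate_per_min=12.0, drift_amplitude=0.004, line_amplitude=0.003
)


@dataclass(frozen=True)
class EEGGroupSpec:
    """Per-channel target band PSD levels (dB) for one style group.

    ``band_levels_db`` is 16 x 3 (canonical channel order x
    band1/band2/band3). ``band_sds_db`` gives the between-task SD of each
    level; it is used only when drawing per-task spec realisations.
    """

    style: str
    band_levels_db: np.ndarray
    band_sds_db: np.ndarray | None = None
    bump: BumpSpec | None = None
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)

    def __post_init__(self) -> None:
        levels = np.asarray(self.band_levels_db, dtype=float)
        object.__setattr__(self, "band_levels_db", levels)
        if levels.shape != (N_CHANNELS, 3):
            raise ValueError(f"band_levels_db must be ({N_CHANNELS}, 3)")
        if self.band_sds_db is not None:
            sds = np.asarray(self.band_sds_db, dtype=float)
            object.__setattr__(self, "band_sds_db", sds)
            if sds.shape != (N_CHANNELS, 3) or (sds < 0).any():
                raise ValueError("band_sds_db must be non-negative with shape (16, 3)")

    @classmethod
    def from_defaults(cls, style: str, artifacts: ArtifactConfig | None = None) -> "EEGGroupSpec":
        means, sds = defaults.eeg_band_levels(style)
        return cls(
            style=style,
            band_levels_db=np.array(means),
            band_sds_db=np.array(sds),
            bump=BumpSpec() if style == "Conservative" else None,
            artifacts=artifacts if artifacts is not None else ArtifactConfig(),
        )

    def draw_task_spec(self, rng: np.random.Generator) -> "EEGGroupSpec":
        """One task's realisation: levels jittered by the between-task SDs."""
        if self.band_sds_db is None:
            return self
        levels = self.band_levels_db + rng.standard_normal((N_CHANNELS, 3)) * self.band_sds_db
        return EEGGroupSpec(
            style=self.style,
            band_levels_db=levels,
            band_sds_db=None,
            bump=self.bump,
            artifacts=self.artifacts,
        )


@dataclass(frozen=True)
class StudyDesign:
    """Subjects, their task counts and per-subject style assignment."""

    subject_styles: tuple[str, ...]
    subject_task_counts: tuple[int, ...]
    task_range: tuple[int, int] = (2, 4)
    subject_consistent: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subject_styles) != len(self.subject_task_counts):
            raise ValueError("one style and one task count per subject required")
        lo, hi = self.task_range
        for c in self.subject_task_counts:
            if not lo <= c <= hi:
                raise ValueError(f"task count {c} outside declared range {self.task_range}")
        for s in self.subject_styles:
            if s not in STYLES:
                raise ValueError(f"unknown style {s!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_styles)

    @property
    def n_tasks(self) -> int:
        return int(sum(self.subject_task_counts))

    def group_task_counts(self) -> dict[str, int]:
        out = {s: 0 for s in STYLES}
        for style, c in zip(self.subject_styles, self.subject_task_counts):
            out[style] += c
        return out


def default_study_design(master_seed: int = 0, subject_consistent: bool = True) -> StudyDesign:
    """The default 23-subject / 75-task design (19/25/31 tasks per style).

    Each subject contributes 2-4 tasks; by default all of a subject's
    tasks share one style (within-subject style variation can be enabled
    via ``subject_consistent=False``, which shuffles task styles across
    subjects while preserving the group totals).
    """
    styles = ("Aggressive",) * 6 + ("Moderate",) * 7 + ("Conservative",) * 10
    counts = (3, 3, 3, 3, 3, 4) + (4, 4, 4, 4, 3, 3, 3) + (3,) * 9 + (4,)
    return StudyDesign(
        subject_styles=styles,
        subject_task_counts=counts,
        subject_consistent=subject_consistent,
        master_seed=master_seed,
    )


# --------------------------------------------------------------------------
# driving tables
# --------------------------------------------------------------------------

def _draw_driving_rows(spec: DrivingGroupSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for var in DRIVING_VARIABLES:
        x = rng.normal(spec.means[var], spec.sds[var], size=n)
        if var in COUNT_VARIABLES:
            x = np.round(np.clip(x, 0.0, None))
        cols[var] = x
    df = pd.DataFrame(cols)
    df["true_style"] = spec.style
    return df


def generate_driving_tasks(
    specs: Sequence[DrivingGroupSpec], seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Draw one driving-task table from group specs; rows shuffled.

    Continuous variables are independent normals with the spec's
    mean/SD; count variables are drawn the same way then clipped at zero
    and rounded to integers. The returned table keeps the generating
    style in ``true_style`` and numbers tasks 0..n-1 after shuffling.
    """
    if not specs:
        raise ValueError("at least one group spec required")
    rng = np.random.default_rng(seed)
    frames = [_draw_driving_rows(s, s.n_tasks, rng) for s in specs]
    df = pd.concat(frames, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "task_id", np.arange(len(df)))
    return df


# --------------------------------------------------------------------------
# EEG synthesis
# --------------------------------------------------------------------------

def _edge(f: np.ndarray, center: float, width: float, rising: bool) -> np.ndarray:
    """Raised-cosine step from 0 to 1 (rising) across [center-w/2, center+w/2]."""
    t = np.clip((f - (center - width / 2)) / width, 0.0, 1.0)
    s = 0.5 * (1 - np.cos(np.pi * t))
    return s if rising else 1.0 - s


def _band_mask(f: np.ndarray, low: float, high: float) -> np.ndarray:
    return _edge(f, low, _TRANSITION_HZ, True) * _edge(f, high, _TRANSITION_HZ, False)


def _bump_mask(f: np.ndarray, bump: BumpSpec) -> np.ndarray:
    x = (f - bump.center_hz) / bump.bandwidth_hz
    m = np.zeros_like(f)
    inside = np.abs(x) < 1
    m[inside] = np.cos(0.5 * np.pi * x[inside]) ** 2
    return m


def _component_masks(f: np.ndarray, bump: BumpSpec | None) -> list[np.ndarray]:
    """Density-domain masks for band1..band3; the bump (if any) rides on
    band2 with a fixed peak-density ratio relative to the band-2 base."""
    masks = [_band_mask(f, lo, hi) for lo, hi in ANALYSIS_BAND_EDGES.values()]
    if bump is not None:
        ratio = 10 ** (bump.rel_level_db / 10) - 1.0
        masks[1] = masks[1] + ratio * _bump_mask(f, bump)
    return masks


def _solve_band_amplitudes(levels_db: np.ndarray, bump: BumpSpec | None) -> np.ndarray:
    """Density scales a (3,) such that sum_b a_b * mask_b, bin-averaged
    over each analysis band (0.5 Hz grid, [low, high) convention),
    equals the target densities. -inf targets give zero scale."""
    grid = np.arange(0.0, 30.0 + 6 * _CAL_BIN_HZ, _CAL_BIN_HZ)
    masks = _component_masks(grid, bump)
    targets = np.where(np.isneginf(levels_db), 0.0, 10 ** (levels_db / 10))
    M = np.zeros((3, 3))
    for i, (lo, hi) in enumerate(ANALYSIS_BAND_EDGES.values()):
        sel = (grid >= lo) & (grid < hi)
        for j, m in enumerate(masks):
            M[i, j] = m[sel].mean()
    a = np.linalg.solve(M, targets)
    a[np.isneginf(levels_db)] = 0.0
    return np.clip(a, 0.0, None)


def target_density(freqs: np.ndarray, levels_db: np.ndarray, bump: BumpSpec | None) -> np.ndarray:
    """Target one-sided PSD (a.u.^2/Hz) at *freqs* for one channel."""
    masks = _component_masks(freqs, bump)
    a = _solve_band_amplitudes(np.asarray(levels_db, dtype=float), bump)
    return sum(ai * mi for ai, mi in zip(a, masks))


def generate_eeg_recording(
    spec: EEGGroupSpec,
    duration_s: float = 60.0,
    fs: float = 512.0,
    seed: int | np.random.SeedSequence = 0,
    with_artifacts: bool = True,
) -> EEGRecording:
    """Generate one artifact-contaminated (optionally clean) recording.

    Channels are independent; each is spectrally shaped white noise whose
    bin-averaged density over each analysis band matches the spec's dB
    target (Conservative-style specs add the 15 Hz bump component).
    """
    if duration_s < 10:
        raise ValueError("duration must be >= 10 s")
    if fs < 2 * 30.0:
        raise ValueError(f"fs={fs} is below Nyquist for 30 Hz content")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    data = np.empty((N_CHANNELS, n))
    for c in range(N_CHANNELS):
        d = target_density(freqs, spec.band_levels_db[c], spec.bump)
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white) * np.sqrt(d * fs / 2.0)
        data[c] = np.fft.irfft(spectrum, n)
    rec = EEGRecording(
        data=data, fs=fs,
        history=(f"synthesized style={spec.style} fs={fs} dur={duration_s}s",),
    )
    if with_artifacts and not spec.artifacts.is_null:
        rec, _ = inject_artifacts(rec, spec.artifacts, rng)
    return rec


def inject_artifacts(
    rec: EEGRecording,
    config: ArtifactConfig,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[EEGRecording, dict]:
    """Add blink transients, slow drift and mains-line noise.

    Blinks are Poisson events (rate per minute) realised as raised-cosine
    pulses, largest on Fp1/Fp2 with decaying spatial weights. Returns the
    contaminated recording and a ground-truth log (blink times, per-type
    amplitudes) for use as an oracle in artifact-removal tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log: dict = {"blink_times_s": [], "config": config}
    if config.is_null:
        return rec.evolve(step="inject_artifacts(null)"), log

    n = rec.n_samples
    t = np.arange(n) / rec.fs
    add = np.zeros_like(rec.data)
    weights = np.array([FRONTAL_PATTERN[ch] for ch in rec.channels])

    if config.blink_rate_per_min > 0:
        n_blinks = rng.poisson(config.blink_rate_per_min * rec.duration / 60.0)
        width = config.blink_duration_s
        times = np.sort(rng.uniform(width, rec.duration - width, size=n_blinks))
        for t0 in times:
            x = (t - t0) / (width / 2)
            inside = np.abs(x) < 1
            pulse = np.zeros(n)
            pulse[inside] = config.blink_amplitude * np.cos(0.5 * np.pi * x[inside]) ** 2
            add += weights[:, None] * pulse[None, :]
        log["blink_times_s"] = times.tolist()

    if config.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        add += config.drift_amplitude * np.sin(
            2 * np.pi * config.drift_freq_hz * t[None, :] + phases[:, None]
        )

    if config.line_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        add += config.line_amplitude * np.sin(
            2 * np.pi * config.line_freq_hz * t[None, :] + phases[:, None]
        )

    out = rec.evolve(rec.data + add, step="inject_artifacts")
    return out, log


# --------------------------------------------------------------------------
# full study bundle
# --------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """One synthetic study: driving table, per-task EEG, truth labels."""

    driving: pd.DataFrame
    eeg: dict[int, EEGRecording]
    labels: pd.Series          # task_id -> true style
    design: StudyDesign


def make_dataset(
    design: StudyDesign,
    driving_specs: Sequence[DrivingGroupSpec] | None = None,
    eeg_specs: Sequence[EEGGroupSpec] | None = None,
    *,
    eeg_duration_s: float = 20.0,
    eeg_fs: float = 256.0,
) -> DatasetBundle:
    """Generate a full study dataset, reproducible from the master seed.

    Per-task seeds derive deterministically from the design's master
    seed. EEG band levels are drawn per task from the group spec's mean
    +/- between-task SD, so across-task dispersion matches the group
    calibration.
    """
    if driving_specs is None:
        driving_specs = [DrivingGroupSpec.from_defaults(s) for s in STYLES]
    if eeg_specs is None:
        eeg_specs = [EEGGroupSpec.from_defaults(s, artifacts=DEFAULT_ARTIFACTS) for s in STYLES]
    dspec = {s.style: s for s in driving_specs}
    espec = {s.style: s for s in eeg_specs}

    group_counts = design.group_task_counts()
    spec_counts = {s: dspec[s].n_tasks for s in dspec}
    if spec_counts != group_counts:
        raise ValueError(
            f"group task counts {spec_counts} inconsistent with design {group_counts}"
        )

    ss = np.random.SeedSequence(design.master_seed)
    layout_ss, *task_ss = ss.spawn(1 + design.n_tasks)

    # per-task (subject, style) layout
    tasks: list[tuple[int, str]] = []
    for subj, (style, cnt) in enumerate(zip(design.subject_styles, design.subject_task_counts)):
        tasks.extend((subj, style) for _ in range(cnt))
    if not design.subject_consistent:
        layout_rng = np.random.default_rng(layout_ss)
        styles = [s for _, s in tasks]
        perm = layout_rng.permutation(len(styles))
        tasks = [(subj, styles[perm[i]]) for i, (subj, _) in enumerate(tasks)]

    rows = []
    eeg: dict[int, EEGRecording] = {}
    for task_id, ((subj, style), tss) in enumerate(zip(tasks, task_ss)):
        rng = np.random.default_rng(tss)
        row = _draw_driving_rows(dspec[style], 1, rng).iloc[0].to_dict()
        row.update(task_id=task_id, subject_id=subj)
        rows.append(row)
        task_spec = espec[style].draw_task_spec(rng)
        eeg[task_id] = generate_eeg_recording(
            task_spec, duration_s=eeg_duration_s, fs=eeg_fs,
            seed=np.random.SeedSequence(entropy=tss.entropy, spawn_key=tss.spawn_key + (1,)),
        )
    driving = pd.DataFrame(rows)[
        ["subject_id", "task_id", *DRIVING_VARIABLES, "true_style"]
    ]
    labels = driving.set_index("task_id")["true_style"]
    return DatasetBundle(driving=driving, eeg=eeg, labels=labels, design=design)
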