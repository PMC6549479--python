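"""EEG conditioning chain.

Fixed stage order: polyphase down-sampling, zero-phase FIR band-pass
(0.5-30 Hz), ICA-based artifact-component removal, bad-channel
replacement by neighbour averaging, average re-referencing and
whole-record baseline correction. Each stage is shape-preserving in the
channel dimension and appends itself to the recording's history log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from .ica import ICADecomposition, fastica
from .montage import CHANNELS, FRONTAL_PATTERN, NEIGHBOURS
from .recording import EEGRecording


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase band-pass design parameters.

    ``transition_hz`` sets the Hamming-window FIR length
    (~3.3 * fs / transition taps); the design meets >= 40 dB stop-band
    attenuation one transition width beyond each edge (the Hamming
    window gives ~53 dB, doubled by forward-backward application).
    """

    low_hz: float = 0.5
    high_hz: float = 30.0
    transition_hz: float = 0.5
    stopband_db: float = 40.0
    phase: str = "zero"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low < high")


@dataclass(frozen=True)
class ArtifactDetectionConfig:
    """Two-rule independent-component rejection: heavy-tailed time
    course (|kurtosis| beyond threshold) or scalp topography matching
    the frontal ocular pattern (absolute correlation beyond threshold)."""

    kurtosis_threshold: float = 5.0
    frontal_corr_threshold: float = 0.8


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 128.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    run_ica: bool = True
    ica_seed: int = 0
    artifact_detection: ArtifactDetectionConfig = field(default_factory=ArtifactDetectionConfig)
    bad_channels: tuple[str, ...] = ()
    auto_bad: bool = True


def resample_to(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase rational down-sampling with anti-alias filtering."""
    if target_fs >= rec.fs:
        raise ValueError(f"target fs {target_fs} must be below current fs {rec.fs}")
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1, padtype="mean")
    return rec.evolve(data, fs=target_fs, step=f"resample_to({target_fs})")


def bandpass_fir(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Zero-phase windowed-sinc FIR band-pass (forward-backward)."""
    if spec.high_hz >= rec.fs / 2:
        raise ValueError(f"high edge {spec.high_hz} not below Nyquist {rec.fs / 2}")
    numtaps = int(math.ceil(3.3 * rec.fs / spec.transition_hz)) | 1
    if 3 * numtaps >= rec.n_samples:
        raise ValueError(
            f"filter length {numtaps} too long for {rec.n_samples} samples; "
            "record longer data or widen transition_hz"
        )
    b = signal.firwin(numtaps, [spec.low_hz, spec.high_hz], pass_zero=False,
                      window="hamming", fs=rec.fs)
    data = signal.filtfilt(b, [1.0], rec.data, axis=1)
    return rec.evolve(data, step=f"bandpass_fir({spec.low_hz}-{spec.high_hz}Hz)")


def remove_artifact_components(
    rec: EEGRecording,
    config: ArtifactDetectionConfig = ArtifactDetectionConfig(),
    seed: int | None = 0,
) -> tuple[EEGRecording, ICADecomposition]:
    """ICA decomposition; flagged components zeroed, data reconstructed.

    If the decomposition does not converge nothing is removed and the
    returned decomposition carries ``converged=False``.
    """
    ica = fastica(rec.data, seed=seed)
    if not ica.converged:
        return rec.evolve(step="ica_removal(skipped: non-convergence)"), ica

    frontal = np.array([FRONTAL_PATTERN[ch] for ch in rec.channels])
    rejected: dict[int, str] = {}
    for i in range(ica.sources.shape[0]):
        kurt = float(stats.kurtosis(ica.sources[i], fisher=True))
        if abs(kurt) > config.kurtosis_threshold:
            rejected[i] = f"kurtosis={kurt:.1f}"
            continue
        topo = ica.mixing[:, i]
        if topo.std() > 0:
            corr = float(np.corrcoef(topo, frontal)[0, 1])
            if abs(corr) > config.frontal_corr_threshold:
                rejected[i] = f"frontal_corr={corr:.2f}"
    ica.rejected = rejected

    keep = [i for i in range(ica.sources.shape[0]) if i not in rejected]
    data = ica.mixing[:, keep] @ ica.sources[keep] + ica.mean[:, None]
    return rec.evolve(data, step=f"ica_removal(rejected={sorted(rejected)})"), ica


def detect_bad_channels(rec: EEGRecording, flat_eps: float = 1e-15,
                        z_threshold: float = 3.0) -> list[str]:
    """Flat channels (variance < eps) and extreme channels
    (log-variance z-score beyond threshold)."""
    var = rec.data.var(axis=1)
    bad = [ch for ch, v in zip(rec.channels, var) if v < flat_eps]
    ok = var >= flat_eps
    if ok.sum() >= 3:
        logv = np.log10(var[ok])
        z = (logv - logv.mean()) / logv.std(ddof=0) if logv.std() > 0 else np.zeros_like(logv)
        bad += [ch for ch, zi in zip(np.array(rec.channels)[ok], z) if abs(zi) > z_threshold]
    return bad


def interpolate_bad_channels(rec: EEGRecording, bad: list[str] | None = None,
                             auto: bool = False) -> EEGRecording:
    """Replace each bad channel by the mean of its two montage neighbours."""
    bad = list(bad or [])
    if auto:
        bad += [ch for ch in detect_bad_channels(rec) if ch not in bad]
    if not bad:
        return rec.evolve(step="interpolate_bad_channels(none)")
    for ch in bad:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
        n1, n2 = NEIGHBOURS[ch]
        if n1 in bad or n2 in bad:
            raise ValueError(
                f"channel {ch!r}: neighbour {n1 if n1 in bad else n2!r} is also bad; "
                "neighbour averaging needs two clean neighbours"
            )
    data = rec.data.copy()
    for ch in bad:
        n1, n2 = NEIGHBOURS[ch]
        data[rec.channels.index(ch)] = 0.5 * (rec.channel(n1) + rec.channel(n2))
    return rec.evolve(data, step=f"interpolate_bad_channels({bad})")


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the across-channel mean at every sample."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.evolve(data, reference="average", step="rereference_average")


def baseline_correct(rec: EEGRecording) -> EEGRecording:
    """Subtract each channel's whole-record mean (continuous-driving data
    has no pre-stimulus interval to use as a baseline)."""
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.evolve(data, step="baseline_correct")


def preprocess_chain(rec: EEGRecording, config: PreprocessConfig = PreprocessConfig()
                     ) -> tuple[EEGRecording, ICADecomposition | None]:
    """Run the full conditioning chain in its fixed order."""
    out = resample_to(rec, config.target_fs) if config.target_fs < rec.fs else rec
    out = bandpass_fir(out, config.filter)
    ica = None
    if config.run_ica:
        out, ica = remove_artifact_components(out, config.artifact_detection,
                                              seed=config.ica_seed)
    out = interpolate_bad_channels(out, list(config.bad_channels), auto=config.auto_bad)
    out = rereference_average(out)
    out = baseline_correct(out)
    return out, ica
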