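"""Frequency-domain EEG features and Fisher discriminant reduction.

Per recording, the canonical delta/theta/alpha/beta bands yield a
4-dimensional FFT amplitude feature plus a 4-dimensional Welch band-PSD
feature (channel-averaged), assembled into the 8-D vector the
classifier consumes. The three wider analysis bands (0.5-7, 7-21,
21-30 Hz) feed the group x channel PSD table used for group-level
spectral comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .defaults import ANALYSIS_BAND_EDGES
from .montage import CHANNELS, N_CHANNELS
from .recording import EEGRecording

#: Canonical EEG bands plus the analysis bands, [low, high) in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "beta1": (13.0, 18.0),
    "beta2": (18.0, 21.0),
    **ANALYSIS_BAND_EDGES,
}

CANONICAL_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
ANALYSIS_BANDS: tuple[str, ...] = ("band1", "band2", "band3")

#: dB floor applied before the log (all-zero-signal sentinel is 10*log10(eps)).
PSD_FLOOR_EPS = 1e-20
PSD_FLOOR_DB = 10 * np.log10(PSD_FLOOR_EPS)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"amp_{b}" for b in CANONICAL_BANDS] + [f"psd_{b}_db" for b in CANONICAL_BANDS]
)


def _band_edges(band: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    low, high = band
    if not 0 <= low < high:
        raise ValueError(f"invalid band edges ({low}, {high})")
    return float(low), float(high)


def fft_band_amplitude(rec: EEGRecording, band: str | tuple[float, float]) -> np.ndarray:
    """Mean single-sided FFT amplitude (2|X_k|/N) over in-band bins, per channel.

    Bins are selected by centre frequency in [low, high).
    """
    low, high = _band_edges(band)
    if high > rec.fs / 2:
        raise ValueError(f"band ({low}, {high}) exceeds Nyquist {rec.fs / 2}")
    if rec.duration < 2.0 / low:
        raise ValueError(f"recording too short to resolve {low} Hz (need >= {2 / low:.1f} s)")
    n = rec.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / rec.fs)
    amp = 2.0 * np.abs(np.fft.rfft(rec.data, axis=1)) / n
    amp[:, 0] /= 2.0                      # DC is not doubled
    if n % 2 == 0:
        amp[:, -1] /= 2.0                 # nor Nyquist
    sel = (freqs >= low) & (freqs < high)
    if not sel.any():
        raise ValueError(f"no FFT bins fall in band ({low}, {high})")
    return amp[:, sel].mean(axis=1)


def welch_spectrum(rec: EEGRecording, nperseg_s: float = 2.0,
                   overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch one-sided PSD per channel (Hamming segments, density scaling)."""
    nperseg = min(int(round(nperseg_s * rec.fs)), rec.n_samples)
    f, p = signal.welch(
        rec.data, fs=rec.fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), axis=1, scaling="density",
        detrend="constant",
    )
    return f, p


def welch_psd(rec: EEGRecording, band: str | tuple[float, float],
              nperseg_s: float = 2.0, overlap: float = 0.5) -> np.ndarray:
    """Per-channel Welch band level: 10*log10(mean in-band PSD), dB.

    An all-zero channel floors at ``PSD_FLOOR_DB``.
    """
    low, high = _band_edges(band)
    if high > rec.fs / 2:
        raise ValueError(f"band ({low}, {high}) exceeds Nyquist {rec.fs / 2}")
    f, p = welch_spectrum(rec, nperseg_s=nperseg_s, overlap=overlap)
    sel = (f >= low) & (f < high)
    if not sel.any():
        raise ValueError(f"no Welch bins fall in band ({low}, {high})")
    mean_p = p[:, sel].mean(axis=1)
    return 10.0 * np.log10(np.maximum(mean_p, PSD_FLOOR_EPS))


def build_feature_vector(amplitudes: Mapping[str, np.ndarray],
                         psd_levels_db: Mapping[str, np.ndarray]) -> np.ndarray:
    """Assemble the 8-D vector: channel-mean amplitude then channel-mean
    PSD level, each in delta/theta/alpha/beta order."""
    out = []
    for family, name in ((amplitudes, "amplitude"), (psd_levels_db, "PSD")):
        for b in CANONICAL_BANDS:
            if b not in family:
                raise ValueError(f"missing {name} entry for band {b!r}")
            v = np.asarray(family[b], dtype=float)
            if v.shape != (N_CHANNELS,):
                raise ValueError(f"{name}[{b!r}] must have one value per channel")
            out.append(v.mean())
    vec = np.array(out)
    if not np.isfinite(vec).all():
        raise ValueError("non-finite feature values")
    return vec


def extract_features(rec: EEGRecording) -> np.ndarray:
    """The 8-D frequency-domain feature vector of one recording."""
    amps = {b: fft_band_amplitude(rec, b) for b in CANONICAL_BANDS}
    psds = {b: welch_psd(rec, b) for b in CANONICAL_BANDS}
    return build_feature_vector(amps, psds)


def feature_table(recordings: Mapping[int, EEGRecording],
                  labels: Mapping[int, str] | pd.Series,
                  subjects: Mapping[int, int] | pd.Series) -> pd.DataFrame:
    """Per-task feature rows: task_id, subject_id, 8 features, label."""
    rows = []
    for task_id, rec in recordings.items():
        vec = extract_features(rec)
        rows.append({"task_id": task_id, "subject_id": subjects[task_id],
                     **dict(zip(FEATURE_NAMES, vec)), "label": labels[task_id]})
    return pd.DataFrame(rows)


def band_psd_table(recordings: Mapping[int, EEGRecording],
                   labels: Mapping[int, str] | pd.Series) -> pd.DataFrame:
    """Group x channel x analysis-band PSD levels: across-task mean and SD.

    Mirrors the group spectral-profile table layout (one row per
    channel x band, one mean +/- SD pair per group).
    """
    per_task: dict[int, np.ndarray] = {
        tid: np.column_stack([welch_psd(rec, b) for b in ANALYSIS_BANDS])
        for tid, rec in recordings.items()
    }
    groups = pd.unique(pd.Series(dict(labels)))
    rows = []
    for g in groups:
        tids = [tid for tid in per_task if labels[tid] == g]
        if not tids:
            raise ValueError(f"group {g!r} has no tasks")
        stack = np.stack([per_task[t] for t in tids])   # tasks x 16 x 3
        mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=0)
        for ci, ch in enumerate(CHANNELS):
            for bi, b in enumerate(ANALYSIS_BANDS):
                rows.append({"group": g, "channel": ch, "band": b,
                             "mean_db": mean[ci, bi], "sd_db": sd[ci, bi],
                             "n": len(tids)})
    return pd.DataFrame(rows)


def channel_mean_band_levels(table: pd.DataFrame) -> pd.DataFrame:
    """Channel-averaged group band levels (group x band, dB)."""
    return table.pivot_table(index="group", columns="band", values="mean_db",
                             aggfunc="mean")


# --------------------------------------------------------------------------
# Fisher LDA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LDAModel:
    projection: np.ndarray        # p x d
    eigenvalues: np.ndarray       # discriminant eigenvalues, descending
    class_means: pd.DataFrame     # class means in projected space
    ridge: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.projection


def lda_reduce(X: np.ndarray, labels, d: int = 2,
               ridge: float = 1e-6) -> tuple[np.ndarray, LDAModel]:
    """Fisher discriminant projection to d <= (classes - 1) dimensions.

    Solves the generalized eigenproblem on (between-class scatter,
    within-class scatter + ridge * tr(Sw)/p * I); columns ordered by
    eigenvalue descending, sign fixed so the largest-magnitude loading
    entry is positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = list(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if d > len(classes) - 1:
        raise ValueError(f"d={d} exceeds classes-1={len(classes) - 1}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xi = X[y == c]
        mu = Xi.mean(axis=0)
        Sw += (Xi - mu).T @ (Xi - mu)
        Sb += len(Xi) * np.outer(mu - grand, mu - grand)
    lam = ridge * np.trace(Sw) / p if np.trace(Sw) > 0 else ridge
    evals, evecs = linalg.eigh(Sb, Sw + lam * np.eye(p))
    order = np.argsort(evals)[::-1]
    W = evecs[:, order[:d]]
    for j in range(d):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    model = LDAModel(
        projection=W,
        eigenvalues=evals[order[:d]],
        class_means=pd.DataFrame(
            [(X[y == c] @ W).mean(axis=0) for c in classes],
            index=pd.Index(classes, name="class"),
        ),
        ridge=lam,
    )
    return X @ W, model
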