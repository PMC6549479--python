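"""Readers and writers: driving-table CSV, delimited EEG tables, EDF.

EDF support is asymmetric on purpose: reading goes through MNE's native
EDF reader, while writing uses a minimal continuous EDF writer
implemented here (16-bit samples, one-second data records), since no
installed library exposes an EDF write path. Samples quantise to the
16-bit grid, so a write-then-read round trip agrees to within one
quantisation step.
"""

from __future__ import annotations

import datetime as _dt
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import DRIVING_VARIABLES
from .montage import CHANNELS, N_CHANNELS
from .recording import EEGRecording

DRIVING_COLUMNS: tuple[str, ...] = ("subject_id", "task_id", *DRIVING_VARIABLES, "true_style")


# --------------------------------------------------------------------------
# driving tables
# --------------------------------------------------------------------------

def write_driving_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DRIVING_COLUMNS if c in table.columns]
    missing = [c for c in (*DRIVING_VARIABLES, "task_id") if c not in table.columns]
    if missing:
        raise ValueError(f"driving table missing columns: {missing}")
    table[cols].to_csv(path, index=False)


def read_driving_csv(path: str | Path) -> pd.DataFrame:
    """Typed driving-task records; schema violations name the location."""
    df = pd.read_csv(path)
    required = ("task_id", *DRIVING_VARIABLES)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"driving CSV {path}: missing column {col!r}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"driving CSV {path}: non-numeric cell at row {row}, column {col!r}"
            )
        df[col] = coerced
    return df


# --------------------------------------------------------------------------
# delimited EEG tables
# --------------------------------------------------------------------------

def write_eeg_table(rec: EEGRecording, path: str | Path, sep: str = ",") -> None:
    """One column per channel; sampling rate stored on a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {rec.fs}\n")
        fh.write(sep.join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=sep, fmt="%.10g")


def read_eeg_table(path: str | Path, sep: str = ",") -> EEGRecording:
    """Read a delimited EEG table; channel order normalised to canonical."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs_hz" not in first:
            raise ValueError(f"EEG table {path}: missing '# fs_hz: <rate>' header line")
        fs = float(first.split(":", 1)[1])
        header = fh.readline().strip().split(sep)
        data = np.loadtxt(fh, delimiter=sep, ndmin=2)
    return _normalise_channels(data.T, header, fs, path)


def _normalise_channels(data: np.ndarray, names: list[str], fs: float,
                        path) -> EEGRecording:
    names = [n.strip() for n in names]
    unknown = [n for n in names if n not in CHANNELS]
    if unknown:
        raise ValueError(f"EEG file {path}: unknown channel name(s) {unknown}")
    absent = [c for c in CHANNELS if c not in names]
    if absent:
        raise ValueError(f"EEG file {path}: absent channel(s) {absent}")
    order = [names.index(c) for c in CHANNELS]
    return EEGRecording(data=data[order], fs=fs, history=(f"read {Path(path).name}",))


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _format_physical(p: float) -> str:
    """<= 7-character decimal representation of p, rounded up."""
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{p:.{prec}g}"
        if len(s) <= 7:
            while float(s) < p:           # never under-represent the range
                p *= 1 + 10.0 ** (-prec)
                s = f"{p:.{prec}g}"
            if len(s) <= 7:
                return s
    return f"{p * 1.1:.0e}"


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a continuous 16-bit EDF file (one-second data records).

    Requires an integer sampling rate; the final partial second, if any,
    is zero-padded. Physical dimension is 'a.u.' (the pipeline is not
    calibrated to volts); per-channel physical range is symmetric about
    zero so quantisation is sign-balanced.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n = rec.n_samples
    n_rec = int(np.ceil(n / fs))
    data = np.zeros((N_CHANNELS, n_rec * fs))
    data[:, :n] = rec.data

    dig_min, dig_max = -32768, 32767
    # the physical range lives in an 8-character ascii header field
    # (7 chars + sign); format first, rounding up so nothing clips, then
    # digitise against the parsed-back value so reader and writer agree
    raw_pmax = np.maximum(np.abs(data).max(axis=1), 1e-12)
    pmax_str = [_format_physical(p) for p in raw_pmax]
    pmax = np.array([float(s) for s in pmax_str])
    # digitise through the same affine map readers use:
    # physical = (digital - dig_min) * cal + phys_min
    cal = 2 * pmax / (dig_max - dig_min)
    digital = np.clip(
        np.round((data + pmax[:, None]) / cal[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        b"0".ljust(8),
        b"X X X X".ljust(80),
        b"Startdate 01-JAN-2000 X X X".ljust(80),
        now.strftime("%d.%m.%y").encode().ljust(8),
        now.strftime("%H.%M.%S").encode().ljust(8),
        str(256 * (1 + N_CHANNELS)).encode().ljust(8),
        b"EDF+C".ljust(44),
        str(n_rec).encode().ljust(8),
        b"1".ljust(8),
        str(N_CHANNELS).encode().ljust(4),
    ])
    fields = []
    fields.append(b"".join(f"EEG {ch}".encode().ljust(16) for ch in rec.channels))
    fields.append(b"".join(b" ".ljust(80) for _ in rec.channels))
    fields.append(b"".join(b"a.u.".ljust(8) for _ in rec.channels))
    fields.append(b"".join(("-" + s).encode()[:8].ljust(8) for s in pmax_str))
    fields.append(b"".join(s.encode()[:8].ljust(8) for s in pmax_str))
    fields.append(b"".join(str(dig_min).encode().ljust(8) for _ in rec.channels))
    fields.append(b"".join(str(dig_max).encode().ljust(8) for _ in rec.channels))
    fields.append(b"".join(b" ".ljust(80) for _ in rec.channels))
    fields.append(b"".join(str(fs).encode().ljust(8) for _ in rec.channels))
    fields.append(b"".join(b" ".ljust(32) for _ in rec.channels))

    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def edf_quantisation_step(rec: EEGRecording) -> np.ndarray:
    """Per-channel amplitude resolution of the 16-bit EDF encoding."""
    pmax = np.maximum(np.abs(rec.data).max(axis=1), 1e-12)
    return 2 * np.array([float(_format_physical(p)) for p in pmax]) / 65535


def read_edf(path: str | Path) -> EEGRecording:
    """Read a 16-channel EDF via MNE; channel order normalised."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    fs = float(raw.info["sfreq"])
    # channels carry dimension 'a.u.', which MNE passes through unscaled
    data = raw.get_data()
    return _normalise_channels(np.asarray(data, dtype=float), names, fs, path)


def read_eeg(path: str | Path) -> EEGRecording:
    """Dispatch on extension: .edf via MNE, otherwise delimited table."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return read_edf(p)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    return read_eeg_table(p, sep=sep)
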