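"""In-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS, N_CHANNELS


@dataclass
class EEGRecording:
    """Channels x samples EEG matrix with metadata.

    data is float64, shape (16, n_samples), in arbitrary units (the
    acquisition chain is not calibrated to physical volts). ``reference``
    is ``"original"`` until average re-referencing. ``history`` is an
    append-only log of processing steps.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS
    reference: str = "original"
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"data must be ({N_CHANNELS}, n_samples); got {self.data.shape}"
            )
        if tuple(self.channels) != CHANNELS:
            raise ValueError("channel names/order must match the canonical montage")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def evolve(self, data: np.ndarray | None = None, *, step: str,
               fs: float | None = None, reference: str | None = None) -> "EEGRecording":
        """Copy with new data and the step appended to the history."""
        return replace(
            self,
            data=self.data if data is None else data,
            fs=self.fs if fs is None else fs,
            reference=self.reference if reference is None else reference,
            history=self.history + (step,),
        )
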