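"""Multichannel EEG container and preprocessing.

Recordings are held as a plain ``channels x samples`` float array in
microvolts together with the sampling rate and 10-20 channel labels.
Preprocessing is limited to zero-phase band-pass filtering and detection
of amplitude-clipped epochs; artifact rejection by visual review is a
human step and is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: Reduced 9-electrode neonatal montage (10-20 system).
REDUCED_9 = ("Fp1", "Fp2", "C3", "C4", "T4", "T3", "O1", "O2", "Cz")

#: Full 19-electrode 10-20 montage.
FULL_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Homologous left/right electrode pairs (left listed first).
HOMOLOGOUS_PAIRS = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
    ("O1", "O2"), ("F7", "F8"), ("T3", "T4"), ("T5", "T6"),
)

_LEFT = {l for l, _ in HOMOLOGOUS_PAIRS}
_RIGHT = {r for _, r in HOMOLOGOUS_PAIRS}
_MIDLINE = {"Fz", "Cz", "Pz"}


def channel_hemisphere(label: str) -> str:
    """Return ``left``, ``right`` or ``midline`` for a 10-20 label."""
    if label in _LEFT:
        return "left"
    if label in _RIGHT:
        return "right"
    if label in _MIDLINE:
        return "midline"
    raise ValueError(f"unknown 10-20 channel label: {label!r}")


@dataclass
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique 10-20 electrode labels, one per row of ``data``.
    subject_id : str
        Identifier carried through feature tables and EDF metadata.
    ga_weeks : float or None
        Gestational age at recording, weeks.
    extras : dict
        Free-form side information (e.g. generator burst-state tracks).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    subject_id: str = ""
    ga_weeks: float | None = None
    extras: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the single-channel series for ``label`` (µV)."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[i]


def bandpass(rec: EEGRecording, lo: float = 0.5, hi: float = 30.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Default 0.5-30 Hz, the analysis band spanned by the neonatal
    frequency-band definitions.
    """
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={rec.fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(data, rec.fs, rec.channel_labels, rec.subject_id,
                        rec.ga_weeks, dict(rec.extras))


def clipped_epochs(rec: EEGRecording, epoch_s: float = 2.0,
                   threshold_uv: float = 500.0) -> np.ndarray:
    """Flag epochs whose absolute amplitude exceeds ``threshold_uv`` on any channel.

    Returns a boolean array over non-overlapping epochs; flagged epochs
    indicate probable clipping/movement artifact.
    """
    step = int(round(epoch_s * rec.fs))
    n_ep = rec.n_samples // step
    if n_ep == 0:
        return np.zeros(0, dtype=bool)
    x = np.abs(rec.data[:, : n_ep * step]).reshape(rec.n_channels, n_ep, step)
    return (x.max(axis=2) > threshold_uv).any(axis=0)
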