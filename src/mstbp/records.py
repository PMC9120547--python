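"""Shared waveform containers.

A :class:`Record` holds synchronized single-lead ECG, PPG, and invasive ABP
waveforms sampled at a common rate (125 Hz by default, matching bedside
monitor extracts). ECG and PPG are in arbitrary units; ABP is in mmHg and is
the source of reference blood-pressure labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FS = 125.0


@dataclass
class Record:
    """Synchronized ECG/PPG/ABP sample arrays at a fixed sampling rate."""

    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError(
                f"channel lengths differ: ecg={len(self.ecg)} "
                f"ppg={len(self.ppg)} abp={len(self.abp)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.abp)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.fs

    def copy(self) -> "Record":
        return Record(
            self.ecg.copy(), self.ppg.copy(), self.abp.copy(), self.fs, self.subject_id
        )


@dataclass
class BeatAnnotations:
    """Ground-truth per-beat markers for a synthetic record.

    Indices are integer sample positions at the record's sampling rate.
    ``trough_indices[j]`` is the diastolic minimum *between* systolic peaks
    ``j`` and ``j+1``, so there is one fewer trough than peaks.
    """

    peak_indices: np.ndarray
    peak_values: np.ndarray
    trough_indices: np.ndarray
    trough_values: np.ndarray
    beat_starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        self.trough_values = np.asarray(self.trough_values, dtype=float)

    @property
    def n_beats(self) -> int:
        return len(self.peak_indices)
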