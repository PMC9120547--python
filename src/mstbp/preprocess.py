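"""Raw-record preprocessing: segmentation, beat detection, labels, denoising.

The pipeline turns a synchronized ECG/PPG/ABP record into model-ready pairs:
an 8-s two-channel (ECG, PPG) input window scaled to [-1, 1], and its
reference SBP/DBP/MAP label triple extracted from the ABP channel.

Arterial peak detection enforces two physiological constraints that together
reject dicrotic "false peaks" and corrupt beats: retained systolic peaks must
be at least 0.6 s apart (a greedy highest-first suppression), and beats whose
systolic value falls outside [80, 180] mmHg or whose diastolic value falls
outside [60, 130] mmHg are discarded.

ECG and PPG are denoised with a Daubechies-8 discrete wavelet decomposition:
the level-1 detail band (the top dyadic octave, 31.25-62.5 Hz at 125 Hz) and
the deepest approximation band (baseline drift) are zeroed, the remaining
detail levels are soft-thresholded, and the signal is reconstructed. ECG uses
seven levels (baseline band 0-0.49 Hz), PPG eight (0-0.24 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import argrelmax

from .records import Record

__all__ = [
    "BeatSet",
    "BPLabels",
    "Segment",
    "segment_record",
    "detect_abp_beats",
    "extract_labels",
    "dwt_denoise",
    "soft_threshold",
    "layer_normalize",
    "build_segments",
]

SBP_RANGE = (80.0, 180.0)
DBP_RANGE = (60.0, 130.0)
LABEL_RANGE = (60.0, 180.0)
MIN_PEAK_GAP_S = 0.6
SEGMENT_SECONDS = 8.0
ECG_DWT_LEVELS = 7
PPG_DWT_LEVELS = 8


@dataclass
class BeatSet:
    """Retained systolic peaks and the diastolic troughs between them."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        self.trough_values = np.asarray(self.trough_values, dtype=float)

    @property
    def n_beats(self) -> int:
        return len(self.peak_indices)

    @property
    def is_empty(self) -> bool:
        return self.n_beats == 0


@dataclass(frozen=True)
class BPLabels:
    """SBP/DBP/MAP triple in mmHg (reference or estimated)."""

    sbp: float
    dbp: float
    map: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sbp, self.dbp, self.map], dtype=float)


@dataclass
class Segment:
    """One 8-s model input: x is (2, 1000) with channel order (ECG, PPG)."""

    x: np.ndarray
    labels: BPLabels
    subject_id: str = ""
    start_index: int = 0


def segment_record(record: Record, length_s: float = SEGMENT_SECONDS) -> list[Record]:
    """Cut a record into non-overlapping windows of ``length_s`` seconds.

    All three channels are cut synchronously; a trailing partial window is
    discarded. A record shorter than one window yields an empty list.
    """
    win = int(round(length_s * record.fs))
    n = len(record) // win
    return [
        Record(
            record.ecg[i * win : (i + 1) * win],
            record.ppg[i * win : (i + 1) * win],
            record.abp[i * win : (i + 1) * win],
            record.fs,
            record.subject_id,
        )
        for i in range(n)
    ]


def _suppress_close_peaks(candidates: np.ndarray, values: np.ndarray, min_gap: float) -> np.ndarray:
    """Greedy highest-first suppression within the exclusion window.

    Keeps the highest candidate, removes all others within ``min_gap``
    samples of it, and repeats — a deterministic, order-independent reading
    of the peak-to-peak time limit.
    """
    order = np.argsort(values, kind="stable")[::-1]
    keep: list[int] = []
    for i in order:
        if all(abs(candidates[i] - candidates[j]) > min_gap for j in keep):
            keep.append(i)
    return np.sort(candidates[keep])


def detect_abp_beats(abp: np.ndarray, fs: float) -> BeatSet:
    """Detect valid systolic peaks and diastolic troughs in an ABP trace.

    Candidates are strict local maxima; any candidate closer than
    ``0.6 * fs`` samples to a higher retained peak is suppressed (dicrotic
    false-peak rejection); peaks outside [80, 180] mmHg are dropped; each
    trough is the minimum between consecutive retained peaks and beats with a
    trough outside [60, 130] mmHg are dropped. Returns an empty BeatSet for
    flat or beat-free signals.
    """
    abp = np.asarray(abp, dtype=float)
    if not np.all(np.isfinite(abp)):
        raise ValueError("ABP signal contains non-finite samples")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    candidates = argrelmax(abp)[0]
    if len(candidates) == 0:
        return BeatSet([], [], [], [])
    peaks = _suppress_close_peaks(candidates, abp[candidates], MIN_PEAK_GAP_S * fs)
    in_range = (abp[peaks] >= SBP_RANGE[0]) & (abp[peaks] <= SBP_RANGE[1])
    peaks = peaks[in_range]
    # troughs between consecutive retained peaks; iterate the diastolic
    # amplitude rule until stable since removing a peak merges two spans
    while True:
        if len(peaks) == 0:
            return BeatSet([], [], [], [])
        troughs = np.array(
            [a + np.argmin(abp[a : b + 1]) for a, b in zip(peaks[:-1], peaks[1:])],
            dtype=int,
        )
        bad = (abp[troughs] < DBP_RANGE[0]) | (abp[troughs] > DBP_RANGE[1])
        if not np.any(bad):
            break
        # drop the beat that ends at the offending trough (its preceding peak)
        first_bad = int(np.flatnonzero(bad)[0])
        peaks = np.delete(peaks, first_bad)
    return BeatSet(peaks, troughs, abp[peaks], abp[troughs])


def extract_labels(beats: BeatSet, aggregate: str = "mean") -> BPLabels:
    """Aggregate a window's beats into one reference SBP/DBP/MAP triple.

    SBP is the aggregate of peak values, DBP of trough values, and
    MAP = (SBP + 2 DBP) / 3. ``aggregate`` is "mean" (default) or "median".
    """
    if beats.is_empty or len(beats.trough_values) == 0:
        raise ValueError("cannot extract labels from an empty beat set")
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    sbp = float(agg(beats.peak_values))
    dbp = float(agg(beats.trough_values))
    return BPLabels(sbp=sbp, dbp=dbp, map=(sbp + 2.0 * dbp) / 3.0)


def soft_threshold(coeffs: np.ndarray, thr: float) -> np.ndarray:
    """Soft shrinkage: sign(c) * max(|c| - thr, 0)."""
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    coeffs = np.asarray(coeffs, dtype=float)
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - thr, 0.0)


def _universal_threshold(detail1: np.ndarray, n: int) -> float:
    """sigma * sqrt(2 ln n) with sigma from the MAD of the finest details."""
    sigma = np.median(np.abs(detail1)) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(max(n, 2))))


def dwt_denoise(
    signal: np.ndarray,
    n_levels: int,
    wavelet_name: str = "db8",
    threshold: bool = True,
    zero_bands: bool = True,
) -> np.ndarray:
    """Daubechies wavelet denoising of a physiological trace.

    Decomposes to ``n_levels`` with symmetric extension, zeroes the level-1
    detail coefficients (high-frequency band) and the deepest approximation
    coefficients (baseline band), soft-thresholds the remaining detail levels
    with the universal threshold, and reconstructs to the original length.
    ``threshold=False`` / ``zero_bands=False`` disable those stages (with
    both off the round trip is the identity up to float error).
    """
    x = np.asarray(signal, dtype=float)
    min_len = 2**n_levels
    if len(x) < min_len:
        raise ValueError(
            f"signal of length {len(x)} too short for {n_levels} levels; "
            f"need at least {min_len} samples"
        )
    with warnings.catch_warnings():
        # levels beyond pywt's "useful" maximum are intentional here: the
        # deepest approximation must isolate the sub-0.5 Hz baseline band
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet_name, mode="symmetric", level=n_levels)
    # coeffs = [cA_n, cD_n, ..., cD_1]
    if threshold:
        thr = _universal_threshold(coeffs[-1], len(x))
        for i in range(1, len(coeffs) - 1):
            coeffs[i] = soft_threshold(coeffs[i], thr)
    if zero_bands:
        coeffs[0] = np.zeros_like(coeffs[0])
        coeffs[-1] = np.zeros_like(coeffs[-1])
    out = pywt.waverec(coeffs, wavelet_name, mode="symmetric")
    return out[: len(x)]


def layer_normalize(signal: np.ndarray) -> np.ndarray:
    """Rescale one channel of one segment to span exactly [-1, 1]."""
    x = np.asarray(signal, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant channel")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def build_segments(
    record: Record,
    length_s: float = SEGMENT_SECONDS,
    denoise: bool = True,
    min_duration_s: float = 0.0,
    aggregate: str = "mean",
    log: list[str] | None = None,
) -> list[Segment]:
    """Full preprocessing: record -> accepted (x, y) segments.

    Composes segmentation, per-window ABP beat detection, label extraction,
    ECG/PPG wavelet denoising (7 and 8 levels), and [-1, 1] normalization.
    Windows with no valid beat, any out-of-range beat removed by the
    amplitude rules, labels outside [60, 180] mmHg, or a constant channel are
    dropped. The ABP channel is consumed only for labels and never enters x.
    ``min_duration_s`` is a record-level gate (the bedside-data pipeline uses
    8 min; synthetic fixtures leave it off). ``log`` collects one
    accept/reject line per window when provided.
    """

    def note(msg: str) -> None:
        if log is not None:
            log.append(msg)

    if record.duration < min_duration_s:
        note(f"record {record.subject_id}: rejected (shorter than {min_duration_s} s)")
        return []
    segments: list[Segment] = []
    win = int(round(length_s * record.fs))
    for i, window in enumerate(segment_record(record, length_s)):
        tag = f"{record.subject_id}[{i * win}:{(i + 1) * win}]"
        naive = argrelmax(window.abp)[0]
        beats = detect_abp_beats(window.abp, window.fs)
        if beats.is_empty or len(beats.trough_values) == 0:
            note(f"{tag}: rejected (no valid beats)")
            continue
        if len(naive) and np.any(
            (window.abp[naive] > SBP_RANGE[1]) | (window.abp[naive] < 0)
        ):
            note(f"{tag}: rejected (out-of-range beat amplitude)")
            continue
        if beats.n_beats < len(
            _suppress_close_peaks(naive, window.abp[naive], MIN_PEAK_GAP_S * window.fs)
        ):
            note(f"{tag}: rejected (beat removed by amplitude rules)")
            continue
        labels = extract_labels(beats, aggregate)
        if not all(
            LABEL_RANGE[0] <= v <= LABEL_RANGE[1] for v in (labels.sbp, labels.dbp, labels.map)
        ):
            note(f"{tag}: rejected (labels outside {LABEL_RANGE} mmHg)")
            continue
        ecg, ppg = window.ecg, window.ppg
        if denoise:
            ecg = dwt_denoise(ecg, ECG_DWT_LEVELS)
            ppg = dwt_denoise(ppg, PPG_DWT_LEVELS)
        try:
            x = np.stack([layer_normalize(ecg), layer_normalize(ppg)])
        except ValueError:
            note(f"{tag}: rejected (constant channel)")
            continue
        note(f"{tag}: accepted (sbp={labels.sbp:.1f} dbp={labels.dbp:.1f})")
        segments.append(Segment(x=x, labels=labels, subject_id=record.subject_id, start_index=i * win))
    return segments
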