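"""Synthetic physiological waveform generator.

Produces ECG/PPG/ABP records with exactly known per-beat systolic and
diastolic pressures so that beat detection, label extraction, denoising, and
the regression network can all be exercised against ground truth.

The arterial pulse is built from trough-to-trough beat segments: a cosine
smoothstep interpolates the diastolic floor between consecutive beats and a
raised-cosine upstroke/decay rides on top of it, so the sampled maximum of
beat *k* equals ``sbp_series[k]`` and the sampled minimum between two peaks
equals the following beat's diastolic target, both to machine precision. A
truncated-Gaussian dicrotic bump after each systolic peak models the
reflected wave; its support excludes the peak and trough samples so the
amplitude guarantees survive. Raising the bump (``false_peak_boost``) turns
it into a genuine local maximum, emulating the dicrotic "false peaks" that
plague naive ABP peak counting.

ECG is a narrow triangular R-spike train (with small P/T bumps) preceding
each ABP peak by the pulse-transit delay; PPG is a low-pass-filtered,
delayed, unit-rescaled copy of the ABP pulse. Neither aims at clinical
realism — they only need to be morphologically distinct periodic channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import DEFAULT_FS, BeatAnnotations, Record

__all__ = [
    "PhysioParams",
    "generate_record",
    "inject_artifacts",
    "make_dataset",
    "DEFAULT_PARAM_RANGES",
]


@dataclass
class PhysioParams:
    """Generator parameters for one synthetic record.

    Pressures are mmHg, times are seconds, ``sampling_rate`` is Hz. The
    per-beat series must both have one entry per beat
    (``floor(duration * heart_rate / 60)``) or be left ``None`` for the
    120/80 default.
    """

    sampling_rate: float = DEFAULT_FS
    duration: float = 8.0
    heart_rate: float = 75.0
    sbp_series: np.ndarray | None = None
    dbp_series: np.ndarray | None = None
    systolic_rise: float = 0.19  # trough-to-peak time, s
    dicrotic_rel_amp: float = 0.08  # fraction of pulse amplitude
    dicrotic_delay: float = 0.30  # s after the systolic peak
    dicrotic_width: float = 0.06  # Gaussian sigma, s
    ptt_delay: float = 0.20  # ECG R-wave precedes ABP peak by this, s
    drift_amp: float = 0.0  # baseline-wander sinusoid amplitude (a.u.)
    drift_freq: float = 0.2  # Hz, must stay below 0.5
    hf_noise_sd: float = 0.0  # additive high-frequency noise amplitude
    hf_noise_band: float = 35.0  # Hz, must stay above 31
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if 60.0 / self.heart_rate <= self.dicrotic_delay:
            raise ValueError("beat period must exceed the dicrotic delay")
        if not 0 <= self.dicrotic_rel_amp < 1:
            raise ValueError("dicrotic_rel_amp must lie in [0, 1)")
        n = self.n_beats
        if self.sbp_series is None:
            self.sbp_series = np.full(n, 120.0)
        if self.dbp_series is None:
            self.dbp_series = np.full(n, 80.0)
        self.sbp_series = np.asarray(self.sbp_series, dtype=float)
        self.dbp_series = np.asarray(self.dbp_series, dtype=float)
        if len(self.sbp_series) != n or len(self.dbp_series) != n:
            raise ValueError(
                f"per-beat series must have length {n} "
                f"(got {len(self.sbp_series)}/{len(self.dbp_series)})"
            )
        if np.any(self.sbp_series <= self.dbp_series):
            raise ValueError("every beat needs sbp > dbp")

    @property
    def n_beats(self) -> int:
        return int(np.floor(self.duration * self.heart_rate / 60.0))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Cosine smoothstep: 0 at x=0, 1 at x=1, zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _truncated_gaussian(idx: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Gaussian rescaled to hit exactly zero at the +-4 sigma truncation."""
    g = np.exp(-0.5 * ((idx - center) / sigma) ** 2)
    floor = np.exp(-8.0)
    return np.clip((g - floor) / (1.0 - floor), 0.0, None)


def _abp_pulse_train(
    params: PhysioParams, boost: float = 0.0
) -> tuple[np.ndarray, BeatAnnotations]:
    fs = params.sampling_rate
    n_samples = int(round(params.duration * fs))
    n_beats = params.n_beats
    period = fs * 60.0 / params.heart_rate
    starts = np.round(np.arange(n_beats + 1) * period).astype(int)
    starts = np.minimum(starts, n_samples)
    peak_off = int(round(params.systolic_rise * fs))

    sbp = params.sbp_series
    dbp = params.dbp_series
    # diastolic target at the *end* of each beat = next beat's DBP
    dbp_next = np.append(dbp[1:], dbp[-1])
    if np.any(sbp <= np.maximum(dbp, dbp_next)):
        raise ValueError("sbp must exceed the diastolic floor on both beat ends")

    abp = np.full(n_samples, dbp[-1], dtype=float)
    peak_idx = np.empty(n_beats, dtype=int)
    for k in range(n_beats):
        s0, s1 = starts[k], starts[k + 1]
        length = s1 - s0
        if length <= peak_off + 1:
            raise ValueError("beat period too short for the systolic rise time")
        j = np.arange(length)
        # diastolic floor: flat at dbp[k] through the systolic peak, then a
        # cosine smoothstep to the next beat's diastolic level; zero slope at
        # the peak and at both beat boundaries keeps the annotated extrema
        # exact even when per-beat DBP varies (requires sbp > next dbp)
        floor_k = np.full(length, dbp[k])
        decay_j = j[peak_off:] - peak_off
        floor_k[peak_off:] += (dbp_next[k] - dbp[k]) * _smoothstep(
            decay_j / (length - peak_off)
        )
        shape = np.empty(length)
        shape[: peak_off + 1] = _smoothstep(j[: peak_off + 1] / peak_off)
        shape[peak_off:] = 0.5 * (
            1.0 + np.cos(np.pi * (j[peak_off:] - peak_off) / (length - peak_off))
        )
        pk = s0 + peak_off
        beat = floor_k + (sbp[k] - floor_k[peak_off]) * shape
        # dicrotic bump: support excludes the peak and trough samples so the
        # annotated extrema stay exact
        amp = (params.dicrotic_rel_amp + boost) * (sbp[k] - dbp[k])
        if amp > 0:
            center = peak_off + params.dicrotic_delay * fs
            sigma = max(params.dicrotic_width * fs, 1.0)
            lo = max(peak_off + 2, int(np.floor(center - 4 * sigma)))
            hi = min(length - 1, int(np.ceil(center + 4 * sigma)) + 1)
            if lo < hi:
                beat[lo:hi] += amp * _truncated_gaussian(j[lo:hi], center, sigma)
        abp[s0:s1] = beat
        peak_idx[k] = pk
        abp[pk] = sbp[k]  # exact by construction; reassert against fp rounding

    trough_idx = starts[1:n_beats]
    ann = BeatAnnotations(
        peak_indices=peak_idx,
        peak_values=sbp.copy(),
        trough_indices=trough_idx,
        trough_values=dbp[1:n_beats].copy(),
        beat_starts=starts[:n_beats].copy(),
    )
    return abp, ann


def _ecg_trace(params: PhysioParams, peak_idx: np.ndarray, n: int) -> np.ndarray:
    fs = params.sampling_rate
    ecg = np.zeros(n)
    idx = np.arange(n, dtype=float)
    r_half = max(int(round(0.02 * fs)), 1)
    for pk in peak_idx:
        r = pk - int(round(params.ptt_delay * fs))
        if r < 0:
            continue
        lo, hi = max(r - r_half, 0), min(r + r_half + 1, n)
        ecg[lo:hi] = np.maximum(
            ecg[lo:hi], 1.0 - np.abs(np.arange(lo, hi) - r) / r_half
        )
        # small P and T deflections
        for c, a, s in ((r - 0.15 * fs, 0.12, 0.03 * fs), (r + 0.25 * fs, 0.25, 0.05 * fs)):
            lo2 = max(int(c - 4 * s), 0)
            hi2 = min(int(c + 4 * s) + 1, n)
            if lo2 < hi2:
                ecg[lo2:hi2] += a * _truncated_gaussian(idx[lo2:hi2], c, s)
    return ecg


def _ppg_trace(params: PhysioParams, abp: np.ndarray) -> np.ndarray:
    fs = params.sampling_rate
    b, a = sps.butter(3, 8.0 / (fs / 2.0), btype="low")
    smooth = sps.filtfilt(b, a, abp)
    delay = max(int(round(0.06 * fs)), 1)
    delayed = np.concatenate([np.full(delay, smooth[0]), smooth[:-delay]])
    lo, hi = delayed.min(), delayed.max()
    if hi <= lo:
        return np.zeros_like(delayed)
    return (delayed - lo) / (hi - lo)


def generate_record(params: PhysioParams) -> tuple[Record, BeatAnnotations]:
    """Generate one synthetic record plus its ground-truth beat annotations.

    With all noise/drift parameters at zero the k-th ABP beat's maximum is
    exactly ``sbp_series[k]`` and the minimum between peaks k and k+1 is
    exactly ``dbp_series[k+1]``. Deterministic under ``params.seed``.
    """
    abp, ann = _abp_pulse_train(params)
    ecg = _ecg_trace(params, ann.peak_indices, len(abp))
    ppg = _ppg_trace(params, abp)
    record = Record(ecg, ppg, abp, params.sampling_rate, params.subject_id)
    if params.drift_amp > 0 or params.hf_noise_sd > 0:
        record = inject_artifacts(
            record,
            drift_amp=params.drift_amp,
            drift_freq=params.drift_freq,
            hf_noise_sd=params.hf_noise_sd,
            hf_noise_band=params.hf_noise_band,
            seed=params.seed,
        )
    return record, ann


def inject_artifacts(
    record: Record,
    drift_amp: float = 0.0,
    drift_freq: float = 0.2,
    hf_noise_sd: float = 0.0,
    false_peak_boost: float = 0.0,
    hf_noise_band: float = 35.0,
    annotations: BeatAnnotations | None = None,
    seed: int = 0,
) -> Record:
    """Return a corrupted copy of ``record``; the input is untouched.

    Baseline drift (a sub-0.5 Hz sinusoid) and band-limited high-frequency
    noise (above 31 Hz) are added to the ECG and PPG channels — the bands the
    wavelet denoiser targets. ``false_peak_boost`` raises each dicrotic bump
    of the ABP channel by ``boost * pulse_amplitude`` so the bumps become
    strict local maxima (detectable false peaks); it requires the generator
    ``annotations`` to locate the beats.
    """
    fs = record.fs
    if drift_freq >= fs / 2.0:
        raise ValueError("drift_freq must be below the Nyquist frequency")
    if drift_amp > 0 and drift_freq >= 0.5:
        raise ValueError("baseline drift must stay below 0.5 Hz")
    if hf_noise_sd > 0 and hf_noise_band <= 31.0:
        raise ValueError("high-frequency noise band must lie above 31 Hz")
    out = record.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    if drift_amp > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        drift = drift_amp * np.sin(2 * np.pi * drift_freq * t + phase)
        out.ecg += drift
        out.ppg += drift
    if hf_noise_sd > 0:
        b, a = sps.butter(4, hf_noise_band / (fs / 2.0), btype="high")
        for chan in (out.ecg, out.ppg):
            noise = sps.lfilter(b, a, rng.standard_normal(n))
            noise *= hf_noise_sd / max(noise.std(), 1e-12)
            chan += noise
    if false_peak_boost > 0:
        if annotations is None:
            raise ValueError("false_peak_boost requires generator annotations")
        idx = np.arange(n, dtype=float)
        sigma = max(0.02 * fs, 1.0)
        starts = annotations.beat_starts
        for k, pk in enumerate(annotations.peak_indices):
            pulse = annotations.peak_values[k] - (
                annotations.trough_values[k - 1]
                if k > 0
                else annotations.trough_values[0]
                if len(annotations.trough_values)
                else 40.0
            )
            center = float(pk + 0.30 * fs)
            end = starts[k + 1] if k + 1 < len(starts) else n
            lo = max(pk + 2, int(center - 4 * sigma))
            hi = min(end - 1, int(center + 4 * sigma) + 1)
            if lo < hi:
                out.abp[lo:hi] += (
                    false_peak_boost * pulse * _truncated_gaussian(idx[lo:hi], center, sigma)
                )
    return out


#: Default sampling windows for :func:`make_dataset`. Diastolic and pulse
#: pressures are drawn so SBP stays within [80, 180] and DBP within [60, 130]
#: mmHg, the label window used for reference-beat filtering.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate": (60.0, 90.0),
    "dbp": (60.0, 105.0),
    "pulse_pressure": (30.0, 60.0),
    "beat_jitter_sd": (0.5, 1.5),
}


def make_dataset(
    n_records: int,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    duration: float = 24.0,
    **param_overrides,
) -> list[tuple[Record, BeatAnnotations]]:
    """Draw ``n_records`` records with per-record physiology sampled uniformly.

    Each record gets a heart rate, mean DBP, and pulse pressure from
    ``param_ranges`` plus small per-beat Gaussian jitter; labels therefore
    vary both between and within records while staying inside the default
    SBP [80, 180] / DBP [60, 130] mmHg window. Reproducible under ``seed``.
    """
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    dataset = []
    for i in range(n_records):
        hr = rng.uniform(*ranges["heart_rate"])
        dbp0 = rng.uniform(*ranges["dbp"])
        pp = rng.uniform(*ranges["pulse_pressure"])
        jitter = rng.uniform(*ranges["beat_jitter_sd"])
        n_beats = int(np.floor(duration * hr / 60.0))
        dbp = np.clip(dbp0 + jitter * rng.standard_normal(n_beats), 60.0, 130.0)
        sbp = np.clip(dbp + pp + jitter * rng.standard_normal(n_beats), 80.0, 180.0)
        params = PhysioParams(
            duration=duration,
            heart_rate=hr,
            sbp_series=sbp,
            dbp_series=dbp,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"synthetic-{i:04d}",
            **param_overrides,
        )
        dataset.append(generate_record(params))
    return dataset
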