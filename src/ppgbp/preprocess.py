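"""Signal preprocessing: from raw recordings to model input triples.

Per PPG channel the chain is band-pass filter -> beat-peak detection ->
cubic-spline envelope -> first/second differences, producing
X1 = [Xp, dXp, d2Xp] and X2 = [Xe, dXe, d2Xe] (each 3 x 1720 for a 40-s,
43-Hz recording).  The force channel is low-pass filtered and a 10-s window
centred on the envelope maximum is cut and resampled to X3 (1 x 215).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessError",
    "PreparedCase",
    "bandpass_ppg",
    "lowpass_force",
    "detect_peaks",
    "compute_envelope",
    "derivatives",
    "segment_force",
    "prepare_case",
]

PPG_BAND_HZ = (0.8, 8.0)
FORCE_CUTOFF_HZ = 0.2
FILTER_ORDER = 4
MAX_PLAUSIBLE_HR_BPM = 180.0
SEGMENT_HALF_WIDTH_S = 5.0
FORCE_SEGMENT_LEN = 215  # 10 s at an effective 21.5 Hz
PPG_STREAM_LEN = 1720  # 40 s at 43 Hz
MIN_PEAKS = 4


class PreprocessError(ValueError):
    """A case that cannot be preprocessed; the message names case/channel."""


@dataclass
class PreparedCase:
    """Model-ready tensors for one case.

    x1, x2: (9, 3, 1720) float arrays — per channel the filtered PPG
    (resp. its envelope) stacked with first and second differences.
    x3: (1, 215) — the segmented, filtered force, shared across channels.
    """

    case_id: str
    subject_id: str
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    ref_sbp: float
    ref_dbp: float

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=np.float32)
        self.x2 = np.asarray(self.x2, dtype=np.float32)
        self.x3 = np.asarray(self.x3, dtype=np.float32)
        if self.x1.shape != self.x2.shape or self.x1.shape[0] != 9:
            raise ValueError("x1/x2 must both be (9, 3, T)")
        if self.x3.ndim != 2 or self.x3.shape[0] != 1:
            raise ValueError("x3 must be (1, L)")
        for name, a in (("x1", self.x1), ("x2", self.x2), ("x3", self.x3)):
            if not np.isfinite(a).all():
                raise ValueError(f"{name} contains non-finite values")


def _sos(kind: str, cutoff, fs: float) -> np.ndarray:
    return signal.butter(FILTER_ORDER, cutoff, btype=kind, fs=fs, output="sos")


def bandpass_ppg(raw_channel: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 0.8–8 Hz."""
    x = np.asarray(raw_channel, dtype=float)
    if fs <= 2 * PPG_BAND_HZ[1]:
        raise PreprocessError(f"fs={fs} Hz leaves no room above the 8 Hz cutoff")
    sos = _sos("bandpass", PPG_BAND_HZ, fs)
    if x.size <= 24:  # sosfiltfilt padding needs some run-in
        raise PreprocessError(f"signal too short to filter ({x.size} samples)")
    return signal.sosfiltfilt(sos, x)


def lowpass_force(raw_force: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass, 0.2 Hz cutoff."""
    x = np.asarray(raw_force, dtype=float)
    if fs <= 2 * FORCE_CUTOFF_HZ:
        raise PreprocessError(f"fs={fs} Hz below Nyquist for the 0.2 Hz cutoff")
    if x.size <= 24:
        raise PreprocessError(f"signal too short to filter ({x.size} samples)")
    return signal.sosfiltfilt(_sos("lowpass", FORCE_CUTOFF_HZ, fs), x)


def detect_peaks(xp: np.ndarray, fs: float) -> np.ndarray:
    """Beat peaks of the filtered PPG.

    Enforces a minimum inter-peak distance corresponding to 180 bpm, the
    fastest plausible heart rate.  Raises if fewer than 4 peaks remain.
    """
    x = np.asarray(xp, dtype=float)
    if x.size < 2 * fs:
        raise PreprocessError("need at least 2 s of signal for peak detection")
    min_dist = max(1, int(round(fs * 60.0 / MAX_PLAUSIBLE_HR_BPM)))
    peaks, _ = signal.find_peaks(x, distance=min_dist)
    if peaks.size < MIN_PEAKS:
        raise PreprocessError(
            f"only {peaks.size} peaks found (< {MIN_PEAKS}); case rejected"
        )
    return peaks


def compute_envelope(xp: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Upper envelope: cubic spline through (peak index, peak value) knots,
    held constant at the first/last peak value beyond the outermost peaks."""
    x = np.asarray(xp, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < MIN_PEAKS:
        raise PreprocessError("envelope needs at least 4 peaks")
    spline = CubicSpline(peaks.astype(float), x[peaks])
    idx = np.arange(x.size, dtype=float)
    env = spline(np.clip(idx, peaks[0], peaks[-1]))
    return env


def derivatives(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second forward differences, last value repeated so both
    outputs keep the input length."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise PreprocessError("need at least 3 samples for differences")

    def fwd(v: np.ndarray) -> np.ndarray:
        d = np.diff(v)
        return np.concatenate([d, d[-1:]])

    d1 = fwd(x)
    return d1, fwd(d1)


def segment_force(
    filtered_force: np.ndarray,
    envelope: np.ndarray,
    fs_force: float,
    out_len: int = FORCE_SEGMENT_LEN,
) -> np.ndarray:
    """Cut a 10-s window of the filtered force centred at the envelope
    maximum and resample it (linear interpolation) to `out_len` samples.

    A centre closer than 5 s to either edge shifts the window inside the
    recording (logged as a warning).
    """
    f = np.asarray(filtered_force, dtype=float)
    env = np.asarray(envelope, dtype=float)
    duration = f.size / fs_force
    if duration < 2 * SEGMENT_HALF_WIDTH_S:
        raise PreprocessError(
            f"recording of {duration:.1f}s shorter than the 10 s segment window"
        )
    t_center = int(np.argmax(env)) / fs_force
    t_start = t_center - SEGMENT_HALF_WIDTH_S
    t_end = t_center + SEGMENT_HALF_WIDTH_S
    last_t = (f.size - 1) / fs_force
    if t_start < 0 or t_end > last_t:
        shift = -t_start if t_start < 0 else last_t - t_end
        t_start += shift
        t_end += shift
        logger.warning(
            "envelope maximum at %.2f s is within 5 s of an edge; "
            "force window shifted by %.2f s",
            t_center,
            shift,
        )
    t_grid = np.linspace(t_start, t_end, out_len)
    t_axis = np.arange(f.size) / fs_force
    return np.interp(t_grid, t_axis, f)


def _check_channel_alive(raw: np.ndarray, case_id: str, channel: int) -> None:
    if np.ptp(raw) < 1e-9 or np.std(raw) < 1e-12:
        raise PreprocessError(
            f"case {case_id}: PPG channel {channel + 1} is flat (disconnected?)"
        )


def prepare_case(rec) -> PreparedCase:
    """Full preprocessing of one raw recording.

    Per channel: band-pass -> peaks -> envelope -> differences.  Force:
    low-pass, then a 10-s segment centred on the envelope maximum of the
    channel whose envelope peak is globally largest.  Any per-channel
    failure rejects the whole case with a reason naming the channel.
    """
    x1 = np.empty((9, 3, rec.n_samples))
    x2 = np.empty((9, 3, rec.n_samples))
    envelopes = np.empty((9, rec.n_samples))
    for i in range(9):
        try:
            _check_channel_alive(rec.ppg[i], rec.case_id, i)
            xp = bandpass_ppg(rec.ppg[i], rec.fs_ppg)
            peaks = detect_peaks(xp, rec.fs_ppg)
            xe = compute_envelope(xp, peaks, rec.fs_ppg)
        except PreprocessError as err:
            raise PreprocessError(
                f"case {rec.case_id}, channel {i + 1}: {err}"
            ) from err
        d1p, d2p = derivatives(xp)
        d1e, d2e = derivatives(xe)
        x1[i] = np.stack([xp, d1p, d2p])
        x2[i] = np.stack([xe, d1e, d2e])
        envelopes[i] = xe

    ref_channel = int(np.argmax(envelopes.max(axis=1)))
    force_filt = lowpass_force(rec.force, rec.fs_force)
    x3 = segment_force(force_filt, envelopes[ref_channel], rec.fs_force)

    return PreparedCase(
        case_id=rec.case_id,
        subject_id=rec.subject_id,
        x1=x1,
        x2=x2,
        x3=x3[None, :],
        ref_sbp=rec.ref_sbp,
        ref_dbp=rec.ref_dbp,
    )
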