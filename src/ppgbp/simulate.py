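"""Synthetic finger-press oscillometric recordings.

Emulates the acquisition protocol of a pressurized multi-channel PPG sensor:
a subject presses a fingertip onto a 3x3 photodetector grid for 40 s while the
applied force ramps up.  As the transmural pressure sweeps past the arterial
pressures, the beat-to-beat PPG amplitude traces the oscillometric bell, which
peaks where applied pressure equals mean arterial pressure (MAP).  Finger
placement is modelled as a Gaussian gain profile over the detector grid, so
channels closer to the finger centre see larger pulsations.

Every recording carries its ground-truth SBP/DBP, which makes the whole
estimation pipeline trainable and testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VirtualSubject",
    "SimConfig",
    "RawRecording",
    "GRID_POSITIONS",
    "oscillometric_amplitude",
    "channel_gains",
    "pulse_train",
    "simulate_case",
    "draw_subjects",
    "simulate_dataset",
]

#: Detector positions on the 3x3 grid, row-major, in grid units centred on the
#: sensor.  Channel i (0-based) sits at GRID_POSITIONS[i].
GRID_POSITIONS = np.array(
    [(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)], dtype=float
)

MIN_PULSE_PRESSURE = 20.0  # mmHg; reject physiologically absurd SBP/DBP pairs


class SimulationError(ValueError):
    """Raised when a requested case cannot produce a learnable recording."""


@dataclass(frozen=True)
class VirtualSubject:
    """Ground-truth physiology and finger placement of one simulated subject."""

    subject_id: str
    sbp_true: float
    dbp_true: float
    heart_rate: float
    finger_offset: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not self.dbp_true < self.map_true < self.sbp_true:
            raise ValueError(
                f"require DBP < MAP < SBP, got {self.dbp_true}/{self.sbp_true}"
            )

    @property
    def map_true(self) -> float:
        """Mean arterial pressure, classical DBP + PP/3 estimate."""
        return self.dbp_true + (self.sbp_true - self.dbp_true) / 3.0

    @property
    def pulse_pressure(self) -> float:
        return self.sbp_true - self.dbp_true


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults are the standard study conditions."""

    n_subjects: int = 200
    cases_per_subject: int = 5
    duration_s: float = 40.0
    fs_ppg: float = 43.0
    fs_force: float = 43.0
    sbp_range: tuple[float, float] = (95.0, 175.0)
    dbp_range: tuple[float, float] = (60.0, 105.0)
    hr_range: tuple[float, float] = (55.0, 100.0)
    force_ramp_exponent: float = 1.0
    pressure_gain: float = 25.0  # mmHg per force unit
    max_pressure: float = 215.0  # mmHg at ramp end; covers 1.2x max jittered SBP
    envelope_width_factor: float = 0.4
    gain_spread: float = 1.5  # grid units
    offset_sd: float = 0.5  # grid units, SD of finger-centre displacement
    pulse_amplitude: float = 100.0  # signal units of a full-strength beat
    baseline: float = 1000.0  # ADC-like DC level
    drift_amplitude: float = 10.0
    noise_sd: float = 3.0  # per-sample white noise, ~20 dB beat SNR
    bp_jitter: float = 2.0  # mmHg, per-case repeat-measurement jitter
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs_ppg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs_ppg must be an integer sample count")
        for name in ("sbp_range", "dbp_range", "hr_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-empty (lo, hi) interval")
        if self.dbp_range[0] >= self.sbp_range[1]:
            raise ValueError("dbp_range must lie below sbp_range")
        if self.envelope_width_factor <= 0:
            raise ValueError("envelope_width_factor must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_ppg))


@dataclass
class RawRecording:
    """One 40-s case: 9-channel PPG + synchronized force, with reference BP."""

    case_id: str
    subject_id: str
    fs_ppg: float
    fs_force: float
    ppg: np.ndarray  # (9, T)
    force: np.ndarray  # (T,)
    ref_sbp: float
    ref_dbp: float
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.ppg.ndim != 2 or self.ppg.shape[0] != 9:
            raise ValueError(f"ppg must be (9, T), got {self.ppg.shape}")
        if self.force.shape != (self.ppg.shape[1],):
            raise ValueError("force must cover the same samples as ppg")

    @property
    def n_samples(self) -> int:
        return self.ppg.shape[1]


def oscillometric_amplitude(
    applied_pressure: np.ndarray | float,
    subject: VirtualSubject,
    width_factor: float,
) -> np.ndarray | float:
    """Relative beat amplitude under external pressure P.

    Gaussian bell exp(-(P - MAP)^2 / (2 sigma^2)) with sigma proportional to
    the subject's pulse pressure: sigma = width_factor * (SBP - DBP).  Maximum
    1 exactly at P = MAP, symmetric, strictly decreasing away from MAP.
    """
    if width_factor <= 0:
        raise SimulationError("width_factor must be positive")
    sigma = width_factor * subject.pulse_pressure
    p = np.asarray(applied_pressure, dtype=float)
    out = np.exp(-((p - subject.map_true) ** 2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def channel_gains(finger_offset: np.ndarray | tuple, gain_spread: float) -> np.ndarray:
    """Per-channel gain from finger placement: Gaussian fall-off with the
    distance of each grid detector from the finger centre."""
    off = np.asarray(finger_offset, dtype=float)
    d2 = ((GRID_POSITIONS - off) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * gain_spread**2))


def pulse_train(t: np.ndarray, heart_rate: float) -> np.ndarray:
    """Periodic PPG beat template: a systolic peak plus a smaller dicrotic
    bump, modelled as two Gaussians per cardiac period."""
    period = 60.0 / heart_rate
    phase = np.mod(t, period) / period
    systolic = np.exp(-((phase - 0.25) ** 2) / (2 * 0.06**2))
    dicrotic = 0.3 * np.exp(-((phase - 0.55) ** 2) / (2 * 0.10**2))
    return systolic + dicrotic


def applied_pressure(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Pressure transmitted to the finger at time t under the ramp protocol."""
    frac = np.clip(t / config.duration_s, 0.0, 1.0)
    return config.max_pressure * frac**config.force_ramp_exponent


def simulate_case(
    subject: VirtualSubject,
    config: SimConfig,
    rng: np.random.Generator,
    case_id: str | None = None,
    sbp: float | None = None,
    dbp: float | None = None,
) -> RawRecording:
    """Synthesize one recording for `subject`.

    ``sbp``/``dbp`` override the subject's values (used for per-case
    repeat-measurement jitter); the recording stores them as reference BP.
    Reproducible: the same (subject, config, rng state) gives bit-identical
    output.
    """
    sbp = subject.sbp_true if sbp is None else float(sbp)
    dbp = subject.dbp_true if dbp is None else float(dbp)
    case_subject = VirtualSubject(
        subject_id=subject.subject_id,
        sbp_true=sbp,
        dbp_true=dbp,
        heart_rate=subject.heart_rate,
        finger_offset=subject.finger_offset,
        noise_sd=subject.noise_sd,
    )
    if config.max_pressure < 1.2 * sbp or config.max_pressure <= case_subject.map_true:
        raise SimulationError(
            f"pressure ramp tops out at {config.max_pressure} mmHg, below "
            f"1.2 x SBP = {1.2 * sbp:.1f}; case {case_id} would be unlearnable"
        )

    T = config.n_samples
    t = np.arange(T) / config.fs_ppg
    pressure = applied_pressure(t, config)
    force = pressure / config.pressure_gain
    if config.noise_sd > 0:
        # small smooth force wobble: low-frequency random sinusoid
        f_phase = rng.uniform(0, 2 * np.pi)
        force = force + 0.01 * force.max() * np.sin(2 * np.pi * 0.1 * t + f_phase)

    bell = oscillometric_amplitude(pressure, case_subject, config.envelope_width_factor)
    beats = pulse_train(t, subject.heart_rate)
    gains = channel_gains(subject.finger_offset, config.gain_spread)

    ppg = np.empty((9, T))
    for i in range(9):
        drift_phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(2 * np.pi * 0.05 * t + drift_phase)
        noise = rng.normal(0.0, subject.noise_sd, size=T) if subject.noise_sd > 0 else 0.0
        ppg[i] = (
            config.baseline
            + config.pulse_amplitude * gains[i] * bell * beats
            + drift
            + noise
        )

    return RawRecording(
        case_id=case_id or f"{subject.subject_id}_c0",
        subject_id=subject.subject_id,
        fs_ppg=config.fs_ppg,
        fs_force=config.fs_force,
        ppg=ppg,
        force=force,
        ref_sbp=sbp,
        ref_dbp=dbp,
        provenance="synthetic",
    )


def draw_subjects(config: SimConfig, rng: np.random.Generator) -> list[VirtualSubject]:
    """Draw the subject population: BP uniform over the configured ranges
    (rejecting pairs with pulse pressure < 20 mmHg), HR uniform, finger
    offsets Gaussian on the grid."""
    subjects = []
    for k in range(config.n_subjects):
        while True:
            sbp = rng.uniform(*config.sbp_range)
            dbp = rng.uniform(*config.dbp_range)
            if sbp - dbp >= MIN_PULSE_PRESSURE:
                break
        subjects.append(
            VirtualSubject(
                subject_id=f"S{k:04d}",
                sbp_true=float(sbp),
                dbp_true=float(dbp),
                heart_rate=float(rng.uniform(*config.hr_range)),
                finger_offset=tuple(rng.normal(0.0, config.offset_sd, size=2)),
                noise_sd=config.noise_sd,
            )
        )
    return subjects


def simulate_dataset(
    config: SimConfig, noise_seed: int | None = None
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate the full dataset: n_subjects x cases_per_subject recordings.

    Subject-level draws are seeded by ``config.seed`` alone; the per-case
    noise stream is seeded by ``noise_seed`` (default: ``config.seed``), so
    two datasets with the same config seed but different noise seeds share
    identical subjects and differ only in noise realizations.

    Returns the recordings plus a subject table (one row per subject) for
    subject-disjoint fold construction.
    """
    subject_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    noise_root = config.seed if noise_seed is None else noise_seed
    noise_rng = np.random.default_rng(np.random.SeedSequence([noise_root, 1]))

    subjects = draw_subjects(config, subject_rng)
    recordings: list[RawRecording] = []
    for subj in subjects:
        for c in range(config.cases_per_subject):
            jit = config.bp_jitter
            sbp = subj.sbp_true + (subject_rng.uniform(-jit, jit) if jit else 0.0)
            dbp = subj.dbp_true + (subject_rng.uniform(-jit, jit) if jit else 0.0)
            recordings.append(
                simulate_case(
                    subj,
                    config,
                    noise_rng,
                    case_id=f"{subj.subject_id}_c{c}",
                    sbp=sbp,
                    dbp=dbp,
                )
            )

    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sbp_true": [s.sbp_true for s in subjects],
            "dbp_true": [s.dbp_true for s in subjects],
            "map_true": [s.map_true for s in subjects],
            "heart_rate": [s.heart_rate for s in subjects],
            "finger_dx": [s.finger_offset[0] for s in subjects],
            "finger_dy": [s.finger_offset[1] for s in subjects],
        }
    )
    return recordings, table
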