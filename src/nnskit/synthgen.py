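"""Synthetic NNS assessment generator with exact ground-truth annotations.

Emulates the statistical structure of a preterm infant's nonnutritive-suck
compression-pressure recording: ~2 Hz suck cycles grouped in bursts of 2-13
cycles separated by 2-5 s respiratory pauses, occasional slow wide non-NNS
posturing events, slow thermal baseline drift, and broadband sensor noise.
Every injected event is recorded in a :class:`SynthGroundTruth` so detector
recall/precision, baseline recovery, and feature values can be scored
exactly without patient data.

Suck cycles are raised-cosine (Hann-shaped) pulses: a pulse of half-height
width ``w`` has support ``2w``, so the half-height width used by the
classifier is analytically exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .assess_io import (FeedMode, FeedingRecord, RawAssessment,
                        write_assessment, write_feeding_log)

#: Default two-point calibration used for synthetic recordings:
#: 0 V -> 0 cm H2O, 1 V -> 10 cm H2O.
DEFAULT_CALIBRATION = ((0.0, 0.0), (1.0, 10.0))
_PRESSURE_PER_VOLT = 10.0


@dataclass
class DriftSpec:
    """Baseline-drift model: ``none``, ``linear`` (slope in cm H2O per
    minute) or ``random_walk`` (per-sample Gaussian step SD in cm H2O)."""

    kind: str = "none"
    slope_cm_h2o_per_min: float = 0.0
    step_sd_cm_h2o: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "random_walk"):
            raise ValueError(f"unknown drift kind {self.kind!r}")

    @classmethod
    def none(cls) -> "DriftSpec":
        return cls("none")

    @classmethod
    def linear(cls, slope_cm_h2o_per_min: float) -> "DriftSpec":
        return cls("linear", slope_cm_h2o_per_min=slope_cm_h2o_per_min)

    @classmethod
    def random_walk(cls, step_sd_cm_h2o: float) -> "DriftSpec":
        return cls("random_walk", step_sd_cm_h2o=step_sd_cm_h2o)


@dataclass
class SynthConfig:
    """Generator parameters; defaults state the emulated world.

    2 Hz modal cycle rate, bursts of 2-13 cycles, 2-5 s pauses, 8 cm H2O
    mean cycle amplitude with 20% jitter, 250 ms cycle half-height width,
    three 900 ms-wide posturing events per record, 1 cm H2O/min linear
    thermal drift, and 0.1 cm H2O sensor noise on a 3-minute, 3 kHz record.
    """

    duration_s: float = 180.0
    sample_rate_hz: float = 3000.0
    cycle_rate_hz: float = 2.0
    cycles_per_burst_range: tuple[int, int] = (2, 13)
    pause_range_s: tuple[float, float] = (2.0, 5.0)
    nns_amplitude_cm_h2o: float = 8.0
    amplitude_jitter_frac: float = 0.2
    cycle_half_width_ms: float = 250.0
    cycle_time_jitter_s: float = 0.02
    n_non_nns_events: int = 3
    non_nns_width_ms: float = 900.0
    non_nns_amplitude_cm_h2o: float = 4.0
    drift: DriftSpec = field(default_factory=lambda: DriftSpec.linear(1.0))
    noise_sd_cm_h2o: float = 0.1
    burst_criterion_ms: float = 1200.0
    subject_id: str = "SYNTH"
    pma_days: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")
        if self.cycle_rate_hz <= 0 or self.nns_amplitude_cm_h2o <= 0:
            raise ValueError("cycle_rate_hz and amplitude must be positive")
        lo, hi = self.cycles_per_burst_range
        if lo < 2 or hi < lo:
            raise ValueError("cycles_per_burst_range must be ordered within [2, inf)")
        plo, phi = self.pause_range_s
        if plo <= 0 or phi < plo:
            raise ValueError("pause_range_s must be ordered and positive")
        if self.noise_sd_cm_h2o < 0 or self.amplitude_jitter_frac < 0:
            raise ValueError("noise and jitter parameters must be non-negative")


@dataclass
class SynthGroundTruth:
    """Exact record of everything injected into one synthetic assessment."""

    peak_times_s: np.ndarray          # true NNS peak times
    peak_amplitudes: np.ndarray       # cm H2O
    non_nns_times_s: np.ndarray
    non_nns_amplitudes: np.ndarray
    burst_membership: np.ndarray      # per-peak burst index
    true_baseline: np.ndarray         # injected drift, full length
    clean_pressure: np.ndarray        # noiseless drift-free pressure series


def _raised_cosine(t: np.ndarray, center: float, amplitude: float,
                   half_width_s: float) -> np.ndarray:
    """Hann pulse with half-height width ``half_width_s`` (support 2x)."""
    support = 2.0 * half_width_s
    x = (t - center) / support
    out = np.zeros_like(t)
    mask = np.abs(x) < 0.5
    out[mask] = amplitude * 0.5 * (1.0 + np.cos(2.0 * np.pi * x[mask]))
    return out


def _add_pulse(sig: np.ndarray, fs: float, center: float, amplitude: float,
               half_width_s: float) -> None:
    """Add a raised-cosine pulse in place, touching only its support."""
    support = 2.0 * half_width_s
    i0 = max(0, int(np.floor((center - support / 2.0) * fs)))
    i1 = min(sig.size, int(np.ceil((center + support / 2.0) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    sig[i0:i1] += _raised_cosine(t, center, amplitude, half_width_s)


def make_drift(n_samples: int, sample_rate_hz: float, drift: DriftSpec,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Drift trajectory of the requested length (zeros for ``none``)."""
    t = np.arange(n_samples) / sample_rate_hz
    if drift.kind == "none":
        return np.zeros(n_samples)
    if drift.kind == "linear":
        return drift.slope_cm_h2o_per_min / 60.0 * t
    if rng is None:
        raise ValueError("random_walk drift requires a random generator")
    steps = rng.normal(0.0, drift.step_sd_cm_h2o, size=n_samples)
    steps[0] = 0.0
    return np.cumsum(steps)


def inject_drift(series: np.ndarray, drift: DriftSpec,
                 sample_rate_hz: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Add the specified drift trajectory to a series; output - input
    equals the trajectory exactly."""
    series = np.asarray(series, dtype=float)
    return series + make_drift(series.size, sample_rate_hz, drift, rng)


def _plan_events(cfg: SynthConfig, rng: np.random.Generator):
    """Lay out burst/pause/posturing timeline; returns (nns peaks, bursts,
    non-NNS events) as lists of (time, amplitude) and membership."""
    period = 1.0 / cfg.cycle_rate_hz
    half_w = cfg.cycle_half_width_ms / 1000.0
    lo, hi = cfg.cycles_per_burst_range
    margin = half_w  # keep pulse support inside the record

    peak_times: list[float] = []
    peak_amps: list[float] = []
    membership: list[int] = []
    non_times: list[float] = []
    non_amps: list[float] = []

    # decide after which bursts to attempt a posturing event
    t = margin + rng.uniform(0.0, 0.5)
    burst_idx = 0
    events_left = cfg.n_non_nns_events
    # rough expected burst count, to spread the posturing events evenly
    mean_burst_span = (lo + hi) / 2.0 * period + np.mean(cfg.pause_range_s)
    expected_bursts = max(1, int(cfg.duration_s / mean_burst_span))
    insert_every = max(1, expected_bursts // max(1, cfg.n_non_nns_events))

    while True:
        n_cycles = int(rng.integers(lo, hi + 1))
        jitter = rng.uniform(-cfg.cycle_time_jitter_s, cfg.cycle_time_jitter_s,
                             size=n_cycles)
        jitter[0] = 0.0
        times = t + np.arange(n_cycles) * period + jitter
        if times[-1] + margin > cfg.duration_s:
            # truncate the final burst to what fits (drop if < 2 cycles fit)
            keep = times + margin <= cfg.duration_s
            times = times[keep]
            if times.size >= 2:
                amps = cfg.nns_amplitude_cm_h2o * (
                    1.0 + rng.uniform(-cfg.amplitude_jitter_frac,
                                      cfg.amplitude_jitter_frac, size=times.size))
                peak_times.extend(times)
                peak_amps.extend(amps)
                membership.extend([burst_idx] * times.size)
            break
        amps = cfg.nns_amplitude_cm_h2o * (
            1.0 + rng.uniform(-cfg.amplitude_jitter_frac,
                              cfg.amplitude_jitter_frac, size=n_cycles))
        peak_times.extend(times)
        peak_amps.extend(amps)
        membership.extend([burst_idx] * n_cycles)

        pause = rng.uniform(*cfg.pause_range_s)
        t = times[-1] + pause
        if (events_left > 0 and (burst_idx + 1) % insert_every == 0):
            # widen this pause to hold a slow posturing pulse clear of
            # both neighbouring bursts
            non_half = cfg.non_nns_width_ms / 1000.0
            gap = max(pause, 2.0)
            center = times[-1] + gap / 2.0 + non_half
            amp = cfg.non_nns_amplitude_cm_h2o * (
                1.0 + rng.uniform(-cfg.amplitude_jitter_frac,
                                  cfg.amplitude_jitter_frac))
            if center + 2.0 * non_half < cfg.duration_s:
                non_times.append(center)
                non_amps.append(amp)
                events_left -= 1
                t = center + non_half + gap / 2.0 + 1.0
        burst_idx += 1
    return peak_times, peak_amps, membership, non_times, non_amps


def generate_assessment(cfg: SynthConfig) -> tuple[RawAssessment, SynthGroundTruth]:
    """Synthesize one assessment recording with its exact ground truth.

    Deterministic for a fixed seed.  The signal is the sum of raised-cosine
    suck-cycle pulses, wide non-NNS posturing pulses, the drift trajectory,
    and white Gaussian sensor noise; the returned
    :class:`~nnskit.assess_io.RawAssessment` carries float voltage samples
    under the default 10 cm H2O/V calibration.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    fs = cfg.sample_rate_hz

    peak_times, peak_amps, membership, non_times, non_amps = _plan_events(cfg, rng)

    clean = np.zeros(n)
    half_w = cfg.cycle_half_width_ms / 1000.0
    for tc, a in zip(peak_times, peak_amps):
        _add_pulse(clean, fs, tc, a, half_w)
    non_half = cfg.non_nns_width_ms / 1000.0
    for tc, a in zip(non_times, non_amps):
        _add_pulse(clean, fs, tc, a, non_half)

    baseline = make_drift(n, fs, cfg.drift, rng)
    pressure = clean + baseline
    if cfg.noise_sd_cm_h2o > 0:
        pressure = pressure + rng.normal(0.0, cfg.noise_sd_cm_h2o, size=n)

    volts = pressure / _PRESSURE_PER_VOLT
    raw = RawAssessment(
        samples=volts,
        sample_rate_hz=fs,
        calibration=DEFAULT_CALIBRATION,
        subject_id=cfg.subject_id,
        session_datetime=datetime(2020, 1, 1, tzinfo=timezone.utc),
        pma_days=cfg.pma_days,
    )
    truth = SynthGroundTruth(
        peak_times_s=np.asarray(peak_times),
        peak_amplitudes=np.asarray(peak_amps),
        non_nns_times_s=np.asarray(non_times),
        non_nns_amplitudes=np.asarray(non_amps),
        burst_membership=_regroup_membership(
            np.asarray(peak_times), cfg.burst_criterion_ms / 1000.0),
        true_baseline=baseline,
        clean_pressure=clean,
    )
    return raw, truth


def _regroup_membership(times: np.ndarray, criterion_s: float) -> np.ndarray:
    """Burst indices from actual (jittered) peak times: successive gaps
    within the criterion share a burst."""
    if times.size == 0:
        return np.zeros(0, dtype=int)
    membership = np.zeros(times.size, dtype=int)
    for i in range(1, times.size):
        membership[i] = membership[i - 1] + (
            1 if times[i] - times[i - 1] > criterion_s + 1e-9 else 0)
    return membership


def write_truth_csv(truth: SynthGroundTruth, path: str | Path) -> None:
    """Persist the per-event ground truth (peaks and posturing events)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event", "time_s", "amplitude_cm_h2o", "burst_index"])
        for t, a, b in zip(truth.peak_times_s, truth.peak_amplitudes,
                           truth.burst_membership):
            w.writerow(["NNS", f"{t:.6f}", f"{a:.6f}", int(b)])
        for t, a in zip(truth.non_nns_times_s, truth.non_nns_amplitudes):
            w.writerow(["NON_NNS", f"{t:.6f}", f"{a:.6f}", ""])


def write_fixture_set(directory: str | Path, n_files: int,
                      cfg: SynthConfig | None = None,
                      seed: int = 0) -> dict:
    """Write a batch-test fixture: ``n_files`` binary assessments, their
    ground-truth CSVs, and one feeding log assigning PO/NG/OG modes.

    Subjects rotate over three synthetic infants; feed modes rotate over
    PO / NG / no-record so the readiness label mapping exercises all of
    ready (1) / not ready (0) / unknown (2).  Returns a manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = cfg or SynthConfig()
    base_date = date(2020, 1, 1)
    feeding: list[FeedingRecord] = []
    entries = []
    for i in range(n_files):
        subject = f"S{i % 3:02d}"
        day = base_date + timedelta(days=i)
        file_cfg = replace(cfg, seed=seed + i, subject_id=subject,
                           pma_days=200 + i)
        raw, truth = generate_assessment(file_cfg)
        raw = replace(raw, session_datetime=datetime(day.year, day.month, day.day,
                                                     tzinfo=timezone.utc))
        assess_path = directory / f"{subject}_{day.isoformat()}.assess"
        truth_path = directory / f"{subject}_{day.isoformat()}.truth.csv"
        write_assessment(raw.quantized(), assess_path)
        write_truth_csv(truth, truth_path)
        mode = i % 3
        if mode == 0:
            feeding.append(FeedingRecord(subject, day, FeedMode.PO, 20.0))
        elif mode == 1:
            feeding.append(FeedingRecord(subject, day, FeedMode.NG, 20.0))
        # mode == 2: no record that day -> label "unknown"
        entries.append({"assessment": str(assess_path), "truth": str(truth_path),
                        "subject_id": subject, "date": day.isoformat(),
                        "seed": seed + i})
    log_path = directory / "feeding_log.csv"
    write_feeding_log(feeding, log_path)
    return {"files": entries, "feeding_log": str(log_path), "n_files": n_files}
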