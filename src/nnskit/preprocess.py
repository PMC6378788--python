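"""Signal conditioning: calibration, low-pass filtering, decimation, and
asymmetric least-squares (ALS) baseline correction.

The standard chain for a raw 3 kHz recording is

    calibrate -> lowpass (4-pole Butterworth, 50 Hz, zero phase)
              -> downsample (100 Hz) -> correct_baseline (ALS)

after which the pressure series is in cm H2O at 100 samples/s with the slow
thermal drift of the closed-volume pneumatic sensor removed, ready for peak
discrimination.  Every step appends to the signal's provenance so later
stages can verify ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.sparse as sp
from scipy.signal import butter, resample_poly, sosfiltfilt
from scipy.sparse.linalg import spsolve

from .assess_io import RawAssessment

DEFAULT_LOWPASS_HZ = 50.0
DEFAULT_LOWPASS_ORDER = 4
DEFAULT_TARGET_HZ = 100.0
DEFAULT_ALS_LAM = 1e9
DEFAULT_ALS_P = 0.01
DEFAULT_ALS_ITERATIONS = 10


@dataclass
class ProcessedSignal:
    """A pressure series (cm H2O) with its processing history.

    ``baseline`` holds the drift estimate subtracted by
    :func:`correct_baseline` (same length as ``pressure``), or ``None``
    before correction.  ``provenance`` is the ordered list of
    ``(step_name, params)`` applied so far.
    """

    pressure: np.ndarray
    sample_rate_hz: float
    baseline: np.ndarray | None = None
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure series contains non-finite values")
        if self.baseline is not None and len(self.baseline) != len(self.pressure):
            raise ValueError("baseline length must match pressure length")

    @property
    def n_samples(self) -> int:
        return int(self.pressure.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def has_step(self, name: str) -> bool:
        return any(step == name for step, _ in self.provenance)

    def with_pressure(self, pressure, step: str, params: dict, *,
                      sample_rate_hz: float | None = None,
                      baseline=None) -> "ProcessedSignal":
        return ProcessedSignal(
            pressure=np.asarray(pressure, dtype=float),
            sample_rate_hz=self.sample_rate_hz if sample_rate_hz is None else sample_rate_hz,
            baseline=self.baseline if baseline is None else baseline,
            provenance=[*self.provenance, (step, params)],
        )

    @classmethod
    def from_pressure(cls, pressure, sample_rate_hz: float, *,
                      assume_corrected: bool = False) -> "ProcessedSignal":
        """Wrap a pressure array already in cm H2O.

        With ``assume_corrected=True`` the signal is marked as
        baseline-corrected (zero baseline) — for synthetic signals built
        directly on a flat baseline.
        """
        pressure = np.asarray(pressure, dtype=float)
        prov = [("from_pressure", {"sample_rate_hz": sample_rate_hz})]
        baseline = None
        if assume_corrected:
            prov.append(("correct_baseline", {"synthetic": True}))
            baseline = np.zeros_like(pressure)
        return cls(pressure=pressure, sample_rate_hz=sample_rate_hz,
                   baseline=baseline, provenance=prov)


def calibrate(raw: RawAssessment) -> ProcessedSignal:
    """Convert raw sensor samples to cm H2O through the two-point
    calibration line."""
    (v0, p0), (v1, p1) = raw.calibration
    if v0 == v1:
        raise ValueError("degenerate calibration: identical sample values")
    slope = (p1 - p0) / (v1 - v0)
    pressure = p0 + slope * (np.asarray(raw.samples, dtype=float) - v0)
    return ProcessedSignal(
        pressure=pressure,
        sample_rate_hz=raw.sample_rate_hz,
        provenance=[("calibrate", {"points": list(raw.calibration)})],
    )


def lowpass(signal: ProcessedSignal,
            order: int = DEFAULT_LOWPASS_ORDER,
            cutoff_hz: float = DEFAULT_LOWPASS_HZ) -> ProcessedSignal:
    """Zero-phase Butterworth low-pass.

    Applied forward-backward (``sosfiltfilt``, reflect padding) so peak
    times used by discrimination are not lag-shifted; the net magnitude
    response is the squared single-pass Butterworth response.
    """
    nyq = signal.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = butter(order, cutoff_hz, btype="low", fs=signal.sample_rate_hz, output="sos")
    filtered = sosfiltfilt(sos, signal.pressure)
    return signal.with_pressure(filtered, "lowpass",
                                {"order": order, "cutoff_hz": cutoff_hz})


def downsample(signal: ProcessedSignal,
               target_hz: float = DEFAULT_TARGET_HZ) -> ProcessedSignal:
    """Resample to ``target_hz`` with polyphase anti-alias filtering.

    Integer decimation for commensurate rates (3000 -> 100 is /30),
    rational-ratio resampling otherwise.  Identity when the rates match.
    """
    if target_hz > signal.sample_rate_hz:
        raise ValueError(
            f"target rate {target_hz} Hz exceeds source {signal.sample_rate_hz} Hz"
        )
    if target_hz == signal.sample_rate_hz:
        return signal.with_pressure(signal.pressure, "downsample",
                                    {"target_hz": target_hz, "ratio": "1/1"})
    frac = Fraction(target_hz / signal.sample_rate_hz).limit_denominator(10_000)
    # line padding avoids edge transients when the signal rides on drift
    out = resample_poly(signal.pressure, frac.numerator, frac.denominator,
                        padtype="line")
    return signal.with_pressure(
        out, "downsample", {"target_hz": target_hz, "ratio": str(frac)},
        sample_rate_hz=target_hz,
    )


def _als_baseline(y: np.ndarray, lam: float, p: float, iterations: int) -> np.ndarray:
    """Iteratively reweighted asymmetric least-squares baseline (Whittaker
    smoother with a second-difference penalty).

    Solves ``(W + lam * D'D) z = W y`` with asymmetric weights ``p`` for
    samples above the current baseline and ``1 - p`` below, re-estimating
    the weights for ``iterations`` rounds.  Small ``p`` makes the baseline
    hug the lower envelope, pulling inter-burst segments to zero while
    ignoring the upward suck-pressure pulses.
    """
    n = y.size
    if n < 3:
        return y.copy()
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    DTD = (lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y.copy()
    for _ in range(iterations):
        W = sp.diags(w, 0, format="csc")
        z = spsolve(W + DTD, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def correct_baseline(signal: ProcessedSignal,
                     lam: float = DEFAULT_ALS_LAM,
                     p: float = DEFAULT_ALS_P,
                     iterations: int = DEFAULT_ALS_ITERATIONS) -> ProcessedSignal:
    """Estimate and subtract the slow thermal-drift baseline.

    Returns ``pressure - baseline`` with the baseline stored, so
    ``output.pressure + output.baseline`` reconstructs the input exactly.
    Defaults (lam=1e9, p=0.01 at 100 Hz, 10 rounds): the smoother's
    half-power point sits near 0.03 Hz, stiff enough not to ride up under
    multi-second suck bursts while still tracking thermal drift with
    periods of tens of seconds.
    """
    if lam <= 0 or p <= 0 or p >= 1:
        raise ValueError(f"require lam > 0 and 0 < p < 1, got lam={lam}, p={p}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    baseline = _als_baseline(signal.pressure, lam, p, iterations)
    return signal.with_pressure(
        signal.pressure - baseline, "correct_baseline",
        {"lam": lam, "p": p, "iterations": iterations},
        baseline=baseline,
    )


def preprocess_assessment(raw: RawAssessment, *,
                          lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                          lowpass_order: int = DEFAULT_LOWPASS_ORDER,
                          target_hz: float = DEFAULT_TARGET_HZ,
                          als_lam: float = DEFAULT_ALS_LAM,
                          als_p: float = DEFAULT_ALS_P,
                          als_iterations: int = DEFAULT_ALS_ITERATIONS) -> ProcessedSignal:
    """Full conditioning chain: calibrate, low-pass, decimate, baseline-correct."""
    sig = calibrate(raw)
    if lowpass_hz < sig.sample_rate_hz / 2.0:
        sig = lowpass(sig, order=lowpass_order, cutoff_hz=lowpass_hz)
    sig = downsample(sig, target_hz=target_hz)
    return correct_baseline(sig, lam=als_lam, p=als_p, iterations=als_iterations)
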