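"""End-to-end session analysis: preprocess -> discriminate -> features ->
STI -> spectra, for one recording or a batch directory."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assess_io, discrimination, features, preprocess, spectral
from .assess_io import RawAssessment
from .discrimination import AnalysisConfig, Burst, PeakEvent
from .features import FeatureVector, STIResult
from .preprocess import ProcessedSignal
from .spectral import SpectrumEstimate

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    lowpass_hz: float = preprocess.DEFAULT_LOWPASS_HZ
    lowpass_order: int = preprocess.DEFAULT_LOWPASS_ORDER
    target_hz: float = preprocess.DEFAULT_TARGET_HZ
    als_lam: float = preprocess.DEFAULT_ALS_LAM
    als_p: float = preprocess.DEFAULT_ALS_P
    als_iterations: int = preprocess.DEFAULT_ALS_ITERATIONS


@dataclass
class SpectralConfig:
    highpass_hz: float = spectral.DEFAULT_HIGHPASS_HZ
    ar_order: int = spectral.DEFAULT_AR_ORDER
    summary_band_hz: tuple[float, float] = spectral.DEFAULT_SUMMARY_BAND


@dataclass
class SessionResult:
    """Everything computed for one recording session."""

    subject_id: str
    session_date: str
    signal: ProcessedSignal
    window: tuple[float, float]
    peaks: list[PeakEvent]            # classified, restricted to the window
    bursts: list[Burst]
    features: FeatureVector
    sti: STIResult
    spectra: dict[str, SpectrumEstimate]
    spectral_summaries: dict[str, tuple[float, float, float]]
    burst_histogram: dict[int, int] = field(default_factory=dict)


def analyze_assessment(raw: RawAssessment,
                       cfg: AnalysisConfig | None = None,
                       pre: PreprocessConfig | None = None,
                       spec: SpectralConfig | None = None) -> SessionResult:
    """Run the full analysis pipeline on one raw assessment."""
    cfg = cfg or AnalysisConfig()
    pre = pre or PreprocessConfig()
    spec = spec or SpectralConfig()

    sig = preprocess.preprocess_assessment(
        raw, lowpass_hz=pre.lowpass_hz, lowpass_order=pre.lowpass_order,
        target_hz=pre.target_hz, als_lam=pre.als_lam, als_p=pre.als_p,
        als_iterations=pre.als_iterations)

    detected = discrimination.detect_peaks(sig, cfg)
    classified = discrimination.classify_peaks(detected, cfg)
    window = discrimination.find_active_window(
        classified, sig.duration_s, cfg, sample_rate_hz=sig.sample_rate_hz)
    start, end = window
    in_window = [p for p in classified if start <= p.time_s <= end]
    bursts = discrimination.extract_bursts(in_window, cfg)

    fv = features.compute_features(sig, in_window, bursts, cfg, window,
                                   pma_days=raw.pma_days)
    sti = features.compute_sti(features.select_sti_bursts(bursts, cfg), sig, cfg)

    i0 = int(round(start * sig.sample_rate_hz))
    i1 = int(round(end * sig.sample_rate_hz))
    window_sig = ProcessedSignal(
        pressure=sig.pressure[i0:i1], sample_rate_hz=sig.sample_rate_hz,
        provenance=[*sig.provenance, ("window", {"start_s": start, "end_s": end})])
    spectra = spectral.all_spectra(window_sig, highpass_hz=spec.highpass_hz,
                                   ar_order=spec.ar_order)
    summaries = {m: spectral.spectral_summary(s, band_hz=spec.summary_band_hz)
                 for m, s in spectra.items()}

    return SessionResult(
        subject_id=raw.subject_id,
        session_date=raw.session_datetime.date().isoformat(),
        signal=sig,
        window=window,
        peaks=in_window,
        bursts=bursts,
        features=fv,
        sti=sti,
        spectra=spectra,
        spectral_summaries=summaries,
        burst_histogram=discrimination.burst_histogram(bursts),
    )


def load_assessment(path: str | Path) -> RawAssessment:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return assess_io.read_csv_signal(path)
    return assess_io.read_assessment(path)


def run_single(input_path: str | Path, out_dir: str | Path,
               cfg: AnalysisConfig | None = None,
               pre: PreprocessConfig | None = None,
               spec: SpectralConfig | None = None) -> SessionResult:
    """Analyze one file and export its intermediates."""
    raw = load_assessment(input_path)
    result = analyze_assessment(raw, cfg=cfg, pre=pre, spec=spec)
    out = Path(out_dir) / "single_intermediate" / Path(input_path).stem
    assess_io.export_intermediates(result, out)
    return result


def run_batch(input_dir: str | Path, out_dir: str | Path,
              cfg: AnalysisConfig | None = None,
              pre: PreprocessConfig | None = None,
              spec: SpectralConfig | None = None,
              pattern: str = "*.assess") -> pd.DataFrame:
    """Analyze every assessment in a directory.

    Per-file intermediates go to ``out/intermediate/<stem>/``; the combined
    feature table (one row per successful file) is written to
    ``out/result/features.csv`` together with a per-file run manifest.
    Failures are logged and skipped; they do not abort the batch.
    """
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no '{pattern}' files in {input_dir}")
    out_dir = Path(out_dir)
    inter = out_dir / "intermediate"
    result_dir = out_dir / "result"
    result_dir.mkdir(parents=True, exist_ok=True)

    rows, manifest = [], []
    for path in paths:
        try:
            raw = load_assessment(path)
            result = analyze_assessment(raw, cfg=cfg, pre=pre, spec=spec)
            assess_io.export_intermediates(result, inter / path.stem)
            row = {"session_id": path.stem, "subject_id": result.subject_id,
                   "date": result.session_date}
            row.update(result.features.as_dict())
            rows.append(row)
            manifest.append({"file": path.name, "status": "ok", "error": ""})
        except Exception as exc:  # robust batch contract: skip and log
            logger.warning("batch: %s failed: %s", path.name, exc)
            manifest.append({"file": path.name, "status": "failed",
                             "error": str(exc)})
    table = pd.DataFrame(rows)
    table.to_csv(result_dir / "features.csv", index=False)
    pd.DataFrame(manifest).to_csv(result_dir / "run_manifest.csv", index=False)
    return table
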