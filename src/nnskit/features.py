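"""Per-session NNS feature profile and the spatiotemporal index (STI).

Eleven features characterize ororhythmic motor activity within the most
active analysis window (default 2 minutes): counts and rates of NNS cycles
and non-NNS posturing events, the NNS/total compression ratio, burst counts
and cycles-per-burst statistics, mean NNS cycle amplitude, and the NNS STI.

The STI quantifies burst-to-burst pattern stability: the first M cycles of
each of N successive bursts are time-normalized to a common 10,000-point
record, amplitude-normalized to z-scores, and the across-burst standard
deviation is sampled every 100 points; the STI is the sum of those 100 SD
values.  Low STI = stereotyped, well-coregistered suck bursts; high STI =
variable, immature patterning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .discrimination import AnalysisConfig, Burst, PeakClass, PeakEvent
from .preprocess import ProcessedSignal

STI_RECORD_LENGTH = 10_000
STI_SD_INTERVAL = 100


@dataclass
class FeatureVector:
    """The 11-feature session profile (rates are per minute of window)."""

    n_nns_cycles: int
    nns_cycles_per_min: float
    n_non_nns_events: int
    total_compressions_per_min: float
    nns_ratio_pct: float | None
    n_bursts: int
    bursts_per_min: float
    mean_cycles_per_burst: float | None
    max_cycles_per_burst: int | None
    mean_nns_amplitude: float | None
    sti: float | None
    window: tuple[float, float]
    pma_days: int | None = None

    FEATURE_NAMES = (
        "n_nns_cycles", "nns_cycles_per_min", "n_non_nns_events",
        "total_compressions_per_min", "nns_ratio_pct", "n_bursts",
        "bursts_per_min", "mean_cycles_per_burst", "max_cycles_per_burst",
        "mean_nns_amplitude", "sti",
    )

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.FEATURE_NAMES}
        d["window_start_s"] = self.window[0]
        d["window_end_s"] = self.window[1]
        d["pma_days"] = self.pma_days
        return d


@dataclass
class STIResult:
    """Record of one STI computation.

    ``normalized_segments`` is the n_bursts x 10,000 matrix of z-scored,
    time-normalized burst traces; ``sd_profile`` the 100 across-burst SDs
    sampled every 100 points; ``sti`` their sum (None when fewer than two
    qualifying bursts were available — flagged by ``insufficient``).
    """

    sti: float | None
    n_bursts_used: int
    m_cycles: int
    normalized_segments: np.ndarray | None = None
    sd_profile: np.ndarray | None = None
    insufficient: bool = False


def compute_features(window_signal: ProcessedSignal,
                     peaks: Sequence[PeakEvent],
                     bursts: Sequence[Burst],
                     cfg: AnalysisConfig,
                     window: tuple[float, float],
                     pma_days: int | None = None) -> FeatureVector:
    """Assemble the 11-feature profile from discrimination outputs.

    ``peaks`` and ``bursts`` must already be restricted to the analysis
    window; rates divide by the window length in minutes.  The NNS ratio is
    None (absent) when no compressions were retained at all.
    """
    start, end = window
    minutes = (end - start) / 60.0
    if minutes <= 0:
        raise ValueError("zero-length analysis window")

    nns = [p for p in peaks if p.klass is PeakClass.NNS]
    non_nns = [p for p in peaks if p.klass is PeakClass.NON_NNS]
    n_nns, n_non = len(nns), len(non_nns)
    total = n_nns + n_non

    cycles_per_burst = [b.n_cycles for b in bursts]
    sti_res = compute_sti(select_sti_bursts(bursts, cfg), window_signal, cfg)

    return FeatureVector(
        n_nns_cycles=n_nns,
        nns_cycles_per_min=n_nns / minutes,
        n_non_nns_events=n_non,
        total_compressions_per_min=total / minutes,
        nns_ratio_pct=(100.0 * n_nns / total) if total > 0 else None,
        n_bursts=len(bursts),
        bursts_per_min=len(bursts) / minutes,
        mean_cycles_per_burst=(float(np.mean(cycles_per_burst))
                               if cycles_per_burst else None),
        max_cycles_per_burst=(max(cycles_per_burst) if cycles_per_burst else None),
        mean_nns_amplitude=(float(np.mean([p.amplitude for p in nns]))
                            if nns else None),
        sti=sti_res.sti,
        window=window,
        pma_days=pma_days,
    )


def select_sti_bursts(bursts: Sequence[Burst], cfg: AnalysisConfig) -> list[Burst]:
    """First ``sti_n_bursts`` bursts (time order) having at least
    ``sti_m_cycles`` cycles; fewer qualify -> returns what exists."""
    qualifying = [b for b in bursts if b.n_cycles >= cfg.sti_m_cycles]
    return qualifying[: cfg.sti_n_bursts]


def _segment_trace(window_signal: ProcessedSignal, burst: Burst,
                   m_cycles: int) -> np.ndarray:
    """Signal from the first cycle's onset to the Mth cycle's offset,
    linearly interpolated onto the common 10,000-point record."""
    t0 = burst.peaks[0].onset_s
    t1 = burst.peaks[m_cycles - 1].offset_s
    grid = np.linspace(t0, t1, STI_RECORD_LENGTH)
    return np.interp(grid, window_signal.times_s, window_signal.pressure)


def compute_sti(selected: Sequence[Burst], window_signal: ProcessedSignal,
                cfg: AnalysisConfig) -> STIResult:
    """Spatiotemporal index over the selected bursts.

    Each burst segment (first-cycle onset to Mth-cycle offset) is resampled
    to 10,000 points and z-scored per segment (population SD); the
    across-burst sample SD (n-1 denominator) is taken at points
    0, 100, ..., 9900 and summed.  Fewer than two usable bursts yields an
    insufficiency result rather than an exception.
    """
    m = cfg.sti_m_cycles
    usable = [b for b in selected if b.n_cycles >= m]
    if len(usable) < 2:
        return STIResult(sti=None, n_bursts_used=len(usable), m_cycles=m,
                         insufficient=True)
    segments = np.vstack([_segment_trace(window_signal, b, m) for b in usable])
    mean = segments.mean(axis=1, keepdims=True)
    sd = segments.std(axis=1, keepdims=True)  # per-segment z-scoring
    sd[sd == 0] = 1.0
    z = (segments - mean) / sd
    grid = np.arange(0, STI_RECORD_LENGTH, STI_SD_INTERVAL)
    sd_profile = z[:, grid].std(axis=0, ddof=1)
    return STIResult(
        sti=float(sd_profile.sum()),
        n_bursts_used=len(usable),
        m_cycles=m,
        normalized_segments=z,
        sd_profile=sd_profile,
    )


def feature_trajectory(feature_vectors: Sequence[FeatureVector]):
    """Developmental trajectories: long-format table of (feature, pma_days,
    value) over sessions with known PMA, plus per-feature least-squares
    slope and Pearson correlation.

    Returns ``(table, summary)`` DataFrames; the summary has one row per
    feature with columns ``slope`` (value units per day) and ``r``.
    """
    import pandas as pd

    rows = []
    for fv in feature_vectors:
        if fv.pma_days is None:
            continue
        for name in FeatureVector.FEATURE_NAMES:
            value = getattr(fv, name)
            if value is not None:
                rows.append({"feature": name, "pma_days": fv.pma_days,
                             "value": float(value)})
    table = pd.DataFrame(rows, columns=["feature", "pma_days", "value"])
    if len({r["pma_days"] for r in rows}) < 2:
        raise ValueError("feature_trajectory requires >= 2 sessions with pma_days")
    table = table.sort_values(["feature", "pma_days"], kind="stable",
                              ignore_index=True)

    summaries = []
    for name, grp in table.groupby("feature", sort=True):
        x, y = grp["pma_days"].to_numpy(float), grp["value"].to_numpy(float)
        if len(x) >= 2 and np.ptp(x) > 0:
            res = stats.linregress(x, y)
            slope, r = float(res.slope), float(res.rvalue)
            if np.isnan(r):  # constant y: define r = 0 alongside slope 0
                r = 0.0
        else:
            slope, r = 0.0, 0.0
        summaries.append({"feature": name, "slope": slope, "r": r})
    summary = pd.DataFrame(summaries, columns=["feature", "slope", "r"])
    return table, summary
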