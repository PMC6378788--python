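"""Reading and writing suck-assessment recordings and session metadata.

Two on-disk representations of a recording are supported:

* a compact little-endian binary dialect (magic ``NNS1``) holding the raw
  sensor samples plus the session header, standing in for proprietary
  instrument formats, and
* a plain CSV alternative (time/pressure or pressure-only columns with a
  ``# key: value`` metadata header block) so recordings from any device can
  enter the pipeline.

Feeding logs — the nursing-staff record of feed times and routes (PO oral,
NG nasogastric, OG orogastric) — are plain CSV.  ``export_intermediates``
writes the per-session analysis products (peaks, bursts, spectra, features,
spatiotemporal index) as stable, documented CSV files.
"""

from __future__ import annotations

import csv
import logging
import struct
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MAGIC = b"NNS1"
FORMAT_VERSION = 1

#: Counts per volt used when a float-voltage assessment is quantized to the
#: 16-bit binary payload (full scale +/-10 V on the signed 16-bit range).
COUNTS_PER_VOLT = 32767.0 / 10.0

_PMA_ABSENT = -1


class AssessFormatError(ValueError):
    """Malformed assessment file (bad magic, bad header, bad CSV layout)."""


class AssessCorruptionError(AssessFormatError):
    """Header/payload mismatch: truncated or zero-length sample block."""


class AssessVersionError(AssessFormatError):
    """File declares a dialect version this reader does not speak."""


class FeedMode(str, Enum):
    """Feeding route recorded by nursing staff."""

    PO = "PO"        # per os: oral feed (bottle or breast)
    NG = "NG"        # nasogastric tube
    OG = "OG"        # orogastric tube
    MIXED = "mixed"  # combination involving an oral component


@dataclass
class RawAssessment:
    """One recording session as acquired: sensor samples plus session header.

    ``samples`` are either integer ADC counts (16-bit range) or float sensor
    voltages; ``calibration`` holds two ``(sample_value, pressure_cm_h2o)``
    points, with the abscissa in the same unit as ``samples``, defining the
    two-point linear map to cm H2O applied downstream.
    """

    samples: np.ndarray
    sample_rate_hz: float
    calibration: tuple[tuple[float, float], tuple[float, float]]
    subject_id: str
    session_datetime: datetime
    pma_days: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        (v0, _), (v1, _) = self.calibration
        if v0 == v1:
            raise ValueError("calibration points must have distinct sample values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def quantized(self, counts_per_volt: float = COUNTS_PER_VOLT) -> "RawAssessment":
        """Return a copy with samples rounded to int16 ADC counts.

        The calibration abscissa is rescaled by the same factor so the
        two-point pressure map is preserved.  Identity for integer samples.
        """
        if np.issubdtype(self.samples.dtype, np.integer):
            return self
        counts = np.rint(self.samples * counts_per_volt)
        if counts.size and (counts.max() > 32767 or counts.min() < -32768):
            raise ValueError("samples overflow the 16-bit range after quantization")
        cal = tuple((v * counts_per_volt, p) for v, p in self.calibration)
        return replace(self, samples=counts.astype(np.int16), calibration=cal)  # type: ignore[arg-type]


@dataclass
class FeedingRecord:
    """One feed event from the unit's feeding log."""

    subject_id: str
    date: date
    feed_mode: FeedMode
    volume_ml: float | None = None


# --------------------------------------------------------------------------
# binary dialect
# --------------------------------------------------------------------------

_HEADER_FIXED = struct.Struct("<4sHd")          # magic, version, sample_rate
_CAL = struct.Struct("<dddd")                   # 2 x (value, pressure)
_TAIL = struct.Struct("<qiQ")                   # epoch_s, pma_days, n_samples


def write_assessment(assessment: RawAssessment, path: str | Path) -> None:
    """Serialize to the binary dialect.  Samples must be integer-valued
    within the signed 16-bit range (use :meth:`RawAssessment.quantized`
    first for float-voltage data)."""
    samples = np.asarray(assessment.samples)
    if not np.issubdtype(samples.dtype, np.integer):
        if samples.size and not np.array_equal(samples, np.rint(samples)):
            raise ValueError(
                "binary dialect stores 16-bit integers; quantize float samples first"
            )
        samples = samples.astype(np.int64)
    if samples.size and (samples.max() > 32767 or samples.min() < -32768):
        raise ValueError("sample values overflow the 16-bit payload")
    samples = samples.astype("<i2")

    subject = assessment.subject_id.encode("utf-8")
    (v0, p0), (v1, p1) = assessment.calibration
    epoch = int(assessment.session_datetime.timestamp())
    pma = _PMA_ABSENT if assessment.pma_days is None else int(assessment.pma_days)

    with open(path, "wb") as fh:
        fh.write(_HEADER_FIXED.pack(MAGIC, FORMAT_VERSION, float(assessment.sample_rate_hz)))
        fh.write(_CAL.pack(v0, p0, v1, p1))
        fh.write(struct.pack("<H", len(subject)))
        fh.write(subject)
        fh.write(_TAIL.pack(epoch, pma, samples.size))
        fh.write(samples.tobytes())


def read_assessment(path: str | Path) -> RawAssessment:
    """Read a binary assessment file, validating magic, version and payload
    length against the header."""
    data = Path(path).read_bytes()
    if len(data) == 0:
        raise AssessCorruptionError(f"{path}: empty file")
    if len(data) < _HEADER_FIXED.size:
        raise AssessCorruptionError(f"{path}: truncated header")
    magic, version, rate = _HEADER_FIXED.unpack_from(data, 0)
    if magic != MAGIC:
        raise AssessFormatError(f"{path}: bad magic bytes {magic!r}")
    if version != FORMAT_VERSION:
        raise AssessVersionError(f"{path}: unsupported dialect version {version}")
    off = _HEADER_FIXED.size
    try:
        v0, p0, v1, p1 = _CAL.unpack_from(data, off)
        off += _CAL.size
        (slen,) = struct.unpack_from("<H", data, off)
        off += 2
        subject = data[off : off + slen].decode("utf-8")
        off += slen
        epoch, pma, n_samples = _TAIL.unpack_from(data, off)
        off += _TAIL.size
    except struct.error as exc:
        raise AssessCorruptionError(f"{path}: truncated header ({exc})") from exc

    payload = data[off:]
    if len(payload) != 2 * n_samples:
        raise AssessCorruptionError(
            f"{path}: header declares {n_samples} samples "
            f"but payload holds {len(payload) // 2}"
        )
    samples = np.frombuffer(payload, dtype="<i2").astype(np.int16)
    return RawAssessment(
        samples=samples,
        sample_rate_hz=rate,
        calibration=((v0, p0), (v1, p1)),
        subject_id=subject,
        session_datetime=datetime.fromtimestamp(epoch, tz=timezone.utc),
        pma_days=None if pma == _PMA_ABSENT else pma,
    )


# --------------------------------------------------------------------------
# CSV signal path
# --------------------------------------------------------------------------

#: Maximum relative deviation of the time-column step for a CSV signal to be
#: accepted as uniformly sampled.
TIME_STEP_RTOL = 1e-6


def read_csv_signal(path: str | Path) -> RawAssessment:
    """Read a recording from CSV: optional ``# key: value`` header lines,
    then either ``time_s,pressure`` columns (rate inferred and checked for
    uniformity) or a single ``pressure`` column with a declared
    ``sample_rate_hz`` header key."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            else:
                rows.append([c.strip() for c in line.split(",")])
    if not rows:
        raise AssessFormatError(f"{path}: no data rows")
    header, data_rows = rows[0], rows[1:]
    if not data_rows:
        raise AssessFormatError(f"{path}: header only, no samples")

    cols = [h.lower() for h in header]
    values = np.asarray([[float(c) for c in r] for r in data_rows])
    if "time_s" in cols and "pressure" in cols:
        t = values[:, cols.index("time_s")]
        pressure = values[:, cols.index("pressure")]
        steps = np.diff(t)
        if steps.size == 0:
            raise AssessFormatError(f"{path}: need at least two samples to infer rate")
        mean_step = float(steps.mean())
        if mean_step <= 0 or np.any(
            np.abs(steps - mean_step) > TIME_STEP_RTOL * abs(mean_step)
        ):
            raise AssessFormatError(f"{path}: time column is not uniformly increasing")
        rate = 1.0 / mean_step
    elif "pressure" in cols:
        if "sample_rate_hz" not in meta:
            raise AssessFormatError(
                f"{path}: pressure-only CSV requires a '# sample_rate_hz:' header"
            )
        rate = float(meta["sample_rate_hz"])
        pressure = values[:, cols.index("pressure")]
    else:
        raise AssessFormatError(f"{path}: expected 'time_s,pressure' or 'pressure' columns")

    cal = ((0.0, 0.0), (1.0, 1.0))  # samples already in cm H2O
    if "calibration" in meta:
        a, b = meta["calibration"].split(";")
        cal = (tuple(float(x) for x in a.split("/")), tuple(float(x) for x in b.split("/")))  # type: ignore[assignment]
    when = meta.get("session_datetime")
    return RawAssessment(
        samples=pressure,
        sample_rate_hz=rate,
        calibration=cal,  # type: ignore[arg-type]
        subject_id=meta.get("subject_id", Path(path).stem),
        session_datetime=(
            datetime.fromisoformat(when) if when else datetime(1970, 1, 1, tzinfo=timezone.utc)
        ),
        pma_days=int(meta["pma_days"]) if "pma_days" in meta else None,
    )


# --------------------------------------------------------------------------
# feeding log
# --------------------------------------------------------------------------

FEEDING_LOG_COLUMNS = ("subject_id", "date", "feed_mode", "volume_ml")


def read_feeding_log(path: str | Path) -> list[FeedingRecord]:
    """Parse a feeding-log CSV (columns ``subject_id,date,feed_mode[,volume_ml]``,
    ISO-8601 dates).  Unknown feed-mode strings raise with the offending row."""
    records: list[FeedingRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty feeding log", path)
            return records
        for i, row in enumerate(reader, start=2):
            mode_str = (row.get("feed_mode") or "").strip()
            try:
                mode = FeedMode(mode_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path} row {i}: unknown feed mode {mode_str!r} "
                    f"(expected one of {[m.value for m in FeedMode]})"
                ) from exc
            vol = row.get("volume_ml")
            records.append(
                FeedingRecord(
                    subject_id=row["subject_id"].strip(),
                    date=date.fromisoformat(row["date"].strip()),
                    feed_mode=mode,
                    volume_ml=float(vol) if vol not in (None, "") else None,
                )
            )
    if not records:
        logger.warning("%s: feeding log contains no records", path)
    return records


def write_feeding_log(records: list[FeedingRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FEEDING_LOG_COLUMNS)
        for r in records:
            w.writerow(
                [r.subject_id, r.date.isoformat(), r.feed_mode.value,
                 "" if r.volume_ml is None else f"{r.volume_ml:g}"]
            )


# --------------------------------------------------------------------------
# intermediate exports
# --------------------------------------------------------------------------


def export_intermediates(result, directory: str | Path) -> dict[str, Path]:
    """Write one session's analysis products as human-readable CSVs.

    ``result`` is a :class:`nnskit.pipeline.SessionResult`.  Returns a
    manifest mapping product name to path.  Deterministic: identical inputs
    produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    peaks_path = directory / "peaks.csv"
    with open(peaks_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "amplitude_cm_h2o", "half_height_width_ms",
                    "onset_s", "offset_s", "class"])
        for p in result.peaks:
            w.writerow([f"{p.time_s:.6f}", f"{p.amplitude:.6f}",
                        f"{p.half_height_width_ms:.3f}", f"{p.onset_s:.6f}",
                        f"{p.offset_s:.6f}", p.klass.value])
    manifest["peaks"] = peaks_path

    bursts_path = directory / "bursts.csv"
    with open(bursts_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "start_s", "end_s", "n_cycles"])
        for b in result.bursts:
            w.writerow([b.index, f"{b.start_s:.6f}", f"{b.end_s:.6f}", b.n_cycles])
    manifest["bursts"] = bursts_path

    for method, spec in sorted(result.spectra.items()):
        sp_path = directory / f"spectrum_{method.lower()}.csv"
        with open(sp_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["freq_hz", "power"])
            for f, p in zip(spec.freqs_hz, spec.power):
                w.writerow([f"{f:.6f}", f"{p:.9e}"])
        manifest[f"spectrum_{method.lower()}"] = sp_path

    feats_path = directory / "features.csv"
    with open(feats_path, "w", newline="") as fh:
        w = csv.writer(fh)
        fv = result.features
        row = fv.as_dict()
        w.writerow(list(row))
        w.writerow(["" if v is None else v for v in row.values()])
    manifest["features"] = feats_path

    sti_path = directory / "sti.csv"
    with open(sti_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sti", "n_bursts_used", "m_cycles", "insufficient"])
        sr = result.sti
        w.writerow(
            ["" if sr.sti is None else f"{sr.sti:.6f}", sr.n_bursts_used,
             sr.m_cycles, int(sr.insufficient)]
        )
    manifest["sti"] = sti_path
    return manifest
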