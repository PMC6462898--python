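"""Waveform record container, delimited-format I/O, and the screening ledger.

A :class:`WaveformRecord` holds one subject's synchronized ECG, PPG and
invasive arterial blood pressure (ABP) channels sampled at a common rate.
The native on-disk format is deliberately plain: a few ``#key=value``
header lines followed by comma-separated sample rows, one column per
present channel, so fixtures are inspectable and diff-able.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

CHANNELS = ("ecg", "ppg", "abp")

#: The seven screening categories, in fixed precedence order.
QUALITY_CATEGORIES = (
    "missing_abp",
    "missing_ecg",
    "missing_ppg",
    "abnormal_abp",
    "abnormal_ecg",
    "abnormal_ppg",
    "good",
)


class RecordFormatError(ValueError):
    """Raised when a waveform file cannot be parsed into a valid record."""


@dataclass
class WaveformRecord:
    """One subject's synchronized waveforms.

    ECG and PPG are in arbitrary units; ABP is in mmHg. A channel may be
    ``None`` (absent), which is distinct from a flat-line channel: absence
    means the signal was never recorded, a flat line means the transducer
    produced a constant.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray | None = None
    ppg: np.ndarray | None = None
    abp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        lengths = {len(getattr(self, c)) for c in CHANNELS if getattr(self, c) is not None}
        if len(lengths) > 1:
            raise ValueError(f"channel length mismatch: {sorted(lengths)}")
        if not lengths:
            raise ValueError("record has no channels")
        for c in CHANNELS:
            x = getattr(self, c)
            if x is not None:
                setattr(self, c, np.asarray(x, dtype=float))

    @property
    def n_samples(self) -> int:
        for c in CHANNELS:
            x = getattr(self, c)
            if x is not None:
                return len(x)
        raise AssertionError("unreachable: record has no channels")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def present_channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS if getattr(self, c) is not None)


def write_record(record: WaveformRecord, path: str | Path, precision: int = 9) -> Path:
    """Write a record in the native delimited format."""
    path = Path(path)
    chans = record.present_channels()
    with open(path, "w", newline="") as f:
        f.write(f"#subject_id={record.subject_id}\n")
        f.write(f"#fs={record.fs!r}\n")
        f.write(f"#channels={','.join(chans)}\n")
        f.write(f"#units={','.join('mmHg' if c == 'abp' else 'a.u.' for c in chans)}\n")
        cols = [getattr(record, c) for c in chans]
        for row in zip(*cols):
            f.write(",".join(f"{v:.{precision}g}" for v in row) + "\n")
    return path


def read_record(path: str | Path, format: str = "native") -> WaveformRecord:
    """Read a waveform record.

    ``format="native"`` reads the package's delimited format;
    ``format="wfdb"`` delegates to :func:`read_wfdb_record`. Channels are
    never resampled — a WFDB record with mismatched per-channel rates is
    an error, not a resampling request.
    """
    if format == "wfdb":
        return read_wfdb_record(path)
    if format != "native":
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise RecordFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                k, v = line[1:].split("=", 1)
                header[k] = v
                continue
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise RecordFormatError(f"{path}:{lineno}: bad sample row: {exc}") from None
    for key in ("subject_id", "fs", "channels"):
        if key not in header:
            raise RecordFormatError(f"{path}: missing header field {key!r}")
    try:
        fs = float(header["fs"])
    except ValueError:
        raise RecordFormatError(f"{path}: non-numeric fs {header['fs']!r}") from None
    if fs <= 0:
        raise RecordFormatError(f"{path}: non-positive fs {fs}")
    chans = tuple(header["channels"].split(","))
    unknown = set(chans) - set(CHANNELS)
    if unknown:
        raise RecordFormatError(f"{path}: unknown channels {sorted(unknown)}")
    widths = {len(r) for r in rows}
    if not rows:
        raise RecordFormatError(f"{path}: no sample rows")
    if widths != {len(chans)}:
        raise RecordFormatError(
            f"{path}: sample rows have widths {sorted(widths)}, expected {len(chans)} "
            f"(truncated or corrupt file)"
        )
    data = np.asarray(rows, dtype=float)
    kwargs = {c: data[:, i] for i, c in enumerate(chans)}
    return WaveformRecord(subject_id=header["subject_id"], fs=fs, **kwargs)


def read_wfdb_record(path: str | Path) -> WaveformRecord:
    """Adapter for WFDB-style records (requires the optional ``wfdb`` package).

    Channel names are matched case-insensitively against II/ECG, PLETH/PPG
    and ABP/ART. All matched channels must share one sampling rate.
    """
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - exercised when wfdb absent
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install it or convert the record to the native delimited format"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    aliases = {"ecg": ("ii", "ecg", "i", "v", "mlii"), "ppg": ("pleth", "ppg"), "abp": ("abp", "art")}
    kwargs: dict[str, np.ndarray] = {}
    for chan, names in aliases.items():
        for i, sig in enumerate(rec.sig_name):
            if sig.lower() in names:
                kwargs[chan] = rec.p_signal[:, i]
                break
    if not kwargs:
        raise RecordFormatError(f"{path}: no ECG/PPG/ABP channels found in {rec.sig_name}")
    return WaveformRecord(subject_id=rec.record_name, fs=float(rec.fs), **kwargs)


@dataclass
class ScreeningLedger:
    """Partition of record IDs into the seven screening categories."""

    categories: dict[str, list[str]] = field(
        default_factory=lambda: {c: [] for c in QUALITY_CATEGORIES}
    )

    def __post_init__(self) -> None:
        extra = set(self.categories) - set(QUALITY_CATEGORIES)
        if extra:
            raise ValueError(f"unknown ledger categories {sorted(extra)}")
        for c in QUALITY_CATEGORIES:
            self.categories.setdefault(c, [])
        seen: dict[str, str] = {}
        for cat, ids in self.categories.items():
            for rid in ids:
                if rid in seen:
                    raise ValueError(f"record {rid!r} in both {seen[rid]!r} and {cat!r}")
                seen[rid] = cat

    def add(self, category: str, record_id: str) -> None:
        if category not in QUALITY_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        for cat, ids in self.categories.items():
            if record_id in ids:
                raise ValueError(f"record {record_id!r} already in {cat!r}")
        self.categories[category].append(record_id)

    def category_of(self, record_id: str) -> str | None:
        for cat, ids in self.categories.items():
            if record_id in ids:
                return cat
        return None


def tabulate_ledger(ledger: ScreeningLedger) -> dict[str, int]:
    """Per-category counts plus a ``total`` key. Pure bookkeeping."""
    counts = {cat: len(ids) for cat, ids in ledger.categories.items()}
    counts["total"] = sum(counts[c] for c in QUALITY_CATEGORIES)
    return counts


def write_ledger(ledger: ScreeningLedger, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["category", "record_id"])
        for cat in QUALITY_CATEGORIES:
            for rid in ledger.categories[cat]:
                w.writerow([cat, rid])
    return path


def read_ledger(path: str | Path) -> ScreeningLedger:
    ledger = ScreeningLedger()
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header != ["category", "record_id"]:
            raise RecordFormatError(f"{path}: bad ledger header {header}")
        for cat, rid in reader:
            ledger.add(cat, rid)
    return ledger


def load_table1_fixture() -> ScreeningLedger:
    """Load the packaged MIMIC screening ledger.

    578 record IDs partitioned into the seven categories; see
    ``data/table1_provenance.md`` for the transcription notes.
    """
    ledger = ScreeningLedger()
    ref = resources.files("patcorr.data").joinpath("table1_screening.csv")
    with ref.open(newline="") as f:
        reader = csv.reader(f)
        next(reader)
        for row in reader:
            if len(row) != 2 or row[0] not in QUALITY_CATEGORIES:
                raise RecordFormatError(f"screening fixture corrupted at row {row!r}")
            ledger.add(row[0], row[1])
    return ledger
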