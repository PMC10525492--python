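"""Data model and I/O for EEG recordings, interval annotations, and montages.

Recordings are multichannel scalp EEG in microvolts. Annotations follow a
TSE-style text dialect: a version header line, then one whitespace-separated
``start stop label confidence`` interval per line, seconds with four decimals,
half-open ``[start, stop)`` time convention. Montages carry the 21 electrode
labels of the standard 10/20 placement with spherical and 2D (azimuthal
equidistant) coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SEIZURE_LABELS",
    "BACKGROUND_LABEL",
    "ALL_LABELS",
    "UNLABELED",
    "Recording",
    "AnnotationEvent",
    "AnnotationSet",
    "Montage",
    "STANDARD_21",
    "REDUCED_8",
    "FormatError",
    "read_recording",
    "write_recording",
    "parse_tse",
    "write_tse",
    "select_channels",
    "label_at",
]

#: The eight seizure type codes plus background.
SEIZURE_LABELS = ("fnsz", "gnsz", "spsz", "cpsz", "absz", "tnsz", "tcsz", "mysz")
BACKGROUND_LABEL = "bckg"
ALL_LABELS = (BACKGROUND_LABEL,) + SEIZURE_LABELS
#: Sentinel returned by :func:`label_at` when no event overlaps the query.
UNLABELED = "unlabeled"

TSE_HEADER = "version = tse_v1.0.0"


class FormatError(ValueError):
    """A file does not parse under the declared format."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Ordered multichannel time series in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; row order matches
    ``channel_names``.
    """

    subject_id: str
    record_id: str
    channel_names: list[str]
    sampling_rate_hz: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def crop(self, t0: float, t1: float) -> "Recording":
        """Return the slice of samples falling in ``[t0, t1)`` seconds."""
        i0 = int(round(t0 * self.sampling_rate_hz))
        i1 = int(round(t1 * self.sampling_rate_hz))
        return replace(self, data=self.data[:, i0:i1].copy())


@dataclass(frozen=True)
class AnnotationEvent:
    """A labeled half-open interval ``[start_s, stop_s)`` over a recording."""

    start_s: float
    stop_s: float
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_s < self.stop_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.stop_s})")
        if self.start_s < 0:
            raise ValueError("start_s must be nonnegative")
        if self.label not in ALL_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {ALL_LABELS}"
            )

    def overlap(self, t0: float, t1: float) -> float:
        return max(0.0, min(self.stop_s, t1) - max(self.start_s, t0))


@dataclass
class AnnotationSet:
    """Sorted, non-overlapping labeled intervals over one recording."""

    events: list[AnnotationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start_s)
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.start_s < prev.stop_s - 1e-9:
                raise ValueError(
                    f"overlapping events: [{prev.start_s}, {prev.stop_s}) "
                    f"{prev.label} and [{cur.start_s}, {cur.stop_s}) {cur.label}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def duration_s(self) -> float:
        return self.events[-1].stop_s if self.events else 0.0

    def seizure_events(self) -> list[AnnotationEvent]:
        return [e for e in self.events if e.label != BACKGROUND_LABEL]


# ---------------------------------------------------------------------------
# Montages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with unit-sphere and projected 2D positions.

    ``positions_3d[i]`` is (x, y, z) with x toward the right ear, y toward the
    nasion, z up; ``positions_2d[i]`` is the azimuthal-equidistant projection,
    radius 1 at the equatorial (ear) plane.
    """

    names: tuple[str, ...]
    positions_3d: np.ndarray
    positions_2d: np.ndarray

    def index(self, name: str) -> int:
        return self.names.index(name)

    def position_3d(self, name: str) -> np.ndarray:
        return self.positions_3d[self.index(name)]

    def subset(self, names) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions_3d[idx], self.positions_2d[idx])

    def scalp_distance(self, a: str, b: str) -> float:
        """Euclidean (chord) distance between two electrodes on the sphere."""
        return float(np.linalg.norm(self.position_3d(a) - self.position_3d(b)))


def _load_ten_twenty() -> dict[str, tuple[float, float]]:
    text = (
        importlib.resources.files("ictalkit.data")
        .joinpath("ten_twenty_positions.tsv")
        .read_text()
    )
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("label"):
            continue
        name, az, incl = line.split("\t")
        table[name] = (float(az), float(incl))
    return table


def _build_montage(names: tuple[str, ...]) -> Montage:
    table = _load_ten_twenty()
    p3, p2 = [], []
    for n in names:
        az, incl = np.deg2rad(table[n][0]), table[n][1]
        incl_r = np.deg2rad(incl)
        p3.append(
            (np.sin(incl_r) * np.sin(az), np.sin(incl_r) * np.cos(az), np.cos(incl_r))
        )
        r = incl / 90.0
        p2.append((r * np.sin(az), r * np.cos(az)))
    return Montage(names, np.array(p3), np.array(p2))


#: The 21 electrodes of the standard 10/20 montage (with earlobe refs A1/A2).
STANDARD_21 = _build_montage(
    (
        "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
        "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "A1", "A2",
    )
)

#: The reduced 8-electrode montage used for the low-channel-count comparison.
REDUCED_8 = STANDARD_21.subset(("F7", "T3", "C3", "Cz", "Fp2", "F8", "O2", "P4"))


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".edf"):
        return "edf"
    if p.endswith(".npz"):
        return "npz"
    raise FormatError(f"cannot infer format from extension of {path!r}")


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording from EDF or the internal npz dialect.

    EDF amplitudes are converted to microvolts; channel order follows the
    file. ``format`` defaults to the file extension.
    """
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "npz":
        return _read_npz(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "npz":
        _write_npz(rec, path)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def _write_npz(rec: Recording, path) -> None:
    np.savez_compressed(
        path,
        data=rec.data,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_names=np.array(rec.channel_names),
        subject_id=rec.subject_id,
        record_id=rec.record_id,
    )


def _read_npz(path) -> Recording:
    with np.load(path, allow_pickle=False) as f:
        try:
            return Recording(
                subject_id=str(f["subject_id"]),
                record_id=str(f["record_id"]),
                channel_names=[str(c) for c in f["channel_names"]],
                sampling_rate_hz=float(f["sampling_rate_hz"]),
                data=f["data"],
            )
        except KeyError as e:
            raise FormatError(f"npz recording missing field {e}") from e


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path) -> None:
    """Write a 16-bit EDF file (one data record per second when possible)."""
    sr = rec.sampling_rate_hz
    if abs(sr - round(sr)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    sr = int(round(sr))
    ns = rec.n_channels
    if rec.n_samples % sr == 0 and rec.n_samples > 0:
        n_records, rec_dur, spr = rec.n_samples // sr, 1.0, sr
    else:
        # whole signal as a single data record
        n_records, rec_dur, spr = 1, rec.n_samples / sr, rec.n_samples
    if rec.n_samples == 0:
        n_records, rec_dur, spr = 0, 1.0, sr

    pmin = np.minimum(rec.data.min(axis=1, initial=0.0), -1e-6)
    pmax = np.maximum(rec.data.max(axis=1, initial=0.0), 1e-6)
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.subject_id, 80),
            _ascii(rec.record_id, 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + ns), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(f"{rec_dur:g}", 8),
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(_ascii(n, 16) for n in rec.channel_names)
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii("uV", 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmin)
    sig += b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmax)
    sig += b"".join(_ascii(dmin, 8) for _ in range(ns))
    sig += b"".join(_ascii(dmax, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii(spr, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 32) for _ in range(ns))

    # re-read the truncated ASCII physical bounds so scaling matches the header
    pmin_h = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_h = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax_h - pmin_h) / (dmax - dmin)
    digital = np.round((rec.data - pmin_h[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(np.ascontiguousarray(block).tobytes())


def _read_edf(path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as e:  # surface the parser's message with context
        raise FormatError(f"unreadable EDF file {path}: {e}") from e
    with open(path, "rb") as fh:
        head = fh.read(168)
    subject_id = head[8:88].decode("ascii", "replace").strip()
    record_id = head[88:168].decode("ascii", "replace").strip()
    return Recording(
        subject_id=subject_id,
        record_id=record_id,
        channel_names=list(raw.ch_names),
        sampling_rate_hz=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # mne loads EEG in volts
    )


# ---------------------------------------------------------------------------
# TSE-dialect annotations
# ---------------------------------------------------------------------------


def parse_tse(path) -> AnnotationSet:
    """Parse a TSE-dialect annotation file into a validated AnnotationSet."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    events = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("version"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 'start stop label confidence'")
        start, stop, label, conf = parts
        if label not in ALL_LABELS:
            raise FormatError(f"{path}:{ln}: unknown label {label!r}")
        try:
            ev = AnnotationEvent(float(start), float(stop), label, float(conf))
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from e
        events.append(ev)
    try:
        return AnnotationSet(events)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_tse(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(TSE_HEADER + "\n\n")
        for e in ann:
            fh.write(f"{e.start_s:.4f} {e.stop_s:.4f} {e.label} {e.confidence:.4f}\n")


# ---------------------------------------------------------------------------
# Channel selection and window labeling
# ---------------------------------------------------------------------------


def select_channels(rec: Recording, montage) -> Recording:
    """Subset/reorder recording rows to a montage (or list of labels)."""
    names = list(montage.names) if isinstance(montage, Montage) else list(montage)
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise ValueError(f"channels missing from recording: {missing}")
    idx = [rec.channel_names.index(n) for n in names]
    return replace(rec, channel_names=names, data=rec.data[idx].copy())


def dominant_event(ann: AnnotationSet, t0: float, t1: float):
    """Event with the largest overlap with ``[t0, t1)``, ties to non-background.

    Returns ``(event, index)`` or ``(None, -1)`` when nothing overlaps.
    """
    if not t0 < t1:
        raise ValueError("t0 must be < t1")
    best, best_idx, best_key = None, -1, None
    for i, ev in enumerate(ann):
        ov = ev.overlap(t0, t1)
        if ov <= 0:
            continue
        key = (ov, ev.label != BACKGROUND_LABEL)
        if best_key is None or key > best_key:
            best, best_idx, best_key = ev, i, key
    return best, best_idx


def label_at(ann: AnnotationSet, t0: float, t1: float) -> str:
    """Majority-overlap label of ``[t0, t1)``; ties favor a seizure label."""
    ev, _ = dominant_event(ann, t0, t1)
    return UNLABELED if ev is None else ev.label
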