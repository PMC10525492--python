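"""Signal preprocessing: filtering, resampling, windowing, STFT tensors, splits.

The chain mirrors a standard seizure-detection front end: a zero-phase 40 Hz
FIR low-pass, polyphase resampling to the working rate, non-overlapping 1 s
windows labeled by majority overlap with the annotations, and a 64-point
short-time Fourier transform per window. Each 1 s window is split into 8
equal non-overlapping segments; each segment is demeaned, edge-tapered with a
Tukey(0.25) window, zero-padded (or truncated) to ``nfft`` points, and
reduced to its one-sided magnitude spectrum, giving an ``n_channels x 33 x
8`` tensor at ``nfft = 64``. This segmentation keeps the 8-timestep axis
identical at every sampling rate in the acquisition sweep (at 50 Hz the
6-sample segments are zero-padded to 64). The mild Tukey taper is used
instead of a full Hann taper because the segments are much shorter than
``nfft`` (31 samples at 250 Hz): a Hann mainlobe then spans four frequency
bins and the bin of a pure sinusoid becomes phase-dependent, while the
near-rectangular Tukey window keeps single-bin localization and still damps
edge-discontinuity sidelobes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_formats import AnnotationSet, Recording, dominant_event

__all__ = [
    "LabeledWindow",
    "SpectroTensor",
    "SplitSpec",
    "fir_lowpass",
    "resample",
    "extract_windows",
    "stft_tensor",
    "tapered_segments",
    "make_splits",
    "kfold_indices",
    "class_weights",
    "save_tensors",
    "load_tensors",
]


@dataclass
class LabeledWindow:
    """One fixed-length window of multichannel samples with its label."""

    data: np.ndarray  # (n_channels, n_samples) microvolts
    label: str
    subject_id: str
    event_index: int  # index of the dominant annotation event in its record
    record_id: str = ""
    channel_names: tuple[str, ...] = ()
    sampling_rate_hz: float = 0.0

    @property
    def group_key(self) -> tuple:
        """Identity of the source annotation event (for leakage-free splits)."""
        return (self.subject_id, self.record_id, self.event_index)


@dataclass
class SpectroTensor:
    """Model input: nonnegative magnitudes, (n_channels, n_freq, n_timesteps)."""

    values: np.ndarray
    label: str
    subject_id: str
    event_index: int
    record_id: str = ""


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.7
    val: float = 0.15
    test: float = 0.15
    grouping: str = "event"  # {"event", "subject"}
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        fracs = (self.train, self.val, self.test)
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.grouping not in ("event", "subject"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


# ---------------------------------------------------------------------------
# Filtering and resampling
# ---------------------------------------------------------------------------


def fir_lowpass(rec: Recording, cutoff_hz: float = 40.0) -> Recording:
    """Zero-phase FIR low-pass; order 4 x (rate / cutoff), rounded odd."""
    nyq = rec.sampling_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz at/above Nyquist {nyq} Hz")
    numtaps = int(round(4 * rec.sampling_rate_hz / cutoff_hz))
    numtaps += 1 - numtaps % 2  # odd
    taps = sps.firwin(numtaps, cutoff_hz, fs=rec.sampling_rate_hz)
    out = sps.filtfilt(taps, [1.0], rec.data, axis=1)
    return replace(rec, data=out)


def resample(rec: Recording, target_hz: float) -> Recording:
    """Polyphase rational resampling to ``target_hz``."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if abs(target_hz - rec.sampling_rate_hz) < 1e-12:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_hz / rec.sampling_rate_hz).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, sampling_rate_hz=target_hz)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def extract_windows(
    rec: Recording, ann: AnnotationSet, window_s: float = 1.0
) -> list[LabeledWindow]:
    """Consecutive non-overlapping windows; trailing remainder discarded."""
    sr = rec.sampling_rate_hz
    wlen = int(round(window_s * sr))
    n_windows = rec.n_samples // wlen
    out = []
    for i in range(n_windows):
        t0, t1 = i * window_s, (i + 1) * window_s
        ev, idx = dominant_event(ann, t0, t1)
        out.append(
            LabeledWindow(
                data=rec.data[:, i * wlen : (i + 1) * wlen].copy(),
                label=ev.label if ev is not None else "unlabeled",
                subject_id=rec.subject_id,
                event_index=idx,
                record_id=rec.record_id,
                channel_names=tuple(rec.channel_names),
                sampling_rate_hz=sr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# STFT tensor
# ---------------------------------------------------------------------------


def tapered_segments(data: np.ndarray, nfft: int = 64, n_timesteps: int = 8):
    """Demeaned, Tukey-tapered nfft-length segments: (C, n_timesteps, nfft)."""
    n_channels, n_samples = data.shape
    seg_len = n_samples // n_timesteps
    if seg_len < 1:
        raise ValueError("window too short for the requested timesteps")
    segs = data[:, : seg_len * n_timesteps].reshape(n_channels, n_timesteps, seg_len)
    segs = segs - segs.mean(axis=2, keepdims=True)
    taper = sps.windows.tukey(seg_len, alpha=0.25)
    segs = segs * taper[None, None, :]
    if seg_len >= nfft:
        return segs[:, :, :nfft]
    out = np.zeros((n_channels, n_timesteps, nfft))
    out[:, :, :seg_len] = segs
    return out


def stft_tensor(w: LabeledWindow, nfft: int = 64) -> SpectroTensor:
    """One-sided magnitude STFT of a window: (C, nfft/2 + 1, 8)."""
    if nfft % 2:
        raise ValueError("nfft must be even")
    if w.data.shape[1] < 8:
        raise ValueError("window must have at least 8 samples")
    segs = tapered_segments(w.data, nfft=nfft, n_timesteps=8)
    mag = np.abs(np.fft.rfft(segs, n=nfft, axis=2))  # (C, 8, nfft/2+1)
    return SpectroTensor(
        values=np.transpose(mag, (0, 2, 1)),
        label=w.label,
        subject_id=w.subject_id,
        event_index=w.event_index,
        record_id=w.record_id,
    )


# ---------------------------------------------------------------------------
# Splits and class weights
# ---------------------------------------------------------------------------


def _group_table(windows, grouping: str):
    """Map group key -> (indices, label of the group)."""
    groups: dict[tuple, list[int]] = {}
    labels: dict[tuple, str] = {}
    for i, w in enumerate(windows):
        key = (w.subject_id,) if grouping == "subject" else w.group_key
        groups.setdefault(key, []).append(i)
        labels.setdefault(key, w.label)
    return groups, labels


def make_splits(windows, spec: SplitSpec = SplitSpec()):
    """Partition window indices into (train, val, test), grouped and stratified.

    All windows of one group (annotation event, or subject) land in the same
    split; within each label stratum groups are shuffled and allotted by the
    largest-remainder rule on window counts.
    """
    groups, glabels = _group_table(windows, spec.grouping)
    rng = np.random.default_rng(spec.seed)
    strata: dict[str, list[tuple]] = {}
    for key, lab in glabels.items():
        strata.setdefault(lab if spec.stratify else "all", []).append(key)
    out: tuple[list[int], list[int], list[int]] = ([], [], [])
    fracs = (spec.train, spec.val, spec.test)
    for lab in sorted(strata):
        keys = sorted(strata[lab])
        rng.shuffle(keys)
        if len(keys) < 3:
            warnings.warn(
                f"label {lab!r} has only {len(keys)} group(s); "
                "best-effort split assignment"
            )
        total = sum(len(groups[k]) for k in keys)
        targets = [f * total for f in fracs]
        filled = [0.0, 0.0, 0.0]
        for k in keys:
            deficit = [t - f for t, f in zip(targets, filled)]
            j = int(np.argmax(deficit))
            out[j].extend(groups[k])
            filled[j] += len(groups[k])
    return tuple(sorted(part) for part in out)


def kfold_indices(windows, k: int = 5, seed: int = 0):
    """Stratified, event-grouped k-fold (train, val) index pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    from sklearn.model_selection import StratifiedGroupKFold

    y = [w.label for w in windows]
    g = [w.group_key for w in windows]
    gid = {key: i for i, key in enumerate(dict.fromkeys(g))}
    g = [gid[key] for key in g]
    skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [
            (sorted(tr.tolist()), sorted(va.tolist()))
            for tr, va in skf.split(np.zeros(len(y)), y, groups=g)
        ]


def class_weights(labels) -> dict[str, float]:
    """Inverse-frequency weights w_c = N / (K * n_c); sum_c w_c n_c == N."""
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n, k = len(labels), len(counts)
    return {lab: n / (k * c) for lab, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_tensors(tensors: list[SpectroTensor], path, meta: dict | None = None):
    """Persist a tensor dataset as a compressed archive + JSON sidecar."""
    values = np.stack([t.values for t in tensors])
    np.savez_compressed(path, values=values)
    sidecar = {
        "labels": [t.label for t in tensors],
        "subjects": [t.subject_id for t in tensors],
        "records": [t.record_id for t in tensors],
        "event_indices": [t.event_index for t in tensors],
        "meta": meta or {},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_tensors(path) -> tuple[list[SpectroTensor], dict]:
    with np.load(path) as f:
        values = f["values"]
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    tensors = [
        SpectroTensor(values[i], sidecar["labels"][i], sidecar["subjects"][i],
                      sidecar["event_indices"][i], sidecar["records"][i])
        for i in range(values.shape[0])
    ]
    return tensors, sidecar["meta"]
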