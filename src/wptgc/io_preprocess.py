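"""Signal ingest and the conditioning chain.

Common average reference -> zero-phase bandpass -> anti-aliased
resampling -> trial segmentation around movement onsets -> baseline
correction over the preparation window -> per-channel amplitude
normalization.  The chain is deterministic and preserves trial count and
segment geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "TrialSegments",
    "read_delimited",
    "write_delimited",
    "common_average_reference",
    "bandpass_filter",
    "resample",
    "segment_trials",
    "baseline_correct",
    "normalize_amplitude",
    "average_trials",
    "preprocess_chain",
]


@dataclass
class RawRecording:
    """Multichannel recording: ``samples`` is channels x time."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: "
                f"{self.channel_labels}"
            ) from None


@dataclass
class TrialSegments:
    """Segmented trials: ``trials`` is channels x trials x time."""

    trials: np.ndarray
    fs: float
    channel_labels: list[str]
    onset_index: int
    period_split: tuple[int, int]

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be channels x trials x time")
        pre, post = self.period_split
        if pre + post != self.trials.shape[2]:
            raise ValueError(
                f"period split {self.period_split} inconsistent with trial "
                f"length {self.trials.shape[2]}"
            )
        if self.onset_index != pre:
            raise ValueError("onset_index must equal the preparation length")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def channel(self, label: str) -> np.ndarray:
        return self.trials[self.channel_labels.index(label)]


def _has_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first:
        return False
    for tok in first.split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_delimited(path, fs: float, columns: list[str] | None = None
                   ) -> RawRecording:
    """Read a CSV (one column per channel, optional header) into a recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = 0 if _has_header(path) else None
    try:
        df = pd.read_csv(path, header=header)
    except pd.errors.EmptyDataError:
        raise ValueError(f"cannot parse {path}: file is empty") from None
    if df.empty:
        raise ValueError(f"cannot parse {path}: no data rows")
    if header is None:
        df.columns = [f"ch{i}" for i in range(df.shape[1])]
    else:
        df.columns = [str(c).strip() for c in df.columns]
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise KeyError(
                f"column(s) {missing} not in {path.name}; available: "
                f"{list(df.columns)}"
            )
        df = df[list(columns)]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {col!r} at data row {row}")
        df[col] = coerced
    return RawRecording(samples=df.to_numpy().T, fs=fs,
                        channel_labels=list(df.columns))


def write_delimited(rec: RawRecording, path) -> None:
    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
        path, index=False)


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference undefined for a single "
                         "channel")
    ref = rec.samples.mean(axis=0, keepdims=True)
    return replace(rec, samples=rec.samples - ref,
                   channel_labels=list(rec.channel_labels))


def bandpass_filter(rec: RawRecording, low: float, high: float,
                    order: int = 4) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2 "
            f"({nyq} Hz); got ({low}, {high})"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered,
                   channel_labels=list(rec.channel_labels))


def resample(rec: RawRecording, target_fs: float) -> RawRecording:
    """Anti-aliased polyphase resampling down to ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling not supported: target {target_fs} Hz > {rec.fs} Hz"
        )
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return replace(rec, samples=rec.samples.copy(),
                       channel_labels=list(rec.channel_labels))
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator,
                            axis=1)
    return RawRecording(samples=out, fs=target_fs,
                        channel_labels=list(rec.channel_labels))


def segment_trials(rec: RawRecording, onsets, pre_s: float, post_s: float
                   ) -> TrialSegments:
    """Cut [onset - pre_s, onset + post_s) windows around each onset."""
    pre = int(round(pre_s * rec.fs))
    post = int(round(post_s * rec.fs))
    if pre + post < 1:
        raise ValueError("segment length must be at least one sample")
    onsets = [int(o) for o in onsets]
    bad = [o for o in onsets if o - pre < 0 or o + post > rec.n_samples]
    if bad:
        raise ValueError(
            f"onset(s) {bad} too near the recording edge for a "
            f"[-{pre_s}s, +{post_s}s) window"
        )
    trials = np.stack([rec.samples[:, o - pre: o + post] for o in onsets],
                      axis=1)
    return TrialSegments(trials=trials, fs=rec.fs,
                         channel_labels=list(rec.channel_labels),
                         onset_index=pre, period_split=(pre, post))


def baseline_correct(segments: TrialSegments,
                     window: tuple[int, int] | None = None) -> TrialSegments:
    """Remove the per-trial mean of the baseline window (default: the
    whole preparation period)."""
    if window is None:
        window = (0, segments.period_split[0])
    b0, b1 = window
    if b1 <= b0:
        raise ValueError(f"baseline window {window} is empty")
    baseline = segments.trials[:, :, b0:b1].mean(axis=2, keepdims=True)
    return replace(segments, trials=segments.trials - baseline,
                   channel_labels=list(segments.channel_labels))


def normalize_amplitude(segments: TrialSegments) -> TrialSegments:
    """Z-score each channel over its concatenated trials.

    Keeps preparation and execution on one scale; EEG-vs-EMG unit
    mismatches disappear.  Idempotent.
    """
    var = segments.trials.var(axis=2)
    flat = np.argwhere(var == 0)
    if flat.size:
        ch, tr = flat[0]
        raise ValueError(
            f"zero-variance trial {tr} in channel "
            f"{segments.channel_labels[ch]!r}: cannot normalize"
        )
    c, ntr, ns = segments.trials.shape
    stacked = segments.trials.reshape(c, ntr * ns)
    mean = stacked.mean(axis=1)[:, None, None]
    sd = stacked.std(axis=1)[:, None, None]
    return replace(segments, trials=(segments.trials - mean) / sd,
                   channel_labels=list(segments.channel_labels))


def average_trials(segments: TrialSegments) -> TrialSegments:
    """Pointwise mean across trials (returned as a single-trial stack)."""
    if segments.n_trials < 1:
        raise ValueError("no trials to average")
    avg = segments.trials.mean(axis=1, keepdims=True)
    return replace(segments, trials=avg,
                   channel_labels=list(segments.channel_labels))


def preprocess_chain(rec: RawRecording, onsets, low: float = 1.0,
                     high: float = 60.0, target_fs: float = 250.0,
                     pre_s: float = 3.0, post_s: float = 4.0,
                     car: bool = True, average: bool = True
                     ) -> tuple[TrialSegments, dict]:
    """Run the full conditioning chain; returns (segments, provenance).

    Onsets are sample indices at the ORIGINAL sampling rate and are
    rescaled after resampling.  CAR is skipped automatically for
    single-channel recordings when ``car`` is true.
    """
    params = {
        "car": car and rec.n_channels >= 2, "band": [low, high],
        "target_fs": target_fs, "pre_s": pre_s, "post_s": post_s,
        "average": average, "source_fs": rec.fs,
    }
    if params["car"]:
        rec = common_average_reference(rec)
    rec = bandpass_filter(rec, low, high)
    ratio = target_fs / rec.fs
    rec = resample(rec, target_fs)
    onsets = [int(round(o * ratio)) for o in onsets]
    segs = segment_trials(rec, onsets, pre_s, post_s)
    segs = baseline_correct(segs)
    if average:
        segs = average_trials(segs)
    segs = normalize_amplitude(segs)
    return segs, params


def save_segments(segments: TrialSegments, out_dir, params: dict | None = None
                  ) -> None:
    """Write per-channel trial CSVs plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ci, label in enumerate(segments.channel_labels):
        pd.DataFrame(segments.trials[ci].T).to_csv(
            out / f"{label}.csv", index=False,
            header=[f"trial{t}" for t in range(segments.n_trials)])
    meta = {
        "fs": segments.fs,
        "onset_index": segments.onset_index,
        "period_split": list(segments.period_split),
        "channels": segments.channel_labels,
        "n_trials": segments.n_trials,
        "chain": params or {},
    }
    (out / "segments.json").write_text(json.dumps(meta, indent=2))
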