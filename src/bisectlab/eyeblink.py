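"""Blink detection and spontaneous eyeblink rate (EBR) from pupil streams.

A resting-state recording is a 500 Hz binary series of pupil-detected
flags.  A blink is a maximal run of >= 3 consecutive missing samples
(runs of 1-2 samples are ignored as tracker noise; runs touching the
stream boundaries count if long enough).  EBR is the number of blinks
per minute whose *onset* falls inside the analysis window — by default
the last 5 minutes of an 8-minute recording, the first 3 minutes being
discarded for light adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MIN_BLINK_SAMPLES = 3


@dataclass
class PupilStream:
    """Binary pupil-detected series at a fixed sampling rate."""

    detected_flags: np.ndarray
    rate_hz: float = 500.0

    def __post_init__(self) -> None:
        flags = np.asarray(self.detected_flags)
        if flags.size == 0:
            raise ValueError("empty pupil stream")
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("detected flags must be 0/1")
        self.detected_flags = flags.astype(np.uint8)

    @property
    def n_samples(self) -> int:
        return int(self.detected_flags.size)

    @property
    def duration_min(self) -> float:
        return self.n_samples / (self.rate_hz * 60.0)


@dataclass(frozen=True)
class BlinkEvent:
    """One blink: half-open sample interval [onset, offset)."""

    onset_sample: int
    offset_sample: int
    rate_hz: float = 500.0

    @property
    def n_samples(self) -> int:
        return self.offset_sample - self.onset_sample

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.rate_hz


@dataclass
class EBRResult:
    ebr: float
    n_blinks_in_window: int
    window_min: float
    discarded_min: float


def detect_blinks(stream: PupilStream) -> list[BlinkEvent]:
    """Find maximal runs of >= 3 missing samples.

    Runs separated by even a single detected sample are distinct blinks;
    no merging of near-adjacent runs is applied.
    """
    flags = stream.detected_flags
    # transitions of the "missing" indicator, padded so boundary runs close
    missing = (flags == 0).astype(np.int8)
    d = np.diff(np.concatenate(([0], missing, [0])))
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    keep = (offsets - onsets) >= MIN_BLINK_SAMPLES
    return [
        BlinkEvent(int(a), int(b), stream.rate_hz)
        for a, b in zip(onsets[keep], offsets[keep])
    ]


def compute_ebr(
    blinks: Sequence[BlinkEvent],
    stream: PupilStream,
    discard_min: float = 3.0,
    window_min: float = 5.0,
) -> EBRResult:
    """Blinks per minute in the analysis window, by blink onset.

    A blink belongs to the window iff its onset sample is at or after
    ``discard_min`` (so a blink starting 2 ms before the boundary and
    ending inside the window is excluded).  Streams shorter than
    ``discard_min + window_min`` are processed with a warning and a
    pro-rated window.
    """
    if discard_min + window_min > stream.duration_min + 1e-9:
        actual = stream.duration_min - discard_min
        if actual <= 0:
            raise ValueError(
                f"window [{discard_min}, {discard_min + window_min}] min exceeds the "
                f"{stream.duration_min:.2f}-min recording"
            )
        warnings.warn(
            f"recording is {stream.duration_min:.2f} min; using a pro-rated "
            f"{actual:.2f}-min window",
            RuntimeWarning,
        )
        window_min = actual
    start = int(round(discard_min * 60.0 * stream.rate_hz))
    n_in = sum(1 for b in blinks if b.onset_sample >= start)
    return EBRResult(
        ebr=n_in / window_min,
        n_blinks_in_window=n_in,
        window_min=window_min,
        discarded_min=discard_min,
    )


def ebr_from_stream(
    stream: PupilStream, discard_min: float = 3.0, window_min: float = 5.0
) -> EBRResult:
    """Convenience: detect blinks then compute the rate."""
    return compute_ebr(detect_blinks(stream), stream, discard_min, window_min)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pupil_stream(path, rate_hz: Optional[float] = None) -> PupilStream:
    """Read the delimited `sample_idx,detected` format.

    The sampling rate comes from a `<path>.meta.yaml` sidecar when
    present, else from the argument, else defaults to 500 Hz.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"sample_idx", "detected"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample_idx,detected")
    df = df.sort_values("sample_idx")
    if rate_hz is None:
        meta = path.with_suffix(path.suffix + ".meta.yaml")
        if meta.exists():
            import yaml

            rate_hz = float(yaml.safe_load(meta.read_text()).get("rate_hz", 500.0))
        else:
            rate_hz = 500.0
    return PupilStream(df["detected"].to_numpy(), rate_hz=rate_hz)


def write_pupil_stream(stream: PupilStream, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"sample_idx": np.arange(stream.n_samples), "detected": stream.detected_flags}
    ).to_csv(path, index=False)
    import yaml

    meta = path.with_suffix(path.suffix + ".meta.yaml")
    meta.write_text(yaml.safe_dump({"rate_hz": stream.rate_hz}))


def read_blink_events(path, rate_hz: float = 500.0) -> list[BlinkEvent]:
    """Read a pre-extracted blink log: one `onset_sample,offset_sample` per line."""
    df = pd.read_csv(path)
    if not {"onset_sample", "offset_sample"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns onset_sample,offset_sample")
    events = []
    for i, row in df.iterrows():
        a, b = int(row["onset_sample"]), int(row["offset_sample"])
        if b - a < MIN_BLINK_SAMPLES:
            raise ValueError(f"{path} row {i}: blink shorter than {MIN_BLINK_SAMPLES} samples")
        events.append(BlinkEvent(a, b, rate_hz))
    return events
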