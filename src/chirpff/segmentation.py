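"""Short-time-energy segmentation of long recordings.

Stridulation is sparse: a five-minute soil recording is mostly silence and
background noise with occasional pulse trains.  Short-time energy (STE) over
coarse 10-s windows flags the acoustically active regions; only those windows
go on to feature extraction, which is where the method's computational saving
comes from (tracked by the segmentation ratio ``S_g``).

Two distinct windowings coexist here on purpose: the 10-s *selection* windows
are rectangular (no taper, 0% overlap), while the 25-ms *analysis* frames
used for features are Hamming-tapered with 50% overlap.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_io import AudioSignal, write_wav

log = logging.getLogger(__name__)

#: Duration of a selection window / retained segment, in seconds.
SEGMENT_SECONDS = 10.0
#: Normalised-STE selection threshold.
STE_THRESHOLD = 0.2
#: Analysis frame length in milliseconds.
FRAME_MS = 25.0
#: Analysis frame overlap fraction.
FRAME_OVERLAP = 0.5


@dataclass
class EnergySeries:
    """Per-window mean-square energy of a recording.

    Windows are half-open ``[start, start + window)`` with 0-based sample
    indexing; a trailing partial window is discarded.  ``normalized_ste`` is
    ``ste`` divided by the recording's maximum window STE, so it is
    dimensionless and invariant to recorder gain (all zeros for a silent
    recording).
    """

    window_start: np.ndarray  # sample index of each window
    ste: np.ndarray  # mean-square energy per window
    normalized_ste: np.ndarray
    window_samples: int
    hop_samples: int


@dataclass
class Segment:
    """A fixed-duration active slice of a recording."""

    source_id: str
    start_s: float
    duration_s: float
    samples: np.ndarray
    rate: int
    label: int | None = None  # 0 = MH, 1 = MM, None = unknown
    normalized_ste: float = float("nan")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        n_expected = int(round(self.duration_s * self.rate))
        if self.samples.size != n_expected:
            raise ValueError(
                f"segment length {self.samples.size} != duration*rate {n_expected}"
            )

    def as_signal(self) -> AudioSignal:
        return AudioSignal(self.samples, self.rate, source_id=self.source_id)


def short_time_energy(
    signal: AudioSignal, window_samples: int, hop_samples: int
) -> EnergySeries:
    """Mean-square energy per (rectangular) window.

    ``ste[w] = mean(x[start : start + window]**2)``; the mean (rather than
    the sum) makes values independent of the window length.
    """
    x = signal.samples
    if not 1 <= window_samples <= x.size:
        raise ValueError(
            f"window_samples {window_samples} outside [1, {x.size}]"
        )
    if hop_samples < 1:
        raise ValueError("hop_samples must be >= 1")
    n_windows = (x.size - window_samples) // hop_samples + 1
    starts = np.arange(n_windows) * hop_samples
    # power via cumulative sum: O(N) regardless of overlap
    csum = np.concatenate(([0.0], np.cumsum(x.astype(np.float64) ** 2)))
    ste = (csum[starts + window_samples] - csum[starts]) / window_samples
    ste = np.maximum(ste, 0.0)  # guard against cancellation
    peak = ste.max() if n_windows else 0.0
    normalized = ste / peak if peak > 0 else np.zeros_like(ste)
    return EnergySeries(starts, ste, normalized, window_samples, hop_samples)


def segment_active_windows(
    signal: AudioSignal,
    window_s: float = SEGMENT_SECONDS,
    overlap_fraction: float = 0.0,
    threshold: float = STE_THRESHOLD,
    label: int | None = None,
) -> list[Segment]:
    """Select the windows whose normalised STE reaches `threshold`.

    Returns the qualifying windows in temporal order as :class:`Segment`
    objects of duration `window_s`.  A window exactly at the threshold is
    selected.  An all-silent recording yields an empty list.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    window = int(round(window_s * signal.rate))
    if signal.samples.size < window:
        raise ValueError(
            f"recording shorter ({signal.duration_s:.1f} s) than window {window_s} s"
        )
    hop = max(1, int(round(window * (1.0 - overlap_fraction))))
    series = short_time_energy(signal, window, hop)
    keep = np.flatnonzero(series.normalized_ste >= threshold)
    if series.ste.max() == 0.0:
        keep = np.array([], dtype=int)  # silent recording: nothing is active
    segments = [
        Segment(
            source_id=signal.source_id,
            start_s=series.window_start[w] / signal.rate,
            duration_s=window / signal.rate,
            samples=signal.samples[
                series.window_start[w] : series.window_start[w] + window
            ].copy(),
            rate=signal.rate,
            label=label,
            normalized_ste=float(series.normalized_ste[w]),
        )
        for w in keep
    ]
    if not segments:
        log.warning("no active windows in %s", signal.source_id)
    return segments


def frame_length(rate: int, frame_ms: float = FRAME_MS) -> int:
    return int(rate * frame_ms / 1000.0)


def frame_signal(
    samples: np.ndarray,
    rate: int,
    frame_ms: float = FRAME_MS,
    overlap_fraction: float = FRAME_OVERLAP,
    window_fn=np.hamming,
) -> np.ndarray:
    """Slice a waveform into tapered analysis frames.

    Frame length is ``floor(frame_ms/1000 * rate)`` samples (1102 at
    44.1 kHz), hop is ``floor(length * (1 - overlap_fraction))``, and each
    row is multiplied by the taper (symmetric Hamming by default).  A 10-s
    segment at 44.1 kHz yields 799 frames.
    """
    x = np.asarray(samples, dtype=np.float64)
    length = frame_length(rate, frame_ms)
    if x.size < length:
        raise ValueError(f"signal shorter than one frame ({length} samples)")
    hop = int(length * (1.0 - overlap_fraction))
    n_frames = (x.size - length) // hop + 1
    idx = np.arange(length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx] * window_fn(length)[None, :]


def segmentation_ratio(
    selected: list[Segment] | int, total_duration_s: float,
    segment_s: float = SEGMENT_SECONDS,
) -> float:
    """Fraction of the original audio retained after segmentation (``S_g``)."""
    if total_duration_s <= 0:
        raise ValueError("total_duration_s must be positive")
    count = selected if isinstance(selected, int) else len(selected)
    return float(np.clip(count * segment_s / total_duration_s, 0.0, 1.0))


def export_segments(segments: list[Segment], out_dir) -> Path:
    """Write each segment as ``<source_id>_<start_s>.wav`` plus a TSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "segments.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source_id", "start_s", "label", "normalized_ste", "path"])
        for seg in segments:
            name = f"{seg.source_id}_{seg.start_s:g}.wav"
            write_wav(out_dir / name, seg.as_signal())
            writer.writerow(
                [seg.source_id, f"{seg.start_s:g}",
                 "" if seg.label is None else seg.label,
                 f"{seg.normalized_ste:.6f}", name]
            )
    return manifest
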