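"""Synthetic stridulation-like recordings for tests and demos.

Real soil recordings of Melolontha larvae are long, mostly silent files with
sparse stridulation bursts.  This generator emulates that structure — not
the actual scarab acoustics — with two synthetic "species" that differ in
carrier frequency and pulse rate:

* class 0 (MH-like): 900 Hz carrier, 12 pulses/s
* class 1 (MM-like): 2200 Hz carrier, 30 pulses/s

Each pulse is an exponentially decaying sinusoid (5-ms decay constant).
Activity occupies whole 10-s windows (a seeded random choice of
``ceil(burst_duty * n_windows)`` of them) so segmentation ground truth is
unambiguous; Gaussian background noise at ``noise_rms`` runs throughout.
The carriers sit well inside the 200-5000 Hz analysis band and the classes
are deliberately separable: these are test-harness parameters, not measured
insect acoustics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_io import TARGET_RATE, AudioSignal, write_wav
from .segmentation import SEGMENT_SECONDS, Segment

CLASS_DEFAULTS = {
    0: {"carrier_hz": 900.0, "pulse_rate_hz": 12.0},
    1: {"carrier_hz": 2200.0, "pulse_rate_hz": 30.0},
}
PULSE_DECAY_S = 0.005  # exponential decay constant of one pulse


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording."""

    class_id: int
    carrier_hz: float | None = None
    pulse_rate_hz: float | None = None
    burst_duty: float = 0.5  # fraction of 10-s windows containing activity
    noise_rms: float = 0.05  # background level relative to pulse peak
    duration_s: float = 60.0
    seed: int = 0
    rate: int = TARGET_RATE

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_DEFAULTS:
            raise ValueError(f"class_id must be 0 or 1, got {self.class_id}")
        defaults = CLASS_DEFAULTS[self.class_id]
        if self.carrier_hz is None:
            self.carrier_hz = defaults["carrier_hz"]
        if self.pulse_rate_hz is None:
            self.pulse_rate_hz = defaults["pulse_rate_hz"]
        if not 200.0 < self.carrier_hz < 5000.0:
            raise ValueError("carrier must lie inside the (200, 5000) Hz band")
        if not 0.0 < self.burst_duty <= 1.0:
            raise ValueError("burst_duty must lie in (0, 1]")
        if self.pulse_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("pulse_rate_hz and duration_s must be positive")
        if self.duration_s % SEGMENT_SECONDS != 0:
            raise ValueError("duration_s must be a multiple of 10 s")


def _pulse(carrier_hz: float, rate: int) -> np.ndarray:
    """One stridulation pulse: decaying sinusoid, ~6 decay constants long."""
    t = np.arange(int(6 * PULSE_DECAY_S * rate)) / rate
    return np.exp(-t / PULSE_DECAY_S) * np.sin(2 * np.pi * carrier_hz * t)


def make_recording(spec: SynthSpec) -> tuple[AudioSignal, list[int]]:
    """Generate one recording; returns the waveform and the ground-truth
    list of active 10-s window indices (sorted)."""
    rng = np.random.default_rng(spec.seed)
    window = int(SEGMENT_SECONDS * spec.rate)
    n_windows = int(spec.duration_s / SEGMENT_SECONDS)
    n_active = math.ceil(spec.burst_duty * n_windows)
    active = np.sort(rng.choice(n_windows, size=n_active, replace=False))
    x = rng.normal(0.0, spec.noise_rms, size=n_windows * window)
    pulse = _pulse(spec.carrier_hz, spec.rate)
    period = int(spec.rate / spec.pulse_rate_hz)
    for w in active:
        # pulse onsets on a regular grid with per-pulse amplitude jitter
        for onset in range(w * window, (w + 1) * window - pulse.size, period):
            x[onset : onset + pulse.size] += rng.uniform(0.8, 1.0) * pulse
    sig = AudioSignal(
        x, spec.rate, source_id=f"synth_c{spec.class_id}_s{spec.seed}"
    )
    return sig, [int(w) for w in active]


def make_dataset(
    n_per_class: int, duration_s: float = 60.0, seed: int = 0, **spec_kwargs
) -> list[tuple[AudioSignal, int, list[int]]]:
    """Balanced list of ``(recording, label, active_windows)`` triples.

    Per-recording seeds are derived as ``seed + index`` so the dataset is
    reproducible and every recording distinct.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = []
    idx = 0
    for class_id in (0, 1):
        for _ in range(n_per_class):
            spec = SynthSpec(
                class_id=class_id, duration_s=duration_s, seed=seed + idx,
                **spec_kwargs,
            )
            sig, active = make_recording(spec)
            out.append((sig, class_id, active))
            idx += 1
    return out


def make_segment_dataset(
    n_segments_per_class: int,
    seed: int = 0,
    duration_s: float = 60.0,
    burst_duty: float = 0.5,
    **spec_kwargs,
) -> list[Segment]:
    """Labelled active 10-s segments cut from synthetic recordings.

    Recordings are generated until each class has `n_segments_per_class`
    ground-truth-active windows; segments are sliced directly at the known
    active windows (no STE pass), so labels are exact by construction.
    """
    window_per_rec = max(1, math.ceil(burst_duty * duration_s / SEGMENT_SECONDS))
    n_rec = math.ceil(n_segments_per_class / window_per_rec)
    segments: list[Segment] = []
    idx = 0
    for class_id in (0, 1):
        cls_segments: list[Segment] = []
        for _ in range(n_rec):
            spec = SynthSpec(
                class_id=class_id, duration_s=duration_s, seed=seed + idx,
                burst_duty=burst_duty, **spec_kwargs,
            )
            sig, active = make_recording(spec)
            window = int(SEGMENT_SECONDS * sig.rate)
            for w in active:
                cls_segments.append(
                    Segment(
                        source_id=sig.source_id,
                        start_s=w * SEGMENT_SECONDS,
                        duration_s=SEGMENT_SECONDS,
                        samples=sig.samples[w * window : (w + 1) * window],
                        rate=sig.rate,
                        label=class_id,
                    )
                )
            idx += 1
        segments.extend(cls_segments[:n_segments_per_class])
    return segments


def make_noise(
    duration_s: float,
    seed: int = 0,
    kind: str = "pink",
    rate: int = TARGET_RATE,
    rms: float = 1.0,
) -> AudioSignal:
    """Synthetic background noise standing in for field recordings.

    "white" is flat Gaussian noise; "pink" has a 1/f amplitude spectrum
    (wind and low-frequency rumble); "forest" is an equal-power sum of the
    two, emulating forest ambience (rumble plus broadband foliage hiss).
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate)

    def pink() -> np.ndarray:
        spec = rng.normal(size=n // 2 + 1) + 1j * rng.normal(size=n // 2 + 1)
        freqs = np.fft.rfftfreq(n, 1.0 / rate)
        spec /= np.sqrt(np.maximum(freqs, 1.0))  # 1/f amplitude above 1 Hz
        spec[0] = 0.0
        return np.fft.irfft(spec, n=n)

    def unit(x: np.ndarray) -> np.ndarray:
        return x / np.sqrt(np.mean(x**2))

    if kind == "white":
        x = rng.normal(size=n)
    elif kind == "pink":
        x = pink()
    elif kind == "forest":
        x = unit(pink()) + unit(rng.normal(size=n))
    else:
        raise ValueError(f"unknown noise kind: {kind}")
    x *= rms / np.sqrt(np.mean(x**2))
    return AudioSignal(x, rate, source_id=f"{kind}_noise_s{seed}")


def export_dataset(dataset, out_dir) -> Path:
    """Write recordings as WAV plus a JSON ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sig, label, active in dataset:
        name = f"{sig.source_id}.wav"
        write_wav(out_dir / name, sig)
        manifest.append({"path": name, "label": label, "active_windows": active})
    (out_dir / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "ground_truth.json"
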