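"""MFCC features and in-input label encoding.

The forward-forward network never sees a label through a loss function;
instead the class identity is written into the input itself.  Each 10-s
segment becomes a flattened 13-coefficient MFCC matrix (frame-major), and
the first ten entries of the flattened vector are overwritten with a
block one-hot code: five zeros + five ones for class 1 (MM), the reverse
for class 0 (MH).  "Positive" samples carry the true-label code,
"negative" samples the wrong-label code — same audio, opposite claim.

MFCC recipe: 25-ms Hamming frames, 50% overlap, 2048-point FFT (frames are
zero-padded from 1102 samples), 26 triangular mel filters spanning the
200-5000 Hz conditioning band (HTK mel scale), log filterbank energies with
a 1e-10 floor, orthonormal DCT-II, coefficients 0-12 retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from sklearn.preprocessing import MinMaxScaler

from .segmentation import FRAME_MS, FRAME_OVERLAP, Segment, frame_signal

log = logging.getLogger(__name__)

N_MFCC = 13
N_MEL_FILTERS = 26
FFT_SIZE = 2048
MEL_LOW_HZ = 200.0
MEL_HIGH_HZ = 5000.0
LOG_FLOOR = 1e-10
#: Number of leading vector positions reserved for the label code.
N_LABEL_SLOTS = 10


@dataclass
class FeatureMatrix:
    """MFCCs of one segment: ``values`` is (n_frames, 13)."""

    values: np.ndarray
    source_id: str = "unknown"
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_MFCC:
            raise ValueError(f"expected (n_frames, {N_MFCC}), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def flatten(self) -> np.ndarray:
        """Row-major (frame-major) flattening — what the first layer consumes."""
        return self.values.reshape(-1)


@dataclass
class EncodedSample:
    """A flattened, scaled feature vector with the label code written in."""

    vector: np.ndarray
    label: int
    polarity: str  # "positive" | "negative"
    source_id: str = "unknown"

    @property
    def label_slots(self) -> np.ndarray:
        return self.vector[:N_LABEL_SLOTS]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int = N_MEL_FILTERS,
    n_fft: int = FFT_SIZE,
    rate: int = 44_100,
    low_hz: float = MEL_LOW_HZ,
    high_hz: float = MEL_HIGH_HZ,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, n_fft//2 + 1).

    Filter edges are equally spaced on the HTK mel scale between `low_hz`
    and `high_hz`; triangles peak at 1 (no area normalisation).
    """
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(low_hz), hz_to_mel(high_hz), n_filters + 2))
    freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        left, centre, right = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - left) / (centre - left)
        down = (right - freqs) / (right - centre)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(
    segment: Segment | np.ndarray,
    rate: int | None = None,
    n_coeffs: int = N_MFCC,
) -> FeatureMatrix:
    """Mel-frequency cepstral coefficients of a segment.

    Returns (n_frames, 13); a 10-s segment at 44.1 kHz gives 799 frames.
    Coefficient 0 (overall log energy) is included.
    """
    if isinstance(segment, Segment):
        samples, rate = segment.samples, segment.rate
        source_id, label = segment.source_id, segment.label
    else:
        if rate is None:
            raise ValueError("rate required when passing a bare array")
        samples, source_id, label = np.asarray(segment), "unknown", None
    frames = frame_signal(samples, rate, FRAME_MS, FRAME_OVERLAP)
    spectrum = rfft(frames, n=FFT_SIZE, axis=1)
    power = (spectrum.real**2 + spectrum.imag**2) / FFT_SIZE
    fb = mel_filterbank(rate=rate, n_fft=FFT_SIZE)
    logmel = np.log(np.maximum(power @ fb.T, LOG_FLOOR))
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    return FeatureMatrix(coeffs, source_id=source_id, label=label)


def label_code(label: int, polarity: str) -> np.ndarray:
    """The 10-slot block one-hot code.

    Positive code for class 1: ``[0]*5 + [1]*5``; class 0 the reverse.
    The negative code is the bitwise complement of the positive one.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be positive/negative, got {polarity}")
    code = np.zeros(N_LABEL_SLOTS)
    code[5 * label : 5 * label + 5] = 1.0
    if polarity == "negative":
        code = 1.0 - code
    return code


class FeatureScaler:
    """Per-position min-max scaling of flattened feature vectors.

    Fitted on the training partition only and reused for validation/test
    (out-of-range values are clipped).  After the min-max map to [0, 1] the
    feature positions are multiplied by a *block gain* chosen so the feature
    block's mean squared norm equals the label code's (five ones): without
    it the ~10k feature entries drown out the 10-slot code, and the code's
    relative scale is what lets the network tell a positive from a negative
    encoding.  All scaled feature entries remain in [0, 1].
    """

    def __init__(self, balance_blocks: bool = True) -> None:
        self._scaler = MinMaxScaler(clip=True)
        self.balance_blocks = balance_blocks
        self.block_gain = 1.0

    def fit(self, matrices: list[FeatureMatrix]) -> "FeatureScaler":
        if not matrices:
            raise ValueError("cannot fit scaler on an empty training set")
        stacked = np.stack([m.flatten() for m in matrices])
        labels = {m.label for m in matrices if m.label is not None}
        if len(labels) < 2:
            log.warning("fitting feature scaler on a single-class partition")
        self._scaler.fit(stacked)
        if self.balance_blocks:
            unit = self._scaler.transform(stacked)
            code_energy = float(np.sum(label_code(0, "positive") ** 2))
            feat_energy = float(np.mean(np.sum(unit[:, N_LABEL_SLOTS:] ** 2, axis=1)))
            self.block_gain = (
                min(1.0, float(np.sqrt(code_energy / feat_energy)))
                if feat_energy > 0 else 1.0
            )  # capped so scaled entries stay inside [0, 1]
        return self

    def transform(self, features: FeatureMatrix) -> np.ndarray:
        vec = self._scaler.transform(features.flatten()[None, :])[0]
        vec[N_LABEL_SLOTS:] *= self.block_gain
        return vec


def encode_label(
    features: FeatureMatrix,
    label: int,
    polarity: str,
    scaler: FeatureScaler | None = None,
) -> EncodedSample:
    """Flatten, scale, and write the label code into slots 0-9."""
    vec = scaler.transform(features) if scaler is not None else features.flatten().copy()
    vec = vec.copy()
    vec[:N_LABEL_SLOTS] = label_code(label, polarity)
    return EncodedSample(vec, label=label, polarity=polarity, source_id=features.source_id)


def make_training_pairs(
    segments: list[Segment] | list[FeatureMatrix],
    scaler: FeatureScaler | None = None,
) -> tuple[list[EncodedSample], list[EncodedSample], FeatureScaler]:
    """One positive and one negative sample per labelled segment.

    Accepts raw segments (MFCCs computed here) or precomputed feature
    matrices.  If `scaler` is None a new one is fitted on these data —
    callers doing cross-validation should fit on the training fold and pass
    the fitted scaler for the held-out fold.
    """
    matrices = [
        m if isinstance(m, FeatureMatrix) else mfcc(m) for m in segments
    ]
    if any(m.label is None for m in matrices):
        raise ValueError("every segment must be labelled")
    if scaler is None:
        scaler = FeatureScaler().fit(matrices)
    positives, negatives = [], []
    for m in matrices:
        positives.append(encode_label(m, m.label, "positive", scaler))
        negatives.append(encode_label(m, m.label, "negative", scaler))
    return positives, negatives, scaler
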