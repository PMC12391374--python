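"""WAV ingestion and signal conditioning.

Recordings of sub-soil insect stridulations are mono WAV files, nominally
sampled at 44.1 kHz.  Everything downstream (short-time-energy segmentation,
MFCC extraction) assumes that rate, so files at other rates are resampled on
read.  Conditioning follows the usual field-recording recipe: remove the DC
offset introduced by the recorder, band-pass to the 200-5000 Hz band that
carries scarab-larva stridulation energy, and normalise to a -1.0 dBFS peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

log = logging.getLogger(__name__)

#: Sampling rate every pipeline stage assumes, in Hz.
TARGET_RATE = 44_100


@dataclass
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples
        Amplitudes, dimensionless, nominal range [-1, 1].
    rate
        Sampling rate in Hz.
    source_id
        Provenance string (file stem, synthetic spec id, ...).
    """

    samples: np.ndarray
    rate: int
    source_id: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if int(self.rate) <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.rate = int(self.rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def _stem(path) -> str:
    return Path(path).stem


_PCM_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
}


def read_wav(path, *, resample_to: int | None = TARGET_RATE) -> AudioSignal:
    """Read a WAV file as a mono :class:`AudioSignal` scaled to [-1, 1].

    Multi-channel input is averaged to mono.  PCM16/PCM32, unsigned 8-bit and
    float WAV encodings are accepted; anything else raises ``ValueError``.
    Files not at `resample_to` Hz are resampled (polyphase).
    """
    rate, data = wavfile.read(str(path))
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    sig = AudioSignal(samples, rate, source_id=_stem(path))
    if resample_to is not None and rate != resample_to:
        sig = resample(sig, resample_to)
    return sig


def write_wav(path, signal: AudioSignal, *, subtype: str = "pcm16") -> None:
    """Write an :class:`AudioSignal` as PCM16 (default) or float32 WAV."""
    x = np.clip(signal.samples, -1.0, 1.0)
    if subtype == "pcm16":
        data = np.round(x * (2**15 - 1)).astype(np.int16)
    elif subtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype: {subtype}")
    wavfile.write(str(path), signal.rate, data)


def resample(signal: AudioSignal, rate: int) -> AudioSignal:
    """Polyphase resampling to `rate` Hz."""
    if rate == signal.rate:
        return signal
    g = math.gcd(rate, signal.rate)
    out = sps.resample_poly(signal.samples, rate // g, signal.rate // g)
    return AudioSignal(out, rate, source_id=signal.source_id)


def bandpass_sos(band_low: float, band_high: float, rate: int, order: int = 2):
    """Butterworth band-pass (order pole pairs per edge; order=2 gives the
    4th-order filter used throughout) as second-order sections."""
    nyq = rate / 2
    if not 0 < band_low < band_high:
        raise ValueError("need 0 < band_low < band_high")
    if band_high >= nyq:
        raise ValueError(f"band_high {band_high} Hz must be below Nyquist {nyq} Hz")
    return sps.butter(order, [band_low, band_high], btype="bandpass", fs=rate, output="sos")


def preprocess(
    signal: AudioSignal,
    band_low: float = 200.0,
    band_high: float = 5000.0,
    peak_dbfs: float = -1.0,
) -> AudioSignal:
    """Condition a raw recording: DC removal, band-pass, peak normalisation.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (zero phase) so pulse onsets used by the STE segmenter are not smeared.
    The peak of the returned waveform equals ``10**(peak_dbfs / 20)``
    (0.89125 for the -1.0 dBFS default).  An all-zero input is returned
    unchanged, with a warning: normalisation is undefined for silence.
    """
    x = signal.samples
    if not np.any(x):
        log.warning("preprocess: all-zero input %s returned unchanged", signal.source_id)
        return replace(signal, samples=x.copy())
    x = x - x.mean()
    sos = bandpass_sos(band_low, band_high, signal.rate)
    x = sps.sosfiltfilt(sos, x)
    x = x - x.mean()  # filtering a finite record can leave a tiny offset
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (10.0 ** (peak_dbfs / 20.0) / peak)
    return replace(signal, samples=x)
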