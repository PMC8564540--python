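"""Audio containers and lossless WAV I/O.

All audio in the pipeline is held as float64 sample arrays in [-1, 1].
WAV files are written as 32-bit float PCM so that round trips through
disk are lossless at test tolerances; integer WAVs are accepted on read
and rescaled to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import ParameterError

#: Linear amplitude corresponding to a -6 dBFS peak.
PEAK_MINUS_6_DB: float = 10.0 ** (-6.0 / 20.0)

#: Sample rate every standardized clip and soundscape uses.
STANDARD_RATE: int = 44100

#: Duration of a standardized per-individual clip, in seconds.
STANDARD_CLIP_S: float = 25.0

#: Exact sample count of a standardized clip (25 s at 44.1 kHz).
STANDARD_CLIP_SAMPLES: int = 1_102_500


@dataclass
class AudioClip:
    """A sampled audio signal.

    ``samples`` is 1-D (mono) for everything downstream of
    standardization; 2-D ``(n, channels)`` arrays are accepted so that
    raw multichannel recordings can be carried to the downmix step.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ParameterError("samples must be 1-D (mono) or 2-D (n, channels)")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")
        if int(self.sample_rate_hz) <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        self.sample_rate_hz = int(self.sample_rate_hz)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def is_mono(self) -> bool:
        return self.samples.ndim == 1

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if self.n_samples else 0.0


@dataclass
class StandardClip(AudioClip):
    """A clip conforming to the construction protocol.

    Exactly 25 s of mono audio at 44.1 kHz with the peak normalized to
    -6 dBFS. Instances are validated on creation.
    """

    file_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.is_mono:
            raise ParameterError("standard clips must be mono")
        if self.sample_rate_hz != STANDARD_RATE:
            raise ParameterError(f"standard clips must be at {STANDARD_RATE} Hz")
        if self.n_samples != STANDARD_CLIP_SAMPLES:
            raise ParameterError(
                f"standard clips must have {STANDARD_CLIP_SAMPLES} samples, "
                f"got {self.n_samples}"
            )
        if abs(self.peak - PEAK_MINUS_6_DB) > 1e-6:
            raise ParameterError("standard clip peak must equal -6 dBFS within 1e-6")


def read_wav(path: str | Path) -> AudioClip:
    """Read a WAV file, rescaling integer formats to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, sample_rate_hz=int(rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip to disk as 32-bit float WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(str(path), clip.sample_rate_hz, clip.samples.astype(np.float32))
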