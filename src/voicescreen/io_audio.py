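"""WAV ingestion, polarity/standardization preprocessing, and segmentation.

Recordings are taken to 16 kHz mono on read.  Preprocessing imposes a
positive speech polarity (the waveform is negated when its skewness is
negative) and standardizes the whole recording to zero mean and unit
variance.  Feature extraction then operates on consecutive non-overlapping
segments of 5, 10 and 15 seconds; a trailing remainder shorter than the
segment length is discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.io import wavfile

log = logging.getLogger(__name__)

TARGET_RATE = 16_000
TASKS = ("story_positive", "story_negative", "story_episodic", "picture")
SEGMENT_LENGTHS = (5, 10, 15)


@dataclass
class Waveform:
    samples: np.ndarray
    rate: int = TARGET_RATE
    participant_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class Segment:
    samples: np.ndarray
    rate: int
    length_s: int
    origin: tuple[str, str, int]  # (participant_id, task, index)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def read_wav(path: str | Path, participant_id: str = "", task: str = "") -> Waveform:
    """Read a PCM WAV file as a 16 kHz mono :class:`Waveform`.

    Multichannel audio is averaged to mono; other sampling rates are
    resampled with a polyphase filter.  Integer PCM is scaled to [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"{path}: empty audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE, int(rate))
        data = sps.resample_poly(data, frac.numerator, frac.denominator)
    return Waveform(samples=data, rate=TARGET_RATE,
                    participant_id=participant_id, task=task)


def preprocess(w: Waveform) -> Waveform:
    """Impose positive speech polarity and standardize the recording.

    Polarity is read off the sign of the skewness of the full recording; a
    negatively skewed waveform is negated.  The result is z-scored (zero
    mean, unit variance) over the whole recording, not per segment.
    """
    x = w.samples
    if np.ptp(x) == 0.0:
        raise ValueError("constant signal: cannot standardize")
    if stats.skew(x) < 0:
        x = -x
    x = (x - x.mean()) / x.std()
    return Waveform(samples=x, rate=w.rate,
                    participant_id=w.participant_id, task=w.task)


def segment(w: Waveform, length_s: int) -> list[Segment]:
    """Cut *w* into consecutive non-overlapping segments of *length_s*
    seconds; the trailing remainder is discarded.  Returns an empty list
    (with a logged warning) when the recording is shorter than one segment.
    """
    if length_s not in SEGMENT_LENGTHS:
        raise ValueError(f"segment length {length_s} not in {SEGMENT_LENGTHS}")
    n_seg = w.samples.size // (length_s * w.rate)
    if n_seg == 0:
        log.warning("recording %s/%s shorter than %d s; skipped",
                    w.participant_id, w.task, length_s)
        return []
    step = length_s * w.rate
    return [Segment(samples=w.samples[i * step:(i + 1) * step], rate=w.rate,
                    length_s=length_s, origin=(w.participant_id, w.task, i))
            for i in range(n_seg)]
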