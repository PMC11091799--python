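import numpy as np
import pytest

from voicescreen.io_audio import Segment, Waveform, preprocess, segment
from voicescreen.synth import VoiceSpec, gen_voice_signal


@pytest.fixture(scope="session")
def rich_signal():
    """A 5-s synthetic segment exercising every feature family: two voiced
    stretches at 150 Hz with 5% alternating amplitude perturbation, 16
    syllable bursts, and one 0.5-s pause."""
    spec = VoiceSpec(
        duration=5.0,
        voiced_intervals=[(0.0, 2.0), (2.6, 4.2)],
        f0=150.0,
        shimmer_eps=0.05,
        syllable_times=[0.11 + 0.22 * k for k in range(9)]
        + [2.71 + 0.22 * k for k in range(7)],
        pause_intervals=[(4.4, 4.9)],
        seed=1,
    )
    x, gt = gen_voice_signal(spec)
    w = preprocess(Waveform(x, 16000, "P0", "story_positive"))
    return segment(w, 5)[0], gt


@pytest.fixture(scope="session")
def rich_voicing(rich_signal):
    from voicescreen.features import detect_voicing

    seg, gt = rich_signal
    return detect_voicing(seg), seg, gt


def make_segment(samples: np.ndarray, rate: int = 16000,
                 length_s: int = 5) -> Segment:
    return Segment(samples=samples, rate=rate, length_s=length_s,
                   origin=("p", "t", 0))
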