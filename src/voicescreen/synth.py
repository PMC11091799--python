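"""Synthetic speech-like signals and cohort feature tables with known ground truth.

The generator produces two kinds of artifacts:

* :func:`gen_voice_signal` — a 16 kHz mono waveform built from a harmonic
  complex (first five harmonics of a fundamental, 1/k amplitude rolloff)
  gated by a voiced/unvoiced schedule, with strictly alternating per-period
  amplitude factors ``(1+eps), (1-eps)`` to inject a known local shimmer,
  raised-cosine syllable bursts shaping the intensity envelope, and silent
  pauses at a -35 dB noise floor.  The returned ground truth records the
  exact schedules so that every acoustic feature extractor can be checked
  against construction.

* :func:`gen_cohort` — a participant-level feature table (138 named columns)
  drawn from gamma distributions, with multiplicative group shifts injected
  into a chosen set of informative features.  Group labels follow the MMSE
  convention (1 = healthy, 2 = mild, 3 = moderate-to-severe impairment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import feature_names, SEGMENT_LENGTHS

RATE = 16_000

#: default noise level of non-pause unvoiced gaps, dB below voiced speech RMS
DEFAULT_NOISE_SNR_DB = 15.0
#: noise floor inside pauses, dB below voiced speech RMS
PAUSE_FLOOR_DB = -35.0
#: envelope floor between syllable bursts inside voiced stretches
BURST_FLOOR = 0.12
#: raised-cosine syllable burst full width in seconds
BURST_WIDTH_S = 0.20

VOICE_BREAK_THRESHOLD_S = 1.25 / 70.0


def _check_intervals(intervals: Sequence[tuple[float, float]], duration: float,
                     name: str) -> list[tuple[float, float]]:
    ivs = [(float(a), float(b)) for a, b in intervals]
    for a, b in ivs:
        if not (0.0 <= a < b <= duration):
            raise ValueError(f"{name} interval ({a}, {b}) outside [0, {duration}]")
    ivs.sort()
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError(f"{name} intervals ({a0},{b0}) and ({a1},{b1}) overlap")
    return ivs


@dataclass
class VoiceSpec:
    """Schedule for one synthetic speech-like signal."""

    duration: float = 5.0
    voiced_intervals: Sequence[tuple[float, float]] = ((0.0, 2.0),)
    f0: float = 150.0
    shimmer_eps: float = 0.0
    syllable_times: Sequence[float] = ()
    pause_intervals: Sequence[tuple[float, float]] = ()
    noise_snr_db: float = DEFAULT_NOISE_SNR_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 < 70.0:
            raise ValueError("f0 must be at least 70 Hz (the pitch floor)")
        if not 0.0 <= self.shimmer_eps < 1.0:
            raise ValueError("shimmer_eps must lie in [0, 1)")
        self.voiced_intervals = _check_intervals(self.voiced_intervals,
                                                 self.duration, "voiced")
        self.pause_intervals = _check_intervals(self.pause_intervals,
                                                self.duration, "pause")
        for pa, pb in self.pause_intervals:
            for va, vb in self.voiced_intervals:
                if pa < vb and va < pb:
                    raise ValueError(
                        f"pause ({pa},{pb}) overlaps voiced ({va},{vb})")


@dataclass
class VoiceGroundTruth:
    """Exact construction-time schedules of a synthetic signal."""

    duration: float
    voiced_intervals: list[tuple[float, float]]
    pause_intervals: list[tuple[float, float]]
    voiced_fraction: float
    unvoiced_fraction: float
    f0: float
    shimmer_percent: float
    pulse_times: list[float]
    voice_break_percent: float
    syllable_times: list[float]
    n_pauses: int
    mean_pause_duration: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _burst_envelope(t: np.ndarray, spec: VoiceSpec) -> np.ndarray:
    """Intensity envelope inside voiced stretches: raised-cosine syllable
    bursts over a low floor; all-ones when no syllable schedule is given."""
    if not spec.syllable_times:
        return np.ones_like(t)
    env = np.zeros_like(t)
    half = BURST_WIDTH_S / 2.0
    for c in spec.syllable_times:
        m = np.abs(t - c) < half
        env[m] = np.maximum(env[m], np.cos(np.pi * (t[m] - c) / BURST_WIDTH_S) ** 2)
    return BURST_FLOOR + (1.0 - BURST_FLOOR) * env


def gen_voice_signal(spec: VoiceSpec, rate: int = RATE
                     ) -> tuple[np.ndarray, VoiceGroundTruth]:
    """Render the schedule in *spec* to a mono waveform at *rate* Hz.

    Returns ``(samples, ground_truth)``.  Voiced intervals carry the harmonic
    complex with per-period alternating amplitudes; pauses carry only the
    -35 dB noise floor; remaining unvoiced gaps carry noise at
    ``spec.noise_snr_db`` below the voiced-speech RMS.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)

    period = 1.0 / spec.f0
    pulse_times: list[float] = []
    for a, b in spec.voiced_intervals:
        i0, i1 = int(round(a * rate)), int(round(b * rate))
        tt = t[i0:i1] - a
        s = np.zeros(i1 - i0)
        for k in range(1, 6):
            s += (1.0 / k) * np.sin(2 * np.pi * k * spec.f0 * tt)
        # strictly alternating per-period amplitude factors (1+eps),(1-eps)
        pidx = np.floor(tt * spec.f0).astype(int)
        factor = np.where(pidx % 2 == 0, 1.0 + spec.shimmer_eps,
                          1.0 - spec.shimmer_eps)
        s *= factor
        s *= _burst_envelope(t[i0:i1], spec)
        x[i0:i1] = s
        n_periods = int(np.floor((b - a) * spec.f0))
        # nominal glottal-pulse schedule: one pulse per period
        pulse_times.extend(a + (p + 0.25) * period for p in range(n_periods))

    voiced_mask = np.zeros(n, dtype=bool)
    for a, b in spec.voiced_intervals:
        voiced_mask[int(round(a * rate)):int(round(b * rate))] = True
    speech_rms = float(np.sqrt(np.mean(x[voiced_mask] ** 2))) if voiced_mask.any() else 1.0

    pause_mask = np.zeros(n, dtype=bool)
    for a, b in spec.pause_intervals:
        pause_mask[int(round(a * rate)):int(round(b * rate))] = True

    gap_mask = ~voiced_mask & ~pause_mask
    noise = rng.standard_normal(n)
    x[gap_mask] += noise[gap_mask] * speech_rms * 10 ** (-spec.noise_snr_db / 20)
    x[pause_mask] += noise[pause_mask] * speech_rms * 10 ** (PAUSE_FLOOR_DB / 20)

    voiced_time = sum(b - a for a, b in spec.voiced_intervals)
    pulses = np.asarray(pulse_times)
    if len(pulses) > 1:
        gaps = np.diff(pulses)
        vb = 100.0 * float(np.mean(gaps > VOICE_BREAK_THRESHOLD_S))
    else:
        vb = float("nan")
    pause_durs = [b - a for a, b in spec.pause_intervals]
    gt = VoiceGroundTruth(
        duration=spec.duration,
        voiced_intervals=list(spec.voiced_intervals),
        pause_intervals=list(spec.pause_intervals),
        voiced_fraction=voiced_time / spec.duration,
        unvoiced_fraction=1.0 - voiced_time / spec.duration,
        f0=spec.f0,
        # alternating a(1+eps), a(1-eps): mean |dA| = 2 a eps, mean A = a
        shimmer_percent=200.0 * spec.shimmer_eps,
        pulse_times=list(pulses),
        voice_break_percent=vb,
        syllable_times=list(spec.syllable_times),
        n_pauses=len(spec.pause_intervals),
        mean_pause_duration=float(np.mean(pause_durs)) if pause_durs else float("nan"),
    )
    return x, gt


def write_wav(path: str | Path, samples: np.ndarray, rate: int = RATE) -> None:
    """Write 16-bit PCM mono WAV."""
    from scipy.io import wavfile

    peak = float(np.max(np.abs(samples))) or 1.0
    scaled = np.clip(samples / peak * 0.95, -1.0, 1.0)
    wavfile.write(str(path), rate, (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: per-feature-code baseline (location mean, dispersion mean) for healthy
#: speakers, on the natural units of each acoustic feature
BASELINE: dict[str, tuple[float, float]] = {
    "F1": (32.7, 10.4),   # unvoiced %
    "F2": (1.08, 0.36),   # voiced duration mean (s)
    "F3": (0.88, 0.32),   # voiced duration median
    "F4": (0.26, 0.10),   # voiced duration p15
    "F5": (2.03, 0.71),   # voiced duration p85
    "F6": (0.50, 0.14),   # unvoiced duration mean
    "F7": (0.37, 0.12),   # unvoiced duration median
    "F8": (0.15, 0.02),   # unvoiced duration p15
    "F9": (0.91, 0.27),   # unvoiced duration p85
    "F10": (34.2, 10.0),  # voice breaks %
    "F11": (5.0, 0.56),   # shimmer %
    "F12": (3.92, 0.59),  # speech rate (syl/s)
    "F13": (70.0, 8.0),   # phonation %
    "F14": (5.61, 0.44),  # articulation rate
    "F15": (0.14, 0.01),  # mean intersyllabic pause (s)
    "F16": (0.74, 0.17),  # mean syllable duration (s)
    "F17": (0.62, 0.19),  # number of pauses
    "F18": (5.09, 1.26),  # mean pause duration (s)
    "F19": (162.0, 25.0),  # pitch mean (Hz)
    "F20": (68.0, 12.0),   # pitch SD (Hz)
    "F21": (466.0, 46.0),  # F3-SD (Hz)
    "F22": (1749.5, 66.0),  # speech temporal regularity
    "F23": (807.8, 154.0),  # spectral centroid (Hz)
}

#: default injected group effects: multiplicative location shifts following
#: the direction of impairment (longer unvoiced stretches, more voice breaks,
#: longer pauses with lower MMSE); the unvoiced-duration template scales
#: 0.5 -> 0.6 -> 0.71 s from healthy to moderate-to-severe
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    f"F6_L{L}_loc": (1.0, 1.2, 1.42) for L in SEGMENT_LENGTHS
}
DEFAULT_EFFECTS.update({f"F1_L{L}_loc": (1.0, 1.17, 1.37) for L in SEGMENT_LENGTHS})
DEFAULT_EFFECTS.update({f"F10_L{L}_loc": (1.0, 1.17, 1.38) for L in SEGMENT_LENGTHS})
DEFAULT_EFFECTS.update({f"F16_L{L}_loc": (1.0, 1.23, 1.54) for L in SEGMENT_LENGTHS})
DEFAULT_EFFECTS.update({f"F17_L{L}_loc": (1.0, 1.27, 1.63) for L in SEGMENT_LENGTHS})

#: a strongly separated cohort: large multiplicative shifts on several
#: features with tight dispersion, for separability / recovery experiments
STRONG_EFFECTS: dict[str, tuple[float, float, float]] = {}
for _code in ("F1", "F6", "F10", "F16", "F17", "F18"):
    STRONG_EFFECTS.update({f"{_code}_L{L}_loc": (1.0, 2.0, 4.0)
                           for L in SEGMENT_LENGTHS})

MMSE_RANGES = {1: (27, 30), 2: (20, 26), 3: (11, 19)}


@dataclass
class CohortSpec:
    """Specification of a synthetic participant cohort."""

    n_per_group: tuple[int, int, int] = (45, 44, 44)
    effect_map: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    dispersion: float | Mapping[str, float] = 0.25
    informative_features: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 participants per group")
        names = set(feature_names())
        unknown = set(self.effect_map) - names
        if unknown:
            raise ValueError(f"unknown feature names in effect_map: {sorted(unknown)}")
        if self.informative_features is None:
            self.informative_features = sorted(self.effect_map)
        if not set(self.informative_features) <= names:
            raise ValueError("informative_features must be generated feature names")
        if isinstance(self.dispersion, Mapping):
            if any(v <= 0 for v in self.dispersion.values()):
                raise ValueError("dispersions must be positive")
        elif self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _column_mean(name: str) -> float:
    code, _, kind = name.split("_")
    loc, disp = BASELINE[code]
    return loc if kind == "loc" else disp


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table with gamma-distributed features and injected
    multiplicative group shifts.

    Returns ``(table, ground_truth)`` where the table has one row per
    participant: 138 feature columns, ``group``/``mmse`` labels and
    demographics, and the ground truth records the injected per-group means.
    """
    rng = np.random.default_rng(spec.seed)
    names = feature_names()
    rows = []
    truth_means: dict[str, dict[int, float]] = {c: {} for c in names}

    def cv_of(name: str) -> float:
        if isinstance(spec.dispersion, Mapping):
            return float(spec.dispersion.get(name, 0.25))
        return float(spec.dispersion)

    pid = 0
    for g, n_g in zip((1, 2, 3), spec.n_per_group):
        lo, hi = MMSE_RANGES[g]
        for _ in range(n_g):
            row: dict[str, object] = {
                "participant_id": f"P{pid:03d}",
                "group": g,
                "mmse": int(rng.integers(lo, hi + 1)),
                "age": float(np.clip(rng.normal(76 + 4 * (g - 1), 5), 65, 97)),
                "gender": "F" if rng.random() < 0.7 else "M",
                "education_years": int(np.clip(rng.normal(13 - 3 * (g - 1), 4), 0, 22)),
                "language": "italian" if pid % 2 == 0 else "spanish",
            }
            for name in names:
                mu = _column_mean(name)
                if name in spec.effect_map:
                    mu *= spec.effect_map[name][g - 1]
                truth_means[name][g] = mu
                cv = cv_of(name)
                shape = 1.0 / cv ** 2
                row[name] = rng.gamma(shape, mu / shape)
            rows.append(row)
            pid += 1

    table = pd.DataFrame(rows)
    truth = {
        "group_means": truth_means,
        "informative_features": list(spec.informative_features),
        "n_per_group": tuple(spec.n_per_group),
    }
    return table, truth


def gen_participant_audio(participant_seed: int, duration: float = 45.0,
                          f0: float = 150.0, group: int = 1,
                          rate: int = RATE
                          ) -> dict[str, tuple[np.ndarray, VoiceGroundTruth]]:
    """Four task recordings (three stories + picture description) for one
    synthetic participant.  Lower implied cognitive function (higher *group*)
    lengthens unvoiced gaps and pauses, mirroring the direction of the group
    effects in real cohorts."""
    rng = np.random.default_rng(participant_seed)
    tasks = ("story_positive", "story_negative", "story_episodic", "picture")
    out = {}
    gap = 0.35 + 0.18 * (group - 1)
    for i, task in enumerate(tasks):
        voiced, syl, pauses = [], [], []
        t = 0.3
        while t < duration - 2.5:
            vlen = float(rng.uniform(0.8, 1.8))
            voiced.append((t, t + vlen))
            nsyl = max(1, int(round(vlen / 0.22)))
            syl.extend(t + 0.11 + 0.22 * k for k in range(nsyl))
            t += vlen + float(rng.uniform(0.6, 1.0) * gap)
            if rng.random() < 0.18 * group:
                plen = float(rng.uniform(0.4, 1.2))
                if t + plen < duration - 2.0:
                    pauses.append((t, t + plen))
                    t += plen + 0.05
        spec = VoiceSpec(duration=duration, voiced_intervals=voiced,
                         f0=f0 + rng.uniform(-15, 15), shimmer_eps=0.025,
                         syllable_times=[s for s in syl if s < duration],
                         pause_intervals=pauses,
                         seed=int(rng.integers(2 ** 31)))
        out[task] = gen_voice_signal(spec, rate=rate)
    return out
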