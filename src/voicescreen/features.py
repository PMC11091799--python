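"""Per-segment acoustic features (codes F1-F23).

The 23 features fall into four families:

* voice periodicity (F1-F10): frame-level voiced/unvoiced decisions from the
  normalized autocorrelation peak in the 70-500 Hz pitch range, run-length
  statistics of voiced/unvoiced stretches, and the voice-break rate over
  inter-pulse intervals (an interval longer than 1.25 / 70 Hz = 17.86 ms
  counts as a break);
* shimmer (F11): local cycle-to-cycle amplitude perturbation over glottal
  pulse peaks, in percent;
* syllabic and pause features (F12-F18): intensity-peak syllable nuclei,
  speech/articulation rates, phonation percentage, and pauses defined as
  low-intensity runs longer than 250 ms;
* spectral features (F19-F23): pitch mean/SD, third-formant SD from
  linear-prediction root-finding, a temporal-regularity index of the
  intensity envelope, and the spectral centroid.

Features that are undefined on a segment (e.g. pitch statistics of an
all-silence segment) are returned as NaN and excluded downstream rather
than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .io_audio import Segment

FEATURE_CODES = tuple(f"F{i}" for i in range(1, 24))
VOICE_BREAK_THRESHOLD_S = 1.25 / 70.0


@dataclass
class FeatureConfig:
    """Tunable analysis parameters (defaults sized for 16 kHz speech)."""

    frame_s: float = 0.040           # analysis window for voicing/intensity
    hop_s: float = 0.010
    f0_min: float = 70.0             # pitch floor (Hz)
    f0_max: float = 500.0            # pitch ceiling (Hz)
    voicing_threshold: float = 0.45  # on the normalized autocorrelation peak
    silence_threshold_db: float = -25.0  # rel. segment max intensity
    min_dip_db: float = 2.0          # syllable-nucleus prominence
    min_pause_s: float = 0.25
    envelope_rate: float = 50.0      # Hz, for the temporal-regularity index
    regularity_scale: float = 2000.0
    regularity_lags_s: tuple[float, float] = (0.1, 1.0)
    lpc_order: int = 12
    formant_rate: int = 10_000
    preemphasis: float = 0.97


@dataclass
class VoicingMap:
    frame_times: np.ndarray          # frame centers (s)
    voiced_flags: np.ndarray         # bool per frame
    f0_track: np.ndarray             # Hz per frame, NaN when unvoiced
    pulses: np.ndarray               # glottal pulse times (s)
    pulse_amplitudes: np.ndarray     # |waveform| at each pulse
    hop_s: float
    frame_s: float


@dataclass
class SyllableAnnotation:
    nuclei_times: np.ndarray
    pause_intervals: list[tuple[float, float]]
    phonation_time: float
    syllable_spans: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# framing helpers
# ---------------------------------------------------------------------------

def _frames(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    if x.size < flen:
        return np.empty((0, flen))
    view = np.lib.stride_tricks.sliding_window_view(x, flen)
    return view[::hop].copy()


def _frame_rms(x: np.ndarray, rate: int, frame_s: float, hop_s: float
               ) -> tuple[np.ndarray, np.ndarray]:
    flen, hop = int(round(frame_s * rate)), int(round(hop_s * rate))
    fr = _frames(x, flen, hop)
    rms = np.sqrt(np.mean(fr ** 2, axis=1))
    times = (np.arange(fr.shape[0]) * hop + flen / 2) / rate
    return rms, times


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# voicing and pulses
# ---------------------------------------------------------------------------

def detect_voicing(seg: Segment, cfg: FeatureConfig | None = None) -> VoicingMap:
    """Frame-level voiced/unvoiced decision and pitch track.

    A frame is voiced when the peak of its normalized autocorrelation over
    candidate periods in [1/f0_max, 1/f0_min] exceeds the voicing threshold;
    the fundamental is read off the first autocorrelation peak within 3% of
    the maximum (guarding against octave-down errors), refined by parabolic
    interpolation.  Glottal pulses are then placed once per period at the
    waveform's absolute peak inside each voiced run.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(seg.samples, dtype=float)
    rate = seg.rate
    flen, hop = int(round(cfg.frame_s * rate)), int(round(cfg.hop_s * rate))
    fr = _frames(x, flen, hop)
    n_fr = fr.shape[0]
    times = (np.arange(n_fr) * hop + flen / 2) / rate

    lag_min = int(np.ceil(rate / cfg.f0_max))
    lag_max = int(np.floor(rate / cfg.f0_min))
    nfft = 1
    while nfft < flen + lag_max + 1:
        nfft *= 2

    fr = fr - fr.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(fr, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :lag_max + 1]
    csum = np.concatenate([np.zeros((n_fr, 1)), np.cumsum(fr ** 2, axis=1)], axis=1)
    total = csum[:, -1]
    lags = np.arange(lag_max + 1)
    e0 = csum[:, flen - lags]                       # energy of x[0:N-lag]
    e1 = total[:, None] - csum[:, lags]             # energy of x[lag:N]
    denom = np.sqrt(e0 * e1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, ac / np.maximum(denom, 1e-300), 0.0)

    voiced = np.zeros(n_fr, dtype=bool)
    f0_track = np.full(n_fr, np.nan)
    band = r[:, lag_min:lag_max + 1]
    peak_val = band.max(axis=1) if band.size else np.zeros(n_fr)
    for i in range(n_fr):
        if peak_val[i] < cfg.voicing_threshold:
            continue
        row = r[i]
        # first local max within 3% of the peak: avoids locking onto 2T
        thr = 0.97 * peak_val[i]
        best = None
        for lag in range(lag_min, lag_max + 1):
            if row[lag] >= thr and row[lag] >= row[lag - 1] and \
                    (lag == lag_max or row[lag] >= row[lag + 1]):
                best = lag
                break
        if best is None:
            best = lag_min + int(np.argmax(band[i]))
        if 0 < best < lag_max:
            y0, y1, y2 = row[best - 1], row[best], row[best + 1]
            d = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / d if abs(d) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        voiced[i] = True
        f0_track[i] = rate / (best + delta)

    pulses, amps = _pick_pulses(x, rate, times, voiced, f0_track, cfg)
    return VoicingMap(frame_times=times, voiced_flags=voiced, f0_track=f0_track,
                      pulses=pulses, pulse_amplitudes=amps,
                      hop_s=cfg.hop_s, frame_s=cfg.frame_s)


def _pick_pulses(x: np.ndarray, rate: int, times: np.ndarray,
                 voiced: np.ndarray, f0_track: np.ndarray,
                 cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    pulses: list[float] = []
    amps: list[float] = []
    half_hop = cfg.hop_s / 2
    for i0, i1 in _runs(voiced):
        t_start = max(0.0, times[i0] - half_hop)
        t_end = min(x.size / rate, times[i1 - 1] + half_hop)
        f0_run = f0_track[i0:i1]
        T = 1.0 / float(np.nanmedian(f0_run))
        a = int(t_start * rate)
        b = min(int((t_start + 1.5 * T) * rate), x.size)
        if b <= a:
            continue
        p = a + int(np.argmax(np.abs(x[a:b])))
        while True:
            pulses.append(p / rate)
            amps.append(abs(x[p]))
            # local period from the nearest frame's pitch
            j = int(np.clip(round((p / rate - times[0]) / cfg.hop_s), 0, voiced.size - 1))
            Tl = 1.0 / f0_track[j] if np.isfinite(f0_track[j]) else T
            a = p + int(0.7 * Tl * rate)
            b = p + int(1.3 * Tl * rate)
            if a / rate > t_end or a >= x.size:
                break
            b = min(b, x.size)
            if b <= a:
                break
            p = a + int(np.argmax(np.abs(x[a:b])))
            if p / rate > t_end:
                break
    return np.asarray(pulses), np.asarray(amps)


# ---------------------------------------------------------------------------
# periodicity family (F1-F10)
# ---------------------------------------------------------------------------

def periodicity_features(vm: VoicingMap, seg: Segment) -> dict[str, float]:
    """F1 unvoiced %, F2-F5 voiced-run and F6-F9 unvoiced-run duration
    statistics (mean/median/p15/p85, seconds), F10 voice-break %."""
    n = vm.voiced_flags.size
    out: dict[str, float] = {f"F{i}": float("nan") for i in range(1, 11)}
    if vm.pulses.size >= 2:
        gaps = np.diff(vm.pulses)
        out["F10"] = 100.0 * float(np.mean(gaps > VOICE_BREAK_THRESHOLD_S))
    if n == 0:
        return out
    out["F1"] = 100.0 * float(np.mean(~vm.voiced_flags))

    def run_stats(mask: np.ndarray) -> list[float]:
        durs = np.array([(b - a) * vm.hop_s for a, b in _runs(mask)])
        if durs.size == 0:
            return [float("nan")] * 4
        return [float(durs.mean()), float(np.median(durs)),
                float(np.percentile(durs, 15)), float(np.percentile(durs, 85))]

    for code, stat in zip(("F2", "F3", "F4", "F5"), run_stats(vm.voiced_flags)):
        out[code] = stat
    for code, stat in zip(("F6", "F7", "F8", "F9"), run_stats(~vm.voiced_flags)):
        out[code] = stat
    return out


def shimmer(vm: VoicingMap) -> float:
    """F11: local shimmer in percent — mean absolute difference of
    consecutive within-run pulse amplitudes over the mean amplitude.
    Pulse pairs separated by a voice break are excluded."""
    if vm.pulses.size < 3:
        return float("nan")
    gaps = np.diff(vm.pulses)
    ok = gaps <= VOICE_BREAK_THRESHOLD_S
    if not ok.any():
        return float("nan")
    diffs = np.abs(np.diff(vm.pulse_amplitudes))[ok]
    used = np.zeros(vm.pulses.size, dtype=bool)
    used[:-1] |= ok
    used[1:] |= ok
    mean_amp = float(vm.pulse_amplitudes[used].mean())
    if mean_amp <= 0:
        return float("nan")
    return 100.0 * float(diffs.mean()) / mean_amp


# ---------------------------------------------------------------------------
# syllabic family (F12-F18)
# ---------------------------------------------------------------------------

def detect_syllables(seg: Segment, vm: VoicingMap,
                     cfg: FeatureConfig | None = None) -> SyllableAnnotation:
    """Syllable nuclei as voiced intensity peaks above the silence threshold
    with at least ``min_dip_db`` prominence; pauses as low-intensity runs
    longer than 250 ms."""
    cfg = cfg or FeatureConfig()
    rms, times = _frame_rms(seg.samples, seg.rate, cfg.frame_s, cfg.hop_s)
    if rms.size == 0:
        return SyllableAnnotation(np.array([]), [(0.0, seg.duration)], 0.0)
    db = 20 * np.log10(np.maximum(rms, 1e-10))
    max_db = float(db.max())
    thr = max_db + cfg.silence_threshold_db

    # a segment with no voiced frames and a flat envelope is one long pause
    if not vm.voiced_flags.any() and max_db - float(np.median(db)) < 10.0:
        return SyllableAnnotation(np.array([]), [(0.0, seg.duration)], 0.0)

    speech = db > thr
    pause_intervals: list[tuple[float, float]] = []
    half = cfg.hop_s / 2
    for a, b in _runs(~speech):
        start = 0.0 if a == 0 else times[a] - half
        end = seg.duration if b == speech.size else times[b - 1] + half
        if end - start > cfg.min_pause_s:
            pause_intervals.append((start, end))
    phonation = seg.duration - sum(b - a for a, b in pause_intervals)

    peaks, _ = sps.find_peaks(db, height=thr, prominence=cfg.min_dip_db)
    # restrict to voiced frames (intensity grid matches the voicing grid)
    nv = min(vm.voiced_flags.size, db.size)
    peaks = peaks[peaks < nv]
    peaks = peaks[vm.voiced_flags[peaks]]
    nuclei = times[peaks]
    nuclei = np.array([t for t in nuclei
                       if not any(a <= t < b for a, b in pause_intervals)])

    spans: list[tuple[float, float]] = []
    below = db <= thr
    for k, p in enumerate(peaks):
        left = p
        while left > 0 and not below[left - 1]:
            if k > 0 and left - 1 <= peaks[k - 1]:
                # valley between adjacent nuclei
                lo = peaks[k - 1] + int(np.argmin(db[peaks[k - 1]:p + 1]))
                left = lo
                break
            left -= 1
        right = p
        while right < db.size - 1 and not below[right + 1]:
            if k < len(peaks) - 1 and right + 1 >= peaks[k + 1]:
                hi = p + int(np.argmin(db[p:peaks[k + 1] + 1]))
                right = hi
                break
            right += 1
        spans.append((times[left] - half, times[right] + half))
    return SyllableAnnotation(nuclei_times=nuclei,
                              pause_intervals=pause_intervals,
                              phonation_time=float(phonation),
                              syllable_spans=spans)


def syllabic_features(sa: SyllableAnnotation, seg: Segment) -> dict[str, float]:
    """F12 speech rate, F13 phonation %, F14 articulation rate, F15 mean
    intersyllabic pause (>250 ms nucleus gaps), F16 mean syllable duration,
    F17 pause count, F18 mean pause duration."""
    dur = seg.duration
    n = sa.nuclei_times.size
    out = {"F12": n / dur,
           "F13": 100.0 * sa.phonation_time / dur,
           "F14": n / sa.phonation_time if sa.phonation_time > 0 else float("nan"),
           "F17": float(len(sa.pause_intervals))}
    gaps = np.diff(sa.nuclei_times) if n > 1 else np.array([])
    long_gaps = gaps[gaps > 0.25]
    out["F15"] = float(long_gaps.mean()) if long_gaps.size else float("nan")
    if sa.syllable_spans:
        out["F16"] = float(np.mean([b - a for a, b in sa.syllable_spans]))
    else:
        out["F16"] = float("nan")
    if sa.pause_intervals:
        out["F18"] = float(np.mean([b - a for a, b in sa.pause_intervals]))
    else:
        out["F18"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# spectral family (F19-F23)
# ---------------------------------------------------------------------------

def _third_formant_track(seg: Segment, vm: VoicingMap,
                         cfg: FeatureConfig) -> np.ndarray:
    """Third-formant frequency per voiced frame via LPC root-finding at
    10 kHz (pre-emphasis, Hamming window, order-12 autocorrelation LPC)."""
    fs = cfg.formant_rate
    x = sps.resample_poly(seg.samples, fs, seg.rate)
    x = np.append(x[0], x[1:] - cfg.preemphasis * x[:-1])
    flen, hop = int(0.025 * fs), int(cfg.hop_s * fs)
    fr = _frames(x, flen, hop)
    if fr.shape[0] == 0:
        return np.array([])
    times = (np.arange(fr.shape[0]) * hop + flen / 2) / fs
    # frames whose center lies in a voiced frame of the 16 kHz analysis
    idx = np.clip(np.round((times - vm.frame_times[0]) / vm.hop_s).astype(int),
                  0, vm.voiced_flags.size - 1)
    fr = fr[vm.voiced_flags[idx]] * np.hamming(flen)
    order = cfg.lpc_order
    track = []
    for frame in fr:
        ac = np.correlate(frame, frame, mode="full")[flen - 1:flen + order]
        if ac[0] <= 0:
            continue
        try:
            a = solve_toeplitz((ac[:order], ac[:order]), ac[1:order + 1])
        except np.linalg.LinAlgError:
            continue
        roots = np.roots(np.concatenate([[1.0], -a]))
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs / (2 * np.pi)
        bw = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / np.pi
        formants = np.sort(freqs[(freqs > 90) & (freqs < fs / 2 - 100) & (bw < 400)])
        if formants.size >= 3:
            track.append(formants[2])
    return np.asarray(track)


def spectral_features(seg: Segment, vm: VoicingMap,
                      cfg: FeatureConfig | None = None) -> dict[str, float]:
    """F19/F20 pitch mean/SD, F21 third-formant SD, F22 temporal-regularity
    index of the intensity envelope, F23 spectral centroid."""
    cfg = cfg or FeatureConfig()
    out: dict[str, float] = {}
    f0 = vm.f0_track[np.isfinite(vm.f0_track)]
    out["F19"] = float(f0.mean()) if f0.size else float("nan")
    out["F20"] = float(f0.std(ddof=1)) if f0.size > 1 else float("nan")

    f3 = _third_formant_track(seg, vm, cfg)
    out["F21"] = float(f3.std(ddof=1)) if f3.size > 1 else float("nan")

    # temporal regularity: peak autocorrelation of the 50 Hz intensity
    # envelope over lags 0.1-1 s, on a fixed scale
    env_hop = 1.0 / cfg.envelope_rate
    rms, _ = _frame_rms(seg.samples, seg.rate, env_hop, env_hop)
    e = rms - rms.mean()
    lag_lo = int(round(cfg.regularity_lags_s[0] * cfg.envelope_rate))
    lag_hi = int(round(cfg.regularity_lags_s[1] * cfg.envelope_rate))
    denom = float(np.sum(e ** 2))
    if e.size > lag_hi and denom > 0:
        ac = np.array([np.dot(e[:-k], e[k:]) / denom
                       for k in range(lag_lo, lag_hi + 1)])
        out["F22"] = cfg.regularity_scale * float(max(ac.max(), 0.0))
    else:
        out["F22"] = float("nan")

    flen, hop = int(cfg.frame_s * seg.rate), int(cfg.hop_s * seg.rate)
    fr = _frames(seg.samples, flen, hop)
    if fr.shape[0]:
        mag = np.abs(np.fft.rfft(fr * np.hanning(flen), axis=1))
        freqs = np.fft.rfftfreq(flen, 1.0 / seg.rate)
        total = mag.sum()
        out["F23"] = float((mag * freqs).sum() / total) if total > 0 else float("nan")
    else:
        out["F23"] = float("nan")
    return out


def extract_all(seg: Segment, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """All 23 features of one segment as a ``{code: value}`` dict (NaN for
    features undefined on the segment)."""
    cfg = cfg or FeatureConfig()
    vm = detect_voicing(seg, cfg)
    out = periodicity_features(vm, seg)
    out["F11"] = shimmer(vm)
    sa = detect_syllables(seg, vm, cfg)
    out.update(syllabic_features(sa, seg))
    out.update(spectral_features(seg, vm, cfg))
    return {code: out[code] for code in FEATURE_CODES}
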