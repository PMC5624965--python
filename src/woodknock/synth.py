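"""Synthetic field observations with known ground truth.

The analyses in this package were motivated by field audio (drum rolls and
double knocks) and video (flap sequences at a known frame rate).  This
module generates controlled stand-ins for those observations:

* knock trains — impact times and amplitudes on a nominal grid with
  Gaussian timing jitter and per-knock amplitude decay;
* audio — each knock rendered as an exponentially decaying sinusoid (a
  minimal resonant-impact model) plus white noise, written as 16-bit WAV;
* onset detection — a moving-RMS envelope threshold detector that closes
  the generate -> render -> detect loop;
* flap sequences — per-flap (start_frame, end_frame) pairs for a bird with
  intermittent flight: each cycle is a flap of duration 1/f followed by a
  folded-wing pause, so that n flaps span n/(duty*f) seconds and the raw
  rate recovered by counting flaps over elapsed time is duty*f.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import wave as _wave
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .flight import DutyFraction, _duty_value
from .oscillator import ValidationError

__all__ = [
    "KnockPattern",
    "KnockTrain",
    "AudioRenderSpec",
    "FlapSequence",
    "generate_impact_train",
    "render_audio",
    "detect_onsets",
    "generate_flap_sequence",
    "estimate_raw_rate",
    "write_wav",
]


@dataclass(frozen=True)
class KnockPattern:
    """Ground-truth description of a knock train.

    ``double_knock``: two knocks ``inter_knock_interval_s`` apart, the
    second at ``amplitude_ratio`` times the first (the rebound is weaker).
    ``drum_roll``: ``n_knocks`` knocks spaced ``period_s`` apart with
    amplitude multiplied by ``amplitude_decay`` at each knock.  Knock times
    are perturbed by N(0, timing_jitter_sd_s**2) and re-sorted.

    Defaults are plausible large-woodpecker values (a ~0.1 s double-knock
    gap; a 12-knock roll at ~17 knocks/s), not measurements of any species.
    """

    kind: Literal["double_knock", "drum_roll"] = "double_knock"
    inter_knock_interval_s: float = 0.1
    amplitude_ratio: float = 0.8
    n_knocks: int = 12
    period_s: float = 0.06
    amplitude_decay: float = 0.95
    timing_jitter_sd_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("double_knock", "drum_roll"):
            raise ValidationError(f"unknown knock kind {self.kind!r}")
        if self.inter_knock_interval_s <= 0 or self.period_s <= 0:
            raise ValidationError("intervals and periods must be > 0")
        if not (0.0 < self.amplitude_ratio <= 1.0):
            raise ValidationError("amplitude_ratio must be in (0, 1]")
        if self.n_knocks < 1:
            raise ValidationError("n_knocks must be >= 1")
        if self.timing_jitter_sd_s < 0:
            raise ValidationError("timing_jitter_sd_s must be >= 0")


@dataclass(frozen=True)
class KnockTrain:
    """Knock times (s, sorted) and relative amplitudes."""

    times_s: np.ndarray
    amplitudes: np.ndarray

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class AudioRenderSpec:
    """How a knock train is turned into a waveform.

    Each knock rings at ``knock_ring_freq_hz`` with an exponential envelope
    of time constant ``knock_decay_s``; ``noise_rms`` sets the RMS of added
    Gaussian white noise relative to a unit-amplitude knock.
    """

    sample_rate_hz: int = 16000
    knock_ring_freq_hz: float = 1200.0
    knock_decay_s: float = 0.02
    noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz < 8000:
            raise ValidationError("sample_rate_hz must be >= 8000")
        if self.knock_decay_s <= 0:
            raise ValidationError("knock_decay_s must be > 0")
        if self.noise_rms < 0:
            raise ValidationError("noise_rms must be >= 0")


def generate_impact_train(pattern: KnockPattern) -> KnockTrain:
    """Knock times and amplitudes for a pattern, jittered and re-sorted."""
    if pattern.kind == "double_knock":
        nominal = np.array([0.0, pattern.inter_knock_interval_s])
        amps = np.array([1.0, pattern.amplitude_ratio])
    else:
        nominal = pattern.period_s * np.arange(pattern.n_knocks)
        amps = pattern.amplitude_decay ** np.arange(pattern.n_knocks)

    rng = np.random.default_rng(pattern.seed)
    times = nominal + rng.normal(0.0, pattern.timing_jitter_sd_s, size=len(nominal))
    order = np.argsort(times)
    times = times[order] - times[order][0]  # first knock at t = 0
    return KnockTrain(times_s=times, amplitudes=amps[order])


def render_audio(
    train: KnockTrain,
    spec: AudioRenderSpec = AudioRenderSpec(),
    duration_s: float | None = None,
) -> np.ndarray:
    """Render a knock train to a mono waveform, peak-normalized to <= 1.

    Each knock contributes a * exp(-(t - t_k)/decay) * sin(2*pi*f*(t - t_k))
    for t >= t_k; Gaussian noise of the requested RMS is added on top.
    """
    if len(train) == 0:
        raise ValidationError("cannot render an empty knock train")
    sr = spec.sample_rate_hz
    if duration_s is None:
        duration_s = float(train.times_s[-1]) + 8.0 * spec.knock_decay_s
    if np.any(train.times_s < 0) or np.any(train.times_s >= duration_s):
        raise ValidationError("knock times fall outside the audio buffer")

    n = int(round(duration_s * sr))
    t = np.arange(n) / sr
    wav = np.zeros(n)
    for tk, a in zip(train.times_s, train.amplitudes):
        tau = t - tk
        live = tau >= 0
        wav[live] += a * np.exp(-tau[live] / spec.knock_decay_s) * np.sin(
            2.0 * np.pi * spec.knock_ring_freq_hz * tau[live]
        )
    if spec.noise_rms > 0:
        rng = np.random.default_rng(spec.seed)
        wav += rng.normal(0.0, spec.noise_rms, size=n)
    peak = np.max(np.abs(wav))
    if peak > 1.0:
        wav /= peak
    return wav


def _moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def detect_onsets(
    waveform: np.ndarray,
    sample_rate: int,
    threshold_frac: float = 0.25,
    min_gap_s: float = 0.02,
    envelope_window_s: float = 0.005,
    release_frac: float = 0.5,
) -> np.ndarray:
    """Knock onset times from upward envelope-threshold crossings.

    The envelope is a moving RMS over ``envelope_window_s``; an onset is an
    upward crossing of ``threshold_frac`` times the envelope peak.  The
    detector uses hysteresis — after an onset it re-arms only once the
    envelope has fallen below ``release_frac`` of the threshold — so noise
    riding on a decaying knock tail cannot retrigger it; onsets closer than
    ``min_gap_s`` to the previous one are merged regardless.  Deterministic;
    silence yields no onsets.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValidationError("threshold_frac must be in (0, 1)")
    if min_gap_s <= 0:
        raise ValidationError("min_gap_s must be > 0")
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) == 0:
        return np.array([])

    window = max(1, int(round(envelope_window_s * sample_rate)))
    env = _moving_rms(waveform, window)
    peak = env.max()
    if peak == 0:
        return np.array([])
    trigger = threshold_frac * peak
    release = release_frac * trigger

    onsets: list[float] = []
    min_gap = min_gap_s * sample_rate
    armed = True
    for idx, value in enumerate(env):
        if armed and value >= trigger:
            armed = False
            if not onsets or idx - onsets[-1] * sample_rate >= min_gap:
                # the RMS window centred at the crossing straddles the attack;
                # shift back half a window toward the true onset
                onsets.append(max(idx - window / 2, 0) / sample_rate)
        elif not armed and value < release:
            armed = True
    return np.array(onsets)


@dataclass(frozen=True)
class FlapSequence:
    """Frame-indexed flap events with their generating ground truth.

    ``starts[k]``/``ends[k]`` are the frames at which flap k begins and the
    wings fold closed again; the pause until the next flap is implicit.
    ``total_span_frames`` is the exact (unrounded) duration of the n full
    cycles, n * fps / (duty * f).
    """

    starts: np.ndarray
    ends: np.ndarray
    fps: float
    true_f_hz: float
    duty: float
    total_span_frames: float

    def __len__(self) -> int:
        return len(self.starts)


def generate_flap_sequence(
    true_f_hz: float,
    duty: DutyFraction | float,
    fps: float = 60.0,
    n_flaps: int = 15,
    jitter_frames_sd: float = 0.0,
    seed: int = 0,
) -> FlapSequence:
    """Generate per-flap (start_frame, end_frame) events.

    Each cycle lasts 1/(duty*f) seconds: a flap of duration 1/f (the flap
    period proper) followed by a folded-wing pause of (1-duty)/(duty*f).
    Event frames are rounded from the nominal times after adding
    N(0, jitter_frames_sd**2) frame jitter, mimicking the uncertainty of
    judging wing motion frame-by-frame.
    """
    d = _duty_value(duty)
    if true_f_hz <= 0:
        raise ValidationError("true_f_hz must be > 0")
    if fps <= 2.0 * true_f_hz:
        raise ValidationError(
            f"fps = {fps} cannot resolve flaps at {true_f_hz} Hz (need fps > 2f)"
        )
    if n_flaps < 2:
        raise ValidationError("n_flaps must be >= 2")

    cycle_frames = fps / (d * true_f_hz)
    flap_frames = fps / true_f_hz
    rng = np.random.default_rng(seed)
    k = np.arange(n_flaps)
    starts = np.rint(k * cycle_frames + rng.normal(0, jitter_frames_sd, n_flaps)).astype(int)
    ends = np.rint(
        k * cycle_frames + flap_frames + rng.normal(0, jitter_frames_sd, n_flaps)
    ).astype(int)
    ends = np.maximum(ends, starts + 1)
    return FlapSequence(
        starts=starts,
        ends=ends,
        fps=fps,
        true_f_hz=true_f_hz,
        duty=d,
        total_span_frames=n_flaps * cycle_frames,
    )


def estimate_raw_rate(seq: FlapSequence) -> float:
    """Raw flap rate f~ (Hz) from a sequence: the mean cycle length is
    estimated from flap-start spacings, whose endpoint errors average out."""
    if len(seq) < 2:
        raise ValidationError("need at least two flaps to estimate a rate")
    span = seq.starts[-1] - seq.starts[0]
    if span <= 0:
        raise ValidationError("degenerate flap sequence: zero span")
    return (len(seq) - 1) * seq.fps / span


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a mono waveform in [-1, 1] as 16-bit PCM WAV."""
    pcm = np.clip(waveform, -1.0, 1.0)
    pcm = (pcm * 32767.0).astype("<i2")
    with _wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(pcm.tobytes())
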