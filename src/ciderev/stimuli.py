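"""Synthetic matrix-style sentences and the concatenation test protocol.

The listening material emulated here is a closed-set matrix sentence test:
every sentence is five short words (~1.8 s total).  The generator produces
speech-like pseudo-sentences - a harmonic voiced carrier with a slowly
drifting fundamental, per-word formant shaping, and a syllabic (2-8 Hz)
amplitude envelope - realistic enough that reverberation demonstrably
smears the temporal envelope and STOI responds, while making no claim to
being intelligible speech.

The processing protocol mirrors the study: each sentence is concatenated
five times, the whole concatenation is reverberated and processed, and the
fourth copy is extracted for presentation, guaranteeing the dereverberation
filter more than 4 s of initialisation and no edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.io import wavfile

from .dereverb import (PostFilterConfig, WpeConfig, late_reverb_postfilter,
                       oracle_psd, wpe_dereverb)
from .room import ImpulseResponse, estimate_rt60
from .spectral import StftConfig, analyze, synthesize

CONDITIONS = ("clean", "clean_wpe", "clean_wpepf",
              "reverb", "reverb_wpe", "reverb_wpepf")

REFERENCE_RMS_DB = -26.0  # dBFS; digital stand-in for the presentation level


@dataclass(frozen=True)
class PseudoSentence:
    samples: np.ndarray
    sample_rate: int
    seed: int

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class ProcessedTrial:
    condition: str
    audio: np.ndarray
    sample_rate: int
    rt60_used: float | None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        clean = self.condition.startswith("clean")
        if clean != (self.rt60_used is None):
            raise ValueError("rt60_used must be None iff condition is clean")


def _resonator(sig: np.ndarray, freq: float, bw: float, fs: int) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * freq / fs
    a = [1.0, -2 * r * np.cos(theta), r * r]
    b = [(1 - r * r) * np.sin(theta)]
    return scipy.signal.lfilter(b, a, sig)


def generate_pseudo_sentence(seed: int,
                             sample_rate: int = 16_000) -> PseudoSentence:
    """Deterministic speech-like pseudo-sentence of ~1.8 s.

    Five word-like bursts (some with two syllables) of a formant-filtered
    harmonic carrier; fundamental drifts within 100-140 Hz; a brief noise
    onset precedes some words as a consonant stand-in.  RMS is normalised
    to the reference level.
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate
    duration = 1.8 + rng.uniform(-0.08, 0.08)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # fundamental: smooth drift between two values in 100-140 Hz, plus
    # cycle-to-cycle jitter (an Ornstein-Uhlenbeck perturbation, ~2.5 %)
    # that decorrelates the harmonic phases across tens of milliseconds,
    # as natural voices do; without it the carrier is a sustained chord
    # that a linear predictor could cancel wholesale
    f0_a, f0_b = rng.uniform(100.0, 140.0, size=2)
    f0 = f0_a + (f0_b - f0_a) * (0.5 - 0.5 * np.cos(np.pi * t / duration))
    f0 = f0 * (1.0 + _ou_noise(rng, n, tau_s=0.02, sd=0.025, fs=fs))
    phase = 2 * np.pi * np.cumsum(f0) / fs
    carrier = np.zeros(n)
    n_harm = int(4000.0 / max(f0_a, f0_b))
    for k in range(1, n_harm + 1):
        carrier += np.cos(k * phase + rng.uniform(0, 2 * np.pi)) / k
    # shimmer: slow multiplicative amplitude fluctuation (~2 dB)
    carrier *= np.exp(_ou_noise(rng, n, tau_s=0.03, sd=0.25, fs=fs))

    # five word slots with gaps; each word 1-2 syllables
    gaps = rng.uniform(0.06, 0.13, size=6)
    word_len = (duration - gaps.sum()) * _dirichlet(rng, 5, 8.0)
    envelope = np.zeros(n)
    word_spans = []
    pos = gaps[0]
    for w in range(5):
        start, end = pos, pos + word_len[w]
        word_spans.append((start, end))
        n_syll = 1 + int(rng.random() < 0.5)
        edges = np.linspace(start, end, n_syll + 1)
        for s in range(n_syll):
            a, b = edges[s], edges[s + 1]
            i0, i1 = int(a * fs), min(int(b * fs), n)
            m = i1 - i0
            if m > 8:
                syl = np.sin(np.linspace(0, np.pi, m)) ** 2
                envelope[i0:i1] = np.maximum(envelope[i0:i1],
                                             syl * rng.uniform(0.6, 1.0))
        pos = end + gaps[w + 1]

    out = np.zeros(n)
    for (start, end) in word_spans:
        i0, i1 = int(start * fs), min(int(end * fs), n)
        seg = carrier[i0:i1]
        # diphthong-like glides: each formant moves across the word
        ranges = ((300, 800), (1000, 2200), (2400, 3200))
        bws = (80.0, 120.0, 160.0)
        shaped = np.zeros_like(seg)
        half = max(1, len(seg) // 2)
        for (lo, hi), bw in zip(ranges, bws):
            fa, fb = rng.uniform(lo, hi, size=2)
            shaped[:half] += _resonator(seg[:half], fa, bw, fs)
            shaped[half:] += _resonator(seg[half:], fb, bw, fs)
        out[i0:i1] += shaped
        if rng.random() < 0.5:  # unvoiced consonant onset
            m = min(int(0.05 * fs), i1 - i0)
            noise = rng.normal(size=m)
            noise = scipy.signal.lfilter([1, -0.95], [1], noise)
            out[i0:i0 + m] += 0.4 * noise * np.linspace(1, 0.2, m) * np.std(shaped[:m] + 1e-12)
    out *= envelope
    out = set_level(out, REFERENCE_RMS_DB)
    return PseudoSentence(out, fs, seed)


def _dirichlet(rng: np.random.Generator, k: int, conc: float) -> np.ndarray:
    g = rng.gamma(conc, size=k)
    return g / g.sum()


def _ou_noise(rng: np.random.Generator, n: int, tau_s: float, sd: float,
              fs: int) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise (one-pole low-passed white)."""
    a = np.exp(-1.0 / (tau_s * fs))
    w = rng.normal(scale=sd * np.sqrt(1 - a * a), size=n)
    return scipy.signal.lfilter([1.0], [1.0, -a], w,
                                zi=[rng.normal(scale=sd)])[0]


def set_level(audio: np.ndarray, target_rms_db: float) -> np.ndarray:
    """Scale to a target RMS in dB re full scale."""
    rms = np.sqrt(np.mean(np.square(audio)))
    if rms == 0.0:
        raise ValueError("cannot set the level of a silent signal")
    return audio * (10.0 ** (target_rms_db / 20.0) / rms)


def apply_protocol(sentence: PseudoSentence,
                   ir: ImpulseResponse | None,
                   processor: str = "none",
                   rt60: float | None = None,
                   wpe_config: WpeConfig | None = None,
                   pf_config: PostFilterConfig | None = None,
                   stft_config: StftConfig | None = None,
                   psd: str = "oracle") -> ProcessedTrial:
    """Concatenate x5, reverberate, process, and extract the fourth copy.

    The whole concatenation is convolved with the impulse response (tails
    flow across copy boundaries) and processed in one piece, then the
    segment aligned with the fourth copy (offset by the direct-path delay)
    is extracted, so the dereverberation filter sees >4 s of signal before
    the presented material and no end transients.
    """
    if processor not in ("none", "wpe", "wpepf"):
        raise ValueError(f"unknown processor {processor!r}")
    if psd not in ("oracle", "iterative"):
        raise ValueError(f"psd must be 'oracle' or 'iterative', got {psd!r}")
    x = sentence.samples
    n = len(x)
    concat = np.tile(x, 5)

    if ir is not None:
        if ir.sample_rate != sentence.sample_rate:
            raise ValueError("impulse response sample rate mismatch")
        wet = scipy.signal.fftconvolve(concat, ir.samples)
        delay = ir.direct_index
        rt60_used = rt60 if rt60 is not None else estimate_rt60(ir)
    else:
        wet = concat
        delay = 0
        rt60_used = None

    if processor == "none":
        seg = wet[3 * n + delay:4 * n + delay]
        cond = "clean" if ir is None else "reverb"
        return ProcessedTrial(cond, seg, sentence.sample_rate, rt60_used)

    cfg = stft_config or StftConfig(sample_rate=sentence.sample_rate)
    frames = analyze(wet, cfg)
    if psd == "oracle":
        ref = np.zeros_like(wet)
        ref[delay:delay + len(concat)] = concat
        lam = oracle_psd(analyze(ref, cfg))
    else:
        lam = None
    wcfg = wpe_config or WpeConfig()
    wpe_out = wpe_dereverb(frames, wcfg, lam)
    out_frames = wpe_out.frames
    if processor == "wpepf":
        pf = pf_config or PostFilterConfig(
            assumed_rt60=rt60_used if rt60_used is not None else 1.0)
        # the post-filter extrapolates the residual tail from what WPE
        # already removed (the reverberation-informed estimator)
        hop_s = cfg.hop / cfg.sample_rate
        removed = np.abs(frames.values - out_frames.values) ** 2
        span = (wcfg.delay * hop_s, (wcfg.delay + wcfg.order) * hop_s)
        out_frames = late_reverb_postfilter(out_frames, pf,
                                            reverb_psd=removed,
                                            reverb_span=span)
    y = synthesize(out_frames)
    seg = y[3 * n + delay:4 * n + delay]
    cond = ("clean_" if ir is None else "reverb_") + processor
    return ProcessedTrial(cond, seg, sentence.sample_rate, rt60_used)


def write_wav(path, audio: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, sample_rate, np.asarray(audio, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    return np.asarray(data, dtype=float), int(sr)
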