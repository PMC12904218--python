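"""Analysis/synthesis STFT shared by the dereverberation stages.

Defaults are a 32 ms square-root Hann window with an 8 ms hop at 16 kHz,
square-root windowing applied at both analysis and synthesis.  With one
frame of lookahead this keeps the algorithmic latency of the processing
chain at roughly 40 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.signal.windows import hann


@dataclass(frozen=True)
class StftConfig:
    window_length: int = 512
    hop: int = 128
    fft_size: int = 512
    window_kind: str = "sqrt_hann"
    sample_rate: int = 16_000

    def __post_init__(self):
        if self.hop > self.window_length:
            raise ValueError("hop must not exceed window_length")
        if self.fft_size < self.window_length:
            raise ValueError("fft_size must be >= window_length")
        if self.window_kind not in ("sqrt_hann", "hann"):
            raise ValueError(f"unknown window_kind {self.window_kind!r}")

    @property
    def window(self) -> np.ndarray:
        w = hann(self.window_length, sym=False)
        return np.sqrt(w) if self.window_kind == "sqrt_hann" else w

    @property
    def synthesis_window(self) -> np.ndarray:
        # sqrt window on both sides; plain hann pairs with a rectangular
        # synthesis window (scaled in synthesize by the COLA denominator).
        w = self.window
        return w if self.window_kind == "sqrt_hann" else np.ones_like(w)

    @property
    def n_bins(self) -> int:
        return self.fft_size // 2 + 1


@dataclass(frozen=True)
class SpectralFrames:
    """Complex time-frequency matrix, shape [frames x bins]."""

    values: np.ndarray
    config: StftConfig
    original_length: int

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != self.config.n_bins:
            raise ValueError(
                f"values must be [frames x {self.config.n_bins}], "
                f"got {self.values.shape}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "SpectralFrames":
        return SpectralFrames(values, self.config, self.original_length)


def analyze(signal: np.ndarray, config: StftConfig | None = None) -> SpectralFrames:
    """Windowed overlapping frames, forward real FFT per frame.

    The signal is zero-padded by one window on each side so that every
    original sample receives full overlap-add coverage; `synthesize`
    undoes the padding exactly.
    """
    config = config or StftConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < config.window_length:
        raise ValueError(
            f"signal length {len(x)} shorter than window {config.window_length}")
    pad = config.window_length
    xp = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n_frames = 1 + (len(xp) - config.window_length) // config.hop
    idx = (np.arange(config.window_length)[None, :]
           + config.hop * np.arange(n_frames)[:, None])
    frames = xp[idx] * config.window[None, :]
    return SpectralFrames(rfft(frames, n=config.fft_size, axis=1),
                          config, len(x))


def synthesize(frames: SpectralFrames) -> np.ndarray:
    """Weighted overlap-add inverse returning ``original_length`` samples."""
    config = frames.config
    wl, hop = config.window_length, config.hop
    t = irfft(frames.values, n=config.fft_size, axis=1)[:, :wl]
    t = t * config.synthesis_window[None, :]
    n_out = wl + hop * (frames.n_frames - 1)
    y = np.zeros(n_out)
    norm = np.zeros(n_out)
    wsq = config.window * config.synthesis_window
    for m in range(frames.n_frames):
        y[m * hop:m * hop + wl] += t[m]
        norm[m * hop:m * hop + wl] += wsq
    good = norm > 1e-10
    y[good] /= norm[good]
    pad = wl
    if pad + frames.original_length > n_out:
        raise ValueError("frames inconsistent with original_length")
    return y[pad:pad + frames.original_length]
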