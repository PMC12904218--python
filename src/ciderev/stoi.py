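"""Short-time objective intelligibility (STOI).

STOI predicts speech intelligibility from the average correlation between
the short-time one-third-octave band envelopes of a clean and a degraded
signal.  Because cochlear implants transmit exactly these slow band
envelopes, STOI is a natural objective proxy for CI speech intelligibility.

Internal constants follow the published method: 10 kHz working rate, 15
one-third-octave bands from 150 Hz, 25.6 ms Hann frames with 50 % overlap,
384 ms (30-frame) analysis segments, a -15 dB signal-to-distortion clipping
bound, and removal of frames more than 40 dB below the loudest clean frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft
from scipy.signal import resample_poly

FS = 10_000            # internal sample rate, Hz
FRAME_LEN = 256        # 25.6 ms
HOP = 128
NFFT = 512
N_BANDS = 15
MIN_FREQ = 150.0       # centre frequency of the lowest band, Hz
SEG_FRAMES = 30        # 384 ms
BETA_DB = -15.0        # clipping bound (signal-to-distortion ratio)
DYN_RANGE_DB = 40.0    # silent-frame threshold below the loudest frame
_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class StoiResult:
    value: float
    n_frames_used: int


@dataclass(frozen=True)
class BatchStoiResult:
    values: np.ndarray
    mean: float
    sd: float


def third_octave_band_matrix(fs: int = FS, nfft: int = NFFT,
                             n_bands: int = N_BANDS,
                             min_freq: float = MIN_FREQ):
    """Boolean matrix [bands x bins] collecting DFT bins per 1/3-octave band."""
    f = np.linspace(0, fs, nfft + 1)[:nfft // 2 + 1]
    k = np.arange(n_bands, dtype=float)
    cf = min_freq * 2.0 ** (k / 3.0)
    f_lo = min_freq * 2.0 ** ((2 * k - 1) / 6.0)
    f_hi = min_freq * 2.0 ** ((2 * k + 1) / 6.0)
    obm = np.zeros((n_bands, len(f)))
    for i in range(n_bands):
        lo = int(np.argmin(np.square(f - f_lo[i])))
        hi = int(np.argmin(np.square(f - f_hi[i])))
        obm[i, lo:hi] = 1.0
    return obm, cf


def _frame(x: np.ndarray, window: np.ndarray) -> np.ndarray:
    n = 1 + (len(x) - FRAME_LEN) // HOP
    idx = np.arange(FRAME_LEN)[None, :] + HOP * np.arange(n)[:, None]
    return x[idx] * window[None, :]


def _remove_silent_frames(x: np.ndarray, y: np.ndarray, window: np.ndarray):
    xf = _frame(x, window)
    yf = _frame(y, window)
    energies = 20.0 * np.log10(np.linalg.norm(xf, axis=1) + _EPS)
    keep = energies > energies.max() - DYN_RANGE_DB
    xf, yf = xf[keep], yf[keep]
    # overlap-add back to waveforms (Hann at 50% overlap sums to one)
    n_out = FRAME_LEN + HOP * (len(xf) - 1) if len(xf) else 0
    xs, ys = np.zeros(n_out), np.zeros(n_out)
    for m in range(len(xf)):
        xs[m * HOP:m * HOP + FRAME_LEN] += xf[m]
        ys[m * HOP:m * HOP + FRAME_LEN] += yf[m]
    return xs, ys, int(keep.sum())


def compute_stoi(clean: np.ndarray, degraded: np.ndarray,
                 sample_rate: int) -> StoiResult:
    """STOI of ``degraded`` against the ``clean`` reference.

    Inputs must be time-aligned and of equal length.  Identical inputs
    give 1; the score is invariant to a positive gain on either signal.
    """
    clean = np.asarray(clean, dtype=float)
    degraded = np.asarray(degraded, dtype=float)
    if clean.shape != degraded.shape:
        raise ValueError(
            f"length mismatch: clean {clean.shape}, degraded {degraded.shape}")
    if sample_rate != FS:
        g = np.gcd(int(sample_rate), FS)
        clean = resample_poly(clean, FS // g, sample_rate // g)
        degraded = resample_poly(degraded, FS // g, sample_rate // g)
    if not np.any(clean):
        raise ValueError("clean reference is all zero")

    window = np.hanning(FRAME_LEN + 2)[1:-1]
    if len(clean) < FRAME_LEN:
        raise ValueError("signal shorter than one analysis frame")
    x, y, n_used = _remove_silent_frames(clean, degraded, window)
    if len(x) < FRAME_LEN + HOP * (SEG_FRAMES - 1):
        raise ValueError(
            f"only {n_used} frames above the silence threshold; need at "
            f"least {SEG_FRAMES} for one 384 ms segment")

    obm, _ = third_octave_band_matrix()
    X = np.abs(rfft(_frame(x, window), n=NFFT, axis=1)) ** 2
    Y = np.abs(rfft(_frame(y, window), n=NFFT, axis=1)) ** 2
    x_tob = np.sqrt(obm @ X.T)  # [bands x frames]
    y_tob = np.sqrt(obm @ Y.T)

    M = x_tob.shape[1]
    clip = 10.0 ** (-BETA_DB / 20.0)
    d_sum, count = 0.0, 0
    for m in range(SEG_FRAMES, M + 1):
        xs = x_tob[:, m - SEG_FRAMES:m]
        ys = y_tob[:, m - SEG_FRAMES:m]
        alpha = (np.linalg.norm(xs, axis=1, keepdims=True)
                 / (np.linalg.norm(ys, axis=1, keepdims=True) + _EPS))
        yp = np.minimum(ys * alpha, xs * (1.0 + clip))
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = yp - yp.mean(axis=1, keepdims=True)
        num = np.sum(xc * yc, axis=1)
        den = (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1) + _EPS)
        d_sum += float(np.sum(num / den))
        count += xs.shape[0]
    return StoiResult(d_sum / count, n_used)


def batch_stoi(clean_set, degraded_set, sample_rate: int) -> BatchStoiResult:
    """Per-sentence STOI for matched lists, with mean and SD."""
    clean_set = list(clean_set)
    degraded_set = list(degraded_set)
    if not clean_set:
        raise ValueError("empty sentence set")
    if len(clean_set) != len(degraded_set):
        raise ValueError("clean and degraded sets differ in length")
    values = np.array([
        compute_stoi(c, d, sample_rate).value
        for c, d in zip(clean_set, degraded_set)
    ])
    return BatchStoiResult(values, float(values.mean()),
                           float(values.std(ddof=1)) if len(values) > 1 else 0.0)
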