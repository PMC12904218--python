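"""WPE dereverberation and a late-reverberation Wiener post-filter.

Reverberation in the short-time spectral domain is modelled per frequency
bin as an autoregressive process: the reverberant tail at frame ``t`` is a
linear combination of earlier frames, and the desired speech is the
prediction error of a delayed linear predictor (weighted prediction error,
WPE).  The prediction weights are the inverse desired-speech PSD, supplied
either by an oracle (the clean signal, standing in for a trained PSD
estimator) or by alternating PSD/filter re-estimation.

The optional post-filter attacks the residual late tail with a spectral
gain derived from an exponential-decay model of late reverberation,
producing the "WPEPF" variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .spectral import SpectralFrames


@dataclass(frozen=True)
class WpeConfig:
    """Prediction geometry and numerics of the WPE stage.

    ``delay`` is in frames.  The default of 4 frames (32 ms at the default
    8 ms hop) skips the span over which successive analysis windows share
    samples: with a 32 ms window and 75 % overlap, frames closer than 4
    hops are deterministically correlated even for anechoic input, and a
    smaller delay would let the predictor cancel clean speech.  ``order``
    is the number of past frames used (default 12, covering a further
    ~100 ms of tail); the residual tail beyond the prediction span is the
    post-filter's job, which is the division of labour that
    distinguishes the WPE and WPEPF variants.

    ``psd_floor`` bounds the spread of the least-squares weights
    (``1/psd``): a near-zero floor lets silent gaps dominate the fit,
    which maximises gap suppression but lets the filter distort
    speech-carrying frames; 3 % of the per-bin mean power balances the
    two.
    """

    delay: int = 4
    order: int = 12
    iterations: int = 3
    psd_floor: float = 0.03      # relative to the mean PSD per bin
    regularization: float = 1e-6  # relative diagonal load on the normal eqs

    def __post_init__(self):
        if self.delay < 1 or self.order < 1 or self.iterations < 1:
            raise ValueError("delay, order and iterations must be >= 1")
        if self.psd_floor <= 0:
            raise ValueError("psd_floor must be positive")


@dataclass(frozen=True)
class PsdEstimate:
    """Desired-speech power per frame and bin (the WPE weights' inverse)."""

    values: np.ndarray

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("PSD must be nonnegative")


@dataclass(frozen=True)
class WpeFilter:
    coefficients: np.ndarray  # [bins x order], complex


@dataclass(frozen=True)
class WpeResult:
    frames: SpectralFrames
    filter: WpeFilter
    #: weighted log-likelihood objective per iteration (non-increasing)
    objective: np.ndarray


def oracle_psd(clean_frames: SpectralFrames,
               floor: float = 1e-6) -> PsdEstimate:
    """Desired-speech PSD from the clean reference: ``|clean|^2``, floored.

    This is the idealised stand-in for a learned PSD estimator, available
    in simulation where the clean signal is known.  The floor is relative
    to the mean power so an all-zero reference yields an all-floor PSD.
    """
    lam = np.abs(clean_frames.values) ** 2
    mean = lam.mean()
    if mean == 0.0:
        mean = 1.0
    return PsdEstimate(np.maximum(lam, floor * mean))


def _delayed_stack(values: np.ndarray, delay: int, order: int) -> np.ndarray:
    """[T x F] -> [F x T x L] stack of frames t-delay .. t-delay-order+1."""
    T, F = values.shape
    stack = np.zeros((F, T, order), dtype=values.dtype)
    for l in range(order):
        tau = delay + l
        stack[:, tau:, l] = values[:T - tau].T
    return stack


def wpe_dereverb(frames: SpectralFrames, config: WpeConfig | None = None,
                 psd: PsdEstimate | None = None) -> WpeResult:
    """Delayed linear prediction per frequency bin.

    ``output_t = x_t - sum_l g_l x_{t-delay-l}`` with ``g`` the weighted
    least-squares solution, weights ``1 / max(psd_t, floor)``.  When
    ``psd`` is None the PSD is estimated iteratively from the output power
    (``config.iterations`` rounds); a supplied PSD is used in a single
    pass.  Singular normal equations are handled by a relative diagonal
    load, never by raising.
    """
    config = config or WpeConfig()
    X = frames.values  # [T x F]
    T, F = X.shape
    if T <= config.delay + config.order:
        raise ValueError(
            f"need more than delay+order = {config.delay + config.order} "
            f"frames, got {T}")

    if psd is not None:
        if psd.values.shape != X.shape:
            raise ValueError(
                f"PSD shape {psd.values.shape} does not match frames {X.shape}")
        lam = psd.values
        n_iter = 1
    else:
        lam = np.abs(X) ** 2
        n_iter = config.iterations

    stack = _delayed_stack(X, config.delay, config.order)  # [F x T x L]
    Xf = X.T  # [F x T]
    eye = np.eye(config.order)
    out = Xf
    objective = []
    for _ in range(n_iter):
        mean_lam = lam.mean(axis=0, keepdims=True)  # per-bin mean power
        mean_lam = np.where(mean_lam > 0, mean_lam, 1.0)
        w = 1.0 / np.maximum(lam, config.psd_floor * mean_lam)  # [T x F]
        wf = w.T  # [F x T]
        ws = stack * wf[:, :, None]  # weighted copy, [F x T x L]
        A = np.swapaxes(stack, 1, 2).conj() @ ws
        b = np.einsum("ftl,ft->fl", ws.conj(), Xf, optimize=True)
        trace = np.trace(A, axis1=1, axis2=2).real
        dead = trace <= 0.0  # bins with no past energy: nothing to predict
        load = (config.regularization * trace / config.order)
        load[dead] = 1.0
        g = np.linalg.solve(A + load[:, None, None] * eye[None],
                            b[..., None])[..., 0]  # [F x L]
        g[dead] = 0.0
        out = Xf - np.einsum("ftl,fl->ft", stack, g, optimize=True)
        lam_used = np.maximum(lam, config.psd_floor * mean_lam)
        objective.append(
            float(np.mean(np.log(lam_used) + (np.abs(out.T) ** 2) / lam_used)))
        if psd is None:
            lam = np.abs(out.T) ** 2
    return WpeResult(frames.with_values(out.T.copy()), WpeFilter(g),
                     np.asarray(objective))


@dataclass(frozen=True)
class PostFilterConfig:
    """Exponential-decay late-reverberation suppressor.

    ``assumed_rt60`` sets the decay constant ``delta = 3 ln10 / RT60`` of
    the late-tail model; ``late_delay`` (seconds) is the direct-plus-early
    span protected from suppression; ``gain_floor`` (dB, negative) limits
    musical noise.  ``smoothing`` is the one-pole constant for the power
    estimates (per frame); ``freq_smooth_bins`` smooths the gain across
    neighbouring frequency bins to tame isolated gain dips.
    """

    assumed_rt60: float = 1.0
    late_delay: float = 0.1
    gain_floor: float = -12.0
    smoothing: float = 0.7
    freq_smooth_bins: int = 5

    def __post_init__(self):
        if self.assumed_rt60 <= 0:
            raise ValueError("assumed_rt60 must be positive")
        if self.late_delay <= 0:
            raise ValueError("late_delay must be positive")
        if self.gain_floor >= 0:
            raise ValueError("gain_floor must be negative (dB)")


def _smooth(power: np.ndarray, alpha: float) -> np.ndarray:
    out = np.empty_like(power)
    acc = power[0]
    for t in range(power.shape[0]):
        acc = alpha * acc + (1.0 - alpha) * power[t]
        out[t] = acc
    return out


def late_reverb_postfilter(frames: SpectralFrames,
                           config: PostFilterConfig | None = None,
                           reverb_psd: np.ndarray | None = None,
                           reverb_span: tuple[float, float] | None = None
                           ) -> SpectralFrames:
    """Wiener-style suppression of the residual late-reverberation tail.

    The late tail is modelled as an exponential decay with constant
    ``delta = 3 ln10 / assumed_rt60``; the Wiener gain
    ``max(phi - phi_late, 0) / phi`` is floored at ``gain_floor`` and
    applied multiplicatively, so all gains lie in ``[floor, 1]``.

    Two estimators for the late-tail PSD ``phi_late`` are available:

    * observation-driven (default): the decay model applied to the
      input's own smoothed power,
      ``phi_late(t) = exp(-2 delta D_s) * phi(t - D)`` with ``D`` the
      late delay in frames.
    * reverberation-informed: when ``reverb_psd`` - the power of the
      reverberant component already removed upstream (e.g. the part a WPE
      stage subtracted) - and its lag span ``reverb_span=(t0, t1)``
      seconds are given, the residual tail beyond ``t1`` is extrapolated
      from the decay model:
      ``phi_late = exp(-2 d t1) / (exp(-2 d t0) - exp(-2 d t1)) *
      smooth(reverb_psd)``.  On anechoic input the upstream stage removes
      essentially nothing, so the gains stay near one and clean speech
      passes through - something the observation-driven variant cannot
      guarantee, as it cannot tell a decaying vowel from a reverberant
      tail.
    """
    config = config or PostFilterConfig()
    delta = 3.0 * np.log(10.0) / config.assumed_rt60
    power = np.abs(frames.values) ** 2
    phi = _smooth(power, config.smoothing)

    if reverb_psd is not None:
        if reverb_psd.shape != power.shape:
            raise ValueError("reverb_psd shape does not match frames")
        if reverb_span is None:
            raise ValueError("reverb_span required with reverb_psd")
        t0, t1 = reverb_span
        if not 0 <= t0 < t1:
            raise ValueError("reverb_span must satisfy 0 <= t0 < t1")
        ratio = (np.exp(-2 * delta * t1)
                 / (np.exp(-2 * delta * t0) - np.exp(-2 * delta * t1)))
        phi_late = ratio * _smooth(reverb_psd, config.smoothing)
    else:
        hop_s = frames.config.hop / frames.config.sample_rate
        D = max(1, int(round(config.late_delay / hop_s)))
        atten = np.exp(-2.0 * delta * config.late_delay)
        phi_late = np.zeros_like(phi)
        phi_late[D:] = atten * phi[:-D]

    floor = 10.0 ** (config.gain_floor / 20.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(phi > 0, np.maximum(phi - phi_late, 0.0) / phi, 1.0)
    nb = config.freq_smooth_bins
    if nb > 1:
        k = np.hanning(nb + 2)[1:-1]
        k /= k.sum()
        gain = scipy.signal.convolve2d(gain, k[None, :], mode="same",
                                       boundary="symm")
    gain = np.clip(gain, floor, 1.0)
    return frames.with_values(frames.values * gain)
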