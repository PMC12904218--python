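"""Shoebox room acoustics: image-source impulse responses, RT60 and DRR.

The virtual listening room used throughout this package is a rectangular
("shoebox") room with uniform, frequency-independent wall absorption.  A
spherical head (radius 16 cm by default) is placed inside the room and each
ear is modelled as an ideal point receiver on the sphere surface; scattering,
diffraction and source/receiver directivity are deliberately not modelled.

Reverberation severity is controlled through the reverberation time RT60,
mapped to a uniform pressure reflection coefficient ``r`` of all six surfaces
via Eyring's formula with absorption ``alpha = 1 - r**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

SPEED_OF_SOUND = 343.0  # m/s, dry air at ~20 degC
DEFAULT_SAMPLE_RATE = 16_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoomSpec:
    """Geometry and acoustics of one simulated listening configuration.

    All positions are in metres in room coordinates: the room occupies
    ``[0, length] x [0, width] x [0, height]``.  ``reflection_coefficient``
    is the pressure reflection magnitude shared by all six surfaces and must
    lie in ``[0, 1)``.  ``ir_length_s`` truncates the simulated impulse
    response; with an exponential decay, 1.5 x RT60 leaves well under 0.1 %
    of the total energy beyond the truncation point.
    """

    length: float
    width: float
    height: float
    source_position: np.ndarray
    head_center: np.ndarray
    reflection_coefficient: float
    head_radius: float = 0.16
    sample_rate: int = DEFAULT_SAMPLE_RATE
    ir_length_s: float = 1.5

    def __post_init__(self):
        object.__setattr__(self, "source_position",
                           np.asarray(self.source_position, dtype=float))
        object.__setattr__(self, "head_center",
                           np.asarray(self.head_center, dtype=float))
        if not (0.0 <= self.reflection_coefficient < 1.0):
            raise ValueError("reflection_coefficient must be in [0, 1)")
        dims = np.array([self.length, self.width, self.height])
        if np.any(dims <= 0):
            raise ValueError("room dimensions must be positive")
        for name, p in (("source", self.source_position),
                        ("head center", self.head_center)):
            if np.any(p <= 0) or np.any(p >= dims):
                raise ValueError(f"{name} position {p} not strictly inside room")

    @property
    def source_distance(self) -> float:
        """Euclidean source to head-centre distance in metres."""
        return float(np.linalg.norm(self.source_position - self.head_center))

    def ear_position(self, ear: str) -> np.ndarray:
        """Point-receiver position of one ear on the sphere surface.

        Ears sit at ``head_center +/- head_radius`` along the horizontal
        direction perpendicular to the source->head axis (left ear on the
        +90 degree side looking from the head towards the source).
        """
        v = self.source_position - self.head_center
        perp = np.array([-v[1], v[0], 0.0])
        n = np.linalg.norm(perp)
        if n == 0.0:  # source directly above/below: pick the y axis
            perp, n = np.array([0.0, 1.0, 0.0]), 1.0
        perp = perp / n
        if ear == "left":
            return self.head_center + self.head_radius * perp
        if ear == "right":
            return self.head_center - self.head_radius * perp
        raise ValueError(f"ear must be 'left' or 'right', got {ear!r}")


@dataclass(frozen=True)
class ImpulseResponse:
    samples: np.ndarray
    sample_rate: int
    direct_index: int

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("impulse response contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class RirMetrics:
    rt60: float
    drr: float


# ---------------------------------------------------------------------------
# Eyring / Sabine reverberation-time model
# ---------------------------------------------------------------------------

def _surface_volume(room_dims) -> tuple[float, float]:
    L, W, H = room_dims
    return 2.0 * (L * W + L * H + W * H), L * W * H


def eyring_rt60(room_dims, reflection_coefficient: float) -> float:
    """Eyring RT60 prediction for uniform absorption alpha = 1 - r^2."""
    S, V = _surface_volume(room_dims)
    alpha = 1.0 - reflection_coefficient**2
    if alpha <= 0.0:
        return np.inf
    return (24.0 * np.log(10.0) / SPEED_OF_SOUND) * V / (-S * np.log1p(-alpha))


def sabine_rt60(room_dims, absorption: float) -> float:
    """Sabine RT60; accurate only for small absorption (live rooms)."""
    S, V = _surface_volume(room_dims)
    return (24.0 * np.log(10.0) / SPEED_OF_SOUND) * V / (S * absorption)


def reflection_coefficient_for_rt60(room_dims, rt60_target: float) -> float:
    """Invert Eyring's formula for the uniform surface reflection coefficient.

    Returns ``r`` in (0, 1) such that ``eyring_rt60(room_dims, r)`` equals
    ``rt60_target``.  The map is monotone: longer RT60 -> larger ``r``.
    """
    if rt60_target <= 0:
        raise ValueError("rt60_target must be positive")
    S, V = _surface_volume(room_dims)
    if np.any(np.asarray(room_dims) <= 0):
        raise ValueError("room dimensions must be positive")
    # Eyring: RT60 = K*V / (-S*ln(1-alpha))  =>  alpha = 1 - exp(-K*V/(S*RT60))
    exponent = (24.0 * np.log(10.0) / SPEED_OF_SOUND) * V / (S * rt60_target)
    alpha = -np.expm1(-exponent)
    if alpha >= 1.0:
        raise ValueError(
            f"rt60_target={rt60_target} s is unattainable: would require "
            f"absorption alpha >= 1 in a {room_dims} room")
    return float(np.sqrt(1.0 - alpha))


# ---------------------------------------------------------------------------
# image-source simulation
# ---------------------------------------------------------------------------

def _axis_images(src: float, rec: float, room_len: float, d_max: float):
    """Image coordinates and reflection counts along one axis.

    Images of a source at ``s`` in ``[0, L]`` lie at ``2*m*L + s`` (``2|m|``
    reflections) and ``2*m*L - s`` (``|2m - 1|`` reflections).
    """
    m_hi = int(np.ceil((rec + d_max) / (2 * room_len))) + 1
    m_lo = int(np.floor((rec - d_max) / (2 * room_len))) - 1
    m = np.arange(m_lo, m_hi + 1)
    coords = np.concatenate([2 * m * room_len + src, 2 * m * room_len - src])
    counts = np.concatenate([2 * np.abs(m), np.abs(2 * m - 1)])
    keep = np.abs(coords - rec) <= d_max
    return coords[keep], counts[keep]


def simulate_rir(spec: RoomSpec, ear: str = "left",
                 highpass_hz: float | None = 100.0) -> ImpulseResponse:
    """Image-source impulse response at one ear of the spherical head.

    Specular reflections only; each image contributes an impulse of
    amplitude ``r**n / d`` (``n`` reflections, distance ``d``) at the
    nearest sample to ``d / c``.  The response is truncated at
    ``spec.ir_length_s``.

    Reverberant responses are high-pass filtered (second-order Butterworth,
    default 100 Hz): with all-positive reflection amplitudes the
    image-source model accumulates a non-physical low-frequency pedestal
    that would otherwise dominate the tail energy.  Anechoic responses
    (``reflection_coefficient == 0``) are returned unfiltered.
    """
    rec = spec.ear_position(ear)
    fs, c = spec.sample_rate, SPEED_OF_SOUND
    d_max = c * spec.ir_length_s
    n_samples = int(round(spec.ir_length_s * fs)) + 1
    h = np.zeros(n_samples)

    cx, nx = _axis_images(spec.source_position[0], rec[0], spec.length, d_max)
    cy, ny = _axis_images(spec.source_position[1], rec[1], spec.width, d_max)
    cz, nz = _axis_images(spec.source_position[2], rec[2], spec.height, d_max)

    dy2 = (cy - rec[1])[:, None] ** 2 + ((cz - rec[2])[None, :]) ** 2  # (ny, nz)
    nyz = ny[:, None] + nz[None, :]
    r = spec.reflection_coefficient

    chunk = max(1, int(4e6 // dy2.size))
    for i0 in range(0, len(cx), chunk):
        sl = slice(i0, i0 + chunk)
        dist = np.sqrt((cx[sl] - rec[0])[:, None, None] ** 2 + dy2[None, :, :])
        mask = dist <= d_max
        order = nx[sl][:, None, None] + nyz[None, :, :]
        amp = np.where(mask, r ** order / np.maximum(dist, 1e-9), 0.0)
        idx = np.minimum(np.rint(dist / c * fs).astype(np.int64), n_samples - 1)
        np.add.at(h, idx[mask], amp[mask])

    if highpass_hz is not None and spec.reflection_coefficient > 0.0:
        sos = scipy.signal.butter(2, highpass_hz, "highpass", fs=fs, output="sos")
        h = scipy.signal.sosfilt(sos, h)

    direct_dist = float(np.linalg.norm(spec.source_position - rec))
    return ImpulseResponse(h, fs, int(round(direct_dist / c * fs)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def schroeder_decay_db(ir: ImpulseResponse) -> np.ndarray:
    """Backward-integrated (Schroeder) energy decay curve in dB re total."""
    energy = ir.samples**2
    edc = np.cumsum(energy[::-1])[::-1]
    total = edc[0]
    if total == 0:
        raise ValueError("impulse response has zero energy")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(edc / total)


def estimate_rt60(ir: ImpulseResponse) -> float:
    """RT60 from the Schroeder decay curve, T30 convention.

    A line is fitted by least squares to the decay curve between -5 and
    -35 dB; RT60 is twice the fitted 30 dB decay time (equivalently
    ``-60 / slope``).  Raises if the curve does not span 35 dB or the
    response is not decaying.
    """
    n = len(ir.samples)
    half = n // 2
    e_first, e_second = np.sum(ir.samples[:half] ** 2), np.sum(ir.samples[half:] ** 2)
    if e_second > e_first:
        raise ValueError("impulse response energy is not decaying over time")
    db = schroeder_decay_db(ir)
    below5 = np.nonzero(db <= -5.0)[0]
    below35 = np.nonzero(db <= -35.0)[0]
    if len(below35) == 0 or len(below5) == 0:
        achieved = float(db[np.isfinite(db)].min(initial=0.0))
        raise ValueError(
            f"decay range insufficient for T30: curve reaches {achieved:.1f} dB, "
            "need -35 dB")
    i5, i35 = below5[0], below35[0]
    t = np.arange(i5, i35 + 1) / ir.sample_rate
    slope, _ = np.polyfit(t, db[i5:i35 + 1], 1)
    if slope >= 0:
        raise ValueError("non-negative decay slope; response is not decaying")
    return float(-60.0 / slope)


def compute_drr(ir: ImpulseResponse, direct_window: float = 0.0025) -> float:
    """Direct-to-reverberant ratio in dB.

    Direct energy is integrated over ``direct_index +/- direct_window``
    (half-width, seconds; default 2.5 ms); everything after that window
    counts as reverberant.  Returns ``+inf`` when the tail carries no
    energy (anechoic response).
    """
    w = int(round(direct_window * ir.sample_rate))
    lo = max(0, ir.direct_index - w)
    hi = min(len(ir.samples), ir.direct_index + w + 1)
    e_direct = float(np.sum(ir.samples[lo:hi] ** 2))
    e_tail = float(np.sum(ir.samples[hi:] ** 2))
    if e_tail == 0.0:
        return np.inf
    if e_direct == 0.0:
        return -np.inf
    return 10.0 * np.log10(e_direct / e_tail)


def rir_metrics(ir: ImpulseResponse, direct_window: float = 0.0025) -> RirMetrics:
    return RirMetrics(rt60=estimate_rt60(ir), drr=compute_drr(ir, direct_window))


# ---------------------------------------------------------------------------
# the study's virtual room
# ---------------------------------------------------------------------------

#: Dimensions (m) of the virtual listening room used throughout the study.
STUDY_ROOM_DIMS = (7.0, 6.0, 3.5)
#: Source to head-centre distance (m).
STUDY_DISTANCE = 1.9
#: Source (talker mouth) and head-centre (seated listener) heights, m.
SOURCE_HEIGHT = 1.5
HEAD_HEIGHT = 1.3


def _study_geometry(r: float, rt60: float, sample_rate: int,
                    ir_length_s: float | None) -> RoomSpec:
    L, W, H = STUDY_ROOM_DIMS
    dz = SOURCE_HEIGHT - HEAD_HEIGHT
    dx = np.sqrt(STUDY_DISTANCE**2 - dz**2)
    return RoomSpec(
        length=L, width=W, height=H,
        source_position=np.array([L / 2 - dx / 2, W / 2, SOURCE_HEIGHT]),
        head_center=np.array([L / 2 + dx / 2, W / 2, HEAD_HEIGHT]),
        reflection_coefficient=r,
        sample_rate=sample_rate,
        ir_length_s=1.5 * rt60 if ir_length_s is None else ir_length_s,
    )


def calibrate_reflection_coefficient(rt60_target: float,
                                     spec_builder,
                                     r_init: float,
                                     ear: str = "left",
                                     rtol: float = 0.005,
                                     max_iter: int = 8) -> float:
    """Adjust the reflection coefficient until the *measured* RT60 matches.

    Eyring predicts the diffuse-field decay, but a specular shoebox decays
    somewhat more slowly (grazing paths along the longest dimension see
    fewer wall hits than the mean free path assumes), so the Schroeder T30
    of a simulated response overshoots the Eyring target by 20-30 %.  This
    performs a deterministic secant search on ``r`` until
    ``estimate_rt60(simulate_rir(spec_builder(r)))`` is within ``rtol`` of
    ``rt60_target`` - i.e. the room is tuned the way one tunes a real
    simulation: by adjusting the surfaces until the achieved RT60 is right.
    """
    r0 = r_init
    t0 = estimate_rt60(simulate_rir(spec_builder(r0), ear))
    r1 = r0 * 0.98
    t1 = estimate_rt60(simulate_rir(spec_builder(r1), ear))
    for _ in range(max_iter):
        if abs(t1 - rt60_target) <= rtol * rt60_target:
            return r1
        if t1 == t0:
            break
        r2 = r1 + (rt60_target - t1) * (r1 - r0) / (t1 - t0)
        r0, t0 = r1, t1
        r1 = float(np.clip(r2, 0.01, 0.999))
        t1 = estimate_rt60(simulate_rir(spec_builder(r1), ear))
    if abs(t1 - rt60_target) > 0.1 * rt60_target:
        raise RuntimeError(
            f"RT60 calibration did not converge: target {rt60_target}, "
            f"achieved {t1:.3f}")
    return r1


_CALIBRATION_CACHE: dict[tuple, float] = {}


def study_room(rt60: float, sample_rate: int = DEFAULT_SAMPLE_RATE,
               ir_length_s: float | None = None,
               calibrated: bool = True) -> RoomSpec:
    """The study's 7 x 6 x 3.5 m room at a given target RT60.

    Source and head centre are 1.9 m apart on the room's long axis,
    symmetric about the room centre, at 1.5 m (source) and 1.3 m (head)
    height.  The height offset deliberately breaks the source/receiver
    mirror symmetry: with both at equal height, mirrored ceiling/floor
    image pairs arrive at exactly the same instant and their coherent
    summation inflates the reverberant energy by up to 3 dB (measurement
    practice likewise avoids symmetric positions).

    With ``calibrated=True`` (default) the uniform reflection coefficient
    is tuned so the simulated response's Schroeder T30 equals ``rt60``;
    otherwise the raw Eyring inversion is used.
    """
    r = reflection_coefficient_for_rt60(STUDY_ROOM_DIMS, rt60)
    if calibrated:
        key = (round(rt60, 6), sample_rate, ir_length_s)
        if key not in _CALIBRATION_CACHE:
            _CALIBRATION_CACHE[key] = calibrate_reflection_coefficient(
                rt60, lambda rr: _study_geometry(rr, rt60, sample_rate,
                                                 ir_length_s), r)
        r = _CALIBRATION_CACHE[key]
    return _study_geometry(r, rt60, sample_rate, ir_length_s)
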