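"""Synthetic transmitral-inflow velocity maps with an analytic ground truth.

The generator emulates the velocity pattern a color M-mode line records
across the mitral valve during diastole: an early (E) and a late,
atrial-contraction (A) inflow wave, each a Gaussian pulse in time that
propagates from the mitral annulus toward the apex at a finite
propagation velocity ``c`` while its amplitude decays linearly with
depth into the ventricle.  Proximal to the annulus (the atrial side of
the scanline) the wave is applied without delay or decay, joined through
a smooth (softplus) clamp so the field stays differentiable.

This is deliberately the simplest velocity model with non-zero inertial
(dv/dt) *and* convective (v dv/ds) acceleration, so the relative
pressure it implies under the 1-D inviscid Euler equation

    dP/ds = -rho (dv/dt + v dv/ds)

can be cross-checked against closed forms and against
:func:`oracle_pressure`, a brute-force reference that solves the same
equation on a spline-supersampled grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.integrate import cumulative_trapezoid

from .cmm_io import BeatTimings, ValidationError, VelocityMap

__all__ = ["InflowParams", "generate_inflow_field", "inflow_velocity",
           "oracle_pressure", "apply_aliasing", "OraclePressureField"]

#: blood density used throughout, kg/m^3
RHO_BLOOD = 1060.0
#: pressure unit conversion
PA_PER_MMHG = 133.322


@dataclass(frozen=True)
class InflowParams:
    """Parameters of the synthetic transmitral inflow field.

    Defaults describe a small-ruminant heart at rest: E and A peaks near
    the mitral E/A velocities of an awake goat (~0.57 and ~0.55 m/s), a
    heart period of 0.55 s (~110 bpm), a 60 mm scanline with the annulus
    20 mm from its proximal (left-atrial) end and a 40 mm LV long axis.
    The grid (ds = 1 mm, dt = 1/300 s) mirrors the display convention of
    a 300 mm/s sweep M-mode strip.
    """

    peak_E: float = 0.57          # E-wave peak velocity at the annulus, m/s
    peak_A: float = 0.55          # A-wave peak velocity, m/s
    sigma_E: float = 0.045        # E-wave temporal width, s
    sigma_A: float = 0.035        # A-wave temporal width, s
    prop_velocity: float = 0.5    # base-to-apex propagation speed c, m/s
    decay: float = 0.4            # linear amplitude decay fraction annulus->apex
    heart_period: float = 0.55    # s
    noise_sd: float = 0.0         # additive velocity noise, m/s
    scan_length: float = 0.060    # scanline extent, m
    lv_length: float = 0.040      # LV long axis (annulus to apex), m
    ds: float = 0.001             # m
    dt: float = 1.0 / 300.0       # s
    n_beats: int = 4
    seed: int = 0
    # timing offsets within a beat (from the Q wave), s
    t_q0: float = 0.05            # Q of the first beat on the time axis
    q_to_mv_open: float = 0.24
    q_to_peak_e: float = 0.32
    q_to_aortic_open: float = 0.06
    q_to_aortic_close: float = 0.21
    a_wave_before_next_q: float = 0.07
    clamp_width: float = 0.004    # softplus width of the proximal clamp, m

    def __post_init__(self) -> None:
        if self.peak_E <= 0:
            raise ValidationError("peak_E must be > 0")
        if self.prop_velocity <= 0:
            raise ValidationError("prop_velocity must be > 0")
        if not (0 <= self.decay < 1):
            raise ValidationError("decay must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if min(self.ds, self.dt, self.heart_period, self.scan_length,
               self.lv_length) <= 0:
            raise ValidationError("grid and geometry parameters must be > 0")
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")

    @property
    def s_annulus(self) -> float:
        return self.scan_length - self.lv_length

    def beat_timings(self) -> list[BeatTimings]:
        out = []
        for k in range(self.n_beats):
            t_q = self.t_q0 + k * self.heart_period
            out.append(BeatTimings(
                t_q=t_q,
                q_to_mv_open=self.q_to_mv_open,
                q_to_peak_e=self.q_to_peak_e,
                aortic_open=t_q + self.q_to_aortic_open,
                aortic_close=t_q + self.q_to_aortic_close,
            ))
        return out


def _smooth_ramp(x: np.ndarray, w: float) -> np.ndarray:
    """C1 clamp of max(x, 0): zero for x <= 0, exactly x for x >= w,
    cubic Hermite blend (matching value and slope at both ends) between."""
    if w <= 0:
        return np.maximum(x, 0.0)
    blend = -x ** 3 / w ** 2 + 2 * x ** 2 / w
    return np.where(x <= 0, 0.0, np.where(x >= w, x, blend))


def inflow_velocity(p: InflowParams, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Noise-free analytic field v(s, t) on the outer product of s and t.

    v(s,t) = sum_w V_w exp(-(t - tau_w - xi/c)^2 / (2 sigma_w^2)) (1 - beta xi/L)

    with xi the smoothly clamped depth past the annulus, summed over all
    beats and both waves.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    xi = _smooth_ramp(s - p.s_annulus, p.clamp_width)[:, None]
    amp_decay = 1.0 - p.decay * xi / p.lv_length
    v = np.zeros((len(s), len(t)))
    for k in range(p.n_beats):
        t_q = p.t_q0 + k * p.heart_period
        tau_E = t_q + p.q_to_peak_e
        tau_A = t_q + p.heart_period - p.a_wave_before_next_q
        for peak, sigma, tau in ((p.peak_E, p.sigma_E, tau_E),
                                 (p.peak_A, p.sigma_A, tau_A)):
            if peak == 0:
                continue
            arg = t[None, :] - tau - xi / p.prop_velocity
            v += peak * np.exp(-arg ** 2 / (2 * sigma ** 2)) * amp_decay
    return v


def generate_inflow_field(p: InflowParams) -> tuple[VelocityMap, list[BeatTimings]]:
    """Sample the inflow model on the grid, add noise, attach beat timings.

    Deterministic for a fixed ``p.seed``.  Raises if the temporal grid
    resolves either wave with fewer than 6 samples per temporal width.
    """
    for name, sigma in (("sigma_E", p.sigma_E), ("sigma_A", p.sigma_A)):
        if sigma / p.dt < 6:
            raise ValidationError(
                f"temporal grid too coarse: {name}={sigma} s spans "
                f"{sigma / p.dt:.1f} < 6 samples of dt={p.dt} s")
    n_s = int(round(p.scan_length / p.ds)) + 1
    t_total = p.t_q0 + p.n_beats * p.heart_period
    n_t = int(round(t_total / p.dt)) + 1
    s = np.arange(n_s) * p.ds
    t = np.arange(n_t) * p.dt
    v = inflow_velocity(p, s, t)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        v = v + rng.normal(0.0, p.noise_sd, size=v.shape)
    beats = p.beat_timings()
    vmap = VelocityMap(
        v=v, ds=p.ds, dt=p.dt,
        s0_annulus_index=int(round(p.s_annulus / p.ds)),
        apex_index=n_s - 1,
        lv_length=p.lv_length,
        beats=beats,
    )
    return vmap, beats


# ---------------------------------------------------------------------------
# brute-force pressure oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OraclePressureField:
    """Reference relative pressure on the source grid, in mmHg, P[0, :] = 0."""

    P: np.ndarray
    ds: float
    dt: float


def oracle_pressure(vmap: VelocityMap, rho: float = RHO_BLOOD,
                    refine: int = 8) -> OraclePressureField:
    """Independent brute-force solution of the 1-D Euler pressure integral.

    The sampled field is interpolated with a bicubic spline in (s, t);
    the Euler integrand ``dv/dt + v dv/ds`` is evaluated from the
    spline's analytic derivatives on a spatial grid supersampled
    ``refine`` times, integrated with the composite trapezoid rule along
    s, and the result is read back at the original row positions.  This
    is intentionally a different numerical route from the production
    estimator (spline derivatives + fine-grid quadrature vs. finite
    differences on the raw grid) so the two can cross-validate.
    """
    if refine < 1:
        raise ValidationError("refine must be >= 1")
    v = vmap.v
    if v.shape[0] < 4 or v.shape[1] < 4:
        raise ValidationError("oracle needs at least a 4 x 4 grid for a bicubic spline")
    s = vmap.s_axis
    t = vmap.t_axis
    spl = RectBivariateSpline(s, t, v, kx=3, ky=3, s=0)
    n_fine = (len(s) - 1) * refine + 1
    s_fine = np.linspace(s[0], s[-1], n_fine)
    dvdt = spl(s_fine, t, dy=1)
    dvds = spl(s_fine, t, dx=1)
    v_fine = spl(s_fine, t)
    g = dvdt + v_fine * dvds
    P_fine = -rho * cumulative_trapezoid(g, x=s_fine, axis=0, initial=0.0)
    P = P_fine[::refine] / PA_PER_MMHG
    return OraclePressureField(P=P, ds=vmap.ds, dt=vmap.dt)


def apply_aliasing(vmap: VelocityMap, nyquist: float) -> VelocityMap:
    """Wrap every sample into [-V_N, V_N), as a Doppler system would.

    The returned map records ``nyquist`` in its metadata so downstream
    processing knows to unwrap.
    """
    if nyquist <= 0:
        raise ValidationError("nyquist must be > 0")
    vn = float(nyquist)
    wrapped = np.mod(vmap.v + vn, 2 * vn) - vn
    return vmap.with_v(wrapped, nyquist=vn)
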