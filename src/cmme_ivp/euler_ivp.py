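"""Intraventricular pressure differences and gradients from a velocity map.

The core computation: the 1-D inviscid Euler equation along the
transmitral scanline,

    dP/ds = -rho (dv/dt + v dv/ds),

is integrated spatially (trapezoid rule, derivatives by second-order
finite differences) to give a relative pressure field P(s, t) referenced
to the proximal end of the scanline.  Within each beat's diastolic
window the time of peak base-to-apex pressure difference is located; at
that single instant the LV span [annulus, apex] is trisected into basal,
mid and apical segments and the pressure drop across each is reported as
the segmental IVPD (mmHg).  IVPG is IVPD normalised by the LV long-axis
length (mmHg/cm).  Evaluating all segments at the same instant makes the
aggregation identities exact by construction:

    mid_to_apical = mid + apical
    basal + mid + apical = P(annulus) - P(apex)   at peak time.

The *total* IVPD spans the full scanline (row 0 to apex) by default,
which may extend proximal of the annulus into the left atrium; a
``total_span="lv_only"`` toggle restricts it to the annulus.

Preprocessing counterparts of acquisition-time controls are provided:
Nyquist unwrapping (:func:`dealias`, the software analogue of a color
baseline shift) and separable Gaussian smoothing (:func:`smooth`, the
pipeline's deterministic "automatic correction").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .cmm_io import BeatTimings, ValidationError, VelocityMap, snap_to_grid
from .synthetic_cmm import PA_PER_MMHG, RHO_BLOOD

__all__ = [
    "PressureField", "SegmentBoundaries", "IVPDResult", "IVPGResult",
    "AnalysisConfig", "RecordingResult",
    "dealias", "smooth", "diastolic_window", "estimate_pressure_field",
    "trisect", "compute_ivpd", "compute_ivpg", "analyze_recording",
    "IVPD_COMPONENTS",
]

IVPD_COMPONENTS = ("total", "basal", "mid", "apical", "mid_to_apical")


@dataclass(frozen=True)
class PressureField:
    """Relative pressure (mmHg) on the source velocity-map grid.

    ``P[reference_row, :]`` is identically zero; only pressure
    *differences* along the scanline are physically meaningful.
    """

    P: np.ndarray
    ds: float
    dt: float
    reference_row: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.P)):
            raise ValidationError("pressure field contains non-finite values")
        if np.any(self.P[self.reference_row, :] != 0.0):
            raise ValidationError("pressure at the reference row must be 0")

    @property
    def s_axis(self) -> np.ndarray:
        return np.arange(self.P.shape[0]) * self.ds

    @property
    def t_axis(self) -> np.ndarray:
        return np.arange(self.P.shape[1]) * self.dt

    def at(self, s_pos: float, col: int) -> float:
        """Pressure at a continuous scanline position (linear interpolation)."""
        s = self.s_axis
        if not (s[0] <= s_pos <= s[-1]):
            raise ValidationError(f"position {s_pos} m outside scanline [0, {s[-1]}]")
        return float(np.interp(s_pos, s, self.P[:, col]))


@dataclass(frozen=True)
class SegmentBoundaries:
    """Continuous positions (m) trisecting the LV span of the scanline."""

    s_base: float
    s_third: float
    s_two_thirds: float
    s_apex: float

    def __post_init__(self) -> None:
        pts = (self.s_base, self.s_third, self.s_two_thirds, self.s_apex)
        if not all(b > a for a, b in zip(pts, pts[1:])):
            raise ValidationError("segment boundaries must be strictly increasing")
        d1 = self.s_third - self.s_base
        d2 = self.s_two_thirds - self.s_third
        d3 = self.s_apex - self.s_two_thirds
        if not (np.isclose(d1, d2, rtol=1e-9, atol=1e-12)
                and np.isclose(d2, d3, rtol=1e-9, atol=1e-12)):
            raise ValidationError("boundaries must trisect the LV span exactly")


@dataclass(frozen=True)
class IVPDResult:
    """Per-beat segmental pressure differences (mmHg) at the diastolic peak."""

    total: float
    basal: float
    mid: float
    apical: float
    mid_to_apical: float
    peak_time: float
    beat_index: int
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in IVPD_COMPONENTS}


@dataclass(frozen=True)
class IVPGResult:
    """Segmental pressure gradients: IVPD / LV length, in mmHg/cm."""

    total: float
    basal: float
    mid: float
    apical: float
    mid_to_apical: float
    lv_length_cm: float
    peak_time: float
    beat_index: int

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in IVPD_COMPONENTS}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dealias(vmap: VelocityMap, nyquist: float | None = None) -> VelocityMap:
    """Unwrap Nyquist-aliased velocities.

    Each spatial row is phase-unwrapped along time (period 2 V_N), then a
    single consistency pass unwraps the first time column along s and
    shifts whole rows, anchoring everything to the map's first sample.
    Recovers the true field exactly for maps whose sample-to-sample
    jumps are below V_N and whose first sample is unaliased.  If more
    than 20 % of samples required correction a quality warning is
    emitted (the map is still returned).
    """
    vn = nyquist if nyquist is not None else vmap.nyquist
    if vn is None or vn <= 0:
        raise ValidationError("dealias requires a positive nyquist velocity")
    period = 2.0 * vn
    u = np.unwrap(vmap.v, axis=1, period=period)
    col0 = np.unwrap(u[:, 0], period=period)
    u = u + (col0 - u[:, 0])[:, None]
    n_corrected = int(np.sum(np.abs(u - vmap.v) > vn * 1e-9))
    if n_corrected > 0.2 * u.size:
        warnings.warn(
            f"dealias corrected {n_corrected}/{u.size} samples (> 20%); "
            "unwrapping may be unreliable", stacklevel=2)
    return vmap.with_v(u, nyquist=None)


def smooth(vmap: VelocityMap, sigma_s: float = 0.0, sigma_t: float = 0.0) -> VelocityMap:
    """Separable Gaussian smoothing with reflecting boundaries.

    ``sigma_s`` (m) and ``sigma_t`` (s) are physical widths; zero means
    identity along that axis.
    """
    if sigma_s < 0 or sigma_t < 0:
        raise ValidationError("smoothing sigmas must be >= 0")
    if sigma_s == 0 and sigma_t == 0:
        return vmap
    v = gaussian_filter(vmap.v, sigma=(sigma_s / vmap.ds, sigma_t / vmap.dt),
                        mode="reflect")
    return vmap.with_v(v)


def diastolic_window(beat: BeatTimings, t_axis: np.ndarray,
                     next_t_q: float | None = None) -> tuple[int, int]:
    """Index interval [i_open, i_end) of one beat's diastole on the time axis.

    Opens at mitral-valve opening (Q + measured delay) and ends at the
    next beat's Q wave, or at the end of the map for the last beat.
    Warns if aortic closure does not precede the window (diastole should
    follow systole).
    """
    n = len(t_axis)
    dt = float(t_axis[1] - t_axis[0])
    i_open = snap_to_grid(beat.t_mv_open, dt, n, "mitral valve opening")
    if next_t_q is None:
        i_end = n
    else:
        i_end = snap_to_grid(next_t_q, dt, n, "next Q wave")
    if i_end <= i_open:
        raise ValidationError(
            f"empty diastolic window: [{i_open}, {i_end}) on {n} samples")
    if beat.aortic_close > beat.t_mv_open:
        warnings.warn("aortic closure follows mitral valve opening; "
                      "check beat timings", stacklevel=2)
    return i_open, i_end


# ---------------------------------------------------------------------------
# pressure estimation
# ---------------------------------------------------------------------------

def estimate_pressure_field(vmap: VelocityMap, rho: float = RHO_BLOOD) -> PressureField:
    """Integrate the Euler equation along the scanline.

    Derivatives are second-order central differences (one-sided
    second-order at the grid edges); the integrand
    ``g = dv/dt + v dv/ds`` is integrated from row 0 with the composite
    trapezoid rule, giving P in mmHg with P(row 0, t) = 0.
    """
    v = vmap.v
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValidationError("pressure estimation needs at least 3 rows and 3 columns")
    dvdt = np.gradient(v, vmap.dt, axis=1, edge_order=2)
    dvds = np.gradient(v, vmap.ds, axis=0, edge_order=2)
    g = dvdt + v * dvds
    P_pa = -rho * cumulative_trapezoid(g, dx=vmap.ds, axis=0, initial=0.0)
    return PressureField(P=P_pa / PA_PER_MMHG, ds=vmap.ds, dt=vmap.dt, reference_row=0)


def trisect(vmap: VelocityMap) -> SegmentBoundaries:
    """Exact thirds of the continuous LV span [annulus, apex].

    Boundaries are *not* snapped to the grid; pressures at non-grid
    positions are evaluated by linear interpolation downstream.
    """
    s_base = vmap.s_annulus
    s_apex = vmap.s_apex
    if s_apex <= s_base:
        raise ValidationError("apex must lie distal to the annulus")
    third = (s_apex - s_base) / 3.0
    return SegmentBoundaries(s_base=s_base, s_third=s_base + third,
                             s_two_thirds=s_base + 2.0 * third, s_apex=s_apex)


def compute_ivpd(pf: PressureField, segs: SegmentBoundaries,
                 window: tuple[int, int], beat_index: int = 0,
                 total_span: str = "scanline") -> IVPDResult:
    """Segmental IVPD at the time of peak total pressure difference.

    ``peak_time`` is the argmax over the window of P(row 0) - P(apex)
    (earliest sample on ties).  All segment drops are read at that one
    instant, which makes ``mid_to_apical == mid + apical`` and
    ``basal + mid + apical == P(annulus) - P(apex)`` exact.  With
    ``total_span="scanline"`` (default) the total spans row 0 to the
    apex; ``"lv_only"`` starts it at the annulus.
    """
    if total_span not in ("scanline", "lv_only"):
        raise ValidationError(f"unknown total_span {total_span!r}")
    i_open, i_end = window
    n_t = pf.P.shape[1]
    if not (0 <= i_open < i_end <= n_t):
        raise ValidationError(f"window [{i_open}, {i_end}) outside field of {n_t} columns")
    p_prox = pf.P[0, i_open:i_end]
    s_axis = pf.s_axis
    # apex may sit between grid rows; interpolate its pressure trace
    w = np.searchsorted(s_axis, segs.s_apex, side="right") - 1
    w = min(w, pf.P.shape[0] - 2)
    frac = (segs.s_apex - s_axis[w]) / pf.ds
    p_apex = (1 - frac) * pf.P[w, i_open:i_end] + frac * pf.P[w + 1, i_open:i_end]
    drive = p_prox - p_apex
    k = int(np.argmax(drive))          # np.argmax returns the first (earliest) max
    col = i_open + k
    peak_time = col * pf.dt
    degenerate = bool(np.all(drive == 0.0))

    p_at = lambda s_pos: pf.at(s_pos, col)
    p_base = p_at(segs.s_base)
    p_third = p_at(segs.s_third)
    p_two_thirds = p_at(segs.s_two_thirds)
    p_apex_c = p_at(segs.s_apex)
    basal = p_base - p_third
    mid = p_third - p_two_thirds
    apical = p_two_thirds - p_apex_c
    total = (pf.P[0, col] - p_apex_c) if total_span == "scanline" else (p_base - p_apex_c)
    if degenerate:
        warnings.warn("pressure difference identically zero in the window",
                      stacklevel=2)
    return IVPDResult(total=total, basal=basal, mid=mid, apical=apical,
                      mid_to_apical=mid + apical, peak_time=peak_time,
                      beat_index=beat_index, degenerate=degenerate)


def compute_ivpg(ivpd: IVPDResult, lv_length: float) -> IVPGResult:
    """Normalise an IVPD result by the LV long-axis length (in cm)."""
    if lv_length <= 0:
        raise ValidationError("lv_length must be > 0")
    lv_cm = lv_length * 100.0
    return IVPGResult(
        total=ivpd.total / lv_cm, basal=ivpd.basal / lv_cm,
        mid=ivpd.mid / lv_cm, apical=ivpd.apical / lv_cm,
        mid_to_apical=ivpd.mid_to_apical / lv_cm,
        lv_length_cm=lv_cm, peak_time=ivpd.peak_time, beat_index=ivpd.beat_index)


# ---------------------------------------------------------------------------
# full-recording analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the per-recording pipeline.

    ``sigma_s``/``sigma_t`` are the Gaussian preprocessing widths (m, s);
    zero disables smoothing.  ``e_wave_only`` restricts the peak search
    to the early-filling part of diastole instead of the whole window.
    """

    rho: float = RHO_BLOOD
    sigma_s: float = 0.002
    sigma_t: float = 0.006
    total_span: str = "scanline"
    e_wave_only: bool = False
    e_wave_margin: float = 0.09    # s past peak E kept when e_wave_only

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValidationError("rho must be > 0")
        if self.sigma_s < 0 or self.sigma_t < 0:
            raise ValidationError("smoothing sigmas must be >= 0")


@dataclass(frozen=True)
class RecordingResult:
    """Per-beat results plus per-recording means of each component."""

    ivpd: list[IVPDResult]
    ivpg: list[IVPGResult]
    mean_ivpd: dict[str, float]
    mean_ivpg: dict[str, float]

    def as_frame(self):
        import pandas as pd
        rows = []
        for d, g in zip(self.ivpd, self.ivpg):
            row = {"beat": d.beat_index, "peak_time_s": d.peak_time}
            row.update({f"{c}_ivpd": getattr(d, c) for c in IVPD_COMPONENTS})
            row.update({f"{c}_ivpg": getattr(g, c) for c in IVPD_COMPONENTS})
            rows.append(row)
        mean_row = {"beat": "mean", "peak_time_s": np.nan}
        mean_row.update({f"{c}_ivpd": self.mean_ivpd[c] for c in IVPD_COMPONENTS})
        mean_row.update({f"{c}_ivpg": self.mean_ivpg[c] for c in IVPD_COMPONENTS})
        rows.append(mean_row)
        return pd.DataFrame(rows)


def analyze_recording(vmap: VelocityMap, config: AnalysisConfig | None = None) -> RecordingResult:
    """Dealias (if flagged) -> smooth -> pressure -> per-beat segmental IVPD/IVPG.

    Beats come from the map's metadata; each beat's diastolic window
    runs from its mitral-valve opening to the next beat's Q wave (or the
    end of the map).
    """
    cfg = config or AnalysisConfig()
    if not vmap.beats:
        raise ValidationError("velocity map carries no beat timings")
    m = vmap
    if m.nyquist is not None:
        m = dealias(m)
    m = smooth(m, cfg.sigma_s, cfg.sigma_t)
    pf = estimate_pressure_field(m, rho=cfg.rho)
    segs = trisect(m)
    t_axis = m.t_axis
    beats = sorted(vmap.beats, key=lambda b: b.t_q)
    ivpds: list[IVPDResult] = []
    ivpgs: list[IVPGResult] = []
    for i, beat in enumerate(beats):
        next_q = beats[i + 1].t_q if i + 1 < len(beats) else None
        i_open, i_end = diastolic_window(beat, t_axis, next_q)
        if cfg.e_wave_only:
            t_stop = beat.t_peak_e + cfg.e_wave_margin
            i_end = min(i_end, max(i_open + 1, int(round(t_stop / m.dt)) + 1))
        d = compute_ivpd(pf, segs, (i_open, i_end), beat_index=i,
                         total_span=cfg.total_span)
        ivpds.append(d)
        ivpgs.append(compute_ivpg(d, m.lv_length))
    mean_ivpd = {c: float(np.mean([getattr(d, c) for d in ivpds]))
                 for c in IVPD_COMPONENTS}
    mean_ivpg = {c: float(np.mean([getattr(g, c) for g in ivpgs]))
                 for c in IVPD_COMPONENTS}
    return RecordingResult(ivpd=ivpds, ivpg=ivpgs,
                           mean_ivpd=mean_ivpd, mean_ivpg=mean_ivpg)
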