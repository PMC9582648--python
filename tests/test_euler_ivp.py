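"""Pressure estimator, segmentation, per-beat IVPD/IVPG extraction."""

import numpy as np
import pytest

from cmme_ivp.cmm_io import BeatTimings, ValidationError
from cmme_ivp.euler_ivp import (AnalysisConfig, PressureField, analyze_recording,
                                compute_ivpd, compute_ivpg, dealias,
                                diastolic_window, estimate_pressure_field,
                                smooth, trisect)
from cmme_ivp.synthetic_cmm import (InflowParams, PA_PER_MMHG, apply_aliasing,
                                    generate_inflow_field, oracle_pressure)

from conftest import make_map

RHO = 1060.0


# ---------------------------------------------------------------------------
# pressure estimation
# ---------------------------------------------------------------------------

def test_zero_velocity_gives_zero_pressure():
    pf = estimate_pressure_field(make_map(np.zeros((8, 8))))
    assert np.all(pf.P == 0.0)
    assert pf.reference_row == 0


def test_steady_linear_field_matches_closed_form():
    """v = a*s: only the convective term acts; P = -rho a^2 s^2 / 2."""
    a, L, n = 5.0, 0.04, 65
    s = np.linspace(0, L, n)
    vm = make_map(np.tile(a * s[:, None], (1, 8)), ds=L / (n - 1))
    pf = estimate_pressure_field(vm, rho=RHO)
    expected = -RHO * a ** 2 * L ** 2 / 2 / PA_PER_MMHG   # = -0.159 mmHg
    assert pf.P[-1, 0] == pytest.approx(expected, rel=1e-3)
    assert pf.P[-1, 0] == pytest.approx(-0.159, abs=2e-4)


def test_oscillatory_uniform_field_matches_closed_form():
    """v = A sin(2 pi f t): only the inertial term; dP/ds = -rho dv/dt."""
    A, f, L, n, dt = 0.5, 2.0, 0.04, 33, 1.0 / 300
    t = np.arange(150) * dt
    vm = make_map(np.tile((A * np.sin(2 * np.pi * f * t))[None, :], (n, 1)),
                  ds=L / (n - 1), dt=dt)
    pf = estimate_pressure_field(vm, rho=RHO)
    expected = -RHO * 2 * np.pi * f * A * L * np.cos(2 * np.pi * f * t) / PA_PER_MMHG
    assert pf.P[-1, :] == pytest.approx(expected, abs=2e-3 * np.abs(expected).max())


def test_estimator_agrees_with_bruteforce_oracle(clean_one_beat):
    """Finite differences vs spline supersampling: < 1% at the apex."""
    _, vmap, _ = clean_one_beat
    est = estimate_pressure_field(vmap).P[-1]
    ref = oracle_pressure(vmap, refine=8).P[-1]
    scale = np.abs(ref).max()
    assert np.abs(est - ref).max() < 0.01 * scale


def test_grid_convergence_of_total_ivpd():
    """Halving ds and dt moves total IVPD by < 0.5%."""
    cfg = AnalysisConfig(sigma_s=0.0, sigma_t=0.0)
    totals = []
    for factor in (1, 2):
        p = InflowParams(noise_sd=0.0, n_beats=1, ds=0.001 / factor,
                         dt=(1.0 / 300) / factor)
        vmap, _ = generate_inflow_field(p)
        totals.append(analyze_recording(vmap, cfg).ivpd[0].total)
    assert totals[1] == pytest.approx(totals[0], rel=0.005)


def test_term_scaling_under_velocity_rescale(clean_one_beat):
    """v -> lam v scales the inertial term by lam, convective by lam^2."""
    _, vmap, _ = clean_one_beat
    lam = 0.5
    def split_terms(m):
        dvdt = np.gradient(m.v, m.dt, axis=1, edge_order=2)
        dvds = np.gradient(m.v, m.ds, axis=0, edge_order=2)
        return dvdt, m.v * dvds
    i1, c1 = split_terms(vmap)
    i2, c2 = split_terms(vmap.with_v(lam * vmap.v))
    assert i2 == pytest.approx(lam * i1)
    assert c2 == pytest.approx(lam ** 2 * c1)


def test_minimum_grid_size_enforced():
    with pytest.raises(ValidationError, match="3 rows"):
        estimate_pressure_field(make_map(np.zeros((2, 8)), apex=1))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_smooth_identity_and_constant_invariance():
    rng = np.random.default_rng(0)
    vm = make_map(rng.normal(0, 0.1, (16, 16)))
    assert np.array_equal(smooth(vm, 0.0, 0.0).v, vm.v)
    const = make_map(np.full((16, 16), 0.4))
    assert smooth(const, 0.003, 0.01).v == pytest.approx(const.v)


def test_smooth_strictly_reduces_noise_variance():
    rng = np.random.default_rng(1)
    vm = make_map(rng.normal(0, 0.2, (32, 32)))
    out = smooth(vm, 0.002, 0.01)
    assert out.v.var() < vm.v.var()


def test_dealias_recovers_aliased_smooth_map(clean_one_beat):
    _, vmap, _ = clean_one_beat
    vn = 0.4  # below peak E of ~0.57 -> genuine wrapping occurs
    aliased = apply_aliasing(vmap, vn)
    assert not np.allclose(aliased.v, vmap.v)
    recovered = dealias(aliased)
    assert recovered.v == pytest.approx(vmap.v, abs=1e-9)
    assert recovered.nyquist is None


def test_dealias_leaves_alias_free_map_unchanged(clean_one_beat):
    _, vmap, _ = clean_one_beat
    out = dealias(vmap, nyquist=2.0)
    assert out.v == pytest.approx(vmap.v, abs=1e-12)


def test_dealias_boundary_constant_unchanged():
    vn, eps = 0.5, 1e-6
    vm = make_map(np.full((6, 6), -vn + eps))
    assert dealias(vm, vn).v == pytest.approx(vm.v)


def test_dealias_warns_on_heavy_correction():
    vn = 0.1
    t = np.linspace(0, 1, 50)
    v = np.tile(0.5 * np.sin(2 * np.pi * t)[None, :], (6, 1))  # |v| up to 5 V_N
    aliased = apply_aliasing(make_map(v), vn)
    with pytest.warns(UserWarning, match="20%"):
        dealias(aliased)


# ---------------------------------------------------------------------------
# windows and segmentation
# ---------------------------------------------------------------------------

def test_diastolic_window_arithmetic():
    beat = BeatTimings(t_q=0.0, q_to_mv_open=0.10, q_to_peak_e=0.2,
                       aortic_open=0.02, aortic_close=0.08)
    t_axis = np.arange(100) * 0.01
    assert diastolic_window(beat, t_axis, next_t_q=0.60) == (10, 60)
    # single-beat map: window extends to the end
    assert diastolic_window(beat, t_axis) == (10, 100)


def test_marker_beyond_extent_raises():
    beat = BeatTimings(t_q=0.0, q_to_mv_open=2.0, q_to_peak_e=2.5,
                       aortic_open=0.02, aortic_close=0.08)
    with pytest.raises(ValidationError, match="outside"):
        diastolic_window(beat, np.arange(100) * 0.01)


def test_trisect_exact_thirds_not_grid_snapped():
    # annulus 0.02 m, apex 0.05 m -> thirds at 0.03 and 0.04
    vm = make_map(np.zeros((51, 8)), ds=0.001, annulus=20, apex=50)
    segs = trisect(vm)
    assert (segs.s_base, segs.s_third, segs.s_two_thirds, segs.s_apex) == \
        pytest.approx((0.02, 0.03, 0.04, 0.05))
    # 10 LV intervals do not divide by 3: boundaries fall between grid rows
    vm2 = make_map(np.zeros((11, 8)), ds=0.001, annulus=0, apex=10)
    s3 = trisect(vm2).s_third
    assert (s3 / vm2.ds) % 1 != pytest.approx(0.0, abs=1e-9)


def test_trisect_rejects_degenerate_lv():
    vm = make_map(np.zeros((8, 8)), annulus=2, apex=5)
    vm.apex_index = 2  # corrupt after construction
    with pytest.raises(ValidationError):
        trisect(vm)


# ---------------------------------------------------------------------------
# IVPD / IVPG extraction
# ---------------------------------------------------------------------------

def _linear_pressure_field(k=25.0, n_s=41, n_t=10, ds=0.001):
    """P(s, t) = -k s (mmHg), steady: every segment drop is k * length."""
    s = np.arange(n_s) * ds
    P = np.tile(-k * s[:, None], (1, n_t))
    return PressureField(P=P, ds=ds, dt=0.01)


def test_linear_pressure_field_segment_arithmetic():
    # LV 0.03 m with a 0.01 m proximal (atrial) extension, k = 25 mmHg/m
    pf = _linear_pressure_field()
    vm = make_map(np.zeros((41, 10)), annulus=10, apex=40)
    segs = trisect(vm)
    res = compute_ivpd(pf, segs, (0, 10))
    assert res.total == pytest.approx(1.0)
    assert (res.basal, res.mid, res.apical) == pytest.approx((0.25, 0.25, 0.25))
    assert res.mid_to_apical == pytest.approx(0.5)
    # lv_only span: total starts at the annulus instead of row 0
    res2 = compute_ivpd(pf, segs, (0, 10), total_span="lv_only")
    assert res2.total == pytest.approx(0.75)


def test_zero_pressure_gives_zero_components_flagged():
    pf = PressureField(P=np.zeros((41, 10)), ds=0.001, dt=0.01)
    segs = trisect(make_map(np.zeros((41, 10)), annulus=10, apex=40))
    with pytest.warns(UserWarning, match="zero"):
        res = compute_ivpd(pf, segs, (0, 10))
    assert res.degenerate
    assert all(getattr(res, c) == 0 for c in
               ("total", "basal", "mid", "apical", "mid_to_apical"))


def test_peak_tie_breaks_to_earliest_time():
    P = np.zeros((41, 10))
    P[-1, 3] = P[-1, 7] = -1.0      # equal peaks at columns 3 and 7
    pf = PressureField(P=P, ds=0.001, dt=0.01)
    segs = trisect(make_map(np.zeros((41, 10)), annulus=10, apex=40))
    res = compute_ivpd(pf, segs, (0, 10))
    assert res.peak_time == pytest.approx(0.03)


def test_additivity_invariants_on_generated_field(clean_one_beat):
    _, vmap, _ = clean_one_beat
    res = analyze_recording(vmap, AnalysisConfig(sigma_s=0.0, sigma_t=0.0))
    d = res.ivpd[0]
    assert d.mid_to_apical == d.mid + d.apical          # exact by construction
    pf = estimate_pressure_field(vmap)
    segs = trisect(vmap)
    col = int(round(d.peak_time / vmap.dt))
    lhs = d.basal + d.mid + d.apical
    rhs = pf.at(segs.s_base, col) - pf.at(segs.s_apex, col)
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_total_ivpd_positive_during_e_wave(clean_one_beat):
    """Base pressure exceeds apex pressure while early inflow accelerates."""
    _, vmap, _ = clean_one_beat
    res = analyze_recording(vmap, AnalysisConfig(sigma_s=0.0, sigma_t=0.0))
    assert res.ivpd[0].total > 0


def test_ivpg_is_ivpd_over_lv_length_cm():
    pf = _linear_pressure_field()
    vm = make_map(np.zeros((41, 10)), annulus=10, apex=40)
    res = compute_ivpd(pf, trisect(vm), (0, 10))
    g = compute_ivpg(res, lv_length=0.04)
    assert g.total == pytest.approx(res.total / 4.0)     # 1.2 mmHg / 4 cm style
    assert g.mid_to_apical == pytest.approx(g.mid + g.apical)
    with pytest.raises(ValidationError):
        compute_ivpg(res, lv_length=0.0)


def test_window_outside_field_rejected():
    pf = _linear_pressure_field()
    segs = trisect(make_map(np.zeros((41, 10)), annulus=10, apex=40))
    with pytest.raises(ValidationError, match="window"):
        compute_ivpd(pf, segs, (5, 20))


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

def test_identical_beats_give_identical_results(clean_four_beats):
    _, vmap, _ = clean_four_beats
    res = analyze_recording(vmap, AnalysisConfig(sigma_s=0.0, sigma_t=0.0))
    assert len(res.ivpd) == 4
    totals = [d.total for d in res.ivpd]
    assert totals == pytest.approx([totals[0]] * 4, rel=1e-6)
    assert res.mean_ivpd["total"] == pytest.approx(totals[0], rel=1e-6)


def test_noisy_mean_near_noiseless_value():
    cfg = AnalysisConfig()
    clean_map, _ = generate_inflow_field(InflowParams(noise_sd=0.0, n_beats=4))
    ref = analyze_recording(clean_map, cfg).mean_ivpd["total"]
    means = []
    for seed in range(8):
        noisy, _ = generate_inflow_field(
            InflowParams(noise_sd=0.02, n_beats=4, seed=seed))
        means.append(analyze_recording(noisy, cfg).mean_ivpd["total"])
    # Monte-Carlo band: the noisy estimate scatters around the clean one
    assert np.mean(means) == pytest.approx(ref, rel=0.03)


def test_recording_requires_beats(clean_one_beat):
    _, vmap, _ = clean_one_beat
    bare = vmap.with_v(vmap.v, beats=[])
    with pytest.raises(ValidationError, match="beat"):
        analyze_recording(bare)
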