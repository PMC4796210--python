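"""Path CV, ratchet dynamics, well-tempered machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrosite import fixtures, metadyn
from hydrosite.metadyn import (
    ABMDParameters,
    ABMDSchedule,
    GaussianHill,
    PathCV,
    TOY_METAD_PARAMS,
    WTMetaDParameters,
    abmd_bias,
    eval_path_cv,
    read_hills,
    reconstruct_free_energy,
    run_binding_path,
    run_metascore,
    wtmetad_height,
    write_hills,
)

KB = fixtures.KB


# ---------------------------------------------------------------------------
# path collective variable
# ---------------------------------------------------------------------------

def test_path_cv_midpoint_is_half():
    cv = PathCV(frames=[0.0, 1.0], lam=0.6)
    assert eval_path_cv(0.5, cv) == pytest.approx(0.5)


def test_path_cv_limits_at_frames():
    cv = PathCV(frames=[0.0, 1.0], lam=500.0)  # sharp lambda -> limit case
    assert eval_path_cv(0.0, cv) < 1e-6
    assert eval_path_cv(1.0, cv) > 1 - 1e-6


def test_path_cv_three_frames_matches_direct_formula():
    frames = [0.0, 0.7, 1.9]
    lam = 1.3
    cv = PathCV(frames=frames, lam=lam)
    x = 0.83
    w = [math.exp(-lam * (x - f) ** 2) for f in frames]
    t = [0.0, 0.5, 1.0]
    expected = sum(ti * wi for ti, wi in zip(t, w)) / sum(w)
    assert eval_path_cv(x, cv) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=-2.0, max_value=3.0, allow_nan=False))
def test_path_cv_stays_in_unit_interval(x):
    cv = PathCV(frames=[0.0, 1.0], lam=3.0)
    s = eval_path_cv(x, cv)
    assert 0.0 <= s <= 1.0


def test_path_cv_gradient_matches_numeric():
    cv = PathCV(frames=[0.0, 1.0], lam=3.0)
    for x in (-0.1, 0.2, 0.5, 0.8, 1.2):
        s, ds = cv.value_and_grad_1d(x)
        num = (cv.value(x + 1e-6) - cv.value(x - 1e-6)) / 2e-6
        assert ds == pytest.approx(num, abs=1e-6)


def test_path_cv_validation():
    with pytest.raises(ValueError):
        PathCV(frames=[0.0])
    with pytest.raises(ValueError):
        PathCV(frames=[0.0, 1.0], lam=-1.0)


# ---------------------------------------------------------------------------
# adiabatic-bias ratchet
# ---------------------------------------------------------------------------

def test_ratchet_bias_off_inside_reference():
    p = ABMDParameters(kappa=2.0, target=0.5)
    assert abmd_bias(0.4, 1.0, p) == (0.0, 0.0)
    assert abmd_bias(1.0, 1.0, p) == (0.0, 0.0)


def test_ratchet_bias_harmonic_outside():
    p = ABMDParameters(kappa=2.0, target=0.0)
    energy, force = abmd_bias(2.0, 1.0, p)
    assert energy == pytest.approx(1.0)
    assert force == pytest.approx(-2.0)
    with pytest.raises(ValueError):
        abmd_bias(-0.1, 1.0, p)
    with pytest.raises(ValueError):
        ABMDParameters(kappa=-1.0, target=0.0)


def test_ratchet_floor_at_target():
    p = ABMDParameters(kappa=2.0, target=0.8)
    # history went below the target: the floor keeps the bias off above it
    energy, _ = abmd_bias(0.9, 0.1, p)
    assert energy == pytest.approx(0.5 * 2.0 * 0.1**2)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_binding_path_ratchet_and_snapshots(seed):
    land = fixtures.make_binding_landscape(-5.0, 3.0)
    sched = ABMDSchedule()
    snaps = run_binding_path(land, sched, seed=seed)
    assert len(snaps) == sched.n_snapshots == 102
    cv = land.path_cv()
    assert cv.value(snaps[0]) < 0.1
    assert cv.value(snaps[-1]) > 0.9
    rho_star = run_binding_path.last_rho_star
    assert np.all(np.diff(rho_star) <= 1e-12)
    assert land.rho(snaps[-1]) <= sched.bound_tolerance


def test_binding_path_deterministic():
    land = fixtures.make_binding_landscape(-5.0, 3.0)
    a = run_binding_path(land, seed=4)
    b = run_binding_path(land, seed=4)
    assert a == b


def test_abmd_schedule_defaults():
    s = ABMDSchedule()
    assert s.n_segments == 6
    assert s.target_divisor == 100.0 and s.kappa_multiplier == 100.0
    assert s.n_snapshots == 102
    assert s.initial_target == 10.0
    assert s.initial_kappa == pytest.approx(0.00239006)


# ---------------------------------------------------------------------------
# well-tempered machinery
# ---------------------------------------------------------------------------

def test_first_hill_height_is_three():
    params = WTMetaDParameters()
    assert params.temperature == 300.0 and params.bias_factor_gamma == 50.0
    assert wtmetad_height(0.0, params) == pytest.approx(3.0)


def test_height_decay_closed_form():
    params = WTMetaDParameters()
    v = KB * (params.bias_factor_gamma - 1.0) * params.temperature
    assert wtmetad_height(v, params) == pytest.approx(3.0 / math.e)
    inf_gamma = WTMetaDParameters(bias_factor_gamma=math.inf)
    assert wtmetad_height(123.0, inf_gamma) == 3.0
    with pytest.raises(ValueError):
        wtmetad_height(-1.0, params)


def test_reconstruct_scaling_and_errors():
    params = WTMetaDParameters()
    hills = [
        GaussianHill(center_s=c, width_sigma=0.1, height=h, walker_id=0,
                     deposit_index=i)
        for i, (c, h) in enumerate([(0.2, 3.0), (0.5, 1.5), (0.8, 2.0)])
    ]
    grid = np.linspace(0, 1, 101)
    prof = reconstruct_free_energy(hills, grid, params)
    v = np.zeros_like(grid)
    for h in hills:
        v += h.height * np.exp(-((grid - h.center_s) ** 2) / (2 * 0.1**2))
    expected = -(50.0 / 49.0) * v
    expected -= expected.min()
    assert np.abs(prof.f_values - expected).max() < 1e-12
    assert prof.f_values.min() == 0.0
    with pytest.raises(ValueError):
        reconstruct_free_energy([], grid, params)


def test_single_hill_carves_minimum_at_its_center():
    """F = -(gamma/(gamma-1)) V: one deposited hill marks its center as
    the (so-far) free-energy minimum, with F rising toward the edges."""
    params = WTMetaDParameters()
    hills = [GaussianHill(0.5, 0.1, 3.0, 0, 0)]
    prof = reconstruct_free_energy(hills, np.linspace(0, 1, 101), params)
    assert prof.value_at(0.5) == pytest.approx(0.0)
    assert prof.value_at(0.0) == prof.f_values.max()


def test_hill_heights_bounded_and_tempered(shared_metascore):
    _, result = shared_metascore
    params = TOY_METAD_PARAMS
    heights = np.array([h.height for h in result.hills])
    assert np.all(heights > 0) and np.all(heights <= params.h0)
    centers = np.array([h.center_s for h in result.hills])
    # at a repeatedly visited spot, heights never increase in deposit order
    bin_mask = np.abs(centers - 0.95) < 0.02
    seq = heights[bin_mask]
    if len(seq) > 3:
        assert seq[-1] <= seq[0] + 1e-12


@pytest.fixture(scope="module")
def shared_metascore():
    land = fixtures.make_binding_landscape(-5.0, 3.0)
    snaps = run_binding_path(land, seed=1)
    result = run_metascore(land, snaps, seed=101)
    return land, result


def test_metascore_result_invariants(shared_metascore):
    land, result = shared_metascore
    assert result.delta_g_bind == result.f_bound - result.f_unbound
    assert result.profile.f_values.min() == pytest.approx(0.0)
    assert len(result.hills) > 0
    with pytest.raises(ValueError):
        run_metascore(land, [], seed=1)


def test_metascore_invariant_under_constant_shift():
    land = fixtures.make_binding_landscape(-4.0, 3.0)
    shifted = fixtures.make_binding_landscape(-4.0, 3.0)
    shifted.offset = 7.5
    snaps = run_binding_path(land, seed=2)
    quick = WTMetaDParameters(h0=0.015, steps_per_walker=4000, deposit_stride=100)
    a = run_metascore(land, snaps, quick, seed=5)
    b = run_metascore(shifted, snaps, quick, seed=5)
    assert abs(a.delta_g_bind - b.delta_g_bind) < 1e-9


def test_shared_hills_split_across_walker_counts():
    """The same total sampling split over 2 vs 102 walkers agrees to 1 kcal."""
    land = fixtures.make_binding_landscape(-5.0, 3.0)
    dgs = {2: [], 102: []}
    for seed in (1, 2, 3):
        snaps = run_binding_path(land, seed=seed)
        many = run_metascore(
            land, snaps,
            WTMetaDParameters(h0=0.015, steps_per_walker=8000, deposit_stride=100),
            seed=seed + 50,
        )
        few = run_metascore(
            land, [snaps[0], snaps[-1]],
            WTMetaDParameters(h0=0.015, steps_per_walker=8000 * 51,
                              deposit_stride=100),
            seed=seed + 50,
        )
        dgs[102].append(many.delta_g_bind)
        dgs[2].append(few.delta_g_bind)
    assert abs(np.mean(dgs[2]) - np.mean(dgs[102])) < 1.0


def test_compare_variants_identity_is_zero():
    land = fixtures.make_binding_landscape(-5.0, 3.0, perturbation=2.0)
    quick = WTMetaDParameters(h0=0.015, steps_per_walker=6000, deposit_stride=100)
    table = metadyn.compare_variants(
        land, {"reference": None, "same": None}, params=quick, seeds=(1,)
    )
    row = table[table["variant"] == "same"].iloc[0]
    assert row["ddg"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        metadyn.compare_variants(land, {"only": "mutant"}, params=quick, seeds=(1,))


def test_hills_ledger_round_trip(tmp_path, shared_metascore):
    _, result = shared_metascore
    params = TOY_METAD_PARAMS
    path = tmp_path / "HILLS"
    write_hills(result.hills[:25], params, path)
    back = read_hills(path)
    assert len(back) == 25
    for a, b in zip(result.hills[:25], back):
        assert b.center_s == pytest.approx(a.center_s, abs=1e-6)
        assert b.height == pytest.approx(a.height, abs=1e-6)
        assert b.walker_id == a.walker_id
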