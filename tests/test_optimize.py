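import numpy as np
import pytest

from letplan.optimize import (
    ObjectiveSpec,
    OptimizationError,
    dose_objective,
    initial_intensities,
    let_objective,
    letd_map,
    make_dose_objective,
    make_let_objective,
    make_robust_objective,
    plan_strategy,
    robust_objective,
    solve_plan,
)
from letplan.uncertainty import generate_scenarios, nominal_only

from conftest import make_random_influence, make_random_structures


def central_fd_gradient(objective, w, h):
    g = np.zeros_like(w)
    for j in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[j] += h
        wm[j] -= h
        g[j] = (objective(wp)[0] - objective(wm)[0]) / (2 * h)
    return g


def assert_gradient_matches(objective, w, rtol=1e-4):
    _, g = objective(w)
    h = 1e-6 * np.linalg.norm(w)
    g_fd = central_fd_gradient(objective, w, h)
    scale = np.maximum(np.abs(g_fd), np.abs(g)).max()
    assert scale > 0
    assert np.max(np.abs(g - g_fd)) / scale < rtol


# ---------------------------------------------------------------------------
# LETd map
# ---------------------------------------------------------------------------

def test_letd_single_beamlet_is_its_let():
    rng = np.random.default_rng(0)
    infl, D, L = make_random_influence(20, 1, rng, density=1.0)
    lmap = letd_map(np.array([2.0]), infl)
    assert np.allclose(lmap.let, L[:, 0])


def test_letd_two_beamlet_weighted_mean():
    from scipy import sparse

    from letplan.beamlets import InfluenceMatrices, SpotGrid

    D = sparse.csr_matrix(np.array([[1.0, 3.0]]))
    L = sparse.csr_matrix(np.array([[2.0, 4.0]]))
    spots = SpotGrid(np.array([0, 0]), np.zeros(2), np.zeros(2),
                     np.full(2, 50.0), 5.0, 5.0, 1)
    infl = InfluenceMatrices(D=D, L=L, scenario_id="nominal", spots=spots)
    lmap = letd_map(np.ones(2), infl)
    assert lmap.let[0] == pytest.approx(3.5)


@pytest.mark.parametrize("seed", range(5))
def test_letd_matches_dense_double_loop(seed):
    rng = np.random.default_rng(seed)
    infl, D, L = make_random_influence(200, 80, rng)
    w = rng.random(80)
    lmap = letd_map(w, infl)
    expected = np.zeros(200)
    for i in range(200):
        num = den = 0.0
        for j in range(80):
            num += D[i, j] * L[i, j] * w[j]
            den += D[i, j] * w[j]
        expected[i] = num / den if den > 0 else 0.0
    assert np.max(np.abs(lmap.let - expected)) < 1e-10


def test_letd_zero_dose_voxels_are_zero():
    rng = np.random.default_rng(3)
    infl, D, _ = make_random_influence(50, 10, rng, density=0.05)
    w = rng.random(10)
    lmap = letd_map(w, infl)
    dead = (D @ w) == 0
    assert np.all(lmap.let[dead] == 0.0)


def test_letd_rejects_negative_intensities():
    rng = np.random.default_rng(1)
    infl, _, _ = make_random_influence(10, 4, rng)
    with pytest.raises(OptimizationError):
        letd_map(np.array([1.0, -1.0, 0.0, 0.0]), infl)


def test_letd_scale_invariance():
    rng = np.random.default_rng(11)
    infl, _, _ = make_random_influence(100, 30, rng)
    w = rng.random(30)
    base = letd_map(w, infl).let
    for c in (0.1, 3.0, 1e4):
        assert np.allclose(letd_map(c * w, infl).let, base)


# ---------------------------------------------------------------------------
# dose objective
# ---------------------------------------------------------------------------

def test_dose_objective_zero_when_dose_equals_prescription():
    from scipy import sparse

    from letplan.beamlets import InfluenceMatrices, SpotGrid

    spec = ObjectiveSpec(prescription=54.0)
    n_vox, n_spots = 9, 3
    D = sparse.csr_matrix(np.ones((n_vox, n_spots)))
    spots = SpotGrid(np.zeros(n_spots, dtype=int), np.zeros(n_spots),
                     np.zeros(n_spots), np.full(n_spots, 50.0), 5.0, 5.0, 1)
    infl = InfluenceMatrices(D=D, L=D.copy(), scenario_id="nominal", spots=spots)
    structures = {"ctv": np.arange(3), "brainstem": np.arange(3, 6),
                  "spinal_cord": np.arange(6, 9)}
    w = np.full(n_spots, 54.0 / 1.1 / n_spots)  # dose == prescription everywhere
    f, g = dose_objective(w, infl, structures, spec)
    assert f == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(g, 0.0)


def test_oar_overdose_term_formula():
    """One OAR voxel exceeding its level by delta contributes p*delta^2/N."""
    from scipy import sparse

    from letplan.beamlets import InfluenceMatrices, SpotGrid

    spec = ObjectiveSpec(
        prescription=54.0,
        target_under_weight=0.0,
        target_over_weight=0.0,
        oar_weights={"brainstem": 7.0, "spinal_cord": 0.0},
    )
    # 1 target voxel (no weight), 4 brainstem voxels, one of which is hot
    D = np.zeros((6, 1))
    D[0, 0] = 1.0
    D[1, 0] = (60.0 + 5.0) / 1.1  # exceeds the 60 Gy(RBE) level by 5
    spots = SpotGrid(np.array([0]), np.zeros(1), np.zeros(1),
                     np.array([50.0]), 5.0, 5.0, 1)
    infl = InfluenceMatrices(D=sparse.csr_matrix(D), L=sparse.csr_matrix(D),
                             scenario_id="nominal", spots=spots)
    structures = {"ctv": np.array([0]), "brainstem": np.arange(1, 5),
                  "spinal_cord": np.array([5])}
    f, _ = dose_objective(np.ones(1), infl, structures, spec)
    assert f == pytest.approx(7.0 * 5.0**2 / 4.0)


@pytest.mark.parametrize("seed", range(3))
def test_dose_objective_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(seed)
    infl, _, _ = make_random_influence(50, 20, rng)
    structures = make_random_structures(50, rng)
    spec = ObjectiveSpec()
    obj = make_dose_objective(infl, structures, spec)
    w = rng.random(20) * 40.0
    assert_gradient_matches(obj, w)


# ---------------------------------------------------------------------------
# LET objective
# ---------------------------------------------------------------------------

def test_let_objective_reduces_to_dose_objective_when_phi_zero():
    rng = np.random.default_rng(4)
    infl, _, _ = make_random_influence(60, 25, rng)
    structures = make_random_structures(60, rng)
    w = rng.random(25) * 30.0
    f_d, g_d = dose_objective(w, infl, structures, ObjectiveSpec())
    f_l, g_l = let_objective(w, infl, structures,
                             ObjectiveSpec(phi_t=0.0, phi_o=0.0))
    assert f_l == pytest.approx(f_d)
    assert np.allclose(g_l, g_d)


def test_raising_phi_t_lowers_objective():
    rng = np.random.default_rng(5)
    infl, _, _ = make_random_influence(60, 25, rng)
    structures = make_random_structures(60, rng)
    w = rng.random(25) * 30.0
    f_lo, _ = let_objective(w, infl, structures, ObjectiveSpec(phi_t=1.0))
    f_hi, _ = let_objective(w, infl, structures, ObjectiveSpec(phi_t=10.0))
    assert f_hi < f_lo


@pytest.mark.parametrize("seed", range(3))
def test_let_objective_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(seed + 10)
    infl, _, _ = make_random_influence(50, 20, rng)
    structures = make_random_structures(50, rng)
    obj = make_let_objective(infl, structures,
                             ObjectiveSpec(phi_t=5.0, phi_o=3.0))
    w = rng.random(20) * 40.0 + 1.0
    assert_gradient_matches(obj, w)


# ---------------------------------------------------------------------------
# robust objective
# ---------------------------------------------------------------------------

def _random_scenario_influences(rng, n_scen=9, n_vox=40, n_spots=15):
    return [make_random_influence(n_vox, n_spots, rng)[0] for _ in range(n_scen)]


def test_robust_with_single_scenario_equals_nominal():
    rng = np.random.default_rng(6)
    infl, _, _ = make_random_influence(40, 15, rng)
    structures = make_random_structures(40, rng)
    spec = ObjectiveSpec()
    w = rng.random(15) * 30.0
    f_n, g_n = dose_objective(w, infl, structures, spec)
    f_r, g_r = robust_objective(w, [infl], structures, spec)
    assert f_r == pytest.approx(f_n)
    assert np.allclose(g_r, g_n)


def test_robust_dominates_nominal_member():
    rng = np.random.default_rng(7)
    infls = _random_scenario_influences(rng)
    structures = make_random_structures(40, rng)
    spec = ObjectiveSpec()
    w = rng.random(15) * 30.0
    f_nom, _ = dose_objective(w, infls[0], structures, spec)
    f_rob, _ = robust_objective(w, infls, structures, spec)
    assert f_rob >= f_nom - 1e-12


def test_robust_equals_explicit_per_term_enumeration():
    """Objective-wise worst case == brute-force per-term max over scenarios."""
    rng = np.random.default_rng(8)
    infls = _random_scenario_influences(rng)
    structures = make_random_structures(40, rng)
    spec = ObjectiveSpec()
    w = rng.random(15) * 30.0
    f_rob, _ = robust_objective(w, infls, structures, spec)

    def term_values(infl):
        out = []
        d_t = 1.1 * (infl.D[structures["ctv"]] @ w)
        nt = structures["ctv"].size
        out.append(spec.target_under_weight / nt
                   * np.sum(np.maximum(0, spec.prescription - d_t) ** 2))
        out.append(spec.target_over_weight / nt
                   * np.sum(np.maximum(0, d_t - spec.prescription) ** 2))
        for name, level in spec.oar_limits.items():
            d_o = 1.1 * (infl.D[structures[name]] @ w)
            no = structures[name].size
            out.append(spec.oar_weights[name] / no
                       * np.sum(np.maximum(0, d_o - level) ** 2))
        return np.array(out)

    expected = np.max(np.stack([term_values(i) for i in infls]), axis=0).sum()
    assert f_rob == pytest.approx(expected, rel=1e-12)


def test_robust_gradient_matches_finite_differences():
    rng = np.random.default_rng(9)
    infls = _random_scenario_influences(rng)
    structures = make_random_structures(40, rng)
    obj = make_robust_objective(infls, structures, ObjectiveSpec())
    w = rng.random(15) * 30.0
    assert_gradient_matches(obj, w)


def test_robust_requires_scenarios():
    rng = np.random.default_rng(10)
    structures = make_random_structures(40, rng)
    with pytest.raises(OptimizationError):
        make_robust_objective([], structures, ObjectiveSpec())


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def test_solver_finds_separable_quadratic_minimizer():
    """min sum (w - t)^2 over w >= 0 has the closed form max(t, 0)."""
    t = np.array([3.0, -2.0, 0.5, 7.0, -0.1])

    def objective(w):
        r = w - t
        return float(r @ r), 2 * r

    plan = solve_plan(objective, np.ones(5), options={"ftol": 1e-16,
                                                      "gtol": 1e-12})
    assert np.max(np.abs(plan.w - np.maximum(t, 0.0))) < 1e-6
    assert np.all(plan.w >= 0)


def test_solver_history_monotone_and_never_worse_than_start():
    rng = np.random.default_rng(12)
    infl, _, _ = make_random_influence(50, 20, rng)
    structures = make_random_structures(50, rng)
    obj = make_dose_objective(infl, structures, ObjectiveSpec())
    w0 = np.full(20, 5.0)
    plan = solve_plan(obj, w0, options={"track_history": True})
    hist = np.array(plan.objective_history)
    assert hist[-1] <= hist[0]
    assert np.all(np.diff(np.minimum.accumulate(hist)) <= 1e-9)


def test_solver_rejects_bad_start():
    def objective(w):
        return np.nan, np.zeros_like(w)

    with pytest.raises(OptimizationError):
        solve_plan(objective, np.ones(3))
    with pytest.raises(OptimizationError):
        solve_plan(lambda w: (0.0, 0 * w), -np.ones(3))


# ---------------------------------------------------------------------------
# plan_strategy on the small phantom
# ---------------------------------------------------------------------------

def test_let_strategy_with_zero_phi_matches_nominal(small_grid, small_beams,
                                                    small_spots,
                                                    small_influence, small_rows):
    spec = ObjectiveSpec(phi_t=0.0, phi_o=0.0)
    shared = {"nominal": small_influence}
    opts = {"maxiter": 40}
    kw = dict(scenario_set=nominal_only(), spots=small_spots,
              influences=shared, rows=small_rows, solver_options=opts)
    p_nom = plan_strategy("nominal", small_grid, small_beams, spec, **kw)
    p_let = plan_strategy("let", small_grid, small_beams, spec, **kw)
    assert np.allclose(p_nom.w, p_let.w)
    assert p_nom.objective_history == p_let.objective_history


def test_robust_strategy_uses_all_scenarios(small_grid, small_beams,
                                            small_spots, small_rows):
    scen = generate_scenarios()
    shared = {}
    spec = ObjectiveSpec()
    plan_strategy("robust", small_grid, small_beams, spec,
                  scenario_set=scen, spots=small_spots, influences=shared,
                  rows=small_rows, solver_options={"maxiter": 5})
    assert len(shared) == 9
    shared_nom = {}
    plan_strategy("nominal", small_grid, small_beams, spec,
                  scenario_set=scen, spots=small_spots, influences=shared_nom,
                  rows=small_rows, solver_options={"maxiter": 5})
    assert len(shared_nom) == 1


def test_initial_intensities_hit_mean_prescription(small_influence,
                                                   small_structures):
    spec = ObjectiveSpec()
    w0 = initial_intensities(small_influence, small_structures, spec)
    mean_dose = 1.1 * (small_influence.D[small_structures["ctv"]] @ w0).mean()
    assert mean_dose == pytest.approx(spec.prescription)
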