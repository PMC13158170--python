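"""Dual-LP assembly, preconditioning, parameter heuristics, and duality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from paretoplan import (
    SliderMap,
    WeightVector,
    bot_column_scaling,
    normalize_rows,
    rho_heuristic,
    scale_bot_columns,
    set_weights,
    sliders_to_weights,
    weights_to_bounds,
)
from paretoplan.lp_build import RhoRule, assemble_dual_lp, slider_grid
from paretoplan.metrics_oracle import solve_lp_exact

from conftest import preconditioned, random_planning_lp


# ---------------------------------------------------------------------------
# shapes and index maps
# ---------------------------------------------------------------------------


def test_minimal_shape_one_isocenter_one_point():
    lp = assemble_dual_lp(
        {"target": np.ones((1, 24))},
        {"target": np.array([20.0])},
        n_iso=1,
        d_ld=10.0,
    )
    assert lp.A.shape == (25, 1 + 8)


@pytest.mark.parametrize(
    "n_iso,n_points,expected",
    [
        (53, 4123, (1325, 4547)),  # clinical ME01 dimensions
        (17, 3910, (425, 4046)),  # clinical VS01 dimensions
        (3, 40, (75, 64)),
    ],
)
def test_shape_law_25_rows_and_8_extra_columns_per_isocenter(n_iso, n_points, expected):
    """m = 25 * n_iso and n = N_points + 8 * n_iso."""
    rng = np.random.default_rng(0)
    n_t = n_points - 30
    lp = assemble_dual_lp(
        {
            "target": rng.uniform(0, 1, (n_t, 24 * n_iso)),
            "shell": rng.uniform(0, 1, (20, 24 * n_iso)),
            "low-dose": rng.uniform(0, 1, (10, 24 * n_iso)),
        },
        {"target": np.full(n_t, 20.0), "shell": np.full(20, 20.0)},
        n_iso=n_iso,
        d_ld=10.0,
    )
    assert lp.A.shape == expected


def test_cost_vector_signs_follow_dose_levels():
    rng = np.random.default_rng(1)
    lp = random_planning_lp(rng, d_presc=20.0, d_ld=10.0, d_oar=12.0)
    assert np.all(lp.c[lp.col_slices["target"]] == -20.0)
    assert np.all(lp.c[lp.col_slices["shell"]] == 20.0)
    assert np.all(lp.c[lp.col_slices["low-dose"]] == 10.0)
    assert np.all(lp.c[lp.col_slices["oar"]] == 12.0)
    assert np.all(lp.c[lp.col_slices["mu"]] == 0.0)


def test_assembly_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        assemble_dual_lp({"target": np.empty((0, 24))}, {"target": np.empty(0)}, 1, 10.0)
    with pytest.raises(ValueError):
        assemble_dual_lp({"target": np.ones((1, 24))}, {"target": np.array([20.0])}, 0, 10.0)


# ---------------------------------------------------------------------------
# weights -> bounds
# ---------------------------------------------------------------------------


def test_alpha_upper_bounds_are_wT_over_NT():
    rng = np.random.default_rng(2)
    lp = normalize_rows(random_planning_lp(rng, n_t=100))
    w = WeightVector(wT=1.0, wS=1.0, wLD=1.0, wBOT=1.0)
    b, u = weights_to_bounds(w, lp)
    assert np.allclose(u[lp.col_slices["target"]], 0.01)
    assert np.isinf(u[lp.col_slices["oar"]]).all()
    assert np.isinf(u[lp.col_slices["mu"]]).all()
    # b carries wBOT on shot-time rows only (scaled by row norms)
    assert np.allclose(b[lp.t_rows], 0.0)
    assert np.all(b[lp.tau_rows] > 0)


def test_nonpositive_weights_rejected():
    with pytest.raises(ValueError):
        WeightVector(wT=1.0, wS=1.0, wLD=0.0, wBOT=1.0)


def test_weight_scaling_leaves_recovered_plan_unchanged():
    """Scaling all four weights scales the LP optimum but not the plan."""
    rng = np.random.default_rng(3)
    base = normalize_rows(random_planning_lp(rng))
    w1 = WeightVector(wT=1.0, wS=1.0, wLD=0.5, wBOT=0.3)
    lam = 7.0
    w2 = WeightVector(wT=lam, wS=lam, wLD=0.5 * lam, wBOT=0.3 * lam)
    lp1 = set_weights(base, [w1], RhoRule(w0_bot=0.3))
    lp2 = set_weights(base, [w2], RhoRule(w0_bot=0.3 * lam))
    r1, r2 = solve_lp_exact(lp1, 0), solve_lp_exact(lp2, 0)
    assert r2.objective == pytest.approx(lam * r1.objective, rel=1e-6)
    np.testing.assert_allclose(r2.plan.t, r1.plan.t, atol=1e-9 * max(1.0, r1.plan.t.max()))
    np.testing.assert_allclose(r2.plan.tau, r1.plan.tau, atol=1e-9 * max(1.0, r1.plan.tau.max()))


# ---------------------------------------------------------------------------
# sliders
# ---------------------------------------------------------------------------


def test_slider_endpoints_hit_weight_ranges():
    m = SliderMap()
    w00 = m(0.0, 0.0)
    w11 = m(1.0, 1.0)
    assert w00.wT == w00.wS == m.scale
    assert w00.wLD == pytest.approx(m.scale * m.wld_range[0])
    assert w00.wBOT == pytest.approx(m.w0_bot)
    assert w11.wLD == pytest.approx(m.scale * m.wld_range[1])
    assert w11.wBOT == pytest.approx(m.scale * m.wbot_range[1])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(s=st.floats(0.0, 1.0), ds=st.floats(0.01, 0.5))
def test_wbot_strictly_increasing_in_slider(s, ds):
    m = SliderMap()
    hi = min(1.0, s + ds)
    if hi > s:
        assert m(0.3, hi).wBOT > m(0.3, s).wBOT


def test_out_of_range_slider_rejected():
    with pytest.raises(ValueError):
        sliders_to_weights(-0.1, 0.5)
    with pytest.raises(ValueError):
        sliders_to_weights(0.5, 1.2)


def test_grid_parsing_21x21_gives_441_vectors():
    assert len(slider_grid("21x21")) == 441
    assert len(slider_grid("3x3")) == 9


# ---------------------------------------------------------------------------
# preconditioning
# ---------------------------------------------------------------------------


def test_row_normalization_example_and_schur_diagonal():
    """[[3, 4]] normalizes to [[0.6, 0.8]]; S = A A^T + I has diagonal 2."""
    norms = np.linalg.norm(np.array([[3.0, 4.0]]), axis=1)
    assert np.allclose(np.array([[3.0, 4.0]]) / norms[:, None], [[0.6, 0.8]])

    rng = np.random.default_rng(4)
    lp = normalize_rows(random_planning_lp(rng))
    S = lp.A @ lp.A.T + np.eye(lp.m)
    assert np.allclose(np.diag(S), 2.0, atol=1e-12)
    off = S - np.diag(np.diag(S))
    assert off.min() >= -1.0 - 1e-12 and off.max() <= 1.0 + 1e-12


def test_zero_row_rejected_with_row_name():
    lp = assemble_dual_lp(
        {"target": np.ones((2, 24))}, {"target": np.full(2, 20.0)}, 1, 10.0
    )
    lp.A[3, :] = 0.0
    with pytest.raises(ValueError, match="row 3"):
        normalize_rows(lp)


@pytest.mark.parametrize("n_points,expected", [(2000, 1.0), (40000, 20.0), (1000, 0.5)])
def test_bot_column_scaling_values(n_points, expected):
    assert bot_column_scaling(n_points) == pytest.approx(expected)


def test_bot_column_scaling_excludes_oar_points():
    counts = {"target": 900, "shell": 600, "low-dose": 500, "oar": 400}
    assert bot_column_scaling(counts) == pytest.approx(1.0)


def test_preconditioning_is_an_equivalence_transform():
    """Oracle plans agree before/after row normalization + beta scaling."""
    rng = np.random.default_rng(5)
    raw = random_planning_lp(rng)
    w = WeightVector(wT=1.0, wS=1.0, wLD=0.5, wBOT=0.3)
    rule = RhoRule(w0_bot=0.3)
    plain = solve_lp_exact(set_weights(raw, [w], rule), 0)
    pre = solve_lp_exact(
        set_weights(scale_bot_columns(normalize_rows(raw), 2.5), [w], rule), 0
    )
    assert pre.plan.objective == pytest.approx(plain.plan.objective, rel=1e-5)
    np.testing.assert_allclose(pre.plan.t, plain.plan.t, atol=1e-7 * max(1.0, plain.plan.t.max()))


# ---------------------------------------------------------------------------
# rho heuristic
# ---------------------------------------------------------------------------


def test_rho_heuristic_values():
    assert rho_heuristic(0.01, 0.01) == pytest.approx(2.5e-3)
    assert rho_heuristic(0.02, 0.01) == pytest.approx(1.25e-3)
    assert rho_heuristic(0.1, 0.01) == pytest.approx(2.5e-4)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(w0=st.floats(1e-4, 1.0), fac=st.floats(1.0, 1e4))
def test_rho_positive_and_nonincreasing_in_wbot(w0, fac):
    assert rho_heuristic(w0 * fac, w0) > 0
    assert rho_heuristic(w0 * fac, w0) <= rho_heuristic(w0, w0)


def test_rho_heuristic_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rho_heuristic(-1.0, 0.01)
    with pytest.raises(ValueError):
        rho_heuristic(0.005, 0.01)  # below lowest allowed


# ---------------------------------------------------------------------------
# duality audit
# ---------------------------------------------------------------------------


def _explicit_primal(lp, w: WeightVector):
    """Build the weighted-sum planning LP directly (independent oracle)."""
    n_iso = lp.n_iso
    phi_t = lp.influences["target"]
    phi_s = lp.influences["shell"]
    phi_ld = lp.influences["low-dose"]
    phi_oar = lp.influences["oar"]
    n_t, n_s, n_ld, n_oar = (len(x) for x in (phi_t, phi_s, phi_ld, phi_oar))
    nt = 24 * n_iso
    nv = nt + n_iso + n_t + n_s + n_ld
    c = np.zeros(nv)
    c[nt : nt + n_iso] = w.wBOT
    c[nt + n_iso : nt + n_iso + n_t] = w.wT / n_t
    c[nt + n_iso + n_t : nt + n_iso + n_t + n_s] = w.wS / n_s
    c[nt + n_iso + n_t + n_s :] = w.wLD / n_ld
    rows, rhs = [], []
    for p in range(n_t):  # -dose - slack <= -D_presc
        r = np.zeros(nv)
        r[:nt] = -phi_t[p]
        r[nt + n_iso + p] = -1
        rows.append(r)
        rhs.append(-lp.levels["target"][p])
    for p in range(n_s):
        r = np.zeros(nv)
        r[:nt] = phi_s[p]
        r[nt + n_iso + n_t + p] = -1
        rows.append(r)
        rhs.append(lp.levels["shell"][p])
    for p in range(n_ld):
        r = np.zeros(nv)
        r[:nt] = phi_ld[p]
        r[nt + n_iso + n_t + n_s + p] = -1
        rows.append(r)
        rhs.append(lp.d_ld)
    for p in range(n_oar):
        r = np.zeros(nv)
        r[:nt] = phi_oar[p]
        rows.append(r)
        rhs.append(lp.levels["oar"][p])
    for i in range(n_iso):
        for s in range(8):
            r = np.zeros(nv)
            r[24 * i + 3 * s : 24 * i + 3 * s + 3] = 1
            r[nt + i] = -1
            rows.append(r)
            rhs.append(0.0)
    return linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                   bounds=[(0, None)] * nv, method="highs")


def test_strong_duality_against_explicit_primal():
    """-min of the dual LP equals the min of the directly built primal."""
    rng = np.random.default_rng(6)
    for k in range(3):
        raw = random_planning_lp(rng, n_iso=2, n_t=5 + k, n_s=4, n_ld=3, n_oar=2)
        w = WeightVector(wT=1.0, wS=1.0, wLD=rng.uniform(0.2, 2), wBOT=rng.uniform(0.1, 1))
        lp = set_weights(raw, [w], RhoRule(w0_bot=w.wBOT))
        dual = solve_lp_exact(lp, 0)
        primal = _explicit_primal(lp, w)
        assert primal.status == 0
        assert -dual.objective == pytest.approx(primal.fun, rel=1e-6)
        # the plan recovered from the dual achieves the primal optimum
        assert dual.plan.objective == pytest.approx(primal.fun, rel=1e-6)
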