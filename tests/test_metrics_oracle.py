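"""Dose reconstruction, clinical metrics, Pareto table, and the LP oracle."""

from itertools import combinations

import numpy as np
import pytest

from paretoplan import (
    PlanSolution,
    WeightVector,
    compute_dose,
    pareto_table,
    plan_metrics,
    set_weights,
    solve_lp_exact,
)
from paretoplan.lp_build import RhoRule
from paretoplan.metrics_oracle import PlanMetrics, compare_to_oracle
from paretoplan.two_pass import evaluation_mask

from conftest import preconditioned, random_planning_lp


def _plan(case, t=None):
    n_iso = case.isocenters.count
    t = np.zeros((n_iso, 8, 3)) if t is None else t
    return PlanSolution(t=t, tau=t.sum(axis=2).max(axis=1), weights=None,
                        objective_terms={}, column=0)


# ---------------------------------------------------------------------------
# dose reconstruction
# ---------------------------------------------------------------------------


def test_zero_plan_zero_dose(tiny_case):
    pts = tiny_case.grid.voxel_centers(tiny_case.structures.target_union)[:50]
    dose = compute_dose(tiny_case.kernels, _plan(tiny_case), points=pts)
    assert np.all(dose == 0)


def test_single_kernel_unit_time_reproduces_kernel_field(tiny_case):
    n_iso = tiny_case.isocenters.count
    t = np.zeros((n_iso, 8, 3))
    t[0, 2, 1] = 1.0
    pts = tiny_case.grid.voxel_centers(tiny_case.structures.target_union)[:100]
    dose = compute_dose(tiny_case.kernels, _plan(tiny_case, t), points=pts)
    np.testing.assert_allclose(
        dose, tiny_case.kernels.dose_rate(pts, iso=0, sector=2, collimator=1), rtol=1e-12
    )


def test_region_restricted_dose_consistent(tiny_case):
    rng = np.random.default_rng(0)
    n_iso = tiny_case.isocenters.count
    t = rng.uniform(0, 1, (n_iso, 8, 3))
    em = evaluation_mask(tiny_case)
    pts = tiny_case.grid.voxel_centers(em)
    full = compute_dose(tiny_case.kernels, _plan(tiny_case, t), points=pts)
    sub = compute_dose(tiny_case.kernels, _plan(tiny_case, t), points=pts[::7])
    np.testing.assert_allclose(sub, full[::7], rtol=1e-12)


# ---------------------------------------------------------------------------
# clinical metrics
# ---------------------------------------------------------------------------


def test_perfect_plan_metrics(tiny_case):
    """Dose = prescription inside target, zero outside: coverage=selectivity=1."""
    em = evaluation_mask(tiny_case)
    inside = tiny_case.structures.target_union[em]
    dose = np.where(inside, tiny_case.structures.prescription_gy[0], 0.0)
    m = plan_metrics(tiny_case, dose, em, bot_minutes=12.0)
    assert m.coverage == 1.0
    assert m.selectivity == 1.0
    assert m.bot == 12.0


def test_gradient_index_of_radial_field(tiny_case):
    """Spherical dose field: GI equals (r50/r100)^3 up to voxelization."""
    em = evaluation_mask(tiny_case)
    centers = tiny_case.grid.voxel_centers(em)
    r = np.linalg.norm(centers, axis=1)
    d_p = tiny_case.structures.prescription_gy[0]
    r100, r50 = 8.0, 12.0
    # piecewise field: >= d_p inside r100, >= d_p/2 inside r50
    dose = np.where(r <= r100, d_p, np.where(r <= r50, 0.6 * d_p, 0.1 * d_p))
    m = plan_metrics(tiny_case, dose, em, bot_minutes=1.0)
    assert m.gradient_index == pytest.approx((r50 / r100) ** 3, rel=0.1)


def test_zero_dose_metrics_undefined(tiny_case):
    em = evaluation_mask(tiny_case)
    m = plan_metrics(tiny_case, np.zeros(int(em.sum())), em, bot_minutes=0.0)
    assert m.coverage == 0.0
    assert m.selectivity is None
    assert "selectivity" in m.reasons


def test_gradient_index_undefined_for_mixed_prescriptions(multi_case):
    em = evaluation_mask(multi_case)
    dose = np.full(int(em.sum()), 25.0)
    m = plan_metrics(multi_case, dose, em, bot_minutes=1.0)
    assert m.gradient_index is None
    assert "prescription" in m.reasons["gradient_index"]
    assert m.coverage == 1.0


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def test_oracle_toy_lp():
    from paretoplan.lp_build import DualLP

    lp = DualLP(
        c=np.array([-1.0]), A=np.array([[1.0]]), n_iso=0, col_slices={}, counts={},
        influences={}, levels={}, d_ld=1.0, B=np.ones((1, 1)), U=np.full((1, 1), 2.0),
    )
    lp.weights = []
    res = __import__("scipy.optimize", fromlist=["linprog"]).linprog(
        lp.c, A_ub=lp.A, b_ub=lp.B[:, 0], bounds=[(0, 2)], method="highs"
    )
    assert res.x[0] == pytest.approx(1.0)
    assert res.fun == pytest.approx(-1.0)
    # multiplier of the active row constraint recovers the primal variable
    assert -res.ineqlin.marginals[0] == pytest.approx(1.0)


def _enumerate_vertices(c, A, b, lo, hi):
    """Brute-force optimum over basic feasible points of a small LP."""
    m, n = A.shape
    rows = [(A[i], b[i]) for i in range(m)]
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        rows.append((e, hi[k]))
        rows.append((-e, -lo[k]))
    best = np.inf
    for idx in combinations(range(len(rows)), n):
        M = np.array([rows[i][0] for i in idx])
        rhs = np.array([rows[i][1] for i in idx])
        if abs(np.linalg.det(M)) < 1e-10:
            continue
        x = np.linalg.solve(M, rhs)
        if np.all(A @ x <= b + 1e-8) and np.all(x >= lo - 1e-8) and np.all(x <= hi + 1e-8):
            best = min(best, c @ x)
    return best


def test_oracle_matches_vertex_enumeration():
    """HiGHS optimum equals brute-force vertex enumeration on random LPs."""
    rng = np.random.default_rng(3)
    from scipy.optimize import linprog

    for _ in range(3):
        m, n = 4, 6
        A = rng.normal(size=(m, n))
        b = rng.uniform(0.5, 2.0, m)
        c = rng.normal(size=n)
        hi = rng.uniform(0.5, 2.0, n)
        res = linprog(c, A_ub=A, b_ub=b, bounds=list(zip(np.zeros(n), hi)), method="highs")
        assert res.status == 0
        best = _enumerate_vertices(c, A, b, np.zeros(n), hi)
        assert res.fun == pytest.approx(best, rel=1e-8, abs=1e-10)


def test_oracle_feasibility_on_planning_lp(small_lp):
    res = solve_lp_exact(small_lp, 0)
    assert res.check_feasible(small_lp, 0)
    assert res.status == "optimal"


def test_bot_term_monotone_in_wbot():
    """Across a wBOT sweep (others fixed), the oracle BOT term never increases."""
    rng = np.random.default_rng(5)
    raw = random_planning_lp(rng, n_iso=2, n_t=50, n_s=25, n_ld=15, n_oar=5)
    bots = []
    for wbot in [0.005, 0.02, 0.08, 0.2]:
        w = WeightVector(wT=1.0, wS=1.0, wLD=0.5, wBOT=wbot)
        lp = preconditioned(raw, [w])
        bots.append(solve_lp_exact(lp, 0).plan.bot)
    assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(bots, bots[1:]))


# ---------------------------------------------------------------------------
# comparisons and Pareto table
# ---------------------------------------------------------------------------


def test_compare_to_oracle_zero_for_identical_plans(small_lp):
    o = [solve_lp_exact(small_lp, j).plan for j in range(2)]
    rep = compare_to_oracle(o, o)
    assert np.allclose(rep["rel_err_total"], 0.0)
    assert np.allclose(rep["rel_err_bot"], 0.0)


def test_compare_rejects_mismatched_instances(small_lp):
    a = solve_lp_exact(small_lp, 0).plan
    b = solve_lp_exact(small_lp, 1).plan
    b.fingerprint = ("other",)
    with pytest.raises(ValueError, match="different LP instances"):
        compare_to_oracle([a], [b])


def _pm(cov, sel, gi, bot, s=(0.0, 0.0)):
    return PlanMetrics(coverage=cov, selectivity=sel, gradient_index=gi, bot=bot,
                       reasons={}, sliders=s)


def test_pareto_single_plan_nondominated():
    df = pareto_table([_pm(0.9, 0.9, 2.5, 20.0)])
    assert not df["dominated"].iloc[0]


def test_pareto_flags_strictly_worse_plan():
    a = _pm(0.95, 0.95, 2.0, 15.0, (0.0, 0.0))
    b = _pm(0.90, 0.90, 2.5, 20.0, (0.5, 0.5))
    df = pareto_table([a, b])
    assert not df["dominated"].iloc[0]
    assert df["dominated"].iloc[1]


def test_pareto_skips_undefined_metrics():
    a = _pm(0.95, None, None, 15.0)
    b = _pm(0.90, None, None, 20.0)
    df = pareto_table([a, b])
    assert df["dominated"].tolist() == [False, True]


# ---------------------------------------------------------------------------
# sampling-noise spread: ADMM vs oracle (scaled replica of the rerun protocol)
# ---------------------------------------------------------------------------


def test_metric_spread_of_admm_matches_oracle(tiny_case):
    """Re-sampling dose points several times, the spread of the ADMM
    clinical metrics is statistically indistinguishable from the spread
    of the exact-solver metrics (dispersion test at alpha = 0.01).

    Scaled replica: one small case, a 3x3 slider grid, 5 re-samplings
    per solver, 1000 iterations per pass.
    """
    from scipy.stats import fligner

    from paretoplan.two_pass import SolverConfig, evaluation_mask, run_two_pass

    eval_inf = tiny_case.kernels.influence(
        tiny_case.grid.voxel_centers(evaluation_mask(tiny_case)), dtype=np.float32
    )
    n_rerun = 5
    metric_names = ["coverage", "selectivity", "gradient_index", "bot"]
    values = {s: {m: [] for m in metric_names} for s in ("admm", "oracle")}
    for rerun in range(n_rerun):
        for solver in ("admm", "oracle"):
            cfg = SolverConfig(n_iter=1000, seed=100 + rerun)
            res = run_two_pass(tiny_case, "3x3", cfg, eval_influence=eval_inf, solver=solver)
            for j, m in enumerate(res.metrics):
                d = m.as_dict()
                for name in metric_names:
                    values[solver][name].append((j, d[name]))

    for name in metric_names:
        pooled = {}
        for solver in ("admm", "oracle"):
            arr = {}
            for j, v in values[solver][name]:
                if v is not None:
                    arr.setdefault(j, []).append(v)
            # normalize by the oracle mean per weight vector, pool over wv
            devs = []
            for j, vs in arr.items():
                ref = np.mean([v for jj, v in values["oracle"][name] if jj == j and v is not None])
                devs.extend([(v - ref) / ref for v in vs])
            pooled[solver] = np.asarray(devs)
        stat, p = fligner(pooled["admm"], pooled["oracle"])
        assert p > 0.01, f"{name}: dispersion differs (p={p:.4f})"
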