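"""Dose reconstruction, clinical plan metrics, Pareto tables, and the
exact linear-program oracle used for quantitative validation.

The oracle solves the very same (preconditioned) dual LP instances with
an exact method (HiGHS through :func:`scipy.optimize.linprog`) and
recovers the plan through the same un-scaling path as the ADMM solver,
so objective and metric comparisons are apples to apples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .admm_core import PlanSolution, recover_from_row_duals
from .case_synth import SyntheticCase
from .lp_build import DualLP

__all__ = [
    "PlanMetrics",
    "OracleResult",
    "compute_dose",
    "plan_metrics",
    "solve_lp_exact",
    "compare_to_oracle",
    "pareto_table",
]


@dataclass
class PlanMetrics:
    """Clinical plan metrics; undefined metrics are None with a reason code.

    coverage    fraction of the target volume receiving at least the
                prescription dose;
    selectivity fraction of the prescription isodose volume (PIV) inside
                the target (None when the PIV is empty);
    gradient_index  volume receiving at least half the prescription
                divided by the PIV (None when prescriptions differ
                between targets or the PIV is empty);
    bot         beam-on time in minutes at the calibration dose rate.
    """

    coverage: float
    selectivity: float | None
    gradient_index: float | None
    bot: float
    reasons: dict[str, str]
    sliders: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "selectivity": self.selectivity,
            "gradient_index": self.gradient_index,
            "bot": self.bot,
        }


def compute_dose(
    kernels,
    plan: PlanSolution,
    points: np.ndarray | None = None,
    influence: np.ndarray | None = None,
) -> np.ndarray:
    """Dose (Gy) delivered by a plan at arbitrary points.

    ``dose(p) = sum_{i,s,c} kernel_{i,s,c}(p) * t(i,s,c)``.  Passing a
    precomputed ``influence`` matrix for the points avoids re-evaluating
    the kernels (the kernels argument may then be None).
    """
    t = np.asarray(plan.t_flat, dtype=np.float64)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("plan sector times must be finite and nonnegative")
    if influence is None:
        if points is None:
            raise ValueError("either points or influence must be given")
        influence = kernels.influence(points)
    return influence.astype(np.float64) @ t


def plan_metrics(
    case: SyntheticCase,
    dose: np.ndarray,
    region_mask: np.ndarray,
    bot_minutes: float,
    sliders: tuple[float, float] | None = None,
) -> PlanMetrics:
    """Clinical metrics of a dose distribution given on ``region_mask`` voxels.

    The region must contain the targets and the half-prescription
    isodose; dose outside the region is treated as below all thresholds.
    """
    st = case.structures
    if not st.target_union.any():
        raise ValueError("case has no target voxels")
    region_idx = np.argwhere(region_mask)
    if len(region_idx) != len(dose):
        raise ValueError("dose vector not conformable with region mask")
    prescriptions = list(st.prescription_gy)
    reasons: dict[str, str] = {}

    dose_grid = np.zeros(case.grid.shape)
    dose_grid[region_mask] = dose

    # coverage: per-target prescription; aggregate over the target union
    covered = 0
    total = 0
    piv = np.zeros(case.grid.shape, dtype=bool)
    target_piv_overlap = 0
    for t_mask, d_p in zip(st.targets, prescriptions):
        covered += int((dose_grid[t_mask] >= d_p).sum())
        total += int(t_mask.sum())
    coverage = covered / total

    if len(set(prescriptions)) == 1:
        d_p = prescriptions[0]
        piv = region_mask & (dose_grid >= d_p)
        piv_size = int(piv.sum())
        target_piv_overlap = int((piv & st.target_union).sum())
        if piv_size == 0:
            selectivity = None
            reasons["selectivity"] = "empty prescription isodose volume"
            gradient_index = None
            reasons["gradient_index"] = "empty prescription isodose volume"
        else:
            selectivity = target_piv_overlap / piv_size
            v50 = int((region_mask & (dose_grid >= 0.5 * d_p)).sum())
            gradient_index = v50 / piv_size
    else:
        # per-target PIVs with their own prescriptions for selectivity
        piv_sizes = 0
        for t_mask, d_p in zip(st.targets, prescriptions):
            piv_k = region_mask & (dose_grid >= d_p)
            piv_sizes += int(piv_k.sum())
            target_piv_overlap += int((piv_k & t_mask).sum())
        selectivity = target_piv_overlap / piv_sizes if piv_sizes else None
        if piv_sizes == 0:
            reasons["selectivity"] = "empty prescription isodose volume"
        gradient_index = None
        reasons["gradient_index"] = "prescription doses differ between targets"

    return PlanMetrics(
        coverage=coverage,
        selectivity=selectivity,
        gradient_index=gradient_index,
        bot=float(bot_minutes),
        reasons=reasons,
        sliders=sliders,
    )


@dataclass
class OracleResult:
    """Exact solution of one dual-LP instance."""

    x: np.ndarray
    objective: float
    row_duals: np.ndarray  # multipliers of A x <= b (>= 0)
    plan: PlanSolution
    status: str

    def check_feasible(self, lp: DualLP, j: int, tol: float = 1e-8) -> bool:
        ax = lp.A @ self.x
        return bool(
            np.all(ax <= lp.B[:, j] + tol)
            and np.all(self.x >= -tol)
            and np.all(self.x <= lp.U[:, j] + tol)
        )


def solve_lp_exact(lp: DualLP, j: int = 0) -> OracleResult:
    """Solve instance ``j`` of the dual LP exactly (HiGHS) and recover the plan.

    The plan is obtained from the LP's constraint duals through the same
    un-scaling used for the ADMM solution, so the two solvers are
    compared on identical footing.
    """
    if lp.B is None:
        raise ValueError("LP has no bound columns; call set_weights first")
    res = linprog(
        lp.c,
        A_ub=lp.A,
        b_ub=lp.B[:, j],
        bounds=lp.bounds(j),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"oracle LP solve failed with status {res.status}: {res.message}")
    lam = -np.asarray(res.ineqlin.marginals)  # >= 0 multipliers of Ax <= b
    plan = recover_from_row_duals(lam, lp, j)
    return OracleResult(
        x=np.asarray(res.x),
        objective=float(res.fun),
        row_duals=lam,
        plan=plan,
        status="optimal",
    )


def compare_to_oracle(
    admm_plans: list[PlanSolution],
    oracle_plans: list[PlanSolution],
) -> pd.DataFrame:
    """Per-instance relative errors of the ADMM plan against the oracle plan.

    Both plan lists must come from the exact same LP instances (checked
    through the instance fingerprint).  Errors are
    ``|term_admm - term_oracle| / term_oracle`` for the total objective
    and the beam-on-time term, plus the per-term absolute differences.
    """
    if len(admm_plans) != len(oracle_plans):
        raise ValueError("plan lists differ in length")
    rows = []
    for a, o in zip(admm_plans, oracle_plans):
        if a.fingerprint != o.fingerprint:
            raise ValueError("plans come from different LP instances")
        tot_o = o.objective
        bot_o = o.objective_terms["bot"]
        rows.append(
            {
                "column": a.column,
                "sliders": a.weights.sliders if a.weights else None,
                "objective_admm": a.objective,
                "objective_oracle": tot_o,
                "rel_err_total": abs(a.objective - tot_o) / abs(tot_o),
                "rel_err_bot": (
                    abs(a.objective_terms["bot"] - bot_o) / bot_o if bot_o > 0 else 0.0
                ),
                "bot_admm_min": a.bot,
                "bot_oracle_min": o.bot,
            }
        )
    return pd.DataFrame(rows)


def pareto_table(metrics: list[PlanMetrics]) -> pd.DataFrame:
    """Tabulate metrics over the slider grid and flag dominated plans.

    A plan is dominated if another plan is at least as good in every
    defined metric (higher coverage and selectivity, lower gradient
    index and beam-on time) and strictly better in one.  Comparisons
    skip metrics that are undefined for either plan.
    """
    if not metrics:
        raise ValueError("at least one plan required")
    df = pd.DataFrame(
        [
            {
                "s_ld": (m.sliders[0] if m.sliders else np.nan),
                "s_bot": (m.sliders[1] if m.sliders else np.nan),
                **m.as_dict(),
            }
            for m in metrics
        ]
    )

    def _key(m: PlanMetrics):
        return (
            -m.coverage,
            -(m.selectivity if m.selectivity is not None else np.nan),
            m.gradient_index if m.gradient_index is not None else np.nan,
            m.bot,
        )

    keys = [np.asarray(_key(m), dtype=float) for m in metrics]
    dominated = np.zeros(len(metrics), dtype=bool)
    for i in range(len(metrics)):
        for j in range(len(metrics)):
            if i == j:
                continue
            ki, kj = keys[i], keys[j]
            ok = ~(np.isnan(ki) | np.isnan(kj))
            if ok.any() and np.all(kj[ok] <= ki[ok]) and np.any(kj[ok] < ki[ok]):
                dominated[i] = True
                break
    df["dominated"] = dominated
    return df
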