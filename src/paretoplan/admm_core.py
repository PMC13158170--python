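"""Batched ADMM solver for box/half-space constrained linear programs.

Solves ``min c^T x  s.t.  A x <= b, l <= x <= u`` for many bound columns
(B, U) at once.  The operator splitting introduces copies (z1, z2) of
(x1, x2 = A x1) and alternates

    1. a coupled least-squares step, reduced via the cached inverse of
       the Schur complement ``S = A A^T + I`` to one matrix product,
    2. element-wise clipping of z1 to [l, u] and z2 to (-inf, b],
    3. a scaled dual ascent on (y1, y2) with step size rho.

All per-iteration work is matrix products, additions and clips, so the
K weight-vector instances (which share A and differ only in their
bounds and rho) are advanced simultaneously as matrix columns.  The
iterations run in single precision by default; the Schur inverse is
always formed in double precision first.  The primal treatment plan is
recovered from the converged scaled dual variable as ``rho * y2``,
un-scaled through the preconditioner record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lp_build import DualLP, WeightVector

__all__ = [
    "SchurOperator",
    "ADMMState",
    "ADMMResult",
    "PlanSolution",
    "precompute_schur",
    "admm_step",
    "solve_batch",
    "recover_primal",
    "recover_from_row_duals",
]

_DTYPES = {"single": np.float32, "double": np.float64}


@dataclass
class SchurOperator:
    """Cached inverse of ``S = A A^T + I``, built in double precision."""

    S: np.ndarray
    inverse: np.ndarray
    build_residual: float

    @classmethod
    def build(cls, A: np.ndarray) -> "SchurOperator":
        A = np.asarray(A, dtype=np.float64)
        if not np.all(np.isfinite(A)):
            raise ValueError("constraint matrix contains non-finite entries")
        m = A.shape[0]
        S = A @ A.T + np.eye(m)
        inv = np.linalg.inv(S)
        resid = float(np.abs(S @ inv - np.eye(m)).max())
        if resid > 1e-8:
            raise ValueError(f"Schur inverse residual {resid:.2e} exceeds 1e-8")
        return cls(S=S, inverse=inv, build_residual=resid)

    def condition_number(self) -> float:
        """2-norm condition number of S (computed on demand; S is SPD)."""
        ev = np.linalg.eigvalsh(self.S)
        return float(ev[-1] / ev[0])

    def cast(self, dtype) -> np.ndarray:
        return self.inverse.astype(dtype, copy=False)


def precompute_schur(A: np.ndarray) -> SchurOperator:
    """Build and cache the Schur operator for a (shared) constraint matrix."""
    return SchurOperator.build(A)


@dataclass
class ADMMState:
    """Batched iterates; every array has one column per weight vector."""

    X1: np.ndarray
    X2: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    V: np.ndarray
    rho: np.ndarray
    k: int = 0
    dtype: np.dtype = np.dtype(np.float32)

    @classmethod
    def zeros(cls, m: int, n: int, K: int, rho: np.ndarray, dtype) -> "ADMMState":
        z = lambda r: np.zeros((r, K), dtype=dtype)
        return cls(X1=z(n), X2=z(m), Z1=z(n), Z2=z(m), Y1=z(n), Y2=z(m), V=z(m),
                   rho=np.asarray(rho, dtype=np.float64), dtype=np.dtype(dtype))


@dataclass
class _Workspace:
    """Problem data cast to the working precision."""

    A: np.ndarray
    AT: np.ndarray
    Sinv: np.ndarray
    C_over_rho: np.ndarray  # (n, K)
    B: np.ndarray
    U: np.ndarray
    L: np.ndarray

    @classmethod
    def from_lp(cls, lp: DualLP, rho: np.ndarray, schur: SchurOperator, dtype) -> "_Workspace":
        A = lp.A.astype(dtype)
        return cls(
            A=A,
            AT=np.ascontiguousarray(A.T),
            Sinv=schur.cast(dtype),
            C_over_rho=(lp.c[:, None] / rho[None, :]).astype(dtype),
            B=lp.B.astype(dtype),
            U=lp.U.astype(dtype),
            L=np.zeros((lp.n, 1), dtype=dtype),
        )


def _step(ws: _Workspace, st: ADMMState) -> None:
    """One full ADMM cycle, in place, on all columns."""
    W = st.Z1 - st.Y1 - ws.C_over_rho
    st.V = ws.Sinv @ (ws.A @ W - st.Z2 + st.Y2)
    st.X1 = W - ws.AT @ st.V
    st.X2 = st.V + st.Z2 - st.Y2
    st.Z1 = np.clip(st.X1 + st.Y1, ws.L, ws.U)
    st.Z2 = np.minimum(st.X2 + st.Y2, ws.B)
    st.Y1 = st.Y1 + (st.X1 - st.Z1)
    st.Y2 = st.Y2 + (st.X2 - st.Z2)
    st.k += 1


def admm_step(state: ADMMState, lp: DualLP, schur: SchurOperator | None = None) -> ADMMState:
    """Advance the batched iterates by one cycle and return the state."""
    if schur is None:
        schur = precompute_schur(lp.A)
    ws = _Workspace.from_lp(lp, state.rho, schur, state.dtype)
    _step(ws, state)
    if not np.all(np.isfinite(state.Z1)):
        raise FloatingPointError(f"non-finite iterate at iteration {state.k}")
    return state


@dataclass
class ADMMResult:
    """Final iterates plus the residual trace of a fixed-budget solve."""

    Z1: np.ndarray
    Z2: np.ndarray
    Y2: np.ndarray
    rho: np.ndarray
    iterations: int
    precision: str
    trace_iters: np.ndarray
    primal_residual: np.ndarray  # (n_trace, K), normalized
    dual_residual: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)  # iter -> Y2 copy
    diverged: np.ndarray | None = None

    def objective(self, lp: DualLP) -> np.ndarray:
        """Dual objective c^T z1 per column."""
        return lp.c @ self.Z1.astype(np.float64)


def solve_batch(
    lp: DualLP,
    n_iter: int = 3000,
    precision: str = "single",
    rho: np.ndarray | float | None = None,
    trace_every: int = 10,
    snapshots: tuple[int, ...] = (),
    schur: SchurOperator | None = None,
) -> ADMMResult:
    """Run a fixed number of batched ADMM iterations on all instances.

    No early stopping is used: the iteration budget is part of the
    method.  The residual trace records, every ``trace_every``
    iterations, the primal residual ``||x - z||`` and the dual residual
    ``rho * ||z^{k+1} - z^k||`` per column, normalized by the current
    iterate norm (no reference solution is assumed).  ``snapshots``
    requests copies of the scaled dual Y2 at given iteration counts, so
    plans at intermediate budgets can be recovered from a single run.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if lp.B is None or lp.U is None:
        raise ValueError("LP has no bound columns; call set_weights first")
    dtype = _DTYPES[precision]
    if rho is None:
        rho_vec = lp.rho
    else:
        rho_vec = np.broadcast_to(np.asarray(rho, dtype=np.float64), (lp.n_instances,))
    if rho_vec is None:
        raise ValueError("no step sizes: pass rho or set them on the LP")
    if np.any(rho_vec <= 0):
        raise ValueError("rho must be positive")

    if schur is None:
        schur = precompute_schur(lp.A)
    ws = _Workspace.from_lp(lp, np.asarray(rho_vec), schur, dtype)
    K = lp.n_instances
    st = ADMMState.zeros(lp.m, lp.n, K, rho_vec, dtype)

    trace_iters, r_prim, r_dual = [], [], []
    snaps: dict[int, np.ndarray] = {}
    rho_f = np.asarray(rho_vec, dtype=np.float64)
    initial_res: np.ndarray | None = None
    diverged = np.zeros(K, dtype=bool)

    for k in range(1, n_iter + 1):
        Z1_prev, Z2_prev = st.Z1, st.Z2
        _step(ws, st)
        if k % trace_every == 0 or k == n_iter:
            dx1 = st.X1 - st.Z1
            dx2 = st.X2 - st.Z2
            rp = np.sqrt((dx1.astype(np.float64) ** 2).sum(0) + (dx2.astype(np.float64) ** 2).sum(0))
            dz1 = st.Z1 - Z1_prev
            dz2 = st.Z2 - Z2_prev
            rd = rho_f * np.sqrt((dz1.astype(np.float64) ** 2).sum(0) + (dz2.astype(np.float64) ** 2).sum(0))
            norm = np.sqrt((st.Z1.astype(np.float64) ** 2).sum(0) + (st.Z2.astype(np.float64) ** 2).sum(0))
            norm = np.maximum(norm, 1e-30)
            trace_iters.append(k)
            r_prim.append(rp / norm)
            r_dual.append(rd / norm)
            if not np.all(np.isfinite(rp)):
                raise FloatingPointError(f"non-finite iterate at iteration {k}")
            if initial_res is None:
                # iterates start at zero, so the first residual can be tiny;
                # reference the problem data scale as well
                data_scale = max(
                    1.0,
                    float(np.abs(ws.B).max()),
                    float(np.abs(ws.U[np.isfinite(ws.U)]).max(initial=0.0)),
                )
                initial_res = np.maximum(rp, data_scale)
            elif np.any(rp > 1e6 * initial_res):
                diverged = rp > 1e6 * initial_res
                warnings.warn(f"ADMM divergence flagged at iteration {k}; partial trace returned")
                break
        if k in snapshots:
            snaps[k] = st.Y2.astype(np.float64).copy()

    return ADMMResult(
        Z1=st.Z1,
        Z2=st.Z2,
        Y2=st.Y2,
        rho=np.asarray(rho_vec, dtype=np.float64),
        iterations=st.k,
        precision=precision,
        trace_iters=np.asarray(trace_iters),
        primal_residual=np.asarray(r_prim),
        dual_residual=np.asarray(r_dual),
        snapshots=snaps,
        diverged=diverged,
    )


@dataclass
class PlanSolution:
    """A recovered treatment plan for one weight vector.

    Sector times ``t`` (n_iso, 8, 3) and shot times ``tau`` (n_iso,) are
    in minutes; ``objective_terms`` holds the four weighted primal cost
    terms evaluated on the LP's own dose points.
    """

    t: np.ndarray
    tau: np.ndarray
    weights: WeightVector | None
    objective_terms: dict[str, float]
    column: int = 0
    fingerprint: tuple = ()

    @property
    def bot(self) -> float:
        """Total beam-on time (minutes)."""
        return float(self.tau.sum())

    @property
    def t_flat(self) -> np.ndarray:
        return self.t.reshape(-1)

    @property
    def objective(self) -> float:
        return float(sum(self.objective_terms.values()))


def _objective_terms(t_flat: np.ndarray, tau: np.ndarray, lp: DualLP, j: int) -> dict[str, float]:
    w = lp.weights[j] if lp.weights else None
    if w is None:
        raise ValueError("LP carries no weight vectors")
    terms: dict[str, float] = {}
    counts = lp.counts
    dose_t = lp.influences["target"] @ t_flat
    terms["target"] = w.wT / counts["target"] * float(np.maximum(lp.levels["target"] - dose_t, 0).sum())
    if counts["shell"]:
        dose_s = lp.influences["shell"] @ t_flat
        terms["shell"] = w.wS / counts["shell"] * float(np.maximum(dose_s - lp.levels["shell"], 0).sum())
    else:
        terms["shell"] = 0.0
    if counts["low-dose"]:
        member = (
            np.ones(counts["low-dose"], dtype=bool)
            if lp.ld_membership is None
            else lp.ld_membership[:, j]
        )
        n_ld = int(member.sum())
        if n_ld:
            dose_ld = lp.influences["low-dose"][member] @ t_flat
            terms["low-dose"] = w.wLD / n_ld * float(np.maximum(dose_ld - lp.d_ld, 0).sum())
        else:
            terms["low-dose"] = 0.0
    else:
        terms["low-dose"] = 0.0
    terms["bot"] = w.wBOT * float(tau.sum())
    return terms


def recover_from_row_duals(lam: np.ndarray, lp: DualLP, j: int, clip_tol: float = 1e-3) -> PlanSolution:
    """Turn row dual variables of ``A x <= b`` into a treatment plan.

    Used identically for the ADMM solution (``lam = rho * y2``) and for
    the exact-LP oracle (``lam`` = the solver's constraint duals), so
    both paths share the same un-scaling: divide by the recorded row
    norms, clip small negative round-off to zero, and split the rows
    into sector times and shot times.
    """
    lam = np.asarray(lam, dtype=np.float64)
    if lp.precond.row_norms is not None:
        lam = lam / lp.precond.row_norms
    neg = lam < -clip_tol * max(lam.max(), 1e-30)
    if neg.any():
        warnings.warn(f"{int(neg.sum())} recovered plan entries below -tol clipped to zero")
    lam = np.maximum(lam, 0.0)
    t = lam[lp.t_rows].reshape(lp.n_iso, 8, 3)
    tau = lam[lp.tau_rows]
    terms = _objective_terms(t.reshape(-1), tau, lp, j)
    return PlanSolution(
        t=t,
        tau=tau,
        weights=lp.weights[j] if lp.weights else None,
        objective_terms=terms,
        column=j,
        fingerprint=lp.fingerprint,
    )


def recover_primal(
    Y2: np.ndarray,
    rho: np.ndarray,
    lp: DualLP,
    clip_tol: float = 1e-3,
) -> list[PlanSolution]:
    """Recover one plan per column from the converged scaled duals (rho * y2)."""
    Y2 = np.asarray(Y2, dtype=np.float64)
    rho = np.broadcast_to(np.asarray(rho, dtype=np.float64), (Y2.shape[1],))
    return [
        recover_from_row_duals(rho[j] * Y2[:, j], lp, j, clip_tol=clip_tol)
        for j in range(Y2.shape[1])
    ]
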