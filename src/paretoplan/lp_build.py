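"""Assembly and preconditioning of the dual planning linear program.

The weighted-sum inverse-planning problem is a linear program over
nonnegative sector times ``t(i, s, c)`` and per-isocenter shot times
``tau_i``:

    minimize  wT/N_T * sum(target underdose)
            + wS/N_S * sum(shell overdose)
            + wLD/N_LD * sum(low-dose excess)
            + wBOT * sum_i tau_i
    s.t.      dose >= D_presc - underdose        (target points)
              dose <= D_presc + overdose        (shell points)
              dose <= D_LD + excess             (low-dose points)
              dose <= D_OARmax                  (OAR points, hard)
              sum_c t(i, s, c) <= tau_i,  t >= 0.

For computational efficiency the problem is solved in its LP dual,

    minimize  c^T x   s.t.  A x <= b,  0 <= x <= u,

which has one column per dose point (alpha for target, beta for shell,
gamma for low-dose, delta for OAR) plus eight sector columns mu(i, s)
per isocenter, and 25 rows per isocenter (one per sector time plus one
per shot time).  The objective weights enter only through the bound
vectors ``b`` and ``u``, which is what makes batching over weight
vectors cheap; the physics (dose-rate influence) lives in ``A``.  The
optimal plan is recovered from the dual variables of ``A x <= b``.

Preconditioning follows the published recipe: rows of ``A`` are
normalized to unit Euclidean norm (making ``diag(A A^T + I) = 2``), the
beam-on-time (mu) columns are then scaled by ``beta = N_pts / 2000``
(non-OAR dose points), and the ADMM step size follows the heuristic
``rho = 2.5e-3 * w0_BOT / wBOT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .case_synth import DosePointSet, N_SECTORS, N_COLLIMATORS

__all__ = [
    "WeightVector",
    "SliderMap",
    "DualLP",
    "Preconditioner",
    "RhoRule",
    "DEFAULT_WEIGHT_SCALE",
    "assemble_dual_lp",
    "weights_to_bounds",
    "sliders_to_weights",
    "slider_grid",
    "normalize_rows",
    "bot_column_scaling",
    "scale_bot_columns",
    "rho_heuristic",
    "set_weights",
]

ROWS_PER_ISOCENTER = 24 + 1
COLS_PER_ISOCENTER = N_SECTORS  # mu columns

#: Overall scale applied to all four objective weights by the default
#: slider mapping.  The treatment plan is invariant to this scale (the
#: weighted-sum LP is positively homogeneous in the weights); it fixes
#: the magnitude of the dual iterates so that the step-size heuristic
#: rho = 2.5e-3 * w0/wBOT sits on its optimal plateau.  The value was
#: calibrated once by a step-size grid search on a separate validation
#: set of synthetic cases (see docs/methods.md): with
#: scale * wbot_min = 4e4 the heuristic reproduces the empirically
#: optimal step size over the whole beam-on-time weight range.
DEFAULT_WEIGHT_SCALE = 8.0e6

RHO_BASE = 2.5e-3


@dataclass(frozen=True)
class WeightVector:
    """Objective weights (wT, wS, wLD, wBOT), all strictly positive."""

    wT: float
    wS: float
    wLD: float
    wBOT: float
    sliders: tuple[float, float] | None = None  # (sLD, sBOT)

    def __post_init__(self) -> None:
        if min(self.wT, self.wS, self.wLD, self.wBOT) <= 0:
            raise ValueError("all objective weights must be strictly positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.wT, self.wS, self.wLD, self.wBOT)


@dataclass(frozen=True)
class SliderMap:
    """Log-linear map from the two clinical sliders to objective weights.

    ``wT = wS = scale`` are fixed; ``wLD`` and ``wBOT`` interpolate
    log-linearly over their ranges as the sliders move over [0, 1].
    """

    wld_range: tuple[float, float] = (0.05, 2.0)
    wbot_range: tuple[float, float] = (0.005, 0.2)
    scale: float = DEFAULT_WEIGHT_SCALE
    #: dose-point count at which ``scale`` applies; because the
    #: objective terms are normalized per point (w/N), the dual-iterate
    #: magnitude scales as w/N, so the weight scale grows linearly with
    #: the case's cost-function point count to keep the step-size rule
    #: size-independent (the plan itself is invariant to this scale)
    reference_points: int = 2000

    @property
    def w0_bot(self) -> float:
        """Lowest allowed beam-on-time weight."""
        return self.scale * self.wbot_range[0]

    def scaled_for(self, n_cost_points: int) -> "SliderMap":
        """Map with the overall scale adjusted to a case's point count."""
        from dataclasses import replace

        factor = max(int(n_cost_points), 1) / self.reference_points
        return replace(self, scale=self.scale * factor)

    def __call__(self, s_ld: float, s_bot: float) -> WeightVector:
        if not (0 <= s_ld <= 1 and 0 <= s_bot <= 1):
            raise ValueError("slider values must lie in [0, 1]")
        lo, hi = self.wld_range
        wld = lo * (hi / lo) ** s_ld
        lo, hi = self.wbot_range
        wbot = lo * (hi / lo) ** s_bot
        return WeightVector(
            wT=self.scale,
            wS=self.scale,
            wLD=self.scale * wld,
            wBOT=self.scale * wbot,
            sliders=(s_ld, s_bot),
        )


def sliders_to_weights(s_ld: float, s_bot: float, mapping: SliderMap | None = None) -> WeightVector:
    """Map slider coordinates (sLD, sBOT) in [0,1]^2 to a weight vector."""
    return (mapping or SliderMap())(s_ld, s_bot)


def slider_grid(spec: str | int, mapping: SliderMap | None = None) -> list[WeightVector]:
    """Uniform slider grid, e.g. ``"3x3"`` (steps of 0.5) or ``"21x21"`` (steps of 0.05)."""
    if isinstance(spec, str):
        a, _, b = spec.partition("x")
        n_ld, n_bot = int(a), int(b or a)
    else:
        n_ld = n_bot = int(spec)
    if n_ld < 2 or n_bot < 2:
        raise ValueError("slider grid needs at least 2 steps per axis")
    mapping = mapping or SliderMap()
    return [
        mapping(s_ld, s_bot)
        for s_ld in np.linspace(0.0, 1.0, n_ld)
        for s_bot in np.linspace(0.0, 1.0, n_bot)
    ]


@dataclass(frozen=True)
class RhoRule:
    """Step-size heuristic ``rho = base * w0_bot / wbot`` (one rho per weight vector)."""

    w0_bot: float
    base: float = RHO_BASE

    def __call__(self, wbot: float) -> float:
        return rho_heuristic(wbot, self.w0_bot, self.base)


def rho_heuristic(wbot: float, w0_bot: float, base: float = RHO_BASE) -> float:
    """ADMM step size for a given beam-on-time weight.

    Decreases inversely with the beam-on-time weight and equals ``base``
    at the lowest allowed weight.
    """
    if w0_bot <= 0 or wbot <= 0:
        raise ValueError("weights must be strictly positive")
    if wbot < w0_bot * (1 - 1e-12):
        raise ValueError("wBOT below its lowest allowed value")
    return base * w0_bot / wbot


@dataclass
class Preconditioner:
    """Record of the scalings applied to the LP, for solution recovery."""

    row_norms: np.ndarray | None = None
    beta: float = 1.0


@dataclass
class DualLP:
    """The dual LP ``min c^T x, A x <= b, 0 <= x <= u`` with K bound columns.

    Shapes: ``A`` is (m, n) with m = 25 * n_iso and
    n = N_points + 8 * n_iso; ``B`` is (m, K) and ``U`` is (n, K), one
    column per weight vector.  ``influences`` keeps the per-category
    influence blocks so the primal objective of a recovered plan can be
    evaluated exactly on the same dose points.
    """

    c: np.ndarray
    A: np.ndarray
    n_iso: int
    col_slices: dict[str, slice]
    counts: dict[str, int]
    influences: dict[str, np.ndarray]
    levels: dict[str, np.ndarray]
    d_ld: float
    precond: Preconditioner = field(default_factory=Preconditioner)
    weights: list[WeightVector] = field(default_factory=list)
    B: np.ndarray | None = None
    U: np.ndarray | None = None
    rho: np.ndarray | None = None
    ld_membership: np.ndarray | None = None  # (N_LD, K) bool, pass-2 point ownership
    fingerprint: tuple = ()

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def n_instances(self) -> int:
        return 0 if self.B is None else self.B.shape[1]

    @property
    def t_rows(self) -> np.ndarray:
        return np.asarray(
            [ROWS_PER_ISOCENTER * i + k for i in range(self.n_iso) for k in range(24)]
        )

    @property
    def tau_rows(self) -> np.ndarray:
        return np.asarray([ROWS_PER_ISOCENTER * i + 24 for i in range(self.n_iso)])

    @property
    def lower(self) -> np.ndarray:
        return np.zeros(self.n)

    def bounds(self, j: int) -> list[tuple[float, float]]:
        """Per-variable (lower, upper) bounds of instance ``j`` (oracle interface)."""
        u = self.U[:, j]
        return [(0.0, float(ub) if np.isfinite(ub) else None) for ub in u]  # type: ignore[list-item]


def assemble_dual_lp(
    influences: dict[str, np.ndarray],
    levels: dict[str, np.ndarray],
    n_iso: int,
    d_ld: float,
) -> DualLP:
    """Assemble the (unpreconditioned) dual LP from influence blocks.

    ``influences`` maps the categories ``target``, ``shell``,
    ``low-dose`` and (optionally) ``oar`` to their influence matrices;
    ``levels`` holds the per-point dose levels (prescription for target
    and shell points, OAR max dose for OAR points).  Column order is
    alpha (target), beta (shell), gamma (low-dose), delta (OAR), mu.
    """
    if n_iso < 1:
        raise ValueError("at least one isocenter required")
    order = ["target", "shell", "low-dose", "oar"]
    blocks = {k: np.asarray(influences.get(k, np.empty((0, 24 * n_iso)))) for k in order}
    if blocks["target"].shape[0] == 0:
        raise ValueError("at least one target dose point required")
    for k, blk in blocks.items():
        if blk.shape[0] and blk.shape[1] != 24 * n_iso:
            raise ValueError(f"influence block {k!r} not conformable with {n_iso} isocenters")
    if d_ld <= 0:
        raise ValueError("dose levels must be positive")

    counts = {k: blocks[k].shape[0] for k in order}
    n_pts = sum(counts.values())
    m = ROWS_PER_ISOCENTER * n_iso
    n = n_pts + COLS_PER_ISOCENTER * n_iso

    sign = {"target": +1.0, "shell": -1.0, "low-dose": -1.0, "oar": -1.0}
    c = np.empty(n)
    A = np.zeros((m, n))
    t_rows = np.asarray([ROWS_PER_ISOCENTER * i + k for i in range(n_iso) for k in range(24)])

    col_slices: dict[str, slice] = {}
    start = 0
    for k in order:
        stop = start + counts[k]
        col_slices[k] = slice(start, stop)
        if counts[k]:
            A[np.ix_(t_rows, np.arange(start, stop))] = sign[k] * blocks[k].T
            if k == "low-dose":
                c[start:stop] = d_ld
            else:
                lev = np.asarray(levels[k], dtype=float)
                if len(lev) != counts[k]:
                    raise ValueError(f"levels for {k!r} not conformable")
                c[start:stop] = -lev if k == "target" else lev
        start = stop
    col_slices["mu"] = slice(start, n)
    c[start:] = 0.0

    for i in range(n_iso):
        for s in range(N_SECTORS):
            mu_col = start + N_SECTORS * i + s
            rows = ROWS_PER_ISOCENTER * i + 3 * s + np.arange(N_COLLIMATORS)
            A[rows, mu_col] = -1.0
            A[ROWS_PER_ISOCENTER * i + 24, mu_col] = 1.0

    fingerprint = (m, n, n_iso, tuple(counts.items()), float(d_ld))
    return DualLP(
        c=c,
        A=A,
        n_iso=n_iso,
        col_slices=col_slices,
        counts=counts,
        influences=blocks,
        levels={k: np.asarray(v, dtype=float) for k, v in levels.items()},
        d_ld=d_ld,
        fingerprint=fingerprint,
    )


def normalize_rows(lp: DualLP) -> DualLP:
    """Scale every row of ``A`` to unit Euclidean norm.

    The same scaling is applied to the corresponding entries of every
    ``b`` column (bounds are built afterwards from the stored norms), and
    the norms are recorded so recovered plans are returned in physical
    units.  After normalization ``diag(A A^T + I) = 2`` and all other
    entries of the Schur complement lie in [-1, 1].
    """
    norms = np.linalg.norm(lp.A, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmin(norms))
        i, k = divmod(bad, ROWS_PER_ISOCENTER)
        row = f"tau({i})" if k == 24 else f"t(iso={i}, sector={k // 3}, collimator={k % 3})"
        raise ValueError(f"cannot normalize zero row {bad} ({row})")
    out = replace(lp, A=lp.A / norms[:, None])
    out.precond = Preconditioner(row_norms=norms, beta=lp.precond.beta)
    return out


def bot_column_scaling(counts: dict[str, int] | int) -> float:
    """Scale factor ``beta`` for the beam-on-time columns of ``A``.

    ``beta = (N_TS + N_TI + N_S + N_1,LD + N_2,LD) / 2000`` -- the number
    of dose points contributing to the cost function (OAR points are
    excluded) relative to a 2000-point reference problem.
    """
    if isinstance(counts, dict):
        n = sum(v for k, v in counts.items() if k != "oar")
    else:
        n = int(counts)
    if n < 0:
        raise ValueError("point count must be nonnegative")
    return n / 2000.0


def scale_bot_columns(lp: DualLP, beta: float | None = None) -> DualLP:
    """Multiply the mu (beam-on-time) columns of ``A`` by ``beta``.

    Applied after row normalization.  This is an exact reparametrization
    of the LP (the mu columns have zero cost and no upper bound), so the
    recovered plan is unchanged in exact arithmetic; it rebalances the
    Schur complement so the beam-on-time term converges at the same rate
    as the dose terms when the number of dose points is large.
    """
    if beta is None:
        beta = bot_column_scaling(lp.counts)
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = lp.A.copy()
    A[:, lp.col_slices["mu"]] *= beta
    out = replace(lp, A=A)
    out.precond = Preconditioner(row_norms=lp.precond.row_norms, beta=beta)
    return out


def weights_to_bounds(
    w: WeightVector,
    lp: DualLP,
    ld_member: np.ndarray | None = None,
    n_ld: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bound columns (b, u) of one weight vector.

    ``u`` carries ``wT/N_T`` on target (alpha) columns, ``wS/N_S`` on
    shell (beta) columns and ``wLD/N_LD`` on low-dose (gamma) columns;
    OAR (delta) and sector (mu) columns are unbounded (OAR points do not
    contribute to the cost function; they are hard constraints).  ``b``
    carries ``wBOT`` on the shot-time rows, scaled by the recorded row
    norms.  For second-pass instances ``ld_member`` marks which of the
    shared low-dose points belong to this instance; the rest get a zero
    upper bound (their penalty is switched off).
    """
    counts = lp.counts
    n_t, n_s, n_ld_total = counts["target"], counts["shell"], counts["low-dose"]
    if n_t == 0:
        raise ValueError("weight vector requires target points")
    u = np.full(lp.n, np.inf)
    u[lp.col_slices["target"]] = w.wT / n_t
    if n_s:
        u[lp.col_slices["shell"]] = w.wS / n_s
    if n_ld_total:
        if ld_member is None:
            u[lp.col_slices["low-dose"]] = w.wLD / n_ld_total
        else:
            member = np.asarray(ld_member, dtype=bool)
            if member.shape != (n_ld_total,):
                raise ValueError("low-dose membership mask not conformable")
            eff = int(member.sum()) if n_ld is None else int(n_ld)
            g = np.zeros(n_ld_total)
            if eff:
                g[member] = w.wLD / eff
            u[lp.col_slices["low-dose"]] = g
    b = np.zeros(lp.m)
    b[lp.tau_rows] = w.wBOT
    if lp.precond.row_norms is not None:
        b = b / lp.precond.row_norms
    return b, u


def set_weights(
    lp: DualLP,
    weights: list[WeightVector],
    rho_rule: RhoRule | None = None,
    ld_membership: np.ndarray | None = None,
) -> DualLP:
    """Attach per-instance bounds and step sizes for a batch of weight vectors."""
    K = len(weights)
    if K == 0:
        raise ValueError("at least one weight vector required")
    if rho_rule is None:
        rho_rule = RhoRule(w0_bot=min(w.wBOT for w in weights))
    B = np.empty((lp.m, K))
    U = np.empty((lp.n, K))
    for j, w in enumerate(weights):
        member = None if ld_membership is None else ld_membership[:, j]
        B[:, j], U[:, j] = weights_to_bounds(w, lp, ld_member=member)
    out = replace(lp, B=B, U=U, weights=list(weights))
    out.rho = np.asarray([rho_rule(w.wBOT) for w in weights])
    out.ld_membership = None if ld_membership is None else np.asarray(ld_membership, bool)
    out.precond = lp.precond
    return out


def lp_from_points(
    case,
    point_sets: dict[str, DosePointSet],
    build_influence_fn=None,
) -> DualLP:
    """Convenience: assemble the dual LP directly from case dose points.

    ``point_sets`` maps ``target``/``shell``/``low-dose``/``oar`` to
    :class:`DosePointSet` objects (the target entry may combine surface
    and interior points).
    """
    from .case_synth import build_influence as _bi

    fn = build_influence_fn or _bi
    influences = {k: fn(case, ps) for k, ps in point_sets.items()}
    levels = {k: ps.levels for k, ps in point_sets.items()}
    return assemble_dual_lp(influences, levels, case.isocenters.count, case.d_ld)
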