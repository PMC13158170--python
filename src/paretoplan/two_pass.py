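"""Two-pass optimization with non-redundant low-dose point sampling.

The gradient-index (low-dose) objective penalizes dose above a
threshold ``D_LD`` in a region where the dose is expected to be near
that threshold.  The first pass takes this region from a geometric
expansion of the target; the second pass recomputes it per weight
vector from the first-pass dose distribution as the band
``[D_LD, D_LD + Delta)``.  Because the second-pass regions differ
between weight vectors but overlap heavily, points are drawn with a
thinning scheme that maximizes reuse: all instances share a single
point union P, and each instance activates only its own points through
the per-instance upper bounds of the dual LP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import case_synth
from .admm_core import ADMMResult, PlanSolution, precompute_schur, recover_primal, solve_batch
from .case_synth import DosePointSet, SyntheticCase, sample_dose_points
from .lp_build import (
    DualLP,
    RhoRule,
    SliderMap,
    WeightVector,
    assemble_dual_lp,
    bot_column_scaling,
    normalize_rows,
    scale_bot_columns,
    set_weights,
)
from .metrics_oracle import PlanMetrics, plan_metrics

__all__ = [
    "LowDoseVolume",
    "SamplingPlan",
    "SolverConfig",
    "TwoPassResult",
    "first_pass_ld_volume",
    "second_pass_ld_volumes",
    "overlap_sample",
    "run_two_pass",
    "evaluation_mask",
]


@dataclass
class LowDoseVolume:
    """A low-dose sampling region (voxel set) with its measure in mm^3."""

    mask: np.ndarray
    measure: float
    owner: int  # weight-vector index; -1 for the shared first-pass volume
    pass_tag: str  # "first" | "second"


@dataclass
class SamplingPlan:
    """Record of the overlapping low-dose sampling (audit trail).

    ``points`` is the shared union P; ``membership[:, j]`` marks the
    points of instance j; ``densities`` are the per-instance target
    densities (points per mm^3), in the processed (non-increasing)
    order ``order``.
    """

    points: np.ndarray
    membership: np.ndarray
    densities: np.ndarray
    measures: np.ndarray
    requested: np.ndarray
    order: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def points_per_instance(self) -> np.ndarray:
        return self.membership.sum(axis=0)


@dataclass
class SolverConfig:
    """Configuration of the two-pass solve."""

    n_iter: int = 3000
    precision: str = "single"
    trace_every: int = 10
    snapshots: tuple[int, ...] = ()
    seed: int = 0
    ld_margins: tuple[float, float] = (0.2, 0.6)
    delta_fraction: float = 0.15  # band width Delta as a fraction of D_LD
    ld_density: float = case_synth.CATEGORY_DENSITIES["low-dose"]
    ld_caps: tuple[int, int] = case_synth.CATEGORY_CAPS["low-dose"]
    rho_rule: RhoRule | None = None
    clip_tol: float = 1e-3


@dataclass
class PassResult:
    """One optimization pass: the LP, solver output, plans and doses."""

    lp: DualLP
    admm: ADMMResult | None
    plans: list[PlanSolution]
    doses: np.ndarray  # (n_eval_voxels, K) Gy
    snapshot_plans: dict[int, list[PlanSolution]] = field(default_factory=dict)


@dataclass
class TwoPassResult:
    case: SyntheticCase
    weights: list[WeightVector]
    config: SolverConfig
    eval_mask: np.ndarray
    first: PassResult
    second: PassResult
    sampling: SamplingPlan
    metrics: list[PlanMetrics]


# ---------------------------------------------------------------------------
# low-dose volumes
# ---------------------------------------------------------------------------


def first_pass_ld_volume(case: SyntheticCase, margins: tuple[float, float] = (0.2, 0.6)) -> LowDoseVolume:
    """Weight-independent low-dose shell from a geometric target expansion.

    The shell spans distances ``margins * r_eff`` outside the target
    surface (r_eff = radius of the volume-equivalent sphere), clipped to
    the skull and excluding targets and OARs.
    """
    inner, outer = margins
    if inner >= outer:
        raise ValueError("inner margin must be smaller than outer margin")
    region = case_synth._geometric_low_dose_region(case, margins)
    dist = case_synth.distance_from_mask(case.structures.target_union, case.grid.spacing)
    unclipped = (dist >= inner * case.effective_radius()) & (dist < outer * case.effective_radius())
    if (unclipped & ~case.structures.skull).any():
        warnings.warn("low-dose expansion exits the skull; clipped")
    return LowDoseVolume(
        mask=region,
        measure=float(region.sum()) * case.grid.voxel_volume,
        owner=-1,
        pass_tag="first",
    )


def second_pass_ld_volumes(
    case: SyntheticCase,
    doses: np.ndarray,
    eval_mask: np.ndarray,
    delta: float | None = None,
    fallback: LowDoseVolume | None = None,
) -> list[LowDoseVolume]:
    """Per-instance low-dose bands from the first-pass dose distributions.

    Instance j's volume is the set of non-target voxels whose first-pass
    dose lies in ``[D_LD, D_LD + delta)``.  An empty band falls back to
    the geometric first-pass volume (with a warning) so the instance
    stays solvable.
    """
    d_ld = case.d_ld
    if delta is None:
        delta = 0.15 * d_ld
    if delta <= 0:
        raise ValueError("band width must be positive")
    idx = np.argwhere(eval_mask)
    if len(idx) != doses.shape[0]:
        raise ValueError("dose array not conformable with evaluation mask")
    exclude = case.structures.target_union | case.structures.oar_union
    vols = []
    voxvol = case.grid.voxel_volume
    for j in range(doses.shape[1]):
        band = np.zeros(case.grid.shape, dtype=bool)
        sel = (doses[:, j] >= d_ld) & (doses[:, j] < d_ld + delta)
        band[idx[sel, 0], idx[sel, 1], idx[sel, 2]] = True
        band &= ~exclude
        if not band.any():
            if fallback is None:
                raise ValueError(f"empty low-dose band for instance {j} and no fallback")
            warnings.warn(f"empty low-dose band for instance {j}; using first-pass volume")
            band = fallback.mask
        vols.append(
            LowDoseVolume(mask=band, measure=float(band.sum()) * voxvol, owner=j, pass_tag="second")
        )
    return vols


# ---------------------------------------------------------------------------
# Algorithm: overlapping low-dose point sampling
# ---------------------------------------------------------------------------


def overlap_sample(
    case: SyntheticCase,
    volumes: list[LowDoseVolume],
    n_points: np.ndarray,
    seed: int = 0,
) -> SamplingPlan:
    """Sample one shared point set representing many overlapping volumes.

    Volumes are processed in order of non-increasing target density
    ``omega_j = N_j / |V_j|``.  For each volume, the running point union
    is first thinned to density omega_j (a random subset of
    ``omega_j * |V_union|`` points); the thinned points inside V_j are
    reused, and only ``V_j \\ V_union`` receives fresh uniform points.
    Every instance keeps (approximately) its desired density while the
    union P stays far smaller than the sum of the per-instance counts.
    """
    m = len(volumes)
    n_points = np.asarray(n_points, dtype=int)
    if len(n_points) != m:
        raise ValueError("one requested count per volume required")
    grid = case.grid
    voxvol = grid.voxel_volume
    measures = np.asarray([v.measure for v in volumes], dtype=float)
    if np.any(measures <= 0):
        raise ValueError("volumes must have positive measure")
    densities = n_points / measures
    # points are continuous (jittered within voxels), so several points per
    # voxel are representable; refuse only absurd requests
    if np.any(densities > 10.0 / voxvol):
        raise ValueError("requested density exceeds the voxel resolution")
    order = np.argsort(-densities, kind="stable")

    rng = np.random.default_rng(np.random.SeedSequence([case.seed, seed, 0x10D]))
    spacing = np.asarray(grid.spacing)

    master: list[np.ndarray] = []  # point coordinate batches
    n_master = 0
    union_ids = np.empty(0, dtype=int)
    union_mask = np.zeros(grid.shape, dtype=bool)
    union_measure = 0.0
    member_ids: dict[int, np.ndarray] = {}

    def _sample_in(mask: np.ndarray, count: int) -> np.ndarray:
        centers = grid.voxel_centers(mask)
        pick = rng.integers(0, len(centers), size=count)
        return centers[pick] + rng.uniform(-0.5, 0.5, size=(count, 3)) * spacing

    for j in order:
        vol = volumes[j]
        omega = densities[j]
        # thin the running union to this volume's density
        n_sel = min(int(round(omega * union_measure)), len(union_ids))
        thinned = rng.choice(union_ids, size=n_sel, replace=False) if n_sel else np.empty(0, int)
        if len(thinned):
            pts = np.concatenate(master)[thinned] if master else np.empty((0, 3))
            inside = grid.contains_mask(pts, vol.mask)
            p_in = thinned[inside]
        else:
            p_in = np.empty(0, dtype=int)
        # fresh points only where the union has not been before
        new_region = vol.mask & ~union_mask
        n_out = int(round(omega * float(new_region.sum()) * voxvol))
        if n_out and new_region.any():
            fresh = _sample_in(new_region, n_out)
            master.append(fresh)
            out_ids = np.arange(n_master, n_master + n_out)
            n_master += n_out
        else:
            out_ids = np.empty(0, dtype=int)
        member_ids[j] = np.concatenate([p_in, out_ids])
        union_ids = np.concatenate([thinned, out_ids])
        union_mask = union_mask | vol.mask
        union_measure = float(union_mask.sum()) * voxvol

    all_pts = np.concatenate(master) if master else np.empty((0, 3))
    used = np.unique(np.concatenate([member_ids[j] for j in order])) if m else np.empty(0, int)
    remap = -np.ones(n_master, dtype=int)
    remap[used] = np.arange(len(used))
    membership = np.zeros((len(used), m), dtype=bool)
    for j in order:
        membership[remap[member_ids[j]], j] = True
    return SamplingPlan(
        points=all_pts[used],
        membership=membership,
        densities=densities,
        measures=measures,
        requested=n_points,
        order=order,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def evaluation_mask(case: SyntheticCase) -> np.ndarray:
    """Voxels where doses are reconstructed: skull voxels near the targets.

    Wide enough to contain the prescription and half-prescription
    isodose volumes and the second-pass low-dose bands.
    """
    r_eff = case.effective_radius()
    dist = case_synth.distance_from_mask(case.structures.target_union, case.grid.spacing)
    return case.structures.skull & (dist <= 0.9 * r_eff + 10.0)


def _doses_on_mask(case, eval_influence, plans) -> np.ndarray:
    T = np.stack([p.t_flat for p in plans], axis=1).astype(np.float32)
    return (eval_influence @ T).astype(np.float64)


def _case_point_sets(case: SyntheticCase, seed: int) -> dict[str, DosePointSet]:
    ts = sample_dose_points(case, "target-surface", seed=seed)
    ti = sample_dose_points(case, "target-interior", seed=seed)
    target = DosePointSet(
        category="target-interior",
        coords=np.vstack([ts.coords, ti.coords]),
        levels=np.concatenate([ts.levels, ti.levels]),
    )
    sets = {"target": target, "shell": sample_dose_points(case, "shell", seed=seed)}
    if case.structures.oars:
        sets["oar"] = sample_dose_points(case, "oar", seed=seed)
    return sets


def _build_pass_lp(case, point_sets, ld_points, ld_levels, counts_extra=None):
    influences = {
        "target": case_synth.build_influence(case, point_sets["target"]),
        "shell": case_synth.build_influence(case, point_sets["shell"]),
        "low-dose": case.kernels.influence(ld_points),
    }
    levels = {
        "target": point_sets["target"].levels,
        "shell": point_sets["shell"].levels,
        "low-dose": ld_levels,
    }
    if "oar" in point_sets:
        influences["oar"] = case_synth.build_influence(case, point_sets["oar"])
        levels["oar"] = point_sets["oar"].levels
    lp = assemble_dual_lp(influences, levels, case.isocenters.count, case.d_ld)
    lp = normalize_rows(lp)
    lp = scale_bot_columns(lp, bot_column_scaling(lp.counts))
    return lp


def _solve_pass(lp: DualLP, config: SolverConfig, solver: str):
    """Solve one pass with the batched ADMM or the exact LP oracle."""
    if solver == "admm":
        admm = solve_batch(
            lp,
            n_iter=config.n_iter,
            precision=config.precision,
            trace_every=config.trace_every,
            snapshots=config.snapshots,
            schur=precompute_schur(lp.A),
        )
        plans = recover_primal(admm.Y2, admm.rho, lp, clip_tol=config.clip_tol)
        snaps = {
            k: recover_primal(y2, admm.rho, lp, clip_tol=config.clip_tol)
            for k, y2 in admm.snapshots.items()
        }
        return admm, plans, snaps
    if solver == "oracle":
        from .metrics_oracle import solve_lp_exact

        plans = [solve_lp_exact(lp, j).plan for j in range(lp.n_instances)]
        return None, plans, {}
    raise ValueError(f"unknown solver {solver!r}")


def run_two_pass(
    case: SyntheticCase,
    weights: list[WeightVector] | str = "3x3",
    config: SolverConfig | None = None,
    slider_map: SliderMap | None = None,
    eval_influence: np.ndarray | None = None,
    solver: str = "admm",
) -> TwoPassResult:
    """Full two-pass optimization for a batch of weight vectors.

    Pass 1 uses the shared geometric low-dose volume; pass 2 rebuilds
    the low-dose block from per-instance dose bands via the overlapping
    sampler, activating each instance's points through its upper-bound
    column.  Returns plans, reconstructed doses on the evaluation
    region, clinical metrics, and the full sampling/solver audit trail.

    ``solver="oracle"`` runs the identical pipeline with per-instance
    exact LP solves instead of batched ADMM (used for validation, e.g.
    comparing the sampling-noise spread of the two solvers).
    """
    config = config or SolverConfig()
    slider_map = slider_map or SliderMap()

    point_sets = _case_point_sets(case, config.seed)
    eval_mask = evaluation_mask(case)
    if eval_influence is None:
        eval_influence = case.kernels.influence(
            case.grid.voxel_centers(eval_mask), dtype=np.float32
        )

    # ---- pass 1 ----------------------------------------------------------
    ld_vol1 = first_pass_ld_volume(case, config.ld_margins)
    ld_pts1 = sample_dose_points(
        case,
        "low-dose",
        density=config.ld_density,
        min_count=config.ld_caps[0],
        max_count=config.ld_caps[1],
        seed=config.seed,
        region_mask=ld_vol1.mask,
    )
    lp1 = _build_pass_lp(case, point_sets, ld_pts1.coords, ld_pts1.levels)
    if isinstance(weights, str):
        # the per-point-normalized objective makes dual magnitudes scale
        # as w/N; adapt the (plan-invariant) weight scale to this case's
        # cost-point count so the step-size rule stays size-independent
        from .lp_build import slider_grid

        n_cost = sum(v for k, v in lp1.counts.items() if k != "oar")
        slider_map = slider_map.scaled_for(n_cost)
        weights = slider_grid(weights, slider_map)
    rho_rule = config.rho_rule or RhoRule(w0_bot=min(w.wBOT for w in weights))
    lp1 = set_weights(lp1, weights, rho_rule)
    admm1, plans1, snap_plans1 = _solve_pass(lp1, config, solver)
    doses1 = _doses_on_mask(case, eval_influence, plans1)
    first = PassResult(lp=lp1, admm=admm1, plans=plans1, doses=doses1, snapshot_plans=snap_plans1)

    # ---- pass 2 ----------------------------------------------------------
    delta = config.delta_fraction * case.d_ld
    vols2 = second_pass_ld_volumes(case, doses1, eval_mask, delta=delta, fallback=ld_vol1)
    lo, hi = config.ld_caps
    requested = np.clip(
        np.rint(config.ld_density * np.asarray([v.measure for v in vols2])).astype(int), lo, hi
    )
    sampling = overlap_sample(case, vols2, requested, seed=config.seed + 1)
    ld_levels2 = np.full(sampling.n_points, case.d_ld)
    lp2 = _build_pass_lp(case, point_sets, sampling.points, ld_levels2)
    lp2 = set_weights(lp2, weights, rho_rule, ld_membership=sampling.membership)
    admm2, plans2, snap_plans2 = _solve_pass(lp2, config, solver)
    doses2 = _doses_on_mask(case, eval_influence, plans2)
    second = PassResult(lp=lp2, admm=admm2, plans=plans2, doses=doses2, snapshot_plans=snap_plans2)

    metrics = [
        plan_metrics(
            case,
            doses2[:, j],
            eval_mask,
            bot_minutes=plans2[j].bot,
            sliders=weights[j].sliders,
        )
        for j in range(len(weights))
    ]
    return TwoPassResult(
        case=case,
        weights=list(weights),
        config=config,
        eval_mask=eval_mask,
        first=first,
        second=second,
        sampling=sampling,
        metrics=metrics,
    )
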