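# Methods

This note documents the model, the parameter choices and the numerical
decisions behind `paretoplan`, in the spirit of a solver's reference
manual: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Planning model

A treatment plan consists of nonnegative sector times `t(i, s, c)`
(minutes) for each isocenter `i`, sector `s ∈ {1..8}` and collimator
`c ∈ {4, 8, 16 mm}`, plus per-isocenter shot times `τ_i ≥ max_s Σ_c
t(i, s, c)`.  Dose is linear in the times through precomputed
dose-rate kernels, `dose(p) = Σ Φ[p, (i,s,c)] · t(i,s,c)`.  The
weighted-sum objective penalizes target underdose (per-point weight
`wT/N_T`), shell overdose (`wS/N_S`), dose above a low-dose threshold
`D_LD` (`wLD/N_LD`), and total beam-on time (`wBOT`); OAR maximum doses
are hard constraints.  Objective terms are normalized by their point
counts so that the trade-off encoded by a weight vector is independent
of the sampling resolution.

The problem is solved in its LP dual `min c^T x, A x ≤ b, 0 ≤ x ≤ u`:
one dual column per dose point (α target, β shell, γ low-dose, δ OAR)
plus eight sector columns μ(i, s) per isocenter; 24 sector-time rows
and one shot-time row per isocenter (`m = 25 n_iso`,
`n = N_points + 8 n_iso`).  The cost vector carries the dose levels
(−D_presc on α, +D_presc on β, +D_LD on γ, +D_OARmax on δ, 0 on μ);
the weights appear only in `u` (per-point upper bounds `w/N`) and `b`
(`wBOT` on shot-time rows).  δ and μ columns are unbounded above — OAR
points do not contribute to the cost function.  Strong duality and the
recovery of the primal plan from the row duals are verified in the
test suite against an explicitly constructed primal LP.

**Assumptions.** Isocenter positions are fixed and weight-independent;
dose is exactly linear in sector times; all randomness is confined to
dose-point sampling.  Plan sequencing, shot pruning and detailed dose
engines are out of scope.

## ADMM solver

The scaled-form splitting introduces copies `(z1, z2)` of
`(x1, A x1)`.  Each iteration is: a least-squares step reduced via the
cached inverse of `S = A Aᵀ + I` to one matrix product; clipping of
`z1` to `[0, u]` and `z2` to `(−∞, b]`; and a dual ascent with step
size ρ.  Because instances share `A` and differ only in `(b, u, ρ)`,
all weight vectors advance together as matrix columns.  Design
choices:

* **Fixed iteration budget** (default 3000 per pass), no early
  stopping.  Residual traces (primal `‖x − z‖`, dual
  `ρ‖z^{k+1} − z^k‖`, both normalized by the current iterate norm
  since no reference solution is assumed) are recorded every 10
  iterations for diagnostics only.
* **Precision policy**: iterations in float32, the inverse of `S`
  always formed in float64 and then cast.  Both configurable; the test
  suite verifies that reconstructed doses from the two precisions
  agree within 0.5% or 0.05 Gy per dose point.
* **Explicit inverse** rather than a factorization, behind a
  `SchurOperator` interface so a factorization backend could be
  swapped in.  The `AᵀA + I` variant for tall matrices is deliberately
  not implemented: planning matrices are always wide.
* All per-iteration math is matrix products, additions and clips, so a
  GPU array backend would be a drop-in replacement; no
  backend-specific behavior is observable beyond round-off.
* Initial iterates are zero.  The divergence guard references the
  problem data scale as well as the first measured residual, because a
  zero start makes the first residual arbitrarily small.

The plan for column j is `ρ_j y₂*`, divided by the recorded row norms,
with small negative round-off clipped to zero, split into `t` (24 rows
per isocenter) and `τ` (1 row).  The exact-LP oracle recovers its plan
from the HiGHS constraint duals through the *same* un-scaling path, so
ADMM/oracle comparisons are apples to apples.

## Preconditioning and step size

* **Row normalization**: every row of `A` scaled to unit Euclidean
  norm (b scaled identically), making `diag(S) = 2` and all other
  entries of `S` lie in [−1, 1].
* **Beam-on-time column scaling**: after row normalization the μ
  columns are multiplied by `β = N_nonOAR_points / 2000`.  This is an
  exact reparametrization (μ columns have zero cost and no upper
  bound) that rebalances `S` so the beam-on-time term converges at the
  same rate as the dose terms when points outnumber isocenters.  With
  a single low-dose threshold, β uses the current pass's non-OAR point
  count (the shared union in pass 2).
* **Step size**: `ρ = 2.5×10⁻³ · w0_BOT / wBOT`, one ρ per weight
  vector (ρ enters only through the iterates, so batching is
  unaffected).
* **Weight scale calibration.** The heuristic's base constant is only
  meaningful relative to the overall magnitude of the weights, which a
  slider map must choose.  The plan itself is invariant to a global
  weight scale (positive homogeneity), but the ADMM trajectory is not.
  We replicated the standard tuning protocol — a step-size grid search
  against the exact oracle on a *separate* validation set of synthetic
  cases — and found the empirically optimal step size follows
  `ρ_opt ≈ 100 / wBOT` at unit weight scale, i.e. exactly the
  heuristic's 1/wBOT form.  Anchoring `scale · wbot_min = 4×10⁴`
  (default scale 8×10⁶ with `wbot ∈ [0.005, 0.2]`, referenced to a
  2000-point case) makes the base constant sit on that optimum across
  the whole slider range.  Because the objective is per-point
  normalized, the dual-iterate magnitude scales as `w/N`; the slider
  map therefore grows the (plan-invariant) weight scale linearly with
  the case's cost-function point count, which keeps the step-size rule
  size-independent.  The anchor multiplier was re-validated by a grid
  search over {1, 2, 4, 8}× on four validation cases spanning 1–9 cm³:
  1× is optimal, with worst-case first-pass deviations of
  0.07%/1.15% (total/BOT) at 2000 iterations and 0.04%/0.82% at 3000.
  The calibration used validation cases only; the evaluation suite was
  never consulted.

## Slider map

`wT = wS = scale` fixed; `wLD` and `wBOT` move log-linearly over
`[0.05, 2] · scale` and `[0.005, 0.2] · scale` as the sliders sweep
[0, 1].  The ranges were chosen so that the extreme corners remain
clinically meaningful on the synthetic suite: the high-BOT corner
still treats (it trims beam-on time rather than abandoning the
target), and the high-low-dose corner trades coverage for gradient
index without producing degenerate multi-hour plans.  A 21×21 grid
corresponds to slider steps of 0.05 (441 weight vectors).

## Two-pass optimization and overlapping sampling

Pass 1 samples low-dose points from a geometric expansion of the
target: the shell between `0.2·r_eff` and `0.6·r_eff` outside the
target surface (`r_eff` = radius of the volume-equivalent sphere),
clipped to the skull, excluding targets and OARs.  Pass 2 recomputes,
per weight vector, the band `[D_LD, D_LD + Δ)` of the first-pass dose
(default `Δ = 0.15·D_LD`; `D_LD = 0.5·D_presc`, aligning with the
half-prescription isodose of the gradient index).  An empty band falls
back to the geometric volume so the instance stays solvable.

Because the per-instance bands overlap heavily, points are drawn by a
thinning scheme: volumes are processed in order of non-increasing
target density `ω_j = N_j/|V_j|`; for each volume the running point
union is thinned to density `ω_j`, thinned points inside `V_j` are
reused, and only `V_j` minus the previous union receives fresh
points.  Every instance keeps its desired density in expectation
(`E|p_j| = ω_j|V_j|`), the reused count is binomial with relative
spread at most `sqrt((1−r)/(ω_j|V_j|))` (r = overlap fraction), and
the shared union P is far smaller than the sum of per-instance counts.
The LP's γ block is built once over P; instance j activates its own
points through its upper-bound column (`wLD/N_LD,j` on members, 0
elsewhere).  Volumes are voxel sets; points are uniformly jittered
voxel centers; ties in ω are broken by instance index.  Two passes are
used, matching clinical practice; the machinery supports more.

## Synthetic cases

Phantoms are spherical: a skull sphere, 1–9 spherical targets (total
volume 0.5–55 cm³; radii nudged ±8% so voxelized volumes match the
request within 5%), and optional small OARs placed 2–10 mm from a
target surface.  Dose-rate kernels are anisotropic Gaussians per
(isocenter, sector, collimator): widths 1.7/3.4/6.8 mm for the
4/8/16 mm collimators, 1.3× elongation along the sector direction, and
peaks `(calibration_rate / 8) · output_factor` with output factors
0.8/0.9/1.0 — so one isocenter with all eight sectors open at the
largest collimator delivers the calibration dose rate (3 Gy/min) at
its center, which is how a calibration dose rate is defined for the
machine.  Isocenters fill a cubic lattice inside each target with a
volume-adaptive pitch `3.4·(V/700 mm³)^0.27` mm (clipped to
[2.5, 8] mm), which keeps counts inside the clinically observed
17–214 range across the supported volume span.  Dose-point densities
(1/mm² target surface, 0.4/mm³ interior, 0.16/mm³ shell, 0.012/mm³
low-dose, 2/mm² OAR surface) and the per-category count caps reproduce
the clinically observed count ranges; the low-dose caps are 250–5000
points.  One case-level seed deterministically derives all per-category
sampling streams.

**What the generator does not emulate:** real anatomy (non-spherical
targets, heterogeneous tissue), measured beam kernels with scatter
tails, machine-exported isocenter placement, and couch/collimator
deliverability constraints.  Passing tests therefore demonstrate the
*algorithmic* claims — solver quality versus an exact oracle, sampling
statistics, precision policy — not clinical dosimetric accuracy.

## Evaluation suite and problem sizes

The evaluation suite holds five cases spanning the clinical envelope
in miniature: 0.7–10 cm³ total target volume, 0–2 OARs, one
multi-target case, prescriptions 13–20 Gy, 1–2 mm voxels, roughly
19–30 isocenters and 1800–6000 dose points per case.  These sizes
keep the batched
iterations cache-resident on a single CPU — the per-iteration cost is
dominated by memory traffic of `A`, `Aᵀ` and `S⁻¹`, so constraint
matrices are kept below ~25 MB in working precision — while preserving
the structural proportions (wide `A`, point-dominated columns) of the
clinical problems.  Dose reconstruction and clinical metrics
(coverage, selectivity, gradient index, beam-on time at 3 Gy/min) are
evaluated on the skull voxels within `0.9·r_eff + 10 mm` of the
target, a region that contains the prescription and half-prescription
isodose volumes.  The gradient index is reported as undefined when
prescriptions differ between targets, and selectivity when the
prescription isodose volume is empty.

## Numerical choices and degenerate inputs

* LP ties: multiple optima are acceptable; all comparisons are on
  objective values and clinical metrics, never on argmin identity.
* Recovered plan entries below `−10⁻³ · max` trigger a warning; all
  negatives are clipped to zero.
* A target too small to host a lattice point receives a single
  isocenter at its voxelized centroid; empty structures raise.
* Second-pass densities may exceed one point per voxel (points are
  continuous, jittered coordinates); requests above ten points per
  voxel are refused as unresolvable.
* Residuals at the fixed budgets settle around 10⁻³–10⁻² (normalized),
  consistent with the ~1% objective agreement of a first-order method;
  they are diagnostics, not stopping criteria.

## Known limitations

* The exact oracle (HiGHS) treats the dense `A` directly; very large
  cases would want a sparse or GPU path, which is out of scope here.
* The weight-scale anchor was calibrated for the per-point-normalized
  objective on planning-scale point counts; unit tests on very small
  instances use the same 1/wBOT law with a size-matched constant.
* Single-precision iterations limit the achievable duality gap; the
  fixed budgets stay well short of that limit.
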