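"""Shared fixtures: small deterministic cases and LPs used across tests."""

from __future__ import annotations

import numpy as np
import pytest

from paretoplan import (
    PhantomSpec,
    WeightVector,
    make_phantom,
    normalize_rows,
    scale_bot_columns,
    set_weights,
)
from paretoplan.lp_build import DualLP, assemble_dual_lp, bot_column_scaling


@pytest.fixture(scope="session")
def tiny_case():
    """Small single-target case with one OAR (fast enough for solves)."""
    spec = PhantomSpec(
        name="tiny",
        target_volumes_mm3=(900.0,),
        n_oars=1,
        prescription_gy=13.0,
        oar_max_gy=8.0,
        spacing_mm=1.0,
    )
    return make_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def multi_case():
    """Two-target case with differing prescriptions (undefined gradient index)."""
    spec = PhantomSpec(
        name="tiny-multi",
        target_volumes_mm3=(700.0, 900.0),
        n_oars=0,
        prescription_gy=(20.0, 18.0),
        spacing_mm=1.0,
    )
    return make_phantom(spec, seed=12)


def random_planning_lp(
    rng,
    n_iso=2,
    n_t=6,
    n_s=4,
    n_ld=3,
    n_oar=2,
    d_presc=20.0,
    d_ld=10.0,
    d_oar=12.0,
    r=8.0,
) -> DualLP:
    """Small random dual LP with genuine planning geometry.

    Random isocenters inside a sphere of radius ``r`` and Gaussian
    sector kernels evaluated at randomly placed target/shell/low-dose/
    OAR points -- the same structure as the full generator, without the
    voxel grid.
    """

    def sphere(rr, n, c=np.zeros(3)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return rr * v + c

    def ball(r0, r1, n):
        u = rng.uniform(r0**3, r1**3, n) ** (1 / 3)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return u[:, None] * v

    iso = ball(0, max(r - 1.5, 1.0), n_iso)
    sig = np.array([1.7, 3.4, 6.8])
    peak = (3.0 / 8) * np.array([0.8, 0.9, 1.0])
    ang = 2 * np.pi * np.arange(8) / 8
    dirs = np.stack([np.cos(ang), np.sin(ang), np.zeros(8)], 1)

    def influence(pts):
        phi = np.empty((len(pts), 24 * n_iso))
        for i in range(n_iso):
            d = pts - iso[i]
            dd = (d * d).sum(1)
            proj = d @ dirs.T
            perp2 = dd[:, None] - proj**2
            for s in range(8):
                for c in range(3):
                    q = perp2[:, s] / sig[c] ** 2 + proj[:, s] ** 2 / (1.3 * sig[c]) ** 2
                    phi[:, 24 * i + 3 * s + c] = peak[c] * np.exp(-0.5 * q)
        return phi

    points = {
        "target": np.vstack([sphere(r, n_t // 2), ball(0, r, n_t - n_t // 2)]),
        "shell": ball(r, r + 3, n_s),
        "low-dose": ball(1.2 * r, 1.6 * r, n_ld),
    }
    influences = {k: influence(v) for k, v in points.items()}
    levels = {"target": np.full(n_t, d_presc), "shell": np.full(n_s, d_presc)}
    if n_oar:
        influences["oar"] = influence(sphere(3.0, n_oar, c=np.array([r + 6.0, 0, 0])))
        levels["oar"] = np.full(n_oar, d_oar)
    return assemble_dual_lp(influences, levels, n_iso, d_ld)


def tuned_rho(lp: DualLP, wbot: float) -> float:
    """Step size matched to unit-scale weights on a small instance.

    Same 1/wBOT form as the production heuristic; the constant absorbs
    the per-point weight normalization (w/N) at this instance size.
    """
    n_cost = sum(v for k, v in lp.counts.items() if k != "oar")
    return 0.02 * n_cost / wbot


def preconditioned(lp: DualLP, weights: list[WeightVector] | None = None) -> DualLP:
    lp = normalize_rows(lp)
    lp = scale_bot_columns(lp, bot_column_scaling(lp.counts))
    if weights is not None:
        rho = [tuned_rho(lp, w.wBOT) for w in weights]
        it = iter(rho)
        lp = set_weights(lp, weights, rho_rule=lambda _w: next(it))
    return lp


@pytest.fixture(scope="session")
def small_lp():
    """A random planning LP with four weight columns spanning the sliders."""
    rng = np.random.default_rng(7)
    lp = random_planning_lp(rng, n_iso=2, n_t=60, n_s=30, n_ld=20, n_oar=10)
    weights = [
        WeightVector(wT=1.0, wS=1.0, wLD=wld, wBOT=wbot, sliders=(sl, sb))
        for (wld, wbot, sl, sb) in [
            (0.05, 0.005, 0.0, 0.0),
            (0.05, 0.2, 0.0, 1.0),
            (2.0, 0.005, 1.0, 0.0),
            (2.0, 0.2, 1.0, 1.0),
        ]
    ]
    return preconditioned(lp, weights)
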