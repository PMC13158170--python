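"""Case-bundle serialization and run configuration.

A case bundle is a directory with a ``case.json`` (metadata: schema
version, grid, dose levels, seeds, kernel parameters) and an
``arrays.npz`` with the dense arrays (masks, isocenter positions).
Round-trips are lossless and schema-versioned; unknown versions are
refused explicitly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .case_synth import (
    IsocenterSet,
    KernelBank,
    PhantomSpec,
    StructureSet,
    SyntheticCase,
    VoxelGrid,
)

__all__ = ["SCHEMA_VERSION", "BundleError", "write_case", "read_case", "RunConfig", "parse_grid"]

SCHEMA_VERSION = 1
SCHEMA_NAME = "paretoplan-case"


class BundleError(RuntimeError):
    """Raised for missing, truncated, corrupted or unsupported bundles."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_case(case: SyntheticCase, out_dir: str | Path) -> Path:
    """Write a case bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {
        "skull": case.structures.skull,
        "iso_positions": case.kernels.positions,
    }
    for k, t in enumerate(case.structures.targets):
        arrays[f"target_{k}"] = t
    for k, o in enumerate(case.structures.oars):
        arrays[f"oar_{k}"] = o
    npz_path = out / "arrays.npz"
    np.savez_compressed(npz_path, **arrays)
    meta = {
        "schema": SCHEMA_NAME,
        "version": SCHEMA_VERSION,
        "name": case.name,
        "seed": case.seed,
        "grid": {
            "shape": list(case.grid.shape),
            "spacing": list(case.grid.spacing),
            "origin": list(case.grid.origin),
        },
        "n_targets": len(case.structures.targets),
        "n_oars": len(case.structures.oars),
        "prescription_gy": list(case.structures.prescription_gy),
        "oar_max_gy": list(case.structures.oar_max_gy),
        "d_ld": case.d_ld,
        "kernels": {
            "calibration_dose_rate": case.kernels.calibration_dose_rate,
            "sigma_mm": list(case.kernels.sigma_mm),
            "anisotropy": case.kernels.anisotropy,
            "output_factors": list(case.kernels.output_factors),
        },
        "spec": asdict(case.spec) if case.spec else None,
        "meta": case.meta,
        "checksum_arrays": _sha256(npz_path),
    }
    (out / "case.json").write_text(json.dumps(meta, indent=2))
    return out


def read_case(bundle_dir: str | Path) -> SyntheticCase:
    """Read a case bundle back; refuses unknown schema versions."""
    bundle = Path(bundle_dir)
    meta_path = bundle / "case.json"
    npz_path = bundle / "arrays.npz"
    if not meta_path.exists() or not npz_path.exists():
        raise BundleError(f"incomplete case bundle at {bundle}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"corrupt case.json: {exc}") from exc
    if meta.get("schema") != SCHEMA_NAME:
        raise BundleError(f"not a {SCHEMA_NAME} bundle")
    if meta.get("version") != SCHEMA_VERSION:
        raise BundleError(
            f"unsupported bundle version {meta.get('version')} (supported: {SCHEMA_VERSION})"
        )
    if meta.get("checksum_arrays") != _sha256(npz_path):
        raise BundleError("array checksum mismatch; bundle is corrupted or truncated")
    try:
        with np.load(npz_path) as data:
            skull = data["skull"]
            targets = [data[f"target_{k}"] for k in range(meta["n_targets"])]
            oars = [data[f"oar_{k}"] for k in range(meta["n_oars"])]
            iso = data["iso_positions"]
    except (KeyError, ValueError, OSError) as exc:
        raise BundleError(f"truncated or invalid arrays.npz: {exc}") from exc

    g = meta["grid"]
    grid = VoxelGrid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
    structures = StructureSet(
        targets=targets,
        oars=oars,
        skull=skull,
        prescription_gy=list(meta["prescription_gy"]),
        oar_max_gy=list(meta["oar_max_gy"]),
    )
    kern = meta["kernels"]
    kernels = KernelBank(
        positions=iso,
        calibration_dose_rate=kern["calibration_dose_rate"],
        sigma_mm=tuple(kern["sigma_mm"]),
        anisotropy=kern["anisotropy"],
        output_factors=tuple(kern["output_factors"]),
    )
    spec = PhantomSpec(**{**meta["spec"], "target_volumes_mm3": tuple(meta["spec"]["target_volumes_mm3"]),
                          "prescription_gy": _tupled(meta["spec"]["prescription_gy"])}) if meta.get("spec") else None
    return SyntheticCase(
        name=meta["name"],
        grid=grid,
        structures=structures,
        isocenters=IsocenterSet(positions=iso),
        kernels=kernels,
        d_ld=meta["d_ld"],
        seed=meta["seed"],
        spec=spec,
        meta=meta.get("meta", {}),
    )


def _tupled(v):
    return tuple(v) if isinstance(v, (list, tuple)) else v


def parse_grid(spec: str) -> list[tuple[float, float]]:
    """Parse a slider grid like ``"21x21"`` into uniform (sLD, sBOT) pairs."""
    a, _, b = spec.partition("x")
    n_ld, n_bot = int(a), int(b or a)
    if n_ld < 2 or n_bot < 2:
        raise ValueError("grid needs at least 2 steps per axis")
    return [
        (float(s_ld), float(s_bot))
        for s_ld in np.linspace(0.0, 1.0, n_ld)
        for s_bot in np.linspace(0.0, 1.0, n_bot)
    ]


@dataclass
class RunConfig:
    """End-to-end experiment configuration (uniform slider grid)."""

    grid: str = "3x3"
    n_iter: int = 3000
    precision: str = "single"
    seed: int = 0
    tol_total: float = 0.03  # validation gate on total-objective error
    tol_bot: float = 0.05  # validation gate on beam-on-time-term error
    out_dir: str = "results"
    extra: dict = field(default_factory=dict)

    def slider_pairs(self) -> list[tuple[float, float]]:
        return parse_grid(self.grid)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        known["extra"] = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cls(**known)
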