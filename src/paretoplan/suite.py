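"""Desk-scale synthetic case suites emulating the clinical test set.

The clinical benchmark spans meningioma (ME), multiple-metastases (MM)
and vestibular-schwannoma (VS) cases with total target volumes from
0.66 to 52 cm^3, 0-2 OARs and 17-214 isocenters.  The suites below
reproduce that structure at sizes a single CPU can sweep in minutes:
five cases covering small/medium/large single targets, a multi-target
case, and OAR-bearing cases.  Prescription doses follow common practice
for the respective indications (vestibular schwannoma ~13 Gy,
meningioma ~15 Gy, metastases ~20 Gy).
"""

from __future__ import annotations

from .case_synth import PhantomSpec, SyntheticCase, make_phantom

__all__ = ["paper_like_specs", "validation_specs", "build_suite"]


def paper_like_specs() -> list[PhantomSpec]:
    """The five-case evaluation suite (seeded separately per case)."""
    return [
        PhantomSpec(
            name="vs-small",
            target_volumes_mm3=(700.0,),
            n_oars=2,
            prescription_gy=13.0,
            oar_max_gy=8.0,
            spacing_mm=1.0,
        ),
        PhantomSpec(
            name="me-small",
            target_volumes_mm3=(2000.0,),
            n_oars=1,
            prescription_gy=15.0,
            oar_max_gy=10.0,
            spacing_mm=1.0,
        ),
        PhantomSpec(
            name="me-mid",
            target_volumes_mm3=(6500.0,),
            n_oars=1,
            prescription_gy=15.0,
            oar_max_gy=10.0,
            spacing_mm=2.0,
        ),
        PhantomSpec(
            name="mm-multi",
            target_volumes_mm3=(1200.0, 1600.0, 2200.0),
            n_oars=0,
            prescription_gy=20.0,
            spacing_mm=2.0,
        ),
        PhantomSpec(
            name="me-large",
            target_volumes_mm3=(10000.0,),
            n_oars=1,
            prescription_gy=15.0,
            oar_max_gy=10.0,
            spacing_mm=2.0,
        ),
    ]


def validation_specs() -> list[PhantomSpec]:
    """Separate cases used to tune solver settings (never for evaluation)."""
    return [
        PhantomSpec(
            name="val-vs",
            target_volumes_mm3=(1000.0,),
            n_oars=1,
            prescription_gy=13.0,
            oar_max_gy=8.0,
            spacing_mm=1.0,
        ),
        PhantomSpec(
            name="val-me",
            target_volumes_mm3=(5000.0,),
            n_oars=1,
            prescription_gy=15.0,
            oar_max_gy=10.0,
            spacing_mm=2.0,
        ),
        PhantomSpec(
            name="val-mm",
            target_volumes_mm3=(1200.0, 3000.0),
            n_oars=0,
            prescription_gy=20.0,
            spacing_mm=2.0,
        ),
    ]


def build_suite(specs: list[PhantomSpec] | None = None, seed: int = 1) -> list[SyntheticCase]:
    """Instantiate a suite with per-case seeds derived from one master seed."""
    specs = paper_like_specs() if specs is None else specs
    return [make_phantom(spec, seed=seed * 1000 + k) for k, spec in enumerate(specs)]
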