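"""Self-contained case interchange: one JSON metadata file + raw arrays.

A *case directory* holds everything a feasibility evaluation needs without
clinical DICOM data: the new plan, structure masks, prior courses with their
rigid transforms and per-OAR trust flags, the prescription and the anatomical
region. Arrays are flat little-endian binaries (C order) whose dtype and
shape are declared in ``case.json``; masks are uint8, doses float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .feasibility import PriorCourse
from .grid import (
    DoseGrid,
    Grid3D,
    Modality,
    OrganClass,
    RigidTransform,
    StructureMask,
    Trust,
)
from .tolerances import Region

__all__ = ["Case", "save_case", "load_case", "CaseFormatError"]

SCHEMA = "rertkit-case/1"


class CaseFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Case:
    """One reirradiation case: new plan + structures + prior courses."""

    reference_grid: Grid3D
    new_plan: DoseGrid | None
    structures: tuple[StructureMask, ...]
    prior_courses: tuple[PriorCourse, ...]
    prescription_gy: float | None = None
    region: Region | None = None
    toxicity_concern: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        object.__setattr__(self, "prior_courses", tuple(self.prior_courses))
        if self.region is not None:
            object.__setattr__(self, "region", Region(self.region))

    def targets(self) -> list[StructureMask]:
        return [s for s in self.structures if s.organ_class is OrganClass.TARGET]

    def oars(self) -> list[StructureMask]:
        return [s for s in self.structures if s.organ_class is not OrganClass.TARGET]


def _grid_meta(grid: Grid3D) -> dict[str, Any]:
    return {
        "origin_mm": list(grid.origin),
        "spacing_mm": list(grid.spacing),
        "shape": list(grid.shape),
    }


def _grid_from_meta(meta: dict[str, Any]) -> Grid3D:
    return Grid3D(
        tuple(meta["origin_mm"]), tuple(meta["spacing_mm"]), tuple(meta["shape"])
    )


def _write_array(directory: Path, stem: str, values: np.ndarray) -> dict[str, Any]:
    dtype = "<u1" if values.dtype == bool else "<f8"
    path = directory / f"{stem}.raw"
    values.astype(dtype).tofile(path)
    return {"file": path.name, "dtype": dtype, "shape": list(values.shape)}


def _read_array(directory: Path, meta: dict[str, Any]) -> np.ndarray:
    path = directory / meta["file"]
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    expected = int(np.prod(meta["shape"]))
    if arr.size != expected:
        raise CaseFormatError(
            f"{path.name}: got {arr.size} values, expected {expected}"
        )
    return arr.reshape(meta["shape"])


def _dose_meta(directory: Path, stem: str, dose: DoseGrid) -> dict[str, Any]:
    return {
        "grid": _grid_meta(dose.grid),
        "n_fractions": dose.n_fractions,
        "modality": dose.modality.value,
        "course_id": dose.course_id,
        "treatment_date": dose.treatment_date,
        "array": _write_array(directory, stem, dose.values),
    }


def _dose_from_meta(directory: Path, meta: dict[str, Any]) -> DoseGrid:
    return DoseGrid(
        grid=_grid_from_meta(meta["grid"]),
        values=_read_array(directory, meta["array"]),
        n_fractions=meta["n_fractions"],
        modality=Modality(meta["modality"]),
        course_id=meta.get("course_id", ""),
        treatment_date=meta.get("treatment_date"),
    )


def _mask_meta(directory: Path, stem: str, mask: StructureMask) -> dict[str, Any]:
    return {
        "grid": _grid_meta(mask.grid),
        "name": mask.name,
        "organ_class": mask.organ_class.value,
        "prv_margin_mm": mask.prv_margin_mm,
        "array": _write_array(directory, stem, mask.values),
    }


def _mask_from_meta(directory: Path, meta: dict[str, Any]) -> StructureMask:
    return StructureMask(
        grid=_grid_from_meta(meta["grid"]),
        values=_read_array(directory, meta["array"]).astype(bool),
        name=meta["name"],
        organ_class=OrganClass(meta["organ_class"]),
        prv_margin_mm=meta.get("prv_margin_mm", 0.0),
    )


def save_case(case: Case, directory: str | Path) -> Path:
    """Write a case directory; returns the path of ``case.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict[str, Any] = {
        "schema": SCHEMA,
        "reference_grid": _grid_meta(case.reference_grid),
        "prescription_gy": case.prescription_gy,
        "region": case.region.value if case.region else None,
        "toxicity_concern": case.toxicity_concern,
        "new_plan": (
            _dose_meta(directory, "new_plan", case.new_plan)
            if case.new_plan is not None else None
        ),
        "structures": [
            _mask_meta(directory, f"struct_{i:02d}_{s.name}", s)
            for i, s in enumerate(case.structures)
        ],
        "prior_courses": [
            {
                "dose": _dose_meta(directory, f"prior_{i:02d}_dose", c.dose),
                "transform": {
                    "rotation": np.asarray(
                        c.transform_to_reference.rotation
                    ).ravel().tolist(),
                    "translation_mm": np.asarray(
                        c.transform_to_reference.translation
                    ).tolist(),
                    "trust": {
                        k: v.value
                        for k, v in c.transform_to_reference.trust.items()
                    },
                },
                "structures": [
                    _mask_meta(directory, f"prior_{i:02d}_struct_{j:02d}_{s.name}", s)
                    for j, s in enumerate(c.structures)
                ],
            }
            for i, c in enumerate(case.prior_courses)
        ],
    }
    out = directory / "case.json"
    out.write_text(json.dumps(doc, indent=2))
    return out


def load_case(directory: str | Path) -> Case:
    """Load a case directory written by :func:`save_case` (schema-checked)."""
    directory = Path(directory)
    doc = json.loads((directory / "case.json").read_text())
    if doc.get("schema") != SCHEMA:
        raise CaseFormatError(
            f"unsupported case schema {doc.get('schema')!r}; expected {SCHEMA!r}"
        )
    for key in ("reference_grid", "structures", "prior_courses"):
        if key not in doc:
            raise CaseFormatError(f"case.json is missing the {key!r} section")
    prior = []
    for c in doc["prior_courses"]:
        tf = c["transform"]
        prior.append(
            PriorCourse(
                dose=_dose_from_meta(directory, c["dose"]),
                transform_to_reference=RigidTransform(
                    rotation=np.asarray(tf["rotation"], dtype=float).reshape(3, 3),
                    translation=np.asarray(tf["translation_mm"], dtype=float),
                    trust={k: Trust(v) for k, v in tf.get("trust", {}).items()},
                ),
                structures=tuple(
                    _mask_from_meta(directory, m) for m in c.get("structures", [])
                ),
            )
        )
    return Case(
        reference_grid=_grid_from_meta(doc["reference_grid"]),
        new_plan=(
            _dose_from_meta(directory, doc["new_plan"])
            if doc.get("new_plan") else None
        ),
        structures=tuple(_mask_from_meta(directory, m) for m in doc["structures"]),
        prior_courses=tuple(prior),
        prescription_gy=doc.get("prescription_gy"),
        region=Region(doc["region"]) if doc.get("region") else None,
        toxicity_concern=bool(doc.get("toxicity_concern", False)),
    )
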