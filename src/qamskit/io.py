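"""CSV/JSON readers and writers for peak tables, matrices and models.

All CSV is comma-separated UTF-8 with a mandatory header row and "." as the
decimal separator. Column schemas are documented in ``docs/formats.md``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    CalibrationCurve,
    ClassificationModel,
    ConcentrationMatrix,
    ConditionLabel,
    DendrogramResult,
    NOMINAL_CONDITION,
    PeakRecord,
    RCFTable,
    UncertaintyBudget,
    ValidationError,
)

__all__ = [
    "PeakTableFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_concentration_matrix",
    "write_concentration_matrix",
    "write_json",
    "read_json",
    "curve_to_dict",
    "curve_from_dict",
    "rcf_table_to_dict",
    "rcf_table_from_dict",
    "model_to_dict",
    "model_from_dict",
    "budget_to_dict",
    "dendrogram_to_dict",
    "dendrogram_from_dict",
]

_MANDATORY = ("sample_id", "compound_id", "area")
_CONDITION_FIELDS = ("instrument", "column", "temperature", "flow_rate")


class PeakTableFormatError(ValueError):
    """Raised when a peak-table CSV does not match the documented schema."""


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a long-format peak table CSV into validated records.

    Mandatory columns: sample_id, compound_id, area. Optional:
    injection_volume, replicate and the condition fields (instrument, column,
    temperature, flow_rate). Row order is preserved.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise PeakTableFormatError(f"peak table {path} is missing column(s): {', '.join(missing)}")
    records: list[PeakRecord] = []
    has_condition = all(c in frame.columns for c in _CONDITION_FIELDS)
    for i, row in enumerate(frame.itertuples(index=False)):
        condition = NOMINAL_CONDITION
        if has_condition:
            condition = ConditionLabel(
                instrument=str(row.instrument),
                column=str(row.column),
                temperature=float(row.temperature),
                flow_rate=float(row.flow_rate),
            )
        try:
            records.append(
                PeakRecord(
                    sample_id=str(row.sample_id),
                    compound_id=str(row.compound_id),
                    area=float(row.area),
                    injection_volume=float(getattr(row, "injection_volume", 1.0)),
                    condition=condition,
                    replicate=int(getattr(row, "replicate", 1)),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i + 2} of {path}: {exc}") from exc
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "compound_id": r.compound_id,
                "area": repr(float(r.area)),
                "injection_volume": repr(float(r.injection_volume)),
                "replicate": r.replicate,
                "instrument": r.condition.instrument,
                "column": r.condition.column,
                "temperature": r.condition.temperature,
                "flow_rate": r.condition.flow_rate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_concentration_matrix(path: str | Path, method: str | None = None) -> ConcentrationMatrix:
    """Read a wide samples x compounds CSV (first column = sample id)."""
    frame = pd.read_csv(path, index_col=0)
    tag = method
    if tag is None:
        tag = "QAMS"
        name = frame.index.name or ""
        if "#" in name:
            tag = name.split("#", 1)[1]
    return ConcentrationMatrix.from_frame(frame, method=tag)


def write_concentration_matrix(matrix: ConcentrationMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = f"sample_id#{matrix.method}"
    # shortest-repr float formatting round-trips bit-exactly
    frame.to_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def curve_to_dict(curve: CalibrationCurve) -> dict:
    d = dataclasses.asdict(curve)
    d["linear_range"] = list(curve.linear_range)
    return d


def curve_from_dict(d: dict) -> CalibrationCurve:
    d = dict(d)
    d["linear_range"] = tuple(d.get("linear_range", (0.0, 0.0)))
    return CalibrationCurve(**d)


def rcf_table_to_dict(table: RCFTable) -> dict:
    return {
        "reference_id": table.reference_id,
        "mean_rcf": table.mean_rcf,
        "per_level_rcfs": table.per_level_rcfs,
        "robustness_rsd_pct": table.robustness_rsd_pct,
    }


def rcf_table_from_dict(d: dict) -> RCFTable:
    return RCFTable(
        reference_id=d["reference_id"],
        mean_rcf=d["mean_rcf"],
        per_level_rcfs=d.get("per_level_rcfs", {}),
        robustness_rsd_pct=d.get("robustness_rsd_pct", {}),
    )


def model_to_dict(model: ClassificationModel) -> dict:
    return {
        "group_labels": model.group_labels,
        "fisher_coefficients": model.fisher_coefficients.tolist(),
        "fisher_constants": model.fisher_constants.tolist(),
        "variable_order": model.variable_order,
        "canonical_eigenvalues": list(model.canonical_eigenvalues),
        "variance_shares_pct": list(model.variance_shares_pct),
    }


def model_from_dict(d: dict) -> ClassificationModel:
    return ClassificationModel(
        group_labels=list(d["group_labels"]),
        fisher_coefficients=np.asarray(d["fisher_coefficients"], dtype=float),
        fisher_constants=np.asarray(d["fisher_constants"], dtype=float),
        variable_order=list(d["variable_order"]),
        canonical_eigenvalues=list(d.get("canonical_eigenvalues", [])),
        variance_shares_pct=list(d.get("variance_shares_pct", [])),
    )


def budget_to_dict(budget: UncertaintyBudget) -> dict:
    return dataclasses.asdict(budget)


def dendrogram_to_dict(result: DendrogramResult) -> dict:
    return {
        "sample_ids": result.sample_ids,
        "merge_steps": [[int(a), int(b), float(h)] for a, b, h in result.merge_steps],
        "rescaled_heights": [float(h) for h in result.rescaled_heights],
    }


def dendrogram_from_dict(d: dict) -> DendrogramResult:
    return DendrogramResult(
        sample_ids=list(d["sample_ids"]),
        merge_steps=[(int(a), int(b), float(h)) for a, b, h in d["merge_steps"]],
        rescaled_heights=[float(h) for h in d["rescaled_heights"]],
    )
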