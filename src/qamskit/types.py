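"""Core data types for single-marker (QAMS) chromatographic quantification.

The vocabulary follows UPLC/HPLC practice: a *peak record* is one integrated
detector response for one compound in one injection; a *calibration curve* is
a linear detector-response model for one compound; a *relative calibration
factor* (RCF, ``f_si``) relates the response factor (area per concentration)
of the internal reference substance *s* to that of a target compound *i*, so
that every target can be quantified from the reference peak alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "ConditionLabel",
    "NOMINAL_CONDITION",
    "PeakRecord",
    "CalibrationPoint",
    "CalibrationCurve",
    "ExtractionParams",
    "RCFTable",
    "ConcentrationMatrix",
    "UncertaintyBudget",
    "ClassificationModel",
    "DendrogramResult",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a record or table violates a domain invariant."""


@dataclass(frozen=True)
class Compound:
    """A quantified analyte; exactly one compound per study is the reference."""

    id: str
    name: str
    role: str = "target"  # "reference" or "target"

    def __post_init__(self) -> None:
        if self.role not in ("reference", "target"):
            raise ValidationError(f"compound role must be reference/target, got {self.role!r}")


@dataclass(frozen=True)
class ConditionLabel:
    """Instrumental condition under which a peak was acquired.

    Robustness studies vary instrument, column, column temperature (degC) and
    mobile-phase flow rate (mL/min); the nominal condition is the default.
    """

    instrument: str = "nominal"
    column: str = "nominal"
    temperature: float = 35.0
    flow_rate: float = 0.30


NOMINAL_CONDITION = ConditionLabel()


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak (detector counts).

    ``injection_volume`` is in uL and must be positive; ``area`` must be
    non-negative.
    """

    sample_id: str
    compound_id: str
    area: float
    injection_volume: float = 1.0
    condition: ConditionLabel = NOMINAL_CONDITION
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError(
                f"peak area must be >= 0 (sample {self.sample_id!r}, "
                f"compound {self.compound_id!r}, got {self.area})"
            )
        if self.injection_volume <= 0:
            raise ValidationError(
                f"injection volume must be > 0 (sample {self.sample_id!r}, got {self.injection_volume})"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class CalibrationPoint:
    """A (concentration mg/L, peak area) pair on a calibration series."""

    concentration: float
    area: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError(f"calibration concentration must be > 0, got {self.concentration}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response for one compound: area = slope*conc + intercept.

    ``lod``/``loq`` are the signal-to-noise 3:1 and 10:1 limits; ``mdl``/``mql``
    are the replicate-spike method detection/quantitation limits. All limits
    and the linear range are in mg/L.
    """

    compound_id: str
    slope: float
    intercept: float
    r_squared: float
    lod: float = 0.0
    loq: float = 0.0
    mdl: float = 0.0
    mql: float = 0.0
    linear_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"calibration slope must be > 0 for {self.compound_id!r}")
        if self.loq < self.lod or self.mql < self.mdl:
            raise ValidationError(f"LOQ >= LOD and MQL >= MDL required for {self.compound_id!r}")

    def response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class ExtractionParams:
    """Extraction scale: powder mass (g) extracted into a solvent volume (mL)."""

    powder_mass: float = 1.0
    extract_volume: float = 25.0

    def __post_init__(self) -> None:
        if self.powder_mass <= 0 or self.extract_volume <= 0:
            raise ValidationError("powder mass and extract volume must be > 0")

    def content_from_solution(self, conc_mg_per_l: float) -> float:
        """Convert a solution concentration (mg/L) to content (mg/g dry powder)."""
        return conc_mg_per_l * (self.extract_volume / 1000.0) / self.powder_mass

    def solution_from_content(self, content_mg_per_g: float) -> float:
        """Inverse of :meth:`content_from_solution`."""
        return content_mg_per_g * self.powder_mass / (self.extract_volume / 1000.0)


@dataclass
class RCFTable:
    """Relative calibration factors f_si for all targets against one reference.

    The reference's factor against itself is exactly 1.
    """

    reference_id: str
    mean_rcf: dict[str, float]
    per_level_rcfs: dict[str, list[float]] = field(default_factory=dict)
    robustness_rsd_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_rcf = dict(self.mean_rcf)
        self.mean_rcf.setdefault(self.reference_id, 1.0)
        for cid, f in self.mean_rcf.items():
            if f <= 0:
                raise ValidationError(f"RCF must be > 0 (compound {cid!r}, got {f})")


@dataclass
class ConcentrationMatrix:
    """Samples x compounds content matrix, mg per g dry powder.

    ``method`` tags how the values were obtained: "ESM" (per-compound external
    calibration), "QAMS" (single-marker), or "truth" (simulation ground truth).
    """

    sample_ids: list[str]
    compound_ids: list[str]
    values: np.ndarray
    method: str = "QAMS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.compound_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.compound_ids)} compounds"
            )
        if np.any(np.isnan(self.values)):
            raise ValidationError("concentration matrix contains missing values")
        if np.any(self.values < 0):
            raise ValidationError("concentration matrix contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.compound_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, method: str = "QAMS") -> "ConcentrationMatrix":
        return cls(
            sample_ids=[str(i) for i in frame.index],
            compound_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            method=method,
        )

    def column(self, compound_id: str) -> np.ndarray:
        return self.values[:, self.compound_ids.index(compound_id)]

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def reorder(self, compound_ids: Sequence[str]) -> "ConcentrationMatrix":
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return ConcentrationMatrix(
            sample_ids=list(self.sample_ids),
            compound_ids=list(compound_ids),
            values=self.values[:, idx],
            method=self.method,
        )


@dataclass(frozen=True)
class UncertaintyBudget:
    """Expanded-uncertainty budget U = k*c*sqrt(sum of squared relative components)."""

    c: float
    k: float
    ur_sample: float
    ur_cal: float
    ur_true: float
    ur_rep: float
    ur_lod: float
    U: float

    @property
    def components(self) -> tuple[float, float, float, float, float]:
        return (self.ur_sample, self.ur_cal, self.ur_true, self.ur_rep, self.ur_lod)


@dataclass
class ClassificationModel:
    """Fisher linear classification functions plus canonical-DA summaries.

    ``fisher_coefficients`` has one row per group in ``group_labels`` and one
    column per compound in ``variable_order`` (score per mg/g). A sample is
    assigned to the group whose linear score is highest.
    """

    group_labels: list[str]
    fisher_coefficients: np.ndarray
    fisher_constants: np.ndarray
    variable_order: list[str]
    canonical_eigenvalues: list[float] = field(default_factory=list)
    variance_shares_pct: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fisher_coefficients = np.asarray(self.fisher_coefficients, dtype=float)
        self.fisher_constants = np.asarray(self.fisher_constants, dtype=float)
        g, p = len(self.group_labels), len(self.variable_order)
        if self.fisher_coefficients.shape != (g, p):
            raise ValidationError(
                f"coefficient matrix shape {self.fisher_coefficients.shape} != ({g}, {p})"
            )
        if self.fisher_constants.shape != (g,):
            raise ValidationError("one constant per group required")
        if self.variance_shares_pct:
            if any(s < 0 for s in self.variance_shares_pct):
                raise ValidationError("variance shares must be >= 0")
            if abs(sum(self.variance_shares_pct) - 100.0) > 0.1:
                raise ValidationError("variance shares must sum to 100 (+-0.1)")

    def scores(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.variable_order),):
            raise ValidationError(
                f"expected {len(self.variable_order)} variables, got {x.shape}"
            )
        return self.fisher_coefficients @ x + self.fisher_constants


@dataclass
class DendrogramResult:
    """Agglomerative merge tree with heights rescaled to the 0-25 axis.

    ``merge_steps`` follows the scipy linkage convention: row i merges
    clusters ``a`` and ``b`` (original samples are 0..n-1; merged clusters
    n+i) at ``height``. ``rescaled_heights`` maps heights linearly so the
    final merge sits at 25 — the dendrogram axis convention of common
    statistics packages.
    """

    sample_ids: list[str]
    merge_steps: list[tuple[int, int, float]]
    rescaled_heights: list[float]

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merge_steps]
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)
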