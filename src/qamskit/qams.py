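"""Single-marker quantification via relative calibration factors.

The relative calibration factor (RCF) of target *i* against reference *s* is
the ratio of response factors measured on paired calibration levels,

    f_si = (A_s / C_s) / (A_i / C_i),

and the final factor is the unweighted mean over levels. Once the factors
are established, only the reference compound needs a calibration curve: the
target concentration follows from the two peak areas in the same injection,

    C_i = f_si * C_s * A_i / A_s.

Because any detector gain multiplies all areas alike, f_si is exactly
invariant under instrument, column, temperature or flow-rate changes that
act as a common multiplicative factor — the basis of the robustness check.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import LinearCalibration, esm_concentration
from .types import (
    CalibrationCurve,
    CalibrationPoint,
    ConcentrationMatrix,
    ExtractionParams,
    PeakRecord,
    RCFTable,
    ValidationError,
)
from .validation import rsd_pct

__all__ = [
    "compute_rcf",
    "rcf_robustness",
    "qams_concentration",
    "quantify_samples",
    "QAMSQuantifier",
]


def compute_rcf(
    ref: Sequence[CalibrationPoint], target: Sequence[CalibrationPoint]
) -> tuple[list[float], float]:
    """Per-level and mean relative calibration factor f_si.

    Levels are paired by position; both series must have the same length and
    strictly positive areas and concentrations.
    """
    if len(ref) != len(target):
        raise ValidationError(
            f"reference ({len(ref)}) and target ({len(target)}) series must pair level-by-level"
        )
    if not ref:
        raise ValidationError("at least one paired level is required")
    per_level = []
    for lvl, (s, i) in enumerate(zip(ref, target), start=1):
        for point, which in ((s, "reference"), (i, "target")):
            if point.area <= 0 or point.concentration <= 0:
                raise ValidationError(
                    f"level {lvl}: {which} area and concentration must be > 0"
                )
        per_level.append((s.area / s.concentration) / (i.area / i.concentration))
    return per_level, float(np.mean(per_level))


def rcf_robustness(
    rcfs_by_condition: Mapping[object, Mapping[str, float]],
    threshold_pct: float = 5.0,
) -> dict[str, tuple[float, bool]]:
    """Per-compound RSD% of the RCF across >= 2 conditions, with pass flag.

    A compound passes when its RSD across conditions is below
    ``threshold_pct`` (the conventional 5% robustness criterion).
    """
    if len(rcfs_by_condition) < 2:
        raise ValidationError("robustness needs >= 2 conditions")
    by_compound: dict[str, list[float]] = defaultdict(list)
    for per_compound in rcfs_by_condition.values():
        for cid, f in per_compound.items():
            by_compound[cid].append(float(f))
    out = {}
    for cid, values in by_compound.items():
        rsd = rsd_pct(values)
        out[cid] = (rsd, rsd < threshold_pct)
    return out


def qams_concentration(
    area_target: float, area_ref: float, conc_ref: float, f_si: float
) -> float:
    """Single-marker concentration C_i = f_si * C_s * A_i / A_s (mg/L)."""
    if area_ref <= 0:
        raise ValidationError(f"reference area must be > 0, got {area_ref}")
    if f_si <= 0:
        raise ValidationError(f"relative calibration factor must be > 0, got {f_si}")
    return f_si * conc_ref * area_target / area_ref


def _mean_areas(peaks: Sequence[PeakRecord]) -> dict[str, dict[str, float]]:
    """sample_id -> compound_id -> replicate-averaged area, preserving order."""
    sums: dict[str, dict[str, list[float]]] = {}
    for p in peaks:
        sums.setdefault(p.sample_id, {}).setdefault(p.compound_id, []).append(p.area)
    return {
        sid: {cid: float(np.mean(v)) for cid, v in comps.items()}
        for sid, comps in sums.items()
    }


def quantify_samples(
    peaks: Sequence[PeakRecord],
    extraction: ExtractionParams,
    method: str = "QAMS",
    ref_curve: CalibrationCurve | None = None,
    rcf: RCFTable | None = None,
    curves: Mapping[str, CalibrationCurve] | None = None,
    skip_invalid: bool = False,
) -> ConcentrationMatrix:
    """Quantify every sample/compound in a peak table to mg/g dry powder.

    In QAMS mode the reference concentration C_s comes from inverting the
    reference curve, and every other compound follows from its RCF; in ESM
    mode each compound is inverted through its own curve. Replicate
    injections of the same sample/compound are averaged first.
    """
    method = method.upper()
    if method not in ("QAMS", "ESM"):
        raise ValidationError(f"method must be QAMS or ESM, got {method!r}")
    if method == "QAMS":
        if ref_curve is None or rcf is None:
            raise ValidationError("QAMS quantification needs ref_curve and rcf")
    elif curves is None:
        raise ValidationError("ESM quantification needs a curve per compound")

    areas = _mean_areas(peaks)
    compound_ids: list[str] = []
    for p in peaks:
        if p.compound_id not in compound_ids:
            compound_ids.append(p.compound_id)

    rows, sample_ids, errors = [], [], []
    for sid, comp_areas in areas.items():
        try:
            row = []
            if method == "QAMS":
                ref_id = rcf.reference_id
                if ref_id not in comp_areas:
                    raise ValidationError(f"sample {sid!r} lacks the reference peak ({ref_id!r})")
                a_ref = comp_areas[ref_id]
                c_ref = esm_concentration(a_ref, ref_curve)
                for cid in compound_ids:
                    if cid not in comp_areas:
                        raise ValidationError(f"sample {sid!r} lacks a peak for {cid!r}")
                    if cid == ref_id:
                        conc = c_ref
                    else:
                        if cid not in rcf.mean_rcf:
                            raise ValidationError(f"no RCF for compound {cid!r}")
                        conc = qams_concentration(comp_areas[cid], a_ref, c_ref, rcf.mean_rcf[cid])
                    row.append(extraction.content_from_solution(conc))
            else:
                for cid in compound_ids:
                    if cid not in comp_areas:
                        raise ValidationError(f"sample {sid!r} lacks a peak for {cid!r}")
                    if cid not in curves:
                        raise ValidationError(f"no calibration curve for compound {cid!r}")
                    conc = esm_concentration(comp_areas[cid], curves[cid])
                    row.append(extraction.content_from_solution(conc))
            rows.append(row)
            sample_ids.append(sid)
        except ValidationError as exc:
            errors.append(str(exc))
    if errors and not skip_invalid:
        raise ValidationError("; ".join(errors))
    if errors:
        warnings.warn(f"skipped {len(errors)} invalid sample(s): {'; '.join(errors)}", stacklevel=2)
    values = np.asarray(rows, dtype=float).reshape(len(sample_ids), len(compound_ids))
    return ConcentrationMatrix(sample_ids, compound_ids, values, method=method)


class QAMSQuantifier(TransformerMixin, BaseEstimator):
    """Learn calibration curves and RCFs, then map peak tables to contents.

    ``fit`` consumes a calibration series — a mapping from compound id to a
    list of :class:`CalibrationPoint` with levels paired across compounds —
    and establishes the reference curve, per-compound curves (for ESM mode)
    and the RCF table. ``transform`` quantifies a peak table into a
    :class:`ConcentrationMatrix` in mg/g.

    Parameters
    ----------
    reference_id : str
        Compound anchoring the single-marker quantification.
    method : {"QAMS", "ESM"}
        Quantification route used by :meth:`transform`.
    extraction : ExtractionParams
        Powder mass / extract volume used for the mg/L -> mg/g conversion.
    noise_sd : float
        Baseline noise (counts) used for LOD/LOQ on the exported curves.
    """

    def __init__(
        self,
        reference_id: str = "DISS",
        method: str = "QAMS",
        extraction: ExtractionParams = ExtractionParams(),
        noise_sd: float = 0.0,
    ):
        self.reference_id = reference_id
        self.method = method
        self.extraction = extraction
        self.noise_sd = noise_sd

    def fit(self, X: Mapping[str, Sequence[CalibrationPoint]], y=None) -> "QAMSQuantifier":
        if self.reference_id not in X:
            raise ValidationError(f"calibration series lacks the reference {self.reference_id!r}")
        ref_points = list(X[self.reference_id])
        curves: dict[str, CalibrationCurve] = {}
        mean_rcf: dict[str, float] = {self.reference_id: 1.0}
        per_level: dict[str, list[float]] = {}
        for cid, pts in X.items():
            est = LinearCalibration(compound_id=cid)
            est.fit([p.concentration for p in pts], [p.area for p in pts])
            curves[cid] = est.to_curve(noise_sd=self.noise_sd)
            if cid != self.reference_id:
                levels, mean = compute_rcf(ref_points, list(pts))
                per_level[cid] = levels
                mean_rcf[cid] = mean
        self.curves_ = curves
        self.ref_curve_ = curves[self.reference_id]
        self.rcf_table_ = RCFTable(
            reference_id=self.reference_id, mean_rcf=mean_rcf, per_level_rcfs=per_level
        )
        return self

    def transform(self, X: Sequence[PeakRecord]) -> ConcentrationMatrix:
        check_is_fitted(self, "rcf_table_")
        return quantify_samples(
            X,
            extraction=self.extraction,
            method=self.method,
            ref_curve=self.ref_curve_,
            rcf=self.rcf_table_,
            curves=self.curves_,
        )
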