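"""Linear calibration curves, detection limits, and external-standard inversion.

The detector response of each compound is modelled as a straight line,
area = slope * concentration + intercept, fitted by ordinary least squares.
Detection limits follow the usual signal-to-noise convention (LOD at S/N 3,
LOQ at S/N 10); the method detection limit multiplies the standard deviation
of low-level replicate spikes by the one-sided 99% Student-t quantile, and
the method quantitation limit is ten times that standard deviation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import CalibrationCurve, CalibrationPoint, ValidationError

__all__ = [
    "LinearCalibration",
    "fit_calibration",
    "lod_loq",
    "mdl_mql",
    "esm_concentration",
]


class LinearCalibration(RegressorMixin, BaseEstimator):
    """Ordinary least-squares calibration line for one compound.

    Parameters
    ----------
    compound_id : str
        Analyte identifier carried into the exported curve.

    Attributes
    ----------
    slope_ : float
        Detector counts per mg/L.
    intercept_ : float
        Detector counts at zero concentration.
    r_squared_ : float
        1 - SS_res/SS_tot; 1.0 for an exact fit (including the zero-variance
        residual case).
    linear_range_ : tuple of float
        (min, max) of the fitted concentrations.
    """

    def __init__(self, compound_id: str = ""):
        self.compound_id = compound_id

    def fit(self, X, y=None) -> "LinearCalibration":
        """Fit on concentrations X (n,) or (n,1) and areas y."""
        conc = np.asarray(X, dtype=float).reshape(-1)
        area = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != area.shape:
            raise ValidationError("concentration and area arrays must have equal length")
        if np.unique(conc).size < 2:
            raise ValidationError(
                f"calibration for {self.compound_id or 'compound'} needs >= 2 distinct concentrations"
            )
        res = stats.linregress(conc, area)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        fitted = self.slope_ * conc + self.intercept_
        ss_res = float(np.sum((area - fitted) ** 2))
        ss_tot = float(np.sum((area - area.mean()) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        self.linear_range_ = (float(conc.min()), float(conc.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * conc + self.intercept_

    def inverse(self, area) -> np.ndarray:
        """Concentration(s) mg/L from area(s); negative inversions clip to 0."""
        check_is_fitted(self, "slope_")
        if self.slope_ <= 0:
            raise ValidationError(f"non-positive slope for {self.compound_id or 'compound'}")
        area = np.asarray(area, dtype=float)
        conc = (area - self.intercept_) / self.slope_
        if np.any(conc < 0):
            warnings.warn(
                f"negative inverted concentration clipped to 0 for {self.compound_id or 'compound'}",
                stacklevel=2,
            )
        return np.clip(conc, 0.0, None)

    def detection_limits(self, noise_sd: float) -> tuple[float, float]:
        check_is_fitted(self, "slope_")
        return lod_loq(noise_sd, self.slope_)

    def to_curve(
        self,
        noise_sd: float = 0.0,
        replicate_concentrations: Sequence[float] | None = None,
    ) -> CalibrationCurve:
        check_is_fitted(self, "slope_")
        lod, loq = self.detection_limits(noise_sd)
        mdl = mql = 0.0
        if replicate_concentrations is not None:
            mdl, mql = mdl_mql(replicate_concentrations)
        return CalibrationCurve(
            compound_id=self.compound_id,
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            lod=lod,
            loq=loq,
            mdl=mdl,
            mql=mql,
            linear_range=self.linear_range_,
        )


def fit_calibration(
    points: Sequence[CalibrationPoint],
    compound_id: str = "",
    noise_sd: float = 0.0,
    replicate_concentrations: Sequence[float] | None = None,
) -> CalibrationCurve:
    """OLS calibration curve from (concentration, area) points."""
    est = LinearCalibration(compound_id=compound_id)
    est.fit([p.concentration for p in points], [p.area for p in points])
    return est.to_curve(noise_sd=noise_sd, replicate_concentrations=replicate_concentrations)


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Signal-to-noise 3:1 and 10:1 limits: (3*noise/slope, 10*noise/slope)."""
    if slope <= 0:
        raise ValidationError(f"slope must be > 0, got {slope}")
    if noise_sd < 0:
        raise ValidationError(f"noise SD must be >= 0, got {noise_sd}")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def mdl_mql(replicate_concentrations: Sequence[float], alpha: float = 0.01) -> tuple[float, float]:
    """Method detection/quantitation limits from low-level replicate spikes.

    MDL = SD * t(n-1, one-sided 1-alpha); MQL = 10 * SD, with SD the n-1
    sample standard deviation. For n = 7 the t multiplier is 3.143 (3.14 to
    two decimals).
    """
    values = np.asarray(replicate_concentrations, dtype=float)
    if values.size < 2:
        raise ValidationError(f"need >= 2 replicates, got {values.size}")
    sd = float(values.std(ddof=1))
    t = float(stats.t.ppf(1.0 - alpha, values.size - 1))
    return sd * t, 10.0 * sd


def esm_concentration(area: float, curve: CalibrationCurve) -> float:
    """External-standard inversion (area - intercept)/slope, clipped at 0."""
    if curve.slope <= 0:
        raise ValidationError(f"invalid curve for {curve.compound_id!r}: slope <= 0")
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"area below intercept for {curve.compound_id!r}; concentration clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return conc
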