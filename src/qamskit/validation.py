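"""Method-validation statistics: precision, recovery, stability, uncertainty.

The expanded uncertainty combines five relative standard-uncertainty
components in quadrature and scales by the analyte level and a coverage
factor (k = 2 for ~95% coverage):

    U = k * c * sqrt(ur_sample^2 + ur_cal^2 + ur_true^2 + ur_rep^2 + ur_lod^2)

with ur_cal = SD_RRF / sqrt(n_cal), ur_rep = SD_results / sqrt(n_rep) and
ur_lod = LOD / c_det. The two SD inputs are taken as *relative* standard
deviations (fractions) so that every term under the root is dimensionless.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import UncertaintyBudget, ValidationError

__all__ = [
    "rsd_pct",
    "recovery_pct",
    "uncertainty_budget",
    "stability_check",
]


def rsd_pct(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 * SD(n-1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError(f"RSD needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def recovery_pct(unspiked_found: float, spiked_found: float, added: float) -> float:
    """Spike recovery, 100 * (found_spiked - found_unspiked) / added."""
    if added <= 0:
        raise ValidationError(f"added amount must be > 0, got {added}")
    return 100.0 * (spiked_found - unspiked_found) / added


def uncertainty_budget(
    c: float,
    k: float = 2.0,
    ur_sample: float = 0.0,
    ur_true: float = 0.0,
    sd_rrf: float = 0.0,
    n_cal: int = 1,
    sd_results: float = 0.0,
    n_rep: int = 1,
    lod: float = 0.0,
    c_det: float = 1.0,
) -> UncertaintyBudget:
    """Expanded-uncertainty budget for one analyte.

    Parameters are the balance/weighing component (``ur_sample``), the
    recovery-trueness component (``ur_true``), the relative SD of the
    calibration series (``sd_rrf`` over ``n_cal`` repetitions), the relative
    SD of replicate results (``sd_results`` over ``n_rep``), and the
    detection-limit component ``lod / c_det``.
    """
    if c_det <= 0:
        raise ValidationError(f"c_det must be > 0, got {c_det}")
    if n_cal < 1 or n_rep < 1:
        raise ValidationError("repetition counts must be >= 1")
    for name, v in (("c", c), ("k", k), ("ur_sample", ur_sample), ("ur_true", ur_true),
                    ("sd_rrf", sd_rrf), ("sd_results", sd_results), ("lod", lod)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    ur_cal = sd_rrf / math.sqrt(n_cal)
    ur_rep = sd_results / math.sqrt(n_rep)
    ur_lod = lod / c_det
    combined = math.sqrt(ur_sample**2 + ur_cal**2 + ur_true**2 + ur_rep**2 + ur_lod**2)
    return UncertaintyBudget(
        c=c,
        k=k,
        ur_sample=ur_sample,
        ur_cal=ur_cal,
        ur_true=ur_true,
        ur_rep=ur_rep,
        ur_lod=ur_lod,
        U=k * c * combined,
    )


def stability_check(
    areas_over_time: Sequence[tuple[float, float]], threshold_pct: float = 3.0
) -> tuple[float, bool]:
    """RSD of peak areas over a time series; pass iff RSD <= threshold."""
    if len(areas_over_time) < 3:
        raise ValidationError(f"stability needs >= 3 time points, got {len(areas_over_time)}")
    rsd = rsd_pct([a for _, a in areas_over_time])
    return rsd, rsd <= threshold_pct
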