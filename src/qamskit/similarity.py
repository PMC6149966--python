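"""Angle-cosine agreement between two quantification methods.

The angle cosine of two non-negative concentration vectors,

    C_ir = sum(u_k v_k) / sqrt(sum(u_k^2) sum(v_k^2)),

is 1 when the vectors point in the same direction and 0 when they are
orthogonal. Comparing an external-standard matrix with a single-marker
matrix column-by-column (one cosine per compound across all samples) or
row-by-row (one cosine per sample across all compounds) quantifies how
closely the two routes agree.
"""

from __future__ import annotations

import numpy as np

from .types import ConcentrationMatrix, ValidationError

__all__ = ["cosine", "compare_methods"]


def cosine(u, v) -> float:
    """Cosine of the angle between two equal-length non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"vectors must be 1-D of equal length, got {u.shape} and {v.shape}")
    if u.size < 1:
        raise ValidationError("vectors must be non-empty")
    nu = float(np.dot(u, u))
    nv = float(np.dot(v, v))
    if nu == 0 or nv == 0:
        raise ValidationError("cosine undefined for an all-zero vector")
    return float(np.dot(u, v) / np.sqrt(nu * nv))


def compare_methods(
    esm: ConcentrationMatrix,
    qams: ConcentrationMatrix,
    orientation: str = "per_compound",
    reference_id: str | None = "DISS",
) -> dict[str, float]:
    """Per-compound (or per-sample) cosines between two concentration matrices.

    In ``per_compound`` orientation the reference compound is excluded when
    present, since its column is identical in both matrices by construction.
    """
    if esm.sample_ids != qams.sample_ids or esm.compound_ids != qams.compound_ids:
        raise ValidationError("matrices must share sample and compound ordering")
    if orientation == "per_compound":
        return {
            cid: cosine(esm.column(cid), qams.column(cid))
            for cid in esm.compound_ids
            if cid != reference_id
        }
    if orientation == "per_sample":
        return {sid: cosine(esm.row(sid), qams.row(sid)) for sid in esm.sample_ids}
    raise ValidationError(f"orientation must be per_compound or per_sample, got {orientation!r}")
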