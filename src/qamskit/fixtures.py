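"""Embedded study data for the 23-batch Polygala tenuifolia extract panel.

Nine marker compounds (seven oligosaccharide esters and two xanthones) were
quantified in 23 extract batches both by the external standard method (ESM)
and by the single-marker method (QAMS) anchored on 3,6'-disinapoyl sucrose
(DISS). The printed concentration table, the per-compound calibration-curve
metadata, the final relative calibration factors, the four published Fisher
linear classification functions, and the four quality groups from the
published cluster analysis are transcribed here verbatim so that the whole
pipeline is exercisable without any external download.

Compound ids follow the elution order of the chromatogram (peaks 1-9):
sibiricose A5, sibiricose A6, sibiricaxanthone B, glomeratose A,
polygalaxanthone III, tenuifoliside B, DISS, tenuifoliside A,
tenuifoliside C.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CalibrationCurve,
    ClassificationModel,
    Compound,
    ConcentrationMatrix,
)

__all__ = [
    "COMPOUNDS",
    "ELUTION_ORDER",
    "TABLE_ORDER",
    "REFERENCE_ID",
    "STANDARD_MIX_MG_PER_L",
    "fixture_table3",
    "fixture_expanded_uncertainties",
    "fixture_calibration_curves",
    "fixture_rcf_means",
    "fixture_fisher_model",
    "fixture_group_labels",
    "fixture_reported_cosines",
]

REFERENCE_ID = "DISS"

#: Elution (peak) order 1-9; also the X1..X9 order of the published
#: classification functions.
ELUTION_ORDER = [
    "sibiricose A5",
    "sibiricose A6",
    "sibiricaxanthone B",
    "glomeratose A",
    "polygalaxanthone III",
    "tenuifoliside B",
    "DISS",
    "tenuifoliside A",
    "tenuifoliside C",
]

#: Column order of the printed concentration table (reference first).
TABLE_ORDER = [
    "DISS",
    "sibiricose A5",
    "sibiricose A6",
    "sibiricaxanthone B",
    "glomeratose A",
    "polygalaxanthone III",
    "tenuifoliside B",
    "tenuifoliside A",
    "tenuifoliside C",
]

COMPOUNDS = [
    Compound(cid, cid, "reference" if cid == REFERENCE_ID else "target")
    for cid in ELUTION_ORDER
]

#: Mixed working-standard solution concentrations, mg/L.
STANDARD_MIX_MG_PER_L = {
    "sibiricose A5": 67.07,
    "sibiricose A6": 49.85,
    "sibiricaxanthone B": 50.59,
    "glomeratose A": 56.82,
    "polygalaxanthone III": 24.06,
    "tenuifoliside B": 57.23,
    "DISS": 342.02,
    "tenuifoliside A": 216.92,
    "tenuifoliside C": 90.30,
}

# Printed concentration table (mg/g, mean +- expanded uncertainty, k=2).
# Per row: DISS single value, then for each remaining compound in TABLE_ORDER
# a (QAMS, ESM) pair; the DISS column is shared by both methods.
_TABLE3 = """\
S1  6.23 0.25 | 1.45 0.09 1.44 0.07 | 1.08 0.08 1.08 0.07 | 0.96 0.06 0.97 0.05 | 0.64 0.04 0.65 0.03 | 0.46 0.03 0.46 0.02 | 0.48 0.03 0.48 0.03 | 4.03 0.38 4.06 0.35 | 1.82 0.15 1.84 0.13
S2  7.15 0.29 | 1.32 0.08 1.31 0.07 | 1.30 0.10 1.30 0.09 | 0.86 0.05 0.87 0.04 | 0.77 0.05 0.77 0.04 | 0.53 0.04 0.54 0.03 | 0.44 0.03 0.45 0.03 | 3.08 0.29 3.12 0.27 | 1.82 0.15 1.84 0.13
S3  3.55 0.16 | 0.57 0.04 0.56 0.03 | 0.52 0.04 0.52 0.04 | 0.66 0.05 0.65 0.04 | 0.88 0.06 0.88 0.04 | 0.55 0.04 0.55 0.03 | 0.31 0.02 0.32 0.02 | 3.68 0.33 3.67 0.29 | 1.88 0.15 1.87 0.12
S4  4.89 0.23 | 0.69 0.05 0.68 0.03 | 0.84 0.07 0.84 0.05 | 0.78 0.06 0.78 0.04 | 0.75 0.05 0.75 0.04 | 0.51 0.04 0.51 0.03 | 0.43 0.03 0.44 0.02 | 2.78 0.27 2.81 0.24 | 1.95 0.16 1.96 0.13
S5  5.00 0.23 | 1.03 0.07 1.02 0.05 | 1.03 0.08 1.03 0.07 | 0.70 0.05 0.71 0.04 | 0.69 0.05 0.70 0.04 | 0.50 0.04 0.51 0.03 | 0.32 0.02 0.32 0.02 | 2.62 0.25 2.65 0.22 | 1.51 0.13 1.52 0.11
S6  6.95 0.28 | 2.15 0.15 2.13 0.11 | 1.44 0.12 1.44 0.11 | 1.08 0.07 1.09 0.05 | 0.77 0.05 0.78 0.04 | 0.66 0.04 0.66 0.03 | 0.49 0.03 0.49 0.03 | 4.32 0.38 4.36 0.35 | 2.40 0.20 2.41 0.18
S7  3.98 0.16 | 1.33 0.09 1.30 0.06 | 1.04 0.08 1.04 0.07 | 0.81 0.05 0.80 0.04 | 0.88 0.06 0.88 0.04 | 0.53 0.04 0.53 0.03 | 0.31 0.02 0.31 0.02 | 4.32 0.41 4.31 0.37 | 1.82 0.15 1.82 0.13
S8  5.16 0.19 | 0.98 0.06 0.97 0.05 | 1.00 0.07 1.00 0.06 | 0.76 0.05 0.77 0.04 | 0.78 0.05 0.78 0.04 | 0.51 0.03 0.51 0.03 | 0.43 0.03 0.44 0.02 | 2.65 0.23 2.68 0.21 | 1.17 0.09 1.18 0.08
S9  7.01 0.29 | 1.38 0.10 1.38 0.08 | 1.38 0.11 1.38 0.09 | 0.65 0.05 0.66 0.04 | 0.81 0.06 0.82 0.05 | 0.49 0.04 0.50 0.03 | 0.55 0.04 0.55 0.04 | 2.39 0.23 2.43 0.21 | 2.00 0.17 2.02 0.15
S10 6.45 0.31 | 1.87 0.13 1.86 0.09 | 1.77 0.15 1.76 0.12 | 1.36 0.10 1.36 0.08 | 1.11 0.07 1.12 0.05 | 0.73 0.05 0.73 0.04 | 0.63 0.05 0.64 0.04 | 5.09 0.48 5.12 0.42 | 2.29 0.19 2.30 0.16
S11 5.89 0.24 | 0.80 0.05 0.79 0.04 | 0.91 0.07 0.91 0.06 | 0.86 0.05 0.86 0.04 | 0.96 0.06 0.97 0.05 | 0.54 0.04 0.55 0.03 | 0.54 0.04 0.55 0.03 | 3.33 0.32 3.36 0.29 | 1.43 0.11 1.44 0.10
S12 5.46 0.25 | 1.91 0.12 1.89 0.09 | 1.37 0.11 1.36 0.09 | 1.16 0.08 1.17 0.05 | 0.86 0.05 0.86 0.04 | 0.88 0.06 0.88 0.04 | 0.93 0.06 0.93 0.05 | 5.17 0.47 5.19 0.41 | 2.01 0.16 2.02 0.13
S13 6.59 0.27 | 1.45 0.09 1.44 0.07 | 1.59 0.12 1.59 0.10 | 0.83 0.06 0.84 0.05 | 0.72 0.04 0.73 0.03 | 0.55 0.04 0.56 0.03 | 0.61 0.04 0.61 0.04 | 4.20 0.40 4.24 0.36 | 2.14 0.17 2.16 0.14
S14 4.96 0.19 | 0.73 0.05 0.71 0.04 | 0.85 0.07 0.85 0.06 | 0.74 0.04 0.74 0.04 | 0.68 0.04 0.68 0.03 | 0.48 0.03 0.49 0.03 | 0.41 0.03 0.41 0.02 | 2.69 0.25 2.71 0.23 | 1.31 0.11 1.32 0.10
S15 3.74 0.16 | 0.79 0.05 0.78 0.04 | 0.75 0.06 0.75 0.05 | 0.77 0.05 0.76 0.04 | 0.94 0.07 0.94 0.06 | 0.48 0.03 0.48 0.02 | 0.33 0.02 0.33 0.02 | 3.74 0.34 3.73 0.30 | 1.50 0.13 1.50 0.11
S16 6.70 0.30 | 2.22 0.14 2.21 0.10 | 1.48 0.12 1.47 0.10 | 1.11 0.07 1.12 0.06 | 0.80 0.05 0.81 0.04 | 0.67 0.05 0.67 0.04 | 0.53 0.04 0.54 0.04 | 4.51 0.42 4.54 0.37 | 2.30 0.18 2.32 0.15
S17 4.19 0.21 | 0.96 0.07 0.94 0.04 | 0.94 0.08 0.94 0.06 | 0.71 0.05 0.71 0.03 | 0.78 0.06 0.78 0.04 | 0.46 0.03 0.46 0.02 | 0.33 0.03 0.34 0.02 | 2.73 0.27 2.75 0.24 | 1.38 0.12 1.38 0.09
S18 3.56 0.17 | 1.02 0.07 1.00 0.05 | 0.70 0.06 0.70 0.05 | 0.69 0.05 0.69 0.03 | 0.69 0.05 0.69 0.04 | 0.53 0.04 0.53 0.03 | 0.31 0.03 0.32 0.02 | 3.15 0.30 3.15 0.26 | 1.39 0.12 1.39 0.10
S19 5.20 0.25 | 1.19 0.08 1.18 0.06 | 1.11 0.10 1.11 0.08 | 0.73 0.05 0.73 0.04 | 0.62 0.04 0.63 0.03 | 0.47 0.03 0.47 0.03 | 0.42 0.03 0.44 0.03 | 2.47 0.24 2.50 0.21 | 1.34 0.11 1.35 0.09
S20 6.11 0.23 | 1.60 0.10 1.58 0.08 | 1.10 0.08 1.10 0.07 | 0.93 0.05 0.94 0.04 | 0.71 0.04 0.72 0.03 | 0.74 0.05 0.74 0.04 | 0.46 0.03 0.48 0.03 | 3.49 0.33 3.53 0.31 | 2.26 0.17 2.27 0.15
S21 5.71 0.21 | 1.16 0.07 1.15 0.05 | 1.22 0.09 1.22 0.08 | 1.08 0.06 1.09 0.05 | 0.78 0.05 0.78 0.04 | 0.77 0.05 0.77 0.04 | 0.85 0.05 0.88 0.04 | 4.08 0.35 4.10 0.32 | 1.32 0.10 1.33 0.09
S22 7.04 0.29 | 1.66 0.11 1.65 0.08 | 1.48 0.12 1.48 0.10 | 0.89 0.06 0.89 0.04 | 0.76 0.05 0.77 0.04 | 0.61 0.04 0.61 0.03 | 0.35 0.03 0.35 0.02 | 3.43 0.33 3.47 0.30 | 1.66 0.13 1.67 0.12
S23 6.35 0.29 | 1.87 0.12 1.86 0.08 | 1.33 0.11 1.33 0.09 | 0.86 0.07 0.86 0.05 | 0.70 0.05 0.70 0.03 | 0.61 0.05 0.62 0.04 | 0.40 0.03 0.41 0.02 | 3.11 0.29 3.14 0.26 | 1.83 0.15 1.85 0.12
"""


def _parse_table3() -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    samples, qams, esm, qams_u, esm_u = [], [], [], [], []
    for line in _TABLE3.strip().splitlines():
        head, *pairs = line.split("|")
        tok = head.split()
        samples.append(tok[0])
        diss, diss_u = float(tok[1]), float(tok[2])
        qrow, erow, qurow, eurow = [diss], [diss], [diss_u], [diss_u]
        for block in pairs:
            qv, qu, ev, eu = (float(t) for t in block.split())
            qrow.append(qv)
            qurow.append(qu)
            erow.append(ev)
            eurow.append(eu)
        qams.append(qrow)
        esm.append(erow)
        qams_u.append(qurow)
        esm_u.append(eurow)
    return samples, np.array(qams), np.array(esm), np.array(qams_u), np.array(esm_u)


def fixture_table3() -> tuple[ConcentrationMatrix, ConcentrationMatrix]:
    """The 23 x 9 content matrices (mg/g) as (ESM, QAMS).

    The reference (DISS) column is quantified by its own calibration curve
    and is therefore identical in both matrices.
    """
    samples, qams, esm, _, _ = _parse_table3()
    return (
        ConcentrationMatrix(samples, list(TABLE_ORDER), esm, method="ESM"),
        ConcentrationMatrix(samples, list(TABLE_ORDER), qams, method="QAMS"),
    )


def fixture_expanded_uncertainties() -> tuple[ConcentrationMatrix, ConcentrationMatrix]:
    """Expanded uncertainties (k=2, mg/g) accompanying :func:`fixture_table3`."""
    samples, _, _, qams_u, esm_u = _parse_table3()
    return (
        ConcentrationMatrix(samples, list(TABLE_ORDER), esm_u, method="ESM"),
        ConcentrationMatrix(samples, list(TABLE_ORDER), qams_u, method="QAMS"),
    )


# Per-compound calibration metadata: slope (counts per mg/L), intercept,
# R^2, linear range (mg/L), LOD, LOQ, MDL, MQL (mg/L).
_CURVES = {
    "sibiricose A5": (6.606e6, 1683.6, 0.9998, (6.71, 93.90), 0.14, 0.45, 0.08, 0.26),
    "sibiricose A6": (6.541e6, -2614.0, 0.9992, (4.99, 69.79), 0.11, 0.36, 0.06, 0.20),
    "sibiricaxanthone B": (4.412e6, -545.72, 0.9999, (5.06, 70.83), 0.13, 0.43, 0.06, 0.19),
    "glomeratose A": (5.450e6, -839.47, 0.9999, (5.68, 79.55), 0.10, 0.33, 0.05, 0.17),
    "polygalaxanthone III": (6.332e6, -2350.7, 0.9999, (2.41, 33.68), 0.06, 0.20, 0.03, 0.10),
    "tenuifoliside B": (4.907e6, -1748.2, 0.9999, (5.72, 80.12), 0.20, 0.66, 0.08, 0.26),
    "DISS": (9.222e6, -24939.0, 0.9999, (34.20, 478.83), 0.06, 0.22, 0.04, 0.12),
    "tenuifoliside A": (4.137e6, -6735.5, 0.9999, (21.69, 303.70), 0.14, 0.45, 0.06, 0.18),
    "tenuifoliside C": (9.104e6, -5511.8, 0.9999, (9.03, 126.42), 0.06, 0.21, 0.03, 0.11),
}


def fixture_calibration_curves() -> dict[str, CalibrationCurve]:
    """Published per-compound calibration curves with detection limits."""
    return {
        cid: CalibrationCurve(
            compound_id=cid,
            slope=s,
            intercept=b,
            r_squared=r2,
            lod=lod,
            loq=loq,
            mdl=mdl,
            mql=mql,
            linear_range=rng,
        )
        for cid, (s, b, r2, rng, lod, loq, mdl, mql) in _CURVES.items()
    }


def fixture_rcf_means() -> dict[str, float]:
    """Final mean relative calibration factors f_si against DISS."""
    return {
        "sibiricose A5": 1.371,
        "sibiricose A6": 1.408,
        "sibiricaxanthone B": 2.033,
        "glomeratose A": 1.652,
        "polygalaxanthone III": 1.475,
        "tenuifoliside B": 1.845,
        "tenuifoliside A": 2.191,
        "tenuifoliside C": 0.995,
        "DISS": 1.0,
    }


def fixture_reported_cosines() -> dict[str, float]:
    """Published per-compound ESM-vs-QAMS angle cosines (unrounded source data)."""
    return {
        "sibiricose A5": 0.999990,
        "sibiricose A6": 0.999998,
        "sibiricaxanthone B": 0.999994,
        "glomeratose A": 0.999990,
        "polygalaxanthone III": 0.999993,
        "tenuifoliside B": 0.999920,
        "tenuifoliside A": 0.999990,
        "tenuifoliside C": 0.999993,
    }


# Published Fisher linear classification functions. Variables X1..X9 follow
# the chromatogram elution order (ELUTION_ORDER); this ordering reproduces
# the published 100% original classification, whereas swapping X4/X5 (as one
# passage of the source text suggests) does not.
_FISHER_COEFFS = np.array(
    [
        [271.95, -508.73, 207.15, 427.79, 182.49, 642.53, 272.69, 40.79, 36.86],
        [221.37, -451.23, 158.84, 355.53, 204.25, 560.04, 254.57, 40.42, 25.18],
        [170.74, -353.18, 135.05, 285.06, 168.98, 436.00, 200.12, 29.62, 21.77],
        [172.30, -327.78, 91.30, 306.93, 143.41, 382.30, 173.63, 33.04, 19.62],
    ]
)
_FISHER_CONSTANTS = np.array([-1488.32, -1196.75, -748.5, -614.96])


def fixture_fisher_model() -> ClassificationModel:
    """The four published Fisher linear classification functions (G1-G4)."""
    return ClassificationModel(
        group_labels=["G1", "G2", "G3", "G4"],
        fisher_coefficients=_FISHER_COEFFS.copy(),
        fisher_constants=_FISHER_CONSTANTS.copy(),
        variable_order=list(ELUTION_ORDER),
    )


def fixture_group_labels() -> dict[str, str]:
    """Published four-group quality partition of the 23 batches."""
    groups = {
        "G1": ["S6", "S10", "S12", "S16"],
        "G2": ["S1", "S2", "S9", "S11", "S13", "S20", "S21", "S22", "S23"],
        "G3": ["S4", "S5", "S8", "S14", "S19"],
        "G4": ["S3", "S7", "S15", "S17", "S18"],
    }
    return {s: g for g, members in groups.items() for s in members}
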