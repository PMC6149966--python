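"""End-to-end orchestration: simulate -> calibrate -> quantify -> classify.

Two entry points: :func:`run_pipeline` executes a YAML-configured synthetic
study (or user-supplied peak tables) through calibration, single-marker and
external-standard quantification, method comparison and chemometrics; and
:func:`reproduce_study` recomputes every desk-checkable number of the
embedded 23-batch panel (summary statistics, cosine agreement, cluster cut,
published-function classification, refit discriminant shares, leave-one-out
accuracy) and compares each against its stored published value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as qio
from .chemometrics import (
    FisherDiscriminantAnalysis,
    classify_fisher,
    cross_validate,
    cut_clusters,
    fit_discriminant,
    hierarchical_cluster,
)
from .fixtures import (
    ELUTION_ORDER,
    REFERENCE_ID,
    STANDARD_MIX_MG_PER_L,
    fixture_fisher_model,
    fixture_group_labels,
    fixture_reported_cosines,
    fixture_table3,
)
from .qams import QAMSQuantifier
from .similarity import compare_methods
from .simulate import (
    default_detector,
    default_group_profiles,
    simulate_batches,
    simulate_calibration_series,
)
from .types import CalibrationPoint, ExtractionParams, ValidationError

__all__ = ["run_pipeline", "reproduce_study"]

log = logging.getLogger("qamskit")


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _stage(name: str, out: Path) -> None:
    log.info("stage=%s output=%s sha256=%s", name, out.name, _hash(out))


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Run the full synthetic-study pipeline from a YAML config.

    Required keys: ``output_dir``; optional: ``seed`` (default 0) and a
    ``simulation`` block (``n_per_group``, ``noise_cv``, ``batch_cv``).
    Writes all intermediate artifacts plus ``summary.json``.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict) or "output_dir" not in cfg:
        raise ValidationError("config must define output_dir")
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    sim = dict(cfg.get("simulation", {}))
    n_per_group = int(sim.get("n_per_group", 6))
    noise_cv = float(sim.get("noise_cv", 0.004))
    batch_cv = float(sim.get("batch_cv", 0.10))
    extraction = ExtractionParams(**cfg.get("extraction", {}))

    # named substreams derived from the single config seed
    root = np.random.default_rng(seed)
    seeds = {name: int(root.integers(0, 2**31 - 1)) for name in ("calibration", "batches")}

    detector = default_detector(noise_cv=noise_cv)
    cal = simulate_calibration_series(detector, seed=seeds["calibration"])
    qio.write_peak_table(cal, out_dir / "calibration_peaks.csv")
    _stage("simulate-calibration", out_dir / "calibration_peaks.csv")

    peaks, truth, labels = simulate_batches(
        default_group_profiles(cv=batch_cv),
        n_per_group=n_per_group,
        extraction=extraction,
        detector=detector,
        seed=seeds["batches"],
    )
    qio.write_peak_table(peaks, out_dir / "sample_peaks.csv")
    qio.write_concentration_matrix(truth, out_dir / "truth.csv")
    _stage("simulate-batches", out_dir / "sample_peaks.csv")

    # paired calibration levels per compound: effective on-column
    # concentration scales with injection volume relative to 1.0 uL
    points = {
        cid: [
            CalibrationPoint(concentration=r.injection_volume * conc, area=r.area)
            for r in cal
            if r.compound_id == cid
        ]
        for cid, conc in STANDARD_MIX_MG_PER_L.items()
    }
    quant = QAMSQuantifier(reference_id=REFERENCE_ID, extraction=extraction).fit(points)
    qio.write_json(qio.rcf_table_to_dict(quant.rcf_table_), out_dir / "rcf.json")
    _stage("rcf", out_dir / "rcf.json")

    qams_matrix = quant.transform(peaks)
    quant_esm = QAMSQuantifier(
        reference_id=REFERENCE_ID, extraction=extraction, method="ESM"
    ).fit(points)
    esm_matrix = quant_esm.transform(peaks)
    qio.write_concentration_matrix(qams_matrix, out_dir / "concentrations_qams.csv")
    qio.write_concentration_matrix(esm_matrix, out_dir / "concentrations_esm.csv")
    _stage("quantify", out_dir / "concentrations_qams.csv")

    cosines = compare_methods(esm_matrix, qams_matrix, reference_id=REFERENCE_ID)
    qio.write_json(cosines, out_dir / "cosines.json")
    _stage("compare", out_dir / "cosines.json")

    dendro = hierarchical_cluster(qams_matrix)
    qio.write_json(qio.dendrogram_to_dict(dendro), out_dir / "dendrogram.json")
    model = fit_discriminant(qams_matrix, labels)
    qio.write_json(qio.model_to_dict(model), out_dir / "discriminant.json")
    conf, loo_pct = cross_validate(qams_matrix, labels)
    conf.to_csv(out_dir / "confusion_loo.csv")
    _stage("chemometrics", out_dir / "discriminant.json")

    summary = {
        "seed": seed,
        "n_samples": len(qams_matrix.sample_ids),
        "cosines": cosines,
        "rcf": quant.rcf_table_.mean_rcf,
        "variance_shares_pct": list(model.variance_shares_pct),
        "loo_pct_correct": loo_pct,
    }
    qio.write_json(summary, out_dir / "summary.json")
    _stage("summary", out_dir / "summary.json")
    return summary


def _partition_match(found: Mapping[str, str], expected: Mapping[str, str]) -> bool:
    def blocks(lab: Mapping[str, str]) -> set[frozenset[str]]:
        inv: dict[str, set[str]] = {}
        for s, g in lab.items():
            inv.setdefault(g, set()).add(s)
        return {frozenset(v) for v in inv.values()}

    return blocks(found) == blocks(expected)


def reproduce_study(cut_height: float = 9.0) -> dict[str, Any]:
    """Recompute the embedded panel's reported results and check each one."""
    esm, qams = fixture_table3()
    frame = qams.to_frame()
    membership = fixture_group_labels()
    checks: dict[str, dict[str, Any]] = {}

    def check(name: str, value, expected, ok) -> None:
        checks[name] = {"value": value, "expected": expected, "pass": bool(ok)}

    means = frame.mean()
    for cid, expected in (
        ("tenuifoliside A", 3.524),
        ("glomeratose A", 0.786),
        ("polygalaxanthone III", 0.577),
    ):
        check(f"mean {cid}", round(float(means[cid]), 3), expected,
              abs(means[cid] - expected) < 5e-4)

    totals = frame.sum(axis=1)
    check("max total", float(totals.max()), 21.291, abs(totals.max() - 21.291) / 21.291 <= 1e-3)
    check("min total", float(totals.min()), 12.053, abs(totals.min() - 12.053) / 12.053 <= 1e-3)
    check("max analyte", float(frame.to_numpy().max()), 7.15, frame.to_numpy().max() == 7.15)
    check("min analyte", float(frame.to_numpy().min()), 0.31, frame.to_numpy().min() == 0.31)

    cos = compare_methods(esm, qams, reference_id=REFERENCE_ID)
    reported = fixture_reported_cosines()
    for cid, c in cos.items():
        check(f"cosine {cid}", round(c, 6), f"> 0.999 (printed {reported[cid]})", c > 0.999)

    dendro = hierarchical_cluster(qams)
    cut = cut_clusters(dendro, cut_height)
    check("cluster count at cut", len(set(cut.values())), 4, len(set(cut.values())) == 4)
    check("cluster membership", {s: cut[s] for s in qams.sample_ids},
          "published four-group partition", _partition_match(cut, membership))

    model = fixture_fisher_model()
    assignments = {}
    correct = 0
    for sid in qams.sample_ids:
        x = qams.reorder(ELUTION_ORDER).row(sid)
        group, _ = classify_fisher(model, x)
        assignments[sid] = group
        correct += group == membership[sid]
    pct = 100.0 * correct / len(qams.sample_ids)
    check("published-function classification %", pct, 100.0, pct == 100.0)
    checks["published-function assignments"] = {"value": assignments, "expected": membership,
                                                "pass": pct == 100.0}

    refit = fit_discriminant(qams, membership)
    shares = [round(float(s), 2) for s in refit.variance_shares_pct]
    check("refit variance shares", shares, [91.9, 7.1, 1.0],
          all(abs(a - b) <= 0.5 for a, b in zip(shares, [91.9, 7.1, 1.0])))

    est = FisherDiscriminantAnalysis().fit(
        qams.values, [membership[s] for s in qams.sample_ids]
    )
    orig_pct = 100.0 * float(
        np.mean(est.predict(qams.values) == np.array([membership[s] for s in qams.sample_ids]))
    )
    check("original classification %", orig_pct, 100.0, orig_pct == 100.0)
    conf, loo_pct = cross_validate(qams, membership)
    check("cross-validated %", loo_pct, 100.0, loo_pct == 100.0)
    check("confusion row totals", conf.sum(axis=1).tolist(), [4, 9, 5, 5],
          conf.sum(axis=1).tolist() == [4, 9, 5, 5])

    return {
        "n_checks": len(checks),
        "n_pass": sum(1 for c in checks.values() if c["pass"]),
        "checks": checks,
    }
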