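"""Confidence gating and per-sample diagnostic reporting.

Classification is trusted only when the sample clears two QC hurdles at
once: the measured cfDNA fraction of total DNA (fragment-length based,
default >= 40%) and the estimated tumor fraction from deconvolution
(default >= 30%). Both thresholds are inclusive and exploratory defaults;
they gate confidence, never the classification itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .deconvolve import DeconvolutionResult
from .exceptions import ValidationError
from .quant import SampleQC

CFDNA_MIN_DEFAULT = 0.40
ETF_MIN_DEFAULT = 0.30


@dataclass
class GateDecision:
    """Outcome of the two-variable confidence gate."""

    cfdna_fraction: float | None
    etf: float
    cfdna_min: float = CFDNA_MIN_DEFAULT
    etf_min: float = ETF_MIN_DEFAULT
    status: str = "low_confidence"
    reasons: list[str] = field(default_factory=list)

    @property
    def confident(self) -> bool:
        return self.status == "confident"


def confidence_gate(
    cfdna_fraction: float | None,
    etf: float,
    cfdna_min: float = CFDNA_MIN_DEFAULT,
    etf_min: float = ETF_MIN_DEFAULT,
) -> GateDecision:
    """AND of the two inclusive thresholds; reasons name each failed one.

    A missing cfDNA fraction (no fragment profile) is low confidence with an
    explicit reason rather than an error.
    """
    reasons: list[str] = []
    if cfdna_fraction is None:
        reasons.append("cfDNA fraction unavailable")
    else:
        if not 0.0 <= cfdna_fraction <= 1.0:
            raise ValidationError("cfdna_fraction must lie in [0, 1]")
        if cfdna_fraction < cfdna_min:
            reasons.append(f"cfDNA fraction {cfdna_fraction:.3f} below {cfdna_min:.2f}")
    if not 0.0 <= etf <= 1.0 + 1e-9:
        raise ValidationError("etf must lie in [0, 1]")
    if etf < etf_min:
        reasons.append(f"estimated tumor fraction {etf:.3f} below {etf_min:.2f}")
    status = "confident" if not reasons else "low_confidence"
    return GateDecision(cfdna_fraction, etf, cfdna_min, etf_min, status, reasons)


def build_report(
    sample_id: str,
    qc: SampleQC | None,
    result: DeconvolutionResult,
    gate: GateDecision,
    truth: str | None = None,
) -> dict:
    """Assemble one flat per-sample record.

    When a known diagnosis is supplied, adds ``correct`` (predicted entity
    equals truth); otherwise the field is absent.
    """
    if result.sample_id != sample_id:
        raise ValidationError(
            f"sample_id mismatch: report {sample_id!r} vs deconvolution "
            f"{result.sample_id!r}"
        )
    if qc is not None and qc.sample_id != sample_id:
        raise ValidationError(
            f"sample_id mismatch: report {sample_id!r} vs QC {qc.sample_id!r}"
        )
    record = {
        "sample_id": sample_id,
        "predicted_entity": result.predicted_entity,
        "etf": result.etf,
        "n_clusters_used": result.n_clusters_used,
        "residual_norm": result.residual_norm,
        "degenerate": result.degenerate,
        "cfdna_fraction": gate.cfdna_fraction,
        "bisulfite_conversion": qc.bisulfite_conversion if qc else None,
        "gate_status": gate.status,
        "gate_reasons": list(gate.reasons),
    }
    if truth is not None:
        record["truth"] = truth
        record["correct"] = result.predicted_entity == truth
    return record


def write_reports(reports: list[dict], path) -> None:
    """Write per-sample reports as JSON lines."""
    with open(path, "w") as fh:
        for rec in reports:
            fh.write(json.dumps(rec) + "\n")


def read_reports(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def cohort_summary(reports: list[dict]) -> pd.DataFrame:
    """Quadrant accounting: correct/incorrect overall and by gate status.

    Only reports carrying a known diagnosis contribute to the correctness
    counts; an empty stratum is reported as 0/0, never NaN counts.
    """
    if not reports:
        raise ValidationError("cohort_summary needs at least one report")
    rows = []
    with_truth = [r for r in reports if "correct" in r]
    strata = [
        ("overall", with_truth),
        ("confident", [r for r in with_truth if r["gate_status"] == "confident"]),
        ("low_confidence",
         [r for r in with_truth if r["gate_status"] == "low_confidence"]),
    ]
    for name, recs in strata:
        n = len(recs)
        n_correct = sum(bool(r["correct"]) for r in recs)
        rows.append(
            {
                "stratum": name,
                "n": n,
                "n_correct": n_correct,
                "n_incorrect": n - n_correct,
                "accuracy": (n_correct / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
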