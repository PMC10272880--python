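"""Expression fold-change arithmetic and stress-viability ratios.

Confirms a predicted regulon member by RT-qPCR logic: each transcript is
normalised to a same-sample reference gene (16S rRNA), fold changes are
taken between regulator-overexpressing and empty-vector strains and between
deletion mutant and wild type, and a gene is called *activated* when
overexpression raises it more than ``threshold``-fold while deletion lowers
it below 1/threshold (and symmetrically *repressed*).  Also provides the
colony-count survival ratio used in acid-stress sensitivity assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import ValidationError

ACTIVATED = "activated"
REPRESSED = "repressed"
UNCHANGED = "unchanged"
NOT_DETECTED = "not_detected"

# condition labels expected in measurement tables
COND_OVEREXPRESSION = "overexpression"
COND_VECTOR = "vector"
COND_DELETION = "deletion"
COND_WILDTYPE = "wildtype"


@dataclass(frozen=True)
class ExpressionMeasure:
    """One relative-abundance measurement with its same-sample reference."""

    gene: str
    condition: str
    quantity: float
    reference_quantity: float
    detected: bool = True


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    fc_over: Optional[float]
    fc_del: Optional[float]
    verdict: str


@dataclass(frozen=True)
class ViabilityResult:
    cfu_stress: float
    cfu_control: float

    @property
    def survival_percent(self) -> float:
        return survival_ratio(self.cfu_stress, self.cfu_control)


def relative_level(test: ExpressionMeasure, control: ExpressionMeasure) -> Optional[float]:
    """Reference-normalised fold change of test over control.

    fold = (test.quantity / test.reference) / (control.quantity / control.reference).
    Returns None (propagated as *not detected*) when either measurement is
    flagged below the detection limit.
    """
    if not (test.detected and control.detected):
        return None
    for m in (test, control):
        if m.quantity <= 0 or m.reference_quantity <= 0:
            raise ValidationError(
                f"non-positive quantity for gene {m.gene!r} ({m.condition})"
            )
    return (test.quantity / test.reference_quantity) / (
        control.quantity / control.reference_quantity
    )


def classify_regulation(fc_over: Optional[float], fc_del: Optional[float],
                        threshold: float = 2.0, lenient: bool = False) -> str:
    """Joint two-arm classification of a regulon candidate.

    Strict (default): activated iff fc_over > threshold AND fc_del <
    1/threshold; repressed iff the mirror holds; otherwise unchanged.
    ``lenient`` accepts either arm alone crossing its threshold (useful when
    a regulator is already near-saturating in the wild type, so deletion
    moves the target but overexpression barely does).
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    if fc_over is None or fc_del is None:
        return NOT_DETECTED
    if fc_over <= 0 or fc_del <= 0:
        raise ValidationError("fold changes must be positive")
    up_over, down_del = fc_over > threshold, fc_del < 1.0 / threshold
    down_over, up_del = fc_over < 1.0 / threshold, fc_del > threshold
    if lenient:
        if (up_over or down_del) and not (down_over or up_del):
            return ACTIVATED
        if (down_over or up_del) and not (up_over or down_del):
            return REPRESSED
        return UNCHANGED
    if up_over and down_del:
        return ACTIVATED
    if down_over and up_del:
        return REPRESSED
    return UNCHANGED


def survival_ratio(cfu_stress: float, cfu_control: float) -> float:
    """Percent survival: 100 x colonies with stress / colonies without."""
    if cfu_control <= 0:
        raise ValidationError("control colony count must be positive")
    if cfu_stress < 0:
        raise ValidationError("colony counts must be non-negative")
    return 100.0 * cfu_stress / cfu_control


def aggregate_folds(folds: Sequence[float], method: str = "mean") -> float:
    """Replicate aggregation: arithmetic mean of folds (default) or geometric."""
    vals = [f for f in folds]
    if not vals:
        raise ValidationError("no folds to aggregate")
    if method == "mean":
        return sum(vals) / len(vals)
    if method == "geometric":
        return math.exp(sum(math.log(v) for v in vals) / len(vals))
    raise ValidationError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# Table-level workflow
# ---------------------------------------------------------------------------


def read_measures(path: str | Path) -> list[ExpressionMeasure]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "quantity", "reference_quantity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
    has_detected = "detected" in df.columns
    out = []
    for r in df.itertuples():
        out.append(
            ExpressionMeasure(
                gene=str(r.gene), condition=str(r.condition),
                quantity=float(r.quantity),
                reference_quantity=float(r.reference_quantity),
                detected=bool(r.detected) if has_detected else True,
            )
        )
    return out


def _arm_fold(measures: Sequence[ExpressionMeasure], gene: str, test_cond: str,
              control_cond: str, method: str) -> Optional[float]:
    tests = [m for m in measures if m.gene == gene and m.condition == test_cond]
    controls = [m for m in measures if m.gene == gene and m.condition == control_cond]
    if not tests or not controls:
        return None
    folds = []
    for t, c in zip(tests, controls):  # replicates pair by row order
        f = relative_level(t, c)
        if f is None:
            return None
        folds.append(f)
    return aggregate_folds(folds, method)


def build_regulation_calls(measures: Sequence[ExpressionMeasure],
                           threshold: float = 2.0, lenient: bool = False,
                           method: str = "mean") -> list[RegulationCall]:
    """Per-gene verdicts from a flat measurement list.

    Expects the four condition labels ``overexpression``/``vector`` and
    ``deletion``/``wildtype``; replicate rows pair by order within each
    condition and aggregate as the mean of per-replicate folds.
    """
    genes = sorted({m.gene for m in measures})
    calls = []
    for gene in genes:
        fc_over = _arm_fold(measures, gene, COND_OVEREXPRESSION, COND_VECTOR, method)
        fc_del = _arm_fold(measures, gene, COND_DELETION, COND_WILDTYPE, method)
        calls.append(
            RegulationCall(
                gene=gene, fc_over=fc_over, fc_del=fc_del,
                verdict=classify_regulation(fc_over, fc_del, threshold, lenient),
            )
        )
    return calls


def write_calls(calls: Sequence[RegulationCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "fc_over": ["" if c.fc_over is None else c.fc_over for c in calls],
            "fc_del": ["" if c.fc_del is None else c.fc_del for c in calls],
            "verdict": [c.verdict for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
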