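"""Four-class corneal-topography grading from decentration and EDCR.

The clinical rules (decentration in mm, EDCR a fraction of the pupil
boundary):

* Class III — decentration > 1 mm (regardless of EDCR);
* Class I   — decentration ≤ 1 mm and EDCR > 3/4;
* Class II  — decentration ≤ 1 mm and 1/4 ≤ EDCR ≤ 3/4;
* Class IV  — decentration ≤ 0.5 mm and EDCR < 1/4.

As printed the rules leave decentration ∈ (0.5, 1] with EDCR < 1/4
unassigned; such cases are surfaced as UNCLASSIFIED rather than silently
mapped to a neighbouring class.  Interval endpoints: EDCR exactly 1/4 or
3/4 is Class II; decentration exactly 1 mm is not Class III.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .indicators import IndicatorSet

__all__ = ["TopoClass", "classify", "classify_with_rule", "classify_batch", "BatchReport"]


class TopoClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNCLASSIFIED = "UNCLASSIFIED"


def _rules(dec_mm: float, edcr: float) -> tuple[TopoClass, str]:
    if dec_mm > 1.0:
        return TopoClass.III, "decentration > 1 mm"
    if edcr > 0.75:
        return TopoClass.I, "decentration <= 1 mm and EDCR > 3/4"
    if edcr >= 0.25:
        return TopoClass.II, "decentration <= 1 mm and 1/4 <= EDCR <= 3/4"
    if dec_mm <= 0.5:
        return TopoClass.IV, "decentration <= 0.5 mm and EDCR < 1/4"
    return TopoClass.UNCLASSIFIED, "no rule covers decentration in (0.5, 1] with EDCR < 1/4"


def classify(ind: IndicatorSet) -> TopoClass:
    """Assign the topography class for one IndicatorSet."""
    return classify_with_rule(ind)[0]


def classify_with_rule(ind: IndicatorSet) -> tuple[TopoClass, str]:
    """Class label plus a human-readable statement of the rule that fired."""
    dec, e = float(ind.decentration_mm), float(ind.edcr)
    if dec < 0:
        raise ValueError("decentration must be nonnegative")
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"edcr {e} outside [0, 1]")
    return _rules(dec, e)


@dataclass
class BatchReport:
    """Per-class sample counts and accuracies plus the overall accuracy."""

    table: pd.DataFrame  # rows: n_samples, accuracy; columns: class labels
    overall_accuracy: float
    n: int


def classify_batch(cases, truth) -> BatchReport:
    """Compare predicted classes against reference labels.

    ``cases`` may hold IndicatorSets (classified here) or TopoClass labels;
    ``truth`` holds the reference TopoClass labels.  Per-class accuracy is
    the fraction of reference-class-c cases predicted as c.
    """
    if len(cases) != len(truth):
        raise ValueError(f"length mismatch: {len(cases)} cases vs {len(truth)} labels")
    pred = [classify(c) if isinstance(c, IndicatorSet) else TopoClass(c) for c in cases]
    ref = [TopoClass(t) for t in truth]
    labels = [c for c in TopoClass if c in set(ref) | set(pred)]
    counts = {c.value: sum(1 for r in ref if r == c) for c in labels}
    acc = {}
    for c in labels:
        n_c = counts[c.value]
        hit = sum(1 for p, r in zip(pred, ref) if r == c and p == c)
        acc[c.value] = hit / n_c if n_c else float("nan")
    table = pd.DataFrame(
        [counts, acc], index=["n_samples", "accuracy"],
        columns=[c.value for c in labels],
    )
    overall = float(np.mean([p == r for p, r in zip(pred, ref)])) if ref else float("nan")
    return BatchReport(table=table, overall_accuracy=overall, n=len(ref))
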