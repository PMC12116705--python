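"""Merging of per-methyl chemical-shift predictions from two predictors.

Structure-based methyl shift predictors differ in coverage and in whether
they report uncertainties (a CH3Shift-like program does, a SHIFTX2-like one
does not). The two prediction sets are combined into one table:

* both predictors cover a nucleus -> value = unweighted mean; uncertainty =
  max(predictor-A uncertainty, |value_A - value_B|);
* only A -> A's value and uncertainty;
* only B -> B's value with a fixed fallback uncertainty (0.2 ppm for 1H,
  1.0 ppm for 13C).

Missing keys in either source are legal (predictors do not cover every
methyl), and a key present in neither source is simply absent from the
merged output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

logger = logging.getLogger("methylassign")


@dataclass(frozen=True)
class ShiftPredictionRecord:
    methyl_id: str
    nucleus: str              # "H" | "C"
    value: float              # ppm
    uncertainty: Optional[float] = None  # ppm; None when the source gives none
    source: str = "A"         # "A" (with uncertainties) | "B" (without)

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"{self.methyl_id}/{self.nucleus}: non-finite value")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        if self.nucleus not in ("H", "C"):
            raise ValueError(f"nucleus must be H or C, got {self.nucleus!r}")


@dataclass(frozen=True)
class MergedPrediction:
    methyl_id: str
    nucleus: str
    value: float        # ppm
    uncertainty: float  # ppm, > 0
    provenance: str     # "both" | "only-A" | "only-B"


def _index(records: Iterable[ShiftPredictionRecord], source: str
           ) -> dict[tuple[str, str], ShiftPredictionRecord]:
    out: dict[tuple[str, str], ShiftPredictionRecord] = {}
    for r in records:
        key = (r.methyl_id, r.nucleus)
        if key in out:
            raise ValueError(f"duplicate key {key} in source {source}")
        out[key] = r
    return out


def merge_predictions(records_a: Iterable[ShiftPredictionRecord],
                      records_b: Iterable[ShiftPredictionRecord],
                      fallback_unc_h: float = 0.2,
                      fallback_unc_c: float = 1.0) -> list[MergedPrediction]:
    """Combine two prediction sets into one table with uncertainties.

    Output is sorted by (methyl id, nucleus) and contains one entry per
    (methyl, nucleus) key present in at least one source.
    """
    a = _index(records_a, "A")
    b = _index(records_b, "B")
    merged: list[MergedPrediction] = []
    for key in sorted(set(a) | set(b)):
        methyl_id, nucleus = key
        fallback = fallback_unc_h if nucleus == "H" else fallback_unc_c
        if key in a and key in b:
            ra, rb = a[key], b[key]
            value = 0.5 * (ra.value + rb.value)
            spread = abs(ra.value - rb.value)
            unc = max(ra.uncertainty or 0.0, spread)
            if unc == 0.0:
                unc = fallback  # identical predictions with no stated uncertainty
            merged.append(MergedPrediction(methyl_id, nucleus, value, unc, "both"))
        elif key in a:
            ra = a[key]
            unc = ra.uncertainty if ra.uncertainty else fallback
            merged.append(MergedPrediction(methyl_id, nucleus, ra.value, unc,
                                           "only-A"))
        else:
            merged.append(MergedPrediction(methyl_id, nucleus, b[key].value,
                                           fallback, "only-B"))
    return merged


def compatibility(peak_h: float, peak_c: float,
                  pred_h: MergedPrediction, pred_c: MergedPrediction) -> float:
    """Uncertainty-normalized distance between a 2D peak and a prediction.

    sqrt(((dH_peak - dH_pred)/uH)^2 + ((dC_peak - dC_pred)/uC)^2);
    0 for a peak sitting exactly on the prediction, ~1 for a 1-sigma offset
    along one axis. Symmetric in peak and prediction values.
    """
    if pred_h.uncertainty <= 0 or pred_c.uncertainty <= 0:
        raise ValueError("prediction uncertainties must be positive")
    return math.hypot((peak_h - pred_h.value) / pred_h.uncertainty,
                      (peak_c - pred_c.value) / pred_c.uncertainty)


def duplicate_stereo_ambiguous(records: Iterable[ShiftPredictionRecord],
                               pairs: dict[str, str]
                               ) -> list[ShiftPredictionRecord]:
    """Expand stereo-ambiguous predictions to both geminal methyls.

    ``pairs`` maps an ambiguous id (e.g. ``L315-QD``) to its partner ids
    joined by ``,``; each record keyed by an ambiguous id is duplicated to
    both members with a logged note.
    """
    out: list[ShiftPredictionRecord] = []
    for r in records:
        if r.methyl_id in pairs:
            members = pairs[r.methyl_id].split(",")
            logger.info("stereo-ambiguous prediction %s duplicated to %s",
                        r.methyl_id, members)
            for m in members:
                out.append(ShiftPredictionRecord(m, r.nucleus, r.value,
                                                 r.uncertainty, r.source))
        else:
            out.append(r)
    return out
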