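"""Inter-methyl NOE contact networks.

Methyl-methyl NOESY cross-peaks report on pairs of methyls closer than
roughly 8 A. The structure side of the analysis is an expected-contact
graph (all methyl pairs within a distance cutoff); the spectrum side is a
list of 3D/4D cross-peaks. Matching the two under an assignment yields a
per-peak explanation and an overall explained fraction — the consistency
score used to validate and propagate assignments.

3D HCH and CCH layouts are normalized into the 4D representation
(H1, C1, C2, H2) with the absent dimension set to None; matching only
checks dimensions that are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .structure import DistanceMatrix

#: default matching tolerances (ppm): typical methyl-TROSY linewidths
DEFAULT_TOL_H = 0.02
DEFAULT_TOL_C = 0.2


@dataclass(frozen=True)
class ExpectedContact:
    """An undirected methyl pair expected to show an NOE (distance <= cutoff)."""

    a: str
    b: str
    distance: float
    rank: int  # 0 = shortest distance = strongest expected NOE (r^-6)

    @property
    def key(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass(frozen=True)
class NOEPeak:
    """One NOESY cross-peak; 3D layouts leave one dimension as None."""

    h1: Optional[float]
    c1: Optional[float]
    c2: Optional[float]
    h2: Optional[float]
    intensity: float = 1.0
    spectrum_id: str = ""
    mixing_time: Optional[float] = None  # s, metadata only

    def __post_init__(self) -> None:
        for v in (self.h1, self.c1, self.c2, self.h2):
            if v is not None and not math.isfinite(v):
                raise ValueError("peak shifts must be finite")
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")


def expected_contacts(matrix: DistanceMatrix, cutoff: float = 8.0,
                      ) -> list[ExpectedContact]:
    """All unordered methyl pairs within ``cutoff`` A, sorted by distance."""
    pairs = []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = float(matrix.values[i, j])
            if d <= cutoff:
                pairs.append((d, ids[i], ids[j]))
    pairs.sort()
    return [ExpectedContact(a, b, d, rank) for rank, (d, a, b) in enumerate(pairs)]


def _side_deviation(h: Optional[float], c: Optional[float],
                    shift_h: float, shift_c: float,
                    tol_h: float, tol_c: float) -> Optional[float]:
    """Normalized deviation of one peak side from a methyl's shifts.

    None if outside tolerance in any present dimension; otherwise the sum of
    |delta|/tol over present dimensions.
    """
    dev = 0.0
    if h is not None:
        dh = abs(h - shift_h)
        if dh > tol_h:
            return None
        dev += dh / tol_h
    if c is not None:
        dc = abs(c - shift_c)
        if dc > tol_c:
            return None
        dev += dc / tol_c
    return dev


def peak_matches_pair(peak: NOEPeak,
                      shifts_a: tuple[float, float],
                      shifts_b: tuple[float, float],
                      tol_h: float = DEFAULT_TOL_H,
                      tol_c: float = DEFAULT_TOL_C) -> Optional[float]:
    """Does a cross-peak connect two methyls at the given (H, C) shifts?

    Both peak orientations are tried; returns the smaller combined
    normalized deviation, or None when neither orientation fits.
    """
    best = None
    for (sa, sb) in ((shifts_a, shifts_b), (shifts_b, shifts_a)):
        d1 = _side_deviation(peak.h1, peak.c1, sa[0], sa[1], tol_h, tol_c)
        if d1 is None:
            continue
        d2 = _side_deviation(peak.h2, peak.c2, sb[0], sb[1], tol_h, tol_c)
        if d2 is None:
            continue
        dev = d1 + d2
        if best is None or dev < best:
            best = dev
    return best


@dataclass
class NOEMatchReport:
    explanations: list[Optional[frozenset]]  # per peak: contact key or None
    explained_fraction: float
    n_peaks: int


def match_noe(peaks: Sequence[NOEPeak],
              assignment: dict[str, tuple[float, float]],
              contacts: Iterable[ExpectedContact],
              tol_h: float = DEFAULT_TOL_H,
              tol_c: float = DEFAULT_TOL_C) -> NOEMatchReport:
    """Explain NOE cross-peaks with an assignment and a contact graph.

    A peak is explained when both of its sides match assigned methyls within
    the tolerances and that methyl pair is an expected contact; ambiguity is
    resolved by the smallest combined shift deviation. An empty peak list
    yields an empty report.
    """
    contact_list = list(contacts)
    explanations: list[Optional[frozenset]] = []
    n_explained = 0
    for peak in peaks:
        best_dev, best_key = None, None
        for contact in contact_list:
            if contact.a not in assignment or contact.b not in assignment:
                continue
            dev = peak_matches_pair(peak, assignment[contact.a],
                                    assignment[contact.b], tol_h, tol_c)
            if dev is not None and (best_dev is None or dev < best_dev):
                best_dev, best_key = dev, contact.key
        explanations.append(best_key)
        if best_key is not None:
            n_explained += 1
    frac = n_explained / len(peaks) if peaks else 0.0
    return NOEMatchReport(explanations, frac, len(peaks))
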