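"""Assignment engine: a formalization of structure-guided manual methyl assignment.

The workflow for assigning methyl-TROSY spectra of a large protein without
backbone assignments runs in stages:

1. **Anchors** — X->Ala point mutants delete one methyl-bearing residue; the
   wild-type peaks with no mutant counterpart belong to that residue.
2. **Geminal pairing** — an out-and-back experiment through the shared
   Cgamma (Leu) / Cbeta (Val) frequency links the two terminal methyls of
   each Leu/Val; the pairing table becomes hard constraints.
3. **Stereospecific labelling** — samples labelled only at pro-R (Leu d1,
   Val g1) or pro-S (Val g2) methyls resolve which member of a geminal pair
   is which.
4. **Propagation** — assignments grow outward from the anchors by greedy
   best-first acceptance of (methyl, peak) pairs scored on NOE support
   against the structure's contact graph, structure-based shift-prediction
   compatibility, and PRE consistency for each spin-label site.
5. **Minor forms** — slow conformational exchange duplicates some peaks;
   unassigned peaks sharing a 1H shift with an assigned peak but displaced
   in 13C are flagged minor-or-exchange and linked to the methyl.
6. **Coverage** — per-residue-type and overall assignment statistics.

The engine itself is deterministic: ties are broken by (residue number,
peak id) and every acceptance must beat its runner-up by a margin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .noe import DEFAULT_TOL_C, DEFAULT_TOL_H, ExpectedContact, NOEPeak
from .shifts import MergedPrediction, compatibility
from .structure import MethylGroup

logger = logging.getLogger("methylassign")

#: residue types carrying signal under each selective labelling scheme
SCHEME_COVERAGE = {
    "I-only": {"ILE"},
    "LV[rac]": {"LEU", "VAL"},
    "ILV[rac]": {"ILE", "LEU", "VAL"},
    "IMLV[rac]": {"ILE", "MET", "LEU", "VAL"},
    "MV[pro-S]": {"MET", "VAL"},
    "LV[pro-R]": {"LEU", "VAL"},
}

#: methyl multiplicity per residue type
METHYLS_PER_RESIDUE = {"ILE": 1, "MET": 1, "LEU": 2, "VAL": 2}


@dataclass
class Peak:
    id: str
    dh: float           # 1H shift, ppm
    dc: float           # 13C shift, ppm
    intensity: float = 1.0
    form: str = "unknown"  # major | minor | exchange | unknown

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dh) and math.isfinite(self.dc)):
            raise ValueError(f"peak {self.id}: non-finite shift")
        if self.intensity < 0:
            raise ValueError(f"peak {self.id}: negative intensity")


@dataclass
class PeakList:
    spectrum_id: str
    scheme: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.spectrum_id}: duplicate peak ids")

    @property
    def by_id(self) -> dict[str, Peak]:
        return {p.id: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class AssignmentState:
    """Evolving injective methyl -> peak mapping with provenance."""

    assignments: dict[str, str] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)
    evidence: dict[str, list[str]] = field(default_factory=dict)
    stereo_ambiguous: set[frozenset] = field(default_factory=set)

    def assign(self, methyl_id: str, peak_id: str, conf: float,
               evidence: Sequence[str]) -> None:
        if methyl_id in self.assignments:
            raise ValueError(f"{methyl_id} already assigned")
        if peak_id in self.assigned_peaks:
            raise ValueError(f"peak {peak_id} already used")
        if not (0.0 <= conf <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        self.assignments[methyl_id] = peak_id
        self.confidence[methyl_id] = conf
        self.evidence[methyl_id] = list(evidence)

    @property
    def assigned_peaks(self) -> set[str]:
        return set(self.assignments.values())

    def unassigned_methyls(self, methyls: Iterable[str]) -> list[str]:
        return [m for m in methyls if m not in self.assignments]

    def unassigned_peaks(self, peaks: Iterable[str]) -> list[str]:
        used = self.assigned_peaks
        return [p for p in peaks if p not in used]

    def check_injective(self) -> None:
        vals = list(self.assignments.values())
        if len(vals) != len(set(vals)):
            raise AssertionError("assignment is not injective")


# ---------------------------------------------------------------- anchors

@dataclass
class AnchorResult:
    residue: tuple[str, int]
    residue_type: str
    candidate_peak_ids: list[str]
    expected: int
    status: str  # ok | surplus | deficit


def detect_anchor(wt: PeakList, mutant: PeakList, mutated_chain: str,
                  mutated_number: int, mutated_type: str,
                  tol_h: float = DEFAULT_TOL_H,
                  tol_c: float = DEFAULT_TOL_C) -> AnchorResult:
    """Anchor-point detection from an X->Ala point-mutant spectrum.

    Candidate peaks for the mutated residue's methyls are the wild-type
    peaks with no mutant counterpart within the tolerances. A surplus or
    deficit relative to the residue's methyl count is flagged, never
    silently resolved.
    """
    if wt.scheme != mutant.scheme:
        raise ValueError(f"labelling schemes differ: {wt.scheme} vs {mutant.scheme}")
    covered = SCHEME_COVERAGE.get(wt.scheme)
    if covered is None:
        raise ValueError(f"unknown labelling scheme {wt.scheme!r}")
    if mutated_type not in covered:
        raise ValueError(f"{mutated_type} mutant is invisible in a "
                         f"{wt.scheme}-labelled sample")
    candidates = []
    for p in wt.peaks:
        if not any(abs(p.dh - q.dh) <= tol_h and abs(p.dc - q.dc) <= tol_c
                   for q in mutant.peaks):
            candidates.append(p.id)
    expected = METHYLS_PER_RESIDUE[mutated_type]
    if len(candidates) == expected:
        status = "ok"
    elif len(candidates) > expected:
        status = "surplus"
    else:
        status = "deficit"
    return AnchorResult((mutated_chain, mutated_number), mutated_type,
                        candidates, expected, status)


# ---------------------------------------------------------------- geminal

def pair_geminal(pairing_records: Iterable[tuple[str, str]],
                 ) -> list[frozenset]:
    """Record geminal constraints from a peak-pairing table.

    Each record links the two peaks of one Leu/Val residue (they share a
    Cgamma/Cbeta frequency upstream). A peak appearing in two pairs is a
    contradiction and raises.
    """
    seen: set[str] = set()
    constraints: list[frozenset] = []
    for a, b in pairing_records:
        if a == b:
            raise ValueError(f"degenerate pair ({a}, {a})")
        for p in (a, b):
            if p in seen:
                raise ValueError(f"peak {p} appears in two geminal pairs")
            seen.add(p)
        constraints.append(frozenset((a, b)))
    return constraints


# ---------------------------------------------------------------- stereo

_PRO_R_PARTNER = {"QD2": "QD1", "QG2": "QG1"}
_PRO_S_PARTNER = {"QD1": "QD2", "QG1": "QG2"}


def _swap_stereo_id(methyl_id: str) -> str:
    stem, pseudo = methyl_id.rsplit("-", 1)
    partner = _PRO_R_PARTNER.get(pseudo) or _PRO_S_PARTNER.get(pseudo)
    if partner is None:
        raise ValueError(f"{methyl_id} has no geminal partner")
    return f"{stem}-{partner}"


def _present_in(peak: Peak, stereo_list: PeakList, tol_h: float,
                tol_c: float) -> bool:
    return any(abs(peak.dh - q.dh) <= tol_h and abs(peak.dc - q.dc) <= tol_c
               for q in stereo_list.peaks)


@dataclass
class StereoReport:
    resolved: list[frozenset]
    ambiguous: list[frozenset]
    conflicts: list[frozenset]


def stereo_assign(state: AssignmentState, peaks: dict[str, Peak],
                  geminal_pairs: Sequence[frozenset],
                  pro_s_peaks: PeakList, pro_r_peaks: PeakList,
                  tol_h: float = DEFAULT_TOL_H,
                  tol_c: float = DEFAULT_TOL_C) -> StereoReport:
    """Resolve delta1/delta2 (gamma1/gamma2) labels within geminal pairs.

    Within each pair whose two peaks are assigned to the two methyls of one
    residue, the member with a counterpart in the pro-R list (a sample
    labelled at Leu d1 / Val g1) keeps or receives the pro-R methyl id and
    the other the pro-S id; pairs matching neither list stay ambiguous, and
    a pair whose two peaks both match the same stereo list is a conflict.
    """
    peak_to_methyl = {p: m for m, p in state.assignments.items()}
    resolved, ambiguous, conflicts = [], [], []
    for pair in geminal_pairs:
        p1, p2 = sorted(pair)
        m1, m2 = peak_to_methyl.get(p1), peak_to_methyl.get(p2)
        if m1 is None or m2 is None:
            ambiguous.append(pair)
            continue
        r1 = _present_in(peaks[p1], pro_r_peaks, tol_h, tol_c)
        r2 = _present_in(peaks[p2], pro_r_peaks, tol_h, tol_c)
        s1 = _present_in(peaks[p1], pro_s_peaks, tol_h, tol_c)
        s2 = _present_in(peaks[p2], pro_s_peaks, tol_h, tol_c)
        if (r1 and r2) or (s1 and s2):
            conflicts.append(pair)
            continue
        pro_r_peak = p1 if r1 else p2 if r2 else (p2 if s1 else p1 if s2 else None)
        if pro_r_peak is None:
            ambiguous.append(pair)
            state.stereo_ambiguous.add(frozenset((m1, m2)))
            continue
        pro_s_peak = p2 if pro_r_peak == p1 else p1
        # which of m1/m2 is the pro-R id (QD1/QG1)?
        pro_r_methyl = m1 if m1.endswith(("QD1", "QG1")) else m2
        pro_s_methyl = m2 if pro_r_methyl == m1 else m1
        if state.assignments[pro_r_methyl] != pro_r_peak:
            # swap the two peaks between the geminal methyl ids
            state.assignments[pro_r_methyl] = pro_r_peak
            state.assignments[pro_s_methyl] = pro_s_peak
            state.confidence[pro_r_methyl], state.confidence[pro_s_methyl] = \
                state.confidence[pro_s_methyl], state.confidence[pro_r_methyl]
            state.evidence[pro_r_methyl], state.evidence[pro_s_methyl] = \
                state.evidence[pro_s_methyl], state.evidence[pro_r_methyl]
        for m in (pro_r_methyl, pro_s_methyl):
            if "stereo" not in state.evidence[m]:
                state.evidence[m].append("stereo")
        state.stereo_ambiguous.discard(frozenset((m1, m2)))
        resolved.append(pair)
    state.check_injective()
    return StereoReport(resolved, ambiguous, conflicts)


# ---------------------------------------------------------------- propagation

@dataclass
class EvidenceWeights:
    """Relative weight of each evidence channel in propagation scores.

    NOE support is the primary evidence (the workflow extends assignments
    along the NOE network), with shift predictions and PREs supplementing.
    """

    noe: float = 0.5
    shift: float = 0.3
    pre: float = 0.2


@dataclass
class PREEvidence:
    """One spin-label site's data: observed ratios by peak id, predictions by methyl."""

    site: str
    observed_by_peak: dict[str, float]
    predicted_by_methyl: dict[str, float]


def _shift_score(methyl_id: str, peak: Peak,
                 merged: dict[tuple[str, str], MergedPrediction]) -> Optional[float]:
    ph = merged.get((methyl_id, "H"))
    pc = merged.get((methyl_id, "C"))
    if ph is None or pc is None:
        return None
    c = compatibility(peak.dh, peak.dc, ph, pc)
    return math.exp(-0.5 * c * c)  # Gaussian kernel: 1 at exact match


def _pre_score(methyl_id: str, peak_id: str,
               pre_evidence: Sequence[PREEvidence]) -> Optional[float]:
    scores = []
    for ev in pre_evidence:
        obs = ev.observed_by_peak.get(peak_id)
        pred = ev.predicted_by_methyl.get(methyl_id)
        if obs is None or pred is None:
            continue
        scores.append(max(0.0, min(1.0, 1.0 - abs(obs - pred))))
    return float(np.mean(scores)) if scores else None


class _NOEIndex:
    """Vectorized, memoized test: does any NOE peak connect two 2D peaks?"""

    def __init__(self, noe_peaks: Sequence[NOEPeak], tol_h: float,
                 tol_c: float) -> None:
        self.tol_h, self.tol_c = tol_h, tol_c
        self.empty = not noe_peaks
        if not self.empty:
            self.h1 = np.array([np.nan if p.h1 is None else p.h1 for p in noe_peaks])
            self.c1 = np.array([np.nan if p.c1 is None else p.c1 for p in noe_peaks])
            self.c2 = np.array([np.nan if p.c2 is None else p.c2 for p in noe_peaks])
            self.h2 = np.array([np.nan if p.h2 is None else p.h2 for p in noe_peaks])
        self._memo: dict[tuple[str, str], bool] = {}

    def _side_ok(self, h: np.ndarray, c: np.ndarray, sh: float,
                 sc: float) -> np.ndarray:
        # NaN (absent dimension) imposes no constraint
        ok_h = np.isnan(h) | (np.abs(h - sh) <= self.tol_h)
        ok_c = np.isnan(c) | (np.abs(c - sc) <= self.tol_c)
        return ok_h & ok_c

    def hit(self, a: Peak, b: Peak) -> bool:
        if self.empty:
            return False
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        fwd = (self._side_ok(self.h1, self.c1, a.dh, a.dc)
               & self._side_ok(self.h2, self.c2, b.dh, b.dc))
        rev = (self._side_ok(self.h1, self.c1, b.dh, b.dc)
               & self._side_ok(self.h2, self.c2, a.dh, a.dc))
        result = bool(np.any(fwd | rev))
        self._memo[key] = result
        return result


def _noe_score(methyl_id: str, peak: Peak, state: AssignmentState,
               contacts_of: dict[str, list[str]], peaks_by_id: dict[str, Peak],
               noe_index: _NOEIndex) -> Optional[float]:
    partners = [a for a in contacts_of.get(methyl_id, ())
                if a in state.assignments]
    if not partners:
        return None
    matched = sum(1 for a in partners
                  if noe_index.hit(peak, peaks_by_id[state.assignments[a]]))
    return matched / len(partners)


def propagate_assignments(anchors: dict[str, str],
                          methyls: Sequence[MethylGroup],
                          peaklist: PeakList,
                          contacts: Sequence[ExpectedContact],
                          noe_peaks: Sequence[NOEPeak],
                          merged_predictions: Sequence[MergedPrediction],
                          pre_evidence: Sequence[PREEvidence] = (),
                          geminal_constraints: Sequence = (),
                          weights: EvidenceWeights = EvidenceWeights(),
                          threshold: float = 0.4,
                          margin: float = 0.1,
                          tol_h: float = DEFAULT_TOL_H,
                          tol_c: float = DEFAULT_TOL_C) -> AssignmentState:
    """Grow assignments outward from anchor points by greedy best-first search.

    Every (unassigned methyl, unassigned major-form peak) pair is scored as
    the weighted sum of NOE support (fraction of the methyl's expected
    contacts to already-assigned methyls explained by an observed NOE
    peak), shift-prediction compatibility (Gaussian kernel on the
    sigma-normalized distance) and PRE consistency (1 - |obs - pred| per
    site, averaged over spin-label sites).

    Moves come in three kinds, mirroring the manual workflow:

    * **deduction** — when one peak of a geminal constraint is assigned to a
      Leu/Val methyl, the other peak necessarily belongs to its geminal
      partner and is assigned immediately (evidence ``geminal``);
    * **individual** — a single (methyl, peak) acceptance; peaks that are
      members of a still-unassigned geminal constraint are reserved for
      joint moves;
    * **joint** — a geminal peak pair placed onto the two methyls of one
      Leu/Val residue in the better-scoring orientation (near-ties are
      marked stereo-ambiguous for later stereospecific resolution).

    Greedy stage: the best move is accepted when its score is at least
    ``threshold`` and beats the runner-up for each of its resources (methyl
    and peak, or residue and peak pair) by ``margin``; repeated until no
    move qualifies. A final elimination stage then accepts remaining moves
    best-first without the margin requirement (still subject to
    ``threshold``), at confidence reduced by ``margin`` — resolving
    residual symmetric ambiguities the way the last peaks of a spin system
    are assigned by exclusion. Deterministic throughout; ties break by
    (residue number, peak id).
    """
    if not anchors:
        raise ValueError("propagation needs at least one anchor")
    state = AssignmentState()
    peaks_by_id = peaklist.by_id
    for m, p in sorted(anchors.items()):
        state.assign(m, p, 1.0, ["anchor"])
    merged = {(mp.methyl_id, mp.nucleus): mp for mp in merged_predictions}
    contacts_of: dict[str, list[str]] = {}
    for c in contacts:
        contacts_of.setdefault(c.a, []).append(c.b)
        contacts_of.setdefault(c.b, []).append(c.a)
    methyl_by_id = {m.id: m for m in methyls}
    pool_peaks = [p for p in peaklist.peaks if p.form in ("major", "unknown")]
    noe_index = _NOEIndex(noe_peaks, tol_h, tol_c)
    gem_pairs = [tuple(sorted(pair)) for pair in geminal_constraints]
    gem_peak_ids = {p for pair in gem_pairs for p in pair}
    # geminal partner map restricted to methyls actually present
    partner_of: dict[str, str] = {}
    for mid in methyl_by_id:
        try:
            partner = _swap_stereo_id(mid)
        except ValueError:
            continue
        if partner in methyl_by_id:
            partner_of[mid] = partner

    # shift and PRE evidence do not depend on the assignment state: cache once
    shift_cache: dict[tuple[str, str], Optional[float]] = {}
    pre_cache: dict[tuple[str, str], Optional[float]] = {}
    for mid in methyl_by_id:
        for peak in pool_peaks:
            shift_cache[(mid, peak.id)] = _shift_score(mid, peak, merged)
            pre_cache[(mid, peak.id)] = _pre_score(mid, peak.id, pre_evidence)

    def pair_score(mid: str, peak: Peak) -> tuple[float, list[str]]:
        parts, used = [], []
        s_noe = _noe_score(mid, peak, state, contacts_of, peaks_by_id,
                           noe_index)
        if s_noe is not None:
            parts.append(weights.noe * s_noe)
            if s_noe > 0:
                used.append("noe")
        s_shift = shift_cache[(mid, peak.id)]
        if s_shift is not None:
            parts.append(weights.shift * s_shift)
            used.append("shift-prediction")
        s_pre = pre_cache[(mid, peak.id)]
        if s_pre is not None:
            parts.append(weights.pre * s_pre)
            used.append("pre")
        return (sum(parts) if parts else -math.inf), used

    def geminal_deductions() -> bool:
        moved = False
        for pa, pb in gem_pairs:
            p2m = {p: m for m, p in state.assignments.items()}
            for known, other in ((pa, pb), (pb, pa)):
                owner = p2m.get(known)
                if owner is None or other in p2m:
                    continue
                partner = partner_of.get(owner)
                if partner is None or partner in state.assignments:
                    continue
                if other not in peaks_by_id:
                    continue
                score, used = pair_score(partner, peaks_by_id[other])
                conf = max(0.0, min(1.0, score)) if math.isfinite(score) else 0.0
                state.assign(partner, other, max(conf, 0.5),
                             ["geminal"] + [u for u in used if u != "geminal"])
                moved = True
        return moved

    def enumerate_moves(free_methyls: list[str], free_peaks: list[Peak]):
        """Individual and joint candidate moves with scores and runner-ups."""
        n_m, n_p = len(free_methyls), len(free_peaks)
        scores = np.full((n_m, n_p), -np.inf)
        evid: dict[tuple[int, int], list[str]] = {}
        for i, mid in enumerate(free_methyls):
            for j, peak in enumerate(free_peaks):
                s, used = pair_score(mid, peak)
                if math.isfinite(s):
                    scores[i, j] = s
                    evid[(i, j)] = used

        peak_index = {p.id: j for j, p in enumerate(free_peaks)}
        free_pair_cols = [
            (peak_index[pa], peak_index[pb]) for pa, pb in gem_pairs
            if pa in peak_index and pb in peak_index]
        reserved_cols = {c for cols in free_pair_cols for c in cols}
        # indices of free residues with both geminal methyls free
        free_rows = {m: i for i, m in enumerate(free_methyls)}
        gem_rows = []
        seen_res = set()
        for mid, i in free_rows.items():
            partner = partner_of.get(mid)
            if partner in free_rows and frozenset((mid, partner)) not in seen_res:
                seen_res.add(frozenset((mid, partner)))
                gem_rows.append((i, free_rows[partner]))

        moves = []  # (score, kind, payload)
        ind_allowed = np.array([j not in reserved_cols for j in range(n_p)])
        for i, mid in enumerate(free_methyls):
            for j in np.nonzero(ind_allowed & np.isfinite(scores[i]))[0]:
                moves.append((float(scores[i, j]), "individual", (i, int(j))))
        joint_scores = {}
        for (i1, i2) in gem_rows:
            for (j1, j2) in free_pair_cols:
                a = 0.5 * (scores[i1, j1] + scores[i2, j2])
                b = 0.5 * (scores[i1, j2] + scores[i2, j1])
                if not (math.isfinite(a) or math.isfinite(b)):
                    continue
                s = max(a, b)
                joint_scores[((i1, i2), (j1, j2))] = s
                moves.append((float(s), "joint",
                              ((i1, i2), (j1, j2), a >= b, abs(a - b))))
        return scores, evid, moves, joint_scores, free_pair_cols, gem_rows

    def joint_runner_up(key, joint_scores) -> float:
        (rows, cols) = key
        best = -math.inf
        for (r, c), s in joint_scores.items():
            if (r, c) != (rows, cols) and (r == rows or c == cols):
                best = max(best, s)
        return best

    def accept_move(kind, payload, score, scores, evid, free_methyls,
                    free_peaks, eliminate: bool) -> None:
        conf_penalty = margin if eliminate else 0.0
        if kind == "individual":
            i, j = payload
            mid, peak = free_methyls[i], free_peaks[j]
            conf = max(0.0, min(1.0, score - conf_penalty))
            state.assign(mid, peak.id, conf, evid[(i, j)])
        else:
            (i1, i2), (j1, j2), forward, orient_gap = payload
            if not forward:
                j1, j2 = j2, j1
            for i, j in ((i1, j1), (i2, j2)):
                conf = max(0.0, min(1.0, scores[i, j] - conf_penalty))
                used = evid.get((i, j), [])
                state.assign(free_methyls[i], free_peaks[j].id, conf,
                             ["geminal"] + [u for u in used if u != "geminal"])
            if orient_gap < 0.05:
                state.stereo_ambiguous.add(
                    frozenset((free_methyls[i1], free_methyls[i2])))
        state.check_injective()

    def run_stage(eliminate: bool) -> None:
        while True:
            if geminal_deductions():
                continue
            free_methyls = state.unassigned_methyls(methyl_by_id)
            free_peaks = [p for p in pool_peaks
                          if p.id not in state.assigned_peaks]
            if not free_methyls or not free_peaks:
                return
            scores, evid, moves, joint_scores, _, _ = enumerate_moves(
                free_methyls, free_peaks)
            moves.sort(key=lambda m: -m[0])
            accepted = False
            for score, kind, payload in moves:
                if not math.isfinite(score) or score < threshold:
                    break
                if not eliminate:
                    if kind == "individual":
                        i, j = payload
                        row = np.delete(scores[i, :], j)
                        col = np.delete(scores[:, j], i)
                        runner = max(row.max(initial=-np.inf),
                                     col.max(initial=-np.inf))
                    else:
                        runner = joint_runner_up(payload[:2], joint_scores)
                    if np.isfinite(runner) and score - runner < margin:
                        continue
                accept_move(kind, payload, score, scores, evid,
                            free_methyls, free_peaks, eliminate)
                accepted = True
                break
            if not accepted:
                return

    run_stage(eliminate=False)
    run_stage(eliminate=True)
    return state


# ---------------------------------------------------------------- minor forms

@dataclass
class MinorFormReport:
    links: dict[str, str]  # flagged peak id -> methyl id


def tag_minor_forms(peaklist: PeakList, state: AssignmentState,
                    tol_h: float = DEFAULT_TOL_H,
                    tol_c: float = DEFAULT_TOL_C) -> MinorFormReport:
    """Flag unassigned peaks displaced only in 13C from an assigned peak.

    Slow conformational exchange produces minor-form or exchange peaks that
    share the major-form 1H shift but differ in 13C. An unassigned peak
    whose 1H shift matches an assigned peak within ``tol_h`` while its 13C
    shift differs by more than ``tol_c`` is flagged ``minor`` and linked to
    the methyl (minor form and exchange peak cannot be distinguished from
    peak positions alone). Flagged peaks never re-enter the assignable pool.
    """
    peak_to_methyl = {p: m for m, p in state.assignments.items()}
    by_id = peaklist.by_id
    links: dict[str, str] = {}
    for peak in peaklist.peaks:
        if peak.id in peak_to_methyl:
            continue
        best: Optional[tuple[float, str]] = None
        for apid, mid in peak_to_methyl.items():
            ap = by_id.get(apid)
            if ap is None:
                continue
            if abs(peak.dh - ap.dh) <= tol_h and abs(peak.dc - ap.dc) > tol_c:
                key = (abs(peak.dh - ap.dh), mid)
                if best is None or key < best:
                    best = key
        if best is not None:
            peak.form = "minor"
            links[peak.id] = best[1]
    return MinorFormReport(links)


# ---------------------------------------------------------------- coverage

@dataclass
class CoverageReport:
    per_type: dict[str, tuple[int, int]]  # type -> (assigned, total)
    assigned: int
    total: int
    percentage: int

    def __str__(self) -> str:
        lines = [f"{t}: {a}/{n}" for t, (a, n) in sorted(self.per_type.items())]
        lines.append(f"overall: {self.assigned}/{self.total} ({self.percentage}%)")
        return "\n".join(lines)


def coverage_percentage(assigned: int, total: int) -> int:
    """Overall coverage as an integer percentage: round(100 * assigned/total)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if assigned > total:
        raise ValueError("assigned cannot exceed total")
    return round(100.0 * assigned / total)


def coverage_report(state: AssignmentState,
                    methyls: Sequence[MethylGroup]) -> CoverageReport:
    """Per-residue-type and overall assignment coverage."""
    per_type: dict[str, list[int]] = {}
    for m in methyls:
        cnt = per_type.setdefault(m.residue_type, [0, 0])
        cnt[1] += 1
        if m.id in state.assignments:
            cnt[0] += 1
    assigned = sum(a for a, _ in per_type.values())
    total = sum(n for _, n in per_type.values())
    pct = coverage_percentage(assigned, total) if total else 0
    return CoverageReport({t: (a, n) for t, (a, n) in per_type.items()},
                          assigned, total, pct)
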