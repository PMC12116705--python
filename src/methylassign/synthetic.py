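"""Synthetic ground-truth data for exercising the assignment pipeline.

Generates a random ILVM methyl constellation with the statistical structure
the pipeline assumes — realistic methyl packing density, per-residue-type
chemical-shift ranges, geminal methyl pairs, a minor conformational form
for a subset of methyls — together with every derived observable: HMQC
peak lists, point-mutant peak lists, PRE intensity-ratio profiles (through
the same forward model the analysis uses, plus noise), and NOE cross-peaks
with r^-6 intensities.

All generators are deterministic given (parameters, seed).

Default shift-sampling ranges (ppm), reflecting the dispersion seen in
methyl-TROSY spectra of large alpha/beta proteins (uniform sampling; only
the relative geometry of shift space matters for testing):

    Ile d1: dC in [9, 16],  dH in [0.2, 1.2]
    Met e : dC in [15, 19], dH in [1.5, 2.3]
    Leu d : dC in [21, 27], dH in [0.3, 1.1]
    Val g : dC in [19, 24], dH in [0.4, 1.1]
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import Peak, PeakList
from .noe import NOEPeak
from .pre import (DEFAULT_CONSTANTS, PhysicalConstants, PREObservation,
                  PREParameters, SpinLabelSite, predict_pre_profile)
from .structure import (METHYL_DEFS, MethylGroup, Structure,
                        methyl_distance_matrix)

#: ppm ranges per residue type: (dC low, dC high, dH low, dH high)
SHIFT_RANGES = {
    "ILE": (9.0, 16.0, 0.2, 1.2),
    "MET": (15.0, 19.0, 1.5, 2.3),
    "LEU": (21.0, 27.0, 0.3, 1.1),
    "VAL": (19.0, 24.0, 0.4, 1.1),
}

#: target packing density: one methyl per 600 A^3
VOLUME_PER_METHYL = 600.0
#: geminal methyl carbon-carbon distance in Leu/Val side chains
GEMINAL_DISTANCE = 2.5


@dataclass
class GroundTruth:
    """The generator's complete knowledge of a synthetic dataset."""

    methyls: list[MethylGroup]
    shifts: dict[str, tuple[float, float]]       # methyl id -> (dH, dC)
    assignment: dict[str, str]                   # methyl id -> peak id
    minor_offsets: dict[str, tuple[float, float]]  # methyl id -> (ddH, ddC)
    seed: int

    @property
    def peak_to_methyl(self) -> dict[str, str]:
        return {p: m for m, p in self.assignment.items()}


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _components(points: np.ndarray, cutoff: float) -> list[list[int]]:
    """Connected components of the distance-cutoff graph on points."""
    n = len(points)
    if n == 0:
        return []
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    adj = d <= cutoff
    unseen = set(range(n))
    comps = []
    while unseen:
        start = min(unseen)
        seen = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(adj[i])[0]:
                j = int(j)
                if j in unseen and j not in seen:
                    seen.add(j)
                    frontier.append(j)
        unseen -= seen
        comps.append(sorted(seen))
    comps.sort(key=len, reverse=True)
    return comps


def _repair_connectivity(per_residue: list[tuple[str, list[np.ndarray]]],
                         rng: np.random.Generator, min_sep: float,
                         cutoff: float, max_rounds: int = 200,
                         ) -> Optional[list[tuple[str, list[np.ndarray]]]]:
    """Re-place residues outside the giant contact-graph component next to it.

    One residue is moved per round (to a random position within NOE range of
    a giant-component methyl, respecting ``min_sep``) until the graph is
    connected; returns None when a placement cannot be found.
    """
    per_residue = [(t, [np.asarray(s) for s in sites])
                   for t, sites in per_residue]
    for _round in range(max_rounds):
        pts_list, owner = [], []
        for ri, (_t, sites) in enumerate(per_residue):
            for s in sites:
                pts_list.append(s)
                owner.append(ri)
        pts = np.array(pts_list)
        comps = _components(pts, cutoff)
        if len(comps) <= 1:
            return per_residue
        giant = comps[0]
        outside = sorted({owner[i] for comp in comps[1:] for i in comp})
        ri = outside[0]
        anchor_pts = pts[giant]
        placed_other = [pts[i] for i in range(len(pts)) if owner[i] != ri]
        for _try in range(500):
            target = anchor_pts[rng.integers(len(anchor_pts))]
            new0 = target + rng.uniform(min_sep, 0.9 * cutoff) * _random_unit(rng)
            sites = [new0]
            if len(per_residue[ri][1]) == 2:
                sites.append(new0 + GEMINAL_DISTANCE * _random_unit(rng))
            if all(np.linalg.norm(s - q) >= min_sep
                   for s in sites for q in placed_other):
                per_residue[ri] = (per_residue[ri][0], sites)
                break
        else:
            return None
    return None


def generate_constellation(n_ile: int = 6, n_leu: int = 12, n_val: int = 8,
                           n_met: int = 4, min_separation: float = 4.0,
                           seed: int = 0, ensure_connected: bool = False,
                           connectivity_cutoff: float = 8.0,
                           max_attempts: int = 200,
                           ) -> tuple[Structure, GroundTruth]:
    """Self-avoiding random methyl constellation inside a sphere.

    Residue sites are placed by rejection sampling in a sphere sized for
    ~one methyl per 600 A^3; Leu/Val contribute a geminal pair 2.5 A apart.
    ``min_separation`` applies between methyls of different residues. With
    ``ensure_connected`` residues falling outside the giant component of
    the contact graph at ``connectivity_cutoff`` are re-placed adjacent to
    it until the graph is connected, emulating the clustered methyl core of
    a folded protein (NOE-guided propagation can only reach connected
    methyls, so recovery benchmarks use this mode).
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    counts = {"ILE": n_ile, "LEU": n_leu, "VAL": n_val, "MET": n_met}
    if any(v < 0 for v in counts.values()):
        raise ValueError("residue counts must be >= 0")
    n_methyls = n_ile + n_met + 2 * (n_leu + n_val)
    rng = np.random.default_rng(seed)
    if n_methyls == 0:
        return Structure(), GroundTruth([], {}, {}, {}, seed)
    radius = (3.0 * n_methyls * VOLUME_PER_METHYL / (4.0 * math.pi)) ** (1.0 / 3.0)

    for _attempt in range(max_attempts):
        placed: list[np.ndarray] = []     # all methyl positions so far
        per_residue: list[tuple[str, list[np.ndarray]]] = []
        failed = False
        for restype in ("ILE", "LEU", "VAL", "MET"):
            n_per_res = len(METHYL_DEFS[restype])
            for _ in range(counts[restype]):
                for _try in range(2000):
                    centre = rng.uniform(-radius, radius, size=3)
                    if np.linalg.norm(centre) > radius:
                        continue
                    sites = [centre]
                    if n_per_res == 2:
                        sites.append(centre + GEMINAL_DISTANCE * _random_unit(rng))
                    if all(np.linalg.norm(s - q) >= min_separation
                           for s in sites for q in placed):
                        placed.extend(sites)
                        per_residue.append((restype, sites))
                        break
                else:
                    failed = True
                    break
            if failed:
                break
        if failed:
            continue
        if ensure_connected:
            per_residue = _repair_connectivity(
                per_residue, rng, min_separation, connectivity_cutoff)
            if per_residue is None:
                continue
        break
    else:
        raise RuntimeError("could not place constellation (density too high "
                           "or connectivity unreachable)")

    structure = Structure()
    methyls: list[MethylGroup] = []
    for idx, (restype, sites) in enumerate(per_residue):
        resnum = idx + 1
        for (label, cname, _parent, _pseudo, stereo), coord in zip(
                METHYL_DEFS[restype], sites):
            structure.add_atom("A", resnum, restype, cname, coord)
            methyls.append(MethylGroup("A", resnum, restype, label,
                                       np.asarray(coord), np.asarray(coord),
                                       stereo))
    methyls.sort(key=MethylGroup.sort_key)

    shifts: dict[str, tuple[float, float]] = {}
    for m in methyls:
        c_lo, c_hi, h_lo, h_hi = SHIFT_RANGES[m.residue_type]
        shifts[m.id] = (float(rng.uniform(h_lo, h_hi)),
                        float(rng.uniform(c_lo, c_hi)))

    perm = rng.permutation(len(methyls))
    assignment = {m.id: f"pk{int(perm[i]) + 1:03d}"
                  for i, m in enumerate(methyls)}
    return structure, GroundTruth(methyls, shifts, assignment, {}, seed)


def add_minor_form(truth: GroundTruth, fraction: float = 0.1,
                   dc_range: tuple[float, float] = (0.2, 1.0),
                   dh_offset: float = 0.0, seed: int = 0) -> None:
    """Mark a random subset of methyls as having a minor conformational form.

    13C offsets |ddC| are sampled uniformly in ``dc_range`` with random
    sign; the 1H offset defaults to 0, emulating minor-form peaks displaced
    only along the 13C axis.
    """
    rng = np.random.default_rng(seed)
    n = max(0, round(fraction * len(truth.methyls)))
    chosen = rng.choice(len(truth.methyls), size=n, replace=False)
    truth.minor_offsets = {}
    for i in chosen:
        mid = truth.methyls[int(i)].id
        ddc = float(rng.uniform(*dc_range)) * (1 if rng.random() < 0.5 else -1)
        truth.minor_offsets[mid] = (dh_offset, ddc)


def simulate_peaklist(truth: GroundTruth, sigma_h: float = 0.0,
                      sigma_c: float = 0.0, seed: int = 0,
                      scheme: str = "IMLV[rac]",
                      minor_intensity: float = 0.3,
                      spectrum_id: str = "synthetic-hmqc") -> PeakList:
    """HMQC peak list: one major peak per methyl plus minor-form duplicates.

    Major peaks sit at the true shifts plus Gaussian jitter (sigma_h/sigma_c
    ppm); methyls in the minor subset contribute an extra peak at the offset
    position with reduced intensity.
    """
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    for m in truth.methyls:
        dh, dc = truth.shifts[m.id]
        pid = truth.assignment[m.id]
        peaks.append(Peak(pid,
                          dh + (rng.normal(0.0, sigma_h) if sigma_h else 0.0),
                          dc + (rng.normal(0.0, sigma_c) if sigma_c else 0.0),
                          intensity=float(rng.uniform(0.5, 1.5))))
        if m.id in truth.minor_offsets:
            ddh, ddc = truth.minor_offsets[m.id]
            peaks.append(Peak(
                f"{pid}-minor",
                dh + ddh + (rng.normal(0.0, sigma_h) if sigma_h else 0.0),
                dc + ddc + (rng.normal(0.0, sigma_c) if sigma_c else 0.0),
                intensity=minor_intensity))
    return PeakList(spectrum_id, scheme, peaks)


def simulate_mutant(truth: GroundTruth, wt_peaklist: PeakList,
                    residue_number: int, perturb_radius: Optional[float] = None,
                    perturb_sigma_h: float = 0.01, perturb_sigma_c: float = 0.1,
                    seed: int = 0) -> PeakList:
    """Peak list of an X->Ala point mutant: the residue's peaks vanish.

    Optionally, peaks of methyls within ``perturb_radius`` A of the mutated
    residue's methyls are jittered to emulate local structural perturbation
    (off by default).
    """
    mutated = [m for m in truth.methyls if m.residue_number == residue_number]
    if not mutated:
        raise ValueError(f"residue {residue_number} has no methyls")
    removed_ids = {truth.assignment[m.id] for m in mutated}
    removed_ids |= {f"{p}-minor" for p in set(removed_ids)}
    rng = np.random.default_rng(seed)
    perturbed: set[str] = set()
    if perturb_radius is not None:
        for m in truth.methyls:
            if m.residue_number == residue_number:
                continue
            if any(np.linalg.norm(m.pseudo - mm.pseudo) <= perturb_radius
                   for mm in mutated):
                perturbed.add(truth.assignment[m.id])
    peaks = []
    for p in wt_peaklist.peaks:
        if p.id in removed_ids:
            continue
        dh, dc = p.dh, p.dc
        if p.id in perturbed:
            dh += rng.normal(0.0, perturb_sigma_h)
            dc += rng.normal(0.0, perturb_sigma_c)
        peaks.append(Peak(p.id, dh, dc, p.intensity, p.form))
    return PeakList(f"{wt_peaklist.spectrum_id}-{residue_number}A",
                    wt_peaklist.scheme, peaks)


def simulate_pre(truth: GroundTruth, site: SpinLabelSite,
                 params: PREParameters,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS,
                 sigma: float = 0.0, unquantifiable_fraction: float = 0.0,
                 seed: int = 0, key_by: str = "peak",
                 ) -> list[PREObservation]:
    """Observed intensity ratios from the PRE forward model plus noise.

    ratio_obs = clip(ratio_pred + N(0, sigma), 0, inf); noise can push
    ratios above 1, as real peak-height ratios do. A random fraction of
    observations is marked unquantifiable (overlapped peaks). Keys are peak
    ids (``key_by="peak"``) or methyl ids (``key_by="methyl"``).
    """
    rng = np.random.default_rng(seed)
    preds = predict_pre_profile(truth.methyls, site, params, constants)
    out = []
    for pred in preds:
        ratio = pred.ratio + (rng.normal(0.0, sigma) if sigma else 0.0)
        ratio = max(0.0, ratio)
        quant = rng.random() >= unquantifiable_fraction
        key = (truth.assignment[pred.methyl_id] if key_by == "peak"
               else pred.methyl_id)
        out.append(PREObservation(key, i_para=ratio, i_dia=1.0,
                                  quantifiable=bool(quant)))
    return out


def simulate_noe(truth: GroundTruth, cutoff: float = 8.0,
                 completeness: float = 1.0, jitter_h: float = 0.0,
                 jitter_c: float = 0.0, seed: int = 0,
                 mixing_time: float = 0.4) -> list[NOEPeak]:
    """4D HCCH-type NOE cross-peaks for the constellation's contact graph.

    One peak per retained contact (Bernoulli(completeness)); intensity
    proportional to r^-6, normalized so the shortest contact has intensity
    1; peak positions are the true shifts plus optional jitter.
    """
    from .noe import expected_contacts

    rng = np.random.default_rng(seed)
    matrix = methyl_distance_matrix(truth.methyls)
    contacts = expected_contacts(matrix, cutoff)
    if not contacts:
        return []
    r_min = min(c.distance for c in contacts)
    peaks = []
    for c in contacts:
        if rng.random() > completeness:
            continue
        ha, ca = truth.shifts[c.a]
        hb, cb = truth.shifts[c.b]
        jit = (lambda s: rng.normal(0.0, s) if s else 0.0)
        peaks.append(NOEPeak(h1=ha + jit(jitter_h), c1=ca + jit(jitter_c),
                             c2=cb + jit(jitter_c), h2=hb + jit(jitter_h),
                             intensity=float((r_min / c.distance) ** 6),
                             spectrum_id="synthetic-4d-noesy",
                             mixing_time=mixing_time))
    return peaks


def simulate_geminal_pairs(truth: GroundTruth,
                           completeness: float = 1.0,
                           seed: int = 0) -> list[tuple[str, str]]:
    """Peak-pairing table from a geminal-connectivity experiment.

    Emulates an out-and-back experiment through the shared Cgamma/Cbeta
    frequency: one (peak id, peak id) record per Leu/Val residue whose two
    methyls are both present, optionally thinned by Bernoulli(completeness).
    """
    rng = np.random.default_rng(seed)
    by_res: dict[tuple[str, int], list[MethylGroup]] = {}
    for m in truth.methyls:
        if m.residue_type in ("LEU", "VAL"):
            by_res.setdefault((m.chain, m.residue_number), []).append(m)
    pairs = []
    for key in sorted(by_res):
        group = sorted(by_res[key], key=MethylGroup.sort_key)
        if len(group) == 2 and rng.random() <= completeness:
            pairs.append((truth.assignment[group[0].id],
                          truth.assignment[group[1].id]))
    return pairs


def simulate_stereo_lists(truth: GroundTruth, sigma_h: float = 0.0,
                          sigma_c: float = 0.0, seed: int = 0,
                          ) -> tuple[PeakList, PeakList]:
    """Peak lists of the stereospecifically labelled samples.

    Returns (pro-S list, pro-R list): the pro-S sample shows Met-e and
    Val-g2 peaks (Met + stereospecific Val labelling), the pro-R sample
    Leu-d1 and Val-g1 peaks. Peaks sit at the true shifts plus jitter and
    reuse the wild-type peak ids.
    """
    rng = np.random.default_rng(seed)

    def build(spectrum_id: str, scheme: str, wanted) -> PeakList:
        peaks = []
        for m in truth.methyls:
            if not wanted(m):
                continue
            dh, dc = truth.shifts[m.id]
            peaks.append(Peak(truth.assignment[m.id],
                              dh + (rng.normal(0.0, sigma_h) if sigma_h else 0.0),
                              dc + (rng.normal(0.0, sigma_c) if sigma_c else 0.0)))
        return PeakList(spectrum_id, scheme, peaks)

    pro_s = build("synthetic-proS", "MV[pro-S]",
                  lambda m: m.residue_type == "MET" or
                  (m.residue_type == "VAL" and m.stereo == "pro-S"))
    pro_r = build("synthetic-proR", "LV[pro-R]",
                  lambda m: m.residue_type in ("LEU", "VAL") and
                  m.stereo == "pro-R")
    return pro_s, pro_r


def pick_anchors(truth: GroundTruth, n_residues: int = 4, seed: int = 0,
                 ) -> dict[str, str]:
    """Choose anchor residues and return their true methyl -> peak mapping.

    Mirrors anchor-point assignment from point mutants: all methyls of each
    chosen residue are anchored. Residues are drawn without replacement,
    deterministically per seed.
    """
    rng = np.random.default_rng(seed)
    residues = sorted({m.residue_number for m in truth.methyls})
    if n_residues > len(residues):
        raise ValueError("not enough residues for the requested anchors")
    chosen = set(rng.choice(residues, size=n_residues, replace=False).tolist())
    return {m.id: truth.assignment[m.id] for m in truth.methyls
            if m.residue_number in chosen}


@dataclass
class SimulatedDataset:
    """A complete simulated study: ground truth plus every observable."""

    truth: GroundTruth
    peaklist: PeakList
    contacts: list           # ExpectedContact
    noe_peaks: list[NOEPeak]
    merged_predictions: list
    pre_evidence: list       # engine.PREEvidence, one per tag site
    anchors: dict[str, str]
    geminal_pairs: list[tuple[str, str]]
    pro_s_list: PeakList
    pro_r_list: PeakList
    sites: list[SpinLabelSite]


def simulate_dataset(seed: int = 0, n_ile: int = 6, n_leu: int = 12,
                     n_val: int = 8, n_met: int = 4, sigma_h: float = 0.0,
                     sigma_c: float = 0.0, pre_sigma: float = 0.0,
                     noe_completeness: float = 1.0, n_anchors: int = 4,
                     noe_cutoff: float = 8.0, n_tags: int = 3,
                     ensure_connected: bool = True,
                     params: Optional[PREParameters] = None,
                     ) -> SimulatedDataset:
    """One-call simulation of everything the assignment workflow consumes.

    Emulates the study design: an HMQC peak list, a suite of NOE
    cross-peaks, structure-based shift predictions (true shifts with the
    standard 0.2 / 1.0 ppm uncertainty floors), PRE profiles for three
    peripheral tag sites placed on orthogonal axes at the constellation
    surface, four anchor residues, a geminal pairing table and the two
    stereospecific peak lists.
    """
    from .engine import PREEvidence
    from .noe import expected_contacts
    from .shifts import MergedPrediction

    params = params or PREParameters()
    _structure, truth = generate_constellation(
        n_ile, n_leu, n_val, n_met, seed=seed,
        ensure_connected=ensure_connected, connectivity_cutoff=noe_cutoff)
    peaklist = simulate_peaklist(truth, sigma_h, sigma_c, seed=seed)
    matrix = methyl_distance_matrix(truth.methyls)
    contacts = expected_contacts(matrix, noe_cutoff)
    noe_peaks = simulate_noe(truth, noe_cutoff, noe_completeness,
                             sigma_h, sigma_c, seed=seed + 1)
    merged = []
    for mid, (dh, dc) in sorted(truth.shifts.items()):
        merged.append(MergedPrediction(mid, "H", dh, 0.2, "both"))
        merged.append(MergedPrediction(mid, "C", dc, 1.0, "both"))
    pts = np.array([m.pseudo for m in truth.methyls])
    centre = pts.mean(axis=0)
    radius = float(np.abs(pts - centre).max())
    axes = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, -1.0])]
    sites, pre_evidence = [], []
    for k in range(n_tags):
        site = SpinLabelSite(f"tag{k}", None,
                             centre + radius * axes[k % len(axes)])
        obs = simulate_pre(truth, site, params, sigma=pre_sigma,
                           seed=seed + 10 + k)
        preds = predict_pre_profile(truth.methyls, site, params)
        sites.append(site)
        pre_evidence.append(PREEvidence(
            site.label, {o.key: o.ratio for o in obs},
            {p.methyl_id: p.ratio for p in preds}))
    anchors = pick_anchors(truth, n_anchors, seed=seed)
    geminal = simulate_geminal_pairs(truth)
    pro_s, pro_r = simulate_stereo_lists(truth, sigma_h, sigma_c,
                                         seed=seed + 5)
    return SimulatedDataset(truth, peaklist, contacts, noe_peaks, merged,
                            pre_evidence, anchors, geminal, pro_s, pro_r,
                            sites)


def run_recovery(dataset: SimulatedDataset, **propagate_kwargs,
                 ) -> tuple[int, int, int]:
    """Run propagation + stereo resolution; (n correct, n assigned, n methyls)."""
    from .engine import propagate_assignments, stereo_assign

    state = propagate_assignments(
        dataset.anchors, dataset.truth.methyls, dataset.peaklist,
        dataset.contacts, dataset.noe_peaks, dataset.merged_predictions,
        dataset.pre_evidence, geminal_constraints=dataset.geminal_pairs,
        **propagate_kwargs)
    stereo_assign(state, dataset.peaklist.by_id,
                  [frozenset(g) for g in dataset.geminal_pairs],
                  dataset.pro_s_list, dataset.pro_r_list)
    correct = sum(1 for m, p in state.assignments.items()
                  if dataset.truth.assignment[m] == p)
    return correct, len(state.assignments), len(dataset.truth.methyls)
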