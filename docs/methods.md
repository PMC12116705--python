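# Methods

`methylassign` formalizes the workflow used to assign the ILVM methyl
resonances of large (>40 kDa), selectively methyl-labelled proteins when no
backbone assignment is available: anchor peaks from X→Ala point mutants,
propagation over the structure's NOE network, and supplementary evidence
from paramagnetic relaxation enhancements (PREs) and structure-based
chemical-shift predictions. This note records the models, the parameters
that matter, and the design decisions taken where the procedure is
genuinely open.

## PRE forward model

A nitroxide spin label conjugated to an engineered cysteine enhances the
transverse relaxation of nearby methyl protons. The package uses the
simplified Solomon–Bloembergen form

    Γ₂ᴴ(r) = κ_H / r⁶ · S² · τ₁ · (4 + 3 / (1 + ω₀² τ₁²))

with `r` the electron–proton distance in Å, `S²` the squared order
parameter of the electron–nucleus vector, `τ₁` its effective correlation
time and `ω₀` the ¹H Larmor frequency in rad s⁻¹. The prefactor is

    κ_H = (γ_H g β)² (μ₀/4π)² S(S+1)/15 ,   S = ½ for a nitroxide.

**Units.** Rates and times are SI; distances are Å. The single m⁶ → Å⁶
conversion (×10⁶⁰) is isolated in `kappa_H`, which fixes the unit contract
for everything downstream.

**The electron g-value defaults to 2.0**, the Zeeman-only approximation for
the nitroxide's unpaired electron; with CODATA γ_H, β and μ₀ this gives
κ_H = 1.2311 × 10¹⁶ Å⁶ s⁻². Using the CODATA free-electron value
(2.00232, exported as `G_E_FREE`) instead raises κ_H by 0.23%; the
difference is irrelevant at the accuracy of the model (a single-point
electron, fixed S² and τ₁) but the constant is configurable.

The multiple-quantum PRE relevant for HMQC peaks is
Γ₂^MQ = [1 + (γ_C/γ_H)²] Γ₂ᴴ ≈ 1.063 Γ₂ᴴ, and the predicted
paramagnetic/diamagnetic peak-height ratio is

    I_para/I_dia = exp(−Γ₂ᴴ Δ) ·
        (R₂ᴹQ + π·LB₁)(R₂ˢQ + π·LB₂) /
        [(R₂ᴹQ + π·LB₁ + Γ₂ᴹQ)(R₂ˢQ + π·LB₂ + Γ₂ᴴ)]

which is exactly 1 at Γ₂ᴴ = 0 and strictly decreasing.

Defaults (all in `PREParameters`, all configurable): S² = 0.8, τ₁ = 20 ns,
Δ = 7.7 ms (total fixed HMQC delay), R₂ᴹQ = R₂ˢQ = 40 s⁻¹, LB₁ = LB₂ =
5 Hz, spectrometer ¹H frequency 850 MHz (the field at which most
methyl-TROSY data of this kind are recorded; ω₀ = 2π·f).

**Electron placement.** Explicit tag model-building is out of scope; the
`cb_offset` mode places the electron at Cβ + 7 Å along the Cα→Cβ direction,
a single-point stand-in for the nitroxide nitrogen of a PROXYL tag. An
explicit coordinate can always be supplied. No conformational ensemble of
the tag is modelled.

**Localization.** `localize_spin_label` inverts the forward model by
exhaustive search on a bounded 3-D lattice, minimizing the sum of squared
ratio residuals. Grid search is deliberate: the objective has broad flat
regions (far-field ratios saturate at 1) where gradient methods stall, the
grid makes the result deterministic (ties resolve to the first node in
lexicographic order), and at the 1–2 Å steps of interest the cost is
negligible. Collinear methyl constellations are flagged as degenerate.

## Structure model

ILVM methyls are enumerated from PDB/mmCIF coordinates (gemmi): Ile δ1,
Leu δ1/δ2, Val γ1/γ2, Met ε, with Ile γ2 only on request (it is not
protonated in the standard labelling schemes). Stereo descriptors follow
the labelling chemistry: Leu δ1 and Val γ1 are pro-R, Leu δ2 and Val γ2
pro-S.

The methyl *pseudo-atom* is the geometric centre of the three methyl
protons. Crystal structures rarely include protons, so the default
fallback is the methyl carbon position; an `ideal` mode instead offsets
the centre by 1.09·cos(70.53°) ≈ 0.36 Å along the parent→carbon bond
axis (the proton centroid of an idealized tetrahedral methyl is axially
symmetric, so no dihedral phase is needed). Carbon-centred and
ideal-centroid distances differ by well under the rounding of reported
nearest-neighbour distances.

χ₂ dihedrals (Leu: Cα–Cβ–Cγ–Cδ1, Ile: Cα–Cβ–Cγ1–Cδ1) use the IUPAC sign
convention in (−180°, +180°]. Rotamers are classified with half-open
120°-wide bins — trans = (120, 180] ∪ (−180, −120], gauche+ = (0, 120],
gauche− = (−120, 0] — chosen so every valid angle falls in exactly one
bin. Altlocs other than blank/'A' are dropped with a warning; residue
numbers are used as authored.

## Chemical-shift prediction merging

Two predictors are merged per (methyl, nucleus): when both cover a
nucleus, the value is the unweighted mean and the uncertainty is
max(predictor-A's stated uncertainty, |difference between predictors|);
when only the uncertainty-reporting predictor covers it, its own numbers
are used; when only the other does, fixed floors of 0.2 ppm (¹H) and
1.0 ppm (¹³C) apply. Missing keys are legal — predictors do not cover
every methyl. Peak–prediction compatibility is the uncertainty-normalized
Euclidean distance in (δH, δC); the simplest metric consistent with the
qualitative way predictions are used (to support or veto a candidate, not
to rank fine differences).

## NOE network

The structure side is an expected-contact graph: all methyl pairs with
pseudo-atom distance ≤ 8 Å (default; methyl–methyl NOESY at 0.4 s mixing
reaches long range, and the cutoff is configurable). The spectrum side is
a list of 3D/4D cross-peaks; 3D HCH/CCH layouts are normalized to the 4D
(H1, C1, C2, H2) representation with the absent dimension unconstrained.
A peak explains a contact when both sides match the assigned shifts within
tolerances (defaults 0.02 ppm ¹H, 0.2 ppm ¹³C — typical methyl-TROSY
linewidths), either orientation; ambiguity resolves to the smallest
combined deviation. Mixing time is metadata only and never enters scoring.

## Assignment engine

Scores for a candidate (methyl, peak) pair combine three channels with
weights NOE 0.5, shift-prediction 0.3, PRE 0.2 (acceptance threshold 0.4,
runner-up margin 0.1; all configurable). The ordering encodes the evidence
hierarchy of the workflow: NOESY propagation is primary, the rest
supplements. Channel scores:

* **NOE support** — fraction of the methyl's expected contacts to
  already-assigned methyls for which an observed NOE peak links the
  candidate peak to the partner's peak (absent when no contact partner is
  assigned yet);
* **shift prediction** — Gaussian kernel exp(−c²/2) on the normalized
  compatibility distance c;
* **PRE** — mean over spin-label sites of clip(1 − |obs − pred|, 0, 1).

Propagation is greedy best-first with three move kinds. *Deductions*: once
one peak of a geminal pair (from the Cγ/Cβ-resolved pairing experiment) is
assigned to a Leu/Val methyl, the partner peak is forced onto the geminal
partner. *Individual moves* place one peak on one methyl; peaks belonging
to an unassigned geminal pair are reserved. *Joint moves* place a geminal
peak pair onto the two methyls of one residue in the better-scoring
orientation, marking near-ties (< 0.05) stereo-ambiguous. A move is
accepted when its score reaches the threshold and beats the runner-up for
each of its resources by the margin; ties break deterministically by
(residue number, peak id).

A pure margin rule cannot finish the map: geminal partners share NOE
partner sets, and occasionally two same-type methyls have predicted shifts
closer than the margin can separate, so the corresponding moves block each
other symmetrically even with perfect data. The engine therefore ends with
an *elimination stage* that re-runs the greedy loop without the margin
requirement (threshold still applies), at confidence reduced by the margin
— the formal counterpart of assigning the last peaks of a spin system by
exclusion. With complete noise-free evidence this yields exact recovery of
the generator's ground truth; under noise it trades a small risk of
swapped near-degenerate pairs for completeness, which the recovery
benchmarks quantify.

Stereospecific resolution then relabels each geminal pair using the
pro-R (Leu δ1/Val γ1) and pro-S (Met ε/Val γ2) sample peak lists; pairs
matching neither stay ambiguous (ambiguity code 2 in NMR-STAR export), and
pairs whose two peaks match the same list are flagged as conflicts rather
than silently resolved.

Minor-form bookkeeping runs last: an unassigned peak that shares an
assigned peak's ¹H shift within tolerance but is displaced in ¹³C by more
than tolerance is flagged `minor` and linked to that methyl. Minor-form
and exchange peaks cannot be distinguished from positions alone (an
exchange peak combines the major-form ¹H shift with the minor-form ¹³C
shift); the flag deliberately conflates them, and flagged peaks never
re-enter the assignable pool.

Anchor detection compares wild-type and X→Ala mutant peak lists under the
same labelling scheme: candidates are wild-type peaks with no mutant
counterpart within tolerances; surpluses and deficits relative to the
residue's methyl count are reported, never resolved silently. X→Ala is the
only supported mutation type.

## Synthetic data

The generator emulates the statistical structure of a real study so every
stage is testable without downloads: residue sites are placed by rejection
sampling in a sphere at ~1 methyl per 600 Å³ (a typical methyl packing
density), geminal methyls 2.5 Å apart, minimum inter-residue methyl
separation 4 Å. True shifts are sampled uniformly per residue type from
ranges reflecting methyl-TROSY dispersion of α/β proteins (Ile δ1:
δC 9–16, δH 0.2–1.2; Met ε: 15–19, 1.5–2.3; Leu δ: 21–27, 0.3–1.1; Val γ:
19–24, 0.4–1.1 ppm); only the relative geometry of shift space matters for
the tests. Derived observables: HMQC peaks (Gaussian shift jitter,
minor-form duplicates displaced only in ¹³C by 0.2–1.0 ppm at reduced
intensity), point-mutant lists (the residue's peaks removed, optional
perturbation of neighbours within a radius), PRE profiles (the forward
model plus clipped Gaussian noise — ratios above 1 are allowed, as in real
peak-height ratios), NOE peaks (one per retained contact, r⁻⁶ intensity),
a geminal pairing table and the two stereospecific peak lists. Everything
is reproducible bit-for-bit from (parameters, seed).

At realistic density, a random constellation routinely contains methyls
with no neighbour within the NOE cutoff — the same structural isolation
that leaves real methyls unassigned. NOE-guided propagation cannot reach
them, so the recovery benchmarks use `ensure_connected=True`: residues
outside the giant component of the 8 Å contact graph are re-placed
adjacent to it until the graph is connected, emulating a clustered
protein core. Recovery benchmarks therefore measure the pipeline's
behaviour on the part of a structure it can in principle reach; they say
nothing about isolated methyls, which remain unassignable by design.

The default benchmark is 50 methyls (6 Ile, 12 Leu, 8 Val, 4 Met — a
scaled-down ILVM composition), 4 anchor residues, three peripheral tag
sites on orthogonal axes at the constellation surface, and predictions
equal to the true shifts with the 0.2/1.0 ppm uncertainty floors. The
noisy condition adds 0.005/0.05 ppm shift jitter, PRE noise σ = 0.05, and
10% missing NOEs. What passing these benchmarks does **not** show: real
predictor errors are structured (systematically wrong near aromatics),
real peak overlap is worse in crowded Leu/Val regions, and real NOE
spectra contain spin-diffusion and artifact peaks — none of which the
generator emulates.

## Numerical choices and degenerate inputs

* Frozen scalar values in the tests come from a 40-digit arbitrary-
  precision evaluation of the closed forms, independent of the package.
* Distances are exact floating point internally; comparisons with reported
  values round to one decimal.
* Dihedrals raise on collinear triples; `intensity_ratio` raises on
  negative rates; `gamma2_H` raises at r ≤ 0; grid localization clamps
  node–methyl distances at 10⁻⁶ Å to avoid division blow-ups on nodes
  coinciding with a methyl.
* TSVs write with `%.17g` and read with round-trip float parsing, so all
  writers/readers are lossless on their own output.
* NMR-STAR export covers the assigned-chemical-shift loop subset only; the
  reader accepts both HD1/QD1-style proton names.

## Limitations

* The PRE model omits Curie-spin and cross-correlated terms, tag rotamer
  ensembles, and any fitting of S² or τ₁ from data.
* The engine assigns major-form peaks only; minor forms are flagged, not
  assigned, and relaxation-dispersion analysis is out of scope.
* Shift prediction itself (ring currents etc.) is not reimplemented; the
  package consumes predictor output tables.
* Geometry benchmarks against a deposited crystal structure require the
  coordinate file; the test suite states the expected values and fails
  (rather than skipping) when the file is unavailable.
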