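# methylassign

A structure-guided assignment toolkit for methyl-TROSY NMR of large
proteins.

For proteins beyond ~40 kDa, backbone-based assignment strategies fail and
the ¹H,¹³C-HMQC spectra of selectively ILVM-methyl-labelled samples
(Ile δ1, Leu δ1/δ2, Val γ1/γ2, Met ε) become the main source of
site-specific information. Assigning those methyl peaks without a backbone
assignment is a puzzle solved from several weak clues at once: peaks that
vanish in X→Ala point mutants ("anchors"), inter-methyl NOESY cross-peaks
interpreted against a crystal structure, paramagnetic relaxation
enhancements (PREs) from nitroxide spin labels, structure-based
chemical-shift predictions, geminal-pair connectivities and
stereospecifically labelled samples. `methylassign` implements each of
those ingredients as a tested, composable library — for NMR
spectroscopists doing such assignments and for method developers who need
a controlled synthetic benchmark.

## What is implemented

* **Structure model** — ILVM methyl enumeration from PDB/mmCIF with
  pseudo-atoms and pro-R/pro-S stereo descriptors, inter-methyl distance
  matrices, nearest-methyl queries, χ₂ dihedrals and trans/gauche± rotamer
  classification.
* **PRE forward model** — the simplified Solomon–Bloembergen rate

      Γ₂ᴴ = κ_H/r⁶ · S²τ₁ · (4 + 3/(1 + ω₀²τ₁²)),
      κ_H = (γ_H g β)² (μ₀/4π)² S(S+1)/15 = 1.2311 × 10¹⁶ Å⁶ s⁻²,

  its multiple-quantum scaling Γ₂ᴹQ = 1.063 Γ₂ᴴ, the HMQC intensity-ratio
  predictor I_para/I_dia, observed/predicted comparison, and grid-search
  localization of a spin label from observed ratios.
* **Shift-prediction merging** — two predictor outputs combined into one
  set with uncertainties (mean value; max of stated uncertainty and
  inter-predictor spread; 0.2/1.0 ppm fallback floors).
* **NOE network** — expected-contact graphs at a distance cutoff and
  matching of 3D/4D NOESY cross-peaks against a candidate assignment.
* **Assignment engine** — anchor detection from mutant spectra, geminal
  pairing, stereospecific resolution, evidence-combining greedy
  propagation, minor-form/exchange-peak flagging, coverage reports, and
  NMR-STAR 3.1 chemical-shift export.
* **Synthetic data** — ground-truth methyl constellations with every
  derived observable (peak lists, mutants, PREs, NOEs, stereo samples),
  reproducible from a seed.
* **Acquisition utilities** — effective NUS sparsity arithmetic and
  coupling-transfer delays.

See `docs/methods.md` for the models, parameter defaults and design
decisions.

## Worked example

Predict how a spin label bleaches methyl peaks, then recover a full
assignment on synthetic data:

```python
>>> import methylassign as ma
>>> p = ma.PREParameters()           # S2=0.8, tau1=20 ns, 850 MHz, Delta=7.7 ms
>>> for r in (12, 16, 20, 25, 30):
...     g = ma.gamma2_H(float(r), p)
...     print(r, round(g, 1), round(ma.intensity_ratio(g, p), 3))
12 263.9 0.004
16 47.0 0.199
20 12.3 0.603
25 3.2 0.869
30 1.1 0.953
```

A methyl 12 Å from the electron is bleached essentially to zero
(I_para/I_dia ≈ 0.004), while at 30 Å the peak barely notices the tag
(≈ 0.95) — the steep r⁻⁶ window that makes PREs useful assignment
evidence.

```python
>>> ds = ma.simulate_dataset(seed=1)          # 50 methyls, 4 anchor residues
>>> ma.run_recovery(ds)
(50, 50, 50)
```

With complete noise-free NOE/PRE/prediction evidence, propagation from 4
anchor residues assigns all 50 methyls correctly (correct, assigned,
total). The same call with `sigma_h=0.005, sigma_c=0.05, pre_sigma=0.05,
noe_completeness=0.9` exercises the noisy benchmark.

The command line mirrors the library:

```sh
methylassign nus-sparsity --nominal 0.0055 --dims 3 --oversample 2,2,2
# effective sparsity: 4.4% (~35% per indirect dimension)
methylassign simulate --out dataset/ --seed 3
methylassign extract-methyls --in structure.pdb --chain A
methylassign predict-pre --structure structure.pdb --site 406 --out pre.tsv
```

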