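# fraglib

Extract, score and reuse the structural information hidden in protein
fragment libraries.

Fragment libraries — per-position collections of short template backbone
structures resembling local regions of a target protein — were built for
fragment-assembly folding, but they carry far more structural signal than
assembly alone uses: secondary structure, backbone torsions φ/ψ, the CA-trace
pseudo-angles θ (planar angle of three consecutive Cα) and τ (dihedral of
four consecutive Cα), and within-fragment Cα–Cα / Cβ–Cβ distances.  `fraglib`
provides three ways to use that signal:

1. **Library quality metrics.**  Besides classical *precision* (fraction of
   fragments with CA RMSD to the native window below a cutoff) and *coverage*
   (fraction of positions spanned by at least one good fragment), seven
   fragment-level metrics are computed as nested expectations — an inner mean
   over each position's fragments, an outer mean over positions:

       ACC_ss(FL)  = E_p [ E_f [ I( SS(f) = SS(f*) ) ] ]
       ERR_ang(FL) = E_p [ E_f [ (1/N) Σ_j min(|Δ_j|, 360° − |Δ_j|) ] ]
       ERR_dist(FL)= E_p [ E_f [ MAE over within-fragment atom pairs ] ]

   for the fragment secondary-structure class (strict-majority H/E/C, else
   O), the four angle properties and the two distance properties.  Weighted
   variants replace the inner mean by a softmax-confidence average over each
   position's fragments, with weights from the predicted RMSD r of each
   fragment, `w_i ∝ exp((5 − r_i)/T)` at temperature `T = 0.1`.

2. **Protein-specific folding potentials.**  Fragments are *smoothed* into
   7-residue windows; each position's property samples are fitted with
   confidence-weighted Gaussian mixtures (wGMM, K = 4 chosen by BIC), giving
   7 models per 1D property and 21 per 2D property — 70 models per position.
   Each model becomes an energy through its negative log likelihood, e.g.

       L_φ(x) = − Σ_i log Σ_t w_{i,t} p(φ_i; μ_{i,t}, σ_{i,t})

   and the combined potential `L_FL = w_φL_φ + w_ψL_ψ + w_θL_θ + w_τL_τ +
   w_CαL_Cα + w_CβL_Cβ` is minimized over torsions by gradient descent in a
   toy folding demo that generates and energy-ranks decoys.

3. **Feature tensors for property prediction.**  The 50 most confident
   fragments per position, padded to 15 residues, are encoded as an
   `L × 50 × 15 × 11` tensor (3-state SS one-hot + sin/cos of φ, ψ, θ, τ),
   together with the monotone distance mapping `d' = tanh((d − 10)/2.4)` and
   its exact inverse.

A synthetic-data module generates toy natives (NeRF-built from canonical
torsions) and noisy fragment libraries with *known* true RMSD per fragment,
so the whole pipeline is testable without external downloads.

## Worked example

```python
from fraglib import (make_worked_example, evaluate_library, weighted_metrics,
                     build_all_potentials)

native, lib, truth = make_worked_example()   # 20-residue helix, 180 fragments
rep = evaluate_library(lib, native)
print(f"precision@1A {rep.precision[1.0]:.2f}  coverage@1A {rep.coverage[1.0]:.2f}")
print(f"acc_ss {rep.acc_ss:.2f}  err_phi {rep.err_phi:.2f} deg  "
      f"err_cb {rep.err_cb_dist:.3f} A")
wrep = weighted_metrics(lib, native)
print(f"weighted err_phi {wrep.err_phi:.2f} deg")
sets = build_all_potentials(lib, seed=1)
print(f"models at position 5: {sets[5].n_models()}")
```

prints

```
precision@1A 1.00  coverage@1A 1.00
acc_ss 1.00  err_phi 3.95 deg  err_cb 0.204 A
weighted err_phi 3.80 deg
models at position 5: 70
```

The library was drawn with 5° torsion noise, so every fragment is within
1 Å of its native window (precision = coverage = 1 at that cutoff); the mean
φ error is close to the half-normal mean 5°·√(2/π) ≈ 3.99°, and weighting by
predicted-RMSD confidence reduces it, because low predicted RMSD marks truly
better fragments.  At every interior position all 4·7 + 2·21 = 70 mixture
models can be fitted.

The same steps are available from a shell:

```bash
fraglib simulate --spec spec.json --out sim/         # toy native + library
fraglib evaluate --library sim/library.extlib --native sim/native.pdb --out report.json
fraglib build-potentials --library sim/library.extlib --out potentials.json
fraglib fold-demo --potentials potentials.json --length 20 --n-decoys 50 --out decoys/
fraglib featurize --library sim/library.extlib --out features.npz
fraglib convert --in sim/library.extlib --in-format extended \
        --out sim/library.frag --out-format nnmake
```

## File formats

`fraglib` reads and writes an NNMake-style fragment text format (per-position
blocks with per-residue amino acid, SS letter and φ/ψ/ω; predicted RMSD on a
`#predRMSD` comment line) and an extended structured-text format that
additionally carries backbone coordinates, which the distance metrics and 2D
potentials require.  One small committed example of each, plus an example
native PDB, lives in `src/fraglib/data/`.

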