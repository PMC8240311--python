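# Methods

This note documents the models, conventions and numerical choices behind
`fraglib`, and what its synthetic benchmarks do and do not show.

## Geometry conventions

All angles are degrees on the branch (−180°, 180°]; missing angles are NaN
in memory and the sentinel `9999.000` in text formats.  Dihedrals follow the
IUPAC convention (cis = 0°, sign by the right-hand rule about the central
bond).  θ_i is the planar angle Cα(i−1)–Cα(i)–Cα(i+1) and τ_i the dihedral
Cα(i−1)–Cα(i)–Cα(i+1)–Cα(i+2), both anchored at residue i, so θ is undefined
at the two chain termini and τ at the first and last two residues.  Positions
are 1-based; a fragment of length n at position p covers the closed interval
[p, p+n−1].

Backbones are rebuilt from torsions by NeRF (natural extension reference
frame) on ideal covalent geometry: bond lengths N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; bond angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°
(standard Engh–Huber-like values, configurable via `IdealGeometry`).  The
build–measure round trip reproduces input torsions to well below 1e−6°.
Virtual Cβ atoms are placed at CA–CB 1.521 Å, N–CA–CB 110.4° and improper
dihedral C–N–CA–CB +122.6°, which matches the widely used fixed-coefficient
Cβ construction for L-amino acids to < 0.01 Å.  RMSD is computed over CA
atoms by Kabsch superposition restricted to proper rotations (reflections
are never used), the convention of fragment-library evaluation.

The three-state torsion-region secondary-structure assigner (H: φ∈[−100,−30],
ψ∈[−80,−5]; E: φ∈[−180,−90], ψ∈[90,180]∪[−180,−170]; else C) exists to label
synthetic natives and torsion-only fragments deterministically; it is not a
DSSP replacement.

## Library metrics

Precision counts fragments with RMSD strictly below the cutoff ("smaller
than" the threshold); the cutoff grid defaults to 0.1–2.0 Å in 0.1 Å steps.
The seven fragment-level metrics are nested expectations: an inner mean over
one position's fragments, an outer mean over positions.  Positions with no
fragments — or whose fragments all lack the property — are excluded from the
outer mean (avoiding 0/0); within a fragment, residues missing the angle on
either the fragment or the native side are skipped and the per-fragment
divisor reduced accordingly.  Angle differences are wrapped:
min(|Δ|, 360° − |Δ|) ∈ [0°, 180°].  Fragment secondary-structure class is the
strict-majority letter (H/E/C) or O when no letter exceeds half; the native
window's class is computed by the same rule.  The weighted variants replace
the inner mean by the softmax-confidence average with weights
w_i ∝ exp((5 − predRMSD_i)/T), default T = 0.1 — the constant offset cancels
in the normalisation and the softmax is computed with a max shift for
stability.

## Weighted Gaussian mixtures

Smoothing slides a 7-residue window over every fragment; parents shorter
than the window are dropped (counted and logged).  Sub-fragments inherit the
parent's predicted RMSD and per-residue angles, with θ/τ computed once over
the parent's full CA trace so that window-boundary values retain source
context, as they do for fragments cut from real proteins.

Each (position, property, slot) sample set is fitted by a 1-D Gaussian
mixture with per-sample weights acting as multiplicities: E-step
responsibilities are standard, every M-step statistic multiplies the
responsibility by the sample weight, and the weighted log-likelihood is
monitored for convergence (tolerance 1e−6, at most 500 iterations).
Initialisation places component means at weighted inverse-CDF quantiles
(2k+1)/(2K) of the sample distribution, variances at the weighted total
variance and mixing weights uniform.  This initialisation is a function of
the weighted empirical distribution only, so it is deterministic and exactly
invariant to replacing a sample by duplicates with split weight — the
property that makes weighted EM verifiable against sample duplication; a
k-means++-style seeded initialisation would break that equivalence, which is
why it was not used.  Variances are floored at 1e−3 (deg² or Å²).  K
defaults to 4 — a BIC scan over K = 2…30 on clean multi-modal angle samples
selects 4 — and is reduced (logged) when the Kish effective sample size
1/Σw² or the number of distinct values cannot support it; identical samples
collapse to a single floor-variance component.  BIC uses the weighted mean
log-likelihood scaled by the effective sample size, with 3K − 1 free
parameters.

Angles are fitted on the linear degree scale (no circular density), matching
how the per-position models are visualised in practice; a property whose
mass straddles the ±180° seam is split into two apparent modes — a documented
limitation that the K = 4 mixture partially absorbs.

## Potentials

A fitted model contributes the negative log of its mixture density at the
structure's property value.  The 1D potentials sum over the 7 offsets of
each position's window, the 2D potentials over the 21 within-window residue
pairs; overlapping windows deliberately re-count shared residues and pairs,
matching the per-position modelling.  In `nll_potential_1d/2d` the density
is floored at ε = 1e−30 before the log; the packed evaluator used by the
folding demo instead computes the mixture log-density exactly in the log
domain (no underflow is possible there), preserving the quadratic Gaussian
tails whose gradients guide descent from distant starting points.  The
combined potential is the weighted sum of the six per-property potentials;
all six weights default to 1.0 and are configuration-exposed, since no
canonical tuned values exist for the toy setting.

## Folding demo

The demo minimizes the combined potential plus a soft-sphere clash term
Σ max(0, 3.4 Å − d_CA)² (weight 1.0, pairs |i−j| ≥ 2) over the φ/ψ torsions
of an ideal-geometry chain (ω fixed trans) — the smallest parameterization
that exercises all six potentials.  Gradients are central finite differences
(h = 0.1°) and steps use a backtracking line search, so accepted steps never
increase the stage objective.  Optimization is staged: the φ/ψ potentials
alone (cheap — no reconstruction needed — and nearly separable per residue)
first funnel the chain into the library's torsion basins, then the full
six-property objective polishes.  Direct descent on the full objective from
a random start tends to stall in the nonconvex coupling of the distance
terms; the torsion-first schedule resolves this while keeping every stage
monotone.  Decoy generation runs n independent folds (default 50) from
seeded basin-mixture torsion initialisations (35% helix / 30% strand / 35%
coil, jitter 15°) and ranks decoys by ascending energy with seed as the
tie-break.

Because the potentials are NLL sums over ~1000 terms, descent started *at*
the native relaxes the energy by tens of percent (the mixture modes sit at
the noisy-library consensus, not exactly at the native) while moving the
structure by only a few tenths of an Å — the meaningful stationarity
statement is structural, and that is what the tests assert.

## Featurization

Per position, the 50 fragments with lowest predicted RMSD (stable sort; ties
keep file order) are padded to 15 residues and encoded with D = 11 channels:
3-state SS one-hot plus sin/cos of φ, ψ, θ, τ.  A missing angle becomes the
(0, 0) pair — distinguishable from any real angle, whose pair has unit norm —
and padded slots are all-zero with a boolean mask marking real residue
slots.  The feature count is configuration-exposed because reasonable
encodings differ in whether they count SS as one feature or three.  Distances
map through d' = tanh((d − 10)/2.4), exactly invertible on (−1, 1) by
d = 10 + 2.4·atanh(d').

## Synthetic data: what it does and does not emulate

`make_toy_native` builds chains from canonical torsions per secondary-
structure segment (H −57/−47, E −120/130, coil from a 3-basin mixture) with
2° jitter.  `sample_fragment_library` copies each native window's torsions
with two flanking residues of context, adds i.i.d. Gaussian noise (default
sd 5°, the worked example's study condition), rebuilds coordinates with
NeRF, and records the true CA RMSD; the predicted RMSD is the true RMSD plus
Gaussian noise (default sd 0.2 Å) floored at zero — the simplest confidence
model that preserves the property the weighting scheme exploits (low
predicted RMSD ⇒ truly better fragment).  The worked example (20-residue
helix, 10 fragments per position, seed 42) regenerates bit-identically and
is the fixture behind the docs, the golden report and the acceptance runs.

The generator reproduces the *statistical* structure real libraries have —
per-position candidate sets, length variation (7–10 residues), noisy but
informative confidences, a half-normal angle-error profile (ERR_ang →
σ·√(2/π) as sampling grows) — but not their failure modes: no wrong-topology
fragments, no sequence-dependent recruitment bias, no correlated errors
along the chain, and torsion noise rather than real conformational
heterogeneity.  Passing tests therefore demonstrate correctness of the
machinery and the expected qualitative behaviours (confidence weighting
helps; potentials prefer the native; energy ranking is informative), not
performance on real targets.

## Problem sizes

The default verification runs use toy scales chosen to exercise every code
path: 12–20-residue natives, 2–10 fragments per position, 25–50 decoys with
40 torsion-stage plus 40 full-stage descent steps, EM samples of 1000–2000
points and a BIC scan over K = 2…10.  All randomness flows from explicit
seeds; identical seeds give bit-identical libraries, fits and decoys.
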