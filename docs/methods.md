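# Methods

## Model

Each residue of a protein is described by the chemical shifts of a fixed
atom set (the *encoding scheme*). After per-(residue type, atom)
standardization, the shift vector x ∈ R^d is compressed by an autoencoder

    encoder:  x → h = tanh(W1 x + b1) → z = σ(w2·h + b2) ∈ (0, 1)
    decoder:  z → h' = tanh(V1 z + c1) → x̂ = V2 h' + c2

trained to minimize the masked reconstruction error
Σ m_k (x̂_k − x_k)² / Σ m_k, where m is the observation mask. The single
logistic bottleneck z is the per-residue compressed value. The premise is
that intra-residue shifts are strongly cross-correlated and their dominant
axis of variation is local conformation, so the 1-D code that best
preserves the vector orders residues along the helix–coil–sheet
continuum. This is a lossy summary: dynamics, ring currents, pH effects
and so on are folded into the same scalar.

Input widths differ between residue types (glycine has no CB and carries
HA2/HA3; proline has no amide proton), so one encoder/decoder pair is
fitted per residue type. The output scale is made comparable across types
in two steps:

* standardization makes every atom dimension zero-mean/unit-variance per
  type, so no type sees a systematically larger input;
* *orientation calibration* flips a type's output (v → 1 − v) when its
  mean value on labelled helix examples exceeds that on sheet examples.
  The sign of a trained bottleneck is arbitrary (negating the first-layer
  weights and mirroring the decoder gives the same loss), so this is a
  convention, not extra fitting. Calibration uses the labelled synthetic
  set; it is idempotent.

## Encoding schemes

* `reduced` (default): H, HA, CA, N, CB, C — robust when side-chain data
  are sparse. GLY uses HA2 in place of HA and drops CB; PRO drops H.
* `dimers`: CA, N, H for every type (PRO's H slot simply never observes).
* `full`: the reduced set plus the side-chain carbons, nitrogens and
  protons commonly assigned in BMRB entries, frozen as a versioned table
  in `encoding.py`. The scheme is pluggable, so an alternative list can
  be swapped in without touching the model code.

## Preprocessing

Training pools all values per (residue type, atom), computes the 1st and
99th empirical percentiles (linear interpolation between order
statistics), discards values outside them — a guard against mis-assigned
or mis-referenced shifts — and fits mean/std on the survivors. On
continuous data this removes ≈2% of values. Pairs with fewer than 50
observations, or zero variance after filtering, are dropped with a
warning. At inference a value outside the stored cutoffs is treated as
missing rather than clipped: clipping would inject a fabricated extreme
value into the reconstruction, whereas masking just withholds one
coordinate. Missing entries are encoded as 0 with mask 0; since 0 is the
type-conditional mean after standardization, this is the
least-informative imputation, and the mask keeps it out of the loss.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3, batch 256, 200 epochs,
hidden width 2 × input dimension; all overridable via `Hyperparams`. The
train/validation split (default 90/10) is by protein, not by residue, so
within-chain correlation cannot leak into the held-out loss. Every random
choice flows from an explicit integer seed (default 42); two runs with
the same seed produce identical weights. The reported baseline is the
masked MSE of predicting 0 (the per-atom mean) — the natural "no
information through the bottleneck" reference.

One caveat on epochs: with few residues per type, an epoch is very few
Adam steps (batch 256). The rank-1 capacity check in the tests and the
acceptance script therefore trains for 1000 epochs so that the measured
loss reflects what the architecture can represent, not an unconverged
optimizer; the ordinary corpus fits use the 200-epoch default.

## Alignment

Global Needleman–Wunsch over the match-cost matrix
c(i, j) = |v_a(i) − v_b(j)|, gap penalty 0.4 per gap column, end gaps
included (true global alignment). The DP minimizes total cost; the score
reported is total / number of columns, which reads as a mean per-column
distance (optimizing the mean directly would be ill-posed because the
alignment length varies). Tie-breaking in the traceback is deterministic:
diagonal, then consuming from the first profile, then the second —
preferring matches maximizes interpretability. A missing profile value
matched to anything contributes exactly the gap penalty, so such residues
are neither attracted to nor repelled from matches.

In `hybrid` mode the cost is
(1 − w)·|v_a − v_b| + w·B(aa_i, aa_j) with default w = 0.5, where B is
BLOSUM62 mapped monotonically onto [0, 1] by the empirical quantile of
each score over the 210 unordered amino-acid pairs (ties share the
midpoint rank) and inverted. W/W, the unique maximum score, has cost
exactly 0, and every identity costs less than every mismatch (all
BLOSUM62 diagonal entries exceed all off-diagonal entries). The quantile
estimator is a deterministic choice among several reasonable monotone
rescalings; the alignment depends only on the induced order and rough
spacing.

Numerical note: the DP accumulates each cell as a left-to-right float sum
over its path (boundaries included), so its optimum is exactly comparable
(`==`, no tolerance) with a brute-force enumeration that sums column
costs in the same order. The tests exploit this for an exact oracle
equivalence check on short profiles.

## Synthetic data

The generator emulates BMRB-like assignment tables: uniform random
sequences; a three-state (H/E/C) Markov secondary-structure path with
per-state persistence (defaults 0.92/0.88/0.85 → geometric segments with
means ≈12/8/7 residues) and entry weights 0.35/0.25/0.40; shifts drawn as
coil mean + structure offset + Gaussian noise (std 0.8 ppm for carbons,
1.5 for nitrogens, 0.15 for protons); atoms dropped independently at a
10% missingness rate. The coil means are synthetic constants — plausible
ppm baselines per atom class with a frozen per-(type, atom) jitter and a
few familiar anchors (e.g. GLY CA 45.4) — not a literature random-coil
table. Offsets follow the canonical secondary-shift directions (helix:
CA +3.1, C +2.2, CB −0.5, HA −0.35, N −1.5; sheet roughly opposite and
larger for CB/HA). Denatured mode emulates urea unfolding: all-coil with
1.5× noise and an optional residual-structure fraction.

What this does *not* emulate: realistic amino-acid composition, sequence-
dependent neighbour effects, ring currents, correlated (referencing)
errors across a whole entry, pH/temperature dependence, or physically
accurate shift prediction. Passing tests therefore demonstrate that the
pipeline recovers the structure signal it is pointed at under controlled
conditions — not that the packaged synthetic-trained models transfer
quantitatively to real BMRB entries. For real data, train on a real
corpus; the packaged models exist so the tool works out of the box and
the pipeline is exercised end to end.

Problem sizes used by the tests and the acceptance script: 300 proteins
(≈30,000 residues) for corpus training; 25 + 25 proteins of length
80–120 (>2,000 residues per set) for the denatured/native distribution
comparison; 10 + 10 proteins for the alignment-score ordering; 300 random
short-profile pairs plus the exhaustive length ≤ 2 grid for the alignment
oracle.

## Degenerate inputs and edge rules

* Duplicate atom rows in a file: first occurrence kept, warning logged.
* Multiple chains / shift lists: first used, warning logged.
* Non-standard residues (ligands, caps): dropped, warning logged.
* Residue with no observed atom, or type absent from the model: missing
  value (null in JSON); alignment treats it as described above.
* Pseudo-atom names (HB%, QB) are kept verbatim; they participate only if
  an encoding scheme lists them (none of the built-ins do).
* Empty profile in `align`: usage error. Empty shift list: valid, empty
  table.
* Model files are JSON with exact float reprs; save→load→transform is
  bit-identical. Loading checks a format marker and version and refuses
  mismatches by name.

## Packaged models

`data/default_reduced_model.json` and `data/default_dimers_model.json`
are trained on 300 synthetic native proteins (seed 2020) and calibrated;
weights are rounded to 6 decimals to keep the files compact, which
perturbs transforms negligibly relative to data noise. No `full`-scheme
model is packaged (its weight count is an order of magnitude larger);
train one with `shiftcrypt train --scheme full` if needed.

## Known limitations

* One chain per file; no multi-chain or complex handling.
* No chemical-shift re-referencing: inputs are assumed correctly
  referenced (the percentile filter only blunts gross outliers).
* The score of an alignment has no significance model; compare scores
  only within a consistent setup.
* Per-type networks mean rare residue types in a small training corpus
  get noisy models (a warning fires below 200 residues per type).
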