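# Methods

## Problem setting

An ASO variant is a pair (sequence, modification pattern): per-position
sugar chemistry (DNA, LNA, or 2′-MOE) and per-linkage backbone chemistry
(phosphodiester PO or phosphorothioate PS). The toolkit ranks the patterns
of one user sequence by predicted knockdown efficacy. Two enumeration
regimes are supported:

* **full** — every position independently DNA or the selected chemistry,
  all linkages PS: `2^l` variants, streamed in binary-counting order with
  the 5′ position as least-significant bit and capped (default `2^18`) so
  a maximum-length query cannot exhaust memory;
* **gapmer** — two wings of `wing_len` nt (default 5) flank a central DNA
  gap. Within each wing, positions listed as *variable* (default 2–5,
  counted 1-based from the outer terminus of each wing inward) take DNA or
  the chemistry independently; remaining wing positions are **fixed as
  modified**, the conventional modified-terminus anchoring of gapmer
  design (a 16-mer thus yields `2^4 = 16` cases per wing, 256 patterns).

The anchored-terminus choice for non-variable wing positions was a
genuinely open design point; anchoring was chosen because wing termini in
published LNA gapmer screens are essentially always modified, and it keeps
the all-DNA "gapmer" out of a set that is meant to explore wing interior
placement.

## Chemistry

Variants are assembled into molecules, not fingerprints: each (base,
sugar) pair maps to a SMILES fragment from a YAML library shipped with the
package, and residues are joined 3′→5′ through phosphate linkages.
Conventions (the library documents all of them; vendors differ and no
single convention is canonical):

* 5′-OH and 3′-OH termini, no terminal phosphate;
* neutral protonated phosphates, `P(=O)(OH)` / `P(=S)(OH)`, with no
  stereo descriptor on phosphorus (Rp/Sp unresolved in practice);
* sugars carry natural β-D stereochemistry; the DNA-T nucleoside's
  canonical SMILES is identical to literature thymidine;
* MOE-modified T is built as the MOE-**uridine** analogue and MOE-modified
  C as MOE-**5-methylcytidine**, following MOE chemistry convention and
  the output-notation token names; LNA and DNA keep the plain DNA base;
* the LNA sugar carries the 2′-O,4′-C methylene bridge (+1 C, +1 O versus
  the DNA sugar — an invariant the tests assert at every position).

Element conservation provides a strong end-to-end check: an `l`-mer must
contain exactly `l−1` phosphorus atoms, one sulfur per PS linkage, and a
heavy-atom total equal to an independent text-level tally of its
fragments. New 2′-chemistries (2′-OMe, 2′-F) can be registered by
extending the YAML library without code changes.

## Featurization

Node features (15 dims): element one-hot over {C, N, O, P, S, F, other},
degree one-hot (0–5), formal charge, aromatic flag. Edge features
(9 dims): a no-bond indicator, bond-order class one-hot (single / double /
triple / aromatic), aromatic and in-ring flags, and two shortest-path
distance encodings, `max(0, 1 − d/64)` and `1/d`. The bond-type block is
zero exactly where the adjacency matrix is zero.

The distance channels are the one deliberate departure from a
purely bond-local vocabulary. Variants of the same sequence differ by a
few atoms on an otherwise identical ~300-atom scaffold; with global
attention, distance encodings are what allow an atom to establish *where
along the backbone* it sits (e.g. by its distance to the chain termini),
which turned rank recovery from near-chance to reliable in our
experiments. They are exactly permutation-equivariant and deterministic,
unlike spectral positional encodings, which suffer sign/degeneracy
ambiguity.

## Model

The ranker is an edge-augmented graph transformer. Both channels are
linearly embedded (node 15→`node_dim`, edge 9→`edge_dim`) and each layer
applies, with pre-layer-norm residuals:

* multi-head attention over nodes whose logits are `QKᵀ/√d_k` **plus** a
  learned linear bias from the edge channel, **times** (after softmax) a
  sigmoid gate from the edge channel;
* a 2× feed-forward block on the node channel;
* an edge update: `E ← E + W·logits`, i.e. the edge channel is refreshed
  from the pre-softmax attention logits.

The edge channel's own feed-forward block found in the original EGT
design is omitted: it dominated compute (it is the only other `N²`-sized
transform) and the layer contract that matters for this task — edges bias
and gate attention, and are updated from the logits — is preserved.

Readout is a **masked sum** over node embeddings followed by a two-layer
head. Sum, not mean: a modification changes only ~2–10 atoms out of
~300, and a mean readout scales that signal by `k/N`, which in practice
pinned the pairwise loss at the margin (the model could not separate
variants at all); the sum readout keeps the contribution of added or
altered atoms additive. Masked mean remains available via
`EGTConfig(pooling="mean")`.

Default configuration: 2 layers, 4 heads, `node_dim` 32, `edge_dim` 8,
dropout 0 — about 1 s per training step (4 pairs, 8 graphs of ~330 atoms)
on one CPU core, which is the deployment target of this desk-scale build.
Depth/width are config fields, not constants.

The model, its training loop and RMSProp are implemented in NumPy on a
minimal reverse-mode autodiff (`asoforge._autodiff`), float32 throughout;
gradients are verified against central differences in the test suite.

## Training

Records are grouped by (sequence, condition); within a group, every pair
whose inhibition difference exceeds `min_gap` (default 0.05, to suppress
pairs whose ordering is plausibly replicate noise) becomes an ordered
comparison. The summed hinge objective
`max(0, t + f(x_neg) − f(x_pos))`, margin `t = 0.1`, is minimized with
RMSProp (lr 1e-3, decay 0.9) with global gradient-norm clipping at 5 —
without clipping, training on near-duplicate graph pairs showed
oscillating batch losses. Pairs are shuffled each epoch; optional early
stopping monitors a held-out pair set and restores the best parameters,
and an epoch callback supports custom model selection (we found hinge
loss on a small noisy validation pair set to be an unreliable selection
signal at desk scale; see the reference experiment). All randomness —
initialization, shuffling, dropout,
subsampling — derives from a single seed, and identical
seed/config/data reproduce bit-identical parameters (checkpoints carry a
content hash, `version_id`, which also keys the query cache so results
are invalidated on retraining).

## Synthetic oracle

The generator emulates the structure of a pattern-screening database:
many variants of one sequence measured under shared conditions, with
pattern-dependent inhibition in [0, 1]. Noiseless efficacy is

```
y = logistic( Σ_p w_p x_p − c · Σ_p x_p x_{p+1} )
```

where `x` is the modified-position indicator, `w_p = 0.5 − 0.18·d(p)`
with `d(p)` the distance of position `p` from the nearest terminus, and
`c = 0.1` penalizes adjacent (crowded) modifications. The weight profile
encodes standard gapmer pharmacology: terminus-proximal modifications
raise affinity and efficacy; positions toward the RNase H-recruiting
center are deleterious. Note the consequence that modification *count*
alone anti-correlates with efficacy on held-out gapmer patterns — a model
must learn positional placement, not just bulk composition, to recover
this oracle's ranking. Replicate noise is truncated Gaussian (sd 0.05 by
default, a qRT-PCR-scale proxy), resampled until the value stays a valid
rate.

What the oracle does **not** emulate: hybridization thermodynamics, RNase
H kinetics, sequence-dependent toxicity, cross-condition scale shifts
beyond the condition key, or any coupling between base identity and
modification effect. Passing the recovery experiment therefore shows the
*pipeline* can learn position-dependent pattern effects from paired
comparisons of real molecules — not that it predicts wet-lab efficacy.

## Reference experiment

`asoforge.experiments.rank_recovery_experiment` is the reference
validation: enumerate the 256 LNA gapmer patterns of the HIF1A-targeting
16-mer 5′-GTTACTGCCTTCTTAC-3′, draw one noisy oracle record per pattern,
train on pairs from 200 patterns (subsampled to 400 pairs, 5 epochs) and
measure the Spearman correlation between model scores and the oracle's
noiseless efficacy on the 56 held-out patterns, plus the oracle
percentile of the top-ranked held-out pattern. The sizes (400 pairs,
5 epochs, 2-layer model) are the package's single-core reference
protocol; the acceptance bar is ρ ≥ 0.7.

Two details matter for reliability. First, the noise floor: with noise
sd 0.05 against a noiseless-efficacy spread of sd ≈ 0.05, the noisy
labels themselves rank the truth at only ρ ≈ 0.7 — the model must
*denoise* through paired comparisons to clear the bar, which it does
(selected-epoch models reach ρ ≈ 0.8–0.92 across seeds). Second, epoch
selection: optimization on near-duplicate graphs is noisy, and the
experiment keeps the epoch whose scores best Spearman-rank the noisy
*training* labels over all 200 training patterns — a selection computed
from training data only. Hinge loss on a small held-out pair set proved
too noisy for this purpose and occasionally selected an underfit epoch.

## Numerical and degenerate-input notes

* Softmax is computed with max-subtraction; padded attention targets get
  −1e9 before softmax; padded rows are excluded from pooling.
* Scoring is run under an inference mode that builds no gradient graph;
  batched and single-graph scores agree to float32 tolerance, and scores
  are invariant under atom renumbering to < 1e-4.
* Length-1 sequences have an empty linkage list and rank fine; the
  all-DNA pattern is a legal variant and appears in full enumeration.
* Ties in ranked output are broken by ascending notation string; CSV
  scores print with 6 decimals so identical models give byte-identical
  files.
* A hinge pair whose two members score identically costs exactly the
  margin `t`; contradictory pair sets plateau at `t` (tested).

## Known limitations

* Scores are uncalibrated and not comparable across sequences, models or
  chemistries; only within-query order is meaningful.
* The fragment library's protonation/termini conventions are one defensible
  choice among several; absolute atom counts depend on them.
* No sequence-space search, off-target assessment, toxicity modeling, 3D
  conformers or duplex thermodynamics.
* Training at production scale (10⁵–10⁶ records, deep configs) is out of
  scope for the NumPy backend; the architecture is deliberately small.
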