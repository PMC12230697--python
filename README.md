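# asoforge

A desk-scale toolkit for designing the **chemical modification pattern** of
an antisense oligonucleotide (ASO). Given a DNA sequence (≤ 22 bases of
A/T/C/G) and a modification chemistry — LNA (locked nucleic acid) or 2′-MOE
(2′-*O*-methoxyethyl) — asoforge:

1. **enumerates** candidate patterns: either all `2^l` single-chemistry
   variants or the classic gapmer wing designs (modified wings, central DNA
   gap, every linkage phosphorothioate);
2. **assembles** each variant into a real molecule: canonical SMILES built
   from an explicit nucleoside fragment library, parsed into a heavy-atom
   molecular graph `G = (V, E)` with binary adjacency matrix `A`;
3. **scores** each graph with an edge-augmented graph transformer (EGT)
   ranker `f_θ(x)` trained by pairwise learning-to-rank; and
4. **exports** a ranked table in the standard screening notation, e.g.
   `[LNA G]*[LNA T]*T*A*C*...`, where `*` marks a PS linkage.

It is aimed at nucleic-acid chemists and ML-for-chemistry researchers who
want an auditable, fully offline version of this design loop: every stage —
chemistry, featurization, model, training objective — is inspectable and
tested, and a synthetic efficacy oracle stands in for proprietary screening
databases so the whole pipeline (including training) runs on one CPU core.

## The model and objective

Each variant is a molecular graph with node features (element, degree,
formal charge, aromaticity) and edge features (bond order class,
aromaticity, ring membership, plus shortest-path distance encodings). The
ranker is an EGT: node embeddings `H` and edge embeddings `E` flow through
every layer; multi-head attention logits over nodes are additively biased
and multiplicatively gated by learned transforms of `E`, and `E` is updated
from the attention logits. A masked sum over final node embeddings feeds a
small head producing the scalar score.

Because absolute inhibition is not comparable across assays, training uses
only within-assay comparisons. For each ordered pair — `x_pos` beat `x_neg`
on the same sequence under the same conditions — the loss is the margin
ranking (hinge) objective

```
θ* = argmin_θ  Σ_i  max(0,  t + f_θ(x_neg^(i)) − f_θ(x_pos^(i)))
```

with margin `t = 0.1`, minimized with RMSProp. Scores are therefore
relative: only the ordering within one query is meaningful.

## Worked example

```bash
# 1. simulate a gapmer screen for the HIF1A-targeting 16-mer
asoforge simulate --seq GTTACTGCCTTCTTAC --chem LNA --out screen.tsv --seed 7

# 2. train the ranker on it
asoforge train --records screen.tsv --out model.npz \
               --epochs 5 --max-pairs 400 --seed 7 -v

# 3. rank all 256 gapmer wing patterns and export the CSV
asoforge rank --seq GTTACTGCCTTCTTAC --chem LNA --mode gapmer \
              --model model.npz --out results/
```

`simulate` writes 256 records (one per wing pattern: 5-nt wings, positions
2–5 of each wing varying). `train` logs the mean hinge loss per epoch —
this run printed `0.3029, 0.1523, 0.1246, 0.0963, 0.0744` over the five
epochs (roughly 105 s/epoch on one CPU core; exact values depend on the
seed) — and saves a self-describing checkpoint. `rank` prints the top-10
table and writes `results/GTTACTGCCTTCTTAC-LNA.csv`, which begins:

```
chemically modified sequence,score
[LNA G]*[LNA T]*[LNA T]*[LNA A]*C*T*G*C*C*T*T*C*[LNA T]*[LNA T]*[LNA A]*[LNA C],0.797478
[LNA G]*[LNA T]*[LNA T]*A*C*T*G*C*C*T*T*C*[LNA T]*[LNA T]*[LNA A]*[LNA C],0.774962
[LNA G]*[LNA T]*[LNA T]*[LNA A]*C*T*G*C*C*T*T*C*T*[LNA T]*[LNA A]*[LNA C],0.759858
...
```

Two columns: the chemically modified sequence in conversion-rule notation
(`[LNA X]` / `[2’-MOE(U)]`-style tokens, `*` for every PS linkage) and the
predicted score, in descending order — higher score, higher predicted
knockdown efficacy. The ranking the model learned here is chemically
sensible: top patterns keep the central gap pure DNA and stack LNA at the
terminus-proximal wing positions, which is exactly the structure the
simulated screen rewards. Repeated identical queries are served from an
optional persistent cache keyed by the model's content hash.

The same pipeline is available as a scikit-learn style estimator:

```python
from asoforge import EGTRanker, validate_sequence, enumerate_gapmer_wing_patterns

seq = validate_sequence("GTTACTGCCTTCTTAC")
patterns = enumerate_gapmer_wing_patterns(seq, "LNA")
est = EGTRanker(epochs=3, seed=7).fit([(seq, p) for p in patterns[:200]], y[:200])
scores = est.predict([(seq, p) for p in patterns[200:]])
```

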