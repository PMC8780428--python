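# smirnet

Prediction of small molecule–miRNA associations from sequence alone.

MicroRNAs (miRNAs) are short (18–24 nt) regulatory RNAs implicated in many
diseases, and small molecules (SMs) that modulate them are candidate drugs
for repurposing. Most computational association predictors need curated
biological similarity features (side effects, functional consistency,
indication phenotypes) that are slow to collect and unavailable for new
compounds. `smirnet` instead derives all similarity information from the
raw strings every entity already has — the miRNA nucleotide sequence and
the compound SMILES — and ranks candidate associations with a
graphlet-interaction network model.

## Method

1. **Continuous feature representation.** One character-level LSTM
   encoder–decoder is trained per entity type. The encoder maps a string
   to a fixed-length latent vector `x ∈ R^D` (D = 64 or 128); the decoder
   reconstructs the string from `x`, and its reconstruction accuracy is
   the diagnostic that the encoding retains the sequence. miRNAs use the
   six-character vocabulary {A, C, G, T, N, −} with maximum length 30;
   SMILES use the characters observed in the corpus with maximum
   length 50.
2. **Similarity.** For two latent vectors `x, y`,
   `d(x, y) = sqrt(Σ_d (x_d − y_d)²)`, and similarity is the negated
   normalised distance `s = 1 − d / d_max`, giving a symmetric matrix in
   [0, 1] with unit diagonal, one per entity type.
3. **Graphlet-interaction ranking.** Each similarity matrix is binarized
   into a sparse network (top quantile of off-diagonal similarities).
   Graphlet interactions between two nodes are counted over the 28 isomer
   classes — equivalence classes of (connected graphlet on ≤ 4 nodes,
   ordered pair of distinguished nodes). A candidate pair (s, m) is scored
   by summing weighted interaction counts between m and the known partners
   of s in the miRNA network, plus those between s and the known partners
   of m in the SM network. All candidate pairs are ranked by score.
4. **Evaluation.** Recall@top-p%: the fraction of held-out known
   associations ranked within the top `ceil(p·N)` of the candidate
   ranking, under 5-fold cross-validation or leave-one-entity case
   studies.

The autoencoder is implemented as a compact, fully deterministic numpy
seq2seq (manual backpropagation through time, Adam); the estimators follow
scikit-learn conventions (`fit`/`transform`, `get_params`, trailing
underscore for fitted attributes) and compose with `sklearn.base.clone`
for cross-validation.

## Worked example

Everything runs on synthetic corpora with planted cluster structure — no
downloads. Sixty miRNAs and sixty SMs are generated in six matched
clusters; associations are planted preferentially between matched
clusters, so latent-space similarity carries a real signal:

```python
from smirnet import (SyntheticSpec, generate_bundle, PipelineConfig,
                     build_predictor, EvaluationConfig, five_fold_cv)

bundle = generate_bundle(SyntheticSpec(seed=1))
print(f"{len(bundle.mirna_records)} miRNAs, {len(bundle.sm_records)} SMs, "
      f"{len(bundle.associations)} known associations")

result = build_predictor(bundle.mirna_records, bundle.sm_records,
                         PipelineConfig(latent_dim=64, seed=1))
curve, _ = five_fold_cv(bundle.associations, result.predictor,
                        EvaluationConfig(seed=1))
for p, r in zip(curve.percent_points, curve.recalls):
    print(f"recall@top-{p:.0%}: {r:.2f}")
```

Output:

```
60 miRNAs, 60 SMs, 183 known associations
recall@top-1%: 0.09
recall@top-2%: 0.14
recall@top-5%: 0.28
recall@top-10%: 0.43
recall@top-15%: 0.62
recall@top-20%: 0.67
recall@top-25%: 0.68
recall@top-30%: 0.69
recall@top-40%: 0.73
recall@top-50%: 0.80
```

A random ranking would give recall ≈ p at every point (0.10 at the top
10%); the pipeline reaches 0.43 there, i.e. the sequence-derived
similarities recover a large share of the planted held-out associations.
The same workflow is available as shell subcommands:

```sh
smirnet synth --outdir data --seed 1
smirnet train-encoder --corpus data/mirna.fasta --domain mirna --model-out mir.pkl
smirnet encode --corpus data/mirna.fasta --model mir.pkl --out mir_lat.tsv
smirnet similarity --encodings mir_lat.tsv --out mir_sim.tsv
# ... same for the SM corpus, then:
smirnet predict --sm-similarity sm_sim.tsv --mirna-similarity mir_sim.tsv \
    --sm-corpus data/sm.tsv --mirna-corpus data/mirna.fasta \
    --associations data/associations.tsv --out ranked.tsv
smirnet evaluate-cv --sm-corpus data/sm.tsv --mirna-corpus data/mirna.fasta \
    --associations data/associations.tsv --seed 1 --out cv.tsv
```

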