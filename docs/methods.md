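# Methods

This note documents the models, conventions, and numerical choices behind
`smirnet`, and what the synthetic benchmarks do and do not demonstrate.

## Sequence autoencoders

Each entity type (miRNA sequence, compound SMILES) gets its own
character-level seq2seq autoencoder; the two models never share a
vocabulary. The implementation is pure numpy with manual
backpropagation through time and the Adam optimiser, which keeps training
bitwise reproducible from `(corpus, random_state)` — a property the test
suite asserts — at the corpus sizes this package targets.

Architecture:

- **Encoder**: single-layer LSTM over the one-hot input. State updates are
  masked past each string's end, so the final state is the state at the
  last real character regardless of padding.
- **Latent**: the encoder's final hidden and cell states are concatenated
  and linearly projected to the latent dimension (64 or 128 by
  convention; other values are accepted).
- **Decoder**: single-layer LSTM initialised by a tanh-squashed linear map
  of the latent vector. Its input at every step is the previous
  character's one-hot concatenated with the latent vector. Conditioning
  the decoder on the latent at every step, not only through the initial
  state, is a deliberate choice: with init-only conditioning the
  teacher-forced decoder can minimise the loss as a pure character-level
  language model of the training corpus and ignore the latent entirely,
  in which case reconstruction from the encoding collapses (we observed
  exact-match 0.0 with all inputs decoding to one string). Per-step
  conditioning restores the intended information path
  string → latent → string.
- **Loss**: per-character cross-entropy over the target sequence plus an
  end-of-sequence symbol, with pad positions masked.
- **Training**: teacher forcing (the true previous character is fed to
  the decoder); evaluation and the reconstruction report use greedy
  free-running decoding, so the reported accuracy measures what the
  latent vector alone supports.

Vocabularies consist of the domain alphabet plus three reserved symbols
(pad, start, end) appended last. The miRNA alphabet is fixed to
{A, C, G, T, N, −} with maximum length 30; FASTA input is uppercased,
U→T, and other letters map to the wildcard N. The SMILES alphabet is
derived from the observed corpus characters (SMILES text is
case-significant and kept verbatim) with maximum length 50. Over-length
strings are rejected during training but truncated with a warning at
encoding time, so every entity in a prediction dataset receives a vector.

Defaults (all exposed in `SequenceAutoencoder` / `PipelineConfig`):
hidden units 64 in the pipeline (128 in the standalone estimator),
learning rate 1e-2, batch size 128, 150 epochs for the pipeline's
desk-scale corpora. These were chosen for corpora of tens to hundreds of
short strings; larger corpora would warrant fewer epochs and larger
hidden states. Gradient correctness of the backward pass was verified
against central finite differences during development.

## Similarity

For latent vectors `x, y` of common dimension `D`,
`d(x, y) = sqrt(Σ_{d=1..D} (x_d − y_d)^2)`. Similarity is
`s_ij = 1 − d_ij / max_kl d_kl`, normalised per matrix (per entity type),
never pooled across the two sets. This guarantees entries in [0, 1], a
unit diagonal, symmetry, similarity 0 for the most distant pair, and
invariance to positive rescaling of the whole latent set. If all vectors
coincide the matrix is all ones by convention. The normaliser (max
pairwise distance within the matrix) is this package's committed
convention; per-row or fixed-constant normalisations would change
absolute values but not the induced ordering of pairs.

## Graphlet isomer catalogue

An interaction isomer is an equivalence class of (connected graph on
2–4 vertices, ordered pair of distinct distinguished vertices) under
isomorphisms fixing both distinguished vertices. Canonical forms fix the
pair at positions (0, 1) and minimise the sorted edge list over
permutations of the remaining vertices. Exhaustive enumeration gives
1 class on 2 nodes, 4 more on 3, 23 more on 4 — 28 in total, with a
source↔target involution fixing 12 classes (12 + 2×8 = 28) and 20 classes
after unordered collapse. Graphlets are induced subgraphs, the standard
convention.

Counting for a pair (a, b) sums over all vertex subsets of size 2–4
containing both whose induced subgraph is connected. The production
counter encodes each subset's induced edges as a bitmask and classifies
through precomputed 8- and 64-entry lookup tables, vectorised over
candidate third/fourth vertices; a literal subset-enumeration oracle
(networkx) is kept in the package and the two are asserted equal on
hundreds of random graphs.

## Similarity networks and ranking

Latent-space similarity matrices are dense, so they are binarized before
graphlet counting: edges are the off-diagonal pairs at or above the
(1 − retain_fraction) quantile of off-diagonal values, ties included.
The default retain_fraction of 0.05 keeps the networks sparse enough for
subset counting while preserving the nearest-neighbour structure; it is
config-exposed and recorded in the network's threshold rule.

The score of candidate pair (s, m) is

    score(s, m) = Σ_{m_t ∈ partners(s), m_t ≠ m} w·counts(m, m_t; G_miRNA)
                + Σ_{s_u ∈ partners(m), s_u ≠ s} w·counts(s, s_u; G_SM)

with uniform per-class weights w = 1 by default (overridable). The two
homogeneous-network terms mirror each other; a known pair never
contributes evidence to itself (the skipped terms correspond to zero
diagonals of the weighted interaction matrices, which makes the whole
score matrix two matrix products: `A·W_m^T + W_s·A`). Interaction
matrices depend only on the networks and weights, not on the association
split, so they are memoised and shared across cross-validation folds.
Rankings sort by score descending with deterministic lexicographic
tie-breaks.

## Evaluation protocol

Recall@top-p% counts held-out known associations with rank ≤ ceil(p·N),
N the ranking length; ceil is this package's committed rounding at
percentage boundaries. 5-fold cross-validation partitions the known
associations into seeded near-equal parts (remainder spread over the
first folds), trains on four parts, and ranks the full candidate universe
minus the training positives. Case studies withhold every association of
one entity and rank against the same full universe. Curves are averaged
unweighted over folds or entities. Two reference scorers calibrate the
machinery: a uniform-random scorer (mean recall@p must equal p; verified
within 3 standard errors over 50 seeded runs) and a truth-table oracle
(recall 1.0 everywhere).

## Synthetic data

The generator emulates the pipeline's three inputs at desk scale. miRNA
clusters are mutated copies (default 10% per-position substitution) of
random 18–24 nt ancestors; SMILES clusters are point-substituted variants
(among C/N/O/S) of ~20 real drug SMILES templates, all within the
50-character cap. Chemical validity is not enforced beyond template
plausibility because the method consumes characters, not molecules.
Associations are planted with probability density×boost between a seeded
random bijection of SM and miRNA clusters and density elsewhere
(defaults: 60+60 entities, 6 clusters, density 0.01, boost 20). With
boost 1 the association pattern is uniform — the negative control under
which the pipeline must not beat a random ranking.

What passing the planted-structure test shows: when string similarity is
informative about association structure, the latent encodings preserve
enough of it for the graphlet model to concentrate held-out associations
near the top of the ranking (observed ≈ 4× the random expectation at the
top 10%). What it does not show: performance on real corpora, where
sequence similarity is a weaker and biased proxy for shared biology,
miRNA families are unevenly sized, and the chemical space is far larger
than the template neighbourhoods used here.

## Numerical and degenerate-input conventions

- Seeds: every stochastic component (initialisation, batch shuffling,
  generation, fold partitions) flows from explicit integer seeds;
  identical seeds give bitwise-identical latent vectors and rankings.
- Divergent training (non-finite loss) raises an error naming the epoch.
- Identical latent sets produce an all-ones similarity matrix; a single
  entity cannot form a similarity matrix (error).
- Empty association sets give a zero score matrix, not an error, at
  predict time; reading an association file that yields zero valid pairs
  is an error.
- Untrained (0-epoch) models decode at chance level; this is asserted
  loosely (accuracy < 0.5 against ~1/9 chance) because greedy decoding
  from random weights is deterministic but arbitrary.

## Known limitations

- The numpy autoencoder is single-threaded and intended for desk-scale
  corpora (hundreds of short strings), not the hundreds of thousands of
  compounds a production run would use; the architecture itself is
  corpus-size-agnostic.
- Per-isomer weights are uniform by default; no weight learning is
  attempted.
- SMILES are treated strictly per character; multi-character tokens
  (Cl, Br) are two symbols, by design.
- The binarization quantile and the uniform weights are committed
  conventions of this package, exposed in config and provenance records.
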