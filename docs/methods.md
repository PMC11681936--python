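# Methods

## Problem and model

The package predicts whether a peptide binds a protein receptor, given each
chain's amino-acid sequence and 3-D structure, as a binary classification of
the pair.  Each chain is represented twice:

* **Sequence branch.**  A per-residue embedding matrix `X ∈ R^{L×d}`
  (d = 1024 at full scale, from a pretrained protein language model behind a
  pluggable provider interface) is zero-padded to a fixed length
  `L_max = 1200` and passed through three (convolution, max-pool) stages —
  kernel 3, stride 1, no padding; pooling step 3 with floor division — each
  with 128 channels.  At `L_max = 1200` the widths are
  1200 → 1198 → 399 → 397 → 132 → 130 → 43.  A final global max-pool over
  positions produces the local-sequence feature `F_s ∈ R^{128}`.  The last
  reduction is not forced by the stage arithmetic; a global max-pool is the
  standard TextCNN closer and adds no parameters, so that is what we use.
  ReLU follows each convolution.  Padded positions are convolved like real
  ones (pad-then-convolve); no masking is applied.

* **Structure branch.**  Residue–residue Euclidean distances between
  representative atoms (Cα by default) are thresholded at 10.0 Å into a
  binary contact map `A` with zero diagonal.  Self-loops enter only through
  the normalization `A_norm = D^{-1/2}(A+I)D^{-1/2}`, with `D` the degree
  matrix of `A+I`.  A single topology-adaptive graph convolution (TAGCN)
  layer applies degree-K polynomials in `A_norm` per output filter:
  `y_f = Σ_c (Σ_{k=0..K} g_{c,f,k} A_norm^k) x_c + b_f·1`, K = 3, followed
  by ReLU.  Because `A_norm^0 = I`, a node's output depends only on inputs
  within K hops (verified exactly on path graphs).  Per-channel max over
  nodes plus a 128-unit linear layer yields `F_g ∈ R^{128}`.  Graphs are
  built at native length; no padded nodes exist on this side.

* **Fusion and head.**  Per chain, `F = (1−w)·F_g + w·F_s` with
  `w ∈ [0, 1]` (default 0.5, configurable; the blend weight is a fixed
  scalar, not learned).  The two chains' fused vectors are concatenated
  (256-d) and classified by three linear layers (256 → 128 → 64 → 1); the
  first two are each followed by batch normalization and *then* ReLU, the
  last by a sigmoid.  Scores ≥ 0.5 are labelled interacting; the reported
  confidence pair is (score, 1 − score).  The hidden widths are our choice;
  only the three-layer BN-ReLU structure is architectural.

Training minimizes binary cross-entropy on the sigmoid output (the
canonical pairing with a single-logit sigmoid head) with Adam at learning
rate 0.001, batch size 32, 50 epochs by default.  No dropout is used;
batch normalization is the regularizer.  Both chains share encoder weights
(siamese), so a chain's feature vector does not depend on its role.

## Numerical substrate

No GPU deep-learning framework is used: all layers (1-D convolution via
sliding windows, max pooling with argmax backward, batch normalization with
running statistics, the TAGCN polynomial, Adam) run on NumPy under a small
reverse-mode autodiff engine (`peppinet.autodiff`), gradient-checked
against central finite differences.  Because the contact graph and the
input features are constants during training, the TAGCN propagation
`[X, A_norm X, …, A_norm^K X]` is precomputed once per chain and the layer
reduces to one dense product — algebraically identical to the literal
polynomial (unit-tested against it) but far cheaper per step.

Everything is seeded: parameter initialization, batch shuffling, fold
assignment, and all synthetic generators derive from explicit integer
seeds, so a fixed seed reproduces losses to 1e-6 and metrics exactly.

## Evaluation protocol

Seven statistics are computed from the 0.5-threshold confusion counts and
the score ranking: ACC, precision, recall, specificity, F1, AUC
(trapezoidal area under the ROC; equal to the Mann–Whitney rank statistic
with ties counted ½, which the tests verify against a from-scratch pairwise
oracle), and AUPRC (trapezoidal area under the recall–precision curve,
matching the geometric definition of the PR area rather than the
average-precision step sum).  Ratio metrics with zero denominators are
reported as 0 with a warning; single-class inputs leave AUC/AUPRC missing
with a warning, so cross-validation tables always render.

Five-fold cross-validation is stratified by label.  Two AUC aggregation
conventions coexist in the literature and can disagree; both are reported:
the **per-fold mean** (average the five fold AUCs) and the **pooled** AUC
(one ranking over the concatenated fold predictions).  A constructed
two-fold example (fold AUCs 1.0 and 0.5, mean 0.75, pooled 0.875) keeps
them distinguishable in the tests.

Negative pairs are drawn uniformly from the receptor × peptide grid minus
the listed positives, without replacement, deterministically per seed.

A **consistency filter** drops any chain whose parsed residue count (after
skipping residues missing the representative atom) differs from its
embedding's row count; pairs touching a dropped chain are excluded, with
the reason recorded in the preprocessing manifest.

## Synthetic data: what it emulates and what it does not

The fixture generator produces single-chain PDB files with one Cα per
residue at the physical 3.8 Å consecutive spacing in three geometries:
extended (contacts only |i−j| ≤ 2 at the 10 Å cutoff), ideal α-helix
(radius 2.3 Å, rise 1.5 Å, 100°/residue; contacts out to |i−j| ≈ 6, i.e. a
dense clique band), and a self-avoiding random walk.  The deterministic
synthetic embedder maps each letter to a seeded base vector plus a seeded
positional perturbation, rows unit-normalized.

Two planted interaction rules make the labels recoverable by construction:

* **Motif rule** — a chain "carries the motif" if embedding channel 0 is
  raised by +5 over a random 3-residue window; a pair interacts iff both
  members carry it.  Dataset defaults: 20 receptors (25–40 residues), 20
  peptides (8–15 residues), 200 balanced pairs, d = 16.
* **Geometry rule** — a pair interacts iff both members are helical;
  embeddings then carry no class signal.

Negatives are sampled outside the carrier × carrier grid so the rule holds
without label noise.  These fixtures validate mechanics — shapes, oracle
equivalences, optimization, protocol plumbing — not biology: real binding
depends on interface chemistry that no planted channel emulates, sequence
and structure signals are correlated rather than cleanly separable, and
real datasets are far larger and unbalanced in chain usage.  Passing these
tests shows the machinery is correct, not that the model's published-scale
accuracy transfers.

## Branch-dissociation design

Two deliberate choices make the "each branch carries its own signal" check
honest:

1. **Chain-disjoint splits.**  With pair-level splits a model can score
   well by memorizing each chain's embedding fingerprint and looking up its
   carrier status, because the same chains recur in train and test.  The
   dissociation experiment therefore holds out ~30 % of receptors and
   peptides entirely; only pairs with both members unseen are evaluated.

2. **Rule-neutral node features.**  At full scale the TAGCN node features
   are the language-model embedding itself, so a motif planted there would
   be visible to the graph branch too and "graph branch fails on the motif
   rule" could not be tested.  The node-feature source is therefore a
   config option: `embedding` (default, used by the headline recovery run),
   `onehot` amino-acid identity (used for the motif-rule dissociation: the
   graph branch sees structure and composition but no motif), and `degree`
   (used for the geometry-rule dissociation: pure topology; note that with
   constant features the *normalized* adjacency has near-unit row sums on
   near-regular graphs, which would erase the density signal — raw degree
   retains it).

With these controls the motif rule is solved only at w = 1 (sequence
branch) and the geometry rule only at w = 0 (graph branch).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `contact_threshold` | 10.0 Å | contact-map cutoff; not architecturally fixed, recorded in all metadata |
| `representative_atom` | CA | distance anchor per residue; CB optional |
| `embedding_dim` | 1024 | language-model width; tests use 16 |
| `max_length` | 1200 | pad/truncate length; over-length keeps the N-terminal part |
| `conv_channels` | 128 | TextCNN channels; must equal `feature_dim` (global max-pool emits one value per channel) |
| `tag_k` | 3 | polynomial order = hop radius of the graph filter |
| `fusion_weight` | 0.5 | structure/sequence blend; 0 and 1 isolate the branches |
| `learning_rate`, `batch_size`, `epochs` | 0.001, 32, 50 | Adam schedule; test profile uses 25 epochs |

## Problem sizes used by the reference experiments

The acceptance experiments run at: 200 pairs, d = 16, L_max = 60, 32
channels, 25 epochs, 5 folds, 4 CV repeats; oracle sweeps use 100 random
graphs (L ≤ 10, K ≤ 4) and 1000 random score vectors.  A full run of the
suite plus the acceptance script completes in a few minutes on one CPU.

## Known limitations

* The synthetic embedder is not a language model; results on it say nothing
  about embedding quality, only about the downstream architecture.
* The attention explainer is fitted post hoc to approximate the max-pool
  readout; it explains which residues dominate the pooled structural
  feature, not causal binding importance, and its mechanism (single-head
  additive attention) is one reasonable choice among several.
* Activation-map positions live in the conv-output coordinate; the helper
  maps position i to the residue window [i, i+2], but a sharp per-residue
  attribution is not defined by the architecture.
* mmCIF, multi-model NMR structures (beyond the first model), and
  non-standard residues richer than an X fallback are unsupported.
* BN uses batch statistics during training; with a trailing batch of size 1
  the variance estimate degenerates — the trainer keeps such batches, which
  is harmless at the default batch size but worth knowing at tiny n.
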