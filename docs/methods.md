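# Methods

This note documents the model implemented by `gradta`, the choices made
where the design was genuinely open, the synthetic benchmark the package
ships, and the limits of what desk-scale experiments can show.

## The prediction task

Drug–target affinity (DTA) prediction is regression: given a small
molecule (a SMILES string) and a protein (an amino-acid sequence), predict
a continuous binding strength such as pK_d = −log10(K_d / 10⁹) for K_d in
nM, or a KIBA score harmonising K_i, K_d and IC50. `gradta.transforms`
implements both transforms. The KIBA combination rule is the case split

    K_i′ = IC50 / (1 + L_i·IC50/K_i),   K_d′ = IC50 / (1 + L_d·IC50/K_d)

returning K_i′, K_d′, or their mean depending on which measurements are
present. The calibration weights L_i, L_d are dataset-specific and have no
defensible universal default, so they are required arguments; public
benchmark tables ship pre-computed KIBA scores anyway.

## Model

**Drug tower.** The molecule is a graph: atoms carry a 78-dimensional
binary feature vector (44-symbol element one-hot, degree 0–10, attached
hydrogens 0–10, implicit valence 0–10, aromaticity bit), bonds are
undirected edges stored as both directed arcs. Three sample-and-aggregate
layers update each atom state as

    h_N(v) = mean_{u∈N(v)} ReLU(W_pool h_u + b)
    h_v    = ReLU(W_u [h_v ‖ h_N(v)])

followed by batch normalisation and ReLU. A global max over atom states
and a ReLU-activated linear layer produce the drug representation Y_d ∈
R^D. Full-neighbourhood aggregation is the default: fixed-size neighbour
sampling with replacement is implemented (`sample_size`), but molecular
graphs have degree ≤ 4–6, so sampling only adds variance at this scale.

**Target tower.** Residues map to integers 1–25 over the alphabet
`ABCDEFGHIKLMNOPQRSTUVWXYZ` (A–Z without J: the 20 standard residues plus
the extended codes B, O, U, X, Z), with 0 reserved for padding; sequences
are truncated/padded to 1000 positions, keeping the prefix. An embedding
layer (padding embeds to the zero vector and stays frozen), two stacked
bidirectional GRU layers, and a soft-attention pool

    s(h_i) = U_a · tanh(W_a h_i),   α = softmax(s),   c = Σ_i α_i h_i

followed by a linear projection give the target representation Y_t ∈ R^D.
The gates are implemented in the bias-free form (z and r sigmoid gates, a
tanh candidate, update h_t = (1−z)⊙h_{t−1} + z⊙h̃_t); biases can be
enabled with `gru_bias` for parity with framework-default GRUs.

**Fusion and head.** A per-dimension attention network scores each of the
D dimensions of the pair, â = U_a ⊙ ReLU(W_a [Y_d ‖ Y_t]) with W_a: 2D→D,
softmaxes over dimensions, and forms V = α ⊙ (Y_d ⊙ Y_t). The prediction
head consumes [Y_d ‖ Y_t ‖ V] through two ReLU/dropout hidden layers
(defaults 1024/512, dropout 0.2) and a scalar linear output. Training
minimises mean squared error with Adam.

**Ablation variants.** `no_att` replaces the attention pool with a mean
over valid positions; `no_ann` feeds the plain concatenation [Y_d ‖ Y_t]
to the head and never builds V. Both are structural contracts only — on
synthetic data we make no claim about their relative accuracy.

## Numerical and design choices

- **Autodiff.** All neural components run on `gradta.autodiff`, a compact
  tape-based reverse-mode engine over float64 numpy arrays with exactly
  the operations the model needs (broadcasting arithmetic, matmul,
  constant-sparse matmul for neighbour averaging, segment max for graph
  readout, softmax, slicing/concat). Its gradients are validated against
  central finite differences both per-op and end-to-end through the whole
  model.
- **Both bond directions are stored** (edge index 2×2M rather than 2×M):
  mean aggregation needs the incoming neighbourhood of every atom of an
  undirected molecule.
- **Atom vocabulary**: the DeepChem-derived 44-symbol list (43 elements +
  a trailing "unknown" slot) conventional in molecular-graph DTA models;
  degree/H-count/valence values above 10 clip into the last bin so the
  featurizer is total. Valence means implicit valence.
- **Residue indices 1–25 with pad 0**: a 0-based residue mapping would
  collide with the padding symbol, so residues shift up by one.
- **Padding is masked, not processed**: recurrence steps and attention
  weights skip padded positions (a padded step would otherwise evolve the
  hidden state through its gates despite carrying no information). A
  sequence of length L costs O(L), not O(1000). The empty sequence is
  encoded as a single padding position so every input yields a finite
  vector.
- **Attention score width** defaults to the hidden dimension; the paper-
  style formulation fixes only that s(h_i) is scalar.
- **Initial hidden states** are zero in both directions; stacked BiGRU
  layers consume the concatenated states of the previous layer, and
  attention is applied once after the final layer.
- **Concordance index** uses the tie convention h = 1/0.5/0 for
  positive/zero/negative prediction differences, normalised by the number
  of ordered pairs with distinct true values; undefined (error) when all
  true values tie.
- **rm²** is r²·(1 − √(r² − r₀²)) with r² the intercept-fitted squared
  Pearson correlation and r₀² the coefficient of determination of the
  through-origin regression of observed on predicted (`symmetric=True`
  swaps the roles). A numerically negative radicand is clamped to zero
  with a warning. rm² ≤ r² always holds.
- **Cold-start splits** apply the 8:1:1 ratio to the constrained *entity*
  sets (largest-remainder rounding, sizes within 1 of exact); pair counts
  then follow entity degrees. In `cold_pair` both entity sets are
  partitioned independently and cross-partition pairs are discarded; the
  discarded fraction is recorded in the split metadata.
- **Weight initialisation** is uniform scaled by fan-in; every source of
  randomness (init, shuffling, dropout, sampling) derives from one seed,
  so runs are bit-reproducible.
- **Checkpoint selection** defaults to the final epoch; `select="best"`
  restores the best-validation-MSE weights instead.

## Synthetic benchmark

`gradta.synthetic` generates desk-scale datasets with a planted,
recoverable structure:

- **Drugs**: template-grammar SMILES — alkyl chains (1–8 carbons) with
  optional methyl/ethyl/hydroxyl/halogen branches, an optional benzene or
  pyridine ring with an optional substituent, and optional terminal
  substituents. All outputs parse with RDKit; the grammar has enough
  entropy that 200 draws stay under 10% duplicates.
- **Targets**: i.i.d. sequences over the 25-letter alphabet, lengths
  50–150 by default (short enough for fast recurrent encoding while still
  exercising variable-length batching; the generator accepts any range in
  [20, 1500]), with a "WWW" motif planted 0–5 times and the realised count
  re-scanned after insertion.
- **Affinities**: a density-0.5 sample of the 50×30 pair grid labelled
  with w_drug·(aromatic atom count) + w_target·(motif count) + N(0,
  noise_sd²), defaults w = 0.5 and noise_sd = 0.1. Both signal components
  are expressible by the two towers (aromaticity is an atom-feature bit;
  the motif is a subsequence pattern), so held-out ranking accuracy
  measures genuine two-tower signal recovery. The noiseless signal is
  stored alongside for recovery tests.

What the synthetic data does *not* emulate: real affinity distributions
(e.g. the strong floor concentration of kinase-panel pK_d values),
realistic medicinal chemistry, long multi-domain proteins, or
structure–activity cliffs. Passing the recovery suite shows the
architecture, training loop and metrics work end-to-end — it does not
certify benchmark-level accuracy on public DTA datasets, which requires
full-scale (GPU, hundreds of epochs) training out of scope here.

## Study sizes and profiles

The default model configuration follows the tuned grid of the reference
setting (128-wide embeddings/hidden states/representations, 2 recurrent
layers, 3 graph layers, dropout 0.2, Adam at 2×10⁻⁴, 600 epochs, batch
128/256 for the small/large profiles). Desk-scale experiments and the
test suite use the `tiny` profiles chosen as this package's own
fast-iteration setting: all widths 32, one recurrent layer, a 64/32 head,
no dropout (capacity checks want the bare model), Adam at 10⁻³, batch
256. The overfit-capacity check trains 300 epochs on 200 noiseless pairs
(train MSE < 0.05 expected; observed orders of magnitude lower); the
recovery check trains 60 epochs on the default 750-pair spec and reaches
held-out CI well above 0.8, while zeroed signal weights give CI ≈ 0.5.

## Known limitations

- Pure-numpy training is single-threaded and desk-scale; hundreds of
  epochs on 10⁵-pair benchmarks are out of reach (and out of scope).
- Batch normalisation uses batch statistics in training and running
  averages (momentum 0.1) in inference, so train-time and eval-time
  outputs differ slightly, as in any batch-normalised model.
- `cold_pair` discards cross-partition pairs, so its effective dataset is
  smaller than the 8:1:1 entity ratio suggests (~34% of a complete grid
  is dropped at 8:1:1).
- The KIBA combination requires IC50; record combinations without it are
  rejected rather than approximated.
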