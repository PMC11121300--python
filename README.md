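# gradta

Drug–target binding-affinity (DTA) regression for computational drug
discovery. Given a small molecule as a SMILES string and a protein as an
amino-acid sequence, `gradta` predicts a continuous binding strength —
pK_d = −log10(K_d/10⁹) for K_d in nM, or a KIBA score — with a
three-module neural architecture:

- a **GraphSAGE drug encoder**: atoms become nodes with 78-dim binary
  features; each of 3 layers aggregates neighbourhoods by
  h_N(v) = mean_{u∈N(v)} ReLU(W_pool h_u + b) and updates
  h_v = ReLU(W_u [h_v ‖ h_N(v)]), with global max pooling as readout;
- a **soft-attention BiGRU target encoder**: residues embed as integers
  1–25 (length fixed to 1000 with zero padding), two stacked
  bidirectional gated recurrent layers produce per-position states h_i,
  and attention α_i = softmax(U_a·tanh(W_a h_i)) pools them;
- an **attention fusion network (ANN)**: per-dimension weights
  α = softmax(U_a ⊙ ReLU(W_a [Y_d ‖ Y_t])) form the pair representation
  V = α ⊙ (Y_d ⊙ Y_t), and a two-hidden-layer head on [Y_d ‖ Y_t ‖ V]
  predicts the affinity, trained with MSE loss and Adam.

The package also provides the standard DTA evaluation metrics (MSE,
concordance index, rm², Spearman), seeded random / 5-fold / cold-start
splitting protocols (`cold_drug`, `cold_target`, `cold_pair`), a
synthetic benchmark generator with a planted recoverable signal, ablation
variants (`no_att`, `no_ann`), and a CLI. The neural stack runs on a
compact reverse-mode autodiff engine over numpy (`gradta.autodiff`)
validated by finite differences, so everything trains reproducibly on a
plain CPU. It is aimed at method developers who want a transparent,
fully-tested reference implementation at desk scale rather than a
GPU benchmark harness.

## Worked example

Generate a synthetic dataset whose affinities are a planted linear
function of drug aromaticity and a protein sequence motif, train a small
model, and evaluate on the held-out split:

```python
from gradta import (SyntheticSpec, generate_dataset, random_split, train,
                    evaluate, ModelConfig, TrainConfig)

spec = SyntheticSpec(n_drugs=30, n_targets=15, density=0.7, seed=5)
data = generate_dataset(spec)
split = random_split(data.dataset, ratio=(5, 1), seed=5)
result = train(data.dataset, split,
               ModelConfig.tiny(), TrainConfig.tiny(epochs=40, seed=5))
report = evaluate(result.model, data.dataset, split.test)
print(f"pairs: {len(data.dataset)}  train: {len(split.train)}  test: {len(split.test)}")
print(f"final train MSE: {result.final_train_loss:.4f}")
print(f"test MSE: {report.mse:.4f}  CI: {report.ci:.4f}  "
      f"rm2: {report.rm2:.4f}  Spearman: {report.spearman:.4f}")
```

Output:

```
pairs: 315  train: 263  test: 52
final train MSE: 0.2795
test MSE: 0.4542  CI: 0.8122  rm2: 0.7608  Spearman: 0.8276
```

A concordance index (CI) of 0.81 means that for 81% of held-out pair
comparisons with different true affinities, the model ranks them in the
right order (0.5 is chance); rm² above 0.5 is the usual bar for
acceptable external predictivity in QSAR work. Here the model has
recovered most of the planted structure from 263 training pairs in under
half a minute on one CPU core.

The same workflow is available from the shell:

```bash
gradta synth --spec spec.yaml --seed 1 --out data/
gradta split --data data/ --scenario cold_target --seed 1 --out split.json
gradta train --data data/ --split split.json --seed 1 --out model.npz
gradta eval  --data data/ --split split.json --model model.npz
gradta rank  --model model.npz --target target.fasta --candidates drugs.smi
```

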