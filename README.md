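# batchfree

Reference-free batch-effect correction for multi-batch single-cell
RNA-seq data, performed **in the original gene-expression space**, plus the
**positive merge divergence (PMD)** metric for scoring integration quality
on datasets with batch-specific cell types.

## Who this is for

Analysts integrating M ≥ 2 scRNA-seq batches who (a) do not want results to
depend on choosing a reference batch or a merge ordering — a reference-based
method must be run up to M! + M times to cover all choices — and (b) need
the corrected output to remain interpretable log-expression over the same
genes, so marker detection and differential expression work directly on the
integrated matrix.

## Method in brief

Each batch j gets a scalar critic W_j estimating, via the
Kantorovich–Rubinstein dual, the Wasserstein-1 distance between batch j and
the mixture of the other batches:

    L_w^j = E_{x~P_j}[W_j(C(x,j))] − (1/(M−1)) Σ_{i≠j} E_{x~P_i}[W_j(C(x,i))]

A corrector C(x, b) = max(x + a_b ⊙ tanh-stack(x) + b_b, 0) — a shared
fully-connected stack with a per-batch affine layer (BS-Norm) and a
non-negativity clamp — minimizes Σ_j L_w^j while the critics maximize their
estimates under a soft 1-Lipschitz gradient penalty
λ E_s[(‖∇_s W_j(s)‖₂ − 1)²] on interpolated samples (λ = 10).  The summed
objective weights batches by f(i,j) = 1 if i=j else −1/(M−1); each row of f
sums to zero, so no batch is privileged.

PMD evaluates the result in two stages: the **positive rate** (fraction of
cells whose k-NN neighbourhood is dominated by their own cell type — low
values flag overcorrection) and the **merge divergence** (base-2
Jensen–Shannon divergence between a positive cell's neighbourhood batch
proportions and its cell type's global batch proportions — high values flag
residual batch effect; batch-specific cell types score 0 by construction).

The networks are small fixed-architecture perceptrons implemented directly
in numpy, with analytically derived backpropagation (including the double
backprop the gradient penalty requires), verified against finite
differences in the test suite.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from batchfree import preset, simulate, TrainConfig, train, apply_full, pmd
from batchfree.pmd import pca_reduce

# three synthetic batches, three shared cell types, constant log-space
# shifts of 0 / +0.5 / -0.35 as the batch effect
collection, truth = simulate(preset("shift_only", seed=0))

before = pmd(pca_reduce(collection.stacked(), 10),
             truth.cell_types, truth.batch_labels)
print(f"before: positive rate {before.positive_rate:.3f}, "
      f"median divergence {before.median_divergence:.4f}")

cfg = TrainConfig(pretrain_steps=100, main_steps=400, minibatch_size=64,
                  lr_corrector=1e-3, lr_critic=1e-3,
                  corrector_hidden=(128, 128), critic_hidden=(128, 32), seed=1)
corrector, critics, log = train(collection, cfg)
corrected = apply_full(collection, corrector)

after = pmd(pca_reduce(corrected.stacked(), 10),
            truth.cell_types, truth.batch_labels)
print(f"after:  positive rate {after.positive_rate:.3f}, "
      f"median divergence {after.median_divergence:.4f}")
```

Output:

```
before: positive rate 1.000, median divergence 0.4934
after:  positive rate 1.000, median divergence 0.2419
```

Before correction every cell's neighbourhood is a single batch (median
divergence 0.49 ≈ JS between a one-hot and the global batch mix); after
correction the median divergence halves while the positive rate stays at
1.0 — batches mix without cell types being smeared together.  Longer
training drives the divergence further down (the acceptance script's run
of the same experiment at a different simulation seed reaches ≈ 0.02).

## Command line

```sh
batchfree simulate shift_only --out sim/          # synthetic fixture
batchfree integrate config.json --seed 1          # preprocess + correct
batchfree evaluate embedding.csv metadata.tsv     # PMD report
batchfree count-refs 5 --mode both                # -> 125
```

`integrate` takes a JSON/YAML config listing the per-batch matrices
(CSV/TSV, or Matrix Market with genes.tsv/barcodes.tsv sidecars),
optional preprocessing switches (gene/cell filters, library-size
normalization, top-2000 HVG selection), and training settings; it writes
corrected per-batch matrices, a checkpoint, a training log and a
provenance record sufficient to re-run the identical integration.

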