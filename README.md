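# otperturb

Prediction of single-cell transcriptional responses to perturbations from
**unpaired** control/stimulated scRNA-seq data, with generalization to
held-out cell types.

The pipeline combines three pieces:

1. an **MMD-regularized variational autoencoder** (pure-NumPy MLP with
   analytic backprop; RBF-kernel MMD or closed-form KL as the ablation arm)
   that embeds cells into a latent space,
2. **exact optimal transport** (earth mover's distance under uniform
   marginals) aligning the latent control and stimulated training
   populations, from which each training control cell receives a
   barycentric *perturbation delta*, and
3. a **top-k cosine-similarity transfer**: each unseen control cell
   aggregates the deltas of its most similar training control cells, shifts
   its latent, and decodes back to gene space.

Optional precomputed embeddings (per-cell matrix and/or per-perturbation
vector, e.g. from external language models) can be injected into the
encoder input through learned zero-initialized linear projections; no
language model is run by this package.

Evaluation follows the gene-level protocol: squared Pearson correlation of
gene-wise means/variances between predicted and observed stimulated cells
(with Fisher-z 95% confidence intervals) and the overlap of top-100
differentially expressed genes (Wilcoxon rank-sum vs the shared control
group). A negative-binomial simulator with known ground truth (shared,
type-scaled response program; low-rank per-cell heterogeneity) makes the
whole pipeline testable offline.

## CLI

```bash
# simulate a synthetic unpaired perturbation dataset (+ truth sidecar)
otperturb simulate --types 3 --cells 400 --genes 1000 --response 100 --seed 0 --out sim.h5ad

# filter / normalize / select HVGs
otperturb preprocess sim.h5ad --out prep.h5ad --min-genes 500 --min-cells 5 --hvg 6998

# train the MMD-VAE
otperturb train prep.h5ad --out model.npz --alpha 1.0 --bandwidth 1.0 \
    --latent 100 --epochs 100 --regularizer mmd --seed 0

# predict the stimulated state of one held-out type's control cells
otperturb predict prep.h5ad --model model.npz --holdout type0 --top-k 30 --out predicted.h5ad

# score predictions against observed stimulated ground truth
otperturb evaluate --predicted predicted.h5ad --stimulated stim.h5ad --control ctrl.h5ad

# one sub-experiment per cell type + aggregate row
otperturb run-all sim.h5ad --outdir runs/ --seed 0

# data-scale sensitivity sweep
otperturb sweep sim.h5ad --outdir sweep/ --fractions 0.1,0.3,0.5,0.7,1.0
```

Input H5AD files (or TSV/CSV with a cell-id index column) need per-cell
`cell_type` and `condition` columns; condition levels are mapped onto
{control, stimulated} via `--control-level/--stimulated-level` equivalents
in the API (`read_dataset`). Embedding files are delimited text: cell
embeddings with a cell-id first column, perturbation embedding as a single
row vector (`otperturb train ... --cell-embed emb.tsv --perturb-embed p.tsv`).

## Package layout

```
src/otperturb/
  data_io.py      data model (ExpressionDataset, RunConfig), H5AD/TSV I/O, seeding
  preprocess.py   filtering, log-normalization, HVG selection, holdout split, subsampling
  embeddings.py   embedding file loading and encoder-input injection
  mmdvae.py       RBF kernel, MMD^2 / KL regularizers, VAE + training loop
  transport.py    latent populations, cost matrix, exact EMD, delta matrix
  predictor.py    cosine top-k weights, delta aggregation, shift-and-decode
  evaluation.py   gene stats, R^2 + Fisher-z CI, top-DEG overlap, reports
  simulate.py     negative-binomial ground-truth simulator
  cli.py          orchestration (run_subexperiment / run_all) and click CLI
```
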