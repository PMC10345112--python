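# mendelrank

Three-class Mendelian variant pathogenicity classification and
zygosity-aware causal-variant prioritization.

## Who this is for

Exome analysis of a patient with a suspected monogenic disease leaves
hundreds of rare protein-altering variants, of which at most one (or one
compound-heterozygous pair) explains the phenotype. Generic pathogenicity
scores rank "damaging" variants but ignore the Mendelian structure of the
problem: a variant that is pathogenic only in the homozygous state should
not top the list when seen heterozygous. `mendelrank` is a toolkit for
researchers building or studying Mendelian variant-prioritization
pipelines: it classifies each variant into *benign*,
*dominant-pathogenic*, or *recessive-pathogenic* and turns those
probabilities into a ranked per-sample candidate list that respects
zygosity, compound heterozygosity, inheritance information, and
gene–phenotype association scores.

## The model

Each variant is encoded as a pair of 201-position context windows (the
reference and the altered protein, centered on the edited residue) with 51
channels per position: one-hot residue identity, a 30-feature per-residue
conservation profile, and a presence flag that implements "logical
deletion" of removed residues. Two transformer-based architectures score
the windows together with 12 quantile-normalized structured annotations
(allele frequency, gene constraint, regional constraint, …):

* **Architecture 1** runs both windows through a weight-shared transformer
  stack and classifies `[d_alt, d_alt − d_ref, structured]` from the
  center tokens;
* **Architecture 2** replaces the reference branch with a bidirectional
  LSTM summary of a protein-language-model embedding of the altered
  sequence (a pluggable contract, with a deterministic mock embedder
  included).

Member softmax outputs p = (p_benign, p_dom, p_rec), which always sum to 1,
are averaged across the ensemble. Training uses class-weighted
cross-entropy under a one-cycle SGD schedule (lr 0.001 → 0.1 → 4·10⁻⁷,
momentum 0.95 → 0.85 → 0.95). Within a sample, heterozygous calls are
ranked by p_dom, homozygous calls by p_rec, and each pair of heterozygous
calls on a gene (on different haplotypes) by the harmonic mean
2ab/(a+b) of their recessive scores; phenotype fusion averages the result
with a per-gene score in [0, 1]. The models run on a small, fully tested
numpy autodiff engine — no deep-learning framework is required.

See `docs/methods.md` for the complete description, assumptions, and
limitations.

## Worked example

Everything below runs on synthetic data generated by the package itself —
no downloads. Desk-scale settings (context radius 8, a two-member ensemble
with model dimension 32) keep the whole example under a minute on one CPU.

```bash
mendelrank simulate --seed 7 --out-dir fixture \
    --n-genes 12 --n-variants-per-class 40 --signal-strength 3.0 \
    --cohort-size 4

cat > cfg.yaml <<'YAML'
model: {model_dim: 32, n_layers: 2, n_heads: 4, ffn_dim: 64,
        head_dims: [64, 32, 3], window_len: 17, embed_dim: 32}
train: {batch_size: 128, epochs: 20}
ensemble:
  - {architecture: 1}
  - {architecture: 2, class_weights: [1, 2, 3]}
YAML

mendelrank train --config cfg.yaml --proteins fixture/proteins.fasta \
    --profiles fixture/profiles.tsv --variants fixture/variants.tsv \
    --radius 8 --seed 1 --out model.npz
mendelrank predict --checkpoint model.npz --proteins fixture/proteins.fasta \
    --profiles fixture/profiles.tsv --variants fixture/variants.tsv \
    --radius 8 --out preds.tsv
mendelrank spikein --cohort fixture/cohort.tsv --scores preds.tsv \
    --out cases.tsv
mendelrank evaluate --scores preds.tsv --cases cases.tsv --out metrics.json
```

The prediction table holds one row per variant with the three class
probabilities (each row sums to 1):

```
variant_id  gene      label   p_benign  p_dominant  p_recessive
var00000    GENE0001  benign  0.7445    0.1217      0.1338
var00001    GENE0006  benign  0.8469    0.0851      0.0680
```

and `metrics.json` reports, for this run:

```
macro_auprc  0.9998   # mean one-vs-rest area under the PR curve
topk_auc     1.0      # normalized area of the spike-in solve curve
solved_at_1  1.0      # fraction of 320 spiked-in cases ranked first
solved_at_5  1.0
```

`macro_auprc` close to 1 says the ensemble recovered the planted class
structure almost perfectly (the synthetic signal here is strong by
design); `solved_at_1 = 1.0` says every spiked-in pathogenic variant
outranked all background candidates in every control sample. With
`--signal-strength 0` the same pipeline drops to the chance baseline
(macro auPRC ≈ mean class prevalence, 1/3 for balanced classes).

Other commands: `mendelrank rank` (per-sample ranked candidates, with
`--inheritance` and `--pheno` fusion), `cv-split` (gene-disjoint
stratified folds), `param-count`, `encode`.

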