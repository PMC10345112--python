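# Methods

## The problem

In a patient with a suspected monogenic (Mendelian) disease, exome
sequencing typically yields hundreds of rare protein-altering variants, of
which at most one or one pair is causal. `mendelrank` implements a
three-class view of this problem: every protein-altering variant is scored
with probabilities *(benign, dominant-pathogenic, recessive-pathogenic)*
that sum to one, and those probabilities are then resolved against the
observed zygosity to rank candidate diagnoses within a sample. The package
covers the full chain — input encoding, the two classifier architectures and
their ensemble, class-weighted training, curation rules for building
labeled datasets from ClinVar/OMIM-style tables, the zygosity-aware ranking
engine with inheritance and phenotype fusion, a spike-in benchmarking
harness, and seeded synthetic-data generators that emulate every input.

## Variant encoding

A variant is presented to the model as a pair of **context windows** — the
reference and the altered protein context — centered on the edited residue.
Each window spans the center ±100 residues (201 positions by default; the
radius is a parameter and the fast test-suite configuration uses ±8) with 51
channels per position: 20 one-hot residue identity, 30 per-residue
conservation-profile features (the shape of an alignment-profile HMM row),
and a presence flag. Positions outside the protein or window are all-zero
and masked out of attention; the mask is *defined* as "column entirely
zero".

Edit semantics (window-local, all checked against an independent
record-list oracle over thousands of fuzzed edits):

* **missense** — the center's one-hot changes; conservation untouched.
* **deletion** — the deleted span's presence flag drops to 0; identity and
  conservation are retained ("logical deletion"), so the model still sees
  what was removed and how conserved it was. Logically deleted positions
  remain attended.
* **insertion** — inserted residues appear after the center with zero
  conservation and presence 1; the tail is trimmed to keep the span fixed;
  everything through the center is bit-identical to the reference.
* **frameshift** — downstream identities are overwritten by the novel
  peptide while the original conservation stays in place; positions past
  the novel stop are logically deleted.
* **stop gain** — the center and everything downstream is logically
  deleted; conservation unchanged.
* **stop loss** — encoded as an insertion of the read-through peptide after
  the final residue. This is a design choice: read-through extension is
  structurally an insertion at the former stop, and no established
  convention exists for it in this input format.
* The unknown residue `X` has all-zero identity but presence 1, so it is
  not confused with a gap.

Residue-level annotation tracks (CCR, pext, GERP-like scores) collapse to a
single value per edit: maximum over the affected span for multi-residue
edits, maximum of the two flanking residues for insertions, the residue's
own value otherwise.

## Structured features

Twelve per-variant numeric annotations accompany the windows: population
allele frequency and homozygote count; gene-constraint summaries (pLI,
pRec, pNull, missense Z, LoF Z); pext; CCR; GDI; RVIS; and a
nucleotide-conservation score (GERP-like). Missing values are encoded as
NaN and imputed to the training-set median, then all features pass through
a quantile transform fit on the training split only (empirical CDF to
[0, 1], out-of-range values clamped to 0/1). The transform is
`sklearn.preprocessing.QuantileTransformer` behind a thin wrapper that owns
imputation and serialization.

## Architectures

**Architecture 1 (contrastive).** Both windows are projected from 51
channels to the model dimension, given sinusoidal positional encodings, and
run through a single weight-shared stack of post-norm transformer encoder
layers (default: 6 layers, 16 heads, feed-forward width 256, model
dimension 64). The center token of each output is reduced to a 64-d branch
embedding; the classifier head consumes `[d_alt, d_alt − d_ref, s]`, where
`s` is a 64-d embedding of the normalized structured features. Weight
sharing is by construction — the same stack object processes both windows —
so the difference branch is exactly zero when the windows are identical.

**Architecture 2 (language-model).** The reference window is dropped.
Instead, the altered sequence is embedded per-residue by a pluggable
protein-language-model contract and summarized to 64 dimensions by a
bidirectional LSTM's final states; the altered window goes through the same
transformer-plus-center-token branch; the head consumes
`[lstm_summary, center_token, s]`.

Both heads are Dense(512) → Dense(64) → Dense(3) with ReLU on the hidden
layers and a softmax output, so predictions always lie on the 3-simplex.
Branch dense layers use ReLU; the framework the original construction was
expressed in defaults to linear dense activations, and the choice is not
observable through any of the package's contracts — it is recorded here as
a design decision.

The **ensemble** averages member softmax outputs arithmetically. The
default composition is eight members: three of architecture 1 with class
weights (1,1,1), (1,2,7), (1,2,7) and five of architecture 2 with (1,1,1)
×3, (1,2,3), (1,2,7).

**Embedder contract.** Production-scale protein language models are out of
scope; the `EmbedderContract` requires only a deterministic per-residue
embedding of configurable width. `HashEmbedder` is the package's synthetic
stand-in: each residue letter maps to a fixed random vector derived from a
seeded generator, so identical sequences embed identically across
processes. `ZeroEmbedder` supports branch-isolation tests.

**Ablation.** Input ablation is an inference-time operation on the encoded
batch: the named input ("reference", "alternate", "embedding",
"structured") is zeroed, and for sequence inputs the attention mask is
forced to all-attend. The mask override is needed because our mask is
derived from the values; without it a fully ablated model would still leak
per-variant window-shape information, whereas the intended behavior is
that ablating every input yields a constant function of the variant.

**Autodiff engine.** No deep-learning framework is a dependency; the
models run on a compact reverse-mode automatic-differentiation engine
(`mendelrank.nn.autodiff`) written on numpy. It implements exactly the
primitives the architectures need, in float64, and every primitive's
gradient is unit-tested against central finite differences. This keeps the
dependency surface to the scientific-Python stack and makes training fully
deterministic given a seed.

## Training

Stochastic gradient descent with momentum (v ← m·v − lr·g; w ← w + v),
batch size 128, 20 epochs. The learning rate and momentum follow a
one-cycle policy: linear warm-up from 0.001 to 0.1 over the first 30% of
steps with momentum annealing 0.95 → 0.85, then linear decay to 4×10⁻⁷
with momentum returning to 0.95. The schedule is continuous and attains its
peak exactly once. A `literal_text_mode` flag provides the variant in which
phase-2 momentum restarts at 0.95 and anneals down to 0.85 again (the two
descriptions circulate; the default follows the canonical one-cycle
construction). Class weights multiply each example's cross-entropy, e.g.
weight 7 on the recessive class makes each recessive variant contribute
seven times a benign variant's loss, trading benign precision for
pathogenic recall. The best epoch is selected by validation categorical
cross-entropy. Training is bit-reproducible given (seed, config, data);
member *i* of an ensemble trains with seed `1000·seed + i`.

## Dataset curation rules

Pure functions over ClinVar-style and OMIM-style tables:

* **Labeling** — benign/likely-benign assertions → benign; variants seen
  homozygous in population data in ≥ 2 individuals → benign regardless of
  assertion (the threshold is a config knob); pathogenic/likely-pathogenic
  assertions resolve to dominant or recessive through the cited phenotype's
  single inheritance mode. Dual-mode phenotypes, flagged phenotypes
  (nondisease/susceptibility/putative), gene-mismatched citations,
  sub-threshold review status, non-germline records and uninformative
  significance are rejected, each with exactly one machine-readable reason
  code.
* **Splice filter** — variants within 2 bp of a canonical splice site drop.
* **Transcript selection** — canonical transcript wins; otherwise highest
  median expression; across genes, prefer the gene whose canonical
  transcript is hit, then the highest-expressed; ties break on the
  lexicographically smallest transcript id, making selection a total
  function.
* **Known/novel split** — a test gene is "known" iff the training set holds
  ≥ 1 pathogenic variant on it; benign-only training genes are novel.
* **Gene folds** — k gene-disjoint folds stratified into
  has-pathogenic vs benign-only strata, balanced within one gene per
  stratum, seeded shuffle. With 1,930 pathogenic and 13,219 benign-only
  genes and k = 5 this yields 386 and 2,643–2,644 genes per fold
  respectively.

## Prioritization

Within a sample, quality-passed calls (depth ≥ 20; heterozygous calls need
alt reads ≥ ½ · ref reads; population and cohort frequency ≤ 1%; all
thresholds configurable; an optional blacklist drops variants seen in
unaffected samples) become candidates:

* each heterozygous call → a dominant candidate scored by its dominant
  probability;
* each homozygous call → a recessive candidate scored by its recessive
  probability;
* each pair of heterozygous calls on one gene with different haplotype
  groups → a compound-heterozygote candidate scored by the harmonic mean of
  the two recessive probabilities. HM(r, r) = r, so a pair of equal scores
  ranks exactly like a homozygote; HM(0, 0) is defined as its limit, 0.
  Candidates and their member singletons coexist in the ranking (the
  alternative — suppressing singletons that appear in a pair — changes
  ranks of non-causal candidates only and is not taken).

Candidates can be filtered to the observed inheritance pattern (dominant
keeps het candidates; recessive keeps homozygous and compound-het
candidates; unknown keeps all) and fused with a per-gene phenotype score by
arithmetic mean. Phenotype scores come either from a gene→score table or
from a GADO-style Z matrix: known gene–term associations are clamped to
Z = 3, a unit-scale logistic squashes Z to (0, 1) — so the matrix centers
on 0.5 and a known association scores logistic(3) ≈ 0.9526 — and a
phenotype's score is the mean over its (at most five, seed-sampled) HPO
terms. Genes absent from any table score 0.5, which makes fusion with an
uninformative table rank-preserving. Ranking is descending by score with a
lexicographic tie-break, hence a deterministic total order.

## Evaluation

* **Spike-in**: a scored pathogenic variant is inserted into a control
  sample's candidate list (dominant variants as heterozygous-dominant,
  recessive variants as homozygotes — equivalent to an equal-scored
  compound-het pair) and its 1-based rank recorded; N variants × M samples
  give N·M cases.
* **Solve curve / top-k AUC**: cumulative fraction of cases solved within
  rank k for k = 1..20; normalized trapezoidal area on x = (k−1)/19, so 1
  means every case solved on the first guess and 0 means none within 20.
  Unranked cases contribute 0 at every k.
* **Precision/recall/F1** from counts, with the F1 form
  TP/(TP + (FP+FN)/2); zero denominators return 0 with a warning.
* **One-vs-rest ROC/PR areas** per class via scikit-learn; the macro auPRC
  baseline for uninformative scores is the mean class prevalence.
* **Calibration**: per class, predicted probability is binned (default 10
  bins), and empirical class frequency is regressed on mean bin confidence;
  a calibrated model has slope ≈ 1. Empty bins are skipped with a warning;
  a constant predictor occupies one bin and is skipped rather than fit.
* **Bootstrap comparison**: two methods' auPRCs are compared by
  bootstrap-resampling the evaluation set (default 1000 iterations) and
  applying a one-sided Mann–Whitney U test to the per-resample auPRC
  samples.

## Synthetic data

The generators produce every input the toolkit consumes — proteins with
conservation profiles, three-class variant tables with structured
annotations, control cohorts with realistic depth/allele-read values, and
phenotype score matrices — as deterministic functions of a seed. They are
built for *analytic control of separability*, not realism:
`signal_strength` scales every channel of class information
simultaneously — the per-class mean shifts of the structured features, the
allele-frequency separation, the conserved-motif profile bump, the
probability that pathogenic variants sit on the motif, and the probability
that pathogenic variants concentrate on role-matched genes. At
`signal_strength = 0` the three classes are exchangeable in every respect
(features, placement, gene identity), which is what makes the null
condition a genuine chance-level control; during development two subtle
departures from this (allele-frequency ranges and gene-role hosting that
stayed informative at signal 0) were found and fixed precisely because the
null drifted off prevalence.

What the generators do **not** emulate: linkage between variants, realistic
site-frequency spectra, correlated constraint scores within genes, indel
length distributions, sequencing artifacts, or phenotype-term ontology
structure. Passing tests on this data therefore demonstrate that the
machinery is correct and can learn planted class structure — not that the
desk-scale models would approach published accuracy on real clinical data,
which additionally requires production-scale training data, real
conservation profiles, and a real protein language model.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
package's default experimental conditions: context radius 8 (window 17),
proteins of 40–80 residues, 24 genes, 80 variants per class for training, a
two-member ensemble (one of each architecture) with model dimension 32, 2
layers, 4 heads, feed-forward width 64, and an independent held-out-gene
test draw of 200 variants per class so the auPRC estimator concentrates.
Float64 throughout; attention masking uses an additive −10⁹ (whose softmax
weight underflows to exactly zero, making masked-position invariance exact
to machine precision); cross-entropy is computed from log-softmax, with an
epsilon floor only in the scalar convenience form. Degenerate inputs have
defined behavior: empty batches predict an empty table, empty calibration
bins are skipped, zero-count metrics return 0 with a warning, and NaN
training loss aborts with a diagnostic rather than propagating.

## Known limitations

* The mock embedder carries no biology; architecture 2's language-model
  branch is exercised structurally, not semantically.
* Printed production parameter counts are not asserted: they depend on
  implementation details (bias and normalization parameters, the structured
  branch's input width) that the package does not pin; `param-count`
  reports this implementation's counts.
* Nucleotide-level annotation (codon → protein edit), splice/noncoding/
  structural variants, and X-chromosome-specific handling are out of scope.
* The ranking treats each sample independently; cohort-level recurrence
  enters only through the frequency filter and the optional blacklist.
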