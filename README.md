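# operonmerge

Enhance in-silico bacterial operon predictions using diel (24-h cycle)
expression time series. Many published operon predictions underestimate
true operon extent; since co-operonic genes share expression signatures,
two adjacent predicted operons with highly similar diel profiles likely
belong to one transcription unit. `operonmerge`:

1. reads a gene annotation (GFF3 or TSV), a log2-expression matrix over
   timepoints, and prior operon predictions;
2. mean-centers each profile and calls a gene *diel* when its log2 range
   reaches 1 (a ≥2× abundance change);
3. measures profile dissimilarity with the **ABLIM** distance — the exact
   area between the piecewise-linear interpolants of two series, computed
   segment-by-segment (trapezoids, and two triangles at sign crossings);
4. represents each gene group by a 4-vector — minimum, mean, sample
   standard deviation, and maximum of its pairwise ABLIM distances
   (merge candidates use cross-prior pairs only);
5. builds positive instances (priors with ≥1 diel gene) and negative
   instances (consecutive-gene windows mixing both strands), evaluates a
   classifier registry by stratified 5-fold cross-validation, trains the
   most accurate one on all instances — the registry includes a native
   **logistic model tree** (information-gain splits with ridge logistic
   leaves), logistic regression, a decision tree, Gaussian naive Bayes
   and k-NN;
6. recommends merging each adjacent, same-strand, same-contig,
   no-gap prior pair with ≥1 diel gene per prior whose classifier score
   exceeds 0.5 (the score is not a calibrated probability).

A synthetic generator (`operonmerge.synthetic`) produces genomes with
planted operons, sinusoidal diel transcriptomes, and deliberately split
prior predictions with known ground truth, so the entire pipeline is
testable offline.

## Quick start

```sh
# make a synthetic dataset with known ground truth
operonmerge simulate --out-dir fixture --seed 7 --n-genes 300 \
    --noise-sd 0.1 --phase-jitter 0.5

# run the full pipeline: featurize, cross-validate, train, classify
operonmerge pipeline \
    --annotation fixture/annotation.tsv \
    --expression fixture/expression.tsv \
    --priors fixture/priors.tsv \
    --out-dir run --seed 7

column -t run/merge_report.tsv | head
```

`run/` will contain `merge_report.tsv` (scored candidate pairs, sorted by
descending score, `merged` true/false), `cv_report.tsv` (per-classifier
fold accuracies), `features.tsv` (training instances) and `model.json`
(the persisted model, reusable via `operonmerge classify --model ...`).
Subcommands `train`, `classify` and `distances` expose the individual
stages. Options may come from a YAML config file (`--config run.yaml`);
command-line flags override it. Outputs carry a header with tool version,
config hash and seed, and reruns are byte-identical.

To merge chains of three or more priors, re-run `classify` on the merged
output; a single pass classifies adjacent pairs only.

## Input formats

- **annotation**: GFF3 (gene/CDS features with `ID` attributes), or a TSV
  with header `gene_id contig strand start end`. Internally coordinates
  are 0-based half-open; gene adjacency is rank by ascending start within
  each contig.
- **expression**: TSV, first column gene id, remaining column headers
  numeric hours. `NA` cells mark missing values; such profiles are
  excluded from diel calls and distances.
- **priors**: `operon_list` dialect (one operon per line, whitespace
  separated gene ids) or `gene_pairs` (two-column adjacent-gene pairs,
  chained into maximal runs).

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-derives the headline properties from scratch
(ABLIM vs. a fine-quadrature oracle; noiseless and noisy recovery of
planted split pairs) and logs them to stderr. There are no numeric
acceptance targets — the originating study's counts depend on external
downloads — so the JSON report is an empty object.
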