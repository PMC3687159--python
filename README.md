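# cascann

Modeling of three-layer transcriptional regulatory cascades
(upper-layer TFs → module-regulating TFs → target gene) with structurally
constrained feed-forward networks.

Given a gene-expression matrix, a TF-binding p-value matrix, a directed
regulator→gene edge list, a binding-site table and a protein-interaction
pair list, the pipeline:

1. **discovers gene modules** — sets of co-bound (p ≤ 0.001), co-expressed
   genes with their direct regulators (GRAM-style heuristic with a 20%
   missingness filter and a minimum core of 3 genes);
2. **builds three-layer cascades** — each module's regulators form the
   middle layer and their own upstream regulators (edges kept only with a
   binding site within 1000 bp upstream) form the upper layer; modules with
   no known, or more than 15, upstream regulators are excluded;
3. **trains masked networks** — one logistic hidden node per middle TF, a
   linear output, input→hidden weights pinned to zero wherever there is no
   regulatory edge; Levenberg–Marquardt training with validation-based
   early stopping; performance is the Pearson correlation on held-out
   experiments over repeated random 50/25/25 splits, with success declared
   above mean CC 0.70;
4. **searches time-delayed (asynchronous) regulation** — every per-TF
   backward shift assignment in {0..n−1}^N is enumerated, evaluated on a
   per-condition shifted design, and the optimum reported;
5. **augments single-regulator modules with heterodimer partners** —
   constitutively expressed (≥95% of points within twofold) interaction
   partners with binding data become a second middle node, with a
   degree-matched random-replacement control;
6. **assesses significance** against a shuffled-target null (the observed
   mean CC must exceed the maximum shuffled mean CC).

A synthetic-data module generates complete input bundles from planted
ground truth (weights, delays, dimer interactions, constitutive TFs,
Gaussian noise) so the entire pipeline is testable without external data.

## CLI

Generate a synthetic bundle and run the pipeline on it:

```sh
cascann simulate --fixture planted_module --seed 1 --outdir bundle/
cat > config.yaml <<EOF
expression: bundle/expression.tsv
metadata: bundle/metadata.tsv
binding: bundle/binding.tsv
edges: bundle/edges.tsv
sites: bundle/sites.tsv
ppi: bundle/ppi.tsv
outdir: out
seed: 1
eval: {n_reps: 20}
EOF
cascann run --config config.yaml --stages modules,cascades,synchronous,asynchronous,null,report
```

Stages communicate through serialized intermediates in `outdir`
(`modules.tsv`, `cascades.jsonl`, `eval_synchronous.tsv`,
`shifts_summary.tsv`, `dimers.tsv`, `null.tsv`, `summary.tsv`, ...), are
resumable, and are bit-reproducible under a fixed global seed.
Individual stage subcommands (`cascann modules`, `cascann shifts`, ...)
are also available; see `cascann --help`.

## Package layout

| module | role |
| --- | --- |
| `cascann.data_io` | TSV readers/writers, replicate averaging, category partition |
| `cascann.module_finder` | GRAM-style module discovery |
| `cascann.cascade_builder` | promoter-window edge filter, three-layer cascade assembly |
| `cascann.cascade_ann` | masked network, analytic-Jacobian Levenberg–Marquardt |
| `cascann.eval_harness` | repeated-split evaluation, Pearson scoring, shuffle null |
| `cascann.timeshift` | shift enumeration, shifted designs, delay search |
| `cascann.heterodimer` | constitutive test, partner proposal, augmentation, controls |
| `cascann.synthetic` | planted-ground-truth bundle generator and canonical fixtures |
| `cascann.pipeline` / `cascann.cli` | stage orchestration, reports, CLI |
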