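# gextemplates

Tissue classification by nearest gene-expression template.

The toolkit derives a compact signature of highly variable genes from
multiple training expression compendia, averages training samples into one
expected-expression template per tissue, and classifies new samples by
maximal Pearson (or Spearman) correlation to the templates
(1-nearest-neighbor over templates). The same correlation score drives two
downstream analyses: regression of template correlation on time for
developmental series, and deviation scoring of cancer-like or engineered
samples against their expected tissue.

## What's inside

| module | role |
| --- | --- |
| `expression_io` | TSV and GEO series-matrix parsing, log2-scale harmonization, gene alignment across platforms, sample metadata |
| `signature_selection` | per-dataset coefficient-of-variation ranking, top-fraction selection, cross-dataset intersection, correlation-clustering redundancy removal |
| `template_builder` | per-tissue templates via equal-weight two-level averaging (or pooled), template similarity diagnostics |
| `template_predictor` | per-sample and batch nearest-template prediction, deviation scores, prediction reports |
| `evaluation` | per-tissue accuracy tables, 2x2 sensitivity/specificity, mean +/- sd correlation summaries |
| `trajectory_analysis` | OLS of correlation on time with slope t-tests, per-template slope ranking |
| `synthetic_data` | seeded simulators: multi-dataset compendia with planted signature genes and batch effects, developmental trajectories, cancer-like perturbations |
| `cli` | `gext` command chaining the stages |

## CLI

```bash
# simulate a training compendium (three datasets, planted signature)
gext simulate --out-dir data/ --n-tissues 24 --n-genes 5000 \
    --n-signature 60 --n-datasets 3 --seed 1

# derive a signature (top 2.5% CV per dataset, intersect, de-redundify)
gext select --matrix data/dataset0.tsv --matrix data/dataset1.tsv \
    --matrix data/dataset2.tsv --metadata data/metadata.tsv \
    --q 0.025 --corr-cut 0.85 --out signature.txt

# build per-tissue templates
gext build --matrix data/dataset0.tsv --matrix data/dataset1.tsv \
    --matrix data/dataset2.tsv --metadata data/metadata.tsv \
    --signature signature.txt --out templates.tsv

# classify new samples and score the result
gext predict --matrix new_samples.tsv --templates templates.tsv \
    --method pearson --out predictions.tsv
gext evaluate --predictions predictions.tsv --metadata new_metadata.tsv \
    --out accuracy.tsv

# 2x2 confusion arithmetic
gext evaluate --tp 24 --fp 5 --fn 1 --tn 40

# developmental time course: slope of correlation vs. time per template
gext trajectory --matrix timecourse.tsv --metadata timecourse_meta.tsv \
    --templates templates.tsv --out slopes.tsv
```

Options can also come from a YAML config (`gext --config conf.yaml select
...`, one section per subcommand; flags win). Every command writes a
`*.manifest.json` run manifest recording its parameters and the package
version. Matrices on linear (MAS5-like) scale are detected heuristically
(`--log2-mode auto`) and log2-transformed before analysis.

## File formats

- **Expression matrix TSV**: header `gene_id<TAB>sample1<TAB>...`, one gene
  per row. The GEO series-matrix dialect (`!`-prefixed metadata, table
  between the begin/end marker lines, optionally quoted cells) is read with
  `--format series_matrix`.
- **Metadata TSV**: columns `sample_id`, `tissue`, `dataset_id`, optional
  `time`, `condition`.
- **Signature**: one gene id per line; `#` comment lines carry provenance.
- **Templates TSV**: first column `tissue`, one column per signature gene,
  plus a JSON provenance sidecar.

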