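# orthoclass

Cross-species tumor-type classification on one-to-one ortholog expression
features.

The package harmonizes bulk RNA-seq expression matrices from two species onto
a shared feature axis of protein-coding one-to-one orthologs, trains
multiclass tumor-type classifiers (a 1D convolutional network plus random
forest and logistic regression baselines) on one species, and evaluates
transfer to the other with support-weighted precision/recall/F1. Supporting
analyses include single-sample gene-set enrichment (ssGSEA) with permutation
FDR, variable-gene selection, and gene-set intersection/coverage tables. A
synthetic two-species cohort generator with planted class signatures, species
batch shifts and negative-binomial noise provides ground truth for every
stage, including a deliberately weak-separation "grade" class pair.

## Layout

| module | role |
| --- | --- |
| `orthoclass.datamodel` | expression-matrix / annotation / label / GMT types and I/O |
| `orthoclass.simulate` | synthetic two-species cohorts, ortholog tables, XOR cohort |
| `orthoclass.orthology` | ortholog-table parsing, 1:1 + protein-coding filters, feature space, projection |
| `orthoclass.normalize` | counts → TPM, FPKM-UQ → TPM, TPM → log10 |
| `orthoclass.classify` | dataset assembly, 80/10/10 split, CNN/RF/LR training, predict, save/load |
| `orthoclass.nn` | the NumPy 1D-CNN (conv/pool/dense, Adam, early stopping) |
| `orthoclass.evaluate` | confusion matrices, weighted metrics, cross-species evaluation |
| `orthoclass.ssgsea` | ssGSEA scores, gene-sampling permutation p-values, BH FDR, selection rule |
| `orthoclass.genesets` | top variable genes, upset/Venn intersection counts, coverage fractions |
| `orthoclass.pipeline` / `orthoclass.cli` | end-to-end synthetic replay and the CLI |

## CLI

```sh
orthoclass simulate --seed 1 --out sim/                 # synthetic bundle
orthoclass orthology --orthologs sim/orthologs.tsv \
    --annotation sim/annotation_A.tsv --out fs.tsv      # feature space
orthoclass normalize --expr sim/counts_A.tsv --from counts --to log10_tpm \
    --annotation sim/annotation_A.tsv --out logA.tsv
orthoclass train --model cnn --features fs.tsv --expr logA.tsv \
    --labels sim/labels_A.tsv --seed 1 --out model/
orthoclass evaluate --model model/ --expr logB.tsv \
    --labels sim/labels_B.tsv --features fs.tsv --out report.json
orthoclass ssgsea --expr logA.tsv --gmt sets.gmt --nperm 1000 --seed 1 \
    --out ssgsea.tsv
orthoclass run-all --seed 1 --out pipeline_out/         # full synthetic replay
```

`run-all` also accepts a TOML config (`--config config.toml`) with
`[simulation]`, `[split]`, `[model]` and `[ssgsea]` sections.

Expression files are genes × samples TSV with `#unit=` / `#species=` header
comments; units are explicit metadata (`counts`, `fpkm_uq`, `tpm`,
`log10_tpm`) and only the normalize module converts between them.

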