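# glandkit

Analysis toolkit for beetle defensive (stink) gland studies: sequencing-library
metrics, a ten-group non-overlapping gland-specificity subtraction classifier,
GC-MS volatile quantification with calibration curves and equivalents, RNAi
phenotype-strength scoring, and phenol-oxidase kinetics — plus seeded synthetic
generators for every input format so each stage is testable with known ground
truth.

## Modules

| module | purpose |
| --- | --- |
| `glandkit.synthetic` | seeded generators: expression libraries with planted subtraction-group genes, GC-MS runs, kinetic plates, phenotype datasets |
| `glandkit.expression` | coverage/depth, library metrics, log2 fold changes, abundance sets, the ten-group subtraction classification |
| `glandkit.volatiles` | calibration fitting, retention-index peak matching, area→mass quantification (with surrogate equivalents), molar totals, compositional statistics |
| `glandkit.phenotype` | phenotype strengths 1–6 from per-beetle relative chemical levels; cohort summaries |
| `glandkit.immunity` | blank correction, linear-phase Vmax, square-root-transformed group statistics, inhibition-zone rank-sum comparisons |
| `glandkit.stats` | shared exact/asymptotic rank-sum test and Welch t-test |
| `glandkit.datasets` | transcribed published reference tables (raw sequencing totals, per-gland volatile means, per-group gene counts) |

## CLI

The `glandkit` entry point has one subcommand per stage:

```sh
glandkit simulate --config cfg.yaml --out outdir/   # library.tsv + ground_truth.json
glandkit metrics summary.csv                        # derived library metrics
glandkit subtract library.tsv --cutoff 6 --pseudocount 1 --out groups/
glandkit quantify peaks.csv --standards standards.csv --out masses.csv
glandkit classify levels.csv --out strengths.tsv
glandkit po plate.csv --window-points 10
glandkit zones zones.csv
```

All inputs are delimited text. A library is a TSV with columns `gene_id`,
`transcript_length`, `s1_ctl`, `s2_tthr`, `s3_mthr`, `s4_fthr`, `s5_mabd`,
`s6_fabd`; kinetic plates are CSV with `well, group, minute, od490, is_blank`;
peak tables are CSV with `sample_id, area` plus `compound` or
`retention_index`.

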