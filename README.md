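# mirmeth

Analysis pipeline linking loss of DNMT3b-regulating microRNAs to the
aberrant DNA hypermethylation (hypermethylator) phenotype in breast cancer,
built around qPCR panel data:

1. **Comparative-Ct quantification** (`mirmeth.quant`) — triplicate Ct
   values are collapsed, normalized to a reference assay (RNU66 for miRs,
   β-actin for genes) and to the mean ΔCt of normal-mammoplasty calibrator
   samples, giving fold changes `2^−ΔΔCt`.
2. **Median-binarized scoring** (`mirmeth.scoring`) — each sample × assay
   fold change is called *low* when strictly below the per-assay median of
   the configured population; the gene-expression score (0–9) and miR score
   (0–9) count low calls. A tumor is classified *hypermethylator* when its
   gene score is ≥ 7; its miR expression group is *low* when the miR score
   is ≥ 6.
3. **Diagnostic thresholds** (`mirmeth.diagnostics`) — for each miR, a
   cutpoint maximizing correct assignments (CA) is found among basal-like
   tumors (low expression ⇒ predicted hypermethylator), with
   sensitivity/specificity/PPV/NPV/CA reported as half-up-rounded percents.
4. **Association statistics** (`mirmeth.association`) — per-subtype
   mean ± SEM summaries, two-tailed unpaired t-tests (Student or Welch),
   and Pearson correlations (score vs score, all 36 miR pairs,
   pairwise-complete).
5. **Synthetic cohorts** (`mirmeth.simulate`) — a generator reproducing the
   study design (36 + 13 + 5 + 16 tumors and 18 normals) with a latent
   hypermethylator state that jointly suppresses the gene panel and most
   regulatory miRs, inverted to noisy triplicate Ct values so the whole
   pipeline can be exercised against known ground truth.

I/O (`mirmeth.cohort`, `mirmeth.report`) covers long-format Ct CSV/TSV
tables (`sample_id, assay_id, replicate, ct`, with `undetermined` cells
treated as missing replicates), sample metadata (`sample_id, subtype,
role`), YAML run configuration, and a checksummed output manifest.

## CLI

```sh
# generate a synthetic cohort (ct_table.csv, metadata.csv, truth.json)
mirmeth simulate --seed 7 --out cohort/

# individual stages
mirmeth quantify  --ct-table cohort/ct_table.csv --metadata cohort/metadata.csv --out matrix.tsv
mirmeth score     --ct-table cohort/ct_table.csv --metadata cohort/metadata.csv --out scores.tsv
mirmeth diagnose  --ct-table cohort/ct_table.csv --metadata cohort/metadata.csv --out diagnostics.json
mirmeth associate --ct-table cohort/ct_table.csv --metadata cohort/metadata.csv --out associations.json

# everything at once: expression_matrix.tsv, scores.tsv, report.json, manifest.json
mirmeth run-all --ct-table cohort/ct_table.csv --metadata cohort/metadata.csv --out report/
```

All subcommands accept `--config config.yaml` (keys mirror
`mirmeth.RunConfig`: panels, references, cutoffs, median population,
rounding rule, t-test variant) and `--seed`.

## Conventions and edge rules

- Ties at the median are called *normal* ("below" is read strictly);
  missing calls count as *normal* and are logged.
- Calibration uses the arithmetic mean ΔCt over calibrator samples, so the
  calibrator group's geometric-mean fold change is exactly 1.
- Percent rounding is half-up by default (10/16 → 63, 11/16 → 69);
  `banker` rounding is available in the config.
- Threshold optimization maximizes unrounded CA; ties prefer higher
  sensitivity, then the larger threshold, and the tie-set size is reported.
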