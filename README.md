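# mstrans

Morphometric-similarity (MS) network analysis linked to regional gene
transcription, as a tested, reusable pipeline:

1. **morphometry** — ComBat-style empirical-Bayes batch harmonization of
   per-subject regional MRI features (7 features x N regions), within-subject
   z-scoring, per-subject MS matrices (pairwise Pearson correlation of
   regional feature vectors) and regional MS (signed weighted degree).
2. **case_control** — per-region OLS group contrasts with age/sex/education
   covariates, Benjamini-Hochberg FDR across regions, subset mean MS, partial
   correlations with behaviour, demographics tables (pooled t / chi-squared).
3. **transcription** — first-component PLS of the regional T map on a
   regions x genes expression matrix (closed-form weights for a univariate
   response), region-resampled bootstrap standard errors, gene Z scores, and
   positive/negative gene sets at a Bonferroni-derived threshold (4.72 for a
   20,737-gene family at overall alpha 0.05).
4. **enrichment** — moderated two-group differential expression
   (empirical-Bayes variance shrinkage), hypergeometric/Fisher overlap tests
   with Bonferroni correction, permutation-calibrated cell-type specificity
   (pSI), and generic over-representation against GMT collections.
5. **simulate** — synthetic cohorts, expression matrices, DE datasets and
   cell-type profiles with planted, recoverable ground truth, so the whole
   pipeline is testable end to end without any external data.
6. **cli_io / pipeline** — TSV readers/writers, YAML configs, a manifest-
   producing orchestrator, and a `mstrans` command-line interface.

## Quick start

Run the full pipeline on synthetic data (simulate -> harmonize -> z-score ->
MS -> regional MS -> T map -> PLS -> gene sets -> enrichment):

```sh
mstrans run --config configs/demo.yaml --seed 7 --out run_demo
mstrans report --run-dir run_demo
```

Every output is TSV; `manifest.json` records the config, its hash, the seed
and per-stage outputs. The same stages are available as subcommands
(`simulate`, `harmonize`, `ms`, `tmap`, `pls`, `enrich`, `celltype`) for
running on your own files; region and gene identifiers are always matched by
id/symbol, never by order.

Library use mirrors the CLI:

```python
from mstrans import morphometry, case_control, transcription
from mstrans.simulate import SimulationConfig, generate_cohort

table, truth = generate_cohort(SimulationConfig(n_per_group=50, seed=7))
regional = morphometry.regional_ms_table(morphometry.zscore_features(table))
tmap = case_control.tmap(regional, table.meta)
```

## Notes

- All randomness flows from a single master seed through named substreams;
  identical config + seed reproduces outputs byte-for-byte.
- `--threads` is accepted for interface compatibility; results are
  independent of thread count.
- Out of scope: raw MRI processing (FreeSurfer/FSL), AHBA probe compilation,
  GO database retrieval, NIfTI/GIFTI ingestion.
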