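# prognet

Network-module prognostic gene-signature discovery and evaluation for
expression cohorts with survival follow-up, plus a synthetic-cohort
generator with planted ground truth so the whole pipeline is testable
end-to-end without any external downloads.

The discovery chain: sample QC over housekeeping probes → variance-based
probe filtering → univariate Cox selection of outcome-associated probes →
mapping onto a functional-interaction network → edge weighting by absolute
Pearson correlation of expression → Markov clustering (MCL) → module
filtering (≥ 8 genes, mean pairwise correlation ≥ 0.25). Discovered modules
are scored per sample as the difference between the geometric means of the
log2 expression of poor- and good-outcome genes; the combination index is
the mean of the module indices. Evaluation covers continuous and
median-split Cox hazard ratios, Kaplan-Meier curves, log-rank tests and
10-year survival estimates. A 3-marker (JUN/CD8/CD20) Allred composite
score for tissue-microarray data is included, as are nearest-centroid
molecular subtyping and hypergeometric over-representation analysis.

Survival statistics (Cox partial-likelihood Newton-Raphson with
Efron/Breslow ties, Kaplan-Meier, log-rank, score test) are implemented in
`prognet.survstats` from first principles; the test suite cross-validates
them against `lifelines` and the analytic score-test/log-rank identity.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (statistical
calibration, MCL correctness, planted-module recovery, exhaustive oracles).

## CLI

All functionality is exposed through the `prognet` command:

```bash
# generate a synthetic cohort (expression, survival, network, truth)
prognet simulate --config cfg.yaml --out cohort/

# QC + variance filtering
prognet preprocess --expr e.tsv --housekeeping hk.txt --top-k 2500 --out top.tsv

# discover outcome-associated network modules
prognet modules --expr e.tsv --surv s.tsv --network net.tsv --out modules.json

# per-sample module indices, combination index, risk groups
prognet score --expr e.tsv --modules modules.json --out scores.tsv

# survival evaluation (Cox HR, log-rank, 10-year survival)
prognet evaluate --scores scores.tsv --surv s.tsv --out report.json

# pathway over-representation, subtyping, IHC composite scoring
prognet enrich --modules modules.json --gmt sets.gmt --out enrichment.json
prognet subtype --expr e.tsv --centroids centroids.tsv --out labels.tsv
prognet ihc --cores cores.tsv --out ihc.tsv

# end-to-end synthetic run: simulate -> discover -> score -> evaluate
prognet run --config run.yaml --out out/
```

Exit codes: 0 ok, 2 input/format error, 3 convergence/numerical error.

A minimal `simulate` config:

```yaml
n_genes: 500
n_samples: 300
planted_modules:
  - {size: 12, direction: poor, beta: 0.8}
  - {size: 12, direction: good, beta: 0.8}
within_module_corr: 0.6
module_edge_prob: 0.9
background_edge_prob: 0.002
censoring_rate: 0.25
n_housekeeping: 10
seed: 1
```

## Layout

- `prognet.synthio` — synthetic cohorts: planted co-expressed prognostic
  modules, planted-partition networks, proportional-hazards survival,
  Allred IHC fixtures.
- `prognet.dataio` — core types and TSV/GCT/SIF/GMT/JSON readers-writers.
- `prognet.preprocess` — housekeeping QC, median/batch centering,
  variance filtering.
- `prognet.subtype` — nearest-centroid subtype assignment (Spearman).
- `prognet.survstats` — Cox, Kaplan-Meier, log-rank, p-value scores.
- `prognet.netmodules` — probe selection, network mapping, edge weighting,
  MCL, module filtering, enrichment.
- `prognet.scoring` — module/combination indices, median split.
- `prognet.evaluate` — survival evaluation and signature comparison.
- `prognet.ihc` — Allred scoring and the 3-marker composite.
- `prognet.pipeline` / `prognet.cli` — orchestration and the CLI.
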