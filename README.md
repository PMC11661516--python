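# ctcpa

Longitudinal plasma copy-number analysis for ctDNA monitoring from
shallow-WGS bin counts:

- **genome_io** — 0-based half-open bin grids (BED), bin-count matrices
  (TSV), SEG-style segment tables and clinical metadata, all with
  deterministic writers.
- **synthetic_cohort** — negative-binomial cfDNA simulator with GC bias and
  an admixture copy-ratio model (`ratio = 1 + tf·(cn−2)/2`); generates
  healthy panels and longitudinal patient series with ground truth.
- **normalization** — depth normalization, LOESS GC correction and per-bin
  z-scores against a panel of normals, with leave-one-out and bootstrap
  panel variants.
- **segmentation** — circular binary segmentation with permutation testing,
  gain/loss state calls (|seg z| > cutoff) and per-bin majority consensus
  across bootstrap panels.
- **scoring** — CPA (length-weighted mean |segment z|) and ctCPA
  (Σ Zᵢ·Dᵢ / n over the patient's cumulative CNV profile with
  gain/loss-conflict exclusion), healthy-maximum detection thresholds and
  strict-inequality positivity.
- **monitoring_outcomes** — score timelines, relative-change threshold
  scans, molecular lead time before radiographic progression,
  Kaplan–Meier/log-rank survival comparison and delegated Cox hazard
  ratios.

Sex-chromosome bins are excluded from all scoring.

## CLI

```sh
ctcpa simulate --config cohort.yaml --seed 7 --out sim/
ctcpa io validate --bins sim/bins.bed --counts sim/counts.tsv
ctcpa normalize --bins sim/bins.bed --counts sim/counts.tsv \
    --panel healthy_ids.txt --loo --out norm.tsv
ctcpa segment --bins sim/bins.bed --norm norm.tsv --alpha 0.01 \
    --nperm 1000 --min-bins 3 --zcall 3 --seed 7 --out segs.seg
ctcpa score --bins sim/bins.bed --counts sim/counts.tsv \
    --panel healthy_ids.txt --mode eq1 --bootstrap 100 --seed 7 \
    --out scores.tsv
ctcpa monitor --scores scores.tsv --clinical sim/clinical.tsv --out timelines.tsv
ctcpa survival --scores scores.tsv --clinical sim/clinical.tsv \
    --timepoint END --out survival.json
```

`cohort.yaml` holds `CohortConfig` fields (`n_healthy`, `n_patients`,
`mean_count`, `dispersion`, `gc_coeffs`, `pd_lag_months`). Every stage is
deterministic for a fixed seed: reruns produce byte-identical files.

`scores.tsv` columns: sample, patient, timepoint, months, cpa,
cpa_threshold, cpa_positive, ctcpa, ctcpa_threshold, ctcpa_positive,
n_segments, horizon. ctCPA scores use cumulative profiles built only up to
the sample's own timepoint; thresholds are per-patient maxima across the
healthy donors evaluated on the same profile.

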