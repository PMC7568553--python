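# diaharmony

Toolkit for QC-gated, multi-site HRMS1-DIA label-free quantification
studies: it models the acquisition method's isolation-window scheme and
cycle timing, reads/writes precursor reports in the Spectronaut-export TSV
dialect, generates synthetic multi-laboratory studies with known mixture
ground truth, scores system-suitability QC with chromatographic vs
mass-spectrometric failure triage, rolls peptides up to protein-level
quantities (geometric-median pairwise-ratio mode for two-sample designs and
summed-intensity mode for tissue cohorts), and benchmarks quantitative
performance against theoretical mixture ratios.

## Layout

| module | what it does |
| --- | --- |
| `diaharmony.dia_method` | isolation-window tiling, MS1/MS2 cycle timing, points-per-peak arithmetic |
| `diaharmony.report_io` | precursor-report TSV dialect, run manifests, study designs |
| `diaharmony.synthetic_data` | multi-lab study simulator, failure injection, tissue cohorts |
| `diaharmony.qc_suite` | the six system-suitability metrics, acceptance evaluation, triage, gating timecourse |
| `diaharmony.rollup` | q-filter, shared-peptide removal, charge selection, combination counting, pairwise-ratio and sum roll-ups |
| `diaharmony.evaluation` | deviation from theory, inter-day CV, completeness/co-quantification, Spearman, RSD summaries |

Full-scale defaults (window scheme m/z 400–1210 / 15 Da / 18 scans per
subcycle, cycle times 1.7 s / 5.2 s, mixture compositions, QC acceptance
criteria) live in `src/diaharmony/data/default_config.yaml`; any subset can
be overridden by a user YAML/JSON config.

## CLI

```bash
diaharmony method describe                      # isolation-window table (TSV)
diaharmony simulate --config study.yaml --out study/ --labs L1,L2 --days 1,3,5,7
diaharmony qc --manifest study/manifest.tsv --out qc_report.tsv --json-out gating.json
diaharmony rollup --manifest study/manifest.tsv --mode pairwise --out proteins.tsv
diaharmony evaluate --proteins proteins.tsv --out summary/
```

`simulate` writes a manifest, one report TSV per injection, and the ground
truth table. `qc` emits one row per (lab, day) with all six metrics,
per-metric pass flags, and the triage verdict. `rollup --mode pairwise`
reports, per analysis group and protein group, the peptide count,
inter-sample combination count, the retained flag (≥ 8 combinations), and
the A/B ratio; `--mode sum` reports summed abundances with the ≥ 3
observation rule. `evaluate` writes per-organism deviation medians,
inter-day CVs, per-lab completeness, co-quantification counts, and the
every-day core set.

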