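# laphase

Phasic left-atrial (LA) quantitation and diagnostic evaluation toolkit.

The package simulates catheterization-style cohorts with ground-truth phasic
LA volumes linked to LV end-diastolic pressure (LVEDP), builds
physiologically shaped time-volume curves at cine temporal resolution,
projects them into noisy biplane planimetry measurements, extracts the
phasic volume triple (LAV_max, LAV_ac, LAV_min) by two comparable routes,
derives the three emptying-fraction indices, and evaluates every index
against dichotomized LVEDP with ROC/cutoff, group-comparison and agreement
statistics.

## Components

| module | purpose |
| --- | --- |
| `laphase.synthetic` | cohort sampling (group-calibrated, LVEDP-truncated), curve generation, biplane projection with observer noise |
| `laphase.volumetry` | biplane area-length volume `0.85*A1*A2/L`, BSA indexing, total/passive/contractile emptying fractions |
| `laphase.phase_extraction` | single-phase (valve-event frames) and multi-phase (curve landmark) triple extraction, atrial-contraction onset detection |
| `laphase.diagnostics` | LVEDP dichotomy at 12 mmHg, Mann-Whitney AUC with DeLong inference, Youden-optimal cutoffs, Student's t / Pearson / Fisher exact |
| `laphase.agreement` | Bland-Altman method comparison, Lin's concordance, observer replicate studies |
| `laphase.cli` / `laphase.pipeline` | CSV schema validation, YAML config, end-to-end deterministic study pipeline |

## CLI

```sh
# full study bundle (cohort/curves/biplane/phasic CSVs, table2/table3,
# agreement table, plain-text summary) — byte-identical under a fixed seed
laphase pipeline --n 41 --prevalence 0.341 --seed 1 --out study/

# or stage by stage
laphase simulate --n 41 --seed 1 --out study/
laphase quantify --method both --curves study/curves.csv \
    --events study/cohort.csv --out study/phasic.csv
laphase evaluate --phasic study/phasic.csv --cohort study/cohort.csv \
    --threshold 12 --out study/
laphase agree --a phasic_single.csv --b phasic_multi.csv --out agreement.csv
```

Every command accepts `--config cfg.yaml` (keys mirror `PipelineConfig` /
`CohortConfig`) and exits 0 on success, 2 on validation failure, 1 on
runtime error.

## Notes

- Fractions are stored in [0, 1] internally and rendered as percentages
  only in reports.
- Emptying fractions are computed on BSA-indexed volumes; the ratios are
  identical on absolute volumes (BSA cancels).
- No multiple-testing correction is applied in the diagnostic tables.
- Records whose extracted triple violates `lav_min <= lav_ac <= lav_max`
  (possible under heavy measurement noise) are flagged, logged, counted and
  excluded from downstream statistics.
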