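# File formats

All tables are tab-separated (TSV) with a header row. Coordinates are
1-based in the annotation and in VCF output. Allele A is the reference
(major) allele, allele B the alternate (minor) allele; contrast
(`log2(A) - log2(B)`) is positive toward AA.

## Inputs

### intensities.tsv
Per-probe two-channel raw linear intensities.

| column | meaning |
| --- | --- |
| `probeset_id` | probeset (variant) identifier |
| `probe_replicate_index` | 1-based replicate probe index within the probeset |
| `sample_id` | sample identifier |
| `channel_A` | raw A-channel intensity (>= 0) |
| `channel_B` | raw B-channel intensity (>= 0) |

### manifest.tsv
`sample_id`, `plate_id`, `batch_id`. A batch groups the plates processed
together and is the unit of cluster fitting (24 plates per batch by
default in the simulator).

### annotation.tsv
`probeset_id`, `rsid`, `chrom`, `pos` (1-based), `ref`, `alt`,
`n_replicate_probes`, `panel` (`;`-separated panel names, may be empty).

### ref_maf.tsv
`variant_id`, `ref_maf` — reference (sequencing-cohort) minor allele
frequency as a fraction.

### gold_standard.tsv
`sample_id`, `variant_id`, `confirmed_genotype` (`AA`/`AB`/`BB`). In
synthetic runs this table is derived from the simulation truth.

### panels.tsv (optional)
`panel`, `variant_id`. If absent, panel membership is taken from the
annotation's `panel` column.

## Outputs

### genotypes_*.tsv
`probeset_id`, `sample_id`, `call` (`AA`/`AB`/`BB`/`NoCall`),
`confidence` (posterior of the chosen cluster; empty where NoCall did not
come from thresholding), `provenance`
(`original`/`rarehet`/`advnorm`/`conflict`).

### rarehet_audit.tsv
One row per inspected heterozygous call: `probeset_id`, `sample_id`,
`dispersion` (max replicate deviation from the replicate median, contrast
units), `replicates_in_ab_cluster`, `verdict` (`keep`/`demote_to_nocall`).

### plate_shifts.tsv
`probeset_id`, `batch_id`, `plate_id`, `delta` (estimated contrast shift),
`n_samples`, `skipped` (plate below the minimum size), `flagged`
(`|delta|` above the shift threshold).

### advnorm_audit.tsv
Calls changed by renormalization: `probeset_id`, `plate_id`, `sample_id`,
`old_call`, `new_call`, `delta`.

### concordance.tsv
`variant_id`, `array_maf`, `ref_maf`, `log2_ratio`, `verdict`
(`retained`/`excluded`/`indeterminate`), `t_upper`, `t_lower`. A variant is
indeterminate when either MAF is 0 (or the array MAF is undefined); such
variants are routed to experimental validation, not excluded.

### screening_report.tsv / .json
Per `panel` x `maf_bin` (`0.01%<MAF<=1%`, `MAF<=0.01%`): `TP`, `FP`, `TN`,
`FN`, `PPV`, `NPV` (percentages, 2 decimals, half-up; empty with the
corresponding `*_defined` flag `False` when the denominator is 0).

### genotypes_final.vcf
VCF 4.2; one record per probeset with coordinates from the annotation;
`GT` per sample (`0/0`, `0/1`, `1/1`, `./.`) and `PV` (provenance) FORMAT
fields; `PROBESET` INFO tag.

### Run metadata
`resolved_config.yaml` (full configuration actually used),
`run_manifest.json` (package version, seed, SHA-256 input digests, output
list), `adjustment_summary.json` (combined and per-algorithm adjustment
accounting).

## Simulation config (YAML)

```yaml
seed: 11                    # mandatory
n_samples: 360
n_plates: 3
plates_per_batch: 3
artifact_rate: 0.01         # fraction of sample x probeset cells hit
artifact_factor_range: [4, 16]
batch_shift:
  channel: A                # A | B | both
  plates: {P002: -2.0}      # additive log2 shift per plate
probesets:                  # explicit specs, and/or probeset_grid below
  - {probeset_id: PS1, true_maf: 0.005, n_replicate_probes: 3}
probeset_grid:              # convenience generator
  n: 40
  maf_range: [0.001, 0.009]
  n_cross_hyb: 2
  contamination_factor: 8
```

## Pipeline config (YAML)

```yaml
inputs:
  intensities: sim/intensities.tsv
  manifest: sim/manifest.tsv
  annotation: sim/annotation.tsv
  ref_maf: sim/ref_maf.tsv
  truth_dir: sim/truth        # or gold_standard: path.tsv
output_dir: run1
seed: 11
params:                       # all optional, defaults shown
  epsilon: 1.0                # pseudocount before log2
  prior_center: 3.0           # cluster prior centers at (+c, 0, -c)
  prior_var: 0.25
  prior_weight: 2.0           # pseudo-observations per cluster
  confidence_threshold: 0.95
  d_max: 1.0                  # rare-het replicate dispersion limit
  shift_threshold: 0.5
  min_plate_n: 8
  t_upper: 1.72
  t_lower: -2.0
  npv_fraction: 0.0135
stages: {rarehet: true, advnorm: true, concordance: true, screening: true}
```

Unknown keys are rejected in both configs.
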