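# rarearray

Rare-variant quality control for two-channel SNP-array genotyping.

Detecting rare variants (minor allele frequency < 1%) on genotyping arrays
is hard: genotype clusters for the minor allele are nearly empty, plate-level
batch effects shift signal distributions across cluster boundaries, and
bubble/scratch artifacts on single probes fake heterozygous signals. This
package implements an end-to-end QC workflow for that regime, plus a
simulator that generates array experiments with known truth and injected
pathologies so every stage is testable without any proprietary data:

1. **Calling** — contrast/size signal summarization and per-batch,
   prior-regularized 3-component Gaussian-mixture genotype calling (empty
   clusters retain their priors, keeping rare genotypes callable).
2. **Rare het adjustment** — heterozygous calls whose replicate probes
   disagree (dispersion or per-replicate cluster membership) are demoted to
   NoCall.
3. **Advanced normalization** — plate-level contrast shifts within a batch
   are estimated by robust medians, and affected calls are re-assigned to
   the correct cluster.
4. **Consolidation** — the two adjustment tracks are merged (conflicts
   become NoCall) and per-variant adjustment outcomes are accounted.
5. **MAF concordance** — array-derived MAFs are compared to reference
   sequencing MAFs on a log2-ratio scale; low-concordance probesets are
   excluded (default thresholds +1.72 / −2).
6. **Screening evaluation** — per-panel, per-MAF-bin TP/FP/TN/FN and
   PPV/NPV against a gold standard (simulation truth, or a wet-lab
   confirmation table).

File formats are plain TSV/VCF and documented in [FORMATS.md](FORMATS.md).

## CLI

```bash
# simulate an experiment with injected pathologies
rarearray simulate --config sim.yaml --out sim/ --seed 11

# full pipeline from a YAML config (see FORMATS.md)
rarearray run --config pipeline.yaml
rarearray report --run-dir run1/

# or stage by stage
rarearray call --intensities sim/intensities.tsv --manifest sim/manifest.tsv \
    --annotation sim/annotation.tsv --out base.tsv
rarearray rarehet  --genotypes base.tsv ... --out rh.tsv
rarearray advnorm  --genotypes base.tsv ... --out an.tsv
rarearray consolidate --base base.tsv --rarehet rh.tsv --advnorm an.tsv --out final.tsv
rarearray concord --genotypes final.tsv --ref-maf sim/ref_maf.tsv --out conc.tsv
rarearray screen  --genotypes final.tsv --annotation sim/annotation.tsv \
    --ref-maf sim/ref_maf.tsv --gold-standard gold.tsv --out screen.tsv
```

## Conventions

* Allele A = reference (major) allele; contrast `log2(A) − log2(B)` is
  positive toward AA. Calls: `AA`, `AB`, `BB`, `NoCall`.
* A batch groups the plates processed together (24 by default) and is the
  unit of cluster fitting.
* Coordinates are 1-based in annotation and VCF output.
* All reported percentages are rounded half-up to 2 decimals.
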