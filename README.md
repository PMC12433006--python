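# nanomsp

Discovery, design and validation of methylation-specific PCR (MSP)
biomarkers from nanopore per-CpG methylation calls.

The package implements an end-to-end in-silico workflow:

1. **Region prediction** (`nanomsp.region_prediction`) — scans per-sample
   bedmethyl files (the extended-BED dialect of nanopore modified-base
   pileup tools) for CpG sites that are methylated in at least one tumor
   sample while unmethylated (≤ 10%) in all controls, groups them into
   primer-length windows (≥ 3 CpGs within 18–24 nt), pairs windows into
   60–400 nt amplicon regions, scores each region by tumor methylation ×
   coverage, and keeps the best region of every overlapping cluster.
2. **Assay design** (`nanomsp.assay_design`) — in-silico bisulfite
   conversion (methylated-allele CpG retention) and constraint-based
   enumeration of MSP primer pairs (14–22 nt, ≥ 1 CpG and ≥ 1 converted C
   per primer, 80–400 bp amplicons with ≥ 3 CpGs, Tm difference < 5 °C,
   dimer/hairpin heuristics) and hydrolysis probes (20–30 nt near the
   forward primer's 3′ end, no 5′ G, no palindrome, Tm 5–10 °C above the
   primers).
3. **Marker validation** (`nanomsp.msp_stats`) — ΔCT normalization against
   the reference assay, Welch t-tests with Bonferroni correction,
   Youden-optimal ΔCT cutpoints with sensitivity/specificity/AUC.
4. **Synthetic data** (`nanomsp.synthetic_data`) — generates every input
   the pipeline consumes (reference with CpG islands, tumor/control
   bedmethyl files under a tumor-purity mixture model, qPCR CT tables)
   for testing and demonstration.

Supporting IO lives in `nanomsp.io_formats` (bedmethyl, BED, FASTA,
manifests, chrom sizes, adaptive-sampling target expansion, region depth
summaries); a small bundled example ΔCT table is in `nanomsp.datasets`.

## CLI

```bash
# generate a synthetic demo dataset
nanomsp simulate --out demo/ --seed 42 --n-islands 20

# predict differentially methylated primer regions
nanomsp predict --manifest demo/manifest.tsv --islands demo/islands.bed \
    --out-prefix demo/pred --min-cpgs 3 --max-meth-control 10

# design primers and probes for the predicted regions
nanomsp design --regions demo/pred.regions.bed --reference demo/reference.fa \
    --out demo/primers.tsv

# validate markers from a qPCR CT table
nanomsp validate --ct demo/ct_table.tsv --manifest demo/manifest.tsv \
    --out-prefix demo/validation

# or run everything from one YAML config
nanomsp run --config config.yaml --out results/
```

`nanomsp run` executes simulate (optional) → predict → design → validate,
copies the exact config into the output directory and writes a
machine-readable `run_manifest.json`; stage failures abort with
stage-specific exit codes.

A minimal `config.yaml`:

```yaml
seed: 42
simulation:        # omit and supply `paths:` instead to use real data
  n_islands: 20
prediction:
  score_threshold: 0.0
```

## Notes

- All internal coordinates are 0-based half-open (BED native).
- CpG strand aggregation (merging the + record at the C with the −
  record at the following G) is the default; pass
  `--no-strand-aggregate` to keep strand-specific sites.
- The region score is `Σ_tumor-samples Σ_site-CpGs (meth% / 100) × depth`;
  it is monotone in methylation and coverage. Absolute score values are
  implementation-defined — thresholds should be chosen per dataset.
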