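# smmipkit

A toolkit for the computational side of single-molecule Molecular Inversion
Probe (smMIP) germline screening. smMIPs are oligonucleotide probes whose two
target-complementary arms hybridize around a genomic region of interest; the
gap between the arms is filled and ligated, circularized, PCR-amplified and
sequenced. Each probe molecule carries an 8-base unique molecular identifier
(UMI), so every read can be traced back to the single captured DNA molecule
it descends from (4^8 = 65,536 distinguishable molecules per probe), and PCR
duplicates can be identified and silenced rather than miscounted as
independent evidence.

The package is aimed at people building or validating smMIP screening
pipelines for gene panels (the motivating application is screening the *ATM*
gene in a 373-patient dystonia cohort). It provides:

- **`probe_model`** — parse and validate MIPGen-style probe design tables;
  derive merged target regions as BED.
- **`mipsim`** — simulate paired-end smMIP capture (molecule counts, UMIs,
  PCR duplication, substitution errors, spiked variants, per-probe capture
  efficiency) with full molecular ground truth, plus a synthetic
  case/control cohort generator for the table-level stages.
- **`readproc`** — extract UMIs, assign read pairs to probes by
  extension-arm Hamming matching, trim arms so only gap-fill insert remains.
- **`dedup`** — group reads into molecules by (probe, UMI); mark PCR
  duplicates by setting their base qualities to 0 (one representative per
  molecule keeps its qualities); a deliberately naive threshold genotyper
  over the condensed pileup closes the loop for end-to-end testing.
- **`covqc`** — condensed-coverage summaries (median target depth, percent
  of target bases at ≥20×) and probe-pool rebalancing factors
  (inverse-depth toward the median, clamped, mean-normalized).
- **`variantfilter`** — the rare-variant filter cascade: population allele
  frequency < 1% (1000 genomes and ExAC), in-house observations < 50, no
  synonymous variants, intronic only within ±8 bp of an exon boundary, no
  benign/likely-benign classifications; CADD > 20 marks the
  "predicted pathogenic" stratum but never filters.
- **`burden`** — case/control carrier collapsing restricted to regions
  covered in both cohorts, and a two-sided Fisher's exact test computed by
  explicit hypergeometric enumeration: conditional on the margins of the
  2×2 carrier table, `p = Σ P(T)` over all tables `T` with
  `P(T) ≤ P(observed)`.

## Worked example

The packaged cohort table (`smmipkit.variantfilter.load_cohort_fixture()`)
holds the rare *ATM* variants reported in a 373-patient dystonia screening,
one row per patient × variant. Running the cascade and summary:

```python
from smmipkit.variantfilter import apply_filter_cascade, load_cohort_fixture, summarize_cohort

passing, trace = apply_filter_cascade(load_cohort_fixture())
print(summarize_cohort(passing, cohort_size=373))
```

prints

```
{'distinct_variants': 21, 'carrier_patients': 22, 'distinct_vus': 20,
 'distinct_cadd_high': 10, 'biallelic_candidate_patients': 1,
 'biallelic_candidate_pct': 0.3, 'cohort_size': 373}
```

that is: 21 distinct rare variants carried by 22 of 373 patients; 20 of the
distinct variants are of uncertain significance (VUS); 10 have a CADD score
above 20 (high in-silico prediction of deleteriousness); and one patient
(0.3% of the cohort) carries a pathogenic class-5 variant plus a second
variant, making them a compound-heterozygosity candidate.

The same pipeline is exposed on the command line:

```sh
smmipkit sim --probes panel.tsv -o simdir --seed 3        # synthetic FASTQ + truth
smmipkit assign --probes panel.tsv --r1 simdir/reads_R1.fastq.gz \
    --r2 simdir/reads_R2.fastq.gz -o assigned
smmipkit dedup --assigned assigned/assigned.tsv -o dedup
smmipkit qc --condensed dedup/condensed.tsv --probes panel.tsv -o qc.json
smmipkit filter --variants variants.tsv -o filtered
smmipkit burden --cases filtered/passing.tsv --controls controls.tsv \
    --n-cases 373 --n-controls 404
```

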