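# Methods

This note documents the models, conventions and defaults behind each stage
of smmipkit, the assumptions they rest on, and what the synthetic data can
and cannot show about real sequencing runs.

## Probe model

A probe is described by its two arm sequences (extension and ligation arm,
stored exactly as written on the oligo), the gap-fill target interval, the
strand it copies, and its UMI length (default 8 bases). All coordinates are
0-based half-open everywhere in the package — design tables, BED output,
internal arithmetic — so there is a single place (the parser boundary)
where any 1-based input would have to be converted. The design-table
dialect is tab-separated with required columns `probe_id`, `chrom`,
`ext_probe_sequence`, `lig_probe_sequence`, `target_start`, `target_end`,
`strand`; extra columns are ignored so that output from different versions
of probe-design software can be consumed without modification.

Target-region derivation is a plain interval union ignoring strand: panels
routinely tile the sense and antisense strand over the same exon (single
molecule damage artifacts appear on one strand only, so two-strand designs
let downstream analysis cross-check), and both probes cover the same bases.

## Capture simulator

The simulator is a generative model of the smMIP library, not of the
chemistry. Per probe:

1. the captured-molecule count is `Binomial(n_molecules_per_probe,
   capture_efficiency)` — thinning the configured molecule number by a
   per-probe efficiency in [0, 1]. At efficiency 1 the count is exact,
   which the exact-recovery tests rely on. The wet-lab molecule:probe
   excess (on the order of 1:800) enters the model only through this
   efficiency knob; the simulator does not model hybridization kinetics,
   exonuclease digestion or cluster formation.
2. each molecule draws a UMI uniformly over `4^umi_length`. Collisions are
   allowed to occur naturally — that is the physical model — and are
   recorded in the truth table so exact-recovery tests can condition on
   collision-free runs while collision-robustness tests can seek them out.
3. spiked variants are planted per molecule with probability equal to the
   configured allele fraction, *before* PCR, so every duplicate of a
   carrier molecule shares the variant (as in reality).
4. each molecule is copied `1 + Poisson(pcr_duplication_mean − 1)` times.
   The shifted Poisson guarantees at least one copy and has a computable
   mean; no published duplication distribution exists to fit against.
5. substitution errors are applied independently per base per read at
   `seq_error_rate` (uniform over the three other bases). Indels are out of
   scope — the downstream quality-zeroing mechanism is exercised equally
   well without them.

Defaults are the conditions of a production panel run: 500 molecules per
probe (the per-smMIP sequencing target the protocol is sized for), 2×125 bp
paired-end reads, 8-base UMIs. PCR duplication mean 3 and error rate 1e-3
are not published figures; they were chosen once as representative of a
PCR-amplified Illumina library at Q30 and are configuration, not claims.

Read layout is a declared contract shared with `readproc` (real pipelines
differ in where the UMI sits; nothing downstream depends on the specific
choice, only on the two modules agreeing): read 1 is extension arm +
insert; read 2 is UMI + ligation arm + reverse-complemented insert; for
'−' strand probes the insert is the reverse complement of the reference
gap-fill. Base qualities are a constant Q30 before duplicate marking so
that quality-zeroing is directly observable in output.

The cohort generator synthesizes annotated-variant *tables* (the input of
the filter and burden stages) rather than per-sample FASTQ: each patient
independently carries one qualifying rare VUS with the cohort's carrier
frequency. Default carrier frequencies are 0.059 for cases (the observed
22/373 carrier rate of the motivating screen) and 0.05 for controls (the
published control carrier counts are not available; a near-null value is
used). An optional background rate adds common/synonymous rows that the
cascade must remove. `write_cohort` can additionally emit FASTQs for a
configurable number of samples; generating read-level data for hundreds of
samples would add cost without adding information, since the read-level
pipeline is validated separately against molecular truth.

### What the simulator does not emulate

Real capture has sequence-dependent arm hybridization efficiency,
GC-dependent amplification, indel and chimera artifacts, and
quality-score degradation along the read. Passing tests on simulated data
therefore demonstrate the *bookkeeping* correctness of the pipeline
(conservation, grouping, silencing, counting, calibration), not variant
sensitivity or specificity on real libraries.

## Read processing

UMI extraction takes the first `umi_length` bases of read 2 (offset and
read configurable). Reads too short to contain the UMI, or whose UMI
contains an ambiguous base, are routed to named reject bins rather than
dropped silently; every input pair lands in exactly one bin (conservation
is asserted in tests).

Probe assignment compares the start of read 1 against every probe's
extension arm by Hamming distance on the arm-length prefix (no indels),
default tolerance 1. The unique probe at minimal distance within tolerance
wins; an exact tie is deliberately UNASSIGNED — a wrong but confident
assignment is worse than a discarded read in a screening context. The
assigned count is monotone in the tolerance, which the tests assert.

## Duplicate condensing

Reads are grouped by exact (probe_id, UMI) match. Exact matching (rather
than 1-mismatch UMI merging) is the simplest defensible rule: UMI
sequencing errors can only split a molecule into two groups, inflating the
molecule count slightly at a 1e-3 per-base error rate, and never merge two
molecules — tests bound the effect. Within each group, the read with the
highest summed base quality is the representative (ties broken by smallest
read id, to be deterministic); every other member has all base qualities
set to zero while sequence bases are left untouched. This silences
duplicates for coverage and calling without discarding data, and makes the
condensed depth per probe exactly the number of molecule groups. A
base-wise majority-consensus rewrite of the representative would be a
natural extension; it is intentionally not implemented, because quality
silencing alone already prevents duplicates from voting.

The naive genotyper is test plumbing, not a variant caller: it counts
alleles per reference position over bases with non-zero quality, placing
each insert by its probe's target coordinates ('−' strand inserts are
mapped back through reverse complement), and emits a call when condensed
depth ≥ 8 and the top non-reference fraction lies in [0.2, 0.8] (het) or
≥ 0.8 (hom). Those thresholds are configurable defaults with no empirical
claim attached. Indels, strand bias and quality weighting are out of scope.

## Coverage QC and rebalancing

Coverage is computed on condensed reads only — duplicates carry zero
quality and contribute no depth — so "depth" means "distinct molecules".
The report gives the median per-base depth over the target (median of an
even count = mean of the two middle values) and the percentage of target
bases at or above the threshold (default 20×, the conventional germline
floor).

Rebalancing maps per-probe condensed depths to pipetting factors:
`factor_i = median(depth) / depth_i`, a zero-depth probe gets the upper
clamp, factors are clamped to [0.2, 5.0] (avoiding impractical pipetting
extremes) and normalized to mean 1 (conserving total pool amount). Clamping
and normalization can conflict at the boundary, so they are iterated to a
fixed point, with the clamp taking final precedence. The specific formula
is this package's construction; what is field-standard is the loop itself —
pilot run, per-probe depth, adjusted pool — and the seed-paired simulation
tests assert the property that matters: one rebalance round reduces the
coefficient of variation of per-probe depth (mean CV ratio ≈ 0.2 in the
packaged experiment).

## Filter cascade

Six independent predicates joined by conjunction; thresholds are strict
inequalities as conventionally stated (AF *below* 1%, *fewer than* 50
in-house observations, CADD *above* 20): population AF (1000 genomes,
ExAC) < 0.01 each; in-house count < 50; consequence not synonymous;
intronic retained only within ±8 bp of the exon boundary (the retained
`c.1066-6T>G` at 6 bp and excluded-at-9-bp behavior pin the convention to
"keep within the window, inclusive"); classification not benign or likely
benign. Missing population AF is treated as 0 — absence from population
databases is evidence of rarity, and treating it as unknown would silently
drop exactly the novel variants a rare-disease screen exists to find.
Missing CADD never excludes: CADD > 20 defines a prioritization stratum,
not a filter. Distinct variants are keyed on the cDNA change string.

Because the cascade is a pure conjunction, rule order cannot change the
passing set (asserted by permutation on random tables) and tightening any
threshold can only shrink it (asserted likewise). The per-variant trace
records the first failing rule in the order used, plus all failing rules.

The packaged cohort fixture carries the published screening results (cDNA
and protein changes, CADD, classification) for the 22 carrier patients of
a 373-patient dystonia cohort; its frequency/consequence annotation
columns are synthetic values consistent with every row surviving the
cascade, because the originating in-house database is not
redistributable. The cohort summary counts distinct variants overall for
the CADD > 20 stratum (10, including the one class-5 pathogenic variant);
counting only distinct VUS would give 9, and the summary exposes both the
VUS count and the CADD-stratum count separately so either reading is
recoverable.

## Burden test

Association is by carrier collapsing: each patient counts once however
many qualifying variants they carry, yielding a 2×2 table of carriers vs
non-carriers in cases (n = 373 by default) and controls (n = 404). Only
variants inside the intersection of the two cohorts' covered regions are
comparable — carrier detection must have been possible in both groups —
so an interval-intersection step restricts the analysis when coordinates
are available.

The two-sided Fisher p-value follows the standard "probability mass ≤
observed" convention: conditional on the margins, sum the hypergeometric
probability of every table whose probability does not exceed the observed
table's, with a relative tie tolerance of 1e-7 to absorb floating-point
noise in the log-gamma evaluation. The implementation is exact
log-factorial enumeration; the test suite checks it exhaustively against
an independent exact-rational brute-force enumerator for every table with
N ≤ 30 (agreement to ~1e-14) and against scipy's implementation
property-wise. Two strata are reported alongside "all": VUS, and
predicted-pathogenic (CADD > 20). No multiple-testing correction is
applied across strata; raw p-values are emitted.

Fisher's exact test is conservative at these sample sizes: under equal
carrier frequencies of 5% in 373 vs 404 patients, the measured type-I
rejection rate at α = 0.05 is ≈ 0.03–0.045 over 500 simulated cohorts —
below nominal, as expected for a discrete exact test, and within binomial
Monte-Carlo error of it.

## Problem sizes and numerical conventions

Simulation-based tests run on toy references of 3–4 kb with 4–6 probes,
25–150 molecules per probe and duplication means of 1.5–3; the
rebalancing experiment uses 20 paired seeds; calibration uses 500
cohorts; the exhaustive Fisher check covers all 46,375 tables with
N ≤ 30. These sizes make every distributional assertion a 3σ bound of the
configured sampler, keep the full suite fast enough to run on every
change, and are stated in each test. All randomness flows from explicit
seeds (numpy `default_rng`); fixing the seed fixes every output byte,
including FASTQ and truth files.

## Known limitations

- No alignment: inserts are positioned by probe coordinates, so the
  pipeline cannot detect mis-hybridized capture or reference mismatch
  beyond arm-distance rejection.
- No indel support anywhere in the read-level path.
- Exact UMI grouping slightly overcounts molecules under UMI sequencing
  errors (split groups), bounded but not corrected.
- The cohort generator draws carriers independently per patient; it has no
  relatedness, population stratification or per-variant effect sizes, so
  the burden calibration speaks to test validity under the null, not to
  power against structured alternatives.
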