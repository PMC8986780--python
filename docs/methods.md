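# Methods

## Screen model and assumptions

A haploid gene-trap screen reads out, per sorted channel (reporter-HIGH and
reporter-LOW), the set of unique genomic integration sites of a retroviral
trap cassette. The analysis assumes:

* **One read coordinate ↔ one integration.** PCR amplification yields many
  reads at identical coordinates; reads are collapsed to unique sites keyed
  by (chromosome, position, strand). Position is the 5′-most aligned base in
  read orientation — the base adjacent to the cassette for single-end
  trap sequencing (start of a `+` read, end − 1 of a `−` read).
  The strand is kept in the identity key: two integrations at the same base
  on opposite strands are biologically distinct events, and collapsing them
  would silently delete antisense evidence needed downstream.
* **Only sense insertions disrupt.** A cassette in the gene's
  transcriptional orientation truncates the transcript; antisense
  insertions are usually tolerated. A site is assigned to gene *g* iff it
  lies in an interval of *g* (0-based half-open) and matches *g*'s strand;
  a site inside several overlapping sense genes counts for each of them.
  Gene models are per-symbol unions of transcript spans — trap insertions
  disrupt anywhere in the locus, so exon resolution is deliberately
  avoided. A symbol appearing on several chromosomes is suffixed with the
  chromosome name to stay unique.
* **The comparison universe is "all other mutations".** For gene *g* the
  2×2 table contrasts *g*'s sense insertions against *all* other unique
  insertions in that channel (any strand, genic or intergenic). A
  `universe="sense-genic"` switch restricts the totals to sense-genic
  insertions for sensitivity analysis; the default is the broadest
  universe, consistent with contrasting a gene's sense integrations with
  every other mutation in the population.

## Test, correction, effect size

* **Fisher's exact test, two-sided**, defined as the sum of the masses of
  all tables with the observed margins whose point hypergeometric
  probability is ≤ the observed probability × (1 + 10⁻⁷); the relative
  tolerance absorbs floating-point ties (symmetric tables with equal
  rational mass). The implementation works in log-space (`lgamma`
  factorials) so it is finite at screen scale (~10⁷ insertions per
  channel), and sums masses with `math.fsum`, which makes the p-value
  exactly invariant under row and column swaps — hence swapping the
  HIGH/LOW inputs of a screen preserves every p-value bit-for-bit while
  inverting every ratio. A zero-margin table admits a single configuration
  and returns p = 1; the all-zero table is an error. Tests verify exact
  agreement (≤ 10⁻¹²) with an exact-rational enumeration oracle for every
  table with grand total ≤ 40, and with `scipy.stats.fisher_exact` away
  from ties.
* **BH-FDR** is the standard step-up adjustment
  (`statsmodels.stats.multitest.multipletests`, `fdr_bh`), computed across
  exactly the tested genes. The tested set defaults to genes with ≥ 1
  combined unique sense insertion (`min_combined=1`); the adjusted values,
  not the ordering, depend on this choice. Note BH is not idempotent on
  its own output (re-adjusting inflates by m/rank); the guaranteed
  properties are adjusted ≥ raw, capped at 1, with the evidence ordering
  preserved.
* **Mutation ratio** r = (a/N_H)/(c/N_L). Raw counts are always emitted;
  a pseudocount of 1 is applied to both gene counts *only when either is
  zero*, purely so the fishtail stays plottable — the raw-count columns
  make the transform reversible.

## Synthetic screens

`ScreenSimConfig` defaults define the study conditions used throughout the
tests: one 5 Mb chromosome, 500 disjoint 2 kb genes (20% genic fraction),
10⁴ insertions per channel, sense probability 0.5, duplicate rate 0.2.
This gives ~20 insertions (~10 sense) per gene per channel — enough signal
for a strong hit to separate while keeping a single screen under half a
second. Baseline insertions are uniform over the genome (no
expression-dependent trap bias); a planted (gene, channel, fold ≥ 1)
multiplies that gene's sampling weight in that channel only, so fold = 1
is exactly the null. Duplicates are emitted as literal repeated reads and
removed by the same catalog code that processes real alignments, so
deduplication is exercised end to end. The fold-10 recovery experiments
use 2×10⁴ insertions per channel, which puts the planted gene's expected
sense count at ≈ 40 (≥ 30) in its enriched channel:
n·f·L/(G − L + f·L)·sense_prob with L = 2 kb, G = 5 Mb.

What the generator does **not** emulate: expression- or chromatin-biased
integration, mappability holes, sequencing error, read-level FASTQ
artifacts, or clonal expansion structure. Passing the calibration and
recovery tests therefore shows the pipeline is correct and well-calibrated
under a uniform-integration null, not that a real screen's null is
uniform.

Calibration and power, both computed by the test suite on the full
simulate → catalog → count → test pipeline: over 200 seeded null screens
the mean realized false-discovery proportion at α = 0.05 stays within
three Monte-Carlo standard errors of 0.05 (empirically it is far below,
since discrete Fisher p-values are conservative); a fold-10 planted
regulator with ≥ 30 expected sense insertions is detected with the correct
direction in ≥ 95 of 100 seeds, symmetrically for HIGH- and LOW-planted
genes.

## Flow-cytometry quantifications

* **Gated reporter ratio**: marker-positive events are those above a gate;
  since no absolute gate generalizes across instruments, the default gate
  is the 99.9th percentile of an untransfected control sample, overridable
  by an absolute threshold. The numerator is the mean reporter intensity
  of the top 10% (configurable) of marker-positive events ranked by marker
  intensity (ties broken by stable event order); the denominator is the
  mean reporter intensity of marker-negative events; an optional
  background intensity is subtracted from both means first. The ratio is
  invariant under rescaling all reporter intensities, and widening the top
  fraction moves the numerator monotonically toward the positive-gate
  mean.
* **Competitive growth**: percent lineage-marker-positive cells per sgRNA
  per day, normalized per day to the non-targeting control and then to the
  reference day (default day 7): value(sg, d) =
  [pct(sg,d)/pct(NTC,d)] / [pct(sg,ref)/pct(NTC,ref)]. NTC maps to 1
  everywhere; any per-day rescaling of all labels cancels.
* **Growth ratio**: elementwise treated/control counts over matched
  timepoints.
* The flow event simulator draws log-normal marker/reporter intensities
  with a transfected subpopulation whose marker is shifted ×50 and whose
  reporter is shifted by the planted factor; a ×5 planted shift is
  recovered by the gated ratio within 10% averaged over 50 seeds.

## Presequence (MTS) feature scans

Matrix processing peptidase (MPP) prefers substrates with arginine at the
−2 or −3 position relative to the scissile bond (the "arginine rules").
The scans: arginine inventory over the first 50 residues (1-based);
candidate cleavage bonds after residue k whenever residue k−1 (R-2) or
k−2 (R-3) is arginine, merged when two rules hit the same bond, with an
optional R-10 extended rule off by default; sliding-window mean hydropathy
(Kyte–Doolittle, window 9, odd windows only); and uncharged/apolar segment
detection — maximal runs of residues covered by a window of length
`min_len` (default 15) whose charged fraction (charged set D, E, K, R and,
by default, the weakly charged H) is ≤ `max_charged_frac` (default 0.2).
The window/tolerance definition of "mostly uncharged" and the inclusion of
histidine are package choices — no claim is made that the default
parameters reproduce any particular protein's published segment
boundaries; on real sequences the scan is a report, not an assertion.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; BED I/O is bit-compatible.
* Default `min_mapq` = 0: trap pipelines typically filter at alignment
  time, not by mapping quality; the flag is exposed.
* Enrichment results are sorted by adjusted p then gene name, and all TSV
  output is deterministic (byte-identical across runs on the same input).
* Plot styling is configurable and explicitly not normative; only the
  coordinate semantics (log-log, ratio vs combined unique sense count,
  three significance classes) are.
* The acceptance script scales the Monte-Carlo studies to 100 null
  screens, 2×50 recovery seeds and 25 flow seeds — sizes chosen so a
  single-CPU run finishes in a couple of minutes while keeping Monte-Carlo
  error well inside the decision margins; the test suite runs the larger
  200/2×100/50-seed versions.

## Known limitations

* Uniform-integration null only (hooks exist for per-gene weights, but no
  biased null ships).
* No gene-length or expression normalization of the enrichment test, and
  no alternative tests (binomial, Poisson GLM).
* Binary cytometry formats (FCS), spillover compensation and automated
  gating are out of scope; events are plain tables.
* Paired-end alignment logic, trimming and demultiplexing are out of
  scope; alignments are consumed, not produced.
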