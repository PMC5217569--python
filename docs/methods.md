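# Methods

## Model overview

The package treats a WGBS run as a chain of four stochastic stages —
methylome, chemistry, sequencing, base calling — each with an explicit,
parameterized model, so that the downstream estimators can be validated
against closed forms.

### Methylome

A `MethylomeSpec` assigns each cytosine a methylation probability:

- **uniform**: every CpG at level *m*; non-CpG cytosines at
  `noncpg_level` (default 0 — vertebrate somatic non-CpG methylation is
  near zero and the package's non-CpG statistic is used as a conversion/
  error sanity check, not a biological signal).
- **sssi**: every CpG at 0.979, the near-complete methylation an SssI
  methyltransferase treatment achieves as validated by clone bisulfite
  sequencing of 58 CpG sites. This is the spike-in substrate model.
- **mixture**: a *physical* two-component mixture. The component (fully
  methylated vs. unmethylated by default) is drawn **once per molecule**,
  then per-site Bernoulli draws use that component's levels. This matters
  statistically: in a mixture of fully methylated/unmethylated DNA all
  calls from one molecule are perfectly correlated (see *Statistical
  tolerances* below).

Cytosines are indexed on both strands with 5'→3' dinucleotide context
(CpG, CpA, CpT, CpC); a cytosine whose next base is N or missing gets
context `unknown` and is excluded from every methylation statistic.

### Chemistry and read generation

Fragments are drawn uniformly over the reference with
length ~ Normal(300, 30) truncated below at the read length — a generic
Illumina insert distribution; nothing downstream is sensitive to it. One
genomic strand is chosen uniformly; each cytosine of that strand is
methylated per the methylome, and unmethylated Cs convert to T with
probability `conversion_rate` (default 1.0, i.e. ideal chemistry;
calibration runs state it explicitly — any simulated inefficiency simply
adds `(1-conversion_rate)` to observed levels).

Reads are 101 bp by default. PBAT: R1 = 5' prefix of the *reverse
complement* of the converted strand, R2 = 5' prefix of the converted
strand; MethylC-seq swaps the mate roles. Hence 5mC codes as G in PBAT R1
and C in PBAT R2, and a fully converted PBAT R1 contains G *only* at
methylated-cytosine positions — the low-diversity situation that breaks
some base callers. Sequencing error is uniform per-base substitution at
`error_rate`; qualities are flat at Phred 38 before artifacts.

### Artifact model

Two failure modes, both on a configurable target mate:

- **G undercall**: each called G becomes A with probability *q* and its
  quality falls by δ (floored at Phred 2). A is specifically the
  unmethylated partner base at 5mC-coding positions in both chemistries,
  so one parameter reproduces the joint observation of depleted G counts
  *and* depressed methylation: **E[observed level] = m(1 − q)**. A
  uniform-miscall variant is available (`uniform_miscall`), under which
  most miscalls land on no-call bases and mainly cost coverage instead.
  By default δ applies only to miscalled Gs; `penalize_retained` extends
  it to every G, which is what makes quality *drops at G* visible in reads
  whose G survived — the variant used when reproducing the
  steep-drop diagnostic.
- **Density collapse** (`R2Collapse`): a cap on all qualities of the
  target mate that falls linearly from the instrument maximum (41) at
  ≤ 300 K clusters/mm² to `quality_floor` at ≥ 650 K. The 300–650 K ramp
  spans the plausible loaded range of the flow cell; only monotonicity
  and the endpoints matter to any statistic here.

### Alignment

Reads are aligned in the three-letter collapsed alphabet: the read is
collapsed C→T or G→A depending on mate/protocol (PBAT R1 is complementary
to the converted strand → G→A; PBAT R2 → C→T; MethylC-seq mirrored), and
scanned against the two matching collapsed reference views (plus and
minus orientation). Defaults mirror common bisulfite-aligner settings:
trim 4 bp from the 5' end and 1 bp from the 3' end (101→96), seed 28 bp
with ≤ 1 seed mismatch. The total-mismatch cap of 3 per 96 bp is this
package's choice (the delegated aligner internals it replaces do not
state one); it is loose enough for 0.1% error rates and tight enough to
exclude random placement on lambda-scale references.

Candidate loci come from exact lookup of seed chunks — the seed is split
into `seed_mismatch_max + 1` pieces, so by pigeonhole every locus passing
the seed filter is found — and are verified by direct mismatch counting.
A strictly best locus is `unique`; ties are `ambiguous` and discarded
(only unique alignments are ever analyzed); reference N mismatches
everything. This full-sensitivity scan was chosen over an FM-index
deliberately: at lambda scale, exact equivalence to the brute-force
all-positions scorer (asserted in tests) is worth more than speed.

### Methylation calls and levels

At each indexed cytosine covered by a unique alignment the read base is
interpreted in the alignment's view: converted-strand views call C
methylated / T unmethylated, complementary views call G methylated / A
unmethylated; **any other base yields no call** rather than an
unmethylated call. This choice is load-bearing: it makes the G→A
undercall behave exactly as m(1−q), while unrelated sequencing errors
merely lose coverage.

All levels are *weighted*: Σ meth / Σ (meth+unmeth) over the selected
cytosines, i.e. depth-weighted, not a mean of per-site levels. R1 and R2
strata are kept separate throughout; the combined level pools strata
without overlap deduplication by default (mate-stratified analysis is the
primary surface), with an optional dedup mode that prefers R1 where both
mates cover the same cytosine.

### QC statistics

- Per-cycle base composition, normalized over called A/C/G/T (N excluded
  but counted).
- Quality classes per base: [0,10), [10,20), [20,30), [30,∞); "over 30"
  is implemented as Q ≥ 30 per the Q30 convention.
- Steep drop: position *i* ≥ 1 is a drop iff `qual[i−1] − qual[i] >
  threshold` (default 10, strict). The drop-at-G statistic is the fraction
  of G-containing reads with ≥ 1 drop located at a G — counted per read,
  not per G. A running-maximum drop definition is exposed behind
  `mode="from_max"` for gradual multi-cycle slides; the adjacent-cycle
  default matches how single steep falls present in raw quality strings.

### Region analysis

Windows are non-overlapping tilings with the trailing partial window
dropped, so CpG counts are comparable across windows. Window levels are
weighted within the window; zero-call windows are *undefined*, never 0.
Run comparison is OLS of run A on run B over the windows where both are
defined. CpG-density classes (default 9) use value-based quantile
boundaries on the per-window CpG count, with duplicate boundaries merged —
so heavily tied counts collapse into fewer classes rather than being
split arbitrarily by window order.

PMDs: 10-kb windows are eligible iff ≥ 10 CpG sites in the window have
≥ 1 call ("ten or more CpG sites, each covered at least once" is read as
a count of covered sites; windows may hold additional uncovered CpGs);
eligible windows with level < 70% are PMD windows; contiguous PMD windows
merge; merged intervals strictly longer than 100 kb are reported. An
ineligible window breaks contiguity — merging across no-data gaps would
manufacture PMD length out of missingness.

## Fixture genome

The calibration reference is a GC-balanced i.i.d.-random sequence of
exactly 48,502 bp (the lambda phage genome length) generated from a fixed
seed, so no external sequence is needed and every run sees the same
fixture. Being i.i.d.-random it has lambda-like CpG density (~1/16 per
strand position) but no repeats, so unique-alignment rates are near 1;
conclusions about mappability on real genomes do not transfer. PMD
demonstrations use longer genomes from the same generator with a planted
intermediate-methylation block.

## Statistical tolerances

Recovery tests accept an estimate within 4 standard deviations of its
sampling distribution, with the sd computed for the *actual* dependence
structure:

- uniform/SssI methylomes: per-site draws are independent across sites
  and molecules, so the binomial sd over pooled calls,
  `sqrt(p(1-p)/n_calls)`, is correct.
- two-component mixtures of fully methylated/unmethylated molecules: all
  calls from one molecule share its component, so the depth-weighted
  estimator's exact sd given per-molecule call counts c_i is
  `100·sqrt(π(1−π)·Σc_i²)/Σc_i` (≈ the molecule-level binomial sd; about
  √12 larger than the naive pooled-call sd at ~12 CpG calls per pair).
  Mixture-recovery checks use this; a pooled-call binomial band would be
  mis-calibrated no matter how many reads are simulated.

## Problem sizes

Mixture calibration points use 17,500–18,000 read pairs (≥ 200,000 CpG
calls, sampling sd ≤ 0.4 points); the clone simulation uses 1,000
molecules × 58 CpG sites; the non-CpG sanity bound uses 100,000 reads
(~1.8 M non-CpG calls, expected level `error_rate/3` ≈ 0.033% under the
no-call rule); analysis drivers use 2,000–8,000 pairs, enough to place
every expected effect well outside its sampling noise. All sizes are the
package's own choices for desk-scale runs of a lambda-sized reference.

## Known limitations

- No indels, adapters, PCR duplicates, M-bias, or SNP awareness; the
  aligner scores substitutions only and is O(genome × reads) by design.
- The artifact model is phenomenological: it reproduces the *signatures*
  of version-dependent base calling (G depletion, low G quality, R2
  collapse), not the internals of any instrument software; parameters
  (q, δ, density ramp) are inputs, not estimates of any real version.
- Headline magnitudes from real instrument comparisons (e.g. a ~5%
  between-version methylation difference) correspond to particular
  unknown q values; the package demonstrates direction and the m(1−q)
  scaling law, and recovers predetermined levels exactly in the clean
  condition.
- The mixture sd formula conditions on the realized call counts c_i;
  variation of c_i across seeds is second-order at these sizes.
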