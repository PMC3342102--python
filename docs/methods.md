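# Methods

## The analysis chain

A small-RNA library of 36-cycle reads is reduced to a transposon piRNA
profile in four stages.

**Adapter trimming.** Each read is scanned for its 3' adapter: the leftmost
position `p` where `read[p:]` matches the adapter prefix of the overlapping
length with at most 2 mismatches (overlap ≥ 6 nt) marks the junction;
`read[:p]` is the insert. `N` always counts as a mismatch. Reads with no
qualifying position are discarded (`no_adapter`); inserts shorter than 23 nt
(including `p = 0`) count as `too_short`, longer than 30 nt as `too_long`.
The four tallies partition the input exactly. Characters outside A/C/G/T/N
are replaced by `N` with a warning rather than dropped, so the partition
survives malformed input; under zero-mismatch mapping an `N` insert is
harmless (it simply cannot map).

**Exact mapping.** Inserts are mapped with zero mismatches, all hits on both
strands reported. The index stores every forward 23-mer of every reference
(23 = the minimum insert length, so one seed lookup serves all query
lengths); a query looks up its own first 23-mer for "+" candidates and its
reverse complement's first 23-mer for "−" candidates, then verifies the full
insert against the reference slice. Coordinates are 0-based half-open in
reference orientation. Reads are collapsed to unique sequences before
mapping and re-expanded after — identical results, far fewer lookups in
deeply duplicated small-RNA libraries.

**Profiling.** The RPM denominator is the number of *distinct* reads with at
least one perfect genome hit (a multi-mapper counts once). Per transposon, a
read counts at most once per (transposon, strand) but counts toward every
transposon it hits — the simplest policy expressible from an all-hits mapper,
and stated explicitly because reference-level read counting is
convention-dependent. The 1U bias is the percentage of distinct
transposon-mapped reads whose insert begins with T; the same statistic over
all genome-mapped reads is exposed alongside (`one_u_bias_genome`) since the
choice of denominator is a reading, not a law. The antisense bias is the
pooled ratio Σ antisense / Σ sense over all transposons — not a mean of
per-transposon ratios, which would be undefined wherever sense counts are
zero. The abundance filter keeps transposons whose baseline total
(sense + antisense) RPM strictly exceeds 500.

**Comparison.** Relative expression RE = sample RPM / baseline RPM is
computed per transposon for sense, antisense, and total abundance. A zero
baseline yields a missing value (NaN), never a fabricated number. Bands:
reduced (RE < 0.6), unchanged (0.6 ≤ RE ≤ 1.6, both boundaries inclusive),
elevated (RE > 1.6). Replicates are summarized with the sample
(n − 1) standard deviation — three biological replicates is the expected
regime, where the population SD would understate spread — and percent
reduction 100·(1 − mean RE). When several baseline libraries are supplied
their mean RPM is the baseline; a pooled-variance two-sample t statistic on
per-library REs is then also reported, raw (no multiple-testing
correction), as a convenience rather than a canonical test. Degenerate
zero-variance groups resolve explicitly to (t = 0, p = 1) for equal means
and the (±∞, 0) limit, flagged, otherwise.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
every parameter a study condition rather than a tuning knob.

* **References.** `n_transposons` random consensi (default 121, the size of
  a well-annotated transposon set; lengths 500–2000 nt) are embedded
  verbatim, once each, in a random genome (default 400 kb), separated by
  ≥ 50 nt random gaps. Embedding guarantees that every transposon-derived
  read also maps perfectly to the genome, so the RPM denominator is well
  defined. Background reads are drawn only from the copy-free gaps, keeping
  ground-truth source labels unambiguous.
* **piRNA reads.** Transposon ∝ abundance weight; strand antisense with the
  transposon's antisense fraction; insert length uniform on 23–30 by
  default; start position rejection-resampled (cap 100) until the insert's
  5' base is T with probability `u_probability`, else non-T — so insert
  content otherwise matches the consensus exactly and stays perfectly
  mappable. Only on cap exhaustion is the first base substituted (a read
  that may then fail to map); with random consensi this is effectively
  never hit.
* **Read assembly.** Insert + adapter, truncated to the 36-nt cycle window,
  constant placeholder quality. The adapter defaults to a documented 20-mer
  stand-in (`TGGAATTCTCGGGTGCCAAG`): the study kit's adapter sequence is
  unpublished, and any ≥ 6 nt sequence works. Substitution errors (no
  indels, no quality model, no PCR duplicates) are applied after ligation,
  so the adapter copy can carry the mismatches the trimmer must tolerate.
  Junk reads are random 36-mers rejected until they contain no adapter
  occurrence within the two-mismatch tolerance.
* **Presets.** `wt-ovary`: u_probability 0.73, antisense fraction
  3.5/4.5; `kg-ovary`: 0.69 and 3.7/4.7 — i.e. the printed 1U-bias
  percentage over 100, and r/(1+r) for the printed pooled ratio r, so the
  profile stage should recover the printed values. `KG_REDUCED_FACTOR =
  0.6` scales designated transposons' abundance weights in the mutant,
  encoding a ~40% drop in relative expression.
* **Randomness.** One `numpy.random.default_rng(seed)` (PCG64) stream per
  library drives all sampling; identical configuration gives byte-identical
  FASTQ and ground truth.

What the generator does **not** emulate: real transposon sequence
divergence (reads always match a consensus exactly, so zero-mismatch
mapping loses nothing here, unlike on real libraries), genomic multi-copy
families with internal variation, ping-pong 10-nt overlap structure,
non-uniform read-length distributions, and realistic error/quality
profiles. Passing tests therefore demonstrate that the pipeline's
accounting is exact and its estimators unbiased under the stated model —
not that real libraries would yield these exact numbers.

## Problem sizes and numerical choices

The canonical recovery experiments (`pirnaprofiler.experiments`,
`scripts/acceptance.py`) use 121 transposons in a 400 kb genome and
200,000 piRNA reads + 20,000 background + 2,000 junk reads per library,
error-free. At n = 2×10⁵ the binomial standard error of the 1U fraction is
≈ 0.1 percentage points and of the antisense ratio ≈ 0.009, so rounding to
the printed precision is stable across seeds. Three mutant replicates
(distinct seeds) feed the mean ± SD summaries.

One subtlety in the reduction experiment: a library has a fixed read
count, so scaling three transposons' weights by 0.6 re-normalizes every
share. With equal unit weights over T transposons the designated ones'
expected RE is 0.6·T/(T − 3 + 3·0.6); for T = 121 that is 0.606 (39.4%
reduction, within the nearest-5% band of 40), while for small reference
sets the dilution is visible (T = 10 gives ≈ 32%). The reduction is
reported from total (sense + antisense) RPM, averaged over the three
designated transposons and the three replicates.

Tie-breaks and edge cases, stated once: leftmost adapter match wins;
min_overlap 6 prevents 1–2 nt chance "adapters" (at overlap 6 a random
6-mer still passes the two-mismatch bound ≈ 4% of the time, which is why
the trimming-idempotence guarantee is meaningful only at full-length
overlap); "more than 500 RPM" is strict; band boundaries 0.6 and 1.6 are
inclusive to "unchanged"; RPM retains full float precision; empty
libraries, zero pooled sense counts, and zero baselines raise or mark
missing rather than guessing.

## Known limitations

* The exact mapper is a pure-Python hash index: ample for consensus-scale
  references (hundreds of kb), not for full genomes at scale.
* Read counting credits a multi-mapping read to every transposon it hits;
  alternative policies (fractional, best-hit) are not implemented, only
  derivable from the emitted all-hits tables.
* The t test on replicate REs requires at least two baseline libraries to
  have a variance estimate on both sides; with a single WT library only
  mean ± SD and percent reduction are reported.
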