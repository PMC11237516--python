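# Methods

This note documents the models and procedures implemented in `polyamp`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Problem setting

A multi-kingdom amplicon run pools full-length bacterial 16S amplicons
(primers 27F `AGRGTTYGATYMTGGCTCAG` / 1492R `CGGYTACCTTGTTACGACTT`) and
fungal ITS amplicons (the inner nested pair ITS1 `TCCGTAGGTGAACCTGCGG` /
ITS4 `TCCTCCGCTTATTGATATGC`) into one barcoded nanopore library. Reads
arrive demultiplexed under `fastq_pass/<barcode>/` in fixed-size batch
files (4,000 reads per file by default). The toolkit consumes those files;
basecalling and demultiplexing are upstream and out of scope, as is the
final high-accuracy abundance re-estimation (an external EM-based tool
whose output table the reporting stage ingests).

## Kingdom segregation

Each primer is located by a semi-global alignment: the primer must align
end-to-end against a read substring under unit-cost edit distance, with an
IUPAC degenerate code matching every base of its set at zero cost. The
matcher is exact and its tie-breaks are part of the contract — minimal
distance, then smaller start, then shorter span — so it can be verified
against an exhaustive substring-enumeration oracle (and it is, for all
tested instances with reads ≤ 60 nt). The inner dynamic program tracks,
per cell, the minimal alignment start among all optimal paths, which makes
the global tie-break a single scan of the last row; it is JIT-compiled
with numba, with a pure-numpy fallback.

Search is restricted to 100-nt end windows (configurable): amplicon reads
begin and end with primers, and windowing prevents spurious internal
matches. For each primer set, four placements are probed on the raw read —
forward primer at 5′, reverse-complemented reverse primer at 3′, and the
two mirror placements of a flipped read. The error budget per primer is
⌈0.2·|primer|⌉, matching the error tolerance conventional for amplicon
primer trimming; the tolerance was an open choice, and 20% of primer
length is deliberately permissive because at ~5% read error a 20-mer
carries one expected error.

A set *supports* a read if at least one of its primers hits. A unique
supporting set decides the verdict; with several, the set with more
distinct primer hits wins, then lower total edit distance, and remaining
ties are reported as conflicts rather than guessed. The retained insert
excludes all matched primer spans and is re-oriented forward-primer-first,
so downstream truncation of the "read tail" always removes the 3′
(reverse-primer-proximal) end.

Filter order is fixed and total: cut to the insert → reject < 200 nt
(too_short) or > 3,500 nt (too_long) → truncate to 1,550 nt → reject
arithmetic mean phred < 20 (low_quality). Mean phred is the arithmetic
mean of per-base scores, not the probability-space mean; with the default
quality emission of the simulator this distinction is what makes the
filter meaningful. Length filters apply to the trimmed insert, since the
thresholds describe insert biology rather than raw read length.

## Per-read classification

Real-time monitoring needs a classifier that is fast and stable rather
than maximally accurate, so the classic naive-Bayes k-mer formulation is
used with its conventional defaults: k = 8, 100 bootstrap resamples,
confidence cutoff 0.8. Presence/absence of distinct k-mers (not counts)
drives both the model and the read representation. With `N` taxa, `n(w)`
of which contain word `w`, and a taxon `t` backed by `M_t` reference
sequences:

    P(w)   = (n(w) + 0.5) / (N + 1)
    P(w|t) = (m(w) + P(w)) / (M_t + 1),   m(w) ∈ {0, 1}

`score(t) = Σ log P(w|t)` over the read's distinct k-mers; the winner is
the argmax, ties resolved to the lexicographically smallest tax_id and
flagged. Each bootstrap resample draws ⌈V/8⌉ of the read's V distinct
k-mers with replacement; per-rank confidence is the fraction of resamples
whose winner shares the best taxon's lineage *prefix* down to that rank,
which makes confidences non-increasing with depth by construction. The
assignment is truncated at the deepest rank reaching the cutoff; reads
that never reach it are pooled as unassigned. Reference k-mer sets include
reverse complements, so an orientation mistake upstream degrades scores
gracefully instead of zeroing them.

The conditional model is held as a dense (taxa × 4^k) log-probability
matrix — appropriate for the reference panels the monitor runs against
(tens to hundreds of taxa); a database of tens of thousands of lineages
would need a sparse presence representation instead, which is a known
limitation. Per-read determinism is guaranteed by seeding the bootstrap
RNG from a global seed XOR a CRC32 of the read id, which also makes
results independent of processing order.

## Rarefaction, Chao1, and the stop rule

For a species count vector (n₁…n_S), n = Σnᵢ:

- interpolation: `E[S(m)] = S − Σᵢ C(n−nᵢ, m)/C(n, m)`, evaluated with
  log-gamma differences for stability (absolute error ≲ 1e-4 species on
  the sizes tested);
- asymptote: bias-corrected Chao1 `Ŝ = S + f₁(f₁−1)/(2(f₂+1))`, the
  f₂+1 denominator avoiding division by zero; `Ŝ = S` when f₁ = 0;
- extrapolation to m > n: `S + f̂₀·[1 − (1 − f₁/(n·f̂₀+f₁))^{m−n}]` with
  `f̂₀ = Ŝ − S`, continuous at m = n and bounded by Chao1.

Only richness (Hill order q = 0) is monitored; Shannon/Simpson curves and
coverage-based stopping are out of scope. Accumulation windows are arrival
batches, not wall-clock intervals: one batch file is one "pore-scan".

The stop rule's thresholds were open choices (the rule's *shape* — a
multi-window plateau — is the given): a barcode/kingdom is saturated when,
over the last W = 3 windows, observed richness grew by ≤ 1 species **and**
the Chao1 asymptote by ≤ 1% relative; barcodes with < 500 cumulative reads
are "insufficient" rather than unsaturated. The run-level recommendation
stops when ≥ 50% of subject barcodes (controls excluded) are saturated for
*both* kingdoms — the stricter of the two possible readings — and reports
the least-accumulated barcodes, which are the ones that gate the decision.
All thresholds are configurable and logged. Confidence intervals on the
curves are deliberately omitted from the decision: point estimates drive
it.

## Real-time orchestration

The watcher polls the run directory (polling is the portable contract; no
filesystem-event backend is required), treats a file as complete when its
size is unchanged across two polls, and records a SHA-256 digest of every
processed file in a JSON ledger written atomically next to the output.
Restarting the watcher therefore never double-counts a batch, and
re-dropping identical files is a no-op. Files are processed in
(barcode, name) order, which together with per-read seeding makes the
streaming result bit-identical to a single offline pass — an invariant the
test suite asserts end-to-end. Unreadable or still-growing files are
skipped and retried on the next poll; the watcher never crashes on them.

## ITS database construction

UNITE-style headers carry `k__…;p__…;c__…;o__…;f__…;g__…;s__…` lineage
strings. Lineage identity is the exact normalized 7-rank tuple (prefixes
stripped, underscores to spaces); no fuzzy synonym merging is attempted.
Placeholder names (`unidentified`, `*_sp`, `Incertae sedis` variants) are
preserved verbatim but flagged uncertain, so they survive to output — as
they do in real mycobiome profiles. tax_ids are assigned 1-based over the
sorted lineage tuples, a pure function of the lineage set. Up to 10
representative sequences are kept per lineage (longest first): the k-mer
model needs sequence support, not the full redundant collection. The
export dialect is fixed — `taxonomy.tsv` with species-first columns after
tax_id, empty ranks preserved as empty fields, and `species_taxid.fasta`
with `tax_id:serial` headers — and is round-tripped bit-exactly in tests.
Only the fungal side is built; a stock bacterial database is assumed, but
the exporter is kingdom-agnostic.

## Reporting

Conformity ratios are printed at two decimals, half-up, in the orientation
of the expected mapping ("1:x" when the minor strain is listed first).
The genus roll-up adds genus-level assignments (e.g. "*Trichophyton* sp.")
to their strain's count before re-forming the ratio. The contamination
screen flags a negative-control taxon only when it is also *dominant*
(≥ 1% relative abundance, configurable) in at least one sample — the
pattern separating genuine community members from reagent contaminants.
Relative abundances are reported against both the assigned-only and the
total-read denominator, since which of the two a study means is often
ambiguous. The ≥ 0.01% lineage filter is implemented as a plot-ready
lineage-table export; cladogram rendering itself is out of scope.

## Synthetic data

The simulator emulates the study conditions, and its defaults are those
conditions: 25% ITS molar fraction (a 3:1 16S:ITS spike), bacterial
references ~1,450 nt and fungal ~550 nt with ±10% length jitter (two
length regimes reproducing the observed bimodality qualitatively, not
empirical length distributions), total per-base error 5% split
3/1/1 substitution/insertion/deletion (the ~95% median-accuracy regime),
a two-strain bacterial positive control at 1:4 and fungal at 2.7:1,
near-empty negative controls, log-normal (σ = 1) subject communities, and
4,000-read batch writes. Reference sequences are random DNA accepted under
a pairwise 8-mer Jaccard < 0.5 constraint, so taxa are k-mer-separable by
construction. Quality strings are emitted so the mean-phred filter has
teeth — erroneous bases draw low phred (mean 8) and correct bases high
(mean 25) — but they do not model basecaller calibration, homopolymer
artifacts, chimeras or barcode hopping. Passing tests on this generator
therefore demonstrates the pipeline's arithmetic, bookkeeping and decision
logic, not robustness to real nanopore error structure or to taxa with
shared k-mer content.

All generators are bit-reproducible under a fixed seed.

## Problem sizes

The test suite and the acceptance script run everything at desk scale, as
the package's own verification conditions: the segregation accuracy suite
uses 1,000 mixed reads at 5% error; the rarefaction oracle 20 random count
vectors (n ≤ 200) against 10,000 Monte-Carlo subsamples; the saturation
suite a 50-species community streamed in 4,000-read batches; and the
end-to-end run 12 barcodes (9 subjects, one positive control, one negative
control, one negative-control pool) × 10,000 reads with 50 bacterial and
20 fungal taxa. Cohort-scale quantities that depend on a real specimen
collection (millions of reads, hundreds of real species) are outside what
synthetic runs can or should reproduce.

## Known limitations

- Dense conditional matrix limits the classifier to modest reference
  panels (see above).
- No chimera detection; the workflow assumes upstream read splitting.
- The Emu-style table adapter reconstructs integer counts from relative
  abundances when no counts column is present (nominal 1e6 total).
- The watcher's completion heuristic (size stability across two polls) can
  be fooled by a writer that stalls longer than one poll interval and then
  appends; the digest ledger makes this at worst a skipped—then
  retried—file, never a double count.
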