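# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the simulator does and does not emulate, and
the design choices made where the design was genuinely open.

## Read selection model

A Pol III SINE transcript is full length: it starts at (or within a few
bases of) the subfamily consensus start and is sequenced from its first
nucleotide, because the library protocol ligates the 5′ adapter directly to
the (RppH-converted) 5′ end. Its RepeatMasker alignment therefore has the
read matching the **sense** strand of a SINE consensus with both the
1-based "position in query start" and "position in repeat start" columns
small. The filter retains alignments with both begins ≤ `max_tss_offset`
(default 5, i.e. allowed begins {1..5} — "within 5 bp" includes the exact
start, which is position 1 in RepeatMasker's coordinates). A read with
several passing alignments keeps the one with the highest Smith–Waterman
score, ties broken by lower divergence then lexicographic subfamily name —
a deterministic rule favouring the better-supported annotation.

Internal-control reads (5S rRNA, 5.8S rRNA, U2 snRNA) are fixed-length
molecules sequenced end to end, so their rule is stricter: sense strand,
both begin columns in {1, 2}, and both leftover columns ("query (left)",
"repeat (left)") ≤ 5. The TSS tally and the control tally are computed
independently from the same annotation stream; a read can appear in both.
Stock RepeatMasker libraries lack a 5.8S entry, so the package ships the
158-nt GenBank J01871.1 sequence (`melrna/data/5.8S_rRNA.fa`) to append to
the library. The U2 rule simply reuses the control rule; unlike the 5S/5.8S
rule it is a package convention, not an established one.

## RepeatMasker `.out` complement rows

For "C" (complement) rows the three repeat-coordinate columns print as
`(left) end begin`. The parser normalizes them so `repeat_begin` is always
the consensus position matched by the read's 5′-most base; on complement
hits that is the *higher* coordinate (the middle column), so complement
records carry `repeat_begin > repeat_end`. Downstream code never sees the
reversed column order. The TSS filter only accepts sense-strand rows, so
the normalization never affects retention.

## Adapter trimming

Matching is Hamming-style: for each candidate cut position `i` the adapter
prefix is compared without indels against `read[i:]`, the overlap must be
≥ `min_overlap` (default 3) and mismatches ≤ ⌊`max_error_rate` × overlap⌋
(default rate 0.1); `N` matches nothing; the leftmost acceptable cut wins,
so the insert ends at the first adapter occurrence. This is deliberately
simpler than cutadapt's edit-distance alignment: it is exactly verifiable
against a brute-force all-cut-positions scorer, and equivalent on data
without indel errors. Reads with no acceptable match are discarded (the
protocol guarantees real inserts carry the adapter); inserts shorter than
`min_insert_length` (default 15 nt — below that genome mapping is
meaningless) or empty are discarded as short.

## Locus quantification

Reads are binned by the number of reported perfect genomic alignments:
unique / 2–9 / 10–99 / ≥100 / unmapped, closed intervals. Only unique-bin
reads are counted; multi-mapped reads are excluded outright (no fractional
allocation) because their source locus is undecidable — their subfamily
information is already captured by the repeat annotation. All aligned SAM
records of a read count toward multiplicity whether or not they carry the
secondary flag, since mappers asked for all alignments differ in how they
mark them.

A unique read is assigned to the same-strand locus whose interval contains
the read's 5′ end, allowing the 5′ end to fall up to `max_tss_offset` bases
upstream of the locus 5′ boundary (mirroring the TSS filter's tolerance;
whether the original analysis allowed this slack is not documented, so it
is a package decision, configurable). Anchoring on the 5′ end rather than
mere overlap prevents misattribution at nested repeats. Among several
candidates, the locus whose 5′ boundary is nearest wins; distance ties go
to the smaller locus, then lexicographic id.

RPM is reads per million **5S rRNA** reads: `rpm = raw_count × 1e6 /
n_5S`. The 5S count reflects both sequencing depth and RppH conversion
efficiency, which per-million-total normalization would not. A zero 5S
count is a hard error — normalization is impossible, not zero.

The stand-alone test asks whether a weakly expressed locus might be debris
of a longer host transcript: it counts uniquely mapped reads **of any
origin** in the same orientation within 5 kb on each side of the locus
(locus body and its own assigned reads excluded; flanks truncate silently
at contig edges). Zero flank reads ⇒ stand-alone. "Poorly expressed"
defaults to 1–3 unique reads (the threshold is not standardized anywhere;
a small transparent integer is used, configurable).

Replicate agreement is Pearson's R over RPM values of loci expressed in at
least one replicate (scipy's estimator; NaN for < 2 loci or zero
variance). The locus-expression histogram bins log2(RPM) over expressed
loci with a separate leftmost bar for zero-count loci, so bar counts always
sum to the locus total.

## Terminator classification

`terminal_u_run` measures the maximal read suffix of T (U in RNA) that is
templated by genomic T on the read's strand. The 5-nt sense-strand window
starting at the U-run's template start (or immediately after the read's 3′
end when the run is empty — degraded or atypical ends must still classify
deterministically) is classified in fixed priority order:

| order | category | rule (positions are 1-based in the window) |
|---|---|---|
| 1 | T4 | positions 1–4 all T |
| 2 | T5_variant | exactly one non-T among positions 1–5 |
| 3 | T4_variant | exactly one non-T among positions 1–4 |
| 4 | T3 | positions 1–3 all T |
| 5 | T3_variant | exactly one non-T among positions 1–3 |
| 6 | T2 | positions 1–2 both T |
| 7 | other | — |

Rules are anchored at position 1 because the window is positioned by where
transcription stopped. The order is essential: `TTTCT` satisfies both
variant definitions and is a T5 variant. Two consequences of the anchored
priority order are worth stating: every `TTTx?` window (x ≠ T) is a T4
variant, so **T3 is unreachable**, and every `TT…` window is a T3 or T3
variant, so **T2 is unreachable**. Both categories remain in the enum for
completeness (membership over the 1024 windows: T4 4, T5v 12, T4v 36, T3 0,
T3v 108, T2 0, other 864). The 5-nt window length follows from the largest
named category (T5 variants); it is configurable. Windows truncated by a
contig edge or containing N classify as `other` and are flagged.

## Simulator

The simulator is the ground-truth oracle for the pipeline. It emulates:

* a random background genome (default 2 × 60 kb) with non-overlapping
  planted SINE copies (default 100 B1-like @ 135 nt + 100 B2-like @ 190 nt,
  synthetic consensuses with A-rich 3′ tails as real SINEs have), each
  mutated at a per-base substitution rate (default 0.03) and followed on
  its sense strand by a terminator window drawn from `terminator_mix`;
* per-locus expression: each locus is expressed with probability
  `fraction_expressed` (default 0.25 — chosen for test coverage; in vivo
  only ~1% of B1 loci are detectably expressed, and that regime is
  exercised explicitly in tests at n = 1000 loci), with counts from a
  discrete power law p(k) ∝ k^−α, α = 1.8, k ≤ 1000, reproducing the
  orders-of-magnitude spread of real locus expression;
* TSS offsets: 80% of transcripts start exactly at the locus 5′ end, the
  rest uniformly 1–8 nt downstream, so a predictable minority fails the ≤5
  filter;
* termination: each transcript ends inside its locus's planted tract,
  keeping 1–4 templated U's (uniform up to the tract's leading T-run; the
  reported U3 ends motivate short runs but no distribution is established).
  After mutation the last body base is forced non-T so the planted tract —
  not a mutated body base — defines where the U-run starts; without this
  ~1% of loci would shift the window by one base for bookkeeping rather
  than biological reasons;
* 5′ chemistry and RppH: SINE transcripts and 5S are triphosphate, U2 is
  capped, 5.8S and background fragments are monophosphate. With
  `rpph_enabled=False`, triphosphate/cap molecules are dropped *after*
  generation, so the RppH(−) library is read-for-read a subset of the
  RppH(+) library under the same seed;
* default `terminator_mix`: T4 0.31 (the reported share of canonical
  terminators) with the reported combined variant mass split over the
  reachable variant categories (T5v 0.13, T4v 0.13, T3v 0.10), remainder
  `other`; T3/T2 get zero mass since no window can classify there;
* gel size selection (113–253 nt inserts) and 3′ adapter ligation;
* control depths 5.8S 1000, 5S 300, U2 100 reads — echoing the real rank
  order (5.8S ≫ 5S > U2) at desk scale;
* genomic placements: the SAM lists *every* exact occurrence of each
  insert in the toy genome (true placement primary, others FLAG 256), so
  zero-divergence duplicated loci genuinely produce multi-mapped reads.

It does **not** emulate sequencing errors, quality-score structure, PCR
duplicates, indel divergence, aminoacylated tRNA chemistry, or a realistic
locus density: 200 loci in 120 kb is ~30× denser than a real genome, so
5-kb stand-alone flanks frequently contain *other* expressed loci and the
simulated stand-alone fraction is far below what sparse real genomes show.
Passing tests therefore demonstrate correctness of the bookkeeping and the
decision rules on known truth, not biological realism of any summary
statistic.

Control reads are annotated (they appear in the `.out`) but not genome-
mapped (unmapped SAM records), since the toy genome contains no rRNA/snRNA
genes; mapping-multiplicity statistics in the report are accordingly
computed over the TSS-selected SINE reads, which is also the population the
mapped-fraction statistics of the real workflow describe.

## Numerical and degenerate-input conventions

All internal coordinates are 0-based half-open; RepeatMasker and SAM
conventions are converted at the parser boundaries. Undefined ratios and
fractions (zero denominators, < 2 data points) return NaN sentinels, never
raise — except zero 5S reads in normalization, which is an error.
Terminator fractions sum to 1 exactly over nonempty inputs. Everything
downstream of a `SimConfig` seed is deterministic, including file bytes.

## Problem sizes

The default simulation (200 loci, ~1800 reads) runs the full pipeline in
under a second; the test suite, including the 200-locus end-to-end
recovery run, the 10,000-read trimmer oracle and the 1024-window
terminator enumeration, completes in a few seconds.
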