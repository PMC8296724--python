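# Methods

## Problem and scope

`hdrpipe` quantifies CRISPR/Cas9 editing outcomes in mosaic founder (F0)
animals from paired-end amplicon deep sequencing. A founder embryo injected
with Cas9, a guide RNA and a single-stranded oligodeoxynucleotide (ssODN)
donor is a mosaic of repair outcomes: unedited (wild-type) cells, cells
carrying the intended edit exactly (*perfect HDR*), cells carrying the edit
flanked by indels or mismatches in the homology region (*erroneous HDR*),
and cells with NHEJ indels at the cut. The pipeline turns raw paired FASTQ
into per-individual percentages of these classes and nonparametric group
comparisons, and ships a truth-known simulator so every stage is testable
without sequencing data.

## Locus model and donor design

A target locus is an amplicon (sense strand, beginning at the forward
gene-specific primer), a 20-nt SpCas9 protospacer with NGG PAM anchored on
it, and an analysis window given as 1-based inclusive positions on the
assembled read. Cut sites are 0-based gap indices; the blunt SpCas9 cut is
placed 3 bp 5' of the PAM (between protospacer positions 17 and 18), with
the rule overridable. Intended edits are either an insertion at the cut
(e.g. a FLAG tag plus a TAA stop) or a set of base substitutions (single
nucleotide replacement, SNR).

The asymmetric donor designer copies `arm_long` (default 90) nt on one side
of the cut and `arm_short` (default 36) nt on the other around the edit, on
the sense strand by default. Which side carries the long arm is genuinely
ambiguous in the source material; the default places 90 nt 5' of the cut,
and `long_arm_side="3p"` swaps it. Antisense polarity reverse-complements
the oligo and swaps the arm annotations, making polarity an involution.

## Expected alleles and classification

`build_expected_alleles` freezes, per locus and edit:

* `wt_window` / `hdr_window` — reference and edited sequence at the fixed
  window coordinates. For insertions the two windows have **equal length**:
  a read is trimmed at fixed positions, so the insert displaces reference
  bases past the window end rather than lengthening the window.
* `core` — the diagnostic edited segment: the full insert, or for
  substitutions a `2*anchor_k + span` k-mer centred on the substituted
  positions (`anchor_k` default 10; long enough to be unique in a ~200-nt
  window, short enough to survive nearby indels).
* junction anchors spanning the 5' and 3' edit boundaries.

Classification is a total, deterministic cascade: perfect HDR
(N-compatible equality with `hdr_window`), wild type (equality with
`wt_window`), erroneous HDR (core occurs N-compatibly as a substring),
otherwise `other`. N is always a wildcard — it encodes a masked
low-quality base, never a mismatch. Priority perfect > wild-type >
erroneous prevents the substring rule from shadowing exact matches.

Junction flags for HDR-class reads are asymmetric by construction: the
window is anchored at the read start, so the 5' flank is fully contained
and is compared positionally (core at its expected offset, prefix exactly
matching), while the 3' flank is compared over the attested overlap from
the core onward — a deletion 5' of the core shifts extra template bases
into the window tail without damaging 3' homology, and such a read is
5'-broken but 3'-perfect. An exhaustive oracle test checks the cascade
against an independent reference implementation on every sequence within
two edit operations of either window.

## Read processing

Stage order is fixed: demultiplex → length filter → pair merge → forward-
read rescue → window extraction → quality masking, with a ledger that
accounts for every input pair. Defaults are the standard analysis
settings: primer demultiplexing with ≤ 2 mismatches per primer and no
indels; minimum mate length 100 bp; ungapped merging with a per-locus
minimum forward/reverse overlap (150 bp for the slc45a2-type amplicon,
200 bp for dnd-type) accepting at most 20% mismatches in the overlap;
unmerged pairs contribute their forward read unchanged; bases below Q20
become N after windowing; reads with more than 5 N are dropped.

Merging picks, among all ungapped suffix/prefix overlaps of at least the
minimum length, the one with the most matching bases (ties to the longer
overlap); disagreeing positions take the higher-quality base (equal
quality: forward), and merged qualities are the per-base maximum. An
exact-overlap fast path and a per-sample overlap cache keyed on the mate
sequences make this linear in practice without changing semantics.

## Variant calling

Identical window sequences collapse into variants. Variants that differ
only at masked positions then merge: two groups are compatible when their
consensus sequences (informative base wherever any member has one) have no
position with two differing non-N bases and at most 5 positions where
exactly one has an N. Pairwise N-compatibility is not transitive, so the
merge follows a declared deterministic convention: groups sorted by
descending read count (lexicographic ties), each group makes one forward
scan absorbing compatible later groups, and passes repeat until a fixed
point. The representative sequence is the member with the fewest N (ties:
higher count, then lexicographic). Consensus-based comparison guarantees
no merged group ever contains conflicting informative bases; a pure-Python
reference implementation agrees on randomized fixtures. Finally only
variants with ≥ 100 supporting reads are retained, and their summed count
is the denominator for all percentages. Samples with no surviving variant
are flagged, not fatal.

## Synthetic data

The simulator emulates a MiSeq-style 2×250 amplicon run on a mosaic
embryo. Each individual is an allele mixture: wild type, perfect HDR,
one 5'-side and one 3'-side erroneous-HDR allele (edit plus a uniform
1–10 bp indel strictly on that side of the core, inside the window,
resampled if it would erode the core), and NHEJ alleles (uniform 1–15 bp
indel at the cut, split over 2 clones since an embryo carries several
independent NHEJ lineages). Reads draw alleles multinomially; substitution
errors are uniform at `per_base_error` (default 1e-3); base qualities are
two-level, `q_low` = 12 with probability `p_lowq` = 0.015 (a typical
below-Q20 base fraction for 2×250 runs) and `q_high` = 38 otherwise.
Indel sizes are uniform because no indel spectrum is assumed — the
least-assumption choice. Output is standard Phred+33 FASTQ plus a
truth table per read and per individual.

Cohorts draw per-individual perfect-HDR fractions from the Beta marginal
of a Dirichlet with a group mean and a single concentration
(dispersion) knob; the remaining classes scale with the leftover mass.
`stratified=True` replaces i.i.d. draws with one draw per equal-probability
quantile stratum (shuffled), a variance-reduction device that makes a
finite cohort's empirical mean and spread match the specified condition
closely; i.i.d. sampling remains the default. The built-in
`STUDY_GROUPS` conditions use concentrations moment-matched to each
group's stated mean and standard deviation (e.g. mean 0.136, sd 0.109
→ concentration ≈ 8.9). Per-individual streams are seeded by
(seed, group index, individual index), so adding a sample never perturbs
another's draws and equal seeds give byte-identical FASTQ.

What the simulator does **not** model: PCR duplicates and chimeras,
position-dependent MiSeq error profiles, adapter read-through, large
structural variants and donor concatemers, and real inter-individual
mosaicism structure (the Beta/Dirichlet family is an assumption). Passing
recovery tests therefore shows the pipeline is correct and unbiased under
this generative model, not that real libraries are free of such artefacts.

## Demo loci

The two bundled amplicons are synthetic stand-ins: random sequences
carrying the real gene-specific primer pairs and a valid protospacer/PAM
at a realistic position (the genomic amplicon sequences are not public).
The FLAG insert uses a standard DYKDDDDK codon choice plus TAA, and the
SNR edit substitutes three bases inside the protospacer — both stand-ins.
Amplicon lengths (300 and 280 nt) are chosen so 2×250 reads satisfy the
per-locus overlap thresholds for unedited templates; a 27-nt insertion at
the dnd-type locus pushes the template past the 200-bp overlap limit, so
its HDR reads exercise the forward-read rescue path, as a real +27 nt
knock-in amplicon would. Because rescued reads are single-coverage, a few
percent of them exceed the 5-N cap, a small real property of the
rescue-then-mask design (≈ −0.3 points on that group's perfect-HDR mean).

## Group statistics

D'Agostino–Pearson K² (scipy `normaltest`, requiring n ≥ 8) screens
normality; analysis then uses Kruskal–Wallis with tie correction plus
Dunn's post-hoc test (two-sided z on pooled tie-corrected ranks,
Bonferroni family-wise adjustment, configurable) with a compact letter
display for three or more groups, and Mann–Whitney (unpaired) or Wilcoxon
signed-rank (paired, zeros dropped) for two. Exact p-values are used for
tie-free inputs when n·m ≤ 10,000 (Mann–Whitney) or ≤ 25 non-zero pairs
(Wilcoxon); these thresholds are declared constants. Degenerate inputs
(all values identical, all differences zero) return H = 0 / p = 1 with a
note instead of raising. At n = m = 8 the exact and continuity-corrected
normal branches differ by up to ≈ 0.011 in p, so agreement is asserted at
a 0.02 band.

## Problem sizes and reproducibility

The test suite simulates cohorts at 4,000 read pairs per individual and
the acceptance script at 12,000 (20,000 for the slc45a2 knock-in cohort so
its ~2% erroneous class clears the 100-read support filter), both with the
full per-group sample sizes of the study conditions (n = 30/24/24/26/12).
At the lower depth the support filter truncates alleles below ~2.5% of
reads, which slightly deflates the smallest class percentages; this is a
property of the support-filter design, shared with any fixed-threshold
analysis, and is why the deeper run is used for reported numbers. All
randomness flows from a single seed through named SeedSequence spawns;
`scripts/acceptance.py --seed N --out f.json` is deterministic given N.
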