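# hdrpipe

Amplicon deep-sequencing analysis of CRISPR/Cas9 homology-directed repair
(HDR) outcomes in mosaic founder animals.

When a fertilised egg is injected with Cas9, a guide RNA and a
single-stranded oligonucleotide (ssODN) donor, the resulting founder (F0)
animal is a mosaic: some cells carry the intended edit exactly (**perfect
HDR**), some carry the edit flanked by indels or mismatches in the
homology arms (**erroneous HDR**), some carry NHEJ indels, and some stay
wild type. `hdrpipe` quantifies these classes per individual from
paired-end MiSeq-style amplicon reads and compares groups of individuals
(e.g. donor-concentration arms) nonparametrically. It is written for
researchers doing knock-in or single-nucleotide-replacement (SNR)
experiments in non-model animals, where every founder is a mixture and
"efficiency" means read fractions, not genotypes.

## What it does

* **Locus/donor model** — amplicon + guide (blunt SpCas9 cut 3 bp 5' of
  the PAM) + edit specification; designs asymmetric ssODN donors copying
  90 + 36 nt on each side of the cut around the insert or substituted
  bases, with configurable arm lengths, arm side and polarity.
* **Read processing** — primer demultiplexing, 100-bp length filter,
  ungapped pair merging (per-locus minimum overlap, ≤ 20% overlap
  mismatches, higher-quality base wins), rescue of unmerged forward
  reads, fixed-window trimming, Q20 masking to N with a 5-N cap per read.
* **Variant calling** — identical reads collapse to variants; variants
  differing only by ≤ 5 masked (N) positions merge, the least-masked
  member representing the group; variants need ≥ 100 supporting reads.
* **Classification** — each variant is perfect HDR, wild type, erroneous
  HDR (correct insert/SNR core present but flanks damaged) or other, with
  5'/3' junction-intactness flags; per-sample percentages of retained
  reads and per-group mean/sd/SEM/max.
* **Statistics** — D'Agostino–Pearson normality, Kruskal–Wallis + Dunn
  (Bonferroni) with compact letter display, Mann–Whitney and paired
  Wilcoxon, exact where feasible.
* **Simulation** — a truth-known generator of mosaic-embryo FASTQ cohorts
  (allele mixtures, 2×250 reads, quality/error model), used by the test
  suite and the acceptance script; see `docs/methods.md`.

## Worked example

Generate a small synthetic two-gene cohort and analyse it end to end:

```bash
hdrpipe demo --out demo_run --seed 3 --n-per-group 2 --read-pairs 800
```

This writes FASTQ, a sample sheet and a run config under `demo_run/`,
runs the pipeline, and prints per-group aggregates, e.g. (seed 3):

```
[
  {
    "group": "slc45a2_KI_1.5uM",
    "n": 2,
    "pct_perfect_mean": 12.838317851260042,
    "pct_perfect_std": 12.254784960052728,
    "pct_perfect_max": 21.50375939849624,
    ...
  },
  ...
]
```

`pct_perfect_mean` is the group's mean percentage of retained reads whose
whole analysis window matches the expected edited sequence; the
per-sample table (`demo_run/results/sample_summaries.tsv`) also reports
erroneous-HDR, wild-type and other percentages plus 5'/3'
junction-perfection percentages, and `demo_run/truth_*.tsv` holds the
simulated ground truth for comparison. Group comparisons:

```bash
hdrpipe stats demo_run/results/sample_summaries.tsv --value pct_perfect
```

prints the Kruskal–Wallis statistic, Dunn pairwise adjusted p-values and
compact significance letters.

The same flow is available as a library:

```python
from hdrpipe import analyze_pairs, ProcessParams
from hdrpipe.demo import DEMO_LOCI, MIN_OVERLAP

locus, edit = (f() for f in DEMO_LOCI["dnd_snr"])
result = analyze_pairs(pairs, locus, edit,
                       ProcessParams(min_overlap=MIN_OVERLAP[locus.name]))
print(result.summary.pct_perfect)
```

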