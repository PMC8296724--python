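"""Built-in demonstration loci and cohort conditions.

The amplicons below are *synthetic stand-ins*: randomly generated
sequences that carry the real gene-specific primer pairs at their ends and
a valid SpCas9 protospacer/PAM at a realistic position, but are not the
genomic slc45a2/dnd amplicons (whose full sequences are not public).  They
let the whole pipeline run end to end with truth-known data.

``STUDY_GROUPS`` encodes the experimental conditions the demo cohorts
emulate: per-group sample sizes and the mean/standard deviation of the
per-individual perfect-HDR read fraction, plus a mean erroneous-HDR
fraction, for each gene x ssODN-concentration group.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus_model import EditSpec, GuideRNA, TargetLocus

FLAG_TAA_INSERT = "GACTACAAGGACGACGATGACAAG" + "TAA"
"""Knock-in insert: a standard DNA encoding of the DYKDDDDK (FLAG) epitope
followed by a TAA stop codon.  Synthetic stand-in for the experimental
insert, whose exact codon usage is not public."""

# synthetic stand-in amplicon for the slc45a2 target (300 nt); real
# gene-specific primers, protospacer at 131-150 (+), PAM 151-153, cut gap 147
SLC45A2_AMPLICON = (
    "CAGATGTCCAGAGGCTGCTGCTCTTAGACTACACTGCTTTTCGATGCAGGCCCGGAGACCTATCAAGTTG"
    "ACTGACCGACAGCCGCTTCATGAACTCAAAAAGACTAGAAGCTCTCTTGACTACTGAAGATCGTCCGACC"
    "TTCGCTTGTTGGGCATTTTCGTCGCTAGAATCTTTTAGTGCCCGGATTAGGGCCTCCCAACAGGAGGTTC"
    "ACGGACTGCGTGCTACTCCGAGCTTATTCCCCCAGACAGCCGGACGAAGACAATCTGATGAGGAGCGGTG"
    "TACATTCTGAGGCTGTGGCA"
)

# synthetic stand-in amplicon for the dnd target (280 nt); real primers,
# protospacer at 141-160 (+), PAM 161-163, cut gap 157
DND_AMPLICON = (
    "GGGGAAAGGCTAGGGAGAGAACAGCAGAGAAACTGGGTGTATTCGACCCGGTCCATCCAATTAAGACTTA"
    "TGGTGACTTACAGTTGAGCCCAAAGCCGATCTAGGGAGTAGATGTGGGATTGCTGGAGCAAAAGTACAGC"
    "CCCTTACGCCTCCGGGCGAATGGAAGATGGATCTGCCCATTTGAGTCTCAGTGCTTAAAACCTTGATGAC"
    "TGCGGGGGACTAGCCGGAATTATCTCTCTGAAAAGTCGTCTCAAAAAGAGAACTTCAGCGGACAGAACCG"
)


def slc45a2_locus() -> TargetLocus:
    """slc45a2-like FLAG knock-in locus (window 20-200, merge overlap 150)."""
    return TargetLocus(
        name="slc45a2",
        amplicon=SLC45A2_AMPLICON,
        fwd_primer="CAGATGTCCAGAGGCTGCTGCT",
        rev_primer="TGCCACAGCCTCAGAATGTACA",
        window=(20, 200),
        guide=GuideRNA(
            protospacer="TCGTCCGACCTTCGCTTGTT", pam="GGG", strand="+", start=131
        ),
    )


def dnd_locus() -> TargetLocus:
    """dnd-like locus (window 60-230, merge overlap 200)."""
    return TargetLocus(
        name="dnd",
        amplicon=DND_AMPLICON,
        fwd_primer="GGGGAAAGGCTAGGGAGAGA",
        rev_primer="CGGTTCTGTCCGCTGAAGTT",
        window=(60, 230),
        guide=GuideRNA(
            protospacer="CCCTTACGCCTCCGGGCGAA", pam="TGG", strand="+", start=141
        ),
    )


def flag_ki_edit() -> EditSpec:
    """FLAG + stop-codon insertion at the cut site."""
    return EditSpec(kind="insertion", insert=FLAG_TAA_INSERT)


def dnd_snr_edit() -> EditSpec:
    """Three-base substitution introducing a premature stop near the cut."""
    return EditSpec(
        kind="substitution", substitutions=((155, "T"), (156, "A"), (157, "A"))
    )


DEMO_LOCI = {
    "slc45a2_flag_ki": (slc45a2_locus, flag_ki_edit),
    "dnd_flag_ki": (dnd_locus, flag_ki_edit),
    "dnd_snr": (dnd_locus, dnd_snr_edit),
}

# the per-locus minimum forward/reverse overlap used during read merging
MIN_OVERLAP = {"slc45a2": 150, "dnd": 200}


@dataclass(frozen=True)
class GroupCondition:
    """Experimental condition for one gene x ODN-concentration group."""

    label: str
    locus_key: str  # key into DEMO_LOCI
    odn_uM: float
    n_individuals: int
    mean_perfect: float  # mean per-individual perfect-HDR read fraction
    std_perfect: float  # inter-individual standard deviation of the same
    mean_erroneous: float  # mean erroneous-HDR read fraction
    mean_nhej: float = 0.35  # mean NHEJ-indel read fraction (remainder is WT)
    indel_bias_5p: float = 0.75  # share of erroneous-HDR indels on the 5' side


# Group-level conditions for the demo cohorts: gene, concentration, number
# of sequenced individuals, and the group mean/std of the per-individual
# perfect-HDR percentage (values as fractions of retained reads).
STUDY_GROUPS: tuple[GroupCondition, ...] = (
    GroupCondition("slc45a2_KI_1.5uM", "slc45a2_flag_ki", 1.5, 30, 0.136, 0.109, 0.020),
    GroupCondition("dnd_KI_1.5uM", "dnd_flag_ki", 1.5, 24, 0.076, 0.101, 0.015),
    GroupCondition("dnd_SNR_0.15uM", "dnd_snr", 0.15, 24, 0.074, 0.148, 0.015),
    GroupCondition("dnd_SNR_1.5uM", "dnd_snr", 1.5, 26, 0.125, 0.143, 0.020),
    GroupCondition("dnd_SNR_4uM", "dnd_snr", 4.0, 12, 0.074, 0.094, 0.015),
)
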