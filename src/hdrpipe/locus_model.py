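"""Target-locus model: amplicon, guide, intended edit, and donor design.

Coordinate conventions (used consistently across the package):

* analysis windows are 1-based inclusive positions on the assembled read,
  whose position 1 is the first base of the forward gene-specific primer
  (reads begin at the primer, so read and amplicon coordinates coincide
  for reads without upstream indels);
* cut sites are 0-based *gap* indices on the amplicon: gap ``g`` sits
  between 1-based positions ``g`` and ``g + 1``.

The donor designer copies unequal homology arms (by default 90 nt on the
5' side and 36 nt on the 3' side of the blunt SpCas9 cut) around the
intended edit, which is either an insertion at the cut or a set of base
substitutions inside the arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .sequtil import is_dna, revcomp


class LocusValidationError(ValueError):
    """Raised when a locus/guide/edit configuration is internally inconsistent."""


class DonorDesignError(ValueError):
    """Raised when the amplicon cannot supply the requested homology arms."""


@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt SpCas9 protospacer with its PAM, anchored on the amplicon.

    ``start`` is the 1-based leftmost amplicon position of the protospacer
    footprint regardless of strand; for a minus-strand guide the amplicon
    carries the reverse complement of the protospacer at that footprint and
    the PAM lies immediately 5' of it on the amplicon (as ``CCN`` reverse
    complement).
    """

    protospacer: str
    pam: str
    strand: str  # "+" or "-" relative to the amplicon sense strand
    start: int

    def __post_init__(self):
        if len(self.protospacer) != 20 or not is_dna(self.protospacer):
            raise LocusValidationError("protospacer must be a 20-nt DNA string")
        if len(self.pam) != 3 or not is_dna(self.pam):
            raise LocusValidationError("PAM must be a 3-nt DNA string")
        if self.strand not in ("+", "-"):
            raise LocusValidationError("guide strand must be '+' or '-'")
        if self.start < 1:
            raise LocusValidationError("guide start must be a positive 1-based position")


@dataclass(frozen=True)
class TargetLocus:
    """Reference amplicon with primers, analysis window, and guide."""

    name: str
    amplicon: str
    fwd_primer: str
    rev_primer: str  # as sequenced: reverse complement of the amplicon tail
    window: tuple[int, int]  # 1-based inclusive on the assembled read
    guide: GuideRNA

    def __post_init__(self):
        if not is_dna(self.amplicon):
            raise LocusValidationError(f"{self.name}: amplicon must be ACGT only")
        if not self.amplicon.startswith(self.fwd_primer):
            raise LocusValidationError(
                f"{self.name}: amplicon must start with the forward primer")
        if not self.amplicon.endswith(revcomp(self.rev_primer)):
            raise LocusValidationError(
                f"{self.name}: reverse complement of the reverse primer must be "
                "a suffix of the amplicon")
        ws, we = self.window
        if not (1 <= ws < we <= len(self.amplicon)):
            raise LocusValidationError(f"{self.name}: invalid window {self.window}")
        self._validate_guide()
        cut = locate_cut_site(self)
        if not (ws <= cut < we):
            raise LocusValidationError(
                f"{self.name}: cut site (gap {cut}) must lie strictly inside "
                f"the window {self.window}")

    def _validate_guide(self) -> None:
        g = self.guide
        s0 = g.start - 1
        footprint = self.amplicon[s0:s0 + 20]
        if g.strand == "+":
            pam = self.amplicon[s0 + 20:s0 + 23]
            if footprint != g.protospacer:
                raise LocusValidationError(
                    f"{self.name}: protospacer not found on + strand at {g.start}")
            if len(pam) != 3 or pam != g.pam:
                raise LocusValidationError(
                    f"{self.name}: PAM mismatch 3' of the protospacer")
        else:
            pam = self.amplicon[s0 - 3:s0] if s0 >= 3 else ""
            if footprint != revcomp(g.protospacer):
                raise LocusValidationError(
                    f"{self.name}: protospacer reverse complement not found at {g.start}")
            if pam != revcomp(g.pam):
                raise LocusValidationError(
                    f"{self.name}: PAM mismatch 5' of the minus-strand footprint")

    @property
    def window_length(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass(frozen=True)
class EditSpec:
    """The intended HDR edit: an insertion at the cut or base substitutions.

    ``substitutions`` holds (1-based amplicon position, new base) pairs.
    """

    kind: str  # "insertion" | "substitution"
    insert: str = ""
    substitutions: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == "insertion":
            if not self.insert or not is_dna(self.insert):
                raise LocusValidationError("insertion edit requires a non-empty DNA insert")
            if self.substitutions:
                raise LocusValidationError("insertion edit cannot carry substitutions")
        elif self.kind == "substitution":
            if not self.substitutions:
                raise LocusValidationError("substitution edit requires at least one position")
            if self.insert:
                raise LocusValidationError("substitution edit cannot carry an insert")
            positions = [p for p, _ in self.substitutions]
            if len(set(positions)) != len(positions):
                raise LocusValidationError("duplicate substitution positions")
        else:
            raise LocusValidationError(f"unknown edit kind {self.kind!r}")

    def validate_for(self, locus: TargetLocus) -> None:
        ws, we = locus.window
        if self.kind == "substitution":
            for pos, base in self.substitutions:
                if not (ws <= pos <= we):
                    raise LocusValidationError(
                        f"substitution at {pos} outside window {locus.window}")
                if locus.amplicon[pos - 1] == base:
                    raise LocusValidationError(
                        f"substitution at {pos} equals the reference base {base}")

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive amplicon span of substituted positions."""
        if self.kind != "substitution":
            raise ValueError("span is defined for substitution edits only")
        positions = [p for p, _ in self.substitutions]
        return min(positions), max(positions)


@dataclass(frozen=True)
class DonorODN:
    """Single-stranded oligonucleotide donor with unequal homology arms.

    ``arm5``/``arm3`` are homology-arm lengths 5' and 3' of the edited
    segment *on the oligo as written*; flipping polarity therefore swaps
    them along with reverse-complementing the sequence.
    """

    sequence: str
    arm5: int
    arm3: int
    polarity: str  # "sense" | "antisense" relative to the amplicon sense strand

    def __post_init__(self):
        if self.polarity not in ("sense", "antisense"):
            raise LocusValidationError("polarity must be 'sense' or 'antisense'")

    def flipped(self) -> "DonorODN":
        """The same donor written on the opposite strand."""
        return DonorODN(
            sequence=revcomp(self.sequence),
            arm5=self.arm3,
            arm3=self.arm5,
            polarity="antisense" if self.polarity == "sense" else "sense",
        )


@dataclass(frozen=True)
class ExpectedAlleles:
    """Window-level reference sequences and junction anchors for classification.

    ``core`` is the diagnostic edited segment: the full insert for an
    insertion, or a ``2*anchor_k + span`` k-mer centred on the substituted
    positions.  ``core_start`` is its 0-based offset within ``hdr_window``.
    ``anchor5``/``anchor3`` are k-mers spanning the 5' and 3' edit
    junctions (ending at the first edited base / starting at the last).
    """

    wt_window: str
    hdr_window: str
    anchor5: str
    anchor3: str
    core: str
    core_start: int

    @property
    def core_end(self) -> int:
        """0-based exclusive end of the core within hdr_window."""
        return self.core_start + len(self.core)


def locate_cut_site(locus: TargetLocus) -> int:
    """Blunt SpCas9 cut site as a 0-based gap index on the amplicon.

    SpCas9 cleaves 3 bp 5' of the PAM (between protospacer positions 17
    and 18); for minus-strand guides the gap is mirrored into sense-strand
    coordinates.
    """
    g = locus.guide
    if g.strand == "+":
        # gap after 1-based amplicon position start+16
        return g.start + 16
    # minus strand: PAM-proximal end of the footprint is its left edge
    return g.start + 2


def apply_edit(locus: TargetLocus, edit: EditSpec) -> str:
    """The full edited amplicon (perfect-HDR allele)."""
    edit.validate_for(locus)
    amp = locus.amplicon
    if edit.kind == "insertion":
        cut = locate_cut_site(locus)
        return amp[:cut] + edit.insert + amp[cut:]
    seq = list(amp)
    for pos, base in edit.substitutions:
        seq[pos - 1] = base
    return "".join(seq)


def design_asymmetric_odn(
    locus: TargetLocus,
    edit: EditSpec,
    arm_long: int = 90,
    arm_short: int = 36,
    polarity: str = "sense",
    long_arm_side: str = "5p",
) -> DonorODN:
    """Design an asymmetric ssODN copying ``arm_long`` + ``arm_short``
    nucleotides on each side of the CRISPR cut site around the edit.

    The long arm sits 5' of the cut on the sense-strand donor by default
    (``long_arm_side="3p"`` swaps the arms).  For substitution edits the
    edited bases are applied in place inside the arms and the donor spans
    ``arm5 + arm3`` bases around the cut.
    """
    if long_arm_side not in ("5p", "3p"):
        raise DonorDesignError("long_arm_side must be '5p' or '3p'")
    arm5, arm3 = (arm_long, arm_short) if long_arm_side == "5p" else (arm_short, arm_long)
    edit.validate_for(locus)
    cut = locate_cut_site(locus)
    amp = locus.amplicon
    if cut - arm5 < 0 or cut + arm3 > len(amp):
        raise DonorDesignError(
            f"{locus.name}: amplicon provides only {cut}/{len(amp) - cut} nt "
            f"around the cut; {arm5}+{arm3} requested")
    if edit.kind == "insertion":
        seq = amp[cut - arm5:cut] + edit.insert + amp[cut:cut + arm3]
    else:
        lo, hi = cut - arm5, cut + arm3  # 0-based half-open on the amplicon
        chars = list(amp[lo:hi])
        for pos, base in edit.substitutions:
            if not (lo < pos <= hi):
                raise DonorDesignError(
                    f"substitution at {pos} falls outside the donor arms")
            chars[pos - 1 - lo] = base
        seq = "".join(chars)
    donor = DonorODN(sequence=seq, arm5=arm5, arm3=arm3, polarity="sense")
    return donor if polarity == "sense" else donor.flipped()


def build_expected_alleles(
    locus: TargetLocus, edit: EditSpec, anchor_k: int = 10
) -> ExpectedAlleles:
    """Window-level expected wild-type and perfect-HDR sequences plus the
    diagnostic core and junction anchors used by the classifier.

    Both windows are read at the fixed window coordinates, so for an
    insertion the HDR window has the same length as the wild-type window:
    the insert displaces reference bases past the window end, exactly as it
    does on an assembled read trimmed at fixed positions.
    """
    ws, we = locus.window
    edit.validate_for(locus)
    wt_window = locus.amplicon[ws - 1:we]
    edited = apply_edit(locus, edit)
    hdr_window = edited[ws - 1:we]
    w0 = ws - 1  # 0-based window offset on the (edited) amplicon

    if edit.kind == "insertion":
        cut = locate_cut_site(locus)
        core = edit.insert
        core_start = cut - w0
        core_end_amp = cut + len(core)  # on the edited amplicon
        if core_start < anchor_k or core_end_amp + anchor_k > we:
            raise LocusValidationError(
                "window too small to contain the insert plus junction anchors")
        anchor5 = edited[cut - anchor_k + 1:cut + 1]
        anchor3 = edited[core_end_amp - 1:core_end_amp - 1 + anchor_k]
    else:
        lo, hi = edit.span  # 1-based inclusive on the amplicon
        core_lo = lo - 1 - anchor_k  # 0-based on the edited amplicon
        core_hi = hi + anchor_k
        if core_lo < w0 or core_hi > we:
            raise LocusValidationError(
                "window too small to contain the substitution context k-mer")
        core = edited[core_lo:core_hi]
        core_start = core_lo - w0
        anchor5 = edited[lo - anchor_k:lo]
        anchor3 = edited[hi - 1:hi - 1 + anchor_k]

    if wt_window == hdr_window:
        raise LocusValidationError("edit has no effect inside the window")
    if core not in hdr_window[core_start:core_start + len(core)]:
        raise AssertionError("core must occur at core_start in hdr_window")
    if core in wt_window:
        raise LocusValidationError(
            "diagnostic core occurs in the wild-type window; increase anchor_k "
            "or revise the edit")
    return ExpectedAlleles(
        wt_window=wt_window,
        hdr_window=hdr_window,
        anchor5=anchor5,
        anchor3=anchor3,
        core=core,
        core_start=core_start,
    )


def infer_donor_arms(donor: DonorODN, locus: TargetLocus, edit: EditSpec) -> tuple[int, int]:
    """Re-derive (arm5, arm3) of a sense-strand donor by matching it back
    to the edited amplicon around the cut site.  Used as a self-check."""
    d = donor if donor.polarity == "sense" else donor.flipped()
    edited = apply_edit(locus, edit)
    start = edited.find(d.sequence)
    if start < 0:
        raise DonorDesignError("donor does not align to the edited amplicon")
    cut = locate_cut_site(locus)
    if edit.kind == "insertion":
        arm5 = cut - start
        arm3 = len(d.sequence) - arm5 - len(edit.insert)
    else:
        arm5 = cut - start
        arm3 = len(d.sequence) - arm5
    return arm5, arm3


# ---------------------------------------------------------------------------
# configuration I/O


def read_amplicon_fasta(path: str | Path, name: str | None = None) -> str:
    """First (or named) record of a FASTA file, upper-cased."""
    for record in SeqIO.parse(str(path), "fasta"):
        if name is None or record.id == name:
            return str(record.seq).upper()
    raise LocusValidationError(f"no record {name!r} in {path}")


def locus_from_config(cfg: dict, base_dir: str | Path = ".") -> tuple[TargetLocus, EditSpec]:
    """Build (TargetLocus, EditSpec) from one locus configuration mapping.

    Expected keys: name, amplicon (inline string) or fasta (path),
    fwd_primer, rev_primer, guide {protospacer, pam, strand, start},
    window {start, end}, edit {kind, insert | substitutions}.
    """
    if "amplicon" in cfg:
        amplicon = cfg["amplicon"].upper()
    else:
        amplicon = read_amplicon_fasta(Path(base_dir) / cfg["fasta"], cfg.get("fasta_record"))
    guide = GuideRNA(
        protospacer=cfg["guide"]["protospacer"].upper(),
        pam=cfg["guide"]["pam"].upper(),
        strand=str(cfg["guide"]["strand"]),
        start=int(cfg["guide"]["start"]),
    )
    locus = TargetLocus(
        name=cfg["name"],
        amplicon=amplicon,
        fwd_primer=cfg["fwd_primer"].upper(),
        rev_primer=cfg["rev_primer"].upper(),
        window=(int(cfg["window"]["start"]), int(cfg["window"]["end"])),
        guide=guide,
    )
    e = cfg["edit"]
    if e["kind"] == "insertion":
        edit = EditSpec(kind="insertion", insert=e["insert"].upper())
    else:
        edit = EditSpec(
            kind="substitution",
            substitutions=tuple((int(p), b.upper()) for p, b in e["substitutions"]),
        )
    edit.validate_for(locus)
    return locus, edit


def load_locus_yaml(path: str | Path) -> tuple[TargetLocus, EditSpec]:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return locus_from_config(cfg, base_dir=path.parent)
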