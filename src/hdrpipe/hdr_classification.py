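"""Editing-outcome classification and per-sample summaries.

Each retained variant gets exactly one label by a fixed cascade:

1. **perfect_hdr** — N-compatibly equal to the expected edited window
   (every informative base matches, same length);
2. **wild_type** — N-compatibly equal to the reference window;
3. **erroneous_hdr** — carries the diagnostic core (the full insert, or
   the substitution context k-mer) as an N-compatible substring, but fails
   1-2: the edit arrived, flanked by mismatches or indels;
4. **other** — everything else (NHEJ indels, partial integrations, noise).

N is a wildcard throughout: it encodes a masked low-quality base, not a
mismatch.  For HDR-class variants two junction flags record whether the
5'- and 3'-side of the core are individually intact.  The window is
anchored at the read start, so the 5' flank is fully contained and is
compared positionally (the core must sit at its expected offset with an
exactly matching prefix), while the 3' flank is compared over the attested
overlap from the core onward — a deletion 5' of the core shifts trailing
template bases into the window without disturbing the 3' homology itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus_model import ExpectedAlleles
from .sequtil import n_compatible, n_find_all
from .variant_calling import Variant

CLASS_LABELS = ("perfect_hdr", "erroneous_hdr", "wild_type", "other")


@dataclass(frozen=True)
class VariantCall:
    variant: Variant
    label: str
    perfect_5p: bool = False
    perfect_3p: bool = False

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.label == "perfect_hdr" and not (self.perfect_5p and self.perfect_3p):
            raise ValueError("perfect HDR implies both junctions intact")
        if self.label in ("wild_type", "other") and (self.perfect_5p or self.perfect_3p):
            raise ValueError("junction flags are defined for HDR classes only")


def _prefix_ok(seq: str, j: int, expected: ExpectedAlleles) -> bool:
    # 5' side: core at its expected offset and a positionally intact prefix
    if j != expected.core_start:
        return False
    return n_compatible(seq[:j], expected.hdr_window[: expected.core_start])


def _suffix_ok(seq: str, j: int, expected: ExpectedAlleles) -> bool:
    # 3' side: from the core start onward, over the attested overlap
    var_tail = seq[j:]
    hdr_tail = expected.hdr_window[expected.core_start:]
    k = min(len(var_tail), len(hdr_tail))
    return n_compatible(var_tail[:k], hdr_tail[:k])


def classify_variant(variant: Variant, expected: ExpectedAlleles) -> VariantCall:
    """Assign one outcome label plus 5'/3' junction flags to a variant."""
    seq = variant.sequence
    if n_compatible(seq, expected.hdr_window):
        return VariantCall(variant, "perfect_hdr", perfect_5p=True, perfect_3p=True)
    if n_compatible(seq, expected.wt_window):
        return VariantCall(variant, "wild_type")
    occurrences = n_find_all(expected.core, seq)
    if occurrences:
        p5 = any(_prefix_ok(seq, j, expected) for j in occurrences)
        p3 = any(_suffix_ok(seq, j, expected) for j in occurrences)
        return VariantCall(variant, "erroneous_hdr", perfect_5p=p5, perfect_3p=p3)
    return VariantCall(variant, "other")


@dataclass(frozen=True)
class SampleSummary:
    """Per-individual class percentages over retained reads."""

    sample_id: str
    group: str
    denominator: int
    pct_perfect: float
    pct_erroneous: float
    pct_wild_type: float
    pct_other: float
    pct_perfect_5p: float
    pct_perfect_3p: float

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group,
            "denominator": self.denominator,
            "pct_perfect": self.pct_perfect,
            "pct_erroneous": self.pct_erroneous,
            "pct_wild_type": self.pct_wild_type,
            "pct_other": self.pct_other,
            "pct_perfect_5p": self.pct_perfect_5p,
            "pct_perfect_3p": self.pct_perfect_3p,
        }


def summarize_sample(
    calls: list[VariantCall], denominator: int, sample_id: str = "", group: str = ""
) -> SampleSummary:
    """Read-count percentages per class; junction percentages count
    perfect- and erroneous-HDR reads whose respective side is intact, over
    the same retained-read denominator as the class percentages."""
    if denominator <= 0:
        raise ValueError("denominator must be positive; flag the sample instead")
    by_class = dict.fromkeys(CLASS_LABELS, 0)
    side5 = side3 = 0
    for c in calls:
        by_class[c.label] += c.variant.read_count
        if c.label in ("perfect_hdr", "erroneous_hdr"):
            if c.perfect_5p:
                side5 += c.variant.read_count
            if c.perfect_3p:
                side3 += c.variant.read_count
    pct = {k: 100.0 * v / denominator for k, v in by_class.items()}
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        denominator=denominator,
        pct_perfect=pct["perfect_hdr"],
        pct_erroneous=pct["erroneous_hdr"],
        pct_wild_type=pct["wild_type"],
        pct_other=pct["other"],
        pct_perfect_5p=100.0 * side5 / denominator,
        pct_perfect_3p=100.0 * side3 / denominator,
    )


PCT_COLUMNS = ("pct_perfect", "pct_erroneous", "pct_wild_type", "pct_other",
               "pct_perfect_5p", "pct_perfect_3p")


def summaries_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])


def aggregate_groups(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Per-group descriptive statistics (n, mean, sample std, SEM, max)
    of each percentage column over individuals."""
    df = summaries_frame(summaries)
    out_rows = []
    for group, sub in df.groupby("group", sort=False):
        n = len(sub)
        row: dict = {"group": group, "n": n}
        for col in PCT_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            std = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_std"] = std
            row[f"{col}_sem"] = std / np.sqrt(n) if n > 1 else 0.0
            row[f"{col}_max"] = float(vals.max())
        out_rows.append(row)
    return pd.DataFrame(out_rows)
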