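"""Small DNA-string helpers shared across the pipeline.

All sequences are upper-case strings over ``ACGT`` plus ``N`` for masked
(low-quality) bases.  ``N`` is a wildcard: it encodes "base unknown", never
"base mismatched", so two sequences are considered compatible wherever at
least one of them carries an ``N``.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return bool(seq) and set(seq) <= alphabet


def n_compatible(a: str, b: str) -> bool:
    """True if the strings have equal length and no position where both
    carry differing non-N bases."""
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def n_mismatch_positions(a: str, b: str) -> list[int]:
    """Positions where both strings carry non-N bases that differ."""
    return [i for i, (x, y) in enumerate(zip(a, b))
            if x != y and x != "N" and y != "N"]


def n_only_diff_count(a: str, b: str) -> int:
    """Number of positions where exactly one of the strings has an N."""
    return sum((x == "N") != (y == "N") for x, y in zip(a, b))


def n_find_all(needle: str, haystack: str) -> list[int]:
    """All start indices where ``needle`` occurs N-compatibly in ``haystack``.

    Falls back to plain substring search when neither string contains N,
    which is the overwhelmingly common case on real reads.
    """
    k, n = len(needle), len(haystack)
    if k == 0 or k > n:
        return []
    if "N" not in needle and "N" not in haystack:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    return [i for i in range(n - k + 1)
            if n_compatible(needle, haystack[i:i + k])]
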