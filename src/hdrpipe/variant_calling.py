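"""Collapse masked window reads into supported variants.

Identical window sequences are grouped into variants; variants that differ
only at N (masked) positions — never at two informative bases — are then
merged, up to a budget of 5 N-only differences per comparison, and the
member with the fewest N becomes the representative.  Pairwise
N-compatibility is not transitive, so merging follows a fixed greedy order
(descending read count, then lexicographic) and compares the group
*consensus* sequences, which guarantees that no merged group ever contains
two conflicting informative bases.  Finally, only variants supported by at
least 100 reads are retained; their summed count is the per-sample
denominator for all percentages downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_processing import ProcessedRead


@dataclass(frozen=True)
class Variant:
    """A collapsed read sequence (possibly containing N) with support."""

    sequence: str
    read_count: int
    member_ids: tuple[str, ...]

    def __post_init__(self):
        if self.read_count != len(self.member_ids) or self.read_count < 1:
            raise ValueError("read_count must equal the number of member reads")

    @property
    def n_count(self) -> int:
        return self.sequence.count("N")


def collapse_identical(reads: list[ProcessedRead]) -> list[Variant]:
    """One variant per distinct window sequence; counts conserve reads."""
    lengths = {len(r.window_seq) for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths after trimming: {sorted(lengths)}")
    members: dict[str, list[str]] = {}
    for r in reads:
        members.setdefault(r.window_seq, []).append(r.id)
    variants = [Variant(seq, len(ids), tuple(ids)) for seq, ids in members.items()]
    variants.sort(key=lambda v: (-v.read_count, v.sequence))
    return variants


def merge_n_compatible(variants: list[Variant], max_n_diff: int = 5) -> list[Variant]:
    """Merge variants differing only by up to ``max_n_diff`` masked bases.

    Greedy passes in descending read-count order repeat until no merge
    applies; each group is represented during merging by its consensus
    (informative base wherever any member has one), and two N-free
    consensuses can never merge, which keeps the scan linear in the number
    of N-containing variants.  The final representative sequence of a
    group is the member with the fewest N (ties: higher read count, then
    lexicographic).
    """
    if not variants:
        return []
    if len({len(v.sequence) for v in variants}) > 1:
        raise ValueError("variants must share one window length")

    # consensus matrix: 0 encodes N, other values are base ASCII codes
    mat = np.frombuffer("".join(v.sequence for v in variants).encode(),
                        dtype=np.uint8).reshape(len(variants), -1).copy()
    mat[mat == ord("N")] = 0
    counts = np.array([v.read_count for v in variants], dtype=np.int64)
    members: list[list[int]] = [[i] for i in range(len(variants))]
    alive = np.ones(len(variants), dtype=bool)

    def consensus_str(row: np.ndarray) -> str:
        out = row.copy()
        out[out == 0] = ord("N")
        return out.tobytes().decode()

    def mergeable_with(ci: np.ndarray, idx: np.ndarray) -> np.ndarray:
        sub = mat[idx]
        conflict = ((sub != ci) & (sub != 0) & (ci != 0)).any(axis=1)
        ndiff = ((sub == 0) != (ci == 0)).sum(axis=1)
        return idx[~conflict & (ndiff <= max_n_diff)]

    changed = True
    while changed:
        changed = False
        order = sorted(np.flatnonzero(alive),
                       key=lambda k: (-counts[k], consensus_str(mat[k])))
        order_arr = np.array(order, dtype=int)
        for pos, i in enumerate(order):
            if not alive[i]:
                continue
            tail = order_arr[pos + 1:]
            start = 0  # single forward scan over the tail, as documented
            while start < tail.size:
                cand = tail[start:]
                cand = cand[alive[cand]]
                if cand.size == 0:
                    break
                ci = mat[i]
                if (ci != 0).all():
                    # an N-free consensus never changes while absorbing; only
                    # N-containing groups (or a filled consensus identical to
                    # this one) can merge into it: take all at once
                    cand = cand[(mat[cand] == 0).any(axis=1)
                                | (mat[cand] == ci).all(axis=1)]
                    for j in mergeable_with(ci, cand):
                        counts[i] += counts[j]
                        members[i].extend(members[j])
                        alive[j] = False
                        changed = True
                    break
                hits = mergeable_with(ci, cand)
                if hits.size == 0:
                    break
                # absorb the first hit, let it fill N positions, then keep
                # scanning forward from the next tail position
                j = int(hits[0])
                fill = (mat[i] == 0) & (mat[j] != 0)
                mat[i, fill] = mat[j, fill]
                counts[i] += counts[j]
                members[i].extend(members[j])
                alive[j] = False
                changed = True
                start = int(np.nonzero(tail == j)[0][0]) + 1

    out = []
    for i in np.flatnonzero(alive):
        group = [variants[k] for k in members[i]]
        rep = min(group, key=lambda v: (v.n_count, -v.read_count, v.sequence))
        ids = tuple(rid for v in group for rid in v.member_ids)
        out.append(Variant(rep.sequence, int(counts[i]), ids))
    out.sort(key=lambda v: (-v.read_count, v.sequence))
    return out


@dataclass(frozen=True)
class SupportFilterResult:
    retained: tuple[Variant, ...]
    denominator: int  # Σ read_count of retained variants
    dropped_variants: int
    dropped_reads: int

    @property
    def no_callable_variants(self) -> bool:
        return not self.retained


def filter_support(variants: list[Variant], min_reads: int = 100) -> SupportFilterResult:
    """Retain variants with at least ``min_reads`` supporting reads."""
    retained = tuple(v for v in variants if v.read_count >= min_reads)
    dropped = [v for v in variants if v.read_count < min_reads]
    return SupportFilterResult(
        retained=retained,
        denominator=sum(v.read_count for v in retained),
        dropped_variants=len(dropped),
        dropped_reads=sum(v.read_count for v in dropped),
    )


def call_variants(
    reads: list[ProcessedRead], max_n_diff: int = 5, min_reads: int = 100
) -> SupportFilterResult:
    """collapse -> N-merge -> support filter, in the standard order."""
    return filter_support(
        merge_n_compatible(collapse_identical(reads), max_n_diff), min_reads)


def variant_table(variants: list[Variant]) -> "list[dict]":
    """Plain-dict rows for TSV export."""
    return [
        {"sequence": v.sequence, "read_count": v.read_count, "n_count": v.n_count}
        for v in variants
    ]
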