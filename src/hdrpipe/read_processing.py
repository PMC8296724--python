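"""Raw paired-FASTQ processing: demultiplex, filter, merge, window, mask.

The stage order is fixed: demultiplex -> length filter -> pair merging ->
forward-read rescue of unmerged pairs -> window extraction -> quality
masking.  A per-stage ledger accounts for every input pair so that no read
silently disappears.

Merging is ungapped: among all suffix(forward)/prefix(reverse-complemented
reverse) overlaps of at least ``min_overlap`` bases, the one with the most
matching bases wins (ties go to the longer overlap), and the merge is
accepted only if the mismatch fraction in the overlap is at most
``max_mismatch_frac``.  At disagreeing positions the higher-quality base
is taken (equal quality: forward base); merged qualities are the per-base
maximum of the contributing mates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .locus_model import TargetLocus
from .sequtil import revcomp


class DemultiplexConfigError(ValueError):
    """Raised when two loci have primer pairs too similar to separate."""


@dataclass
class ReadPair:
    """One paired-end read; qualities are Phred score arrays (not ASCII)."""

    id: str
    fwd_seq: str
    fwd_quals: np.ndarray
    rev_seq: str
    rev_quals: np.ndarray

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_quals) or len(self.rev_seq) != len(self.rev_quals):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ProcessedRead:
    """A window-trimmed, quality-masked read ready for variant collapsing."""

    id: str
    window_seq: str  # over {A,C,G,T,N}
    n_count: int
    origin: str  # "assembled" | "forward_only"


@dataclass(frozen=True)
class ProcessParams:
    """Stage thresholds; defaults are the standard analysis settings."""

    min_len: int = 100
    min_overlap: int = 150
    max_mismatch_frac: float = 0.20
    q_thresh: int = 20
    max_n: int = 5
    demux_mismatches: int = 2


def _mismatch_count(primer: str, prefix: str) -> int:
    return sum(a != b for a, b in zip(primer, prefix))


def _primer_matches(pair: ReadPair, locus: TargetLocus, tol: int) -> bool:
    fp, rp = locus.fwd_primer, locus.rev_primer
    if len(pair.fwd_seq) < len(fp) or len(pair.rev_seq) < len(rp):
        return False
    return (_mismatch_count(fp, pair.fwd_seq[: len(fp)]) <= tol
            and _mismatch_count(rp, pair.rev_seq[: len(rp)]) <= tol)


def check_primer_distinctness(loci: list[TargetLocus], tol: int = 2) -> None:
    """Reject locus sets whose primers could both match one read."""
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            n = min(len(a.fwd_primer), len(b.fwd_primer))
            m = min(len(a.rev_primer), len(b.rev_primer))
            if (_mismatch_count(a.fwd_primer[:n], b.fwd_primer[:n]) <= 2 * tol
                    and _mismatch_count(a.rev_primer[:m], b.rev_primer[:m]) <= 2 * tol):
                raise DemultiplexConfigError(
                    f"primers of {a.name} and {b.name} are within the demultiplex "
                    "tolerance of each other")


def demultiplex(
    pairs: list[ReadPair], loci: list[TargetLocus], max_mismatches: int = 2
) -> tuple[dict[str, list[ReadPair]], dict[str, int]]:
    """Assign each pair to the unique locus whose primers match both read
    prefixes within ``max_mismatches`` (no indels).

    Returns (per-locus pair lists, counts including unassigned/ambiguous).
    """
    check_primer_distinctness(loci, max_mismatches)
    assigned: dict[str, list[ReadPair]] = {loc.name: [] for loc in loci}
    counts = {loc.name: 0 for loc in loci}
    counts["unassigned"] = 0
    counts["ambiguous"] = 0
    for pair in pairs:
        hits = [loc for loc in loci if _primer_matches(pair, loc, max_mismatches)]
        if len(hits) == 1:
            assigned[hits[0].name].append(pair)
            counts[hits[0].name] += 1
        elif not hits:
            counts["unassigned"] += 1
        else:  # unreachable once check_primer_distinctness passes, kept defensive
            counts["ambiguous"] += 1
    return assigned, counts


def filter_length(pairs: list[ReadPair], min_len: int = 100) -> tuple[list[ReadPair], int]:
    """Drop pairs where either mate is shorter than ``min_len`` bases."""
    kept = [p for p in pairs
            if len(p.fwd_seq) >= min_len and len(p.rev_seq) >= min_len]
    return kept, len(pairs) - len(kept)


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    quals: np.ndarray
    overlap: int
    mismatches: int


def _best_overlap(
    fwd_seq: str, rseq: str, min_overlap: int
) -> tuple[int, int]:
    """(overlap length, mismatches) of the best ungapped suffix/prefix
    overlap, maximising matching bases with ties to the longer overlap;
    (0, 0) when no overlap of at least ``min_overlap`` exists."""
    nf, nr = len(fwd_seq), len(rseq)
    lmax = min(nf, nr)
    if lmax < min_overlap:
        return 0, 0
    # fast path: a mismatch-free overlap of length L scores L, and every
    # longer candidate was already examined, so the first exact hit wins
    fwd = np.frombuffer(fwd_seq.encode(), dtype=np.uint8)
    rev = np.frombuffer(rseq.encode(), dtype=np.uint8)
    best_l, best_matches, best_mism = 0, -1, 0
    for L in range(lmax, min_overlap - 1, -1):
        if best_matches >= L:  # no shorter overlap can beat the current best
            break
        if fwd_seq[nf - L:] == rseq[:L]:
            best_l, best_matches, best_mism = L, L, 0
            break
        mism = int(np.count_nonzero(fwd[nf - L:] != rev[:L]))
        if L - mism > best_matches:
            best_l, best_matches, best_mism = L, L - mism, mism
    return best_l, best_mism


def merge_pair(
    pair: ReadPair, min_overlap: int, max_mismatch_frac: float = 0.20,
    _overlap_cache: dict | None = None,
) -> MergedRead | None:
    """Ungapped overlap merge of a read pair, or None on failure.

    ``_overlap_cache`` memoises the overlap search per (fwd, rev) sequence
    pair; amplicon reads repeat heavily, while the quality-aware consensus
    still uses each pair's own quality strings.
    """
    rseq = revcomp(pair.rev_seq)
    if _overlap_cache is None:
        best_l, best_mism = _best_overlap(pair.fwd_seq, rseq, min_overlap)
    else:
        key = (pair.fwd_seq, pair.rev_seq)
        hit = _overlap_cache.get(key)
        if hit is None:
            hit = _best_overlap(pair.fwd_seq, rseq, min_overlap)
            _overlap_cache[key] = hit
        best_l, best_mism = hit
    if best_l == 0 or best_mism / best_l > max_mismatch_frac:
        return None
    nf = len(pair.fwd_seq)
    L = best_l
    if best_mism == 0:
        quals = np.concatenate([
            pair.fwd_quals[: nf - L],
            np.maximum(pair.fwd_quals[nf - L:], pair.rev_quals[::-1][:L]),
            pair.rev_quals[::-1][L:],
        ])
        return MergedRead(pair.id, pair.fwd_seq[: nf - L] + rseq,
                          quals, overlap=L, mismatches=0)
    fwd = np.frombuffer(pair.fwd_seq.encode(), dtype=np.uint8)
    rev = np.frombuffer(rseq.encode(), dtype=np.uint8)
    fo = fwd[nf - L:]
    ro = rev[:L]
    fq = pair.fwd_quals[nf - L:]
    rq = pair.rev_quals[::-1][:L]  # reverse-complement orientation
    take_rev = (fo != ro) & (rq > fq)
    overlap_seq = np.where(take_rev, ro, fo)
    overlap_q = np.maximum(fq, rq)
    seq = pair.fwd_seq[: nf - L] + overlap_seq.tobytes().decode() + rseq[L:]
    quals = np.concatenate(
        [pair.fwd_quals[: nf - L], overlap_q, pair.rev_quals[::-1][L:]])
    return MergedRead(pair.id, seq, quals, overlap=L, mismatches=best_mism)


def rescue_unassembled(
    assembled: list[MergedRead], failures: list[ReadPair]
) -> list[tuple[str, str, np.ndarray, str]]:
    """Combine merged reads with the forward mates of unmerged pairs.

    Returns (id, seq, quals, origin) tuples; rescued reads keep their own
    forward quality strings.
    """
    out = [(m.id, m.seq, m.quals, "assembled") for m in assembled]
    out.extend((p.id, p.fwd_seq, p.fwd_quals, "forward_only") for p in failures)
    return out


def extract_window(
    seq: str, quals: np.ndarray, window: tuple[int, int]
) -> tuple[str, np.ndarray] | None:
    """Bases at 1-based inclusive positions window.start..window.end of the
    read, or None when the read does not reach the window end."""
    ws, we = window
    if not (1 <= ws < we):
        raise ValueError(f"invalid window {window}")
    if len(seq) < we:
        return None
    return seq[ws - 1:we], quals[ws - 1:we]


def mask_low_quality(
    seq: str, quals: np.ndarray, q_thresh: int = 20, max_n: int = 5
) -> tuple[str, int] | None:
    """Convert bases below ``q_thresh`` to N; drop reads with more than
    ``max_n`` N.  Quality exactly at the threshold is kept."""
    low = quals < q_thresh
    n_count = int(low.sum())
    if n_count > max_n:
        return None
    if n_count == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[low] = ord("N")
    return arr.tobytes().decode(), n_count


def process_pairs(
    pairs: list[ReadPair], locus: TargetLocus, params: ProcessParams
) -> tuple[list[ProcessedRead], dict[str, int]]:
    """Run one locus' pairs through length filter -> merge -> rescue ->
    window -> mask.  (Demultiplexing, when needed, happens upstream.)"""
    ledger: dict[str, int] = {"input_pairs": len(pairs)}
    kept, dropped = filter_length(pairs, params.min_len)
    ledger["dropped_short"] = dropped
    assembled: list[MergedRead] = []
    failures: list[ReadPair] = []
    overlap_cache: dict = {}
    for pair in kept:
        merged = merge_pair(pair, params.min_overlap, params.max_mismatch_frac,
                            _overlap_cache=overlap_cache)
        if merged is None:
            failures.append(pair)
        else:
            assembled.append(merged)
    ledger["assembled"] = len(assembled)
    ledger["rescued_forward"] = len(failures)
    reads = rescue_unassembled(assembled, failures)
    processed: list[ProcessedRead] = []
    n_short, n_many_n = 0, 0
    for rid, seq, quals, origin in reads:
        win = extract_window(seq, quals, locus.window)
        if win is None:
            n_short += 1
            continue
        masked = mask_low_quality(win[0], win[1], params.q_thresh, params.max_n)
        if masked is None:
            n_many_n += 1
            continue
        processed.append(ProcessedRead(rid, masked[0], masked[1], origin))
    ledger["dropped_window"] = n_short
    ledger["dropped_masking"] = n_many_n
    ledger["processed"] = len(processed)
    assert (ledger["dropped_short"] + ledger["dropped_window"]
            + ledger["dropped_masking"] + ledger["processed"]) == ledger["input_pairs"]
    return processed, ledger


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Read mate-synchronised FASTQ files (optionally gzipped, Phred+33)."""
    pairs = []
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = id1.split()[0]
            if rid.endswith("/1"):
                rid = rid[:-2]
            pairs.append(ReadPair(
                rid,
                s1.upper(), np.frombuffer(q1.encode(), dtype=np.uint8) - 33,
                s2.upper(), np.frombuffer(q2.encode(), dtype=np.uint8) - 33,
            ))
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write 4-line Phred+33 FASTQ; gzip when the path ends in .gz."""
    op = gzip.open if str(r1_path).endswith(".gz") else open
    with op(str(r1_path), "wt") as f1, op(str(r2_path), "wt") as f2:
        for p in pairs:
            q1 = (p.fwd_quals.astype(np.uint8) + 33).tobytes().decode()
            q2 = (p.rev_quals.astype(np.uint8) + 33).tobytes().decode()
            f1.write(f"@{p.id}/1\n{p.fwd_seq}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.rev_seq}\n+\n{q2}\n")
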