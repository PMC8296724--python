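"""Truth-known read simulation for mosaic founder embryos.

A founder (F0) embryo is a mosaic of repair outcomes: wild-type cells,
cells carrying the intended edit exactly (perfect HDR), cells carrying the
edit plus a flanking indel (erroneous HDR, biased towards the 5' side for
sense-polarity donors), and cells with NHEJ indels at the cut.  Each
simulated individual is an allele mixture; amplicon read pairs are drawn
multinomially from it, sequenced with a two-level Phred quality model and
uniform substitution errors, and emitted with a truth table.

Cohorts draw per-individual mixtures around group means, either i.i.d.
(Beta-marginal draws) or stratified across quantiles of the same marginal
so that a finite cohort's empirical mean and spread match the specified
condition closely (a variance-reduction device for small cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import (
    EditSpec,
    ExpectedAlleles,
    TargetLocus,
    apply_edit,
    build_expected_alleles,
    locate_cut_site,
)
from .read_processing import ReadPair
from .sequtil import DNA_ALPHABET, revcomp

ALLELE_LABELS = ("wild_type", "perfect_hdr", "erroneous_hdr_5p", "erroneous_hdr_3p", "nhej")

_BASE_ARR = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class AlleleMixture:
    """(label, sequence, fraction) triples describing one mosaic individual."""

    alleles: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        fracs = [f for _, _, f in self.alleles]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("allele fractions must be non-negative and sum to 1")
        for label, _, _ in self.alleles:
            if label not in ALLELE_LABELS:
                raise ValueError(f"unknown allele label {label!r}")

    def fractions_by_label(self) -> dict[str, float]:
        out = dict.fromkeys(ALLELE_LABELS, 0.0)
        for label, _, f in self.alleles:
            out[label] += f
        return out


@dataclass(frozen=True)
class ReadSimConfig:
    """MiSeq-style 2x250 amplicon sequencing model."""

    n_read_pairs: int = 10000
    read_length: int = 250
    per_base_error: float = 0.001
    q_high: int = 38
    q_low: int = 12
    p_lowq: float = 0.015
    seed: int = 0

    def __post_init__(self):
        for p in (self.per_base_error, self.p_lowq):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.read_length < 100:
            raise ValueError("read_length must be at least the 100-bp length filter")


def _random_indel(
    seq: str, rng: np.random.Generator, lo: int, hi: int, size_range: tuple[int, int]
) -> str:
    """Apply one random indel with 0-based positions constrained to [lo, hi).

    Deletions are fully contained in [lo, hi); insertions of random bases
    go at a gap inside it.  ``hi`` must leave room for the largest deletion.
    """
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    if rng.random() < 0.5 and hi - lo > size:  # deletion
        start = int(rng.integers(lo, hi - size))
        return seq[:start] + seq[start + size:]
    gap = int(rng.integers(lo, hi))
    ins = "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size))
    return seq[:gap] + ins + seq[gap:]


def make_allele(
    locus: TargetLocus,
    edit: EditSpec,
    label: str,
    rng: np.random.Generator,
    anchor_k: int = 10,
    max_tries: int = 50,
) -> str:
    """One allele sequence of the requested repair class.

    Erroneous-HDR alleles carry the full edit plus a 1-10 bp indel strictly
    on the stated side of the edited core, inside the analysis window and
    clear of the junction anchors (indels that would erode the core are
    resampled).  NHEJ alleles carry a 1-15 bp indel at the cut without the
    edit.
    """
    if label == "wild_type":
        return locus.amplicon
    if label == "perfect_hdr":
        return apply_edit(locus, edit)

    exp = build_expected_alleles(locus, edit, anchor_k)
    ws, we = locus.window
    w0 = ws - 1
    if label == "nhej":
        cut = locate_cut_site(locus)
        for _ in range(max_tries):
            size = int(rng.integers(1, 16))
            if rng.random() < 0.5:
                # deletion spanning the cut, inside the window
                left = int(rng.integers(0, size + 1))
                start = cut - left
                if start < w0 or start + size > we:
                    continue
                allele = locus.amplicon[:start] + locus.amplicon[start + size:]
            else:
                ins = "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size))
                allele = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
            if allele != locus.amplicon and exp.core not in allele:
                return allele
        raise RuntimeError("failed to sample an NHEJ allele")

    if label not in ("erroneous_hdr_5p", "erroneous_hdr_3p"):
        raise ValueError(f"unknown allele label {label!r}")
    edited = apply_edit(locus, edit)
    core_abs_lo = w0 + exp.core_start  # 0-based on the edited amplicon
    core_abs_hi = core_abs_lo + len(exp.core)
    for _ in range(max_tries):
        if label == "erroneous_hdr_5p":
            lo, hi = w0, core_abs_lo
        else:
            # window coordinates are read coordinates, which coincide with
            # edited-amplicon coordinates for reads starting at the primer
            lo, hi = core_abs_hi, we
        if hi - lo < 12:
            raise ValueError(f"window leaves no room for a {label} indel")
        allele = _random_indel(edited, rng, lo, hi, (1, 10))
        if exp.core in allele and allele != edited:
            return allele
    raise RuntimeError(f"failed to sample a {label} allele")


def build_mixture(
    locus: TargetLocus,
    edit: EditSpec,
    fractions: dict[str, float],
    rng: np.random.Generator,
    n_nhej_clones: int = 2,
    anchor_k: int = 10,
) -> AlleleMixture:
    """Concrete allele mixture for one individual.

    ``fractions`` maps class labels to read fractions; the NHEJ fraction is
    split across ``n_nhej_clones`` distinct indel alleles (a mosaic embryo
    carries a few independent NHEJ clones, not one)."""
    alleles: list[tuple[str, str, float]] = []
    for label, frac in fractions.items():
        if frac <= 0:
            continue
        if label == "nhej":
            share = frac / n_nhej_clones
            for _ in range(n_nhej_clones):
                alleles.append((label, make_allele(locus, edit, label, rng, anchor_k), share))
        else:
            alleles.append((label, make_allele(locus, edit, label, rng, anchor_k), frac))
    return AlleleMixture(tuple(alleles))


def simulate_sample(
    mixture: AlleleMixture,
    cfg: ReadSimConfig,
    sample_id: str = "sample",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate paired reads from one individual.

    Forward reads are the first ``read_length`` bases of the fragment,
    reverse reads the reverse complement of the last ``read_length``;
    substitution errors are uniform at ``per_base_error`` and each base's
    quality is ``q_low`` with probability ``p_lowq``, else ``q_high``.
    Deterministic given ``cfg.seed``; returns (pairs, truth table).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = [a[0] for a in mixture.alleles]
    fracs = np.array([a[2] for a in mixture.alleles], dtype=float)
    counts = rng.multinomial(cfg.n_read_pairs, fracs) if cfg.n_read_pairs else np.zeros(
        len(fracs), dtype=int)

    pairs: list[ReadPair] = []
    truth_rows = []
    read_no = 0
    for (label, allele, _), m in zip(mixture.alleles, counts):
        if m == 0:
            continue
        rl = min(cfg.read_length, len(allele))
        fwd_t = np.frombuffer(allele[:rl].encode(), dtype=np.uint8)
        rev_t = np.frombuffer(revcomp(allele)[:rl].encode(), dtype=np.uint8)
        fwd = np.tile(fwd_t, (m, 1))
        rev = np.tile(rev_t, (m, 1))
        for mat in (fwd, rev):
            if cfg.per_base_error > 0:
                err = rng.random(mat.shape) < cfg.per_base_error
                n_err = int(err.sum())
                if n_err:
                    # replace with one of the three other bases
                    idx = np.searchsorted(_BASE_ARR, mat[err])
                    shift = rng.integers(1, 4, n_err)
                    mat[err] = _BASE_ARR[(idx + shift) % 4]
        fq = np.where(rng.random(fwd.shape) < cfg.p_lowq, cfg.q_low, cfg.q_high).astype(np.uint8)
        rq = np.where(rng.random(rev.shape) < cfg.p_lowq, cfg.q_low, cfg.q_high).astype(np.uint8)
        for i in range(m):
            rid = f"{sample_id}:{read_no:07d}"
            read_no += 1
            pairs.append(ReadPair(rid, fwd[i].tobytes().decode(), fq[i],
                                  rev[i].tobytes().decode(), rq[i]))
            truth_rows.append((rid, label))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_label"])
    return pairs, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortGroupSpec:
    """Simulation condition for one experimental group.

    ``mean_fractions`` gives the group-mean read fraction of perfect HDR,
    erroneous HDR and NHEJ (wild type absorbs the remainder);
    ``concentration`` is the Beta/Dirichlet-style dispersion: larger means
    less inter-individual mosaicism spread.
    """

    label: str
    n_individuals: int
    mean_perfect: float
    mean_erroneous: float = 0.02
    mean_nhej: float = 0.35
    concentration: float = 9.0
    indel_bias_5p: float = 0.75

    def __post_init__(self):
        total = self.mean_perfect + self.mean_erroneous + self.mean_nhej
        if not 0 < total < 1:
            raise ValueError("mean class fractions must leave room for wild type")


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    group: str
    pairs: list[ReadPair]
    truth_fractions: dict[str, float]
    truth_reads: pd.DataFrame


def _perfect_fractions(spec: CohortGroupSpec, rng: np.random.Generator,
                       stratified: bool) -> np.ndarray:
    """Per-individual perfect-HDR fractions from the Beta marginal of a
    Dirichlet with the group's mean and concentration."""
    a = spec.mean_perfect * spec.concentration
    b = (1.0 - spec.mean_perfect) * spec.concentration
    n = spec.n_individuals
    if not stratified:
        return rng.beta(a, b, size=n)
    # quantile-stratified: one draw per equal-probability stratum, shuffled
    q = (np.arange(n) + 0.5) / n
    vals = stats.beta.ppf(q, a, b)
    rng.shuffle(vals)
    return vals


def simulate_cohort(
    locus: TargetLocus,
    edit: EditSpec,
    groups: list[CohortGroupSpec],
    cfg: ReadSimConfig,
    seed: int,
    stratified: bool = False,
) -> list[SimulatedSample]:
    """Simulate one FASTQ sample per individual for each group.

    The perfect-HDR fraction varies across individuals with the group's
    Beta marginal; the other edited classes scale with the remaining
    non-perfect mass so their cohort means match the spec.  Each
    individual gets an independent seed derived from (seed, group, index)
    so adding a sample never perturbs the others' draws.
    """
    samples: list[SimulatedSample] = []
    for g_idx, spec in enumerate(groups):
        g_ss = np.random.SeedSequence((seed, g_idx))
        perf = _perfect_fractions(spec, np.random.default_rng(g_ss), stratified)
        rest_scale = (1.0 - perf) / (1.0 - spec.mean_perfect)
        for i in range(spec.n_individuals):
            child = np.random.SeedSequence((seed, g_idx, i))
            rng = np.random.default_rng(child)
            err = spec.mean_erroneous * rest_scale[i]
            nhej = spec.mean_nhej * rest_scale[i]
            fractions = {
                "perfect_hdr": float(perf[i]),
                "erroneous_hdr_5p": float(err * spec.indel_bias_5p),
                "erroneous_hdr_3p": float(err * (1.0 - spec.indel_bias_5p)),
                "nhej": float(nhej),
            }
            fractions["wild_type"] = 1.0 - sum(fractions.values())
            mixture = build_mixture(locus, edit, fractions, rng)
            sid = f"{spec.label}_ind{i + 1:02d}"
            sample_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            pairs, truth = simulate_sample(
                mixture, replace(cfg, seed=sample_seed), sample_id=sid)
            samples.append(SimulatedSample(sid, spec.label, pairs, fractions, truth))
    return samples


def cohort_truth_table(samples: list[SimulatedSample]) -> pd.DataFrame:
    """Per-individual true class fractions, one row per sample."""
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "group": s.group}
        row.update({f"true_{k}": v for k, v in s.truth_fractions.items()})
        row["true_erroneous_hdr"] = (s.truth_fractions.get("erroneous_hdr_5p", 0.0)
                                     + s.truth_fractions.get("erroneous_hdr_3p", 0.0))
        rows.append(row)
    return pd.DataFrame(rows)
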