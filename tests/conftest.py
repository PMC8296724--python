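"""Shared fixtures: demo loci and a small toy locus for exhaustive tests."""

import numpy as np
import pytest

from hdrpipe.demo import dnd_locus, dnd_snr_edit, flag_ki_edit, slc45a2_locus
from hdrpipe.locus_model import EditSpec, GuideRNA, TargetLocus


@pytest.fixture(scope="session")
def slc_locus():
    return slc45a2_locus()


@pytest.fixture(scope="session")
def ki_edit():
    return flag_ki_edit()


@pytest.fixture(scope="session")
def dnd():
    return dnd_locus()


@pytest.fixture(scope="session")
def snr_edit():
    return dnd_snr_edit()


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_toy_locus(seed: int = 11, window=(45, 82)) -> TargetLocus:
    """A 150-nt locus with a short analysis window (<= 40 nt) so that
    exhaustive edit-neighbourhood enumeration stays small."""
    rng = np.random.default_rng(seed)
    while True:
        amp = _random_dna(rng, 150)
        # plus-strand protospacer at 41-60, PAM 61-63 forced to NGG
        amp = amp[:61] + "GG" + amp[63:]
        proto = amp[40:60]
        if amp.count(proto) == 1:
            break
    return TargetLocus(
        name="toy",
        amplicon=amp,
        fwd_primer=amp[:10],
        rev_primer=_revcomp(amp[-10:]),
        window=window,
        guide=GuideRNA(protospacer=proto, pam=amp[60:63], strand="+", start=41),
    )


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="session")
def toy_locus():
    return make_toy_locus()


@pytest.fixture(scope="session")
def toy_insert_edit():
    # short insert so the +-2-op neighbourhood stays enumerable
    return EditSpec(kind="insertion", insert="TTAGGC")


@pytest.fixture(scope="session")
def toy_sub_edit(toy_locus):
    subs = []
    for pos in (55, 56, 57):
        ref = toy_locus.amplicon[pos - 1]
        subs.append((pos, "A" if ref != "A" else "C"))
    return EditSpec(kind="substitution", substitutions=tuple(subs))
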