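import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dcapsim import builtin_lhon_assay
from dcapsim.synthetic_fixtures import make_lhon_like_reference, make_rcrs_emulation


# ---------------------------------------------------------------------------
# Independent brute-force IUPAC window scanner (the oracle for site finding).
# Deliberately self-contained: its own IUPAC table, its own complement map.

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def brute_force_sites(seq: str, motif: str):
    """All (1-based start, strand) motif matches, both strands; palindromic
    motifs (equal IUPAC sets to their reverse complement) reported once."""
    seq = seq.upper()
    motif = motif.upper()
    rc = "".join(_COMP[c] for c in reversed(motif))
    palindromic = all(set(_IUPAC[a]) == set(_IUPAC[b]) for a, b in zip(motif, rc))
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        if all(b in _IUPAC[c] for b, c in zip(window, motif)):
            hits.append((i + 1, "+"))
        if not palindromic and all(b in _IUPAC[c] for b, c in zip(window, rc)):
            hits.append((i + 1, "-"))
    return sorted(hits)


@pytest.fixture(scope="session")
def oracle_sites():
    return brute_force_sites


# ---------------------------------------------------------------------------
# Shared references (session-scoped: construction runs the full verification
# pipeline and is not free)

@pytest.fixture(scope="session")
def lhon_fixture():
    """~3 kb linear pseudo-reference: (reference, snps, primer pairs)."""
    return make_lhon_like_reference(seed=1)


@pytest.fixture(scope="session")
def emulation():
    """Synthetic 16.6-kb circular stand-in for the mito reference genome."""
    return make_rcrs_emulation(seed=1)


@pytest.fixture(scope="session")
def emu_assay(emulation):
    ref, _, _ = emulation
    return builtin_lhon_assay(ref)


@pytest.fixture(scope="session")
def fixture_assay(lhon_fixture):
    ref, snps, primers = lhon_fixture
    return builtin_lhon_assay(ref, targets=snps, primers=primers)
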