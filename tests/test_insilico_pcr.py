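import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dcapsim.sequence_core import NucSequence, SequenceError, revcomp, revcomp_str
from dcapsim.insilico_pcr import (
    Primer,
    amplify,
    find_bindings,
    multiplex_amplify,
    primer_from_string,
)
from dcapsim.assay_engine import LHON_PUBLISHED_PRIMERS


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(11)


class TestPrimer:
    def test_lowercase_marks_alterations(self):
        p = primer_from_string("3460F", LHON_PUBLISHED_PRIMERS["3460"][0])
        assert p.altered_positions == frozenset({30})  # penultimate base
        p2 = primer_from_string("14484F", LHON_PUBLISHED_PRIMERS["14484"][0])
        assert p2.altered_positions == frozenset({32, 33})

    def test_too_short_rejected(self):
        with pytest.raises(SequenceError):
            Primer("p", "ACGTACGT")


class TestFindBindings:
    def test_perfect_match_on_source_region(self, rng):
        t = _random_seq(rng, 300)
        primer = Primer("f", t[50:72])
        hits = find_bindings(NucSequence("t", t), primer, max_mismatch=0)
        assert [(b.template_start, b.strand, b.mismatch_count) for b in hits] == [(51, "+", 0)]

    def test_minus_strand_binding(self, rng):
        t = _random_seq(rng, 300)
        primer = Primer("r", revcomp_str(t[100:122]))
        hits = find_bindings(NucSequence("t", t), primer, max_mismatch=0)
        assert [(b.template_start, b.strand) for b in hits] == [(101, "-")]

    def test_terminal_3prime_mismatch_rejects_binding(self, rng):
        t = _random_seq(rng, 200)
        core = t[50:70]
        bad_last = "A" if core[-1] != "A" else "C"
        primer = Primer("f", core[:-1] + bad_last)
        assert find_bindings(NucSequence("t", t), primer, max_mismatch=3) == []

    def test_internal_mismatches_counted_at_primer_coordinates(self, rng):
        t = _random_seq(rng, 200)
        core = list(t[50:74])
        core[5] = "A" if core[5] != "A" else "C"
        primer = Primer("f", "".join(core))
        (hit,) = find_bindings(NucSequence("t", t), primer, max_mismatch=2)
        assert hit.mismatch_count == 1 and hit.mismatch_positions == (6,)

    def test_primer_longer_than_template(self):
        assert find_bindings(NucSequence("t", "ACGTACGTACGTACG"),
                             Primer("p", "A" * 20)) == []

    def test_published_lhon_primers_bind_wildtype_with_expected_mismatches(self, emulation):
        ref, _, _ = emulation
        f3460 = primer_from_string("3460F", LHON_PUBLISHED_PRIMERS["3460"][0])
        (hit,) = find_bindings(ref, f3460)
        assert hit.strand == "+" and hit.mismatch_count == 1
        assert hit.mismatch_positions == (30,)  # exactly the altered position
        f14484 = primer_from_string("14484F", LHON_PUBLISHED_PRIMERS["14484"][0])
        (hit,) = find_bindings(ref, f14484)
        assert hit.mismatch_count == 2 and hit.mismatch_positions == (32, 33)


class TestAmplify:
    def test_constructed_template(self, rng):
        fwd = Primer("f", _random_seq(rng, 20))
        rev = Primer("r", _random_seq(rng, 20))
        t = fwd.upper + _random_seq(rng, 50) + revcomp_str(rev.upper)
        products = amplify(NucSequence("t", t), fwd, rev, max_mismatch=0)
        assert len(products) == 1
        assert products[0].length == 90
        # with verbatim primers the product equals the template exactly
        assert products[0].sequence.upper == t

    def test_primer_override_semantics(self, rng):
        t = _random_seq(rng, 200)
        footprint = t[40:64]
        # alter an internal base of the forward primer
        altered = footprint[:10] + ("a" if footprint[10] != "A" else "c") + footprint[11:]
        fwd = primer_from_string("f", altered)
        rev = Primer("r", revcomp_str(t[140:160]))
        (amp,) = amplify(NucSequence("t", t), fwd, rev)
        # the amplicon carries the primer base, not the template base
        assert amp.sequence.upper[:len(fwd)] == fwd.upper
        assert amp.sequence.upper[10] != t[50]
        # and its 3' end carries the reverse primer
        assert amp.sequence.upper[-len(rev):] == revcomp_str(rev.upper).upper()

    def test_zero_products_is_valid(self, rng):
        t = NucSequence("t", _random_seq(rng, 200))
        fwd = Primer("f", "ACGTACGTACGTACGTACGT")
        rev = Primer("r", "TGCATGCATGCATGCATGCA")
        assert amplify(t, fwd, rev, max_mismatch=0) == []

    def test_strand_symmetry(self, rng):
        fwd = Primer("f", _random_seq(rng, 20))
        rev = Primer("r", _random_seq(rng, 20))
        t = _random_seq(rng, 30) + fwd.upper + _random_seq(rng, 60) \
            + revcomp_str(rev.upper) + _random_seq(rng, 30)
        template = NucSequence("t", t)
        (a,) = amplify(template, fwd, rev, max_mismatch=0)
        (b,) = amplify(revcomp(template), fwd, rev, max_mismatch=0)
        assert a.length == b.length
        assert b.sequence.upper == a.sequence.upper  # product is strand-agnostic


class TestMultiplex:
    def test_single_pair_equals_amplify(self, emulation):
        ref, _, primers = emulation
        fwd, rev = primers["G3460A"]
        single = amplify(ref, fwd, rev)
        multi = multiplex_amplify(ref, [("G3460A", fwd, rev)])
        assert [a.length for a in multi] == [a.length for a in single] == [333]

    def test_three_lhon_pairs_product_lengths(self, emulation):
        ref, _, primers = emulation
        pairs = [(name, fwd, rev) for name, (fwd, rev) in primers.items()]
        products = multiplex_amplify(ref, pairs)
        assert sorted(a.length for a in products) == [164, 236, 333]

    def test_resolution_warning_for_close_products(self, rng, caplog):
        f1, r1 = Primer("f1", _random_seq(rng, 20)), Primer("r1", _random_seq(rng, 20))
        f2, r2 = Primer("f2", _random_seq(rng, 20)), Primer("r2", _random_seq(rng, 20))
        t = (f1.upper + _random_seq(rng, 160) + revcomp_str(r1.upper)
             + _random_seq(rng, 10)
             + f2.upper + _random_seq(rng, 165) + revcomp_str(r2.upper))
        with caplog.at_level(logging.WARNING):
            products = multiplex_amplify(
                NucSequence("t", t), [("a", f1, r1), ("b", f2, r2)],
                max_mismatch=0, min_spacing=30,
            )
        assert sorted(a.length for a in products) == [200, 205]
        assert any("resolve" in r.message for r in caplog.records)
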