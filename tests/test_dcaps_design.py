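from collections import Counter

import numpy as np
import pytest

from dcapsim.sequence_core import NucSequence
from dcapsim.restriction import MAEIII, RestrictionEnzyme, bundled_enzymes, get_enzyme
from dcapsim.insilico_pcr import Primer
from dcapsim.dcaps_design import (
    DesignConstraints,
    SnpTarget,
    TargetValidationError,
    classify_natural_site_change,
    design_mismatch_primer,
    load_snp_table,
    select_multiplex_enzyme,
    simulate_candidate,
    validate_candidate,
)
from dcapsim.assay_engine import LHON_SNP_TARGETS


def _snp(emulation, name):
    return next(s for s in LHON_SNP_TARGETS if s.name == name)


class TestSnpTarget:
    def test_reference_allele_validated(self, emulation):
        ref, _, _ = emulation
        with pytest.raises(TargetValidationError):
            SnpTarget("bad", 3460, "T", "A").validate_against(ref)

    def test_load_snp_table(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("# targets\nG11778A\t11778\tG\tA\n")
        (t,) = load_snp_table(p)
        assert (t.position, t.ref_allele, t.alt_allele) == (11778, "G", "A")

    def test_load_snps_vcf_snvs_only(self, tmp_path):
        from dcapsim.dcaps_design import load_snps_vcf

        p = tmp_path / "snps.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chrM,length=16569>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chrM\t11778\tG11778A\tG\tA\t.\tPASS\t.\n"
            "chrM\t300\t.\tGT\tG\t.\tPASS\t.\n"  # indel: skipped
        )
        (t,) = load_snps_vcf(p)
        assert (t.name, t.position, t.ref_allele, t.alt_allele) == (
            "G11778A", 11778, "G", "A")


class TestNaturalSiteChange:
    def test_11778_gains_a_maeiii_site(self, emulation):
        ref, _, _ = emulation
        assert classify_natural_site_change(ref, _snp(emulation, "G11778A"), MAEIII) == "gained"

    def test_3460_and_14484_need_engineering(self, emulation):
        ref, _, _ = emulation
        assert classify_natural_site_change(ref, _snp(emulation, "G3460A"), MAEIII) == "none"
        assert classify_natural_site_change(ref, _snp(emulation, "T14484C"), MAEIII) == "none"

    def test_identity_allele_is_none(self, emulation):
        ref, _, _ = emulation
        base = ref.base(5000)
        assert classify_natural_site_change(
            ref, SnpTarget("same", 5000, base, base), MAEIII) == "none"

    def test_lost_site(self):
        # destroy an implanted site: GTAAC -> GAAAC
        seq = NucSequence("s", "AAAAAAAAAAGTAACAAAAAAAAAA")
        t = SnpTarget("loss", 12, "T", "A")
        assert classify_natural_site_change(seq, t, MAEIII) == "lost"


class TestDesignSearch:
    def test_3460_single_alteration_at_penultimate_position(self, emulation):
        ref, _, _ = emulation
        best = design_mismatch_primer(ref, _snp(emulation, "G3460A"), MAEIII)[0]
        assert best.mode == "engineered" and best.n_alterations == 1
        assert best.orientation == "forward"
        # the published design's 3' signature: ...G t C with the altered base
        # at the penultimate position
        assert best.primer.display()[-3:] == "GtC"
        assert best.primer.altered_positions == {len(best.primer) - 1}
        assert best.site_start == 3457

    def test_14484_two_alterations_gt_signature(self, emulation):
        ref, _, _ = emulation
        cands = design_mismatch_primer(ref, _snp(emulation, "T14484C"), MAEIII)
        best = cands[0]
        assert best.n_alterations == 2
        assert best.site_start == 14480
        # the published 3'-region pattern (...GACAgtCA) is among the
        # minimal-alteration candidates
        assert any(
            c.n_alterations == 2 and c.primer.display().endswith("GACAgtCA")
            for c in cands
        )

    def test_11778_natural_zero_alterations(self, emulation):
        ref, _, _ = emulation
        best = design_mismatch_primer(ref, _snp(emulation, "G11778A"), MAEIII)[0]
        assert best.mode == "natural" and best.n_alterations == 0
        assert best.primer.altered_positions == frozenset()

    def test_zero_alteration_search_reduces_to_natural_classification(self, emulation):
        ref, _, _ = emulation
        constraints = DesignConstraints(max_alterations=0)
        for snp in LHON_SNP_TARGETS:
            cands = design_mismatch_primer(ref, snp, MAEIII, constraints)
            natural = classify_natural_site_change(ref, snp, MAEIII) == "gained"
            assert bool(cands) == natural

    def test_discrimination_guarantee(self, emulation):
        ref, _, _ = emulation
        for snp in LHON_SNP_TARGETS:
            for cand in design_mismatch_primer(ref, snp, MAEIII):
                assert Counter(cand.predicted_fragments["ref"]) != \
                    Counter(cand.predicted_fragments["alt"])

    def test_minimality_dropping_any_alteration_breaks_discrimination(self, emulation):
        ref, _, _ = emulation
        for name in ("G3460A", "T14484C"):
            snp = _snp(emulation, name)
            best = design_mismatch_primer(ref, snp, MAEIII)[0]
            for drop in best.primer.altered_positions:
                seq = list(best.primer.upper)
                # revert this alteration to the template base
                top = best.anchor_3prime - len(best.primer) + drop
                seq[drop - 1] = ref.base(top)
                reduced = Primer(
                    best.primer.name + "-reduced", "".join(seq),
                    best.primer.altered_positions - {drop},
                )
                frags = simulate_candidate(
                    ref, reduced, best.orientation, best.anchor_3prime, snp, MAEIII,
                    product_size=best.product_size,
                )
                assert Counter(frags["ref"]) == Counter(frags["alt"])

    def test_discrimination_on_random_templates(self):
        # random template, random SNP, random enzyme panel: every returned
        # candidate must separate the alleles when independently re-simulated
        rng = np.random.default_rng(23)
        panel = bundled_enzymes()
        checked = 0
        for _ in range(15):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
            pos = int(rng.integers(150, 250))
            ref_allele = s[pos - 1]
            alt_allele = "ACGT".replace(ref_allele, "")[rng.integers(0, 3)]
            seq = NucSequence("r", s)
            snp = SnpTarget("rnd", pos, ref_allele, alt_allele)
            enz = panel[rng.integers(0, len(panel))]
            for cand in design_mismatch_primer(seq, snp, enz, product_size=150):
                frags = simulate_candidate(
                    seq, cand.primer, cand.orientation, cand.anchor_3prime,
                    snp, enz, product_size=150,
                )
                assert Counter(frags["ref"]) != Counter(frags["alt"])
                checked += 1
        assert checked > 0


class TestValidation:
    def test_3460_design_has_internal_control_when_product_spans_it(self, emulation):
        ref, _, _ = emulation
        snp = _snp(emulation, "G3460A")
        # long enough to reach the constant site at 3736
        best = design_mismatch_primer(ref, snp, MAEIII, product_size=320)[0]
        report = validate_candidate(best, ref)
        assert report.has_internal_control
        assert report.confounding_sites == []
        assert report.meets_delta

    def test_11778_design_has_no_constant_site_in_own_product(self, emulation):
        ref, _, _ = emulation
        best = design_mismatch_primer(ref, _snp(emulation, "G11778A"), MAEIII)[0]
        report = validate_candidate(best, ref)
        assert not report.has_internal_control

    def test_below_threshold_delta_is_flagged(self, emulation):
        ref, _, _ = emulation
        best = design_mismatch_primer(ref, _snp(emulation, "G11778A"), MAEIII)[0]
        strict = DesignConstraints(min_diagnostic_delta=10_000)
        assert not validate_candidate(best, ref, strict).meets_delta


class TestMultiplexSelection:
    def test_lhon_targets_select_maeiii_like_enzyme(self, emulation):
        ref, _, _ = emulation
        result = select_multiplex_enzyme(ref, LHON_SNP_TARGETS, bundled_enzymes())
        assert result.solved
        assert result.enzyme.name == "MaeIII"
        alts = {n: c.n_alterations for n, c in result.candidates.items()}
        assert alts == {"G3460A": 1, "G11778A": 0, "T14484C": 2}
        # product sizes must be pairwise separable
        sizes = result.product_sizes
        names = list(sizes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert abs(sizes[a] - sizes[b]) >= 20

    def test_single_natural_target(self, emulation):
        ref, _, _ = emulation
        result = select_multiplex_enzyme(
            ref, [_snp(emulation, "G11778A")], [MAEIII, get_enzyme("EcoRI")]
        )
        assert result.solved and result.enzyme.name == "MaeIII"
        assert result.candidates["G11778A"].n_alterations == 0

    def test_empty_panel_reports_no_solution(self, emulation):
        ref, _, _ = emulation
        result = select_multiplex_enzyme(ref, LHON_SNP_TARGETS[:2], [])
        assert not result.solved and result.enzyme is None

    def test_unserved_target_lists_per_enzyme_failures(self, emulation):
        ref, _, _ = emulation
        result = select_multiplex_enzyme(
            ref, LHON_SNP_TARGETS, [get_enzyme("EcoRI"), get_enzyme("HindIII")]
        )
        assert not result.solved
        assert set(result.failures) == {"EcoRI", "HindIII"}
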