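import itertools

import numpy as np
import pytest

from dcapsim.sequence_core import NucSequence
from dcapsim.assay_engine import (
    AssayConstructionError,
    CONTROL_MIXES,
    SMALL_BAND_FLOOR,
    assay_from_definition,
    build_controls,
    builtin_lhon_assay,
    call_genotype,
    estimate_heteroplasmy,
    expected_fragment_table,
    heteroplasmy_detection_limit,
    load_assay_definition,
    observation_from_sizes,
    read_lane_csv,
    simulate_lane,
    simulate_mix_lane,
    write_lane_csv,
)

#: The published expectation: per-genotype digestion products of the
#: three multiplex amplicons (333/164/236 bp), as fragment multisets.
EXPECTED_TABLE = {
    "all_ref": {"G3460A": {307, 26}, "G11778A": {164}, "T14484C": {236}},
    "3460_alt": {"G3460A": {279, 28, 26}, "G11778A": {164}, "T14484C": {236}},
    "11778_alt": {"G3460A": {307, 26}, "G11778A": {135, 29}, "T14484C": {236}},
    "14484_alt": {"G3460A": {307, 26}, "G11778A": {164}, "T14484C": {205, 31}},
}


class TestBuiltinAssay:
    def test_product_sizes_and_control_fragment(self, emu_assay):
        assert [t.product_size for t in emu_assay.targets] == [333, 164, 236]
        assert emu_assay.control_fragment == 26

    def test_same_geometry_fixture_yields_identical_tables(self, emu_assay, fixture_assay):
        for a, b in zip(emu_assay.targets, fixture_assay.targets):
            assert a.product_size == b.product_size
            assert a.ref_fragments == b.ref_fragments
            assert a.alt_fragments == b.alt_fragments

    def test_scrambled_reference_raises(self, emulation):
        ref, _, _ = emulation
        rng = np.random.default_rng(0)
        shuffled = "".join(rng.permutation(list(ref.upper)))
        with pytest.raises((AssayConstructionError, Exception)):
            builtin_lhon_assay(NucSequence("scrambled", shuffled, "circular"))

    def test_bundled_definition_binds_and_validates(self, emulation):
        ref, _, _ = emulation
        assay = assay_from_definition(load_assay_definition(), ref)
        assert assay.name == "LHON-MaeIII"
        assert [t.product_size for t in assay.targets] == [333, 164, 236]


class TestExpectedFragmentTable:
    @pytest.mark.parametrize(
        "genotypes,key",
        [({}, "all_ref"),
         ({"G3460A": "alt"}, "3460_alt"),
         ({"G11778A": "alt"}, "11778_alt"),
         ({"T14484C": "alt"}, "14484_alt")],
    )
    def test_matches_published_columns(self, emu_assay, genotypes, key):
        table = expected_fragment_table(emu_assay, genotypes)
        assert table["uncut"] == [333, 164, 236]
        for name, expected in EXPECTED_TABLE[key].items():
            assert set(table[name]) == expected

    def test_mutant_patterns_differ_in_a_large_band(self, emu_assay):
        # calls must never rest on sub-floor fragments alone
        ref_large = {
            n: {f for f in frags if f >= SMALL_BAND_FLOOR}
            for n, frags in expected_fragment_table(emu_assay, {}).items()
        }
        for t in emu_assay.targets:
            mutant = expected_fragment_table(emu_assay, {t.target.name: "alt"})
            large = {f for f in mutant[t.target.name] if f >= SMALL_BAND_FLOOR}
            assert large != ref_large[t.target.name]


class TestCallGenotype:
    def test_all_ref_lane(self, emu_assay):
        call = call_genotype(observation_from_sizes([307, 236, 164, 26]), emu_assay)
        assert call.control_status == "pass"
        assert {n: c.status for n, c in call.per_target.items()} == {
            "G3460A": "ref", "G11778A": "ref", "T14484C": "ref"}
        assert call.unmatched == []

    def test_11778_mutant_lane(self, emu_assay):
        call = call_genotype(observation_from_sizes([307, 236, 135, 29, 26]), emu_assay)
        assert call.per_target["G11778A"].status == "alt"
        assert call.per_target["G3460A"].status == "ref"
        assert call.per_target["T14484C"].status == "ref"

    def test_missing_small_fragments_do_not_block_calls(self, emu_assay):
        # 26/28/29/31-bp bands routinely run off 2.5% agarose
        call = call_genotype(observation_from_sizes([279, 236, 164]), emu_assay)
        assert call.per_target["G3460A"].status == "alt"
        assert call.control_status == "pass"

    def test_uncut_control_band_suppresses_all_calls(self, emu_assay):
        call = call_genotype(observation_from_sizes([333, 236, 164]), emu_assay)
        assert call.control_status == "fail_incomplete_digestion"
        assert all(c.status == "uncalled" for c in call.per_target.values())

    def test_size_tolerance_window(self, emu_assay):
        call = call_genotype(observation_from_sizes([309, 234, 166, 25]), emu_assay)
        assert {n: c.status for n, c in call.per_target.items()} == {
            "G3460A": "ref", "G11778A": "ref", "T14484C": "ref"}

    def test_unexpected_band_reported(self, emu_assay):
        call = call_genotype(observation_from_sizes([307, 236, 164, 26, 600]), emu_assay)
        assert call.unmatched == [600.0]
        assert any("no expected size" in w for w in call.warnings)

    def test_heteroplasmic_lane_with_intensities(self, emu_assay):
        # forward-model a 90/10 wild-type/mutant mixture at 11778 through
        # the mass-proportional staining model, then call
        f = 0.10
        obs = observation_from_sizes(
            [307, 236, 164, 135, 26],
            [307, 236, 164 * (1 - f), 135 * f, 26],
        )
        call = call_genotype(obs, emu_assay)
        tc = call.per_target["G11778A"]
        assert tc.status == "heteroplasmic"
        assert tc.fraction == pytest.approx(0.10, abs=1e-9)

    def test_both_bands_without_intensities_fraction_unknown(self, emu_assay):
        call = call_genotype(observation_from_sizes([307, 236, 164, 135, 26]), emu_assay)
        tc = call.per_target["G11778A"]
        assert tc.status == "heteroplasmic" and tc.fraction is None

    def test_round_trip_every_genotype_vector(self, emu_assay):
        for vec in itertools.product(["ref", "alt"], repeat=3):
            genotypes = dict(zip(emu_assay.target_names, vec))
            obs = simulate_lane(emu_assay, genotypes)
            call = call_genotype(obs, emu_assay)
            assert call.control_status == "pass"
            got = tuple(call.per_target[n].status for n in emu_assay.target_names)
            assert got == vec

    def test_empty_lane_rejected(self, emu_assay):
        with pytest.raises(ValueError):
            call_genotype(observation_from_sizes([]), emu_assay)


class TestHeteroplasmyEstimator:
    def test_boundaries(self):
        assert estimate_heteroplasmy(0, 135, 5, 164) == 0.0
        assert estimate_heteroplasmy(5, 135, 0, 164) == 1.0

    def test_exact_inversion_of_the_mass_model(self):
        for f in np.linspace(0.0, 1.0, 21):
            if f in (0.0, 1.0):
                continue
            i_cut, i_uncut = 135 * f, 164 * (1 - f)
            assert estimate_heteroplasmy(i_cut, 135, i_uncut, 164) == pytest.approx(f)

    def test_noisy_recovery_within_five_points(self):
        # 5% multiplicative noise on both bands perturbs the estimate by
        # ~f(1-f)*sqrt(2)*0.05 (one sigma), so +/-0.05 is a ~95% band at
        # the worst case f=0.5; assert that quantile, seeded
        rng = np.random.default_rng(42)
        for f in (0.1, 0.25, 0.5, 0.75, 0.9):
            errs = []
            for _ in range(200):
                i_cut = 135 * f * (1 + 0.05 * rng.standard_normal())
                i_uncut = 164 * (1 - f) * (1 + 0.05 * rng.standard_normal())
                errs.append(abs(estimate_heteroplasmy(
                    max(i_cut, 0), 135, max(i_uncut, 0), 164) - f))
            assert np.quantile(errs, 0.95) <= 0.05
            assert np.mean(errs) <= 0.02

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValueError):
            estimate_heteroplasmy(0, 135, 0, 164)

    def test_detection_limit_near_ten_percent(self, emu_assay):
        assert heteroplasmy_detection_limit(emu_assay, "G11778A") == pytest.approx(0.10)


class TestControls:
    def test_insert_lengths_from_declared_regions(self, emulation):
        ref, _, _ = emulation
        mixes = build_controls(ref)
        normal = next(m for m in mixes if m.name == "Normal")
        assert [len(s.residues) for _, s in normal.inserts] == [998, 539, 574]

    def test_mix_compositions(self, emulation):
        ref, _, _ = emulation
        by_name = {m.name: m for m in build_controls(ref)}
        assert [lbl for lbl, _ in by_name["3460A"].inserts] == ["3460A", "11778G", "14484T"]
        assert [lbl for lbl, _ in by_name["11778A"].inserts] == ["3460G", "11778A", "14484T"]
        assert [lbl for lbl, _ in by_name["14484C"].inserts] == ["3460G", "11778G", "14484C"]
        for m in by_name.values():
            mutants = sum(1 for lbl, _ in m.inserts if lbl in ("3460A", "11778A", "14484C"))
            assert len(m.inserts) == 3 and mutants <= 1

    def test_each_mix_reproduces_its_genotype_column(self, emulation, emu_assay):
        ref, _, _ = emulation
        for mix in build_controls(ref):
            obs = simulate_mix_lane(emu_assay, mix)
            call = call_genotype(obs, emu_assay)
            assert call.control_status == "pass"
            want = CONTROL_MIXES[mix.name]
            got = {n: c.status for n, c in call.per_target.items()}
            assert got == want


class TestLaneCSV:
    def test_roundtrip(self, tmp_path):
        obs = observation_from_sizes([307, 26], [0.8, 0.2])
        p = tmp_path / "lane.csv"
        write_lane_csv(obs, p)
        back = read_lane_csv(p)
        assert back.bands == obs.bands

    def test_intensity_optional(self, tmp_path):
        p = tmp_path / "lane.csv"
        p.write_text("size,intensity\n307,\n26,\n")
        back = read_lane_csv(p)
        assert back.bands == ((307.0, None), (26.0, None))
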