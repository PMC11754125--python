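"""Assembly grammar: binding sites, shields, architectures, backbone fixes."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirswitch import grammar
from mirswitch.core import (
    BindingSiteSpec,
    DesignError,
    MiRNA,
    MismatchPattern,
    RnaSequence,
    SpacerGuide,
    is_pair,
    reverse_complement,
    validate_design,
)


@pytest.fixture(scope="module")
def spacer(panel):
    return panel.spacers[0]


class TestBindingSite:
    def test_full_length_is_perfect_reverse_complement(self, mir17):
        site = grammar.build_binding_site(
            mir17, BindingSiteSpec(mode="full_length")
        )
        assert site.sequence.residues == reverse_complement(mir17.sequence).residues
        # pairing map: site position s matches miRNA position L+1-s
        L = len(mir17)
        assert site.pairing_map[1] == L and site.pairing_map[L] == 1

    def test_seed_only_covers_the_seed(self, mir17):
        site = grammar.build_binding_site(
            mir17, BindingSiteSpec(mode="seed_only")
        )
        assert len(site.sequence) == 7
        assert site.sequence.residues == reverse_complement(mir17.seed_sequence()).residues

    def test_preset_mismatches_change_exactly_those_positions(self, mir17):
        perfect = reverse_complement(mir17.sequence).residues
        site = grammar.build_binding_site(
            mir17, BindingSiteSpec(mode="full_length", mismatch_positions=frozenset({2, 9, 17}))
        )
        L = len(mir17)
        diffs = {L - i for i, (a, b) in enumerate(zip(perfect, site.sequence.residues)) if a != b}
        assert diffs == {2, 9, 17}
        for m in (2, 9, 17):
            s = L + 1 - m
            assert not is_pair(site.sequence[s], mir17.sequence[m])

    def test_seed_only_rejects_mismatch_outside_seed(self, mir17):
        with pytest.raises(DesignError):
            grammar.build_binding_site(
                mir17, BindingSiteSpec(mode="seed_only", mismatch_positions=frozenset({9}))
            )


class TestShieldAndFullLength:
    def test_shield_length_arithmetic(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        assert len(d.component("shield")) == 16 + spacer.spacer_length + 1
        assert len(d.component("loop")) == len(mir17) - 16

    def test_element_order(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        names = [n for n, _ in d.components]
        assert names == ["shield", "loop", "binding_site", "spacer", "scaffold"]

    def test_spacer_content_preserved(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        iv = d.spacer_interval
        assert d.full_sequence.residues[iv.start - 1 : iv.end] == spacer.spacer.residues

    def test_designed_pairs_are_canonical_and_mismatches_are_not(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        seq = d.full_sequence.residues
        for i, j in d.designed_pairs:
            assert is_pair(seq[i - 1], seq[j - 1])
        # every stem position not designed to pair must fail the pair predicate
        ls = len(d.component("shield"))
        loop = len(d.component("loop"))
        designed = set(d.designed_pairs)
        for s in range(1, ls + 1):
            j = ls + loop + (ls + 1 - s)
            if (s, j) not in designed:
                assert not is_pair(seq[s - 1], seq[j - 1])

    def test_trigger_interval_covers_shield_through_first_repeat_g(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        iv = d.trigger_hairpin_interval
        assert iv.start == 1
        assert d.full_sequence[iv.end] == "G"
        assert iv.end == d.spacer_interval.end + 1

    def test_ago_cleavage_ablating_preset(self, mir17, spacer):
        d = grammar.assemble_full_length(
            mir17, spacer, site_mismatches=grammar.PRESET_AGO_CLEAVAGE_ABLATED
        )
        assert d.binding_site_spec.mismatch_positions == frozenset({10, 11})

    @given(st.integers(0, 7))
    def test_validator_accepts_assembler_output(self, panel, idx):
        m, s = panel.pairs()[idx % len(panel.mirnas)]
        d = grammar.assemble_full_length(m, s)
        assert validate_design(d) == []


class TestSeedOnly:
    def test_default_single_mismatch_at_position_2(self, mir17, spacer):
        d = grammar.assemble_seed_only(mir17, spacer)
        assert d.binding_site_spec.mismatch_positions == frozenset({2})

    def test_loop_is_gaaa_tetraloop(self, mir17, spacer):
        d = grammar.assemble_seed_only(mir17, spacer)
        iv = d.component("loop")
        assert d.full_sequence.residues[iv.start - 1 : iv.end] == "GAAA"

    def test_single_mismatch_scan_moves_across_seed(self, mir17, spacer):
        designs = grammar.seed_mismatch_scan(mir17, spacer)
        positions = [next(iter(d.binding_site_spec.mismatch_positions)) for d in designs]
        assert positions == list(range(2, 9))


class TestSeedSwap:
    def test_chimera_reproduces_donor_seed_segment(self, mir17, mir206, spacer):
        chimera = grammar.chimeric_mirna(mir206, mir17)
        assert chimera.seed_sequence().residues == mir17.seed_sequence().residues
        d_chim = grammar.assemble_seed_only(chimera, spacer)
        d_donor = grammar.assemble_seed_only(mir17, spacer)
        for d in (d_chim, d_donor):
            iv = d.component("binding_site")
        seg = lambda d: d.full_sequence.residues[
            d.component("binding_site").start - 1 : d.component("binding_site").end
        ]
        assert seg(d_chim) == seg(d_donor)


class TestTetraloopShield:
    def test_shield_sits_inside_scaffold_region(self, mir17, spacer):
        d = grammar.assemble_tetraloop_shield(mir17, spacer)
        names = [n for n, _ in d.components]
        assert names.index("shield") > names.index("scaffold_5p")
        assert names.index("shield") < names.index("scaffold_3p")
        assert validate_design(d) == []

    def test_spacer_position_unchanged(self, mir17, spacer):
        d = grammar.assemble_tetraloop_shield(mir17, spacer)
        assert d.spacer_interval.start == 1

    def test_missing_tetraloop_annotation_rejected(self, mir17, spacer):
        from mirswitch.core import Scaffold
        bare = Scaffold(
            "standard",
            grammar.load_scaffold("standard").sequence,
            {"repeat": grammar.load_scaffold("standard").annotations["repeat"]},
        )
        with pytest.raises(DesignError):
            grammar.assemble_tetraloop_shield(mir17, spacer, scaffold=bare)


class TestSplitAndGate:
    def test_units_block_disjoint_elements(self, mir17, mir16, spacer):
        pair = grammar.assemble_split_and_gate(mir17, mir16, spacer)
        assert pair.cr_unit.blocked_element == "spacer"
        assert pair.tracr_unit.blocked_element == "antirepeat"
        assert validate_design(pair.cr_unit) == []
        assert validate_design(pair.tracr_unit) == []

    def test_units_sense_distinct_mirnas(self, mir17, mir16, spacer):
        pair = grammar.assemble_split_and_gate(mir17, mir16, spacer)
        assert pair.cr_unit.mirna.sequence.residues != pair.tracr_unit.mirna.sequence.residues

    def test_same_mirna_twice_rejected(self, mir17, spacer):
        with pytest.raises(DesignError):
            grammar.assemble_split_and_gate(mir17, mir17, spacer)


class TestPolyUFix:
    def test_long_run_interrupted_once(self):
        out, edits = grammar.fix_poly_u("GUUUUUG")
        assert out.residues.count("UUUU") == 0
        assert len(edits) == 1 and edits[0][1] == "U->C"

    def test_no_long_run_is_identity(self):
        out, edits = grammar.fix_poly_u("GUUUAGAGC")
        assert out.residues == "GUUUAGAGC" and edits == []

    @given(st.text(alphabet="ACGU", min_size=1, max_size=50))
    def test_idempotent_and_run_free(self, seq):
        once, _ = grammar.fix_poly_u(seq)
        twice, edits = grammar.fix_poly_u(once)
        assert twice.residues == once.residues and edits == []
        assert "UUUU" not in once.residues


class TestScaffolds:
    def test_standard_annotations(self):
        sc = grammar.load_scaffold("standard")
        assert sc.first_repeat_g == 1
        tet = sc.annotations["tetraloop"]
        assert sc.sequence.residues[tet.start - 1 : tet.end] == "GAAA"

    def test_optimized_derives_from_standard_by_rule(self):
        std = grammar.load_scaffold("standard").sequence.residues
        opt = grammar.load_scaffold("optimized").sequence.residues
        extended = std[:12] + "UGCUG" + "GAAA" + "CAGCA" + std[16:]
        fixed, edits = grammar.fix_poly_u(extended)
        assert fixed.residues == opt
        assert len(edits) == 1

    def test_optimized_has_no_uracil_run(self):
        assert "UUUU" not in grammar.load_scaffold("optimized").sequence.residues[:40]


class TestTemplates:
    def test_u6_template_ends_in_terminator(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        tpl = grammar.emit_dna_template(d, grammar.TemplateSpec("U6"))
        assert tpl.endswith("T" * 6)
        assert "U" not in tpl

    def test_t7_template_starts_gg_after_promoter(self, mir17, spacer):
        d = grammar.assemble_full_length(mir17, spacer)
        spec = grammar.TemplateSpec("T7")
        tpl = grammar.emit_dna_template(d, spec)
        assert tpl.startswith(grammar.T7_PROMOTER)
        assert tpl[len(grammar.T7_PROMOTER) :].startswith("GG")

    @pytest.mark.parametrize("promoter", ["U6", "H1", "7SK", "T7"])
    def test_transcription_round_trip_modulo_leading_g(self, mir17, spacer, promoter):
        d = grammar.assemble_full_length(mir17, spacer)
        spec = grammar.TemplateSpec(promoter)
        rna = grammar.transcribe_template(grammar.emit_dna_template(d, spec), spec)
        assert rna.residues.lstrip("G") == d.full_sequence.residues.lstrip("G")

    def test_unknown_promoter_rejected(self):
        with pytest.raises(DesignError):
            grammar.TemplateSpec("CMV")
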