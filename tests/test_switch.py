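"""Switching diagnostics: OFF/ON states, invasion cost, displacement,
pathway robustness and the composite score."""

import dataclasses

import pytest

from mirswitch import grammar, switch, thermo
from mirswitch.core import DesignConstraints, DesignError, MismatchPattern
from mirswitch.thermo import CofoldParams


@pytest.fixture(scope="module")
def full_design(default_designs):
    return default_designs[0]


@pytest.fixture(scope="module")
def full_report(full_design):
    return switch.full_report(full_design)


class TestOffState:
    def test_switch_guide_sequesters_spacer(self, full_report):
        assert full_report.off_spacer_paired_fraction >= 0.75

    def test_standard_guide_spacer_mostly_accessible(self, panel, full_report):
        sg = grammar.standard_guide(panel.spacers[0])
        rep = switch.off_state_report(sg)
        assert rep.off_spacer_paired_fraction < full_report.off_spacer_paired_fraction

    def test_scaffold_stems_reported(self, full_report):
        assert "stem_loop_2" in full_report.scaffold_stem_probabilities
        assert all(0 <= v <= 1 for v in full_report.scaffold_stem_probabilities.values())

    def test_designed_pair_probabilities_reported(self, full_design, full_report):
        assert set(full_report.stem_pair_probabilities) == set(full_design.designed_pairs)


class TestOnStateProxy:
    def test_non_cognate_mirna_refused(self, full_design, mir206):
        with pytest.raises(DesignError):
            switch.on_state_proxy(full_design, mir206)

    def test_standard_guide_on_equals_off(self, panel):
        sg = grammar.standard_guide(panel.spacers[0])
        rep = switch.full_report(sg)
        assert rep.on_gain == 0.0
        assert rep.on_spacer_accessible_fraction == rep.off_spacer_accessible_fraction

    def test_cognate_mirna_accepted(self, full_design):
        rep = switch.on_state_proxy(full_design, full_design.mirna)
        assert 0.0 <= rep.on_spacer_accessible_fraction <= 1.0


class TestSeedInvasionCost:
    def test_cost_is_non_negative(self, default_designs):
        for d in default_designs:
            assert switch.seed_invasion_cost(d) >= 0.0

    def test_seed_mismatch_lowers_cost(self, mir17, panel):
        sp = panel.spacers[3]
        with_mm = grammar.assemble_seed_only(mir17, sp, site_mismatches=frozenset({2}))
        without = grammar.assemble_seed_only(mir17, sp, site_mismatches=frozenset())
        assert switch.seed_invasion_cost(with_mm) < switch.seed_invasion_cost(without)

    def test_no_binding_site_costs_nothing(self, panel):
        sg = grammar.standard_guide(panel.spacers[0])
        assert switch.seed_invasion_cost(sg) == 0.0


class TestStrandDisplacement:
    def test_weak_hairpin_toy_is_displaceable(self, panel):
        # dense shield mismatches leave only a marginal hairpin facing a
        # perfectly complementary trigger: displacement must win
        dense = MismatchPattern(
            frozenset({1, 2, 4, 5, 7, 8, 10, 11, 13, 14, 16}),
            frozenset({2, 3, 5, 6, 8, 9, 11, 12, 14, 15, 17}),
        )
        m, s = panel.pairs()[0]
        toy = grammar.assemble_full_length(m, s, site_mismatches=frozenset(), pattern=dense)
        dg, favorable = switch.strand_displacement_check(toy, m)
        assert favorable and dg < 0

    def test_seed_only_strictly_less_favorable_than_full(self, mir17, panel):
        sp = panel.spacers[3]
        d_full = grammar.assemble_full_length(mir17, sp)
        d_seed = grammar.assemble_seed_only(mir17, sp)
        dg_full, _ = switch.strand_displacement_check(d_full, mir17)
        dg_seed, _ = switch.strand_displacement_check(d_seed, mir17)
        assert dg_seed > dg_full

    def test_non_cognate_refused(self, full_design, mir206):
        with pytest.raises(DesignError):
            switch.strand_displacement_check(full_design, mir206)


class TestPathwayRobustness:
    def test_default_assembled_designs_are_robust(self, default_designs):
        for d in default_designs:
            assert switch.pathway_robustness(d)

    def test_alpha_zero_always_robust(self, default_designs):
        d = default_designs[0]
        assert switch.pathway_robustness(d, cofold_params=CofoldParams(alpha=0.0))

    def test_constructed_counterexample(self, panel):
        # a sequence whose equilibrium fold uses a long-range pairing the
        # reach-rescaled model abandons
        seq = "CAAGUACAUUUUUUCGUAGAUGUGCCUUGCUAACGAAAGUAUUAAACACGUCCCUCACAAU"
        eq = thermo.fold_mfe(seq)
        co = thermo.cofold_mfe(seq, None, CofoldParams())
        assert eq.dot_bracket != co.dot_bracket


class TestStabilityTrend:
    def test_sequestration_rises_and_score_falls_with_stability(self, reference):
        """Designed stem pairs hold ever more tightly as the hairpin gets
        more stable, while the design-criteria pass count drops (the
        over-stable variants stop being usable switches).  Sequestration is
        measured on the designed pairs because the thresholded
        spacer-fraction metric has a design-dependent ceiling."""
        constraints = DesignConstraints()
        stem_means, passes = [], []
        for d, _dg in reference.stability_series:
            rep = switch.full_report(d)
            _, checks = switch.switch_score(rep, constraints)
            vals = list(rep.stem_pair_probabilities.values())
            stem_means.append(sum(vals) / len(vals))
            passes.append(sum(checks.values()))
        assert all(b >= a - 0.02 for a, b in zip(stem_means, stem_means[1:]))
        assert stem_means[-1] > stem_means[0]
        assert passes[-1] < passes[0]


class TestSwitchScore:
    def test_reference_base_design_passes_core_criteria(self, reference):
        score, checks = switch.switch_score(reference.base_report, DesignConstraints())
        assert checks["off_sequestered"]
        assert checks["on_gain"]
        assert checks["dg_in_window"]
        assert checks["pair_probabilities"]
        assert checks["displacement_unfavorable"]
        assert score > 0

    def test_over_stable_design_fails(self, reference):
        d30, _ = reference.stability_series[-1]
        rep = switch.full_report(d30)
        _, checks = switch.switch_score(rep, DesignConstraints())
        assert not checks["over_stable"] or not checks["dg_in_window"]

    def test_over_blocked_seed_fails(self, reference):
        d10, _ = reference.seed_run_series[-1]
        rep = switch.full_report(d10)
        _, checks = switch.switch_score(rep, DesignConstraints())
        assert not checks["seed_not_over_blocked"]

    def test_incomplete_report_rejected(self):
        with pytest.raises(ValueError):
            switch.switch_score(switch.SwitchReport(), DesignConstraints())
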