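"""Mismatch-pattern search: enumeration, optimization, ranking, series."""

import itertools
import random
from statistics import median

import pytest

from mirswitch import grammar, optimize, switch
from mirswitch.core import DesignConstraints, MismatchPattern
from mirswitch.optimize import SearchConfig, _spacing_ok, _stem_space


@pytest.fixture(scope="module")
def skeleton(mir17, panel):
    return grammar.assemble_full_length(
        mir17, panel.spacers[3], pattern=MismatchPattern()
    )


class TestEnumeration:
    def test_pinned_with_no_extras_yields_single_pattern(self, skeleton):
        pinned = MismatchPattern(
            positions_in_binding_site=frozenset({3}),
            positions_in_shield_vs_spacer=frozenset({7}),
        )
        patterns = list(
            optimize.enumerate_mismatch_patterns(skeleton, pinned=pinned, max_extra=0)
        )
        assert patterns == [pinned]

    def test_clustered_patterns_excluded(self, skeleton):
        for pattern in optimize.enumerate_mismatch_patterns(skeleton, max_extra=2):
            space = _stem_space(skeleton)
            assert _spacing_ok(space.from_pattern(pattern))
        # four consecutive stem mismatches can never be yielded
        bad = frozenset({5, 6, 7, 8})
        assert not _spacing_ok(bad)

    def test_count_matches_brute_force_filter(self, skeleton):
        space = _stem_space(skeleton)
        positions = space.searchable
        brute = 0
        for r in range(0, 3):
            for combo in itertools.combinations(positions, r):
                if _spacing_ok(frozenset(combo)):
                    brute += 1
        enumerated = sum(
            1 for _ in optimize.enumerate_mismatch_patterns(skeleton, max_extra=2)
        )
        assert enumerated == brute

    def test_deterministic_order(self, skeleton):
        a = list(optimize.enumerate_mismatch_patterns(skeleton, max_extra=1))
        b = list(optimize.enumerate_mismatch_patterns(skeleton, max_extra=1))
        assert a == b


FAST = SearchConfig(seed=1, max_mismatches=6, shortlist=4, max_results=2)


class TestOptimizeDesign:
    def test_returned_designs_satisfy_hard_constraints(self, mir17, reference):
        cons = DesignConstraints()
        res = optimize.optimize_design(mir17, reference.spacer, constraints=cons, search=FAST)
        assert res.feasible
        for d, r in zip(res.designs, res.reports):
            lo, hi = cons.target_dg_window
            assert lo <= r.trigger_dg <= hi
            assert (r.seed_duplex_run or 0) <= cons.max_seed_duplex_run

    def test_same_seed_gives_identical_ranked_lists(self, mir17, reference):
        run = lambda: optimize.optimize_design(
            mir17, reference.spacer, search=FAST
        )
        a, b = run(), run()
        assert [d.full_sequence.residues for d in a.designs] == [
            d.full_sequence.residues for d in b.designs
        ]

    def test_unsatisfiable_window_reported(self, mir17, panel):
        cons = DesignConstraints(target_dg_window=(-200.0, -150.0))
        res = optimize.optimize_design(mir17, panel.spacers[3], constraints=cons, search=FAST)
        assert not res.feasible
        assert res.binding_constraint == "target_dg_window"

    def test_feasibility_monotone_in_window(self, mir17, panel):
        narrow = DesignConstraints(target_dg_window=(-18.0, -16.0))
        wide = DesignConstraints(target_dg_window=(-25.0, -10.0))
        cfg = SearchConfig(strategy="exhaustive_small", max_candidates=120, max_mismatches=2)
        res_n = optimize.optimize_design(mir17, panel.spacers[3], constraints=narrow, search=cfg)
        res_w = optimize.optimize_design(mir17, panel.spacers[3], constraints=wide, search=cfg)
        feas = lambda res: {
            (tuple(sorted(e.pattern.positions_in_binding_site)),
             tuple(sorted(e.pattern.positions_in_shield_vs_spacer)))
            for e in res.evaluations
            if e.feasible
        }
        assert feas(res_n) <= feas(res_w)

    def test_recovery_of_probability_target(self, reference):
        # from the mismatch-free skeleton the search recovers a pattern whose
        # designed-pair median sits at the hybridization target
        med = median(reference.base_report.stem_pair_probabilities.values())
        cons = DesignConstraints()
        assert abs(med - cons.per_pair_probability_target) <= 0.05


class TestRankDesigns:
    def test_single_candidate_is_itself(self, reference):
        d, r = reference.base_design, reference.base_report
        designs, reports = optimize.rank_designs([d], [r])
        assert designs == [d]

    def test_permutation_invariance(self, reference):
        designs = [d for d, _ in reference.stability_series[:3]]
        reports = [switch.full_report(d) for d in designs]
        a, _ = optimize.rank_designs(designs, reports)
        order = [2, 0, 1]
        b, _ = optimize.rank_designs([designs[i] for i in order], [reports[i] for i in order])
        assert [d.full_sequence.residues for d in a] == [d.full_sequence.residues for d in b]

    def test_length_mismatch_rejected(self, reference):
        with pytest.raises(ValueError):
            optimize.rank_designs([reference.base_design], [])


class TestSeries:
    def test_stability_series_hits_targets_in_order(self, reference):
        targets = (-15.0, -19.0, -25.0, -30.0)
        dgs = [dg for _, dg in reference.stability_series]
        for dg, t in zip(dgs, targets):
            assert abs(dg - t) <= 2.0
        assert dgs[0] > dgs[1] > dgs[2] > dgs[3]

    def test_seed_run_series_exact_runs_at_constant_dg(self, reference):
        for (d, dg), run in zip(reference.seed_run_series, (6, 8, 10)):
            assert switch.longest_seed_duplex_run(d) == run
            assert abs(dg - (-15.0)) <= 2.0
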