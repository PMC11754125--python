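"""Thermodynamics engine vs the exhaustive-enumeration oracle.

The MFE dynamic program, the partition function and the constrained folds
are all checked against brute-force enumeration of every nested structure
at small n, scored by the same loop-energy grammar.
"""

import math
import random

import numpy as np
import pytest

from mirswitch import thermo
from mirswitch.core import is_pair
from mirswitch.thermo import CofoldParams, EnergyModelParams


def random_seq(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


def boltzmann_reference(seq, params):
    """Exhaustive Z, MFE and pair probabilities for a short sequence."""
    structs = list(thermo.enumerate_structures(seq, params))
    rt = params.rt
    dgs = [s.delta_g for s in structs]
    z = sum(math.exp(-dg / rt) for dg in dgs)
    n = len(seq)
    p = np.zeros((n, n))
    for s in structs:
        w = math.exp(-s.delta_g / rt) / z
        for (i, j) in s.pairs:
            p[i - 1, j - 1] += w
            p[j - 1, i - 1] += w
    return structs, min(dgs), z, p


class TestEnumeration:
    def test_unpairable_sequence_has_single_structure(self, params):
        structs = list(thermo.enumerate_structures("AAAA", params))
        assert len(structs) == 1 and structs[0].dot_bracket == "...."

    def test_designed_hairpin_is_enumerated(self, params):
        dbs = {s.dot_bracket for s in thermo.enumerate_structures("GCGCAAAAGCGC", params)}
        assert "((((....))))" in dbs

    def test_count_matches_independent_recursion(self, params):
        rng = random.Random(3)
        for _ in range(10):
            seq = random_seq(rng, 12)

            def count(i, j):
                # independent recursion over nested matchings with min loop 3
                if j - i < params.min_loop + 1:
                    return 1
                total = count(i + 1, j)
                for k in range(i + params.min_loop + 1, j + 1):
                    if is_pair(seq[i - 1], seq[k - 1]):
                        total += count(i + 1, k - 1) * count(k + 1, j)
                return total

            assert count(1, len(seq)) == sum(
                1 for _ in thermo.enumerate_structures(seq, params)
            )

    def test_enumeration_cap_enforced(self, params):
        with pytest.raises(ValueError):
            next(thermo.enumerate_structures("A" * 30, params))


class TestStructureEnergy:
    def test_open_chain_scores_zero(self, params):
        assert thermo.structure_energy("ACGUACGUA", "." * 9, params) == 0.0

    def test_hand_summed_hairpin(self, params):
        # GGGAAAACCC folded (((....))): two GG/CC stacks at -3.26 each plus
        # a tetraloop initiation of +5.6 (AAAA is not a GNRA loop)
        e = thermo.structure_energy("GGGAAAACCC", "(((....)))", params)
        assert e == pytest.approx(2 * -3.26 + 5.6, abs=1e-9)

    def test_additive_over_independent_substructures(self):
        p = EnergyModelParams(dangle_mode="none")
        a, sa = "GGGAAAACCC", "(((....)))"
        b, sb = "GGCGCAAAAGCGCC", "(((((....)))))"
        e_sep = thermo.structure_energy(a, sa, p) + thermo.structure_energy(b, sb, p)
        e_join = thermo.structure_energy(a + "AAAA" + b, sa + "...." + sb, p)
        assert e_join == pytest.approx(e_sep, abs=1e-9)

    def test_inconsistent_structure_rejected(self, params):
        with pytest.raises(ValueError):
            thermo.structure_energy("AAAAAAAAA", "((.....))", params)  # A:A pair
        with pytest.raises(ValueError):
            thermo.structure_energy("GAAC", "(..)", params)  # loop too short


class TestOracleAgreement:
    def test_mfe_and_partition_function_match_enumeration(self, params):
        rng = random.Random(11)
        for _ in range(40):
            seq = random_seq(rng, rng.randint(5, 17))
            structs, brute_mfe, z, p_ref = boltzmann_reference(seq, params)
            mfe = thermo.fold_mfe(seq, params)
            assert mfe.delta_g == pytest.approx(brute_mfe, abs=1e-6)
            assert mfe.delta_g == pytest.approx(
                thermo.structure_energy(seq, mfe.pairs, params), abs=1e-9
            )
            pf = thermo.partition_function(seq, params)
            assert pf.log_z == pytest.approx(math.log(z), rel=1e-9, abs=1e-9)
            assert np.allclose(p_ref, pf.probabilities.matrix, rtol=1e-6, atol=1e-9)

    def test_constrained_fold_matches_constrained_enumeration(self, params):
        rng = random.Random(5)
        for _ in range(12):
            seq = random_seq(rng, rng.randint(6, 14))
            cons = {rng.randint(1, len(seq)): "unpaired"}
            brute = min(
                s.delta_g for s in thermo.enumerate_structures(seq, params, cons)
            )
            assert thermo.constrained_fold(seq, params, cons).delta_g == pytest.approx(
                brute, abs=1e-6
            )


class TestFoldBasics:
    def test_too_short_to_pair(self, params):
        s = thermo.fold_mfe("ACGUA", params)
        assert s.dot_bracket == "....." and s.delta_g == 0.0

    def test_poly_a_ensemble_is_trivial(self, params):
        pf = thermo.partition_function("AAAAAAAA", params)
        assert pf.log_z == 0.0
        assert pf.probabilities.matrix.max() == 0.0
        assert np.allclose(pf.probabilities.p_unpaired, 1.0)

    def test_probability_conservation(self, params):
        rng = random.Random(7)
        seq = random_seq(rng, 60)
        pf = thermo.partition_function(seq, params)
        row = pf.probabilities.matrix.sum(axis=1) + pf.probabilities.p_unpaired
        assert np.allclose(row, 1.0, atol=1e-9)

    def test_stack_extension_never_raises_mfe(self, params):
        prev = 0.0
        for k in range(3, 9):
            seq = "G" * k + "AAAA" + "C" * k
            dg = thermo.fold_mfe(seq, params).delta_g
            assert dg <= prev + 1e-9
            prev = dg

    def test_bitwise_determinism(self, params):
        rng = random.Random(13)
        seq = random_seq(rng, 90)
        first = thermo.fold_mfe(seq, params)
        thermo.clear_caches()
        second = thermo.fold_mfe(seq, params)
        assert first.dot_bracket == second.dot_bracket
        assert first.delta_g == second.delta_g

    def test_constrained_all_unpaired_is_open_chain(self, params):
        seq = "GCGCAAAAGCGC"
        s = thermo.constrained_fold(seq, params, {i: "unpaired" for i in range(1, 13)})
        assert s.dot_bracket == "." * 12 and s.delta_g == 0.0

    def test_empty_constraints_equal_unconstrained(self, params):
        seq = "GCGCAAAAGCGC"
        assert (
            thermo.constrained_fold(seq, params, {}).dot_bracket
            == thermo.fold_mfe(seq, params).dot_bracket
        )

    def test_contradictory_constraints_raise(self, params):
        with pytest.raises(ValueError):
            thermo.constrained_fold("AAAA", params, {1: "paired"})


class TestCofold:
    def test_alpha_zero_is_equilibrium_fold(self, params):
        rng = random.Random(17)
        for _ in range(5):
            seq = random_seq(rng, 70)
            eq = thermo.fold_mfe(seq, params)
            co = thermo.cofold_mfe(seq, params, CofoldParams(alpha=0.0))
            assert co.dot_bracket == eq.dot_bracket and co.delta_g == eq.delta_g

    def test_huge_tau_preserves_equilibrium_structure(self, params):
        seq = "GGGGAAAACCCCAAAGGGCAAACCC"
        eq = thermo.fold_mfe(seq, params)
        co = thermo.cofold_mfe(seq, params, CofoldParams(alpha=0.5, tau=1e9))
        assert co.dot_bracket == eq.dot_bracket

    def test_reach_scaling_can_change_the_structure(self, params):
        # found by search: equilibrium prefers a long-range pairing that the
        # distance-rescaled model abandons
        seq = "CAAGUACAUUUUUUCGUAGAUGUGCCUUGCUAACGAAAGUAUUAAACACGUCCCUCACAAU"
        eq = thermo.fold_mfe(seq, params)
        co = thermo.cofold_mfe(seq, params, CofoldParams(alpha=0.5, tau=640.0))
        assert eq.dot_bracket != co.dot_bracket

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CofoldParams(alpha=1.5)
        with pytest.raises(ValueError):
            CofoldParams(tau=0.0)


class TestDuplexEnergy:
    def test_no_complementarity_scores_zero(self, params):
        assert thermo.duplex_energy("AAAA", "CCCC", params) == 0.0

    def test_perfect_duplex_more_stable_than_mismatched(self, params, mir17):
        from mirswitch.core import reverse_complement

        perfect = reverse_complement(mir17.sequence)
        site = thermo.duplex_energy(perfect, mir17.sequence, params)
        from mirswitch.grammar import build_binding_site
        from mirswitch.core import BindingSiteSpec

        mm = build_binding_site(
            mir17, BindingSiteSpec(mode="full_length", mismatch_positions=frozenset({2, 9, 17}))
        )
        mismatched = thermo.duplex_energy(mm.sequence, mir17.sequence, params)
        assert site < mismatched < 0


class TestExternalCrossCheck:
    def test_mfe_ranks_agree_with_independent_package(self, params):
        import RNA  # ViennaRNA, used only as an independent oracle

        rng = random.Random(23)
        mine, ref = [], []
        for _ in range(30):
            seq = random_seq(rng, 50)
            mine.append(thermo.fold_mfe(seq, params).delta_g)
            ref.append(RNA.fold(seq)[1])
        order = lambda v: np.argsort(np.argsort(v))
        rho = np.corrcoef(order(mine), order(ref))[0, 1]
        assert rho > 0.8
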