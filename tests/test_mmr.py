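"""MMR attrition model: repair probabilities, expectation and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smartrbs import (
    GlosSpec,
    RepairModel,
    glos_candidates,
    repair_probability,
    simulate_editing,
)
from smartrbs.mmr import member_repair_probability
from smartrbs.seq_core import ALL_MISMATCH_PAIRS


class TestRepairProbability:
    def test_default_table_cutoff(self):
        m = RepairModel()
        assert repair_probability(6, m) == 0.0
        assert repair_probability(9, m) == 0.0   # clamp beyond table
        assert repair_probability(0, m) == 0.0   # nothing to repair
        assert repair_probability(1, m) == 0.9

    def test_user_table_lookup(self):
        m = RepairModel(table={3: 0.6})
        assert repair_probability(3, m) == 0.6
        assert repair_probability(7, m) == 0.6   # clamp to max key

    def test_validation(self):
        with pytest.raises(ValueError):
            RepairModel(table={})
        with pytest.raises(ValueError):
            RepairModel(table={2: 1.5})
        assert not RepairModel(table={1: 0.1, 2: 0.9}).is_monotone
        assert RepairModel().is_monotone


class TestMemberRepair:
    def test_long_run_invisible(self):
        assert member_repair_probability("CCCCCC", "AAAAAA", RepairModel()) == 0.0

    def test_all_cc_run_invisible_at_any_length(self):
        # oligo C opposite genomic G: C:C pairs, never recognized
        assert member_repair_probability("CCC", "GGG", RepairModel()) == 0.0

    def test_cc_inside_long_run_does_not_resurrect_repair(self):
        # full 6 bp mismatch containing one C:C position is still one
        # >= 6 nt heteroduplex bubble, hence invisible
        wild = "ACGTAC"
        member = "CACACA"  # mismatches at all six positions, C:C at the G
        assert member_repair_probability(member, wild, RepairModel()) == 0.0

    def test_short_recognized_run_repaired(self):
        assert member_repair_probability(
            "GAAAAA", "AAAAAA", RepairModel()
        ) == pytest.approx(0.9)

    def test_independent_runs_combine(self):
        # two separated 1 bp recognized mismatches: survives only if
        # neither is repaired
        p = member_repair_probability("GAAGAA", "AAAAAA", RepairModel(table={1: 0.5}))
        assert p == pytest.approx(1 - 0.5 * 0.5)

    def test_all_pairs_recognized_restores_cc_repair(self):
        m = RepairModel(table={3: 0.6}, recognized_pairs=ALL_MISMATCH_PAIRS)
        assert member_repair_probability("CCC", "GGG", m) == pytest.approx(0.6)


class TestExpectationMode:
    def test_glos_identity_full_counterselection(self, glos_pool_6mer):
        """The central design guarantee: a fully GLOS-compliant library is
        invisible to MMR, so composition passes through unchanged."""
        f = {m: 1 / len(glos_pool_6mer) for m in glos_pool_6mer}
        out = simulate_editing(f, "ACGTAC", beta=1.0, kappa=1.0)
        assert out.ar_efficiency == 1.0
        np.testing.assert_allclose(
            out.frequencies, [f[m] for m in out.members], atol=1e-9
        )

    def test_hand_arithmetic_example(self):
        model = RepairModel(table={1: 1.0, 6: 0.0})
        out = simulate_editing(
            {"CCCCCC": 0.5, "GAAAAA": 0.5}, "AAAAAA", model, beta=0.2, kappa=0.0
        )
        assert out.ar_efficiency == pytest.approx(0.1)
        assert out.member_frequencies == pytest.approx((1.0, 0.0))
        assert out.wild_fraction == pytest.approx(0.9)

    def test_frequencies_and_wild_sum_to_one(self):
        out = simulate_editing(
            {"CCCCCC": 0.3, "GTGTGT": 0.7}, "AAAAAA", beta=0.4, kappa=0.5
        )
        assert sum(out.frequencies) + out.wild_fraction == pytest.approx(1.0, abs=1e-9)

    def test_no_survivors_is_an_error(self):
        with pytest.raises(ValueError, match="no surviving clones"):
            simulate_editing({"CCCCCC": 1.0}, "AAAAAA", beta=0.0, kappa=1.0)

    @given(
        st.floats(0.05, 1.0), st.floats(0.0, 1.0),
        st.floats(0.05, 1.0), st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_ar_monotone_in_beta_and_kappa(self, b1, k1, b2, k2):
        freqs = {"GAAAAA": 0.5, "CCCCCC": 0.5}  # one repairable, one not
        model = RepairModel(table={1: 0.7, 6: 0.0})

        def ar(beta, kappa):
            return simulate_editing(
                freqs, "AAAAAA", model, beta=beta, kappa=kappa
            ).ar_efficiency

        lo_b, hi_b = sorted((b1, b2))
        assert ar(hi_b, k1) >= ar(lo_b, k1) - 1e-12
        lo_k, hi_k = sorted((k1, k2))
        assert ar(b1, hi_k) >= ar(b1, lo_k) - 1e-12

    def test_n6_diversity_bounded_by_glos_diversity(self):
        """Strong repair of short mismatches prunes a fully randomized
        library but not its GLOS counterpart."""
        wild = "ACGTAC"
        model = RepairModel(table={1: 1.0, 2: 1.0, 3: 1.0, 4: 0.3, 5: 0.1, 6: 0.0})
        from smartrbs import expand_degenerate

        n6 = sorted(expand_degenerate("N" * 6) - {wild})
        f_n6 = {m: 1 / len(n6) for m in n6}
        out_n6 = simulate_editing(f_n6, wild, model, beta=1.0, kappa=1.0)
        glos = sorted(glos_candidates(GlosSpec(wild)))
        f_g = {m: 1 / len(glos) for m in glos}
        out_g = simulate_editing(f_g, wild, model, beta=1.0, kappa=1.0)
        assert out_n6.diversity < len(n6)
        assert out_g.diversity == len(glos)


class TestSampledMode:
    def test_deterministic_under_seed(self):
        freqs = {"CCCCCC": 0.5, "GTGTGT": 0.5}
        a = simulate_editing(freqs, "AAAAAA", beta=0.5, kappa=0.3,
                             mode="sampled", seed=7, n_clones=200)
        b = simulate_editing(freqs, "AAAAAA", beta=0.5, kappa=0.3,
                             mode="sampled", seed=7, n_clones=200)
        assert a.frequencies == b.frequencies
        assert a.ar_efficiency == b.ar_efficiency

    def test_counts_are_exact_fractions(self):
        out = simulate_editing(
            {"CCCCCC": 1.0}, "AAAAAA", beta=0.5, kappa=0.0,
            mode="sampled", seed=1, n_clones=100,
        )
        total = sum(out.frequencies) + out.wild_fraction
        assert total == pytest.approx(1.0)

    def test_sampling_agrees_with_expectation(self):
        """Binomial check: sampled composition within 3 SE of expectation."""
        freqs = {"CCCCCC": 0.6, "GTGTGT": 0.4}
        model = RepairModel(table={1: 0.5, 6: 0.0})
        exp = simulate_editing(freqs, "AAAAAA", model, beta=0.7, kappa=0.5)
        n = 20_000
        smp = simulate_editing(freqs, "AAAAAA", model, beta=0.7, kappa=0.5,
                               mode="sampled", seed=123, n_clones=n)
        for p_exp, p_obs in zip(
            list(exp.frequencies) + [exp.wild_fraction],
            list(smp.frequencies) + [smp.wild_fraction],
        ):
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs(p_obs - p_exp) <= 3 * se + 1e-12
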