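import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midecomp import (
    ContingencyTable,
    FactorSpec,
    LoglinModel,
    conditional_mi,
    graph_extract,
    ipf_fit,
    make_alpha_split,
    model_deviance,
    mutual_information,
    parse_model,
    pythagorean_split,
    two_step_test,
)
from midecomp.infodecomp import InfoTerm
from midecomp.loglin import PythagoreanSplit, graph_to_dot
from midecomp.validation import poisson_glm_homogeneous_deviance, random_table


def gens(*sets):
    return LoglinModel(tuple(frozenset(s) for s in sets))


class TestModelParsing:
    def test_single_letter_concatenation(self):
        m = parse_model("{CA, CS, ADG}", list("CASDGMH"))
        assert frozenset("ADG") in m.generators
        assert len(m.generators) == 3

    def test_star_and_crossing_sign(self):
        m = parse_model("{A1*A3, A1×A12}", ["A1", "A3", "A12"])
        assert frozenset({"A1", "A12"}) in m.generators

    def test_ambiguity_requires_separator(self):
        # "A1A12" could split as A1+A12 only, but "A12A1" and tokens with
        # overlapping prefixes must not silently mis-parse
        with pytest.raises(ValueError):
            parse_model("{A1A2}", ["A1", "A2", "A1A", "2"])

    def test_subset_generator_rejected(self):
        with pytest.raises(ValueError):
            gens("XY", "X")


class TestIPF:
    def test_saturated_model_reproduces_counts(self, make_table):
        t = make_table(seed=20, n_factors=3)
        fit = ipf_fit(t, gens(t.factor_names))
        np.testing.assert_allclose(fit.fitted_means, t.counts, atol=1e-6)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        assert fit.p == 1.0

    def test_independence_model_closed_form(self):
        counts = np.array([[20, 10], [10, 20]])
        t = ContingencyTable(
            [FactorSpec("X", ("0", "1")), FactorSpec("Y", ("0", "1"))], counts
        )
        fit = ipf_fit(t, gens("X", "Y"))
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        np.testing.assert_allclose(fit.fitted_means, expected, atol=1e-8)
        # independence deviance is exactly the MI statistic
        assert fit.deviance == pytest.approx(
            mutual_information(t, "X", "Y").stat, abs=1e-8
        )
        assert fit.df == 1

    def test_homogeneous_model_true_gives_zero_deviance(self):
        # equal conditional odds ratios across strata by construction
        base = np.array([[40.0, 20.0], [10.0, 30.0]])
        counts = np.stack([base, 2 * base], axis=-1).astype(int)
        t = ContingencyTable([FactorSpec(n, ("0", "1")) for n in "XYZ"], counts)
        fit = ipf_fit(t, gens("XY", "XZ", "YZ"))
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)

    def test_margins_match_observed(self, make_table):
        t = make_table(seed=21, n_factors=3)
        a, b, c = t.factor_names
        model = gens((a, b), (b, c))
        fit = ipf_fit(t, model)
        assert fit.converged
        for g in model.generators:
            keep = [n for n in t.factor_names if n in g]
            obs = t.marginalize(keep).counts
            axes = tuple(i for i, n in enumerate(t.factor_names) if n not in g)
            np.testing.assert_allclose(fit.fitted_means.sum(axis=axes), obs, rtol=1e-6)

    def test_nested_models_monotone_deviance(self, make_table):
        t = make_table(seed=22, n_factors=3)
        a, b, c = t.factor_names
        d_small, *_ = model_deviance(t, gens((a,), (b,), (c,)))
        d_mid, *_ = model_deviance(t, gens((a, b), (c,)))
        d_big, *_ = model_deviance(t, gens((a, b), (a, c), (b, c)))
        assert d_small >= d_mid - 1e-8 >= d_big - 2e-8

    def test_non_convergence_warns(self, make_table):
        t = make_table(seed=23, n_factors=3)
        a, b, c = t.factor_names
        with pytest.warns(RuntimeWarning, match="IPF did not converge"):
            fit = ipf_fit(t, gens((a, b), (a, c), (b, c)), tol=1e-14, max_iter=1)
        assert not fit.converged

    def test_conditional_independence_deviance_equals_cmi(self, make_table):
        t = make_table(seed=24, n_factors=3)
        a, b, c = t.factor_names
        dev, df, _ = model_deviance(t, gens((a, c), (b, c)))
        term = conditional_mi(t, (a,), (b,), (c,))
        assert dev == pytest.approx(term.stat, abs=1e-6)
        assert df == term.df


class TestPythagoreanSplit:
    def test_conditionally_independent_table_all_zero(self):
        strata = [np.outer([3, 7], [4, 6]), np.outer([5, 5], [2, 8])]
        counts = (np.stack(strata, axis=-1) * 10).astype(int)
        t = ContingencyTable([FactorSpec(n, ("0", "1")) for n in "XYZ"], counts)
        s = pythagorean_split(t, ("X",), ("Y",), ("Z",))
        assert s.cmi.stat == pytest.approx(0.0, abs=1e-6)
        assert s.interaction.stat == pytest.approx(0.0, abs=1e-6)
        assert s.partial.stat == pytest.approx(0.0, abs=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_additivity_and_df_identity(self, seed):
        t = random_table(np.random.default_rng(seed), n_factors=3, max_levels=4)
        a, b, c = t.factor_names
        s = pythagorean_split(t, (a,), (b,), (c,))
        assert s.additivity_error < 1e-6
        assert s.interaction.df + s.partial.df == s.cmi.df

    def test_interaction_matches_poisson_glm_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            counts = rng.integers(1, 6, size=(2, 2, 2))
            t = ContingencyTable([FactorSpec(n, ("0", "1")) for n in "XYZ"], counts)
            s = pythagorean_split(t, ("X",), ("Y",), ("Z",), tol=1e-12, max_iter=5000)
            assert s.interaction.stat == pytest.approx(
                poisson_glm_homogeneous_deviance(counts), abs=1e-6
            )

    def test_credit_data_composite_conditioning(self, german_table):
        s = pythagorean_split(german_table, ("A12",), ("A21",), ("A1", "A3"))
        assert s.cmi.stat == pytest.approx(83.84, abs=0.01)
        assert s.cmi.df == 60
        assert s.interaction.stat == pytest.approx(66.97, abs=0.01)
        assert s.interaction.df == 57
        assert s.partial.stat == pytest.approx(16.87, abs=0.015)
        assert s.partial.df == 3


class TestAlphaSplit:
    def test_equal_mode_closed_form(self):
        split = make_alpha_split(0.05)
        assert split.alpha1 == pytest.approx(1 - math.sqrt(0.95))
        assert split.alpha1 == pytest.approx(0.02532, abs=1e-5)
        assert split.alpha1 == split.alpha2

    def test_specified_mode_solves_identity(self):
        split = make_alpha_split(0.05, "specified", alpha1=0.01)
        assert split.alpha2 == pytest.approx((0.05 - 0.01) / (1 - 0.01))
        ident = split.alpha1 + split.alpha2 - split.alpha1 * split.alpha2
        assert ident == pytest.approx(0.05, abs=1e-15)

    def test_zero_alpha1_degenerates_to_single_test(self):
        split = make_alpha_split(0.05, "specified", alpha1=0.0)
        assert split.alpha2 == pytest.approx(0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_alpha_split(0.0)
        with pytest.raises(ValueError):
            make_alpha_split(0.05, "specified", alpha1=0.06)


class TestTwoStepTest:
    @staticmethod
    def split_with_ps(p_int, p_par):
        """Build a split whose component p-values equal the given targets."""
        from scipy.stats import chi2

        cmi_df, int_df, par_df = 16, 15, 1
        int_stat = chi2.isf(p_int, int_df)
        par_stat = chi2.isf(p_par, par_df)
        return PythagoreanSplit(
            cmi=InfoTerm("CMI", ("X",), ("T",), ("Z",), int_stat + par_stat, cmi_df),
            interaction=InfoTerm("INT", ("X",), ("T",), ("Z",), int_stat, int_df),
            partial=InfoTerm("PAR", ("X",), ("T",), ("Z",), par_stat, par_df),
        )

    def test_partial_only_rejection(self):
        # interaction insignificant, partial highly significant
        split = self.split_with_ps(0.416, 0.001)
        dec = two_step_test(split, make_alpha_split(0.05, "specified", alpha1=0.0253))
        assert not dec.interaction_significant
        assert dec.partial_significant
        assert dec.rejected

    def test_nothing_significant(self):
        split = self.split_with_ps(0.99, 0.99)
        dec = two_step_test(split, make_alpha_split(0.05))
        assert not dec.rejected

    def test_alpha1_zero_boundary(self):
        split = self.split_with_ps(0.0001, 0.5)
        dec = two_step_test(split, make_alpha_split(0.05, "specified", alpha1=0.0))
        assert not dec.interaction_significant  # the Int test is switched off
        assert not dec.rejected


class TestGraphExtract:
    def test_stroke_style_model(self):
        model = parse_model("{CA, CS, MG, MS, ADG, ADH, SAH, SD}", list("CASDGMH"))
        edges, cliques = graph_extract(model)
        for pair in ({"C", "A"}, {"C", "S"}, {"M", "G"}, {"M", "S"}, {"S", "D"}):
            assert frozenset(pair) in edges
        assert frozenset({"A", "D"}) in edges  # inside ADG
        assert {frozenset(c) for c in cliques} == {
            frozenset("ADG"),
            frozenset("ADH"),
            frozenset("SAH"),
        }

    def test_pairwise_model_has_no_cliques(self):
        _, cliques = graph_extract(gens("XY", "YZ", "XZ"))
        assert cliques == []

    def test_single_four_factor_generator(self):
        edges, cliques = graph_extract(gens("WXYZ"))
        assert len(edges) == 6
        assert len(cliques) == 1 and len(cliques[0]) == 4

    def test_dot_output_is_text(self):
        dot = graph_to_dot(gens("XYZ"))
        assert dot.startswith("graph loglin {") and dot.endswith("}")
        assert '"X" -- "Y" [style=bold];' in dot
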