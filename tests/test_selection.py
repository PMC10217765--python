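import itertools

import numpy as np
import pytest

from midecomp import (
    SelectionConfig,
    backward_delete,
    build_model,
    crosstab,
    forward_select,
    pythagorean_split,
    rearrange_identity,
    select_and_build,
)
from midecomp.synth import FactorSpec, ScenarioSpec, sample_logistic_records
from midecomp.tables import GERMAN_CATEGORICAL


def logistic_records(coeffs, names, N=2000, seed=0, intercept=-0.5):
    params = {
        "target": "T",
        "coefficients": {"intercept": intercept, **coeffs},
        "predictor_probs": {n: [0.5, 0.5] for n in names},
    }
    factors = [FactorSpec(n, ("0", "1")) for n in names] + [FactorSpec("T", ("0", "1"))]
    spec = ScenarioSpec(factors, "logistic", params, N, seed)
    return sample_logistic_records(spec)


class TestForwardSelect:
    def test_single_strong_predictor_dominates(self):
        names = ["X1", "X2", "X3", "X4", "X5"]
        hits = 0
        base = np.random.default_rng(101)
        for _ in range(40):
            seed = int(base.integers(2**31))
            rec = logistic_records({"X1": [0.0, 2.0]}, names, seed=seed)
            selected, _ = forward_select(rec, "T", names)
            hits += selected[:1] == ["X1"]
        assert hits >= 38  # the active predictor leads essentially always

    def test_null_selection_rate_matches_family_size(self):
        """With no true effects, empty selection occurs in roughly
        (1 - alpha)^m of replicates."""
        names = ["X1", "X2", "X3", "X4"]
        base = np.random.default_rng(303)
        empty = 0
        reps = 60
        for _ in range(reps):
            seed = int(base.integers(2**31))
            rec = logistic_records({}, names, seed=seed)
            selected, _ = forward_select(rec, "T", names)
            empty += not selected
        expected = 0.95**4
        sd = np.sqrt(expected * (1 - expected) / reps)
        assert abs(empty / reps - expected) < 3 * sd + 1e-9

    def test_credit_data_first_pick_is_checking_status(self, german_records):
        """Among all 17 natively categorical credit attributes, A1 (account
        status) has both the largest MI ratio and the smallest p-value."""
        for criterion in ("mir", "min_p"):
            config = SelectionConfig(criterion=criterion, max_predictors=1)
            selected, _ = forward_select(
                german_records, "A21", list(GERMAN_CATEGORICAL), config
            )
            assert selected[0] == "A1"

    def test_target_among_candidates_rejected(self, german_records):
        with pytest.raises(ValueError):
            forward_select(german_records, "A21", ["A1", "A21"])


class TestBackwardDelete:
    def test_credit_data_drops_dispensable_predictor(self, german_records):
        retained, trace = backward_delete(german_records, "A21", ["A1", "A3", "A9"])
        assert sorted(retained) == ["A1", "A3"]
        assert trace.steps[0].chosen == "A9"

    def test_strongly_associated_set_is_kept(self):
        names = ["X1", "X2", "X3"]
        rec = logistic_records(
            {"X1": [0.0, 1.5], "X2": [0.0, -1.5], "X3": [0.0, 1.5]}, names, seed=7
        )
        retained, _ = backward_delete(rec, "T", names)
        assert sorted(retained) == names

    def test_appended_noise_predictor_is_deleted(self):
        names = ["X1", "X2", "X3"]
        base = np.random.default_rng(505)
        deleted = 0
        for _ in range(40):
            seed = int(base.integers(2**31))
            rec = logistic_records({"X1": [0.0, 1.5], "X2": [0.0, 1.5]}, names, seed=seed)
            retained, _ = backward_delete(rec, "T", names)
            deleted += sorted(retained) == ["X1", "X2"]
        assert deleted >= 36  # >= 90 percent of replicates


class TestRearrange:
    def test_credit_data_order_eliminates_significant_interactions(self, german_records):
        """With {A1, A3, A12}, one ordering leaves every interaction
        component insignificant; the search must find it (A12 outermost)."""
        r = rearrange_identity(german_records, "A21", ["A1", "A3", "A12"])
        assert r.order == ["A1", "A3", "A12"]
        config = SelectionConfig()
        alpha1 = config.alpha_split.alpha1
        for split in r.splits[1:]:
            assert split.interaction.p > alpha1

    def test_exhaustive_search_minimizes_significant_interactions(self, make_table):
        """Brute-force check: no permutation has fewer significant
        interaction components than the chosen order."""
        config = SelectionConfig()
        alpha1 = config.alpha_split.alpha1
        for seed in (31, 32, 33):
            t = make_table(seed=seed, n_factors=4, max_levels=3)
            names = t.factor_names
            target = names[-1]
            preds = names[:-1]

            def n_sig(order):
                count = 0
                for k in range(1, len(order)):
                    s = pythagorean_split(t, (order[k],), (target,), tuple(order[:k]))
                    count += s.interaction.p <= alpha1
                return count

            r = rearrange_identity(t, target, preds, config)
            chosen = n_sig(r.order)
            assert chosen == min(n_sig(list(p)) for p in itertools.permutations(preds))

    def test_chain_decomposition_is_attached_and_additive(self, german_records):
        r = rearrange_identity(german_records, "A21", ["A1", "A3"])
        assert r.decomposition.additivity_error < 1e-8
        assert len(r.splits) == 2 and r.splits[0] is None


class TestBuildModel:
    def test_credit_data_model_is_pure_main_effects(self, german_records):
        """The credit model keeps A1, A3, A12 as main effects with no
        interaction terms (the published decomposition has none)."""
        r = rearrange_identity(german_records, "A21", ["A1", "A3", "A12"])
        model = build_model(r, german_records, "A21")
        assert sorted(m[0] for m in model.mains) == ["A1", "A12", "A3"]
        assert model.interactions == []

    def test_single_predictor_model(self, german_records):
        r = rearrange_identity(german_records, "A21", ["A1"])
        model = build_model(r, german_records, "A21")
        assert model.mains == [("A1",)]
        assert model.interactions == []

    def test_all_interactions_insignificant_gives_pure_mains(self):
        names = ["X1", "X2"]
        rec = logistic_records({"X1": [0.0, 1.5], "X2": [0.0, 1.5]}, names, seed=11, N=4000)
        r = rearrange_identity(rec, "T", names)
        model = build_model(r, rec, "T")
        assert sorted(m[0] for m in model.mains) == names
        assert model.interactions == []


class TestDeterminism:
    def test_identical_runs_reproduce_trace(self):
        names = ["X1", "X2", "X3"]
        rec = logistic_records({"X1": [0.0, 1.5]}, names, seed=99)
        m1, t1 = select_and_build(rec, "T", names)
        m2, t2 = select_and_build(rec, "T", names)
        assert t1.to_tsv() == t2.to_tsv()
        assert m1.mains == m2.mains
        assert m1.interactions == m2.interactions

    def test_records_and_table_paths_agree(self):
        names = ["X1", "X2", "X3"]
        rec = logistic_records({"X1": [0.0, 1.5], "X2": [0.0, -1.0]}, names, seed=13)
        table = crosstab(rec, names + ["T"])
        sel_rec, _ = forward_select(rec, "T", names)
        sel_tab, _ = forward_select(table, "T", names)
        assert sel_rec == sel_tab

    def test_retained_is_subset_of_selected(self):
        names = ["X1", "X2", "X3", "X4"]
        rec = logistic_records({"X1": [0.0, 1.5], "X2": [0.0, 1.0]}, names, seed=5)
        selected, _ = forward_select(rec, "T", names)
        retained, _ = backward_delete(rec, "T", selected)
        assert set(retained) <= set(selected)
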