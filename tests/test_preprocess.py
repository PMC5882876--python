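"""QC filter, imputation, remission-derivation and split contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rxremit as rx
from rxremit.preprocess import (
    QcThresholds,
    SplitSpec,
    bagged_tree_impute,
    derive_remission,
    empirical_maf,
    filter_completeness,
    filter_maf,
    ld_prune,
    round_categorical,
    split_train_validation,
)


def _meta(names, vtype="continuous", levels=None):
    return pd.DataFrame(
        {
            "kind": "clinical",
            "vtype": vtype,
            "maf": np.nan,
            "levels": [levels] * len(names),
            "mean": np.nan,
            "sd": np.nan,
        },
        index=pd.Index(names, name="name"),
    )


class TestMafFilter:
    def test_monomorphic_dropped(self):
        # all-zeros has MAF 0; an all-heterozygote column has allele frequency
        # 0.5 (it is caught later by the zero-variance rule in LD pruning)
        G = pd.DataFrame({"a": np.zeros(100), "b": np.ones(100)})
        assert filter_maf(G, 0.01) == ["b"]
        assert ld_prune(G[["b"]], 0.8)[0] == []

    def test_three_heterozygotes_in_100_retained(self):
        col = np.zeros(100)
        col[:3] = 1.0  # MAF 3/200 = 0.015
        assert filter_maf(pd.DataFrame({"a": col}), 0.01) == ["a"]

    def test_exact_threshold_dropped(self):
        col = np.zeros(100)
        col[:2] = 1.0  # MAF exactly 0.01: strict inequality drops it
        assert filter_maf(pd.DataFrame({"a": col}), 0.01) == []

    def test_frequency_folded_above_half(self):
        col = np.full(100, 2.0)
        col[:3] = 1.0  # major allele coded as 2: folded MAF = 0.015
        assert empirical_maf(col) == pytest.approx(0.015)

    def test_all_missing_column_dropped(self):
        G = pd.DataFrame({"a": np.full(10, np.nan)})
        assert filter_maf(G, 0.01) == []


class TestCompletenessFilter:
    @pytest.mark.parametrize(
        "n_missing,expected", [(0, True), (4, True), (5, False)]
    )
    def test_430_sample_boundary(self, n_missing, expected):
        col = np.ones(430)
        col[:n_missing] = np.nan
        retained = filter_completeness(pd.DataFrame({"a": col}), 0.99)
        assert (retained == ["a"]) is expected


class TestLdPrune:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 200).astype(float)
        G = pd.DataFrame({"a": x, "b": x.copy()})
        retained, dropped = ld_prune(G, 0.8)
        assert retained == ["a"]
        assert dropped == {"b": "a"}

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(1)
        G = pd.DataFrame(rng.integers(0, 3, (500, 2)).astype(float),
                         columns=["a", "b"])
        retained, _ = ld_prune(G, 0.8)
        assert retained == ["a", "b"]

    def test_two_satellites_of_first_column_both_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        G = pd.DataFrame({
            "a": x,
            "b": x + 0.2 * rng.standard_normal(500),
            "c": x + 0.2 * rng.standard_normal(500),
        })
        # brute-force pairwise oracle confirms the construction
        r2 = G.corr().to_numpy() ** 2
        assert r2[0, 1] > 0.8 and r2[0, 2] > 0.8
        retained, dropped = ld_prune(G, 0.8)
        assert retained == ["a"]
        assert dropped == {"b": "a", "c": "a"}

    def test_chain_breaks_when_pairwise_low(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        z = rng.standard_normal(500)
        G = pd.DataFrame({"a": x, "b": x + 0.2 * rng.standard_normal(500), "c": z})
        retained, _ = ld_prune(G, 0.8)
        assert retained == ["a", "c"]

    def test_zero_variance_dropped(self):
        G = pd.DataFrame({"a": np.ones(50), "b": np.arange(50, dtype=float)})
        retained, _ = ld_prune(G, 0.8)
        assert retained == ["b"]

    def test_filter_order_insensitive_on_complete_data(self):
        cohort = rx.generate_cohort(
            rx.SimulationConfig(n_participants=300, n_snps=80, n_clinical=0,
                                maf_range=(0.02, 0.5), missing_rate=0.0, seed=5)
        )
        G = cohort.features
        a = set(filter_completeness(G[filter_maf(G, 0.01)], 0.99))
        b = set(filter_maf(G[filter_completeness(G, 0.99)], 0.01))
        assert a == b


class TestBaggedTreeImpute:
    def test_no_missing_identity(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        out = bagged_tree_impute(X, _meta(list("abc")), seed=0)
        pd.testing.assert_frame_equal(out, X)

    def test_perfect_predictor_recovery(self):
        rng = np.random.default_rng(1)
        donor = rng.integers(0, 5, 300).astype(float)
        col = donor.copy()
        mask = rng.random(300) < 0.1
        col[mask] = np.nan
        X = pd.DataFrame({"donor": donor, "target": col})
        meta = _meta(["donor", "target"], vtype="ordinal", levels=(0, 1, 2, 3, 4))
        out = bagged_tree_impute(X, meta, seed=0)
        agree = np.mean(out["target"].to_numpy()[mask] == donor[mask])
        assert agree >= 0.95

    def test_beats_marginal_sd_on_linear_signal(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(400), rng.standard_normal(400)
        target = 2.0 * a - b + 0.3 * rng.standard_normal(400)
        col = target.copy()
        mask = rng.random(400) < 0.1
        col[mask] = np.nan
        X = pd.DataFrame({"a": a, "b": b, "t": col})
        out = bagged_tree_impute(X, _meta(["a", "b", "t"]), seed=0)
        rmse = np.sqrt(np.mean((out["t"].to_numpy()[mask] - target[mask]) ** 2))
        assert rmse < target.std()

    def test_observed_cells_unaltered_and_deterministic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((80, 4)), columns=list("abcd"))
        X.loc[::7, "a"] = np.nan
        out1 = bagged_tree_impute(X, _meta(list("abcd")), seed=9)
        out2 = bagged_tree_impute(X, _meta(list("abcd")), seed=9)
        pd.testing.assert_frame_equal(out1, out2)
        obs = X["a"].notna()
        assert np.array_equal(out1.loc[obs, "a"], X.loc[obs, "a"])

    def test_fully_missing_column_is_error(self):
        X = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="'a'"):
            bagged_tree_impute(X, _meta(list("ab")), seed=0)


class TestRoundCategorical:
    @pytest.mark.parametrize(
        "value,levels,expected",
        [
            (2.6, (0, 1, 2, 3, 4), 3.0),
            (2.5, (0, 1, 2, 3, 4), 2.0),  # tie toward the smaller value
            (0.8, (0, 1), 1.0),
        ],
    )
    def test_nearest_admissible(self, value, levels, expected):
        X = pd.DataFrame({"a": [value]})
        out = round_categorical(X, _meta(["a"], vtype="ordinal", levels=levels))
        assert out["a"].iloc[0] == expected

    def test_only_imputed_cells_touched_with_mask(self):
        X = pd.DataFrame({"a": [2.6, 1.0]})
        mask = pd.DataFrame({"a": [True, False]})
        out = round_categorical(
            X, _meta(["a"], vtype="ordinal", levels=(0, 1, 2, 3, 4)), mask
        )
        assert list(out["a"]) == [3.0, 1.0]


class TestDeriveRemission:
    def test_boundary(self):
        assert list(derive_remission(np.array([7, 8, 0]))) == [1, 0, 1]

    @pytest.mark.parametrize("bad", [[-1], [53], [3.5]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            derive_remission(np.array(bad))


class TestSplit:
    def test_430_participants_gives_280_150(self):
        rng = np.random.default_rng(0)
        outcome = rng.integers(0, 2, 430)
        drug = np.where(rng.random(430) < 0.5, "A", "B")
        tr, va = split_train_validation(outcome, drug, SplitSpec(seed=1))
        assert len(tr) == 280 and len(va) == 150

    def test_small_balanced_split_preserves_proportions(self):
        outcome = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        drug = np.array(["A"] * 10)
        tr, va = split_train_validation(outcome, drug,
                                        SplitSpec(train_fraction=0.5, seed=2))
        assert len(tr) == 5 and len(va) == 5
        assert outcome[tr].sum() in (2, 3) and outcome[va].sum() in (2, 3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        outcome = rng.integers(0, 2, 97)
        drug = np.where(rng.random(97) < 0.5, "A", "B")
        s = SplitSpec(seed=7)
        assert np.array_equal(split_train_validation(outcome, drug, s)[0],
                              split_train_validation(outcome, drug, s)[0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n=st.integers(10, 300), seed=st.integers(0, 100))
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        rng = np.random.default_rng(seed)
        outcome = rng.integers(0, 2, n)
        drug = np.where(rng.random(n) < 0.5, "A", "B")
        tr, va = split_train_validation(outcome, drug, SplitSpec(seed=seed))
        assert len(np.intersect1d(tr, va)) == 0
        assert len(tr) + len(va) == n
        assert len(tr) == int(np.floor(n * 0.65 + 0.5))

    def test_stratum_proportions_within_one(self):
        rng = np.random.default_rng(2)
        outcome = rng.integers(0, 2, 430)
        drug = np.where(rng.random(430) < 0.5, "A", "B")
        tr, va = split_train_validation(outcome, drug, SplitSpec(seed=3))
        for o in (0, 1):
            for d in ("A", "B"):
                stratum = np.flatnonzero((outcome == o) & (drug == d))
                expected = len(stratum) * 280 / 430
                got = len(np.intersect1d(tr, stratum))
                assert abs(got - expected) <= 1.0

    def test_tiny_stratum_warns_and_goes_to_training(self):
        outcome = np.array([1] + [0] * 20)
        drug = np.array(["A"] + ["B"] * 20)
        with pytest.warns(UserWarning, match="fewer than 2"):
            tr, _ = split_train_validation(outcome, drug, SplitSpec(seed=0))
        assert 0 in tr


def test_preprocess_cohort_end_to_end(small_null_cohort):
    prep = small_null_cohort
    assert not prep.features.isna().to_numpy().any()
    assert set(np.unique(prep.outcome)) <= {0, 1}
    # imputed ordinal/binary clinical values are admissible
    for c in prep.clinical_columns:
        row = prep.feature_meta.loc[c]
        if row["vtype"] in ("ordinal", "binary"):
            assert set(np.unique(prep.features[c])) <= set(float(v) for v in row["levels"])
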