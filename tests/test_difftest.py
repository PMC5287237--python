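"""Designs, Bayes factors, permutation FDR, contrasts, hierarchy, enrichment."""

import numpy as np
import pandas as pd
import pytest

import gpgrowth as gg
from gpgrowth.difftest import (
    BFResult,
    STRAIN_TEST,
    STRESS_TEST,
    build_design,
    encode_table,
    fit_design,
    hierarchical_fit,
    permute_strain_labels,
)
from gpgrowth.exceptions import ParameterError, ValidationError
from gpgrowth.simulate import mean_curve


def _small_pair(seed=0, mu_scale=1.0, n_reps=4, stress=False, **kw):
    spec = gg.SyntheticSpec(
        strain_effect=gg.Effect(mu_scale=mu_scale),
        include_stress=stress,
        n_replicates=n_reps,
        timegrid=np.arange(0.0, 48.01, 6.0),
        seed=seed,
        **kw,
    )
    return gg.simulate_dataset(spec)


class TestBuildDesign:
    def test_strain_test_designs(self):
        tab = _small_pair()
        enc, null, alt = build_design(tab, STRAIN_TEST)
        assert null.columns == ("time",)
        assert alt.columns == ("time", "x_strain")
        assert set(enc.data["x_strain"]) == {0.0, 1.0}

    def test_parent_only_table_rejected(self):
        tab = _small_pair()
        parent_only = tab.with_data(tab.data[tab.data["strain"] == "parent"])
        with pytest.raises(ValidationError):
            build_design(parent_only, STRAIN_TEST)

    def test_stress_test_interaction_encoding(self):
        tab = _small_pair(stress=True)
        enc, null, alt = build_design(tab, STRESS_TEST)
        assert alt.columns == ("time", "x_strain", "x_stress", "x_interaction")
        df = enc.data
        on = (df["strain"] == "mutant") & (df["condition"] == "stress")
        assert (df.loc[on, "x_interaction"] == 1.0).all()
        assert (df.loc[~on, "x_interaction"] == 0.0).all()

    def test_interaction_is_product_of_encodings(self):
        tab = _small_pair(stress=True, seed=3)
        enc = encode_table(tab)
        df = enc.data
        assert np.array_equal(
            df["x_interaction"].to_numpy(),
            df["x_strain"].to_numpy() * df["x_stress"].to_numpy(),
        )

    def test_three_level_strain_rejected(self):
        tab = _small_pair()
        df = tab.data.copy()
        df.loc[df.index[:20], "strain"] = "other"
        df = df.drop_duplicates(subset=["replicate", "strain", "condition", "time"])
        with pytest.raises(ValidationError, match="3 levels"):
            build_design(tab.with_data(df), STRAIN_TEST)


class TestPermuteLabels:
    def test_per_timepoint_counts_preserved(self):
        tab = _small_pair(seed=1)
        out = permute_strain_labels(tab, "strain", seed=4)
        for t, idx in tab.data.groupby("time").indices.items():
            before = sorted(tab.data.loc[idx, "strain"])
            after = sorted(out.data.loc[idx, "strain"])
            assert before == after

    def test_single_label_is_identity(self):
        tab = _small_pair()
        parent = tab.with_data(tab.data[tab.data["strain"] == "parent"])
        out = permute_strain_labels(parent, "strain", seed=0)
        assert (out.data["strain"] == "parent").all()

    def test_different_seeds_differ(self):
        tab = _small_pair(seed=2, n_reps=6)
        a = permute_strain_labels(tab, "strain", seed=1)
        b = permute_strain_labels(tab, "strain", seed=2)
        assert not a.data["strain"].equals(b.data["strain"])

    def test_within_preserves_arm_composition(self):
        tab = _small_pair(stress=True, seed=5)
        out = permute_strain_labels(tab, "strain", seed=0, within=("condition",))
        for (_, _), idx in out.data.groupby(["time", "condition"]).indices.items():
            assert sorted(out.data.loc[idx, "strain"]) == sorted(
                tab.data.loc[idx, "strain"]
            )


class TestBFResultArithmetic:
    def test_fdr_at_threshold_boundary(self):
        # real score at the 80th-percentile boundary of 100 permutations:
        # 20 permuted exceedances over 1 real x 100 -> 0.2
        perm = np.arange(1.0, 101.0)
        res = BFResult(80.5, perm)
        assert res.fdr(80.4) == pytest.approx(20 / 100)

    def test_real_above_all_permutations(self):
        res = BFResult(200.0, np.arange(1.0, 101.0))
        assert res.fdr_at_real == 0.0
        assert res.significant

    def test_hand_built_vector(self):
        # perm BFs 1..100, real 90.5, threshold c = 90
        res = BFResult(90.5, np.arange(1.0, 101.0))
        assert res.fdr(90.0) == pytest.approx(10 / 100)

    def test_tie_at_threshold_not_significant(self):
        perm = np.concatenate([np.zeros(80), np.ones(20)])
        res = BFResult(np.quantile(perm, 0.8), perm)
        assert not res.significant


class TestBayesFactor:
    def test_strong_effect_detected(self):
        tab = _small_pair(seed=11, mu_scale=0.5, n_reps=6)
        enc, null, alt = build_design(tab, STRAIN_TEST)
        bf = gg.bayes_factor(enc, null, alt, seed=0)
        assert bf > 10

    def test_all_zero_covariate_changes_little(self):
        tab = _small_pair(seed=12, mu_scale=0.5, n_reps=4)
        enc, _, alt = build_design(tab, STRAIN_TEST)
        df = enc.data.assign(x_zero=0.0)
        enc2 = enc.with_data(df)
        m1 = fit_design(enc2, alt, seed=0)
        m2 = gg.fit_gp(enc2, ("time", "x_strain", "x_zero"), family="ard_rbf", seed=0,
                       restarts=1)
        assert abs(m1.log_marginal - m2.log_marginal) < 1.0

    def test_non_nested_designs_rejected(self):
        tab = _small_pair()
        enc, null, alt = build_design(tab, STRAIN_TEST)
        with pytest.raises(ParameterError):
            gg.bayes_factor(enc, alt, null)


class TestPermutationTest:
    def test_reproducible_given_seed(self):
        tab = _small_pair(seed=21, mu_scale=0.7, n_reps=3)
        a = gg.permutation_test(tab, STRAIN_TEST, n_perm=8, seed=3)
        b = gg.permutation_test(tab, STRAIN_TEST, n_perm=8, seed=3)
        assert a.log_bf == b.log_bf
        assert np.array_equal(a.perm_log_bfs, b.perm_log_bfs)

    def test_effect_significant(self):
        tab = _small_pair(seed=22, mu_scale=0.5, n_reps=6)
        res = gg.permutation_test(tab, STRAIN_TEST, n_perm=20, seed=1)
        assert res.significant
        assert res.fdr_at_real <= 0.2

    def test_too_few_permutations_refused(self):
        tab = _small_pair()
        with pytest.raises(ParameterError):
            gg.permutation_test(tab, STRAIN_TEST, n_perm=4)


@pytest.fixture(scope="module")
def offset_model():
    spec = gg.SyntheticSpec(
        strain_effect=gg.Effect(offset=0.5),
        n_replicates=6,
        timegrid=np.arange(0.0, 48.01, 2.0),
        seed=31,
    )
    tab = gg.simulate_dataset(spec)
    enc, _, alt = build_design(tab, STRAIN_TEST)
    return fit_design(enc, alt, restarts=2, seed=0)


class TestODDelta:
    def test_t0_is_exactly_zero(self, offset_model):
        series = gg.od_delta(offset_model, np.linspace(0, 48, 20))
        assert series.mean[0] == 0.0
        assert series.variance[0] == 0.0
        assert not series.significant_mask[0]

    def test_t0_prepended_when_missing(self, offset_model):
        series = gg.od_delta(offset_model, np.linspace(10, 48, 10))
        assert series.times[0] == pytest.approx(0.0)

    def test_offset_recovered_and_significant_late(self, offset_model):
        series = gg.od_delta(offset_model, np.linspace(0, 48, 25))
        late = series.times > 24
        assert 0.3 <= np.mean(series.mean[late]) <= 0.7
        assert series.significant_mask[late].all()

    def test_null_pair_mostly_not_significant(self):
        spec = gg.SyntheticSpec(
            n_replicates=6, timegrid=np.arange(0.0, 48.01, 3.0), seed=32
        )
        tab = gg.simulate_null_pair(spec, seed=32)
        enc, _, alt = build_design(tab, STRAIN_TEST)
        model = fit_design(enc, alt, restarts=2, seed=0)
        series = gg.od_delta(model, np.linspace(0, 48, 17))
        assert np.abs(series.mean).max() < 4 * 0.05 / np.sqrt(6) + 0.05
        assert series.significant_mask.mean() <= 0.25

    def test_interaction_contrast_mode(self):
        spec = gg.SyntheticSpec(
            include_stress=True,
            interaction_effect=gg.Effect(mu_scale=0.6),
            n_replicates=4,
            timegrid=np.arange(0.0, 48.01, 6.0),
            seed=33,
        )
        tab = gg.simulate_dataset(spec)
        enc, _, alt = build_design(tab, STRESS_TEST)
        model = fit_design(enc, alt, restarts=2, seed=0)
        series = gg.od_delta(model, np.arange(0.0, 48.01, 6.0), "interaction_contrast")
        # slower growth under the interaction: the contrast dips negative
        assert series.mean.min() < -0.2
        assert series.significant_mask.any()


class TestHierarchical:
    def test_additive_decomposition(self):
        spec = gg.SyntheticSpec(
            n_batches=2,
            n_replicates=3,
            batch_offsets=gg.BatchOffsets(mode="sinusoid", amplitudes=(0.3, -0.3)),
            timegrid=np.arange(0.0, 48.01, 4.0),
            seed=41,
        )
        tab = gg.simulate_dataset(spec)
        par = tab.with_data(tab.data[tab.data["strain"] == "parent"])
        batches = [par.with_data(df) for _, df in par.data.groupby("batch")]
        h = hierarchical_fit(batches, ("time",), seed=0)
        tg = np.arange(0.0, 48.01, 4.0)[:, None]
        total = h.predict_batch("batch0", tg).mean
        parts = h.predict_shared(tg).mean + h.predict_batch_deviation("batch0", tg).mean
        assert np.allclose(total, parts, atol=1e-8)

    def test_zero_batch_effect_matches_pooled_fit(self):
        spec = gg.SyntheticSpec(
            n_batches=2,
            n_replicates=4,
            batch_offsets=gg.BatchOffsets(mode="sinusoid", amplitudes=(0.0, 0.0)),
            timegrid=np.arange(0.0, 48.01, 3.0),
            seed=42,
        )
        tab = gg.simulate_dataset(spec)
        par = tab.with_data(tab.data[tab.data["strain"] == "parent"])
        batches = [par.with_data(df) for _, df in par.data.groupby("batch")]
        h = hierarchical_fit(batches, ("time",), seed=0)
        pooled = par.with_data(par.data.drop(columns=["batch"]))
        plain = gg.fit_gp(pooled, ("time",), restarts=2, seed=0)
        tg = np.arange(0.0, 48.01, 3.0)[:, None]
        pg, pp = h.predict_shared(tg), plain.predict(tg)
        sd = np.sqrt(np.maximum(pg.var, 1e-10))
        assert np.all(np.abs(pg.mean - pp.mean) <= 2 * sd + 0.02)

    def test_opposite_offsets_removed_from_shared_function(self):
        spec = gg.SyntheticSpec(
            n_batches=2,
            n_replicates=6,
            batch_offsets=gg.BatchOffsets(mode="sinusoid", amplitudes=(0.4, -0.4)),
            timegrid=np.arange(0.0, 48.01, 2.0),
            seed=21,
        )
        tab = gg.simulate_dataset(spec)
        par = tab.with_data(tab.data[tab.data["strain"] == "parent"])
        batches = [par.with_data(df) for _, df in par.data.groupby("batch")]
        h = hierarchical_fit(batches, ("time",), seed=0)
        tg = np.arange(0.0, 48.01, 2.0)
        post = h.predict_shared(tg[:, None])
        truth = mean_curve(spec, 0, 0)
        assert np.max(np.abs(post.mean - truth)) < 0.15

    def test_single_batch_falls_back_with_warning(self):
        tab = _small_pair(seed=43)
        enc = encode_table(tab)
        with pytest.warns(UserWarning, match="single batch"):
            model = hierarchical_fit([enc], ("time", "x_strain"), seed=0)
        assert isinstance(model, gg.FittedGP)

    def test_identical_batches_match_plain_stress_test(self):
        spec = gg.SyntheticSpec(
            include_stress=True,
            n_batches=2,
            interaction_effect=gg.Effect(mu_scale=0.7),
            batch_offsets=gg.BatchOffsets(mode="sinusoid", amplitudes=(0.0, 0.0)),
            n_replicates=3,
            timegrid=np.arange(0.0, 48.01, 6.0),
            seed=44,
        )
        tab = gg.simulate_dataset(spec)
        batches = [tab.with_data(df) for _, df in tab.data.groupby("batch")]
        enc_b = [encode_table(b) for b in batches]
        alt_cols = ("time", "x_strain", "x_stress", "x_interaction")
        null_cols = ("time", "x_strain", "x_stress")
        h_alt = hierarchical_fit(enc_b, alt_cols, seed=0)
        h_null = hierarchical_fit(enc_b, null_cols, seed=0)
        h_bf = h_alt.log_marginal - h_null.log_marginal

        pooled = gg.GrowthTable(tab.data.drop(columns=["batch"]), True)
        enc, null, alt = build_design(pooled, STRESS_TEST)
        p_bf = fit_design(enc, alt, seed=0).log_marginal - fit_design(
            enc, null, seed=0
        ).log_marginal
        assert h_bf == pytest.approx(p_bf, abs=max(1.0, 0.2 * abs(p_bf)))


class TestEnrichment:
    def test_certainty(self):
        assert gg.enrichment_test(10, 5, 10, 5) == pytest.approx(1.0)

    def test_exact_combinatorics(self):
        # all 5 successes drawn in 5 draws from 10 with 5 successes: 1/C(10,5)
        assert gg.enrichment_test(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_observed(self):
        assert gg.enrichment_test(20, 8, 6, 0) == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ParameterError):
            gg.enrichment_test(10, 5, 5, 6)
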