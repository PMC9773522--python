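"""Normalization core: CPM/FPKM, filtering, TMM, log-CPM, weights, MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sexdiff as sd
from sexdiff.expression import leading_logfc_mds, precision_weights, remove_batch_effect

from conftest import make_count_matrix


class TestSumTechnicalReplicates:
    def _cm(self):
        counts = pd.DataFrame(
            {"s1a": [3, 1], "s1b": [4, 0], "s2a": [5, 2], "s2b": [6, 3]},
            index=["g1", "g2"],
        )
        meta = pd.DataFrame(
            {
                "sex": ["female"] * 4,
                "batch": ["b1"] * 4,
                "lane": ["L1", "L2", "L1", "L2"],
                "replicate_group": ["s1", "s1", "s2", "s2"],
            },
            index=counts.columns,
        )
        return make_count_matrix(counts, meta=meta)

    def test_counts_summed_and_conserved(self):
        out = sd.sum_technical_replicates(self._cm())
        assert out.counts.loc["g1", "s1"] == 7
        assert out.counts.to_numpy().sum() == 24
        assert list(out.counts.columns) == ["s1", "s2"]
        assert out.sample_metadata.loc["s1", "lane"] == "L1,L2"

    def test_singleton_groups_identity(self):
        cm = make_count_matrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
        out = sd.sum_technical_replicates(cm)
        assert (out.counts.to_numpy() == cm.counts.to_numpy()).all()

    def test_conflicting_metadata_rejected(self):
        cm = self._cm()
        cm.sample_metadata.loc["s1a", "sex"] = "male"
        with pytest.raises(ValueError, match="conflicting.*sex"):
            sd.sum_technical_replicates(cm)


class TestCPMFPKM:
    def test_cpm_arithmetic(self):
        cm = make_count_matrix(pd.DataFrame({"s": [1, 3]}))
        cpm = sd.compute_cpm(cm)
        assert list(cpm["s"]) == [250_000.0, 750_000.0]

    def test_cpm_scale_invariance_and_zero_gene(self):
        counts = pd.DataFrame({"a": [0, 10, 30], "b": [0, 20, 60]})
        cpm = sd.compute_cpm(make_count_matrix(counts))
        assert (cpm.loc[0] == 0).all()
        assert np.allclose(cpm["a"], cpm["b"])

    def test_zero_depth_rejected_naming_sample(self):
        cm = make_count_matrix(pd.DataFrame({"ok": [1], "empty": [0]}))
        with pytest.raises(ValueError, match="empty"):
            sd.compute_cpm(cm)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 1000), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_cpm_columns_sum_to_1e6(self, rows):
        counts = pd.DataFrame(rows, columns=[f"s{j}" for j in range(3)])
        if (counts.sum(axis=0) == 0).any():
            return
        cpm = sd.compute_cpm(make_count_matrix(counts))
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_fpkm_arithmetic(self):
        cm = make_count_matrix(
            pd.DataFrame({"s": [10, 0] + [0] * 8 + [999_990]}), lengths=[2000] * 11
        )
        fpkm = sd.compute_fpkm(cm)
        assert fpkm.loc[0, "s"] == pytest.approx(5.0)
        assert fpkm.loc[1, "s"] == 0.0

    def test_fpkm_halved_length_doubles(self):
        counts = pd.DataFrame({"s": [10, 10]})
        f1 = sd.compute_fpkm(make_count_matrix(counts, lengths=[2000, 1000]))
        assert f1.loc[1, "s"] == pytest.approx(2 * f1.loc[0, "s"])


class TestFilterExpressed:
    def _cm(self):
        counts = pd.DataFrame(
            {
                "f1": [100, 0, 0, 50],
                "f2": [120, 0, 0, 60],
                "m1": [0, 90, 0, 55],
                "m2": [0, 80, 0, 1],
            },
            index=["fem_only", "male_only", "silent", "mixed"],
        )
        cm = make_count_matrix(counts, lengths=[1000] * 4)
        cm.sample_metadata["sex"] = ["female", "female", "male", "male"]
        return cm

    def test_one_full_group_suffices(self):
        cm = self._cm()
        groups = {"female": ["f1", "f2"], "male": ["m1", "m2"]}
        out, kept = sd.filter_expressed(cm, groups)
        assert "fem_only" in kept and "male_only" in kept
        assert "silent" not in kept
        assert "mixed" in kept  # passes via the female group

    def test_idempotent(self):
        cm = self._cm()
        groups = {"female": ["f1", "f2"], "male": ["m1", "m2"]}
        once, kept1 = sd.filter_expressed(cm, groups)
        twice, kept2 = sd.filter_expressed(once, groups)
        assert kept1 == kept2

    def test_mean_rule_and_empty_group(self):
        cm = self._cm()
        groups = {"female": ["f1", "f2"], "male": ["m1", "m2"]}
        _, kept = sd.filter_expressed(cm, groups, rule="mean_of_any_group")
        assert "mixed" in kept
        with pytest.raises(ValueError, match="empty group"):
            sd.filter_expressed(cm, {"a": []})


def brute_force_tmm(counts: pd.DataFrame, logratio_trim=0.30, abs_trim=0.05):
    """Independent evaluation of the trimmed weighted-mean definition,
    using explicit sorting instead of ranks."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    x = counts.to_numpy(dtype=float)
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(x.shape[1]):
        obs, refv = x[:, j], x[:, ref]
        keep = (obs > 0) & (refv > 0)
        o, r = obs[keep] / lib[j], refv[keep] / lib[ref]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (
            lib[ref] - refv[keep]
        ) / (lib[ref] * refv[keep])
        if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        from scipy.stats import rankdata

        n = len(m)
        cut_m = np.floor(n * logratio_trim)
        cut_a = np.floor(n * abs_trim)
        rm, ra = rankdata(m), rankdata(a)
        sel = (
            (rm >= cut_m + 1)
            & (rm <= n - cut_m)
            & (ra >= cut_a + 1)
            & (ra <= n - cut_a)
        )
        if not sel.any():
            factors.append(1.0)
            continue
        f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors.append(2.0 ** f if np.isfinite(f) else 1.0)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        f, eff = sd.tmm_normalize(make_count_matrix(counts))
        assert np.allclose(f, 1.0)
        assert np.allclose(eff, counts.sum(axis=0))

    def test_pure_depth_change_gives_unit_factor(self):
        base = np.array([5, 10, 3, 40, 7])
        counts = pd.DataFrame({"a": base, "b": base * 3, "c": base})
        f, _ = sd.tmm_normalize(make_count_matrix(counts))
        assert np.allclose(f, 1.0)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for trial in range(25):
            g = rng.integers(6, 11)
            n = rng.integers(2, 6)
            counts = pd.DataFrame(
                rng.negative_binomial(4, 0.2, size=(g, n)) + rng.integers(0, 2, size=(g, n)),
                columns=[f"s{j}" for j in range(n)],
            )
            if (counts.sum(axis=0) == 0).any():
                continue
            f, _ = sd.tmm_normalize(make_count_matrix(counts))
            expected = brute_force_tmm(counts)
            assert np.allclose(f.to_numpy(), expected, atol=1e-8), trial

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 4)), columns=list("abcd"))
        f, _ = sd.tmm_normalize(make_count_matrix(counts))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            sd.tmm_normalize(make_count_matrix(pd.DataFrame({"a": [1, 2]})))


class TestLogCPM:
    def test_zero_count_finite(self):
        counts = pd.DataFrame({"a": [0, 100, 50], "b": [0, 90, 60]})
        lc = sd.log_cpm_transform(make_count_matrix(counts))
        assert np.isfinite(lc.to_numpy()).all()

    def test_monotone_within_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [1, 1, 1]})
        lc = sd.log_cpm_transform(make_count_matrix(counts))
        assert lc.loc[1, "a"] > lc.loc[0, "a"] > lc.loc[2, "a"]

    def test_small_prior_limit_equals_log2_cpm(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [15, 25, 35]})
        cm = make_count_matrix(counts)
        lc = sd.log_cpm_transform(cm, prior_count=1e-9)
        assert np.allclose(lc, np.log2(sd.compute_cpm(cm)), atol=1e-6)

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            sd.log_cpm_transform(make_count_matrix(pd.DataFrame({"a": [1], "b": [1]})), prior_count=0)


class TestPrecisionWeights:
    def test_homoskedastic_data_gets_flat_weights(self):
        rng = np.random.default_rng(5)
        n, g = 16, 2000
        means = rng.uniform(2, 10, size=g)
        y = means[:, None] + rng.normal(0, 0.5, size=(g, n))
        lc = pd.DataFrame(y, columns=[f"s{j}" for j in range(n)])
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        w, _ = precision_weights(lc, X)
        assert w.to_numpy().max() / w.to_numpy().min() < 1.5

    def test_decreasing_trend_weights_increase_with_mean(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        n, g = 16, 2000
        means = rng.uniform(0, 10, size=g)
        sds = 1.0 / (1.0 + 0.5 * means)  # variance falls with mean
        y = means[:, None] + rng.normal(0, 1, size=(g, n)) * sds[:, None]
        lc = pd.DataFrame(y, columns=[f"s{j}" for j in range(n)])
        X = np.ones((n, 1))
        w, _ = precision_weights(lc, X)
        rho = spearmanr(means, w.mean(axis=1)).statistic
        assert rho > 0.9

    def test_weights_positive_finite(self, small_fit):
        w = small_fit.norm.precision_weight.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()


class TestMDS:
    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, size=(40, 4))
        y[:, 3] = y[:, 0]
        lc = pd.DataFrame(y, columns=list("abcd"))
        coords, dist = leading_logfc_mds(lc, n_top=40)
        assert dist.loc["a", "d"] == 0
        assert np.allclose(coords.loc["a"], coords.loc["d"], atol=1e-9)

    def test_three_sample_coordinates_reproduce_distances(self):
        # hand-computable: distances from 2 genes, RMS differences
        lc = pd.DataFrame(
            {"a": [0.0, 0.0], "b": [2.0, 0.0], "c": [0.0, 2.0]}
        )
        coords, dist = leading_logfc_mds(lc, n_top=2)
        d_ab = np.sqrt(np.mean([4.0, 0.0]))
        assert dist.loc["a", "b"] == pytest.approx(d_ab)
        for i in "abc":
            for j in "abc":
                got = np.linalg.norm(coords.loc[i] - coords.loc[j])
                assert got == pytest.approx(dist.loc[i, j], abs=1e-8)

    def test_distance_matrix_properties(self, small_fit):
        _, dist = leading_logfc_mds(small_fit.norm.log_cpm, n_top=100)
        d = dist.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all()

    def test_pairwise_selection_and_validation(self):
        rng = np.random.default_rng(9)
        lc = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        coords, dist = leading_logfc_mds(lc, n_top=10, gene_selection="pairwise")
        assert coords.shape == (5, 2)
        with pytest.raises(ValueError, match="n_top"):
            leading_logfc_mds(lc, n_top=0)


class TestRemoveBatchEffect:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(10)
        lc = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        out = remove_batch_effect(lc, ["b1"] * 4)
        pd.testing.assert_frame_equal(out, lc)

    def test_pure_additive_shift_removed(self):
        rng = np.random.default_rng(11)
        base = rng.normal(5, 1, size=(30, 6))
        shifted = base.copy()
        shifted[:, 3:] += 0.7
        lc = pd.DataFrame(shifted, columns=list("abcdef"))
        out = remove_batch_effect(lc, ["b1"] * 3 + ["b2"] * 3)
        diff = out[list("abc")].mean(axis=1) - out[list("def")].mean(axis=1)
        assert np.allclose(diff, 0, atol=1e-10)

    def test_orthogonal_batch_preserves_sex_difference(self):
        rng = np.random.default_rng(12)
        n = 8
        sex = np.array([1, 0] * 4)
        batch = np.array(["b1"] * 4 + ["b2"] * 4)
        y = rng.normal(size=(25, n)) + 2.0 * sex + 0.5 * (batch == "b2")
        lc = pd.DataFrame(y, columns=[f"s{j}" for j in range(n)])
        X = np.column_stack([np.ones(n), sex])
        out = remove_batch_effect(lc, batch, retained_design=X)
        before = lc.loc[:, sex == 1].mean(axis=1) - lc.loc[:, sex == 0].mean(axis=1)
        after = out.loc[:, sex == 1].mean(axis=1) - out.loc[:, sex == 0].mean(axis=1)
        assert np.allclose(before, after, atol=1e-10)

    def test_confounded_batch_rejected(self):
        lc = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        X = np.column_stack([np.ones(4), [1, 1, 0, 0]])
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effect(lc, ["b1", "b1", "b2", "b2"], retained_design=X)
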