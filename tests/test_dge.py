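"""Filtering, TMM, dispersion estimation, NB tests and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cortiseq.dge import (
    adjust_bh,
    estimate_common_dispersion,
    filter_by_expression,
    filter_threshold,
    nb_exact_test,
    nb_glm_batch_test,
    tmm_factors,
)
from cortiseq.errors import ConfigError, DataError
from cortiseq.io import CountMatrix
from cortiseq.simulate import GroupSpec, SimConfig, simulate_counts
from tests.conftest import make_metadata, two_group_counts


class TestFilterThreshold:
    def test_study_depth_gives_one_third_cpm(self):
        assert round(filter_threshold(10, 30_000_000), 2) == 0.33

    @pytest.mark.parametrize("mc, lib, expected", [(10, 1e6, 10.0), (1, 1e6, 1.0)])
    def test_arithmetic(self, mc, lib, expected):
        assert filter_threshold(mc, lib) == pytest.approx(expected)

    @pytest.mark.parametrize("mc, lib", [(0, 1e6), (10, 0), (-1, 1e6)])
    def test_nonpositive_rejected(self, mc, lib):
        with pytest.raises(ConfigError):
            filter_threshold(mc, lib)


class TestFilterByExpression:
    def _matrix(self):
        # 4 samples in groups of 2; all libraries 1000 => threshold(5) = 5000 CPM = 5 counts
        df = pd.DataFrame(
            {
                "a1": [5, 5, 4, 986],
                "a2": [4, 5, 4, 987],
                "b1": [5, 5, 4, 986],
                "b2": [4, 0, 4, 992],
            },
            index=["boundary", "three_hits", "low", "anchor"],
        )
        groups = ["A", "A", "B", "B"]
        return df, groups

    def test_boundary_gene_with_n_min_hits_kept(self):
        df, groups = self._matrix()
        res = filter_by_expression(df, groups, min_count=5)
        assert res.threshold_cpm == pytest.approx(5000.0)
        assert res.n_min == 2
        assert "boundary" in res.kept  # >= threshold in exactly n_min samples
        assert "three_hits" in res.kept
        assert "low" in res.removed
        assert res.n_removed == 1

    def test_one_hit_short_is_removed(self):
        df, groups = self._matrix()
        # drop "boundary" to a single above-threshold sample (n_min - 1 = 1)
        df.loc["boundary", "b1"] = 4
        df.loc["anchor", "b1"] = 987
        res = filter_by_expression(df, groups, min_count=5)
        assert "boundary" in res.removed

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 60, size=(10, 6)))
        groups = ["x", "x", "x", "y", "y", "y"]
        res = filter_by_expression(df, groups, min_count=10)
        lib = df.sum(axis=0)
        thr = 10 / np.median(lib) * 1e6
        kept_brute = [
            g for g in df.index
            if sum(df.loc[g, s] / lib[s] * 1e6 >= thr for s in df.columns) >= 3
        ]
        assert list(res.kept) == kept_brute

    def test_monotone_in_min_count(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(0, 100, size=(40, 6)))
        groups = ["x"] * 3 + ["y"] * 3
        kept = [
            set(filter_by_expression(df, groups, min_count=m).kept) for m in (1, 5, 10, 20)
        ]
        for small, big in zip(kept[1:], kept):
            assert small <= big

    def test_single_group_rejected(self):
        df = pd.DataFrame({"s1": [1], "s2": [2]}, index=["g"])
        with pytest.raises(ConfigError):
            filter_by_expression(df, ["only", "only"], min_count=1)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30], "s3": [10, 20, 30]})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_pure_depth_change_gives_unit_factor(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 500, size=100)
        df = pd.DataFrame({"s1": base, "s2": base * 2, "s3": base * 5})
        assert np.allclose(tmm_factors(df), 1.0, atol=1e-12)

    def test_matches_step_by_step_oracle(self):
        """Independent plain-loop trimmed-mean computation on a 20-gene toy."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.integers(1, 400, size=(20, 3)), columns=["r", "s", "t"]
        )
        factors = tmm_factors(df, ref_sample="r")

        lib = {c: df[c].sum() for c in df.columns}
        oracle = {}
        for c in ["s", "t"]:
            ms, as_, ws = [], [], []
            for g in df.index:
                y, yr = df.loc[g, c], df.loc[g, "r"]
                if y > 0 and yr > 0:
                    ms.append(np.log2((y / lib[c]) / (yr / lib["r"])))
                    as_.append(0.5 * np.log2((y / lib[c]) * (yr / lib["r"])))
                    ws.append(
                        (lib[c] - y) / (lib[c] * y) + (lib["r"] - yr) / (lib["r"] * yr)
                    )
            n = len(ms)
            order_m = sorted(range(n), key=lambda i: ms[i])
            order_a = sorted(range(n), key=lambda i: as_[i])
            rank_m = {i: r + 1 for r, i in enumerate(order_m)}
            rank_a = {i: r + 1 for r, i in enumerate(order_a)}
            lo_m = int(np.floor(n * 0.3)) + 1
            lo_a = int(np.floor(n * 0.05)) + 1
            keep = [
                i for i in range(n)
                if lo_m <= rank_m[i] <= n + 1 - lo_m and lo_a <= rank_a[i] <= n + 1 - lo_a
            ]
            num = sum(ws[i] * ms[i] for i in keep)
            den = sum(ws[i] for i in keep)
            oracle[c] = 2 ** (num / den)
        oracle["r"] = 1.0
        geo = np.exp(np.mean([np.log(v) for v in oracle.values()]))
        for c in df.columns:
            assert factors[c] == pytest.approx(oracle[c] / geo, rel=1e-12)

    def test_disjoint_support_rejected(self):
        df = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]}, index=["a", "b"])
        with pytest.raises(DataError):
            tmm_factors(df, ref_sample="s1")


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(5)
        cpm = 10 ** rng.uniform(1, 3, 2000)
        mu = np.tile(cpm[:, None], (1, 16))
        y = pd.DataFrame(rng.poisson(mu))
        phi = estimate_common_dispersion(y, ["a"] * 8 + ["b"] * 8)
        assert phi <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        counts, groups = two_group_counts(rng, n_genes=2000, phi=0.1)
        phi = estimate_common_dispersion(counts, groups)
        assert phi == pytest.approx(0.1, abs=0.03)

    def test_constant_matrix_floors(self):
        df = pd.DataFrame(7, index=range(5), columns=["a", "b", "c", "d"])
        phi = estimate_common_dispersion(df, ["x", "x", "y", "y"])
        assert phi == pytest.approx(1e-6)

    def test_all_singleton_groups_rejected(self):
        df = pd.DataFrame({"s1": [1], "s2": [2]}, index=["g"])
        with pytest.raises(DataError):
            estimate_common_dispersion(df, ["a", "b"])


class TestExactTest:
    def test_identical_groups_give_p_one_and_zero_fc(self):
        df = pd.DataFrame(
            {"c1": [10, 50], "c2": [20, 60], "t1": [10, 50], "t2": [20, 60]},
            index=["g1", "g2"],
        )
        res = nb_exact_test(df, ["c", "c", "t", "t"], pair=("c", "t"), dispersion=0.1)
        assert (res["pvalue"] == 1.0).all()
        assert np.allclose(res["logFC"], 0.0)

    def test_label_swap_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(7)
        counts, groups = two_group_counts(rng, n_genes=60)
        fwd = nb_exact_test(counts, groups, pair=("ctrl", "trt"), dispersion=0.1)
        rev = nb_exact_test(counts, groups, pair=("trt", "ctrl"), dispersion=0.1)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-10)
        assert np.allclose(fwd["logFC"], -rev["logFC"], atol=1e-10)

    def test_all_zero_gene_is_null_not_error(self):
        df = pd.DataFrame(
            {"c1": [0, 100], "c2": [0, 90], "t1": [0, 110], "t2": [0, 105]},
            index=["dead", "alive"],
        )
        res = nb_exact_test(df, ["c", "c", "t", "t"], pair=("c", "t"), dispersion=0.1)
        assert res.loc["dead", "pvalue"] == 1.0
        assert res.loc["dead", "logFC"] == 0.0

    def test_planted_effect_power_and_sign(self):
        """log2FC=2 at 50 CPM, n=8 vs 8: recovered with the right sign in
        >=95% of 200 replicates at adj p < 0.05."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            counts, groups = two_group_counts(rng, n_genes=120, mean_cpm_range=(20, 500))
            # plant one gene at 50 CPM with a 4-fold treatment increase
            mu_c, mu_t = 50.0, 200.0
            planted = np.concatenate(
                [
                    rng.poisson(rng.gamma(10.0, 0.1 * mu_c, 8)),
                    rng.poisson(rng.gamma(10.0, 0.1 * mu_t, 8)),
                ]
            )
            counts.loc["planted"] = planted
            res = nb_exact_test(counts, groups, pair=("ctrl", "trt"), dispersion=0.1)
            row = res.loc["planted"]
            if row["adj_pvalue"] < 0.05 and row["logFC"] > 0:
                hits += 1
        assert hits / n_rep >= 0.95


class TestBatchGLM:
    def test_single_batch_tracks_exact_test(self):
        cfg = SimConfig(
            n_genes=800,
            groups=(GroupSpec("c", "control", 5, 8), GroupSpec("t", "cort", 5, 8)),
            tier_weights=(0, 0, 0.2, 0.5, 0.3, 0),
            de_fraction=0.05,
            seed=10,
        )
        cm, _ = simulate_counts(cfg)
        kept = filter_by_expression(cm).kept
        sub = cm.counts.loc[kept]
        exact = nb_exact_test(sub, cm.metadata["treatment"], pair=("control", "cort"), dispersion=0.1)
        glm = nb_glm_batch_test(sub, cm.metadata["treatment"], cm.metadata["timepoint"], dispersion=0.1)
        rho = stats.spearmanr(exact["pvalue"], glm["pvalue"]).statistic
        assert rho > 0.9
        assert np.corrcoef(exact["logFC"], glm["logFC"])[0, 1] > 0.98

    def test_confounded_design_rejected(self):
        df = pd.DataFrame(np.arange(40).reshape(10, 4), columns=["a", "b", "c", "d"])
        with pytest.raises(ConfigError, match="alias"):
            nb_glm_batch_test(
                df, ["ctrl", "ctrl", "cort", "cort"], ["b1", "b1", "b2", "b2"], dispersion=0.1
            )

    def test_agrees_with_statsmodels_glm(self):
        """Independent route: statsmodels NB GLM with fixed alpha."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        counts, _ = two_group_counts(rng, n_genes=30, n_per_group=6)
        treatment = ["c"] * 6 + ["t"] * 6
        batch = ["b1", "b2", "b3"] * 4
        phi = 0.1
        mine = nb_glm_batch_test(counts, treatment, batch, dispersion=phi)

        lib = counts.sum(axis=0).to_numpy(dtype=float)
        from cortiseq.dge import effective_library_sizes, tmm_factors as tf

        eff = effective_library_sizes(counts).to_numpy(dtype=float)
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "b2": [1.0 if b == "b2" else 0.0 for b in batch],
                "b3": [1.0 if b == "b3" else 0.0 for b in batch],
                "trt": [1.0 if t == "t" else 0.0 for t in treatment],
            }
        )
        for g in list(counts.index)[:10]:
            y = counts.loc[g].to_numpy(dtype=float)
            full = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=phi), offset=np.log(eff)
            ).fit()
            red = sm.GLM(
                y, X[["intercept", "b2", "b3"]],
                family=sm.families.NegativeBinomial(alpha=phi), offset=np.log(eff),
            ).fit()
            lr = 2 * (full.llf - red.llf)
            p_sm = stats.chi2.sf(max(lr, 0.0), 1)
            assert mine.loc[g, "logFC"] == pytest.approx(full.params["trt"] / np.log(2), abs=1e-4)
            assert mine.loc[g, "pvalue"] == pytest.approx(p_sm, abs=1e-6)

    def test_batch_shifts_inflate_naive_test_not_glm(self):
        """Per-timepoint shifts: the pooled exact test overstates precision
        for shifted genes; the per-gene batch covariate restores calibration."""
        cfg = SimConfig(
            n_genes=2500,
            tier_weights=(0, 0, 0, 0.6, 0.4, 0),
            nb_dispersion=0.1,
            de_fraction=0.0,
            batch_shift_sd=1.5,
            batch_gene_fraction=0.3,
            seed=12,
        )
        cm, truth = simulate_counts(cfg)
        kept = filter_by_expression(cm).kept
        sub = cm.counts.loc[kept]
        shifted = truth.batch_offsets.index[
            (truth.batch_offsets != 0).any(axis=1)
        ].intersection(sub.index)
        naive = nb_exact_test(
            sub, cm.metadata["treatment"], pair=("control", "cort"), dispersion=0.1
        )
        glm = nb_glm_batch_test(
            sub, cm.metadata["treatment"], cm.metadata["timepoint"], dispersion=0.1
        )
        fp_naive = float((naive.loc[shifted, "pvalue"] < 0.05).mean())
        fp_glm = float((glm.loc[shifted, "pvalue"] < 0.05).mean())
        assert fp_naive > 0.07  # clearly above nominal 0.05 (~750 genes)
        assert fp_glm < 0.07
        assert fp_naive > fp_glm + 0.02


class TestBH:
    def test_printed_toy_vectors(self):
        assert adjust_bh([0.04]) == pytest.approx([0.04])
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(DataError):
            adjust_bh([-0.1])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_preserving_monotone_and_above_raw(self, p):
        p = np.array(p)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_fixed_points_of_step_up(self):
        """Constant vectors are fixed points of BH (min over tail ranks is
        attained at rank n); general adjusted vectors are not."""
        for c in (0.0, 0.2, 1.0):
            p = np.full(6, c)
            assert np.allclose(adjust_bh(p), p)

    def test_matches_step_up_arithmetic(self):
        """Direct step-up oracle: p_(i) * n / i with a running minimum."""
        rng = np.random.default_rng(13)
        p = rng.uniform(size=25)
        order = np.argsort(p)
        n = len(p)
        stepup = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            running = min(running, p[order[rank]] * n / (rank + 1))
            stepup[order[rank]] = running
        assert np.allclose(adjust_bh(p), stepup, atol=1e-12)
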