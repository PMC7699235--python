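import numpy as np
import pandas as pd
import pytest

from gutnet import preprocess, simulate
from gutnet.io import TraitTable
from gutnet.wgcna import (
    GRAY,
    detect_modules,
    eigengenes,
    fit_wgcna,
    membership_and_significance,
    module_eigengene,
    module_trait,
    pick_power,
    sample_outlier_screen,
    scale_free_fit,
    soft_adjacency,
    tom_similarity,
)

from conftest import make_traits


def _zscore_log(dataset):
    return preprocess.zscore(preprocess.log2_stabilized(dataset.features))


class TestOutlierScreen:
    def test_homogeneous_cohort_all_kept(self, rng):
        z = preprocess.zscore(pd.DataFrame(rng.standard_normal((100, 19))))
        screen = sample_outlier_screen(z)
        assert screen.flagged == []
        assert len(screen.kept) == 19

    def test_gross_outlier_flagged(self, rng):
        x = rng.standard_normal((100, 19))
        x[:, 7] *= 10.0
        z = preprocess.zscore(pd.DataFrame(x))
        screen = sample_outlier_screen(z)
        assert screen.flagged == [7]

    def test_duplicate_samples_merge_at_zero(self, rng):
        x = rng.standard_normal((50, 5))
        x[:, 1] = x[:, 0]
        screen = sample_outlier_screen(pd.DataFrame(x))
        assert screen.linkage[:, 2].min() == pytest.approx(0.0, abs=1e-9)

    def test_explicit_cut_keeps_main_cluster(self, rng):
        x = rng.standard_normal((100, 10))
        x[:, 0] += 40.0
        screen = sample_outlier_screen(pd.DataFrame(x), cut_height=30.0)
        assert screen.flagged == [0]

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            sample_outlier_screen(pd.DataFrame(rng.standard_normal((5, 2))))


class TestScaleFreeFit:
    def test_exact_decaying_distribution_one(self):
        # counts halve as degree doubles: log-log slope -1, perfect fit
        degrees = np.repeat([1, 2, 4, 8, 16], [16, 8, 4, 2, 1])
        fit = scale_free_fit(degrees)
        assert fit.signed_r2 == pytest.approx(1.0)
        assert fit.slope < 0

    def test_exact_increasing_distribution_minus_one(self):
        degrees = np.repeat([1, 2, 4, 8, 16], [1, 2, 4, 8, 16])
        fit = scale_free_fit(degrees)
        assert fit.signed_r2 == pytest.approx(-1.0)
        assert fit.slope > 0

    def test_sampled_power_law_fits_well(self):
        ks = np.arange(1, 101)
        probs = ks ** -2.0
        probs /= probs.sum()
        worst = 1.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            deg = rng.choice(ks, size=500, p=probs)
            worst = min(worst, scale_free_fit(deg).signed_r2)
        assert worst >= 0.8

    def test_too_few_bins_undefined(self):
        fit = scale_free_fit([3.0, 3.0, 3.0, 3.0])
        assert not fit.ok


class TestPickPower:
    def test_mean_connectivity_non_increasing(self, rng):
        z = preprocess.zscore(pd.DataFrame(rng.standard_normal((60, 19))))
        sweep = pick_power(z, powers=range(1, 15))
        k = sweep.table["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-9).all()

    def test_some_power_reaches_target_on_modular_data(self):
        ds, _ = simulate.generate_study(
            simulate.SynthConfig(module_sizes=(121, 90, 55, 33), seed=11)
        )
        sweep = pick_power(_zscore_log(ds))
        assert 1 <= sweep.beta <= 20
        assert np.isfinite(sweep.table["signed_r2"]).any()

    def test_manual_override_in_fit(self, rng):
        ds, _ = simulate.generate_study(
            simulate.SynthConfig(n_otus=40, n_vocs=30, n_nonvocs=10,
                                 module_sizes=(25, 20), n_modules=2,
                                 n_shifted=20, seed=1)
        )
        model = fit_wgcna(_zscore_log(ds), ds.traits, beta=5)
        assert model.beta == 5


class TestTom:
    def test_tom_in_unit_interval_symmetric(self, rng):
        z = preprocess.zscore(pd.DataFrame(rng.standard_normal((30, 15))))
        tom = tom_similarity(soft_adjacency(z, 6)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-9
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_tom_formula_small_case(self):
        a = pd.DataFrame(
            [[0.0, 0.5, 0.2], [0.5, 0.0, 0.4], [0.2, 0.4, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        tom = tom_similarity(a)
        k = a.sum(axis=1)
        expected = (0.2 * 0.4 + 0.5) / (min(k["a"], k["b"]) + 1 - 0.5)
        assert tom.loc["a", "b"] == pytest.approx(expected)


class TestModuleEigengene:
    def test_identical_rows_me_proportional(self, rng):
        p = rng.standard_normal(12)
        data = pd.DataFrame([p, p, p], index=list("abc"))
        me = module_eigengene(data, list("abc"))
        r = np.corrcoef(me, p)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign oriented towards the members

    def test_sign_flipped_members_split(self, rng):
        p = rng.standard_normal(10)
        data = pd.DataFrame([p, p, -p, -p], index=list("abcd"))
        me = module_eigengene(data, list("abcd"))
        cors = [np.corrcoef(data.loc[i], me)[0, 1] for i in "abcd"]
        assert all(abs(c) == pytest.approx(1.0) for c in cors)
        assert sorted(np.sign(cors)) == [-1, -1, 1, 1]

    def test_me_unit_norm(self, rng):
        data = pd.DataFrame(rng.standard_normal((8, 14)))
        me = module_eigengene(data, list(range(8)))
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_me_tracks_planted_factor(self):
        cfg = simulate.SynthConfig(module_sizes=(40,), n_modules=1,
                                   n_shifted=0, zero_inflation=0.0, seed=6)
        ds, truth = simulate.generate_study(cfg)
        z = _zscore_log(ds)
        me = module_eigengene(z.values, truth.members(0))
        r = np.corrcoef(me, truth.factors.iloc[0])[0, 1]
        assert abs(r) >= 0.9

    def test_me_explains_most_variance(self, rng):
        """The eigengene (PC1) explains at least as much member variance
        as the best single member profile does."""
        data = pd.DataFrame(rng.standard_normal((10, 15)))
        data.iloc[1:] += data.iloc[0] * 0.8
        members = list(range(10))
        me = module_eigengene(data, members)
        x = data.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        xn = xc / np.linalg.norm(xc, axis=1, keepdims=True)
        mec = (me - me.mean()).to_numpy()
        mec /= np.linalg.norm(mec)
        var_me = ((xn @ mec) ** 2).sum()
        for row in xn:
            assert var_me >= ((xn @ row) ** 2).sum() - 1e-9


class TestDetectModules:
    def test_planted_modules_recovered_one_seed(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = simulate.SynthConfig(module_sizes=(120, 90, 60, 30),
                                   n_shifted=44, zero_inflation=0.0, seed=3)
        ds, truth = simulate.generate_study(cfg)
        colors = detect_modules(_zscore_log(ds).values, beta=6)
        planted = truth.module >= 0
        ari = adjusted_rand_score(
            truth.module[planted].astype(str), colors[planted]
        )
        assert ari >= 0.9
        assert colors[colors != GRAY].nunique() == 4

    def test_pure_noise_features_land_gray(self):
        cfg = simulate.SynthConfig(module_sizes=(80, 60), n_modules=2,
                                   n_shifted=0, zero_inflation=0.0, seed=8)
        ds, truth = simulate.generate_study(cfg)
        colors = detect_modules(_zscore_log(ds).values, beta=6)
        noise = truth.module.index[truth.module == -1]
        assert (colors.loc[noise] == GRAY).mean() >= 0.8

    def test_colors_ordered_by_size(self):
        cfg = simulate.SynthConfig(module_sizes=(100, 50), n_modules=2,
                                   n_shifted=0, zero_inflation=0.0, seed=2)
        ds, _ = simulate.generate_study(cfg)
        colors = detect_modules(_zscore_log(ds).values, beta=6)
        sizes = colors[colors != GRAY].value_counts()
        assert list(sizes.index[:2]) == ["turquoise", "blue"]
        assert sizes["turquoise"] >= sizes["blue"]

    def test_static_single_cut_mode(self):
        cfg = simulate.SynthConfig(module_sizes=(100, 60), n_modules=2,
                                   factor_loading=0.95, n_shifted=0,
                                   zero_inflation=0.0, seed=5)
        ds, truth = simulate.generate_study(cfg)
        colors = detect_modules(
            _zscore_log(ds).values, beta=6, cut_height=0.97, refine=False
        )
        assert colors[colors != GRAY].nunique() >= 2

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_modules(pd.DataFrame(rng.standard_normal((5, 10))), beta=6)


class TestMembershipAndTraits:
    @staticmethod
    def _fitted(seed=3):
        cfg = simulate.SynthConfig(module_sizes=(120, 90, 60, 30),
                                   n_shifted=44, zero_inflation=0.0, seed=seed)
        ds, truth = simulate.generate_study(cfg)
        z = _zscore_log(ds)
        model = fit_wgcna(z.values, ds.traits)
        return ds, truth, z, model

    def test_feature_equal_to_me_has_unit_mm(self, rng):
        data = pd.DataFrame(rng.standard_normal((20, 12)))
        data.iloc[:10] = data.iloc[0].to_numpy() + 0.1 * rng.standard_normal((10, 12))
        colors = pd.Series([GRAY] * 20, index=data.index)
        colors.iloc[:10] = "turquoise"
        mes = eigengenes(data, colors)
        probe = pd.DataFrame([mes.loc["turquoise"]], index=["probe"])
        traits = make_traits(6, 6, sample_ids=list(data.columns))
        tables = membership_and_significance(probe, mes, traits)
        assert tables["mm"].loc["probe", "turquoise"] == pytest.approx(1.0)
        assert tables["mm_p"].loc["probe", "turquoise"] < 1e-9

    def test_bs_tracks_condition_construction(self, rng):
        cond = np.array([1.0] * 11 + [0.0] * 8)
        x = np.vstack([
            cond + 0.1 * rng.standard_normal(19),
            rng.standard_normal(19),
        ])
        data = pd.DataFrame(x, index=["hit", "null"])
        traits = make_traits(11, 8, sample_ids=list(data.columns))
        mes = pd.DataFrame([cond], index=["turquoise"],
                           columns=data.columns)
        tables = membership_and_significance(data, mes, traits)
        assert tables["bs"].loc["hit", "condition"] > 0.9
        assert abs(tables["bs"].loc["null", "condition"]) < 0.6

    def test_treatment_dropped_pairwise_for_controls(self):
        ds, truth, z, model = self._fitted()
        # treatment BS must be computed from patients only (8+ non-missing)
        assert model.bs["treatment"].notna().any()

    def test_module_trait_perfect_me(self):
        cond = pd.Series([1.0] * 6 + [0.0] * 6,
                         index=[f"s{i}" for i in range(12)])
        mes = pd.DataFrame([cond], index=["turquoise"])
        traits = make_traits(6, 6, sample_ids=list(cond.index))
        r, p = module_trait(mes, traits)
        assert r.loc["turquoise", "condition"] == pytest.approx(1.0)

    def test_null_trait_correlations_small(self, rng):
        mes = pd.DataFrame(rng.standard_normal((3, 19)),
                           index=["turquoise", "blue", "brown"],
                           columns=[f"s{i}" for i in range(19)])
        traits = make_traits(11, 8, sample_ids=list(mes.columns))
        r, p = module_trait(mes, traits)
        assert r["condition"].abs().max() < 0.75
        assert p["condition"].min() > 1e-4

    def test_shifted_module_tops_condition_association(self):
        ds, truth, z, model = self._fitted(seed=4)
        top = model.module_trait_r["condition"].abs().idxmax()
        members = model.colors.index[model.colors == top]
        overlap = (truth.shift.loc[members] > 0).mean()
        assert overlap > 0.5
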