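import numpy as np
import pandas as pd
import pytest
import scipy.stats

from liverspatial import coloc, zonation


def _spots(n, sample="s1", group="young", prefix=None):
    prefix = prefix or sample
    ids = [f"{prefix}_spot{i}" for i in range(n)]
    meta = pd.DataFrame({"obs_id": ids, "sample_id": sample, "group": group})
    return ids, meta


def _layers(meta, scores=None):
    rng = np.random.default_rng(0)
    s = pd.Series(scores if scores is not None
                  else rng.normal(size=len(meta)),
                  index=meta["obs_id"], name="region_score")
    return zonation.assign_layers(s, meta)


class TestLayerProfile:
    def test_uniform_type_has_zero_scaled_profile(self):
        ids, meta = _spots(90)
        ab = pd.DataFrame({"A": 2.0, "B": 1.0}, index=pd.Index(ids, name="obs_id"))
        prof = coloc.layer_profile(ab, _layers(meta), meta)
        np.testing.assert_allclose(prof.density["A"], 2.0)
        np.testing.assert_allclose(prof.scaled_density["A"], 0.0)
        np.testing.assert_allclose(prof.proportion["A"], 2 / 3)

    def test_layer_restricted_type_peaks_there(self):
        ids, meta = _spots(90)
        zn = _layers(meta, scores=np.arange(90, 0, -1, dtype=float))
        ab = pd.DataFrame({"A": 0.0, "B": 1.0}, index=pd.Index(ids, name="obs_id"))
        layer9 = zn.loc[zn["layer"] == 9, "obs_id"]
        ab.loc[layer9, "A"] = 5.0
        prof = coloc.layer_profile(ab, zn, meta)
        scaled = prof.scaled_density["A"]
        assert scaled.idxmax() == ("s1", 9)

    def test_missing_layers_rejected(self):
        ids, meta = _spots(90)
        zn = _layers(meta).iloc[:-5]
        ab = pd.DataFrame({"A": 1.0}, index=pd.Index(ids, name="obs_id"))
        with pytest.raises(ValueError, match="no layer"):
            coloc.layer_profile(ab, zn, meta)

    def test_pv_graded_type_tracks_layers_on_synthetic_data(
            self, spatial_data, spatial_scores):
        _, _, meta, ab, truth = spatial_data
        rs = zonation.region_score(spatial_scores, "CV", "PV")
        zn = zonation.assign_layers(rs, meta)
        prof = coloc.layer_profile(ab, zn, meta)
        old_samples = meta.loc[meta["group"] == "old", "sample_id"].unique()
        dens = prof.density.loc[old_samples[0], "PP_hepatocyte"]
        rho = scipy.stats.spearmanr(dens.index, dens).statistic
        assert rho > 0.9


class TestDensityCorrelation:
    def _profile(self, a, b):
        ids, meta = _spots(len(a) * 10)
        zn = _layers(meta, scores=-np.arange(len(meta), dtype=float))
        ab = pd.DataFrame(index=pd.Index(ids, name="obs_id"))
        ab["A"] = np.repeat(a, 10)
        ab["B"] = np.repeat(b, 10)
        return coloc.layer_profile(ab, zn, meta)

    def test_self_correlation_is_one(self):
        x = np.arange(9, dtype=float) + 1
        prof = self._profile(x, x)
        res = coloc.density_correlation(prof, "A", ["B"])[0]
        assert res.r == pytest.approx(1.0)

    def test_anticorrelated_profile_gives_minus_one(self):
        x = np.arange(9, dtype=float)
        prof = self._profile(x, -x)
        res = coloc.density_correlation(prof, "A", ["B"], mode="density")[0]
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_reported_as_missing(self):
        prof = self._profile(np.ones(9), np.arange(9, dtype=float))
        res = coloc.density_correlation(prof, "A", ["B"])[0]
        assert res.r is None and "zero-variance" in res.note


class TestScoreCorrelation:
    def test_self_and_affine_correlation(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"a": rng.normal(size=50)})
        scores["b"] = 2.5 * scores["a"] + 1.0
        res = coloc.score_correlation(scores, "a", "b")
        assert res.r == pytest.approx(1.0)

    def test_too_few_spots_rejected(self):
        scores = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3"):
            coloc.score_correlation(scores, "a", "b")


class TestPermutationColoc:
    def test_identical_types_give_max_statistic_and_min_p(self):
        rng = np.random.default_rng(2)
        ids, meta = _spots(200)
        dens = rng.gamma(2.0, size=200)
        ab = pd.DataFrame({"A": dens, "B": dens}, index=pd.Index(ids, name="obs_id"))
        res = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=999, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_scaling_one_type_changes_nothing(self):
        rng = np.random.default_rng(3)
        ids, meta = _spots(150)
        ab = pd.DataFrame({"A": rng.gamma(2.0, size=150),
                           "B": rng.gamma(2.0, size=150)},
                          index=pd.Index(ids, name="obs_id"))
        r1 = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=499, seed=4)
        ab2 = ab.assign(B=ab["B"] * 2.0)
        r2 = coloc.permutation_coloc(ab2, meta, "A", "B", n_perm=499, seed=4)
        assert r1.observed == pytest.approx(r2.observed)
        assert r1.p_perm == pytest.approx(r2.p_perm)

    def test_p_is_never_zero(self):
        ids, meta = _spots(50)
        x = np.linspace(0, 1, 50)
        ab = pd.DataFrame({"A": x, "B": x}, index=pd.Index(ids, name="obs_id"))
        res = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=99, seed=5)
        assert res.p_perm > 0

    def test_observed_matches_single_sample_pearson(self):
        rng = np.random.default_rng(6)
        ids, meta = _spots(80)
        ab = pd.DataFrame({"A": rng.gamma(2.0, size=80),
                           "B": rng.gamma(2.0, size=80)},
                          index=pd.Index(ids, name="obs_id"))
        res = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=99, seed=7)
        r, _ = scipy.stats.pearsonr(ab["A"], ab["B"])
        assert res.observed == pytest.approx(r, abs=1e-12)

    def test_min_product_statistic_available(self):
        rng = np.random.default_rng(8)
        ids, meta = _spots(100)
        ab = pd.DataFrame({"A": rng.gamma(2.0, size=100),
                           "B": rng.gamma(2.0, size=100)},
                          index=pd.Index(ids, name="obs_id"))
        res = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=99, seed=9,
                                      stat="min_product")
        assert res.observed > 0 and 0 < res.p_perm <= 1

    def test_tiny_sample_excluded_with_warning(self):
        ids1, meta1 = _spots(50, sample="s1")
        ids2, meta2 = _spots(2, sample="s2")
        meta = pd.concat([meta1, meta2], ignore_index=True)
        rng = np.random.default_rng(10)
        ab = pd.DataFrame({"A": rng.gamma(2.0, size=52),
                           "B": rng.gamma(2.0, size=52)},
                          index=pd.Index(ids1 + ids2, name="obs_id"))
        with pytest.warns(UserWarning, match="s2"):
            res = coloc.permutation_coloc(ab, meta, "A", "B", n_perm=99, seed=11)
        assert res.p_perm is not None
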