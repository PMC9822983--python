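"""QC filters, CSS normalization, diversity indices, Bray-Curtis,
PERMANOVA and volatility."""

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix as SkbioDM, permanova as skbio_permanova

from stressbiome import microbiome as mb


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

class TestQC:
    def _toy(self):
        # 3 samples x 5 ASVs; asv4 is rare everywhere (max count 3, max rel 0.4%)
        counts = pd.DataFrame(
            [[500, 200, 100, 3, 50],
             [600, 150, 120, 2, 40],
             [550, 180, 90, 1, 60]],
            index=["s1", "s2", "s3"],
            columns=["asv0", "asv1", "asv2", "asv4", "asv5"])
        return counts

    def test_rare_asv_rule(self):
        counts = self._toy()
        out, audit = mb.qc_filter(counts)
        assert "asv4" not in out.columns and out.shape[1] == 4
        assert any(a == "asv4" for a, _ in audit.dropped_asvs)

    def test_low_read_sample_dropped(self):
        counts = self._toy()
        counts.loc["empty"] = [1, 1, 1, 1, 0]
        out, audit = mb.qc_filter(counts)
        assert "empty" not in out.index
        assert ("empty", "total reads < 5") in audit.dropped_samples

    def test_length_boundaries_inclusive(self):
        counts = self._toy()
        lengths = pd.Series([250, 251, 254, 255, 252], index=counts.columns)
        out, audit = mb.qc_filter(counts, lengths=lengths, min_count=1,
                                  min_rel_abund=0.0)
        assert set(out.columns) == {"asv1", "asv2", "asv5"}

    def test_control_based_contaminant_rule(self):
        counts = self._toy()
        # contaminant dominates the blanks, minor in study samples
        counts["contam"] = [5, 6, 4]
        counts.loc["blank1"] = [0, 0, 0, 0, 0, 400]
        counts.loc["blank2"] = [10, 0, 0, 0, 0, 300]
        out, audit = mb.qc_filter(counts, controls={"blank1", "blank2"})
        assert "contam" not in out.columns
        assert set(out.index) == {"s1", "s2", "s3"}

    def test_empty_after_filter_is_error(self):
        counts = pd.DataFrame([[2, 1], [1, 2]], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            mb.qc_filter(counts, min_reads=50)


# --------------------------------------------------------------------------
# CSS
# --------------------------------------------------------------------------

class TestCSS:
    def test_identical_samples_equal_factors(self):
        row = [10, 5, 0, 30, 4]
        counts = pd.DataFrame([row, row, row])
        norm = mb.CSSNormalizer().fit(counts)
        assert norm.scaling_factors_.nunique() == 1
        out = norm.transform(counts)
        assert (out.nunique() == 1).all()

    def test_scale_equivariance(self):
        counts = pd.DataFrame([[10, 5, 1, 30], [8, 6, 2, 25], [12, 4, 3, 28]])
        doubled = counts.copy()
        doubled.iloc[1] *= 2
        f1 = mb.CSSNormalizer(quantile=0.5).fit(counts).scaling_factors_
        f2 = mb.CSSNormalizer(quantile=0.5).fit(doubled).scaling_factors_
        assert f2[1] == pytest.approx(2 * f1[1])
        n1 = mb.CSSNormalizer(quantile=0.5).fit(counts).transform(counts)
        n2 = mb.CSSNormalizer(quantile=0.5).fit(doubled).transform(doubled)
        pd.testing.assert_frame_equal(n1, n2)

    def test_fixed_median_quantile_hand_computed(self):
        # per-sample sums of counts at or below the sample's median
        counts = pd.DataFrame(
            [[1, 2, 3, 4, 100],
             [10, 20, 30, 40, 50],
             [5, 5, 5, 5, 5]])
        norm = mb.CSSNormalizer(quantile=0.5).fit(counts)
        # medians: 3, 30, 5 -> sums 1+2+3, 10+20+30, 25
        assert norm.scaling_factors_.tolist() == [6.0, 60.0, 25.0]
        assert norm.transform(counts).iloc[0, 0] == pytest.approx(1 / 6 * 1000)

    def test_positive_factors_and_zero_sample_error(self, study):
        qc, _ = mb.qc_filter(study.asv_counts)
        norm = mb.CSSNormalizer().fit(qc)
        assert (norm.scaling_factors_ > 0).all()
        assert norm.quantile_ >= 0.5
        bad = qc.copy()
        bad.iloc[0] = 0
        with pytest.raises(ValueError, match="all-zero"):
            mb.CSSNormalizer().fit(bad)


# --------------------------------------------------------------------------
# diversity
# --------------------------------------------------------------------------

class TestDiversity:
    def test_single_taxon(self):
        d = mb.alpha_diversity(pd.DataFrame([[50, 0, 0]]))
        assert d.loc[0, "observed"] == 1
        assert d.loc[0, "shannon"] == pytest.approx(0.0)
        assert d.loc[0, "inv_simpson"] == pytest.approx(1.0)

    def test_uniform_ten_taxa_shannon(self):
        d = mb.alpha_diversity(pd.DataFrame([[10] * 10]))
        assert d.loc[0, "shannon"] == pytest.approx(np.log(10))
        assert d.loc[0, "inv_simpson"] == pytest.approx(10.0)

    def test_chao1_hand_computed(self):
        # counts (6,3,1): F1=1, F2=0 -> bias-corrected Chao1 = 3 + 1*0/2 = 3
        d = mb.alpha_diversity(pd.DataFrame([[6, 3, 1]]))
        assert d.loc[0, "chao1"] == pytest.approx(3.0)

    def test_reorder_invariance_and_scale_invariance(self, rng):
        row = rng.integers(0, 50, 20)
        base = mb.alpha_diversity(pd.DataFrame([row]))
        perm = mb.alpha_diversity(pd.DataFrame([row[rng.permutation(20)]]))
        pd.testing.assert_frame_equal(base, perm)
        scaled = mb.alpha_diversity(pd.DataFrame([row * 10]))
        assert scaled.loc[0, "shannon"] == pytest.approx(base.loc[0, "shannon"])
        assert scaled.loc[0, "inv_simpson"] == pytest.approx(base.loc[0, "inv_simpson"])

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mb.alpha_diversity(pd.DataFrame([[0, 0]]))


class TestBrayCurtis:
    def test_hand_cases(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
                         index=list("abcd"))
        D = mb.bray_curtis(m)
        assert D.loc["a", "b"] == pytest.approx(0.5)
        assert D.loc["a", "c"] == 0.0
        assert D.loc["b", "d"] == pytest.approx(1.0)  # disjoint supports
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            mb.bray_curtis(pd.DataFrame([[1, -1]]))

    def test_rarefaction_drops_and_is_seeded(self):
        counts = pd.DataFrame([[4000] * 3, [1000] * 3, [3000] * 3],
                              index=list("abc"))
        with pytest.warns(UserWarning, match="below depth"):
            r1 = mb.rarefy(counts, 6000, seed=1)
        assert list(r1.index) == ["a", "c"]
        assert (r1.sum(axis=1) == 6000).all()
        r2 = mb.rarefy(counts, 6000, seed=1)
        pd.testing.assert_frame_equal(r1, r2)


class TestPermanova:
    def test_separated_clusters_significant(self, rng):
        a = rng.normal(0, 1, size=(15, 8)) + 10
        b = rng.normal(0, 1, size=(15, 8)) + 30
        counts = pd.DataFrame(np.vstack([a, b]).clip(0))
        design = pd.DataFrame({"group": ["a"] * 15 + ["b"] * 15})
        res = mb.permanova(mb.bray_curtis(counts), design, ["group"],
                           n_perm=999, seed=1)
        assert res.loc["group", "p"] <= 0.001

    def test_relabeling_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 10)))
        design = pd.DataFrame({"group": rng.choice(["x", "y"], 20)})
        D = mb.bray_curtis(counts)
        f1 = mb.permanova(D, design, ["group"], n_perm=49, seed=2)
        perm = rng.permutation(20)
        D2 = D.iloc[perm, perm]
        f2 = mb.permanova(D2, design.iloc[perm].reset_index(drop=True),
                          ["group"], n_perm=49, seed=2)
        assert f1.loc["group", "pseudo_F"] == pytest.approx(
            f2.loc["group", "pseudo_F"])

    def test_single_term_matches_skbio(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(24, 12)))
        groups = rng.choice(["x", "y", "z"], 24)
        D = mb.bray_curtis(counts)
        ours = mb.permanova(D, pd.DataFrame({"g": groups}), ["g"], n_perm=99)
        ref = skbio_permanova(SkbioDM(D.to_numpy()), groups, permutations=99)
        assert ours.loc["g", "pseudo_F"] == pytest.approx(ref["test statistic"],
                                                          rel=1e-9)

    def test_constant_term_error(self, rng):
        counts = pd.DataFrame(rng.integers(1, 10, size=(6, 4)))
        with pytest.raises(ValueError, match="constant term"):
            mb.permanova(mb.bray_curtis(counts),
                         pd.DataFrame({"g": ["a"] * 6}), ["g"])

    def test_p_in_valid_range(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(16, 6)))
        design = pd.DataFrame({"g": rng.choice(["x", "y"], 16)})
        res = mb.permanova(mb.bray_curtis(counts), design, ["g"], n_perm=99)
        assert 1 / 100 <= res.loc["g", "p"] <= 1


class TestVolatility:
    def test_identical_visits_zero(self, study):
        counts = study.asv_counts.copy()
        t3 = study.metadata.index[study.metadata.trimester == "T3"]
        t2 = study.metadata.index[study.metadata.trimester == "T2"]
        counts.loc[t3] = counts.loc[t2].to_numpy()
        vol, _ = mb.volatility(mb.bray_curtis(counts), study.metadata)
        assert vol["volatility"].abs().max() == pytest.approx(0.0)

    def test_slope_recovery(self, study):
        # plant volatility = 0.1 + 0.02 * delta_weeks + noise directly
        rng = np.random.default_rng(3)
        meta = study.metadata
        parts = meta["participant"].unique()
        D = pd.DataFrame(0.0, index=meta.index, columns=meta.index)
        for p in parts:
            t2, t3 = f"{p}_T2", f"{p}_T3"
            dw = meta.loc[t3, "gestational_weeks"] - meta.loc[t2, "gestational_weeks"]
            v = 0.1 + 0.02 * dw + rng.normal(0, 0.01)
            D.loc[t2, t3] = D.loc[t3, t2] = max(v, 0)
        vol, model = mb.volatility(D, meta)
        assert len(vol) == 84
        assert abs(model.params["delta_weeks"] - 0.02) < 0.005

    def test_no_pairs_error(self, study):
        meta_t2 = study.metadata[study.metadata.trimester == "T2"]
        D = pd.DataFrame(0.0, index=meta_t2.index, columns=meta_t2.index)
        with pytest.raises(ValueError):
            mb.volatility(D, meta_t2)
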