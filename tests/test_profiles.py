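"""Compositional transforms, ordination, PERMANOVA, batch removal, DA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

from hepmicro import profiles as pr
from hepmicro.profiles import MicrobialProfile


def prof(array, meta=None, form="counts", **kw):
    df = pd.DataFrame(np.asarray(array, float))
    df.index = [f"s{i}" for i in range(df.shape[0])]
    df.columns = [f"t{j}" for j in range(df.shape[1])]
    if meta is not None:
        meta = pd.DataFrame(meta, index=df.index)
    return MicrobialProfile(df, meta, form=form, **kw)


class TestClr:
    def test_identity_composition(self):
        out = pr.clr_transform(prof([[1, 1, 1, 1]]), pseudocount=0)
        assert np.allclose(out.abundance.to_numpy(), 0)

    def test_direct_formula(self):
        out = pr.clr_transform(prof([[1, 2, 4]]), pseudocount=0)
        assert np.allclose(out.abundance.to_numpy()[0],
                           [-np.log(2), 0, np.log(2)], atol=1e-4)

    def test_rows_sum_to_zero(self, rng):
        counts = rng.integers(0, 200, size=(12, 30))
        out = pr.clr_transform(prof(counts))
        assert np.abs(out.abundance.sum(axis=1)).max() < 1e-9

    def test_zero_pseudocount_with_zeros_errors(self):
        with pytest.raises(ValueError):
            pr.clr_transform(prof([[0, 1, 2]]), pseudocount=0)


class TestShannon:
    def test_known_values(self):
        p = prof([[1, 1, 1, 1], [4, 0, 0, 0], [1, 1, 0, 0]])
        h = pr.shannon_index(p)
        assert h.iloc[0] == pytest.approx(np.log(4))
        assert h.iloc[1] == pytest.approx(0.0)
        assert h.iloc[2] == pytest.approx(np.log(2))

    def test_clr_variant_defined(self, rng):
        p = prof(rng.integers(1, 100, size=(5, 10)))
        h = pr.shannon_index(p, on_clr=True)
        assert np.isfinite(h).all() and (h >= 0).all()


class TestAitchison:
    def test_scale_invariance_and_zero_diagonal(self):
        p = prof([[1, 2, 4], [2, 4, 8], [8, 2, 1]])
        d = pr.aitchison_distance(p, pseudocount=0)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert d.iloc[0, 2] > 0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_equals_euclidean_on_clr_oracle(self, rng):
        counts = rng.integers(1, 500, size=(10, 20)).astype(float)
        p = prof(counts)
        d = pr.aitchison_distance(p, pseudocount=0.5)
        x = np.log(counts + 0.5)
        clr = x - x.mean(axis=1, keepdims=True)
        oracle = squareform(pdist(clr))
        assert np.abs(d.to_numpy() - oracle).max() < 1e-10

    def test_triangle_inequality(self, rng):
        counts = rng.integers(1, 500, size=(15, 12)).astype(float)
        d = pr.aitchison_distance(prof(counts)).to_numpy()
        for _ in range(200):
            i, j, k = rng.choice(15, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPcoa:
    def test_line_recovered_and_distances_preserved(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        d = pd.DataFrame(squareform(pdist(pts)))
        coords, ev = pr.pcoa(d, k=4)
        d2 = squareform(pdist(coords.to_numpy()))
        assert np.abs(d2 - d.to_numpy()).max() < 1e-8
        assert coords.shape[1] == 1  # a line needs one positive axis

    def test_euclidean_roundtrip(self, rng):
        pts = rng.standard_normal((10, 4))
        d = pd.DataFrame(squareform(pdist(pts)))
        coords, _ = pr.pcoa(d, k=10)
        assert np.abs(squareform(pdist(coords.to_numpy())) - d.to_numpy()).max() < 1e-8

    def test_all_zero_distances(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        coords, ev = pr.pcoa(d, k=2)
        assert np.allclose(coords.to_numpy(), 0) if coords.size else True

    def test_asymmetric_errors(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pr.pcoa(d)


class TestPermanova:
    def test_separated_clusters_significant(self, rng):
        a = rng.normal(0, 1, size=(10, 3))
        b = rng.normal(6, 1, size=(10, 3))
        d = pd.DataFrame(squareform(pdist(np.vstack([a, b]))))
        f, p = pr.permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0)
        assert p <= 0.01

    def test_null_calibration(self, rng):
        """Under exchangeable labels, p is uniform (KS at alpha=0.01)."""
        ps = []
        for r in range(200):
            x = rng.standard_normal((16, 4))
            d = pd.DataFrame(squareform(pdist(x)))
            _, p = pr.permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=r)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_errors(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            pr.permanova(d, ["a"] * 4)
        with pytest.raises(ValueError):
            pr.permanova(d, ["a", "a", "b", "b"], n_perm=0)

    def test_matches_skbio_pseudo_f(self, rng):
        """Cross-check the statistic against the reference implementation."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.standard_normal((12, 3))
        x[6:] += 1.5
        d = squareform(pdist(x))
        labels = ["a"] * 6 + ["b"] * 6
        f, _ = pr.permanova(pd.DataFrame(d), labels, n_perm=9, seed=0)
        ref = sk_permanova(DistanceMatrix(d), grouping=labels, permutations=9)
        assert f == pytest.approx(ref["test statistic"], rel=1e-9)


class TestRemoveBatch:
    def test_single_batch_identity(self, rng):
        m = pd.DataFrame(rng.standard_normal((8, 5)))
        out = pr.remove_batch(m, ["x"] * 8)
        pd.testing.assert_frame_equal(out, m)

    def test_pure_additive_shift_removed(self, rng):
        base = rng.standard_normal((20, 6))
        shift = np.where(np.arange(20) < 10, 2.0, -2.0)[:, None]
        m = pd.DataFrame(base + shift)
        batch = ["b1"] * 10 + ["b2"] * 10
        out = pr.remove_batch(m, batch)
        means = out.groupby(pd.Series(batch, index=out.index)).mean()
        assert np.abs(means.iloc[0] - means.iloc[1]).max() < 0.8

    def test_feature_means_preserved(self, rng):
        m = pd.DataFrame(rng.standard_normal((12, 4)) + 5.0)
        out = pr.remove_batch(m, ["a"] * 6 + ["b"] * 6)
        assert np.allclose(out.mean(0), m.mean(0), atol=0.7)

    def test_confounded_design_errors(self):
        m = pd.DataFrame(np.random.default_rng(0).standard_normal((8, 3)))
        batch = ["a"] * 4 + ["b"] * 4
        cov = pd.DataFrame({"stage": ["x"] * 4 + ["y"] * 4}, index=m.index)
        with pytest.raises(ValueError, match="confounded"):
            pr.remove_batch(m, batch, covariates=cov)


class TestRareTaxonFilter:
    def test_single_dataset_rule(self):
        # taxon reaches 0.02% in 15% of one dataset, absent elsewhere
        counts = np.ones((20, 2)) * 1000
        extra = np.zeros(20)
        extra[:3] = 5  # 0.5% in 3/10 of DS1 samples
        counts = np.column_stack([counts, extra])
        meta = {"dataset": ["DS1"] * 10 + ["DS2"] * 10}
        p = prof(counts, meta)
        out = pr.rare_taxon_filter(p, min_rel=1e-4, min_prev=0.10,
                                   min_datasets=2)
        assert "t2" not in out.abundance.columns
        assert {"t0", "t1"} <= set(out.abundance.columns)

    def test_empty_profile(self):
        p = MicrobialProfile(pd.DataFrame(), None)
        assert pr.rare_taxon_filter(p).abundance.empty

    def test_monotone_in_thresholds(self, small_cohort):
        _, _, abund, meta, _ = small_cohort
        p = MicrobialProfile(abund, meta)
        loose = pr.rare_taxon_filter(p, min_rel=1e-5, min_prev=0.05)
        tight = pr.rare_taxon_filter(p, min_rel=1e-3, min_prev=0.20)
        assert set(tight.abundance.columns) <= set(loose.abundance.columns)


class TestDifferentialAbundance:
    def test_identical_groups_nothing_significant(self, rng):
        counts = rng.integers(1, 300, size=(20, 15))
        clr = pr.clr_transform(prof(counts))
        groups = ["control"] * 10 + ["NASH"] * 10
        da = pr.differential_abundance(clr, groups, "control")
        assert not da["significant"].any() or da["significant"].mean() < 0.1

    def test_planted_taxa_recovered_with_correct_sign(self, small_cohort):
        _, _, abund, meta, truth = small_cohort
        clr = pr.clr_transform(MicrobialProfile(abund, meta))
        da = pr.differential_abundance(clr, meta["stage"], "control")
        sig = da[da["significant"]]
        for g in ("NAFL", "Borderline", "NASH"):
            hits = sig[sig["group"] == g]
            found = set(hits["taxon"]) & set(truth.diff_taxa)
            assert len(found) / len(truth.diff_taxa) >= 0.5
            for taxon in found:
                fc = hits.set_index("taxon").loc[taxon, "log2fc"]
                assert np.sign(fc) == np.sign(truth.diff_taxa[taxon])

    def test_missing_control_errors(self, rng):
        clr = pr.clr_transform(prof(rng.integers(1, 50, (6, 4))))
        with pytest.raises(ValueError):
            pr.differential_abundance(clr, ["a"] * 6, "control")
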