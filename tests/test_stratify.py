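import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from _oracles import complete_linkage_two_clusters
from conftest import toy_manifest, toy_regions
from epiorigin import stratify as strat
from epiorigin.model import BetaMatrix


class TestMapProbesToRegions:
    def _setup(self):
        manifest = toy_manifest(
            [
                ("cg1", "chr1", 100),
                ("cg2", "chr1", 199),
                ("cg3", "chr1", 200),
                ("cg4", "chr2", 150),
            ]
        )
        regions = toy_regions([("r1", "chr1", 100, 200, "UK")])
        return manifest, regions

    def test_half_open_boundaries(self):
        manifest, regions = self._setup()
        prmap = strat.map_probes_to_regions(manifest, regions)
        mapped = set(prmap.pairs["probe_id"])
        assert "cg1" in mapped  # left-closed
        assert "cg2" in mapped
        assert "cg3" not in mapped  # right-open
        assert "cg4" not in mapped  # other chromosome

    def test_probe_in_both_classes_contributes_to_both(self):
        manifest = toy_manifest([("cg1", "chr1", 150)])
        regions = toy_regions(
            [("u", "chr1", 100, 200, "UK"), ("d", "chr1", 120, 180, "DK")]
        )
        prmap = strat.map_probes_to_regions(manifest, regions)
        assert sorted(prmap.pairs["region_class"]) == ["DK", "UK"]


class TestRegionBeta:
    def _prmap(self):
        manifest = toy_manifest(
            [("cg1", "chr1", 110), ("cg2", "chr1", 120), ("cg3", "chr1", 130)]
        )
        regions = toy_regions([("r1", "chr1", 100, 200, "UK")])
        return strat.map_probes_to_regions(manifest, regions)

    def test_mean_over_probes(self):
        beta = BetaMatrix(
            pd.DataFrame({"s": [0.2, 0.4, np.nan]}, index=["cg1", "cg2", "cg3"])
        )
        rb = strat.region_beta(beta, self._prmap())
        assert rb.values.loc["r1", "s"] == pytest.approx(0.3)

    def test_missing_values_excluded_from_mean(self):
        beta = BetaMatrix(
            pd.DataFrame({"s": [0.2, np.nan, 0.8]}, index=["cg1", "cg2", "cg3"])
        )
        rb = strat.region_beta(beta, self._prmap())
        assert rb.values.loc["r1", "s"] == pytest.approx(0.5)

    def test_single_probe_region_identity(self):
        manifest = toy_manifest([("cg1", "chr1", 110)])
        regions = toy_regions([("r1", "chr1", 100, 200, "DK")])
        prmap = strat.map_probes_to_regions(manifest, regions)
        beta = BetaMatrix(pd.DataFrame({"s": [0.77]}, index=["cg1"]))
        rb = strat.region_beta(beta, prmap)
        assert rb.values.loc["r1", "s"] == pytest.approx(0.77)

    def test_all_missing_region_stays_missing(self):
        beta = BetaMatrix(
            pd.DataFrame({"s": [np.nan, np.nan, np.nan]}, index=["cg1", "cg2", "cg3"])
        )
        rb = strat.region_beta(beta, self._prmap())
        assert np.isnan(rb.values.loc["r1", "s"])

    def test_probe_permutation_invariance(self):
        prmap = self._prmap()
        beta = BetaMatrix(
            pd.DataFrame({"s": [0.2, 0.4, 0.9]}, index=["cg1", "cg2", "cg3"])
        )
        shuffled = BetaMatrix(beta.values.loc[["cg3", "cg1", "cg2"]])
        pd.testing.assert_frame_equal(
            strat.region_beta(beta, prmap).values,
            strat.region_beta(shuffled, prmap).values,
        )


def _region_df(values_by_sample):
    return pd.DataFrame(values_by_sample, index=["r1"]).astype(float)


class TestHierarchicalStratify:
    def test_separated_tumors_are_epsc_like(self):
        mat = _region_df({"h1": [0.0], "h2": [0.1], "t1": [0.9], "t2": [1.0]})
        res = strat.hierarchical_stratify(mat, ["h1", "h2"])
        assert res.labels["t1"] == res.labels["t2"] == strat.EPSC_LIKE
        assert res.labels["h1"] == strat.HEALTHY_REF

    def test_mixed_tumors_split_by_branch(self):
        mat = _region_df({"h1": [0.0], "h2": [0.1], "t1": [0.05], "t2": [0.95]})
        res = strat.hierarchical_stratify(mat, ["h1", "h2"])
        assert res.labels["t1"] == strat.KER_LIKE
        assert res.labels["t2"] == strat.EPSC_LIKE

    def test_matches_brute_force_oracle_on_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(4, 8))
            X = rng.normal(size=(n, 3))
            ids = [f"s{i}" for i in range(n)]
            mat = pd.DataFrame(X.T, columns=ids)
            res = strat.hierarchical_stratify(mat, [ids[0]])
            ours = frozenset(
                frozenset(i for i, s in enumerate(ids) if (res.labels[s] != strat.EPSC_LIKE) == side)
                for side in (True, False)
            )
            assert ours == complete_linkage_two_clusters(X)

    def test_sample_and_region_order_invariance(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.uniform(size=(20, 8)), columns=[f"s{i}" for i in range(8)]
        )
        base = strat.hierarchical_stratify(mat, ["s0"])
        perm = mat.sample(frac=1.0, axis=0, random_state=1).sample(
            frac=1.0, axis=1, random_state=2
        )
        shuffled = strat.hierarchical_stratify(perm, ["s0"])
        pd.testing.assert_series_equal(
            base.labels.sort_index(), shuffled.labels.sort_index()
        )

    def test_even_healthy_split_is_ambiguous(self):
        mat = _region_df({"h1": [0.0], "h2": [1.0], "t1": [0.05], "t2": [0.95]})
        with pytest.raises(strat.AmbiguousHealthyAnchorError):
            strat.hierarchical_stratify(mat, ["h1", "h2"])

    def test_high_missingness_sample_dropped(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            rng.uniform(size=(10, 5)), columns=["h1", "t1", "t2", "t3", "bad"]
        )
        mat.loc[mat.index[:5], "bad"] = np.nan
        with pytest.warns(UserWarning, match="bad"):
            res = strat.hierarchical_stratify(mat, ["h1"])
        assert "bad" in res.dropped_samples
        assert "bad" not in res.labels.index

    def test_newick_export_contains_all_leaves(self):
        mat = _region_df({"h1": [0.0], "t1": [0.5], "t2": [0.9]})
        res = strat.hierarchical_stratify(mat, ["h1"])
        nwk = res.to_newick()
        for s in ("h1", "t1", "t2"):
            assert s in nwk
        assert nwk.endswith(";")


class TestClassifyCohort:
    def test_healthy_copy_coclusters_with_reference(self, cohort):
        healthy = cohort["bulk"].subset_samples(cohort["healthy_ids"])
        renamed = BetaMatrix(
            healthy.values.rename(columns=lambda s: f"new_{s}"),
            healthy.sample_group.rename(index=lambda s: f"new_{s}"),
        )
        # a near-copy of the healthy reference plus two genuine EpSC-like
        # tumors to give the dendrogram a second branch
        truth = cohort["truth_bulk"].sample_subclass
        epsc_ids = list(truth.index[truth == "epsc_like"][:2])
        new = BetaMatrix(
            pd.concat([renamed.values, cohort["bulk"].values[epsc_ids]], axis=1)
        )
        res = strat.classify_cohort(
            new, healthy, cohort["regions"], cohort["manifest"]
        )
        for s in renamed.sample_ids:
            assert res.labels[s] == strat.KER_LIKE
        for s in epsc_ids:
            assert res.labels[s] == strat.EPSC_LIKE

    def test_zero_overlap_errors(self, cohort):
        healthy = cohort["bulk"].subset_samples(cohort["healthy_ids"])
        foreign = BetaMatrix(
            pd.DataFrame(
                np.full((3, 3), 0.5), index=["x1", "x2", "x3"], columns=["a", "b", "c"]
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            strat.classify_cohort(
                foreign, healthy, cohort["regions"], cohort["manifest"]
            )


class TestPcaOverview:
    def test_duplicated_sample_coincident_coordinates(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(30, 4))
        vals[:, 3] = vals[:, 2]
        beta = BetaMatrix(pd.DataFrame(vals, columns=["a", "b", "c", "d"]))
        coords, _ = strat.pca_overview(beta)
        assert np.allclose(coords.loc["c"], coords.loc["d"], atol=1e-10)

    def test_two_samples_put_all_variance_on_pc1(self):
        beta = BetaMatrix(
            pd.DataFrame({"a": [0.1, 0.2, 0.9], "b": [0.9, 0.3, 0.1]})
        )
        _, evr = strat.pca_overview(beta, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        beta = BetaMatrix(pd.DataFrame(np.full((10, 3), 0.4), columns=list("abc")))
        with pytest.raises(ValueError, match="constant"):
            strat.pca_overview(beta)

    def test_subclasses_separate_on_leading_components(self, cohort):
        from sklearn.metrics import silhouette_score

        coords, _ = strat.pca_overview(cohort["bulk"])
        truth = cohort["truth_bulk"].sample_subclass
        tumors = truth.index[truth != "healthy"]
        score = silhouette_score(coords.loc[tumors], truth[tumors])
        assert score > 0.5


class TestDmpTest:
    def _toy(self, seed=0, n_probes=60, n1=4, n2=4):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.05, 0.95, size=(n_probes, n1 + n2))
        cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        beta = BetaMatrix(pd.DataFrame(vals, columns=cols))
        groups = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
        return beta, groups

    def test_identical_groups_flat(self):
        rng = np.random.default_rng(1)
        half = rng.uniform(size=(20, 3))
        vals = np.hstack([half, half])
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        beta = BetaMatrix(pd.DataFrame(vals, columns=cols))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)
        res = strat.dmp_test(beta, groups)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        beta, groups = self._toy()
        res = strat.dmp_test(beta, groups, prior_df=0.0)
        t_ref, p_ref = stats.ttest_ind(
            beta.values.iloc[:, 4:], beta.values.iloc[:, :4], axis=1, equal_var=True
        )
        assert np.abs(res.table["t"].to_numpy() - t_ref).max() < 1e-8
        assert np.abs(res.table["p"].to_numpy() - p_ref).max() < 1e-8

    def test_infinite_shrinkage_limit_uses_pooled_variance(self):
        beta, groups = self._toy()
        res = strat.dmp_test(beta, groups, prior_df=np.inf)
        A = beta.values.iloc[:, :4].to_numpy()
        B = beta.values.iloc[:, 4:].to_numpy()
        d = 6
        s2 = (
            ((A - A.mean(1, keepdims=True)) ** 2).sum(1)
            + ((B - B.mean(1, keepdims=True)) ** 2).sum(1)
        ) / d
        s0 = np.exp(np.mean(np.log(s2)) - special.digamma(d / 2) + np.log(d / 2))
        t_ref = (B.mean(1) - A.mean(1)) / np.sqrt(s0 * (1 / 4 + 1 / 4))
        assert np.abs(res.table["t"].to_numpy() - t_ref).max() < 1e-8

    def test_estimated_prior_between_limits(self):
        beta, groups = self._toy(seed=5, n_probes=400)
        res = strat.dmp_test(beta, groups)
        assert res.prior_df > 0
        ord_t = strat.dmp_test(beta, groups, prior_df=0.0).table["t"].abs()
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()
        # shrinkage moderates the extreme statistics
        assert res.table["t"].abs().max() <= ord_t.max() + 1e-9

    def test_small_group_rejected(self):
        beta, groups = self._toy(n1=1, n2=4)
        with pytest.raises(ValueError):
            strat.dmp_test(beta, groups)


class TestProbeContextFractions:
    def test_all_island(self):
        manifest = toy_manifest(
            [("cg1", "chr1", 1, "Island"), ("cg2", "chr1", 2, "Island")]
        )
        fr = strat.probe_context_fractions(["cg1", "cg2"], manifest)
        assert fr.to_list() == [1.0, 0.0, 0.0, 0.0]

    def test_half_island_half_opensea(self):
        manifest = toy_manifest(
            [
                ("cg1", "chr1", 1, "Island"),
                ("cg2", "chr1", 2, "Island"),
                ("cg3", "chr1", 3, "OpenSea"),
                ("cg4", "chr1", 4, "OpenSea"),
            ]
        )
        fr = strat.probe_context_fractions(["cg1", "cg2", "cg3", "cg4"], manifest)
        assert fr["Island"] == fr["OpenSea"] == 0.5
        assert fr.sum() == pytest.approx(1.0)

    def test_empty_list_rejected(self, cohort):
        with pytest.raises(ValueError):
            strat.probe_context_fractions([], cohort["manifest"])


class TestMarkerRegionScore:
    def test_score_is_mean_over_marker_probes(self):
        manifest = toy_manifest(
            [
                ("cg1", "chr1", 1, "Island", {"TSS200"}, "MIR205"),
                ("cg2", "chr1", 2, "Island", {"TSS200"}, "MIR205"),
            ]
        )
        beta = BetaMatrix(
            pd.DataFrame({"s1": [0.9, 0.7], "s2": [0.1, 0.1]}, index=["cg1", "cg2"])
        )
        groups = pd.Series({"s1": "tumor", "s2": "healthy"})
        scores, _ = strat.marker_region_score(
            beta, manifest, {"MIR205": ["cg1", "cg2"]}, groups
        )
        assert scores.loc["MIR205", "s1"] == pytest.approx(0.8)

    def test_identical_groups_p_one(self):
        manifest = toy_manifest([("cg1", "chr1", 1, "Island", {"TSS200"}, "M")])
        vals = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.5], "d": [0.5]},
                            index=["cg1"])
        beta = BetaMatrix(vals)
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        _, tests = strat.marker_region_score(beta, manifest, {"M": ["cg1"]}, groups)
        assert tests.loc["M", "p"] == 1.0

    def test_empty_marker_rejected(self, cohort):
        with pytest.raises(ValueError, match="nothere"):
            strat.marker_region_score(
                cohort["bulk"],
                cohort["manifest"],
                {"nothere": ["cg_missing"]},
                cohort["truth_bulk"].sample_subclass,
            )

    def test_planted_mir_hypermethylation_detected(self, cohort):
        spec = strat.markers_from_gene_symbols(
            cohort["manifest"], {"MIR200C/141": ["MIR200C"], "MIR205": ["MIR205"]}
        )
        truth = cohort["truth_bulk"].sample_subclass
        scores, tests = strat.marker_region_score(
            cohort["bulk"],
            cohort["manifest"],
            spec,
            truth,
            compare=("epsc_like", "healthy"),
        )
        for marker in spec:
            assert tests.loc[marker, "mean_epsc_like"] > tests.loc[marker, "mean_healthy"]
            assert tests.loc[marker, "p"] < 0.01
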