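"""Genome scan, permutation thresholds, credible intervals, multi-QTL models."""

import numpy as np
import pandas as pd
import pytest

from vinevigor import qtl
from vinevigor.synthetic_data import (QtlSpec, SimConfig, simulate_genetic_map,
                                      simulate_progeny_genotypes)

from conftest import planted_marker, planted_trait


def brute_force_lod(y, X):
    """Independent two-RSS marker-regression LOD via explicit OLS."""
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    return 0.5 * n * np.log10(rss0 / rss1)


class TestHaldane:
    def test_zero_distance(self):
        assert qtl.haldane(0.0) == 0.0

    def test_large_distance_limit(self):
        assert qtl.haldane(1e6) == pytest.approx(0.5)

    def test_ten_cm(self):
        assert qtl.haldane(10.0) == pytest.approx(0.090635, abs=1e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qtl.haldane(-1.0)


class TestDuplicateMarkers:
    def test_identical_columns_collapse(self):
        geno = pd.DataFrame({"m1": ["ac", "bd"], "m2": ["ac", "bd"],
                             "m3": ["ad", "bd"]})
        out = qtl.remove_duplicate_markers(geno)
        assert list(out.columns) == ["m1", "m3"]

    def test_all_distinct_identity(self):
        geno = pd.DataFrame({"m1": ["ac", "bd"], "m2": ["ad", "bd"]})
        assert list(qtl.remove_duplicate_markers(geno).columns) == ["m1", "m2"]

    def test_zero_cm_triples_leave_one_survivor(self):
        # markers at identical positions recombine with r(0)=0, so their
        # columns are identical and only the first survives
        table = pd.DataFrame({
            "marker": ["c1_0", "c1_1", "c1_2", "c1_100"],
            "chromosome": ["c1"] * 4,
            "position_cM": [0.0, 0.0, 0.0, 40.0],
            "position_bp": [0, 1, 2, 100],
        })
        gmap = qtl.GeneticMap(table)
        geno = simulate_progeny_genotypes(gmap, 50, seed=2)
        out = qtl.remove_duplicate_markers(geno)
        assert list(out.columns)[:1] == ["c1_0"]
        assert "c1_1" not in out.columns and "c1_2" not in out.columns

    def test_missing_matched_literally(self):
        geno = pd.DataFrame({"m1": ["ac", None], "m2": ["ac", "bd"]})
        assert list(qtl.remove_duplicate_markers(geno).columns) == ["m1", "m2"]


class TestGenotypeProbabilities:
    @pytest.fixture()
    def trio_map(self):
        return qtl.GeneticMap(pd.DataFrame({
            "marker": ["c1_0", "c1_10", "c1_20"],
            "chromosome": ["c1"] * 3,
            "position_cM": [0.0, 10.0, 20.0],
            "position_bp": [0, 10, 20],
        }))

    def test_observed_gives_indicator(self, trio_map):
        geno = pd.DataFrame({"c1_0": ["ac"], "c1_10": ["bd"], "c1_20": ["ac"]})
        probs = qtl.genotype_probabilities(geno, trio_map, "c1_10")
        assert np.allclose(probs[0], [0, 0, 0, 1])

    def test_missing_with_agreeing_zero_distance_flanks(self):
        gmap = qtl.GeneticMap(pd.DataFrame({
            "marker": ["c1_a", "c1_b", "c1_c"],
            "chromosome": ["c1"] * 3,
            "position_cM": [5.0, 5.0, 5.0],
            "position_bp": [0, 1, 2],
        }))
        geno = pd.DataFrame({"c1_a": ["ad"], "c1_b": [None], "c1_c": ["ad"]})
        probs = qtl.genotype_probabilities(geno, gmap, "c1_b")
        assert np.allclose(probs[0], [0, 1, 0, 0])

    def test_flanking_enumeration_oracle(self, trio_map):
        # missing centre, same class 10 cM on each side: enumerate the
        # recombination events in the two intervals per parent
        geno = pd.DataFrame({"c1_0": ["ac"], "c1_10": [None], "c1_20": ["ac"]})
        probs = qtl.genotype_probabilities(geno, trio_map, "c1_10")
        r = qtl.haldane(10.0)

        def parent_prob(gl, gr):
            num = {0: 0.0, 1: 0.0}
            for x in (0, 1):
                p = (1 - r if x == gl else r) * (1 - r if x == gr else r)
                num[x] += p
            return num[0] / (num[0] + num[1])

        pa = parent_prob(0, 0)   # allele 'a' on both flanks
        pc = parent_prob(0, 0)   # allele 'c' on both flanks
        expected = np.outer([pa, 1 - pa], [pc, 1 - pc]).ravel()
        assert np.allclose(probs[0], expected, atol=1e-12)

    def test_no_informative_marker_uniform(self, trio_map):
        geno = pd.DataFrame({"c1_0": [None], "c1_10": [None], "c1_20": [None]})
        probs = qtl.genotype_probabilities(geno, trio_map, "c1_10")
        assert np.allclose(probs[0], 0.25)

    def test_rows_sum_to_one(self, trio_map):
        geno = pd.DataFrame({"c1_0": ["ac", None, "bd"],
                             "c1_10": [None, None, None],
                             "c1_20": [None, "ad", "bc"]})
        probs = qtl.genotype_probabilities(geno, trio_map, "c1_10")
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestScanLod:
    def test_constant_phenotype_zero_lod(self, small_map):
        geno = simulate_progeny_genotypes(small_map, 30, seed=4)
        y = pd.Series(np.ones(30), index=geno.index)
        with pytest.warns(UserWarning, match="constant"):
            res = qtl.scan_lod(y, geno, small_map)
        assert (res.table["lod"] == 0).all()

    def test_perfect_separation_infinite(self, small_map):
        geno = simulate_progeny_genotypes(small_map, 40, seed=5)
        marker = geno.columns[3]
        y = pd.Series((geno[marker] == "ac").astype(float), index=geno.index)
        with pytest.warns(UserWarning, match="perfect fit"):
            res = qtl.scan_lod(y, geno, small_map)
        assert np.isinf(res.table.set_index("marker").loc[marker, "lod"])

    def test_matches_bruteforce_rss_oracle(self):
        # 50 individuals x 100 markers, no missing data
        cfg = SimConfig(seed=6, chromosomes=[("c1", 49.5, 10_000_000)],
                        marker_spacing_cM=0.5)
        gmap = simulate_genetic_map(cfg)
        assert len(gmap) == 100
        geno = simulate_progeny_genotypes(gmap, 50, seed=6)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=50), index=geno.index)
        res = qtl.scan_lod(y, geno, gmap)
        for marker, lod in zip(res.table["marker"], res.table["lod"]):
            X = np.zeros((50, 4))
            idx = [qtl.GENOTYPE_CLASSES.index(c) for c in geno[marker]]
            X[np.arange(50), idx] = 1.0
            assert abs(lod - brute_force_lod(y.to_numpy(), X)) < 1e-8

    def test_affine_invariance(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (QtlSpec("chr2", 25.0, 0.2),), seed=8)
        lod1 = qtl.scan_lod(y, geno, gmap, scanner=study_scanner).table["lod"]
        lod2 = qtl.scan_lod(4.0 * y - 7.0, geno, gmap,
                            scanner=study_scanner).table["lod"]
        assert np.allclose(lod1, lod2, atol=1e-8)

    def test_too_few_individuals_rejected(self, small_map):
        geno = simulate_progeny_genotypes(small_map, 5, seed=1)
        with pytest.raises(ValueError, match="at least 10"):
            qtl.scan_lod(pd.Series(np.ones(5), index=geno.index), geno, small_map)


class TestPermutationThreshold:
    def test_deterministic_for_same_seed(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (), seed=9)
        t1 = qtl.permutation_threshold(y, geno, gmap, n_perm=100, seed=42,
                                       scanner=study_scanner)
        t2 = qtl.permutation_threshold(y, geno, gmap, n_perm=100, seed=42,
                                       scanner=study_scanner)
        assert t1 == t2

    def test_alpha_one_gives_minimum(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (), seed=10)
        rng_thr = qtl.permutation_threshold(y, geno, gmap, n_perm=100,
                                            alpha=1.0, seed=3,
                                            scanner=study_scanner)
        rng_mid = qtl.permutation_threshold(y, geno, gmap, n_perm=100,
                                            alpha=0.5, seed=3,
                                            scanner=study_scanner)
        assert rng_thr <= rng_mid

    def test_too_few_permutations_rejected(self, study):
        gmap, geno = study
        y = planted_trait(geno, gmap, (), seed=1)
        with pytest.raises(ValueError):
            qtl.permutation_threshold(y, geno, gmap, n_perm=10)


class TestBayesCredibleInterval:
    def _scan(self, lods, positions=None):
        n = len(lods)
        pos = positions if positions is not None else np.arange(n, dtype=float)
        tab = pd.DataFrame({
            "marker": [f"c1_{i}" for i in range(n)],
            "chromosome": ["c1"] * n,
            "position_cM": pos,
            "position_bp": (pos * 1e5).astype(int),
            "lod": lods,
        })
        return qtl.ScanResult(tab)

    def test_single_dominant_marker(self):
        ci = qtl.bayes_credible_interval(self._scan([0, 0, 10, 0, 0]), "c1")
        assert ci.low_cM == ci.high_cM == ci.peak_cM == 2.0

    def test_uniform_profile_spans_coverage_fraction(self):
        ci = qtl.bayes_credible_interval(self._scan([1.0] * 20), "c1", 0.95)
        assert (ci.high_cM - ci.low_cM) >= 0.95 * 19 - 1

    def test_flat_zero_spans_chromosome(self):
        with pytest.warns(UserWarning, match="flat"):
            ci = qtl.bayes_credible_interval(self._scan([0.0] * 10), "c1")
        assert ci.low_cM == 0.0 and ci.high_cM == 9.0

    def test_triangular_profile_matches_enumeration(self):
        lods = [0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0]
        ci = qtl.bayes_credible_interval(self._scan(lods), "c1", 0.95)
        # exhaustive cumulative-weight enumeration
        w = 10.0 ** np.asarray(lods, float)
        w = w / w.sum()
        order = np.argsort(-w, kind="stable")
        cum, chosen = 0.0, []
        for i in order:
            chosen.append(i)
            cum += w[i]
            if cum >= 0.95:
                break
        assert ci.low_cM == float(min(chosen))
        assert ci.high_cM == float(max(chosen))
        assert ci.low_cM <= ci.peak_cM <= ci.high_cM


class TestMultiQtlModel:
    def test_single_locus_matches_scan(self, study, study_scanner):
        gmap, geno = study
        spec = QtlSpec("chr4", 30.0, 0.25)
        y = planted_trait(geno, gmap, (spec,), seed=12)
        marker = planted_marker(gmap, spec)
        res = qtl.scan_lod(y, geno, gmap, scanner=study_scanner)
        model = qtl.fit_multi_qtl_model(y, geno, gmap, [marker],
                                        scanner=study_scanner)
        scan_lod_at = float(res.table.set_index("marker").loc[marker, "lod"])
        assert model.loci[0].lod == pytest.approx(scan_lod_at, abs=1e-8)
        assert model.overall_lod == pytest.approx(scan_lod_at, abs=1e-8)

    def test_unlinked_loci_variance_adds(self, study, study_scanner):
        gmap, geno = study
        s1, s2 = QtlSpec("chr3", 20.0, 0.15), QtlSpec("chr12", 35.0, 0.12)
        pct1 = pct2 = pct_joint = 0.0
        reps = 10
        for rep in range(reps):
            y = planted_trait(geno, gmap, (s1, s2), seed=200 + rep)
            m1, m2 = planted_marker(gmap, s1), planted_marker(gmap, s2)
            pct1 += qtl.fit_multi_qtl_model(y, geno, gmap, [m1],
                                            scanner=study_scanner).overall_pct_var
            pct2 += qtl.fit_multi_qtl_model(y, geno, gmap, [m2],
                                            scanner=study_scanner).overall_pct_var
            pct_joint += qtl.fit_multi_qtl_model(
                y, geno, gmap, [m1, m2], scanner=study_scanner).overall_pct_var
        assert pct_joint / reps == pytest.approx((pct1 + pct2) / reps, abs=2.0)

    def test_null_trait_small_overall_variance(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (), seed=13)
        model = qtl.fit_multi_qtl_model(
            y, geno, gmap, ["chr1_0", "chr7_0"], scanner=study_scanner)
        assert model.overall_pct_var <= 5.0

    def test_nested_models_monotone(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (QtlSpec("chr6", 10.0, 0.2),), seed=14)
        markers = ["chr6_5000000", "chr2_0", "chr9_0"]
        prev = -1.0
        for k in range(1, 4):
            pct = qtl.fit_multi_qtl_model(y, geno, gmap, markers[:k],
                                          scanner=study_scanner).overall_pct_var
            assert pct >= prev - 1e-9
            prev = pct

    def test_duplicate_locus_rejected(self, study, study_scanner):
        gmap, geno = study
        y = planted_trait(geno, gmap, (), seed=15)
        with pytest.raises(ValueError, match="distinct"):
            qtl.fit_multi_qtl_model(y, geno, gmap, ["chr1_0", "chr1_0"],
                                    scanner=study_scanner)


class TestStepwiseSearch:
    def test_null_traits_mostly_empty(self, study, study_scanner):
        gmap, geno = study
        n_nonempty = 0
        for rep in range(40):
            y = planted_trait(geno, gmap, (), seed=300 + rep)
            thr = qtl.permutation_threshold(y, geno, gmap, n_perm=200,
                                            seed=rep, scanner=study_scanner)
            model = qtl.stepwise_model_search(y, geno, gmap, thr,
                                              scanner=study_scanner)
            n_nonempty += bool(model.loci)
        assert n_nonempty <= 4  # ~5% genome-wide type-I error

    def test_noise_free_qtl_refines_to_planted_marker(self, study, study_scanner):
        gmap, geno = study
        spec = QtlSpec("chr8", 40.0, 0.999)
        y = planted_trait(geno, gmap, (spec,), seed=16)
        model = qtl.stepwise_model_search(y, geno, gmap, threshold=5.0,
                                          scanner=study_scanner)
        assert planted_marker(gmap, spec) in model.markers
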