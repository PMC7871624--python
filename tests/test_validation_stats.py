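"""Group comparisons, replicate variance, feature distances, rank correlation."""

import numpy as np
import pandas as pd
import pytest

from quod import synthetic, validation_stats
from quod.errors import ParameterError, ValidationError
from quod.models import DispensabilityScores, GeneModel

from conftest import make_matrix


def make_scores(values, prefix="g"):
    return DispensabilityScores(
        scores=pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))]),
        n_genomes_used=10,
    )


def u_by_pairwise_counting(a, b):
    """Exhaustive oracle: wins + half-ties over all (a, b) pairs."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestCompareScoreGroups:
    def test_complete_separation_gives_u_zero(self):
        scores = make_scores([0.9, 1.0, 1.1, 1.5, 2.0, 2.5])
        res = validation_stats.compare_score_groups(scores, {"g0", "g1", "g2"})
        assert res.u_statistic == 0.0
        assert res.n_a == 3 and res.n_b == 3

    def test_identical_samples_carry_no_evidence(self):
        scores = make_scores([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = validation_stats.compare_score_groups(scores, {"g0", "g1", "g2"})
        assert res.u_statistic == pytest.approx(4.5)
        assert res.u_pvalue == pytest.approx(1.0)

    def test_u_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 7), rng.integers(1, 7)
            values = np.round(rng.uniform(0.5, 3.0, size=n_a + n_b), 1)  # force ties
            scores = make_scores(values)
            members = {f"g{i}" for i in range(n_a)}
            res = validation_stats.compare_score_groups(scores, members)
            a, b = values[:n_a], values[n_a:]
            assert res.u_statistic == pytest.approx(u_by_pairwise_counting(a, b), abs=1e-9)

    def test_levene_matches_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n_a, n_b = rng.integers(3, 12), rng.integers(3, 12)
            values = rng.uniform(0.5, 3.0, size=n_a + n_b)
            scores = make_scores(values)
            res = validation_stats.compare_score_groups(scores, {f"g{i}" for i in range(n_a)})
            from scipy.stats import f_oneway

            a, b = values[:n_a], values[n_a:]
            ref = f_oneway(np.abs(a - a.mean()), np.abs(b - b.mean()))
            assert res.levene_statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.levene_pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_in_both_groups_flagged_not_crashed(self):
        scores = make_scores([1.0, 1.0, 2.0, 2.0])
        res = validation_stats.compare_score_groups(scores, {"g0", "g1"})
        assert not res.levene_applicable
        assert np.isnan(res.levene_statistic)

    def test_group_means_and_variances_reported(self):
        scores = make_scores([1.0, 3.0, 2.0, 4.0, 6.0])
        res = validation_stats.compare_score_groups(scores, {"g0", "g1"}, ("busco", "rest"))
        assert res.mean_a == 2.0 and res.mean_b == 4.0
        assert res.variance_a == pytest.approx(np.var([1.0, 3.0], ddof=1))
        assert res.group_a_label == "busco"

    def test_infinite_scores_refused(self):
        scores = make_scores([1.0, np.inf, 2.0])
        with pytest.raises(ValidationError, match="cap_infinite_scores"):
            validation_stats.compare_score_groups(scores, {"g0"})

    def test_empty_group_rejected(self):
        scores = make_scores([1.0, 2.0])
        with pytest.raises(ParameterError):
            validation_stats.compare_score_groups(scores, {"g0", "g1"})

    def test_unknown_members_rejected(self):
        with pytest.raises(ValidationError, match="gZ"):
            validation_stats.compare_score_groups(make_scores([1.0, 2.0]), {"gZ"})


class TestReplicateVariance:
    def _replicate_matrix(self, full, n_genomes=14, seed=0):
        # technical replicates: same accession, depth differences plus a
        # little multiplicative coverage noise, no presence/absence
        spec = synthetic.PangenomeSpec(
            n_genes=full.n_genes,
            n_genomes=n_genomes,
            depth_per_genome=list(np.random.default_rng(seed).uniform(15, 35, n_genomes)),
            noise_cv=0.05,
            seed=seed + 1000,
        )
        return synthetic.simulate_coverage_matrix(spec)[0]

    def _full_matrix(self, n_genes=40, n_genomes=30, seed=1):
        spec = synthetic.PangenomeSpec(
            n_genes=n_genes,
            n_genomes=n_genomes,
            pav_genes={i: 0.5 for i in range(0, n_genes, 5)},
            depth_per_genome=list(np.random.default_rng(seed).uniform(12, 40, n_genomes)),
            noise_cv=0.05,
            seed=seed,
        )
        return synthetic.simulate_coverage_matrix(spec)[0]

    def test_scaled_uniform_replicates_have_zero_variance(self):
        # columns constant within each genome up to a depth factor:
        # every score is exactly 1, so the replicate variance vanishes
        full = self._full_matrix()
        depths = np.random.default_rng(2).uniform(12, 40, 14)
        flat = make_matrix(np.outer(np.ones(full.n_genes), depths), gene_ids=full.gene_ids)
        res = validation_stats.replicate_variance_analysis(flat, full, iterations=5, seed=3)
        assert res.replicate_variance == pytest.approx(0.0, abs=1e-18)

    def test_pav_subsets_exceed_replicate_variance(self):
        full = self._full_matrix()
        res = validation_stats.replicate_variance_analysis(
            self._replicate_matrix(full), full, iterations=20, seed=4
        )
        assert res.pooled_subset_variance > res.replicate_variance
        assert res.levene_pvalue < 0.05

    def test_bit_reproducible_for_fixed_seed(self):
        full = self._full_matrix()
        rep = self._replicate_matrix(full)
        r1 = validation_stats.replicate_variance_analysis(rep, full, iterations=10, seed=9)
        r2 = validation_stats.replicate_variance_analysis(rep, full, iterations=10, seed=9)
        assert r1.subset_variances == r2.subset_variances
        assert r1.levene_pvalue == r2.levene_pvalue

    def test_single_iteration_is_well_formed(self):
        full = self._full_matrix()
        res = validation_stats.replicate_variance_analysis(
            self._replicate_matrix(full), full, iterations=1, seed=5
        )
        assert len(res.subset_variances) == 1
        assert res.iterations == 1

    def test_oversized_subset_rejected(self):
        full = self._full_matrix(n_genomes=10)
        with pytest.raises(ParameterError):
            validation_stats.replicate_variance_analysis(
                self._replicate_matrix(full), full, subset_size=14
            )

    def test_gene_set_mismatch_rejected(self):
        full = self._full_matrix()
        rep = make_matrix(np.full((3, 14), 20.0), gene_ids=["x0", "x1", "x2"])
        with pytest.raises(ValidationError):
            validation_stats.replicate_variance_analysis(rep, full)


class TestNearestFeatureDistances:
    def test_overlap_and_gap_and_missing_chromosome(self):
        genes = [
            GeneModel("a", "Chr1", 100, 200),
            GeneModel("b", "Chr1", 100, 200),
            GeneModel("c", "Chr2", 100, 200),
        ]
        tes = [GeneModel("te1", "Chr1", 150, 250), GeneModel("te2", "Chr1", 300, 400)]
        d = validation_stats.nearest_feature_distances(genes, tes)
        assert d["a"] == 0.0  # overlap
        assert d["b"] == 0.0
        assert np.isnan(d["c"])  # no feature on Chr2
        d2 = validation_stats.nearest_feature_distances(
            [GeneModel("x", "Chr1", 100, 200)], [GeneModel("te2", "Chr1", 300, 400)]
        )
        assert d2["x"] == 100.0

    def test_adjacent_intervals_have_distance_one(self):
        d = validation_stats.nearest_feature_distances(
            [GeneModel("a", "Chr1", 100, 200)], [GeneModel("t", "Chr1", 201, 300)]
        )
        assert d["a"] == 1.0

    def test_self_feature_excluded(self):
        te = GeneModel("te1", "Chr1", 100, 200)
        other = GeneModel("te2", "Chr1", 500, 600)
        d = validation_stats.nearest_feature_distances([te], [te, other])
        assert d["te1"] == 300.0  # 500 - 200, not 0 against itself

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(31)
        genes, tes = [], []
        for i in range(120):
            start = int(rng.integers(1, 100_000))
            genes.append(GeneModel(f"g{i}", f"Chr{rng.integers(1, 4)}", start, start + int(rng.integers(1, 5000))))
        for i in range(80):
            start = int(rng.integers(1, 100_000))
            tes.append(GeneModel(f"t{i}", f"Chr{rng.integers(1, 4)}", start, start + int(rng.integers(1, 5000))))
        result = validation_stats.nearest_feature_distances(genes, tes)
        for gene in genes:
            candidates = [
                max(0, t.start - gene.end, gene.start - t.end)
                for t in tes
                if t.seq_id == gene.seq_id and t.gene_id != gene.gene_id
            ]
            expected = min(candidates) if candidates else np.nan
            if np.isnan(expected):
                assert np.isnan(result[gene.gene_id])
            else:
                assert result[gene.gene_id] == expected

    def test_empty_reference_rejected(self):
        with pytest.raises(ParameterError):
            validation_stats.nearest_feature_distances([GeneModel("a", "Chr1", 1, 10)], [])


class TestCoverageRankCorrelation:
    def test_identical_matrices_correlate_perfectly(self):
        m = make_matrix(np.random.default_rng(0).uniform(0, 30, size=(15, 4)))
        rho, _ = validation_stats.coverage_rank_correlation(m, m)
        assert rho == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        a = make_matrix(np.arange(1.0, 11.0)[:, None])
        b = make_matrix(np.arange(10.0, 0.0, -1.0)[:, None])
        rho, _ = validation_stats.coverage_rank_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_constant_side_is_undefined(self):
        a = make_matrix(np.full((5, 2), 7.0))
        b = make_matrix(np.random.default_rng(1).uniform(0, 9, size=(5, 2)))
        with pytest.raises(ValidationError, match="undefined"):
            validation_stats.coverage_rank_correlation(a, b)


class TestPredictorTableAndGeneLists:
    def test_gene_list_parsing_with_comments(self, tmp_path):
        path = tmp_path / "busco.txt"
        path.write_text("# conserved genes\ng1\ng2  # trailing\n\ng3\n")
        assert validation_stats.read_gene_list(path) == {"g1", "g2", "g3"}

    def test_predictor_table_columns(self):
        genes = [GeneModel("g0", "Chr1", 1, 100), GeneModel("g1", "Chr1", 500, 899)]
        tes = [GeneModel("g1", "Chr1", 500, 899)]
        scores = make_scores([1.2, 0.8])
        table = validation_stats.build_predictor_table(
            scores, genes, tes, exon_counts=pd.Series({"g0": 3, "g1": 1})
        )
        assert list(table.columns) == [
            "dispensability_score",
            "distance_to_nearest_TE",
            "gene_length",
            "exon_count",
        ]
        assert table.loc["g0", "gene_length"] == 100
        assert table.loc["g0", "distance_to_nearest_TE"] == 400.0
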