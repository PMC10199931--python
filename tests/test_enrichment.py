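"""ssGSEA statistics: ranking, running scores, permutation calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssgimme.enrichment import (
    GeneSetCollection,
    SsgseaConfig,
    enrichment_score,
    normalize_scores,
    permutation_null,
    rank_transform,
    read_gmt,
    running_score,
    ssgsea,
    write_gmt,
)

from conftest import brute_force_es

RANK_CFG = SsgseaConfig(correlation_type="rank")


class TestReadGmt:
    def test_single_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\n")
        collection = read_gmt(str(path))
        assert collection.genes("S1") == ("g1", "g2")
        assert collection.description("S1") == "desc"

    def test_duplicate_genes_deduplicated(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\tg1\n")
        assert read_gmt(str(path)).genes("S1") == ("g1", "g2")

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gmt(str(path))

    def test_short_line_names_line_number(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\td\tg1\nS2\tonly-two-fields\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gmt(str(path))

    def test_empty_file(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("")
        assert len(read_gmt(str(path))) == 0

    def test_write_read_round_trip(self, tmp_path, pathway_sets):
        path = tmp_path / "sets.gmt"
        write_gmt(pathway_sets, str(path))
        assert read_gmt(str(path)).sets == pathway_sets.sets


class TestRankTransform:
    def test_rank_mode_values(self):
        profile = rank_transform({"a": 3.0, "b": 1.0, "c": 2.0}, RANK_CFG)
        assert profile.genes == ("a", "c", "b")
        np.testing.assert_allclose(profile.correlations, [3 / 3, 2 / 3, 1 / 3])

    def test_zscore_mode_standardizes_ranks(self):
        profile = rank_transform({"a": 3.0, "b": 1.0, "c": 2.0})
        expected = (np.array([3.0, 2.0, 1.0]) - 2.0) / np.std([1, 2, 3])
        np.testing.assert_allclose(profile.correlations, expected)
        assert profile.correlations.mean() == pytest.approx(0.0, abs=1e-12)
        assert profile.correlations.std() == pytest.approx(1.0)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="all expression values are equal"):
            rank_transform({"a": 1.0, "b": 1.0})

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3, max_size=12, unique=True,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transform(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        base = rank_transform(dict(zip(genes, values)), RANK_CFG)
        # scaling by a power of two is exact in floats: strictly monotone
        # and tie-free whenever the inputs are distinct
        warped = rank_transform(
            {g: 8.0 * v for g, v in zip(genes, values)}, RANK_CFG
        )
        assert base.genes == warped.genes
        np.testing.assert_allclose(base.correlations, warped.correlations)

    def test_ties_broken_reproducibly(self):
        values = {"a": 2.0, "b": 2.0, "c": 1.0}
        first = rank_transform(values, RANK_CFG)
        second = rank_transform(values, RANK_CFG)
        assert first.genes == second.genes


def four_gene_profile():
    return rank_transform(
        {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}, RANK_CFG
    )


class TestRunningScore:
    def test_top_gene_set_walk(self):
        rs = running_score(four_gene_profile(), {"g1"}, alpha=0.0)
        np.testing.assert_allclose(rs.res, [1.0, 2 / 3, 1 / 3, 0.0])

    def test_bottom_gene_set_walk(self):
        rs = running_score(four_gene_profile(), {"g4"}, alpha=0.0)
        np.testing.assert_allclose(rs.res, [-1 / 3, -2 / 3, -1.0, 0.0])

    def test_res_ends_at_zero_and_ecdfs_monotone(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        profile = rank_transform(dict(zip(genes, rng.normal(size=40))))
        rs = running_score(profile, set(rng.choice(genes, 9, replace=False)))
        assert rs.res[-1] == pytest.approx(0.0, abs=1e-12)
        assert (np.diff(rs.p_in) >= -1e-12).all() and rs.p_in[-1] == pytest.approx(1.0)
        assert (np.diff(rs.p_out) >= 0).all() and rs.p_out[-1] == pytest.approx(1.0)

    def test_degenerate_sets_rejected(self):
        profile = four_gene_profile()
        with pytest.raises(ValueError, match="no genes"):
            running_score(profile, {"zz"})
        with pytest.raises(ValueError, match="whole profile"):
            running_score(profile, {"g1", "g2", "g3", "g4"})

    @pytest.mark.parametrize("statistic, expected", [
        ("area_under_RES", 2.0),
        ("kolmogorov_smirnov", 1.0),
    ])
    def test_enrichment_score_statistics(self, statistic, expected):
        rs = running_score(four_gene_profile(), {"g1"}, alpha=0.0)
        assert enrichment_score(rs, statistic) == pytest.approx(expected)

    @pytest.mark.parametrize("statistic", ["area_under_RES", "kolmogorov_smirnov"])
    @pytest.mark.parametrize("alpha", [0.0, 0.75, 1.0])
    def test_matches_brute_force_oracle(self, statistic, alpha):
        rng = np.random.default_rng(42)
        for _ in range(25):
            genes = [f"g{i}" for i in range(50)]
            profile = rank_transform(
                dict(zip(genes, rng.lognormal(1, 1, size=50)))
            )
            members = set(rng.choice(genes, rng.integers(3, 20), replace=False))
            es = enrichment_score(
                running_score(profile, members, alpha=alpha), statistic
            )
            oracle = brute_force_es(
                profile.genes, profile.correlations, members, alpha, statistic
            )
            assert es == pytest.approx(oracle, abs=1e-9)


class TestPermutationNull:
    def test_deterministic_for_fixed_seed(self):
        profile = four_gene_profile()
        config = SsgseaConfig(n_permutations=50, seed=11)
        np.testing.assert_array_equal(
            permutation_null(profile, 2, config), permutation_null(profile, 2, config)
        )

    def test_single_permutation(self):
        null = permutation_null(
            four_gene_profile(), 2, SsgseaConfig(n_permutations=1)
        )
        assert null.shape == (1,)

    def test_null_mean_near_zero_for_symmetric_correlations(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        profile = rank_transform(dict(zip(genes, rng.normal(size=100))))
        null = permutation_null(profile, 10, SsgseaConfig(n_permutations=2000, seed=3))
        assert abs(null.mean()) < 3 * null.std(ddof=1) / np.sqrt(len(null))

    def test_set_size_out_of_range(self):
        with pytest.raises(ValueError, match="set size"):
            permutation_null(four_gene_profile(), 4, SsgseaConfig())


class TestNormalizeScores:
    def test_es_at_null_mean(self):
        null = np.array([-1.0, 0.0, 1.0, 2.0])
        nes, p = normalize_scores(float(null.mean()), null)
        assert nes == pytest.approx(0.0)
        assert p > 0.5

    def test_extreme_es_gets_add_one_bound(self):
        null = np.random.default_rng(0).normal(size=1000)
        _, p = normalize_scores(1e6, null)
        assert p == pytest.approx(1 / 1001)

    def test_normal_tail_recovers_five_percent(self):
        null = np.random.default_rng(1).normal(size=100_000)
        _, p = normalize_scores(1.96, null)
        assert p == pytest.approx(0.05, abs=0.005)

    def test_zero_variance_null_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_scores(1.0, np.ones(10))


class TestSsgsea:
    def test_small_sets_dropped(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        matrix = pd.DataFrame({"s1": rng.lognormal(size=20)}, index=genes)
        sets = GeneSetCollection(
            {"tiny": ("", ("g1", "g2")), "ok": ("", ("g3", "g4", "g5"))}
        )
        result = ssgsea(matrix, sets, SsgseaConfig(n_permutations=50))
        assert set(result.table["set"]) == {"ok"}

    def test_no_set_passes_filter_gives_empty_result(self):
        matrix = pd.DataFrame(
            {"s1": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"]
        )
        sets = GeneSetCollection({"tiny": ("", ("g1",))})
        assert ssgsea(matrix, sets, SsgseaConfig(n_permutations=10)).table.empty

    def test_top_gene_set_scores_highest_by_exhaustive_check(self):
        """The set holding a sample's top genes beats every other same-size
        set, confirmed by scoring all C(10,3) subsets directly."""
        genes = [f"g{i}" for i in range(10)]
        matrix = pd.DataFrame(
            {"s1": np.arange(10, 0, -1, dtype=float)}, index=genes
        )
        config = SsgseaConfig(n_permutations=100, seed=2)
        profile = rank_transform(matrix["s1"], config)
        scores = {
            subset: enrichment_score(
                running_score(profile, set(subset), config.weight_exponent),
                config.statistic,
            )
            for subset in itertools.combinations(genes, 3)
        }
        top_set = ("g0", "g1", "g2")
        assert max(scores, key=scores.get) == top_set
        result = ssgsea(
            matrix,
            GeneSetCollection(
                {"top": ("", top_set), "other": ("", ("g5", "g7", "g9"))}
            ),
            config,
        )
        table = result.table.set_index("set")
        assert table.loc["top", "nes"] > table.loc["other", "nes"]

    def test_scores_invariant_under_gene_relabeling(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        matrix = pd.DataFrame({"s1": rng.lognormal(size=30)}, index=genes)
        sets = GeneSetCollection(
            {"A": ("", tuple(genes[:5])), "B": ("", tuple(genes[10:16]))}
        )
        config = SsgseaConfig(n_permutations=200, seed=8)
        base = ssgsea(matrix, sets, config).table

        mapping = {g: f"x_{g}" for g in genes}
        renamed_matrix = matrix.rename(index=mapping)
        renamed = ssgsea(matrix=renamed_matrix, sets=sets.rename_genes(mapping),
                         config=config).table
        np.testing.assert_allclose(base["es"], renamed["es"], atol=1e-12)
        np.testing.assert_allclose(base["nes"], renamed["nes"], atol=1e-12)

    def test_null_calibration_near_five_percent(self):
        """Random expression, random sets, cutoff 1.96: about 5% of
        (set, sample) scores come out significant."""
        rng = np.random.default_rng(1)
        n_genes, n_sets, size, n_samples = 500, 300, 20, 4
        genes = [f"g{i}" for i in range(n_genes)]
        matrix = pd.DataFrame(
            rng.lognormal(2, 1, size=(n_genes, n_samples)),
            index=genes,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        sets = GeneSetCollection(
            {
                f"set{k}": ("", tuple(rng.choice(genes, size=size, replace=False)))
                for k in range(n_sets)
            }
        )
        result = ssgsea(matrix, sets, SsgseaConfig(seed=1))
        fraction = float(result.table["significant"].mean())
        assert len(result.table) == n_sets * n_samples
        assert 0.03 <= fraction <= 0.07
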