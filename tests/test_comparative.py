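"""Correlation distances, PHYLIP export, LS trees, per-codon ANOVA."""

import numpy as np
import pytest

import _tree_oracle as oracle
from codonheg import (
    DistanceMatrix,
    FixtureSpec,
    ProfileError,
    StrainProfile,
    biased_codon_probs,
    build_distance_matrix,
    correlation_distance,
    fit_tree,
    informative_codons,
    make_profile,
    metric_table_for,
    per_codon_anova,
    profile_correlation,
    read_phylip_matrix,
    write_newick,
    write_phylip_matrix,
)


def profile(label, values, codons=None):
    codons = codons if codons is not None else informative_codons()
    return StrainProfile(label, "NRSCU", tuple(codons[: len(values)]), np.asarray(values, float))


class TestCorrelation:
    def test_identical_profiles_give_r_one(self, rng):
        values = rng.uniform(0, 1, size=59)
        assert profile_correlation(profile("a", values), profile("b", values)) == pytest.approx(1.0)

    def test_reflection_about_mean_gives_r_minus_one(self, rng):
        values = rng.uniform(0, 1, size=59)
        mirrored = 2 * values.mean() - values
        r = profile_correlation(profile("a", values), profile("b", mirrored))
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.uniform(0, 1, size=59)
        y = rng.uniform(0, 1, size=59)
        r = profile_correlation(profile("a", x), profile("b", y))
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_masked_entries_dropped_pairwise(self, rng):
        x = rng.uniform(0, 1, size=59)
        y = x.copy()
        x[3], y[7] = np.nan, np.nan
        assert profile_correlation(profile("a", x), profile("b", y)) == pytest.approx(1.0)

    def test_errors_name_the_pair(self):
        few = profile("few1", [1.0, np.nan, np.nan, 2.0])
        other = profile("few2", [1.0, 2.0, np.nan, np.nan])
        with pytest.raises(ProfileError, match="few1 vs few2"):
            profile_correlation(few, other)
        flat = profile("flat", [0.5] * 10)
        varied = profile("varied", list(range(10)))
        with pytest.raises(ProfileError, match="zero variance"):
            profile_correlation(flat, varied)

    def test_spearman_option(self, rng):
        x = rng.uniform(0, 1, size=30)
        r = profile_correlation(profile("a", x), profile("b", x**3), method="spearman")
        assert r == pytest.approx(1.0)  # monotone transform


class TestCorrelationDistance:
    def test_endpoints_and_midpoint(self):
        assert correlation_distance(1.0) == 0.0
        assert correlation_distance(-1.0) == 1.0
        assert correlation_distance(0.0) == 0.5

    def test_affine_monotone_decreasing(self):
        grid = np.linspace(-1, 1, 11)
        distances = [correlation_distance(r) for r in grid]
        assert all(a > b for a, b in zip(distances, distances[1:]))
        np.testing.assert_allclose(np.diff(distances), np.diff(distances)[0])

    def test_out_of_range_rejected_beyond_tolerance(self):
        with pytest.raises(ValueError):
            correlation_distance(1.1)
        assert correlation_distance(1.0 + 1e-12) == 0.0  # round-off clipped


class TestDistanceMatrix:
    def test_identical_profiles_give_zero_matrix(self, rng):
        values = rng.uniform(0, 1, size=59)
        matrix = build_distance_matrix([profile(f"s{i}", values) for i in range(3)])
        np.testing.assert_allclose(matrix.d, 0.0, atol=1e-12)

    def test_entries_equal_pairwise_composition(self, rng):
        profiles = [profile(f"s{i}", rng.uniform(0, 1, size=59)) for i in range(4)]
        matrix = build_distance_matrix(profiles)
        assert matrix.d == pytest.approx(matrix.d.T)
        assert np.diag(matrix.d) == pytest.approx(np.zeros(4))
        for i in range(4):
            for j in range(i + 1, 4):
                expected = correlation_distance(
                    profile_correlation(profiles[i], profiles[j])
                )
                assert matrix.d[i, j] == pytest.approx(expected)

    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.3, 0.0]]))


class TestPhylipFormat:
    def test_three_taxon_layout(self, tmp_path):
        matrix = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        path = tmp_path / "m.phy"
        write_phylip_matrix(matrix, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].strip() == "3"
        assert lines[1].startswith("A         0.000000")

    def test_truncation_collision_uniquified(self, tmp_path, caplog):
        matrix = DistanceMatrix(
            ("Salmonella enterica A", "Salmonella enterica B"),
            np.array([[0, 0.1], [0.1, 0]]),
        )
        path = tmp_path / "m.phy"
        with caplog.at_level("WARNING"):
            write_phylip_matrix(matrix, path)
        names = [line[:10].strip() for line in path.read_text().splitlines()[1:]]
        assert len(set(names)) == 2
        assert "uniquified" in caplog.text or "shortened" in caplog.text

    def test_round_trip(self, tmp_path, rng):
        profiles = [profile(f"s{i}", rng.uniform(0, 1, size=59)) for i in range(4)]
        matrix = build_distance_matrix(profiles)
        path = tmp_path / "m.phy"
        write_phylip_matrix(matrix, path)
        reread = read_phylip_matrix(path)
        assert reread.labels == matrix.labels
        np.testing.assert_allclose(reread.d, matrix.d, atol=5.1e-7)


class TestFitTree:
    def test_three_taxon_exact_branch_lengths(self):
        matrix = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = fit_tree(matrix)
        assert tree.newick() == "(A:0.100000,B:0.100000,C:0.300000);"
        assert tree.residual == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_matrix_gives_star_with_zero_lengths(self):
        matrix = DistanceMatrix(("A", "B", "C"), np.zeros((3, 3)))
        tree = fit_tree(matrix)
        np.testing.assert_allclose(tree.lengths, 0.0, atol=1e-12)
        assert tree.bipartitions() == set()

    def test_newick_round_trip_with_dendropy(self, tmp_path, rng):
        import dendropy

        d, _, _ = oracle.random_additive_matrix(rng, 5)
        matrix = DistanceMatrix(tuple("ABCDE"), d)
        tree = fit_tree(matrix)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ABCDE")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate("ABCDE"):
            for j, b in enumerate("ABCDE"):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        tree.path_length_matrix()[i, j], abs=5e-6
                    )

    def test_labels_with_spaces_are_quoted(self):
        matrix = DistanceMatrix(
            ("E coli", "B subtilis", "V cholerae"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        newick = fit_tree(matrix).newick()
        assert "'E coli'" in newick and "'B subtilis'" in newick

    def test_recovers_additive_six_taxon_matrices(self, rng):
        """Topology matches the exhaustive LS optimum; distances reproduced."""
        for _ in range(5):
            d, true_edges, _ = oracle.random_additive_matrix(rng, 6)
            matrix = DistanceMatrix(tuple("ABCDEF"), d)
            tree = fit_tree(matrix)
            # additive matrices are reproduced exactly by the fitted tree
            np.testing.assert_allclose(tree.path_length_matrix(), d, atol=1e-9)
            best_edges, _, best_residual = oracle.best_tree(
                d[np.triu_indices(6, 1)], 6
            )
            label_splits = {
                frozenset("ABCDEF"[i] for i in split)
                for split in oracle.bipartitions(6, best_edges)
            }
            assert tree.bipartitions() == label_splits  # RF distance 0
            assert tree.residual <= best_residual + 1e-9

    def test_invariant_to_taxon_input_order(self, rng):
        d, _, _ = oracle.random_additive_matrix(rng, 6)
        labels = tuple("ABCDEF")
        tree = fit_tree(DistanceMatrix(labels, d))
        perm = rng.permutation(6)
        permuted = fit_tree(
            DistanceMatrix(tuple(labels[i] for i in perm), d[np.ix_(perm, perm)])
        )
        assert tree.bipartitions() == permuted.bipartitions()
        # same path lengths between the same labelled strains
        original = {
            (labels[i], labels[j]): tree.path_length_matrix()[i, j]
            for i in range(6)
            for j in range(6)
        }
        for i in range(6):
            for j in range(6):
                a, b = labels[perm[i]], labels[perm[j]]
                assert permuted.path_length_matrix()[i, j] == pytest.approx(
                    original[(a, b)], abs=1e-9
                )

    def test_cherry_forced_by_two_identical_strains(self, rng):
        values = rng.uniform(0, 1, size=59)
        divergent = rng.uniform(0, 1, size=59)
        other = rng.uniform(0, 1, size=59)
        profiles = [
            profile("twin1", values),
            profile("far", divergent),
            profile("twin2", values + rng.normal(0, 1e-6, size=59)),
            profile("other", other),
        ]
        tree = fit_tree(build_distance_matrix(profiles))
        # splits are canonicalized to one side; the cherry may appear as its complement
        assert {frozenset({"twin1", "twin2"}), frozenset({"far", "other"})} & tree.bipartitions()


class TestPerCodonAnova:
    @staticmethod
    def tables_for(seeds, favored="first"):
        return [
            metric_table_for(
                FixtureSpec(
                    seed=s, gene_length=20, codon_probs=biased_codon_probs(favored)
                ),
                strain_label=f"s{s}",
            )
            for s in seeds
        ]

    def test_identical_value_multisets_give_f_zero(self, code):
        import pandas as pd
        from codonheg.metrics import CODONS, MetricTable

        def fake_table(label, offset):
            data = pd.DataFrame(
                {
                    "AA": [code.code[c] for c in CODONS],
                    "Count": 1,
                    "RSCU": 1.0,
                    "NRSCU": [1.0, 2.0, 3.0][offset % 3],
                    "HEG_FB": 0.01,
                },
                index=pd.Index(CODONS, name="Codon"),
            )
            return MetricTable(label, data)

        groups = {
            "g1": [fake_table("a", 0), fake_table("b", 1), fake_table("c", 2)],
            "g2": [fake_table("d", 0), fake_table("e", 1), fake_table("f", 2)],
        }
        result, summary = per_codon_anova(groups, "nrscu")
        assert (result["F"] == 0.0).all()
        assert summary["n_raw_p_below_0.05"] == 0

    def test_matches_hand_sums_of_squares(self, code):
        """F for a small printed layout vs the textbook SS decomposition."""
        import pandas as pd
        from codonheg.metrics import CODONS, MetricTable

        layout = {"g1": [0.1, 0.2, 0.3], "g2": [0.4, 0.5, 0.9]}

        def fake(label, value):
            data = pd.DataFrame(
                {
                    "AA": [code.code[c] for c in CODONS],
                    "Count": 1,
                    "RSCU": 1.0,
                    "NRSCU": value,
                    "HEG_FB": 0.01,
                },
                index=pd.Index(CODONS, name="Codon"),
            )
            return MetricTable(label, data)

        groups = {
            name: [fake(f"{name}{k}", v) for k, v in enumerate(values)]
            for name, values in layout.items()
        }
        result, _ = per_codon_anova(groups, "nrscu")
        # hand decomposition
        values = np.array(layout["g1"] + layout["g2"])
        grand = values.mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in layout.values()
        )
        ss_within = sum(
            ((np.array(v) - np.mean(v)) ** 2).sum() for v in layout.values()
        )
        f_expected = (ss_between / 1) / (ss_within / 4)
        np.testing.assert_allclose(result["F"], f_expected, atol=1e-10)

    def test_separated_groups_are_detected(self):
        # at weight 0.5 only the first and last codons of families with >= 3
        # members differ between the two regimes: 18 codons carry true signal
        groups = {
            "first": self.tables_for([1, 2, 3], "first"),
            "last": self.tables_for([4, 5, 6], "last"),
        }
        result, summary = per_codon_anova(groups, "nrscu")
        assert summary["n_adj_p_below_0.05"] >= 12
        assert summary["min_p_adj"] < 0.01

    def test_same_distribution_groups_mostly_insignificant(self):
        groups = {
            "a": self.tables_for([11, 12, 13]),
            "b": self.tables_for([14, 15, 16]),
        }
        result, summary = per_codon_anova(groups, "nrscu")
        assert summary["n_adj_p_below_0.05"] <= 3

    def test_requires_two_groups_of_two(self):
        from codonheg import UsageError

        tables = self.tables_for([1, 2])
        with pytest.raises(UsageError):
            per_codon_anova({"only": tables})
        with pytest.raises(UsageError):
            per_codon_anova({"a": tables, "b": tables[:1]})
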