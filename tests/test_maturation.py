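"""Affinity maturation: grid expansion, pooling, dedup, sequence space, picks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nbselect.descriptors import AMINO_ACIDS, N_DESCRIPTORS, synthetic_descriptor_table
from nbselect.fixtures import NANOBODY_TEMPLATE, gen_variant_pool
from nbselect.maturation import (
    DesignParameterGrid,
    SequenceSpace,
    cluster_density,
    dedupe_variants,
    delta_flexddg,
    expand_grid,
    featurize_sequences,
    maturation_select,
    nearest_to_centroid,
    project_pca,
    retain_lowest_k,
    validate_mutation_positions,
)


class TestExpandGrid:
    def test_four_binary_axes_give_16_variations(self):
        configs = expand_grid(DesignParameterGrid())
        assert len(configs) == 16
        assert len({tuple(sorted(c.items())) for c in configs}) == 16
        assert configs[0]["variation_id"] == "var01"

    def test_zero_axes_give_one_empty_config(self):
        assert expand_grid({}) == [{"variation_id": "var01"}]

    def test_three_axes_match_manual_enumeration(self):
        axes = {"a": (0, 1), "b": (0, 1), "c": (0, 1)}
        configs = expand_grid(axes)
        manual = [
            {"a": x, "b": y, "c": z}
            for x in (0, 1)
            for y in (0, 1)
            for z in (0, 1)
        ]
        assert [{k: c[k] for k in "abc"} for c in configs] == manual


class TestRetainAndDedupe:
    def test_16_variations_times_100_gives_1600(self):
        rng = np.random.default_rng(0)
        frames = {
            f"var{i:02d}": pd.DataFrame(
                {
                    "sequence": [f"S{i}_{j}" for j in range(150)],
                    "ddg": rng.normal(size=150),
                }
            )
            for i in range(16)
        }
        pool = retain_lowest_k(frames, k=100)
        assert len(pool) == 1600

    def test_lowest_k_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"sequence": [f"s{i}" for i in range(9)], "ddg": rng.normal(size=9)}
        )
        got = retain_lowest_k({"v": df}, k=4)
        assert got["ddg"].tolist() == sorted(df["ddg"])[:4]

    def test_k_exceeding_n_warns_and_keeps_all(self):
        df = pd.DataFrame({"sequence": ["a", "b"], "ddg": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert len(retain_lowest_k({"v": df}, k=10)) == 2

    def test_dedupe_five_copies_to_one(self):
        pool = pd.DataFrame({"sequence": ["X"] * 5, "ddg": [3.0, 1.0, 2.0, 5.0, 4.0]})
        out = dedupe_variants(pool)
        assert len(out) == 1
        assert out["ddg"].iloc[0] == 1.0  # representative keeps min ddg

    def test_dedupe_1600_pool_with_89_unique(self, maturation_pool):
        assert len(maturation_pool) == 1600
        out = dedupe_variants(maturation_pool)
        assert len(out) == 89
        assert len(set(maturation_pool["sequence"])) == 89  # hash-set oracle

    def test_dedupe_representative_matches_groupby_oracle(self, maturation_pool):
        out = dedupe_variants(maturation_pool).set_index("sequence")["ddg"]
        oracle = maturation_pool.groupby("sequence")["ddg"].min()
        pd.testing.assert_series_equal(
            out.sort_index(), oracle.sort_index(), check_names=False
        )


class TestDeltaFlexddg:
    def test_values(self):
        assert delta_flexddg(-1.0, -1.0) == 0.0
        assert delta_flexddg(-3.2, -1.0) == pytest.approx(-2.2)
        # improvement is negative
        assert delta_flexddg(-5.0, -1.0) < 0

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            delta_flexddg(-3.0, float("nan"))


class TestFeaturize:
    def test_single_residue_gives_66(self):
        assert featurize_sequences(["A"]).shape == (1, 66)

    def test_identical_sequences_identical_rows(self):
        m = featurize_sequences(["ACD", "ACD"])
        np.testing.assert_array_equal(m[0], m[1])

    def test_shape_and_cell_lookup(self):
        table = synthetic_descriptor_table()
        seqs = ["ACD", "WYV", "GGG", "KLM", "PQR"]
        m = featurize_sequences(seqs, table)
        assert m.shape == (5, 3 * N_DESCRIPTORS)
        # cell = direct table lookup (position-major layout)
        assert m[1, 66 + 5] == table.loc["Y"].iloc[5]

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            featurize_sequences(["AA", "AAA"])
        with pytest.raises(ValueError, match="Z"):
            featurize_sequences(["AZ"])


class TestProjectPca:
    def test_collinear_points_have_zero_pc2(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=66)
        t = rng.normal(size=30)
        matrix = np.outer(t, direction)
        coords = project_pca(matrix)
        assert np.max(np.abs(coords[:, 1])) < 1e-8

    def test_variance_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 10)) @ rng.normal(size=(10, 40))
        coords = project_pca(x, n_components=2)
        cov = np.cov(x - x.mean(0), rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(coords.var(axis=0, ddof=1), eigvals[:2], rtol=1e-8)

    def test_identical_rows_project_identically(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 15))
        x[7] = x[3]
        coords = project_pca(x)
        np.testing.assert_allclose(coords[7], coords[3], atol=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            project_pca(np.ones((5, 8)))


class TestClusterDensity:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(0, 0.1, size=(50, 2))
        blob_b = rng.normal(0, 0.1, size=(50, 2)) + [10.0, 0.0]
        coords = np.vstack([blob_a, blob_b])
        truth = np.repeat([0, 1], 50)
        labels, centroids = cluster_density(coords, min_cluster_size=5)
        assert len(centroids) == 2
        # membership agreement up to label permutation
        agreement = max(
            np.mean(labels == truth),
            np.mean(labels == 1 - truth),
        )
        assert agreement >= 0.95

    def test_identical_points_single_cluster(self):
        coords = np.tile([1.0, 2.0], (20, 1))
        labels, centroids = cluster_density(coords, min_cluster_size=5)
        assert set(labels) == {0} and len(centroids) == 1

    def test_centroid_is_member_mean(self):
        rng = np.random.default_rng(4)
        coords = np.vstack(
            [rng.normal(0, 0.2, (30, 2)), rng.normal(8, 0.2, (30, 2))]
        )
        labels, centroids = cluster_density(coords, min_cluster_size=5)
        for lab, cen in centroids.items():
            np.testing.assert_allclose(cen, coords[labels == lab].mean(axis=0))

    def test_too_few_points_all_noise(self):
        with pytest.warns(UserWarning):
            labels, centroids = cluster_density(np.zeros((2, 2)), min_cluster_size=5)
        assert (labels == -1).all() and centroids == {}


class TestNearestToCentroid:
    def test_singleton_cluster(self):
        coords = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = np.array([0, -1])
        centroids = {0: coords[0]}
        assert nearest_to_centroid(coords, labels, centroids, 0) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(5, 2))
        labels = np.zeros(5, dtype=int)
        centroids = {0: coords.mean(axis=0)}
        expected = int(np.argmin(np.linalg.norm(coords - centroids[0], axis=1)))
        assert nearest_to_centroid(coords, labels, centroids, 0) == expected

    def test_noise_label_errors(self):
        with pytest.raises(ValueError):
            nearest_to_centroid(np.zeros((3, 2)), np.zeros(3), {}, -1)


class TestMaturationSelect:
    def toy_variants(self):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(1, 7)],
                "sequence": list("UVWXYZ"),
                "mmpbsa": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "delta_flexddg": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )

    def test_alternating_union_matches_manual_trace(self):
        got = maturation_select(self.toy_variants(), model=None, n_score=4, n_diversity=0)
        assert got["variant_id"].tolist() == ["v1", "v6", "v2", "v5"]
        assert got["provenance"].tolist() == [
            "score:mmpbsa",
            "score:delta_flexddg",
            "score:mmpbsa",
            "score:delta_flexddg",
        ]

    def test_duplicate_sequences_skipped(self):
        df = self.toy_variants()
        df.loc[1, "sequence"] = "U"  # v2 duplicates v1's sequence
        got = maturation_select(df, model=None, n_score=4, n_diversity=0)
        assert got["variant_id"].tolist() == ["v1", "v6", "v3", "v5"]

    def test_whole_pool_when_n_score_covers_it(self):
        got = maturation_select(self.toy_variants(), model=None, n_score=6, n_diversity=0)
        assert len(got) == 6

    def test_fixture_pool_yields_23_candidates(self, maturation_pool):
        unique = dedupe_variants(maturation_pool)
        model = SequenceSpace(min_cluster_size=5).fit(unique["sequence"].tolist())
        final = maturation_select(unique, model, n_score=20, n_diversity=3)
        assert len(final) == 23
        assert final["sequence"].is_unique
        assert (final["provenance"].str.startswith("cluster")).sum() == 3
        # score picks concentrate in the favorable score families
        score_picks = final[final["provenance"].str.startswith("score")]
        assert set(score_picks["family"]) <= {0, 1}

    def test_excluded_clusters_are_skipped(self, maturation_pool):
        unique = dedupe_variants(maturation_pool)
        model = SequenceSpace(min_cluster_size=5).fit(unique["sequence"].tolist())
        all_labels = set(model.centroids_)
        final = maturation_select(
            unique, model, n_score=20, n_diversity=10, excluded_clusters=sorted(all_labels)
        )
        assert not final["provenance"].str.startswith("cluster").any()


class TestValidateMutationPositions:
    def test_identity_is_valid(self):
        ok, bad = validate_mutation_positions("ACDEF", "ACDEF", [])
        assert ok and bad == []

    def test_whitelisted_and_forbidden_positions(self):
        template = NANOBODY_TEMPLATE
        cdr_variant = template[:28] + "L" + template[29:]  # position 29 (CDR1)
        ok, bad = validate_mutation_positions(cdr_variant, template, [29, 59])
        assert ok
        fw_variant = template[:9] + "W" + template[10:]  # position 10 (framework)
        ok, bad = validate_mutation_positions(fw_variant, template, [29, 59])
        assert not ok and bad == [10]

    def test_two_position_difference(self):
        # two designs forked at whitelisted loop positions 29 and 59 only
        template = NANOBODY_TEMPLATE
        nb01 = template[:28] + "L" + template[29:58] + "K" + template[59:]
        ok, bad = validate_mutation_positions(nb01, template, [29, 59])
        assert ok and bad == []
        diffs = [i + 1 for i, (a, b) in enumerate(zip(nb01, template)) if a != b]
        assert diffs == [29, 59]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            validate_mutation_positions("AA", "AAA", [1])
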