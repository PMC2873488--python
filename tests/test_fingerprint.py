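"""Fingerprint profiles, contributions, clustering and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from ldrua.annotations import default_probe_annotation, ecology_map
from ldrua.fingerprint import (
    SchemaError,
    binary_fingerprint,
    cluster_fingerprints,
    distance_matrix,
    group_contribution_summary,
    relative_contributions,
    replicate_reproducibility,
)


def calls_frame(presence, mean_ifs=None, probes=None):
    probes = probes or [f"p{i}" for i in range(len(presence))]
    return pd.DataFrame(
        {
            "probe_id": probes,
            "present": presence,
            "mean_if": mean_ifs if mean_ifs is not None else [100.0] * len(probes),
        }
    )


def ward_oracle(X):
    """Naive Ward agglomeration via the Lance-Williams update on squared
    Euclidean distances; returns the merged leaf-sets in order and heights."""
    X = np.asarray(X, float)
    n = len(X)
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())

    def dist(a, b):
        return d2[(a, b) if a < b else (b, a)]

    merges, heights = [], []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((dist(a, b), a, b) for i, a in enumerate(active) for b in active[i + 1 :]),
        )
        h2, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        heights.append(np.sqrt(h2))
        for k in active:
            if k in (a, b):
                continue
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            val = (
                (na + nk) * dist(a, k) + (nb + nk) * dist(b, k) - nk * dist(a, b)
            ) / (na + nb + nk)
            d2[(k, next_id) if k < next_id else (next_id, k)] = val
        clusters[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        active = [k for k in active if k not in (a, b)] + [next_id]
        next_id += 1
    return merges, heights


def linkage_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges, heights = [], []
    for k, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        merges.append(merged)
        heights.append(h)
    return merges, heights


class TestBinaryFingerprint:
    def test_all_present_gives_ones(self):
        fp = binary_fingerprint(calls_frame([True] * 5))
        assert fp.tolist() == [1] * 5

    def test_all_absent_gives_zeros(self):
        fp = binary_fingerprint(calls_frame([False] * 5))
        assert fp.tolist() == [0] * 5

    def test_default_probe_set_has_30_probes(self):
        ann = default_probe_annotation()
        calls = calls_frame([True] * len(ann), probes=list(ann.index))
        assert len(binary_fingerprint(calls, list(ann.index))) == 30

    def test_missing_probe_is_schema_error(self):
        with pytest.raises(SchemaError):
            binary_fingerprint(calls_frame([True] * 3), ["p0", "p1", "p2", "p99"])


class TestRelativeContributions:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "sub_probe": [False, False, True, False],
                "grouping": ["major", "minor", "major", "opportunistic"],
            },
            index=["a", "b", "a_sub", "c"],
        )

    def test_single_probe_takes_all(self, annotation):
        calls = calls_frame([True], mean_ifs=[500.0], probes=["a"])
        contrib = relative_contributions([calls], annotation)
        assert contrib["a"] == pytest.approx(100.0)

    def test_equal_intensities_split_evenly(self, annotation):
        calls = calls_frame([True, True], mean_ifs=[300.0, 300.0], probes=["a", "b"])
        contrib = relative_contributions([calls], annotation)
        assert contrib["a"] == pytest.approx(50.0)
        assert contrib["b"] == pytest.approx(50.0)

    def test_sub_probes_excluded_from_total(self, annotation):
        calls = calls_frame(
            [True] * 3, mean_ifs=[300.0, 100.0, 999.0], probes=["a", "b", "a_sub"]
        )
        contrib = relative_contributions([calls], annotation)
        assert "a_sub" not in contrib.index
        assert contrib.sum() == pytest.approx(100.0)
        assert contrib["a"] == pytest.approx(75.0)

    def test_replicate_tables_averaged(self, annotation):
        r1 = calls_frame([True, True], mean_ifs=[100.0, 300.0], probes=["a", "b"])
        r2 = calls_frame([True, True], mean_ifs=[300.0, 100.0], probes=["a", "b"])
        contrib = relative_contributions([r1, r2], annotation)
        assert contrib["a"] == pytest.approx(50.0)

    def test_zero_total_is_degenerate(self, annotation):
        calls = calls_frame([False, False], mean_ifs=[0.0, 0.0], probes=["a", "b"])
        with pytest.raises(ValueError):
            relative_contributions([calls], annotation)


class TestClustering:
    def test_identical_profiles_merge_at_zero_height(self):
        profiles = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["x", "y"])
        fc = cluster_fingerprints(profiles)
        assert fc.linkage[0, 2] == pytest.approx(0.0)

    def test_tree_matches_brute_force_ward_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(8, 12)).astype(float)
        profiles = pd.DataFrame(X, index=[f"s{i}" for i in range(8)])
        fc = cluster_fingerprints(profiles)
        got_merges, got_heights = linkage_merge_sets(fc.linkage, 8)
        exp_merges, exp_heights = ward_oracle(X)
        assert set(got_merges) == set(exp_merges)
        assert got_heights == pytest.approx(exp_heights, abs=1e-9)

    def test_replicate_pairs_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2, size=(4, 20)).astype(float)
        rows, names = [], []
        for i in range(4):
            for r in ("a", "b"):
                rows.append(base[i])
                names.append(f"s{i}{r}")
        profiles = pd.DataFrame(rows, index=names)
        fc = cluster_fingerprints(profiles)
        merges, heights = linkage_merge_sets(fc.linkage, 8)
        first_four = set(map(frozenset, [(0, 1), (2, 3), (4, 5), (6, 7)]))
        assert set(merges[:4]) == first_four
        assert heights[:4] == pytest.approx([0.0] * 4)
        # duplicated samples are adjacent in the leaf order
        order = fc.leaf_order
        for i in range(4):
            assert abs(order.index(f"s{i}a") - order.index(f"s{i}b")) == 1

    def test_topology_invariant_under_input_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(7, 15)).astype(float)
        names = [f"s{i}" for i in range(7)]
        profiles = pd.DataFrame(X, index=names)
        ref_merges, _ = linkage_merge_sets(cluster_fingerprints(profiles).linkage, 7)
        ref = {frozenset(names[i] for i in m) for m in ref_merges}
        for _ in range(20):
            perm = rng.permutation(7)
            shuffled = profiles.iloc[perm]
            merges, _ = linkage_merge_sets(cluster_fingerprints(shuffled).linkage, 7)
            got = {frozenset(shuffled.index[i] for i in m) for m in merges}
            assert got == ref

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.integers(0, 2, size=(5, 10)).astype(float))
        d = distance_matrix(profiles).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_ward_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(rng.integers(0, 2, size=(8, 10)).astype(float))
        Z = cluster_fingerprints(profiles).linkage
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_newick_exported_with_all_leaves(self):
        profiles = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1]], index=["x", "y", "z"]
        )
        fc = cluster_fingerprints(profiles)
        assert fc.newick.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in fc.newick


class TestReproducibility:
    def test_identical_profiles_100_percent(self):
        assert replicate_reproducibility([1, 0, 1], [1, 0, 1]) == 100.0

    def test_complementary_profiles_0_percent(self):
        assert replicate_reproducibility([1, 0, 1], [0, 1, 0]) == 0.0

    def test_29_of_30_agree(self):
        a = [1] * 30
        b = [1] * 29 + [0]
        assert replicate_reproducibility(a, b) == pytest.approx(96.7, abs=0.05)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        assert replicate_reproducibility(a, b) == replicate_reproducibility(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            replicate_reproducibility([1, 0], [1, 0, 1])


class TestGroupContributionSummary:
    def test_single_major_probe_dominates(self):
        contrib = pd.Series({"Bacteroides/Prevotella": 100.0})
        s = group_contribution_summary(contrib, default_probe_annotation())
        assert s == {"major": 100.0, "minor": 0.0, "opportunistic": 0.0}

    def test_sums_total_100_and_order_invariant(self):
        ann = default_probe_annotation()
        top = ann[~ann["sub_probe"]]
        rng = np.random.default_rng(6)
        weights = rng.dirichlet(np.ones(len(top))) * 100.0
        contrib = pd.Series(weights, index=top.index)
        s1 = group_contribution_summary(contrib, ann)
        s2 = group_contribution_summary(contrib.sample(frac=1, random_state=0), ann)
        assert sum(s1.values()) == pytest.approx(100.0)
        assert s1 == pytest.approx(s2)

    def test_ecology_map_covers_probe_set(self):
        eco = ecology_map()
        assert len(eco) == 30
        assert {g for _, g in eco.values()} == {"major", "minor", "opportunistic"}

    def test_unmapped_probe_rejected(self):
        with pytest.raises(SchemaError):
            group_contribution_summary(
                pd.Series({"no_such_probe": 100.0}), default_probe_annotation()
            )
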