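"""Pooling, reproducibility filtering, clustering and MeC calling."""

import numpy as np
import pytest

from metacomp import (
    call_mecs,
    cluster_components,
    discover_mecs,
    filter_reproducible,
    leave_one_out,
    mean_max_correlation,
    pool_and_correlate,
    select_feature_genes,
    select_resolution,
)
from metacomp.containers import Component, ComponentPool, DecompositionResult


def fake_result(Z, dataset_id):
    comps = [
        Component(zweights=np.asarray(z, float), dataset_id=dataset_id,
                  component_index=i)
        for i, z in enumerate(Z)
    ]
    n_genes = len(Z[0])
    return DecompositionResult(
        components=comps,
        cell_loadings=np.zeros((1, len(Z))),
        gene_ids=np.asarray([f"g{j}" for j in range(n_genes)], dtype=object),
        cell_ids=np.asarray(["c0"], dtype=object),
        dataset_id=dataset_id,
        k=len(Z),
        seed=0,
    )


def brute_corr(Z):
    Z = np.asarray(Z, float)
    n = len(Z)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            a, b = Z[i] - Z[i].mean(), Z[j] - Z[j].mean()
            out[i, j] = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return out


class TestPoolAndCorrelate:
    def test_identical_and_negated_components(self, rng):
        z = rng.normal(0, 1, 50)
        pool = pool_and_correlate(
            [fake_result([z, -z], "a"), fake_result([z], "b")]
        )
        assert pool.similarity[0, 2] == pytest.approx(1.0)
        assert pool.similarity[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_on_random_components(self, rng):
        Z = rng.normal(0, 1, (4, 30))
        pool = pool_and_correlate([fake_result(Z[:2], "a"), fake_result(Z[2:], "b")])
        np.testing.assert_allclose(pool.similarity, brute_corr(Z), atol=1e-10)
        assert np.allclose(pool.similarity, pool.similarity.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(pool.similarity), 1.0)

    def test_single_dataset_is_error(self, rng):
        with pytest.raises(ValueError, match=">=2 datasets"):
            pool_and_correlate([fake_result(rng.normal(0, 1, (3, 20)), "a")])


class TestFilterReproducible:
    def test_planted_program_survives_in_carrier_datasets(self, rng):
        shared = rng.normal(0, 1, 60)
        rows = []
        for d in range(5):
            noise = rng.normal(0, 1, 60)
            z = shared + rng.normal(0, 0.2, 60) if d < 3 else noise
            rows.append(fake_result([z], f"d{d}"))
        pool = pool_and_correlate(rows)
        kept = filter_reproducible(pool, min_corr=0.3)
        assert sorted(kept.dataset_ids) == ["d0", "d1", "d2"]

    def test_pure_noise_pool_is_error_with_diagnostic(self, rng):
        rows = [fake_result([rng.normal(0, 1, 500)], f"d{i}") for i in range(4)]
        pool = pool_and_correlate(rows)
        with pytest.raises(ValueError, match="max observed"):
            filter_reproducible(pool, min_corr=0.3)

    def test_min_corr_minus_one_keeps_everything(self, rng):
        rows = [fake_result(rng.normal(0, 1, (2, 40)), f"d{i}") for i in range(3)]
        pool = pool_and_correlate(rows)
        kept = filter_reproducible(pool, min_corr=-1.0)
        assert kept.n_components == pool.n_components

    def test_cross_dataset_requirement(self, rng):
        z = rng.normal(0, 1, 40)
        # twin components within one dataset only
        rows = [fake_result([z, z + rng.normal(0, 0.05, 40)], "a"),
                fake_result([rng.normal(0, 1, 40)], "b")]
        pool = pool_and_correlate(rows)
        with pytest.raises(ValueError):
            filter_reproducible(pool, min_corr=0.3, cross_dataset=True)
        kept = filter_reproducible(pool, min_corr=0.3, cross_dataset=False)
        assert kept.n_components == 2


def brute_connected_clusters(similarity, threshold, min_size):
    """Connected components of the thresholded graph (union-find)."""
    n = similarity.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if similarity[i, j] >= threshold:
                parent[find(i)] = find(j)
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    return [sorted(v) for v in roots.values() if len(v) >= min_size]


def make_pool(Z, dataset_ids):
    comps = [
        Component(zweights=z, dataset_id=d, component_index=i)
        for i, (z, d) in enumerate(zip(Z, dataset_ids))
    ]
    sim = np.corrcoef(Z)
    np.fill_diagonal(sim, 1.0)
    return ComponentPool(
        components=comps,
        gene_ids=np.asarray([f"g{j}" for j in range(Z.shape[1])], dtype=object),
        similarity=(sim + sim.T) / 2,
    )


class TestClusterComponents:
    def test_planted_clique_plus_noise_singletons(self, rng):
        base = rng.normal(0, 1, 80)
        Z = np.vstack(
            [base + rng.normal(0, 0.05, 80) for _ in range(6)]
            + [rng.normal(0, 1, 80) for _ in range(4)]
        )
        pool = make_pool(Z, [f"d{i}" for i in range(10)])
        labels = cluster_components(pool, resolution=1.0, seed=0)
        assert sorted(labels.tolist()) == [-1] * 4 + [0] * 6

    def test_matches_bruteforce_connected_components(self, rng):
        # disjoint duplicate groups of size >= 2
        Z = []
        for g in range(4):
            base = rng.normal(0, 1, 100)
            for _ in range(g % 2 + 2):
                Z.append(base + rng.normal(0, 0.05, 100))
        Z = np.vstack(Z)
        pool = make_pool(Z, [f"d{i}" for i in range(len(Z))])
        labels = cluster_components(pool, resolution=1.0, min_cluster_size=1,
                                    seed=0)
        expected = brute_connected_clusters(pool.similarity, 0.3, 1)
        got = {}
        for i, l in enumerate(labels):
            got.setdefault(l, []).append(i)
        assert sorted(map(sorted, got.values())) == sorted(expected)

    def test_deterministic(self, small_run):
        pool = small_run.reproducible_pool
        a = cluster_components(pool, 1.0, seed=3)
        b = cluster_components(pool, 1.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_order_invariance_up_to_relabeling(self, rng):
        base = [rng.normal(0, 1, 60) for _ in range(3)]
        Z = np.vstack([b + rng.normal(0, 0.05, 60) for b in base for _ in range(5)])
        pool = make_pool(Z, [f"d{i}" for i in range(len(Z))])
        perm = rng.permutation(len(Z))
        pool_p = make_pool(Z[perm], [f"d{i}" for i in perm])
        la = cluster_components(pool, 1.0, seed=0)
        lb = cluster_components(pool_p, 1.0, seed=0)
        # same partition after undoing the permutation
        groups_a = {}
        groups_b = {}
        for i, l in enumerate(la):
            groups_a.setdefault(l, set()).add(i)
        for i, l in enumerate(lb):
            groups_b.setdefault(l, set()).add(int(perm[i]))
        assert sorted(map(sorted, groups_a.values())) == sorted(
            map(sorted, groups_b.values())
        )

    def test_tiny_pool_warns_and_returns_empty(self, rng):
        Z = rng.normal(0, 1, (3, 40))
        pool = make_pool(Z, list("abc"))
        with pytest.warns(UserWarning, match="smaller than"):
            labels = cluster_components(pool, 1.0, min_cluster_size=5, seed=0)
        assert (labels == -1).all()


class TestSelectResolution:
    def test_recovers_planted_cluster_count(self, rng):
        Z = np.vstack([
            base + rng.normal(0, 0.03, 120)
            for base in rng.normal(0, 1, (10, 120))
            for _ in range(6)
        ])
        pool = make_pool(Z, [f"d{i}" for i in range(len(Z))])
        scan = select_resolution(pool, grid=[0.25, 0.5, 1.0, 2.0], seed=0)
        chosen = scan.grid.index(scan.chosen_resolution)
        assert scan.n_clusters[chosen] == 10
        # near-duplicate clusters separate almost perfectly
        assert scan.silhouette[chosen] > 0.95

    def test_singleton_grid(self, small_run):
        scan = select_resolution(small_run.reproducible_pool, grid=[0.75], seed=0)
        assert scan.chosen_resolution == 0.75


class TestCallMecs:
    def test_cluster_of_identical_components_equals_member(self, rng):
        z = rng.normal(0, 1, 50)
        Z = np.vstack([z] * 5)
        pool = make_pool(Z, [f"d{i}" for i in range(5)])
        mecs = call_mecs(pool, np.zeros(5, dtype=int))
        assert len(mecs) == 1
        np.testing.assert_allclose(mecs[0].zweights, z, atol=1e-12)
        assert mecs[0].cluster_size == 5

    def test_averaging_denoises(self, rng):
        clean = rng.normal(0, 1, 200)
        noisy = np.vstack([clean + rng.normal(0, 0.5, 200) for _ in range(8)])
        pool = make_pool(noisy, [f"d{i}" for i in range(8)])
        mecs = call_mecs(pool, np.zeros(8, dtype=int))
        r_mec = np.corrcoef(mecs[0].zweights, clean)[0, 1]
        r_members = [np.corrcoef(row, clean)[0, 1] for row in noisy]
        assert r_mec >= max(r_members)

    def test_significant_gene_cutoff_is_exact(self):
        z = np.asarray([1.99, 2.0, 2.5, -3.0, 0.0])
        pool = make_pool(np.vstack([z, z]), ["a", "b"])
        mecs = call_mecs(pool, np.zeros(2, dtype=int))
        assert list(mecs[0].significant_genes) == ["g1", "g2"]

    def test_ordering_by_descending_cluster_size(self, rng):
        b1, b2 = rng.normal(0, 1, (2, 80))
        Z = np.vstack([b1 + rng.normal(0, 0.05, 80) for _ in range(3)]
                      + [b2 + rng.normal(0, 0.05, 80) for _ in range(7)])
        pool = make_pool(Z, [f"d{i}" for i in range(10)])
        labels = cluster_components(pool, 1.0, min_cluster_size=3, seed=0)
        mecs = call_mecs(pool, labels)
        sizes = [m.cluster_size for m in mecs]
        assert sizes == sorted(sizes, reverse=True)
        assert [m.mec_id for m in mecs] == list(range(len(mecs)))


class TestFeatureGenes:
    def test_bruteforce_scan(self, rng):
        Z = rng.normal(0, 1.2, (3, 20))
        pool = make_pool(Z, list("abc"))
        got = set(select_feature_genes(pool))
        expected = {
            f"g{j}" for j in range(20) if (np.abs(Z[:, j]) >= 2).any()
        }
        assert got == expected

    def test_threshold_sides(self):
        Z = np.vstack([[2.5, -2.1, 1.9, 0.0]] * 2)
        pool = make_pool(Z, ["a", "b"])
        assert set(select_feature_genes(pool)) == {"g0", "g1"}


class TestMeanMaxCorrelation:
    def test_identical_sets_give_one(self):
        assert mean_max_correlation(np.eye(4)) == pytest.approx(1.0)

    def test_orthogonal_sets_give_zero(self):
        assert mean_max_correlation(np.zeros((3, 3))) == pytest.approx(0.0)


class TestLeaveOneOut:
    def test_redundant_holdout_barely_moves_mecs(self, small_logs):
        # four copies of one dataset: every holdout is fully redundant
        from metacomp.containers import LogExpressionMatrix

        base = small_logs[0]
        copies = [
            LogExpressionMatrix(values=base.values.copy(), cell_ids=base.cell_ids,
                                gene_ids=base.gene_ids, dataset_id=f"copy{i}")
            for i in range(4)
        ]
        report = leave_one_out(
            copies, k=6, seed=0, resolution=1.0, min_cluster_size=3
        )
        assert report["mean_max_correlation"] > 0.95
        assert len(report["mec_counts"]) == 4

    def test_requires_three_datasets(self, small_logs):
        with pytest.raises(ValueError, match=">=3"):
            leave_one_out(small_logs[:2], k=4, seed=0)


class TestDiscoveryInvariants:
    def test_mec_count_monotone_in_min_cluster_size(self, small_run):
        pool = small_run.reproducible_pool
        counts = []
        for mcs in (2, 4, 6):
            labels = cluster_components(pool, small_run.resolution,
                                        min_cluster_size=mcs, seed=0)
            counts.append(len(call_mecs(pool, labels)))
        assert counts == sorted(counts, reverse=True)

    def test_duplication_stability(self, small_logs):
        from metacomp.containers import LogExpressionMatrix

        base = small_logs[0]
        copies = [
            LogExpressionMatrix(values=base.values.copy(), cell_ids=base.cell_ids,
                                gene_ids=base.gene_ids, dataset_id=f"copy{i}")
            for i in range(5)
        ]
        run = discover_mecs(copies, k=5, seed=0, resolution="auto")
        Z = run.decompositions[0].zweight_matrix()
        for m in run.mecs:
            corr = np.corrcoef(np.vstack([m.zweights[None, :], Z]))[0, 1:]
            assert corr.max() >= 0.999
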