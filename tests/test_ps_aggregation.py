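import numpy as np
import pytest
from scipy import sparse

from msrdb.asv_io import AsvTable
from msrdb.ps_aggregation import (
    PSConfig,
    compute_weights,
    da_statistic,
    group_means,
    identity_weights,
    ps_iterate,
    relative_abundance,
    weighted_group_mean,
)
from msrdb.sequence_space import build_distance_index, profiles_for

from .conftest import random_sequences, random_table


class TestPSConfig:
    def test_rdb_forces_k1(self):
        cfg = PSConfig(mode="rdb", k_max=25)
        assert cfg.k_max == 1
        assert cfg.schedule(100) == []

    def test_knn_single_scale(self):
        assert PSConfig(mode="knn", k_max=20).schedule(100) == [20]

    def test_schedule_strictly_increasing_to_kmax(self):
        for k_max in (1, 2, 5, 10, 37):
            ks = PSConfig(k_max=k_max).schedule(1000)
            assert ks[0] == 1
            assert ks[-1] == k_max
            assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_schedule_capped_by_n(self):
        assert PSConfig(k_max=10).schedule(5)[-1] == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_max": 0},
            {"growth": 1.0},
            {"h": 0.0},
            {"spatial_kernel": "box"},
            {"adaptive_kernel": "cosine"},
            {"mode": "other"},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            PSConfig(**kwargs)


class TestRelativeAbundance:
    def test_example(self):
        t = AsvTable(np.array([[2, 2], [1, 3]]), ["S1", "S2"], ["a", "b"])
        assert np.allclose(relative_abundance(t), [[0.5, 0.5], [0.25, 0.75]])

    def test_single_asv_all_ones(self):
        t = AsvTable(np.array([[5], [9]]), ["S1", "S2"], ["a"])
        assert np.allclose(relative_abundance(t), 1.0)

    def test_scale_invariance(self, rng):
        t = random_table(rng)
        p = relative_abundance(t)
        scaled = t.counts.copy()
        scaled[2] *= 10
        t2 = AsvTable(scaled, t.sample_ids, t.asv_ids, t.group)
        assert np.allclose(relative_abundance(t2)[2], p[2])

    def test_rows_sum_to_one(self, rng):
        p = relative_abundance(random_table(rng))
        assert np.allclose(p.sum(axis=1), 1.0)


class TestGroupMeans:
    def test_one_sample_per_group(self):
        p = np.array([[0.2, 0.8], [0.6, 0.4]])
        g = np.array(["a", "b"])
        m1, m2 = group_means(p, g)
        assert np.allclose(m1, p[0])
        assert np.allclose(m2, p[1])

    def test_identical_samples(self):
        p = np.array([[0.3, 0.7], [0.3, 0.7], [0.5, 0.5]])
        m1, _ = group_means(p, np.array(["a", "a", "b"]))
        assert np.allclose(m1, [0.3, 0.7])

    def test_loop_oracle(self, rng):
        p = rng.random((6, 4))
        g = np.array(["x", "y", "x", "y", "x", "y"])
        m1, m2 = group_means(p, g)
        for j in range(4):
            exp1 = np.mean([p[i, j] for i in range(6) if g[i] == "x"])
            exp2 = np.mean([p[i, j] for i in range(6) if g[i] == "y"])
            assert m1[j] == pytest.approx(exp1)
            assert m2[j] == pytest.approx(exp2)


class TestWeightedGroupMean:
    def test_identity(self, rng):
        v = rng.random(7)
        assert np.allclose(weighted_group_mean(identity_weights(7), v), v)

    def test_half_half(self):
        w = sparse.csr_matrix(np.array([[0.5, 0.5], [0.0, 1.0]]))
        out = weighted_group_mean(w, np.array([0.2, 0.4]))
        assert out[0] == pytest.approx(0.3)

    def test_dense_oracle(self, rng):
        dense = rng.random((20, 20)) * (rng.random((20, 20)) < 0.2)
        np.fill_diagonal(dense, 1.0)
        dense /= dense.sum(axis=1, keepdims=True)
        v = rng.random(20)
        out = weighted_group_mean(sparse.csr_matrix(dense), v)
        assert np.allclose(out, dense @ v)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            weighted_group_mean(identity_weights(3), np.ones(4))

    def test_convexity(self, rng):
        dense = rng.random((10, 10))
        dense /= dense.sum(axis=1, keepdims=True)
        v = rng.random(10)
        out = weighted_group_mean(sparse.csr_matrix(dense), v)
        assert np.all(out >= v.min() - 1e-12)
        assert np.all(out <= v.max() + 1e-12)


class TestDaStatistic:
    def test_equal_means_zero(self):
        assert da_statistic(np.array([0.2]), np.array([0.2]))[0] == 0.0

    def test_boundary_plus_one(self):
        assert da_statistic(np.array([0.3]), np.array([0.0]))[0] == 1.0

    def test_formula_value(self):
        # (0.1 - 0.3) / (0.1 + 0.3) = -0.5
        assert da_statistic(np.array([0.1]), np.array([0.3]))[0] == pytest.approx(-0.5)

    def test_both_zero_convention(self):
        assert da_statistic(np.zeros(3), np.zeros(3)).tolist() == [0.0, 0.0, 0.0]

    def test_bounds(self, rng):
        da = da_statistic(rng.random(50), rng.random(50))
        assert np.all(np.abs(da) <= 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            da_statistic(np.array([-0.1]), np.array([0.1]))


def _index_for(seqs, k=4):
    return build_distance_index(profiles_for(seqs, k))


class TestComputeWeights:
    def test_duplicates_equal_da_uniform(self):
        seqs = {f"a{i}": "ACGTACGTAC" for i in range(4)}
        idx = _index_for(seqs)
        w = compute_weights(idx, np.zeros(4), 3, PSConfig())
        assert np.allclose(w.toarray(), 0.25)

    def test_opposite_da_self_only(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAC"}
        idx = _index_for(seqs)
        w = compute_weights(idx, np.array([1.0, -1.0]), 1, PSConfig(h=0.3)).toarray()
        # cross weight exp(-(2/0.3)^2) ~ 5e-20
        assert w[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert w[0, 1] < 1e-12

    def test_brute_force_kernel_oracle(self, rng):
        seqs = random_sequences(rng, 10)
        idx = _index_for(seqs)
        da = rng.uniform(-1, 1, size=10)
        cfg = PSConfig(h=0.25)
        k_t = 4
        w = compute_weights(idx, da, k_t, cfg).toarray()
        for i in range(10):
            nbrs = idx.neighbor_order[i, :k_t]
            r = idx.distance[i, nbrs[-1]] + 1e-9
            raw = {i: 1.0}
            for j in nbrs:
                ks = max(0.0, 1.0 - idx.distance[i, j] / r)
                ka = np.exp(-((abs(da[i] - da[j]) / cfg.h) ** 2))
                raw[j] = ks * ka
            total = sum(raw.values())
            for j in range(10):
                assert w[i, j] == pytest.approx(raw.get(j, 0.0) / total, abs=1e-12)

    def test_rows_normalized_and_self_positive(self, rng):
        seqs = random_sequences(rng, 15)
        idx = _index_for(seqs)
        w = compute_weights(idx, rng.uniform(-1, 1, 15), 6, PSConfig())
        assert np.allclose(np.asarray(w.sum(axis=1)).ravel(), 1.0, atol=1e-12)
        assert np.all(w.diagonal() > 0)

    def test_support_within_knn(self, rng):
        seqs = random_sequences(rng, 15)
        idx = _index_for(seqs)
        k_t = 5
        w = compute_weights(idx, np.zeros(15), k_t, PSConfig()).toarray()
        for i in range(15):
            allowed = set(idx.neighbor_order[i, :k_t]) | {i}
            assert set(np.flatnonzero(w[i])) <= allowed

    def test_k_clipped_with_warning(self, rng, caplog):
        seqs = random_sequences(rng, 5)
        idx = _index_for(seqs)
        w = compute_weights(idx, np.zeros(5), 10, PSConfig())
        assert w.shape == (5, 5)

    def test_knn_mode_ignores_da(self, rng):
        seqs = random_sequences(rng, 8)
        idx = _index_for(seqs)
        cfg = PSConfig(mode="knn")
        w1 = compute_weights(idx, np.zeros(8), 3, cfg)
        w2 = compute_weights(idx, np.linspace(-1, 1, 8), 3, cfg)
        assert np.allclose(w1.toarray(), w2.toarray())


def _sim_table(rng, seqs, shift=None, n_per_group=6, depth=3000):
    """Multinomial table over the given ASVs; `shift` indexes enriched ASVs."""
    n = len(seqs)
    base = np.ones(n)
    p1 = base / base.sum()
    base2 = base.copy()
    if shift is not None:
        base2[shift] *= 8
    p2 = base2 / base2.sum()
    counts = np.vstack(
        [rng.multinomial(depth, p1) for _ in range(n_per_group)]
        + [rng.multinomial(depth, p2) for _ in range(n_per_group)]
    )
    counts[0, counts.sum(axis=0) == 0] += 1  # keep columns nonzero
    group = np.array(["g1"] * n_per_group + ["g2"] * n_per_group, dtype=object)
    return AsvTable(counts, [f"S{i}" for i in range(2 * n_per_group)],
                    list(seqs), group)


class TestPsIterate:
    def test_rdb_mode_identity(self, rng):
        seqs = random_sequences(rng, 6)
        table = _sim_table(rng, seqs)
        idx = _index_for(seqs)
        w, q, da, trace = ps_iterate(table, idx, PSConfig(mode="rdb"))
        assert (w != identity_weights(6)).nnz == 0
        assert np.array_equal(q, relative_abundance(table))
        assert trace.k == []

    def test_weighted_table_dense_product_oracle(self, rng):
        seqs = random_sequences(rng, 12)
        table = _sim_table(rng, seqs)
        idx = _index_for(seqs)
        w, q, da, _ = ps_iterate(table, idx, PSConfig(k_max=4))
        p = relative_abundance(table)
        assert np.allclose(q, p @ w.toarray().T, atol=1e-12)

    def test_duplicate_blocks_separation(self, rng):
        # two blocks of identical sequences with strongly opposite DA
        seqs = {f"a{i}": "ACGTACGTACGTACGT" for i in range(4)}
        seqs.update({f"b{i}": "TTTTCCCCGGGGAAAA" for i in range(4)})
        n = 8
        counts1 = np.tile(np.array([100] * 4 + [5] * 4), (6, 1))
        counts2 = np.tile(np.array([5] * 4 + [100] * 4), (6, 1))
        table = AsvTable(
            np.vstack([counts1, counts2]),
            [f"S{i}" for i in range(12)],
            list(seqs),
            np.array(["g1"] * 6 + ["g2"] * 6, dtype=object),
        )
        idx = _index_for(seqs)
        w, _, da, _ = ps_iterate(table, idx, PSConfig(k_max=7))
        w = w.toarray()
        for i in range(4):
            cross = w[i, 4:].sum()
            within = w[i, :4].sum()
            assert cross < 1e-6 * within
        # oracle: direct kernel bound for the DA gap
        gap = abs(da[0] - da[4])
        assert np.exp(-((gap / 0.1) ** 2)) < 1e-6

    def test_group_swap_negates_da(self, rng):
        seqs = random_sequences(rng, 10)
        table = _sim_table(rng, seqs, shift=[0, 1])
        idx = _index_for(seqs)
        _, q1, da1, _ = ps_iterate(table, idx, PSConfig())
        swapped = np.where(table.group == "g1", "g2", "g1")
        swapped = np.asarray(swapped, dtype=object)
        table2 = AsvTable(table.counts, table.sample_ids, table.asv_ids, swapped)
        _, q2, da2, _ = ps_iterate(table2, idx, PSConfig())
        assert np.allclose(da1, -da2, atol=1e-12)
        assert np.allclose(q1, q2, atol=1e-12)

    def test_sample_scale_invariance(self, rng):
        seqs = random_sequences(rng, 8)
        table = _sim_table(rng, seqs, shift=[2])
        idx = _index_for(seqs)
        _, q1, da1, _ = ps_iterate(table, idx, PSConfig())
        counts = table.counts.copy()
        counts[3] *= 7
        table2 = AsvTable(counts, table.sample_ids, table.asv_ids, table.group)
        _, q2, da2, _ = ps_iterate(table2, idx, PSConfig())
        assert np.allclose(da1, da2)
        assert np.allclose(q1, q2)

    def test_determinism(self, rng):
        seqs = random_sequences(rng, 10)
        table = _sim_table(rng, seqs, shift=[0])
        idx = _index_for(seqs)
        w1, q1, da1, _ = ps_iterate(table, idx, PSConfig())
        w2, q2, da2, _ = ps_iterate(table, idx, PSConfig())
        assert np.array_equal(w1.toarray(), w2.toarray())
        assert np.array_equal(q1, q2)
        assert np.array_equal(da1, da2)

    def test_convexity_of_weighted_values(self, rng):
        seqs = random_sequences(rng, 9)
        table = _sim_table(rng, seqs)
        idx = _index_for(seqs)
        _, q, _, _ = ps_iterate(table, idx, PSConfig())
        p = relative_abundance(table)
        for i in range(p.shape[0]):
            assert q[i].min() >= p[i].min() - 1e-12
            assert q[i].max() <= p[i].max() + 1e-12

    def test_trace_contents(self, rng):
        seqs = random_sequences(rng, 10)
        table = _sim_table(rng, seqs)
        idx = _index_for(seqs)
        cfg = PSConfig(k_max=5)
        _, _, _, trace = ps_iterate(table, idx, cfg)
        assert trace.k == cfg.schedule(10)
        assert len(trace.mean_row_entropy) == len(trace.k)
        assert all(e >= 0 for e in trace.mean_row_entropy)
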