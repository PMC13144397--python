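"""Modularity Q against exhaustive oracles, Louvain recovery, null behavior."""

import numpy as np
import networkx as nx
import pytest

from entropath import (
    CohortConfig,
    fc_matrix,
    generate_parcel_timeseries,
    louvain_partition,
    modularity_score,
    q_value,
)
from entropath.modularity import ParcelTimeseries, _rewired_null
from oracles import best_partition_exhaustive, modularity_reference


def _two_cliques(k=5):
    n = 2 * k
    w = np.zeros((n, n))
    w[:k, :k] = 1.0
    w[k:, k:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w, np.array([0] * k + [1] * k)


class TestFcMatrix:
    def test_duplicated_regions_correlate_perfectly(self, rng):
        ts = rng.standard_normal((4, 200))
        ts[1] = ts[0]
        w = fc_matrix(ts).w
        assert w[0, 1] == pytest.approx(1.0)

    def test_independent_regions_near_zero(self, rng):
        ts = rng.standard_normal((20, 10000))
        w = fc_matrix(ts).w
        off = np.abs(w[~np.eye(20, dtype=bool)])
        assert off.mean() < 0.05

    def test_block_input_recovers_rho(self):
        cfg = CohortConfig(n_regions=40, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=0, n_samples=3000)
        w = fc_matrix(ts).w
        labels = cfg.module_assignment()
        same = (labels[:, None] == labels[None, :]) & ~np.eye(40, dtype=bool)
        assert abs(w[same].mean() - 0.8) < 0.05

    def test_constant_region_warns_and_zeroes(self, rng):
        ts = rng.standard_normal((5, 100))
        ts[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            w = fc_matrix(ts).w
        assert np.all(w[2, [0, 1, 3, 4]] == 0.0)

    def test_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            fc_matrix(rng.standard_normal((5, 1)))

    def test_parcel_timeseries_type_accepted(self, rng):
        ts = ParcelTimeseries("sub-00", "pre", rng.standard_normal((6, 50)))
        assert fc_matrix(ts).n_regions == 6


class TestQValue:
    def test_two_cliques_closed_form(self):
        w, part = _two_cliques(5)
        assert q_value(w, part) == pytest.approx(0.5)

    def test_k_cliques_closed_form(self):
        for k_cliques, size in [(3, 4), (4, 3)]:
            n = k_cliques * size
            w = np.zeros((n, n))
            labels = np.repeat(np.arange(k_cliques), size)
            for c in range(k_cliques):
                idx = labels == c
                w[np.ix_(idx, idx)] = 1.0
            np.fill_diagonal(w, 0.0)
            assert q_value(w, labels) == pytest.approx(1.0 - 1.0 / k_cliques)

    def test_single_module_is_zero(self, rng):
        a = rng.random((10, 10))
        w = (a + a.T) / 2
        np.fill_diagonal(w, 0.0)
        assert q_value(w, np.zeros(10, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_on_random_signed_graphs(self, rng):
        for _ in range(30):
            a = rng.standard_normal((7, 7))
            w = (a + a.T) / 2
            part = rng.integers(0, 3, size=7)
            assert q_value(w, part) == pytest.approx(modularity_reference(w, part), abs=1e-12)

    def test_matches_networkx_on_nonnegative_graphs(self, rng):
        for _ in range(10):
            a = rng.random((9, 9))
            w = (a + a.T) / 2
            np.fill_diagonal(w, 0.0)
            part = rng.integers(0, 3, size=9)
            comms = [set(np.flatnonzero(part == c)) for c in range(3) if (part == c).any()]
            G = nx.from_numpy_array(w)
            assert q_value(w, part) == pytest.approx(
                nx.community.modularity(G, comms, weight="weight"), abs=1e-12
            )

    def test_scale_invariance(self, rng):
        a = rng.standard_normal((12, 12))
        w = (a + a.T) / 2
        part = rng.integers(0, 4, size=12)
        assert q_value(w, part) == pytest.approx(q_value(17.3 * w, part))

    def test_size_mismatch_errors(self, rng):
        w = np.eye(5)
        with pytest.raises(ValueError, match="partition"):
            q_value(w, np.zeros(4, dtype=int))


class TestLouvain:
    def test_recovers_disconnected_cliques(self):
        w, truth = _two_cliques(5)
        part, q = louvain_partition(w, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(part[:5])) == 1 and len(set(part[5:])) == 1
        assert part[0] != part[5]

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        hits = 0
        n_graphs = 40
        for g in range(n_graphs):
            a = rng.random((7, 7))
            w = (a + a.T) / 2
            np.fill_diagonal(w, 0.0)
            w -= 0.4  # mix in negative weights
            np.fill_diagonal(w, 0.0)
            w = (w + w.T) / 2
            _, q_best = best_partition_exhaustive(w)
            qs = [louvain_partition(w, seed=s)[1] for s in range(5)]
            hits += max(qs) >= q_best - 1e-9
        assert hits >= 0.95 * n_graphs

    def test_planted_blocks_recovered(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        cfg = CohortConfig(n_regions=60, n_modules=4, rho_within=0.8, rho_between=0.1)
        aris = []
        for s in range(5):
            ts = generate_parcel_timeseries(cfg, seed=s, n_samples=300)
            part, _ = louvain_partition(fc_matrix(ts), seed=s)
            aris.append(adjusted_rand_score(cfg.module_assignment(), part))
        assert np.mean(aris) >= 0.9

    def test_nonfinite_weights_rejected(self):
        w = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            louvain_partition(w, seed=0)


class TestModularityScore:
    def test_self_null_ratio_near_one(self, rng):
        cfg = CohortConfig(n_regions=60, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=3, n_samples=200)
        shuffled = _rewired_null(fc_matrix(ts).w, rng)
        res = modularity_score(shuffled, n_louvain=10, n_null=20, seed=0)
        assert abs(res.q_norm - 1.0) < 0.1

    def test_partition_covers_all_regions(self):
        cfg = CohortConfig(n_regions=60, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=4, n_samples=200)
        res = modularity_score(fc_matrix(ts), n_louvain=5, n_null=5, seed=0)
        assert res.partition.shape == (60,)
        assert -1.0 <= res.q_raw <= 1.0
        assert res.q_norm > 0

    def test_region_relabeling_leaves_q_raw_stable(self, rng):
        cfg = CohortConfig(n_regions=60, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=5, n_samples=200)
        w = fc_matrix(ts).w
        perm = rng.permutation(60)
        w_perm = w[np.ix_(perm, perm)]
        q1 = modularity_score(w, n_louvain=10, n_null=2, seed=0).q_raw
        q2 = modularity_score(w_perm, n_louvain=10, n_null=2, seed=1).q_raw
        assert abs(q1 - q2) < 0.005

    def test_rewired_null_preserves_weight_multiset(self, rng):
        a = rng.standard_normal((20, 20))
        w = (a + a.T) / 2
        wn = _rewired_null(w, rng)
        iu = np.triu_indices(20, k=1)
        assert np.allclose(sorted(w[iu]), sorted(wn[iu]))
        assert np.allclose(wn, wn.T)
        assert np.allclose(np.diag(wn), np.diag(w))

    def test_deterministic_given_seed(self, rng):
        cfg = CohortConfig(n_regions=40, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=6, n_samples=150)
        w = fc_matrix(ts)
        r1 = modularity_score(w, n_louvain=5, n_null=5, seed=7)
        r2 = modularity_score(w, n_louvain=5, n_null=5, seed=7)
        assert r1.q_raw == r2.q_raw
        assert r1.q_norm == r2.q_norm


class TestRawQMonotonicity:
    def test_raw_q_decreases_as_between_module_coupling_rises(self):
        """Raising between-module correlation erodes raw modular structure."""
        cfg = CohortConfig(n_regions=60, n_modules=4, rho_within=0.8, rho_between=0.0)
        means = []
        for shift in (0.0, 0.2, 0.4, 0.6):
            qs = []
            for s in range(5):
                ts = generate_parcel_timeseries(cfg, modularity_shift=shift, seed=100 + s, n_samples=200)
                qs.append(modularity_score(fc_matrix(ts), n_louvain=5, n_null=2, seed=s).q_raw)
            means.append(np.mean(qs))
        assert all(a > b for a, b in zip(means, means[1:]))
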