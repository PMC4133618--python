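import numpy as np
import pytest

from comdp import (
    recovery_score,
    sim_data1,
    sim_data2,
    sim_data3,
    iterative_discovery,
)
from comdp.simulate import SimulationTruth

from conftest import make_matrix


class TestSimData1:
    def test_default_dimensions_and_truth(self):
        A, truth = sim_data1(seed=0)
        assert (A.m, A.n) == (500, 1000)
        assert len(truth.embedded_sets) == 10
        assert all(len(s.genes) == 10 for s in truth.embedded_sets)
        sets = truth.gene_sets()
        assert len(frozenset.union(*sets)) == 100  # pairwise disjoint columns

    def test_first_set_coverage_near_binomial_expectation(self):
        A, truth = sim_data1(seed=3)
        cov = A.cells[:, :10].any(axis=1).sum()
        p1 = truth.embedded_sets[0].p
        mean, sd = 500 * p1, np.sqrt(500 * p1 * (1 - p1))
        assert abs(cov - mean) <= 3 * sd

    def test_embedded_gene_rate_matches_analytic_expectation(self):
        # per-gene mutation rate inside M_i is p_i * (1/10 + 9/10 * p0)
        rates = []
        for seed in range(5):
            A, truth = sim_data1(seed=seed)
            rates.append(A.cells[:, :10].mean())
        p1, p0 = 0.95, 0.04
        expect = p1 * (0.1 + 0.9 * p0)
        se = np.sqrt(expect * (1 - expect) / (5 * 500 * 10))
        assert abs(np.mean(rates) - expect) <= 3 * se

    def test_passengers_hit_at_most_three_samples(self):
        A, _ = sim_data1(seed=1)
        cs = A.column_sums[100:]
        assert cs.min() >= 1 and cs.max() <= 3

    def test_deterministic(self):
        A1, _ = sim_data1(seed=9)
        A2, _ = sim_data1(seed=9)
        assert np.array_equal(A1.cells, A2.cells)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sim_data1(n=50, I=10)
        with pytest.raises(ValueError):
            sim_data1(I=10, delta=0.2)


class TestSimData2:
    def test_default_grid_size(self):
        datasets = sim_data2(m=50, n=120, seed=0)
        assert len(datasets) == 11

    def test_mean_rate_monotone_in_noise(self):
        datasets = sim_data2(seed=4)
        rates = [A.cells.mean() for A, _ in datasets]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sim_data2(p0_grid=[])


class TestSimData3:
    def test_nested_prefix_structure(self):
        A, truth = sim_data3(seed=0)
        assert (A.m, A.n) == (600, 1000)
        assert len(truth.embedded_sets) == 9
        stops = [s.rows[1] for s in truth.embedded_sets]
        assert stops == [301, 302, 304, 308, 316, 332, 364, 428, 556]
        assert sum(len(s.genes) for s in truth.embedded_sets) == 45

    def test_first_set_coverage_near_expectation(self):
        A, truth = sim_data3(seed=2)
        cov = A.cells[:, :5].any(axis=1).sum()
        mean = 301 * 0.95
        sd = np.sqrt(301 * 0.95 * 0.05)
        assert abs(cov - mean) <= 3 * sd
        # no activity below the set's sample prefix
        assert A.cells[301:, :5].sum() == 0

    def test_truth_round_trips_through_json(self, tmp_path):
        _, truth = sim_data3(s=60, seed=5)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimulationTruth.from_json(path)
        assert back.gene_sets() == truth.gene_sets()
        assert back.params == truth.params


class TestRecoveryScore:
    def _truth(self):
        _, truth = sim_data1(m=30, n=40, I=3, seed=0)
        return truth

    def test_verbatim_recovery(self):
        truth = self._truth()
        exact, jac = recovery_score(truth.gene_sets(), truth)
        assert exact == 3
        assert jac == [1.0, 1.0, 1.0]

    def test_disjoint_found_scores_zero(self):
        truth = self._truth()
        exact, jac = recovery_score([frozenset({"g0999"})], truth)
        assert exact == 0
        assert all(j == 0.0 for j in jac)

    def test_split_pair_union_counts_as_exact(self):
        truth = self._truth()
        genes = sorted(truth.gene_sets()[0])
        exact, _ = recovery_score([(genes[:4], genes[4:])], truth)
        assert exact >= 1


class TestIterativeDiscovery:
    def test_single_round(self):
        A = make_matrix({
            "a": ["s1", "s2"], "b": ["s3", "s4"],
            "c": ["s1", "s3"], "d": ["s2", "s4"],
        })
        results = iterative_discovery(A, k=2, lam=10, eta=-2, rounds=1)
        assert len(results) == 1
        assert results[0].solver_status == "optimal"

    def test_early_stop_when_genes_exhausted(self):
        A = make_matrix({
            "a": ["s1", "s2"], "b": ["s3", "s4"],
            "c": ["s1", "s3"], "d": ["s2", "s4"],
        })
        results = iterative_discovery(A, k=3, lam=10, eta=-2, rounds=5)
        assert len(results) == 1  # 4 genes: one k=3 round leaves only 1 gene

    def test_rounds_validation(self, f1):
        with pytest.raises(ValueError):
            iterative_discovery(f1, k=2, lam=1, eta=1, rounds=0)

    def test_planted_structure_dominates_recovered_sets(self):
        # 3 planted 10-gene sets: each exclusivity-regime round must return
        # a proven-optimal set at least as heavy as every planted set, and
        # the planted blocks must dominate what is recovered (noise genes
        # can displace the weakest drivers, so exact equality is not
        # guaranteed by optimality)
        from comdp import weight_W

        A, truth = sim_data1(m=120, n=40, I=3, seed=6)
        results = iterative_discovery(A, k=10, lam=-10, eta=1, rounds=3)
        assert all(r.solver_status == "optimal" for r in results)
        best_planted = max(weight_W(A, t) for t in truth.gene_sets())
        assert results[0].stats.w1 >= best_planted
        _, jac = recovery_score(results, truth)
        assert np.mean(jac) >= 0.5
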