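"""Weir-Cockerham F_ST components, aggregates, PCA and cluster separation."""

import numpy as np
import pytest

from svcurate import popgen, simdata
from svcurate.popgen import (GenotypeMatrix, fst_aggregate, fst_components,
                             pairwise_fst, pca, separation_score, wc_components)


def wc84_oracle(dosages, pops):
    """Scalar translation of the published 1984 variance-component formulas,
    written independently of the vectorized implementation."""
    by_pop = {}
    for d, p in zip(dosages, pops):
        if d is None or (isinstance(d, float) and np.isnan(d)) or d < 0:
            continue
        by_pop.setdefault(p, []).append(d)
    r = len(by_pop)
    n_i, p_i, h_i = [], [], []
    for pop in by_pop:
        geno = by_pop[pop]
        n_i.append(len(geno))
        p_i.append(sum(geno) / (2.0 * len(geno)))
        h_i.append(sum(1 for g in geno if g == 1) / len(geno))
    n_total = sum(n_i)
    nbar = n_total / r
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_total
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_total
    nc = (n_total - sum(n * n for n in n_i) / n_total) / (r - 1)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - 1.0 / (nbar - 1) *
                       (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def random_site(rng):
    r = rng.integers(2, 5)
    sizes = rng.integers(2, 10, size=r)
    pops = np.repeat([f"p{j}" for j in range(r)], sizes)
    dosages = rng.integers(0, 3, size=sizes.sum()).astype(float)
    return dosages, pops


def test_wc_components_match_independent_oracle():
    rng = np.random.default_rng(123)
    checked = 0
    for _ in range(1000):
        dosages, pops = random_site(rng)
        comp = wc_components(dosages, pops)
        if not comp.defined:
            continue
        a, b, c = wc84_oracle(dosages, pops)
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)
        checked += 1
    assert checked > 900


def test_fixed_difference_site_is_one():
    """Two populations fixed for opposite alleles, no hets: F_ST = 1 exactly."""
    dosages = [2, 2, 2, 0, 0, 0]
    pops = ["A"] * 3 + ["B"] * 3
    comp = wc_components(dosages, pops)
    assert comp.fst == pytest.approx(1.0)
    assert comp.b == pytest.approx(0.0) and comp.c == 0.0


def test_identical_populations_give_nonpositive_estimate():
    """Identical genotype vectors in both populations: the unbiased estimator
    goes to zero or below; negative values are kept, not clamped."""
    dosages = [0, 1, 2, 1, 0, 1, 2, 1]
    pops = ["A"] * 4 + ["B"] * 4
    comp = wc_components(dosages, pops)
    assert comp.defined and comp.fst <= 0


def test_single_population_errors():
    with pytest.raises(ValueError):
        wc_components([0, 1, 2], ["A", "A", "A"])


def test_monomorphic_site_undefined():
    comp = wc_components([0, 0, 0, 0], ["A", "A", "B", "B"])
    assert not comp.defined


def test_missing_genotypes_excluded():
    with_missing = wc_components([2, 2, np.nan, 0, 0, -1], ["A", "A", "A", "B", "B", "B"])
    without = wc_components([2, 2, 0, 0], ["A", "A", "B", "B"])
    assert with_missing.a == pytest.approx(without.a)


class TestAggregates:
    def test_single_site_mean_equals_weighted(self):
        comp = wc_components([2, 1, 0, 0], ["A", "A", "B", "B"])
        mean, weighted = fst_aggregate([comp])
        assert mean == pytest.approx(weighted) == pytest.approx(comp.fst)

    def test_all_fixed_differences_give_one(self):
        comps = [wc_components([2, 2, 0, 0], ["A", "A", "B", "B"])] * 5
        assert fst_aggregate(comps) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_weighted_invariant_to_site_order(self):
        rng = np.random.default_rng(3)
        comps = [wc_components(*random_site(rng)) for _ in range(50)]
        _, w1 = fst_aggregate(comps)
        _, w2 = fst_aggregate(list(reversed(comps)))
        assert w1 == pytest.approx(w2)

    def test_no_defined_sites_is_nan(self):
        comp = wc_components([0, 0, 0, 0], ["A", "A", "B", "B"])
        mean, weighted = fst_aggregate([comp])
        assert np.isnan(mean) and np.isnan(weighted)


def _structured_matrix(F, n_sites, sizes, seed):
    cfg = simdata.SimulationConfig(
        n_populations=len(sizes), samples_per_population=sizes, fst_param=F, seed=seed)
    rng = np.random.default_rng(seed)
    dosages = np.stack([simdata._true_site_genotypes(cfg, rng)
                        for _ in range(n_sites)], axis=1)
    pops = np.repeat([f"p{j}" for j in range(len(sizes))], sizes)
    samples = [f"i{k}" for k in range(sum(sizes))]
    return GenotypeMatrix(dosages.astype(float), samples, list(pops))


def test_balding_nichols_parameter_recovery():
    """Weighted F_ST over 200 sites recovers the simulation's F = 0.2."""
    G = _structured_matrix(0.2, 200, (50, 50), seed=42)
    _, weighted = fst_aggregate(fst_components(G))
    assert weighted == pytest.approx(0.2, abs=0.05)


def test_pairwise_fst_two_individual_design():
    """The 2-individuals-per-cluster design stays finite and ordered."""
    G = _structured_matrix(0.3, 150, (2, 2), seed=9)
    mean, weighted = pairwise_fst(G, "p0", "p1")
    assert np.isfinite(mean) and np.isfinite(weighted)
    assert -0.2 < weighted < 1.0


class TestPca:
    def test_identical_individuals_identical_coordinates(self):
        dosages = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=float)
        G = GenotypeMatrix(dosages, ["a", "b", "c"], ["X", "X", "Y"])
        coords, _ = pca(G)
        assert np.allclose(coords[0], coords[1])

    def test_fixed_difference_blocks_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        block = np.zeros((20, 50))
        block[10:] = 2.0
        noise = rng.normal(0, 1e-6, block.shape)
        G = GenotypeMatrix(block + noise, [f"i{k}" for k in range(20)],
                           ["A"] * 10 + ["B"] * 10)
        coords, var_frac = pca(G)
        a, b = coords[:10, 0], coords[10:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            min(a.max(), b.max()) < max(a.min(), b.min())
        assert a.max() < b.min() or b.max() < a.min()
        assert var_frac[0] > 0.99

    def test_variance_fractions_non_increasing(self):
        G = _structured_matrix(0.1, 60, (10, 10), seed=4)
        _, var_frac = pca(G, n_components=5)
        assert np.all(np.diff(var_frac) <= 1e-12)
        assert var_frac.sum() <= 1.0 + 1e-9

    def test_constant_matrix_warns_and_zeroes(self):
        G = GenotypeMatrix(np.ones((4, 5)), list("abcd"), ["A", "A", "B", "B"])
        coords, var_frac = pca(G)
        assert np.allclose(coords, 0) and np.allclose(var_frac, 0)

    def test_missing_entries_mean_imputed(self):
        dosages = np.array([[0, 2.0], [0, np.nan], [2, 0], [2, 0]])
        G = GenotypeMatrix(dosages, list("abcd"), ["A", "A", "B", "B"])
        coords, _ = pca(G)
        assert np.all(np.isfinite(coords))


class TestSeparationScore:
    def test_structured_clusters_score_high(self):
        G = _structured_matrix(0.3, 150, (15, 15, 15), seed=11)
        coords, _ = pca(G)
        assert separation_score(coords, G.populations) > 0.5

    def test_shuffled_labels_score_near_zero(self):
        G = _structured_matrix(0.3, 150, (15, 15, 15), seed=11)
        coords, _ = pca(G)
        rng = np.random.default_rng(0)
        labels = np.array(G.populations)
        rng.shuffle(labels)
        assert abs(separation_score(coords, labels)) < 0.15

    def test_identical_clusters_score_nonpositive(self):
        coords = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (4, 1))
        labels = ["A", "A", "B", "B"] * 2
        assert separation_score(coords, labels) <= 0

    def test_single_label_undefined(self):
        with pytest.raises(ValueError):
            separation_score(np.zeros((3, 2)), ["A", "A", "A"])


def test_matrix_construction_from_calls(sim_dataset):
    calls, table, _ = sim_dataset
    G = GenotypeMatrix.from_calls(calls[:40], table)
    assert G.dosages.shape == (33, 40)
    assert set(G.populations) == set(table["population"])
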