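import math

import numpy as np
import pytest

from decluster import (
    DEConfig,
    Individual,
    Population,
    binomial_crossover,
    diversity_lambda,
    init_population,
    mutate_best_1,
    mutate_current_to_best_1,
    mutate_rand_1,
    select,
)
from decluster.engine import batch_crossover, batch_distinct_indices, batch_mutants


def make_pop(genes, fitness=None):
    genes = np.asarray(genes, dtype=float)
    lo = genes.min(0) - 10.0
    hi = genes.max(0) + 10.0
    pop = Population(genes, np.stack([lo, hi], axis=1))
    if fitness is not None:
        pop.fitness[:] = fitness
    return pop


# ------------------------------------------------------------- init


def test_init_degenerate_bounds_collapse():
    cfg = DEConfig(NP=6, seed=0)
    bounds = np.array([[2.0, 2.0], [-1.0, -1.0]])
    pop = init_population(bounds, cfg, np.random.default_rng(0))
    assert np.all(pop.genes == np.array([2.0, -1.0]))
    assert pop.generation == 0


def test_init_deterministic():
    cfg = DEConfig(NP=8, seed=0)
    bounds = np.array([[0.0, 1.0], [5.0, 9.0]])
    a = init_population(bounds, cfg, np.random.default_rng(42))
    b = init_population(bounds, cfg, np.random.default_rng(42))
    assert np.array_equal(a.genes, b.genes)


def test_init_uniform_mean():
    # 10^4 samples of each gene: empirical mean within 3 SE of the midpoint
    cfg = DEConfig(NP=10_000, seed=0)
    bounds = np.array([[-2.0, 6.0], [10.0, 11.0]])
    pop = init_population(bounds, cfg, np.random.default_rng(3))
    for j, (lo, hi) in enumerate(bounds):
        se = (hi - lo) / math.sqrt(12.0) / math.sqrt(cfg.NP)
        assert abs(pop.genes[:, j].mean() - (lo + hi) / 2) < 3 * se
        assert pop.genes[:, j].min() >= lo and pop.genes[:, j].max() <= hi


def test_init_inverted_bounds_error():
    with pytest.raises(ValueError):
        init_population(np.array([[1.0, 0.0]]), DEConfig(NP=4), np.random.default_rng(0))


# ------------------------------------------------------------- mutation
#
# Tagged-basis oracle: with genes = identity matrix, the mutant's
# coefficients reveal exactly which indices r1, r2, r3 were drawn, so the
# formula can be verified without mirroring the internal RNG protocol.


def decompose_rand1(v, F):
    """Recover (r1, r2, r3) from v = e_r1 + F (e_r2 - e_r3) over basis vectors."""
    r1 = int(np.argmin(np.abs(v - 1.0)))
    r2 = int(np.argmin(np.abs(v - F)))
    r3 = int(np.argmin(np.abs(v + F)))
    return r1, r2, r3


def test_mutate_rand1_formula_and_index_constraints():
    F = 0.37
    NP = 6
    pop = make_pop(np.eye(NP))
    for i in range(NP):
        for trial in range(10):
            v = mutate_rand_1(pop, i, F, np.random.default_rng(trial * 100 + i))
            r1, r2, r3 = decompose_rand1(v, F)
            assert len({r1, r2, r3}) == 3 and i not in {r1, r2, r3}
            expected = pop.genes[r1] + F * (pop.genes[r2] - pop.genes[r3])
            np.testing.assert_allclose(v, expected, atol=1e-12)


def test_mutate_rand1_collapsed_population():
    pop = make_pop(np.ones((5, 3)) * 2.5)
    v = mutate_rand_1(pop, 0, 0.6, np.random.default_rng(0))
    np.testing.assert_array_equal(v, pop.genes[0])


def test_mutate_rand1_f_zero_returns_population_row():
    pop = make_pop(np.random.default_rng(1).normal(size=(5, 3)))
    v = mutate_rand_1(pop, 2, 0.0, np.random.default_rng(9))
    assert any(np.array_equal(v, row) for i, row in enumerate(pop.genes) if i != 2)


def test_mutate_best1_formula():
    F = 0.42
    NP = 6
    fitness = np.arange(NP, dtype=float)  # best is index 0
    pop = make_pop(np.eye(NP), fitness)
    for i in range(1, NP):
        v = mutate_best_1(pop, i, F, np.random.default_rng(i))
        # v = e_0 + F (e_r1 - e_r2): the residual v - e_0 has +F at r1, -F at r2
        resid = v - pop.genes[0]
        r1 = int(np.argmax(resid))
        r2 = int(np.argmin(resid))
        assert resid[r1] == pytest.approx(F) and resid[r2] == pytest.approx(-F)
        assert r1 != r2 and i not in {r1, r2}
        expected = pop.genes[0] + F * (pop.genes[r1] - pop.genes[r2])
        np.testing.assert_allclose(v, expected, atol=1e-12)


def test_mutate_best1_collapsed_and_f_zero():
    pop = make_pop(np.ones((5, 2)) * 3.0, fitness=np.arange(5.0))
    v = mutate_best_1(pop, 1, 0.6, np.random.default_rng(0))
    np.testing.assert_array_equal(v, pop.genes[0])
    pop2 = make_pop(np.random.default_rng(2).normal(size=(5, 2)), fitness=np.arange(5.0))
    v2 = mutate_best_1(pop2, 1, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(v2, pop2.genes[0])


def test_mutate_current_to_best_trivials():
    pop = make_pop(np.ones((5, 2)), fitness=np.arange(5.0))
    v = mutate_current_to_best_1(pop, 0, 0.6, np.random.default_rng(0))
    np.testing.assert_array_equal(v, pop.genes[0])
    pop2 = make_pop(np.random.default_rng(3).normal(size=(5, 2)), fitness=np.arange(5.0))
    v2 = mutate_current_to_best_1(pop2, 3, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(v2, pop2.genes[3])


def test_mutate_current_to_best_formula():
    F = 0.5
    NP = 6
    pop = make_pop(np.eye(NP), fitness=np.arange(NP, dtype=float))
    i = 3
    v = mutate_current_to_best_1(pop, i, F, np.random.default_rng(11))
    # v = e_i + F (e_0 - e_i) + F (e_r1 - e_r2); recover r1, r2 from residual
    resid = v - (pop.genes[i] + F * (pop.genes[0] - pop.genes[i]))
    r1 = int(np.argmax(resid))
    r2 = int(np.argmin(resid))
    assert resid[r1] == pytest.approx(F) and resid[r2] == pytest.approx(-F)
    assert r1 != r2 and i not in {r1, r2}


def test_mutation_needs_four_individuals():
    pop = make_pop(np.ones((2, 2)))
    with pytest.raises(ValueError):
        mutate_rand_1(pop, 0, 0.5, np.random.default_rng(0))


# ------------------------------------------------------------- crossover


def test_crossover_cr_one_gives_mutant(rng):
    p, m = rng.normal(size=(2, 8))
    np.testing.assert_array_equal(binomial_crossover(p, m, 1.0, rng), m)


def test_crossover_cr_zero_exactly_one_mutant_gene(rng):
    p = np.zeros(10)
    m = np.ones(10)
    for _ in range(50):
        trial = binomial_crossover(p, m, 0.0, rng)
        assert trial.sum() == 1.0  # exactly one gene from the mutant


def test_crossover_no_invented_values(rng):
    p, m = rng.normal(size=(2, 12))
    trial = binomial_crossover(p, m, 0.5, rng)
    assert all(t == a or t == b for t, a, b in zip(trial, p, m))


def test_crossover_inheritance_rate(rng):
    # per-gene mutant frequency ~ CR + (1-CR)/D within 3 standard errors
    D, CR, n = 10, 0.5, 10_000
    p = np.zeros(D)
    m = np.ones(D)
    hits = np.zeros(D)
    for _ in range(n):
        hits += binomial_crossover(p, m, CR, rng)
    expected = CR + (1 - CR) / D
    se = math.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(hits / n - expected) < 3 * se + 1e-9)


def test_crossover_length_mismatch():
    with pytest.raises(ValueError):
        binomial_crossover(np.zeros(3), np.zeros(4), 0.5, np.random.default_rng(0))


# ------------------------------------------------------------- selection


def test_select_trivials():
    p = Individual(np.zeros(2), fitness=2.0)
    t = Individual(np.ones(2), fitness=1.0)
    assert select(p, t) is t
    t_eq = Individual(np.ones(2), fitness=2.0)
    assert select(p, t_eq) is p  # ties keep the parent


def test_select_matches_comparison_oracle(rng):
    for _ in range(100):
        fp, ft = rng.normal(size=2)
        p = Individual(np.zeros(1), fitness=float(fp))
        t = Individual(np.ones(1), fitness=float(ft))
        chosen = select(p, t)
        assert chosen is (t if ft < fp else p)
        assert chosen.fitness <= p.fitness  # never increases fitness


def test_select_requires_fitness():
    with pytest.raises(RuntimeError):
        select(Individual(np.zeros(1)), Individual(np.ones(1), fitness=1.0))


# ------------------------------------------------------------- diversity


def test_diversity_collapsed_nonzero():
    pop = make_pop(np.full((4, 3), 5.0))
    d = diversity_lambda(pop)
    assert d.sigma == 0.0 and d.lam == 0.0


def test_diversity_two_individuals_forced():
    pop = make_pop(np.array([[0.0, 2.0], [0.0, 4.0]]))
    d = diversity_lambda(pop)
    np.testing.assert_array_equal(d.mu, [0.0, 3.0])
    assert d.sigma == pytest.approx(1.0)
    assert d.lam == pytest.approx(1.0 / 3.0)


def test_diversity_matches_loop_oracle(rng):
    genes = rng.normal(size=(9, 4)) + 2.0
    pop = make_pop(genes)
    d = diversity_lambda(pop)
    mu = [sum(genes[i][j] for i in range(9)) / 9 for j in range(4)]
    dists = [sum((genes[i][j] - mu[j]) ** 2 for j in range(4)) ** 0.5 for i in range(9)]
    sigma = sum(dists) / 9
    lam = sigma / sum(m * m for m in mu) ** 0.5
    np.testing.assert_allclose(d.mu, mu, atol=1e-12)
    assert d.sigma == pytest.approx(sigma, abs=1e-12)
    assert d.lam == pytest.approx(lam, abs=1e-12)


def test_diversity_rms_variant(rng):
    genes = rng.normal(size=(6, 3)) + 1.0
    pop = make_pop(genes)
    mu = genes.mean(0)
    dists = np.linalg.norm(genes - mu, axis=1)
    d = diversity_lambda(pop, sigma_mode="rms")
    assert d.sigma == pytest.approx(math.sqrt((dists**2).mean()), abs=1e-12)
    assert d.sigma >= diversity_lambda(pop).sigma  # RMS >= mean


def test_diversity_permutation_invariant(rng):
    genes = rng.normal(size=(8, 3))
    lam = diversity_lambda(make_pop(genes)).lam
    perm = rng.permutation(8)
    assert diversity_lambda(make_pop(genes[perm])).lam == pytest.approx(lam, abs=1e-12)


def test_diversity_scale_invariant(rng):
    genes = rng.normal(size=(8, 3)) + 4.0
    lam = diversity_lambda(make_pop(genes)).lam
    for c in (0.1, 3.0, 1e4):
        assert diversity_lambda(make_pop(c * genes)).lam == pytest.approx(lam, rel=1e-9)


def test_diversity_zero_centroid_sentinel():
    pop = make_pop(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]))
    d = diversity_lambda(pop)
    assert math.isinf(d.lam) and d.sigma > 0


def test_diversity_collapsed_at_origin_is_zero():
    d = diversity_lambda(make_pop(np.zeros((4, 2))))
    assert d.lam == 0.0


# ------------------------------------------------------------- batch helpers


def test_batch_distinct_indices_constraints(rng):
    for NP in (5, 17, 64):
        idx = batch_distinct_indices(rng, NP, 3)
        assert idx.shape == (3, NP)
        target = np.arange(NP)
        for c in range(3):
            assert np.all(idx[c] != target)
        assert np.all(idx[0] != idx[1]) and np.all(idx[0] != idx[2]) and np.all(idx[1] != idx[2])


def test_batch_mutants_match_formula_tagged_basis(rng):
    NP = 8
    genes = np.eye(NP)
    F = 0.31
    v = batch_mutants(genes, "rand_1", F, rng)
    for i in range(NP):
        r1 = int(np.argmin(np.abs(v[i] - 1.0)))
        r2 = int(np.argmin(np.abs(v[i] - F)))
        r3 = int(np.argmin(np.abs(v[i] + F)))
        assert len({r1, r2, r3}) == 3 and i not in {r1, r2, r3}
        np.testing.assert_allclose(v[i], genes[r1] + F * (genes[r2] - genes[r3]), atol=1e-12)
    vb = batch_mutants(genes, "best_1", F, rng, best_index=4)
    for i in range(NP):
        resid = vb[i] - genes[4]  # +F at r1, -F at r2
        r1, r2 = int(np.argmax(resid)), int(np.argmin(resid))
        assert resid[r1] == pytest.approx(F) and resid[r2] == pytest.approx(-F)
        assert r1 != r2 and i not in {r1, r2}


def test_batch_crossover_mixes_only_parent_and_mutant(rng):
    genes = np.zeros((6, 10))
    mutants = np.ones((6, 10))
    trials = batch_crossover(genes, mutants, 0.0, rng)
    assert np.all(trials.sum(axis=1) == 1.0)  # exactly one mutant gene per row
    trials2 = batch_crossover(genes, mutants, 1.0, rng)
    assert np.all(trials2 == 1.0)


# ------------------------------------------------------------- config


def test_deconfig_validation():
    with pytest.raises(ValueError):
        DEConfig(NP=3)
    with pytest.raises(ValueError):
        DEConfig(NP=10, F=0.0)
    with pytest.raises(ValueError):
        DEConfig(NP=10, CR=1.5)
    with pytest.raises(ValueError):
        DEConfig(NP=10, strategy="nope")
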