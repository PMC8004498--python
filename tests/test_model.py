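"""Model data: migration matrices, marginalisation, recombinators, and the
migration-recombination probabilities."""

import logging
from fractions import Fraction

import numpy as np
import pytest

from migrec import (
    DomainError,
    LabelledPartition,
    MetaPopulation,
    MigrationModel,
    Model,
    Partition,
    PopulationMeasure,
    RecombinationDistribution,
    TypeSpace,
    ValidationError,
    backward_from_forward,
    marginal_mr_probabilities,
    mr_probabilities,
    recombinator,
    restrict,
    tensor,
    top,
)
from migrec.partitions import bottom


class TestBackwardFromForward:
    def test_equal_sizes_is_transpose(self):
        # doubly stochastic forward keeps equal sizes constant
        F = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        m = backward_from_forward(F, [1.0, 1.0, 1.0], ["a", "b", "c"])
        assert np.allclose(m.backward, F.T)

    def test_identity_forward(self):
        m = backward_from_forward(np.eye(3), [2.0, 5.0, 1.0], ["a", "b", "c"])
        assert np.allclose(m.backward, np.eye(3))

    def test_worked_example(self):
        m = backward_from_forward(
            [[0.9, 0.1], [0.2, 0.8]], [2.0, 1.0], ["a", "b"]
        )
        assert m("a", "b") == pytest.approx(0.1)
        assert m("b", "a") == pytest.approx(0.2)
        assert np.allclose(m.backward.sum(axis=1), 1.0)

    def test_unbalanced_sizes_warn_and_renormalise(self, caplog):
        with caplog.at_level(logging.WARNING, logger="migrec"):
            m = backward_from_forward(
                [[0.9, 0.1], [0.2, 0.8]], [1.0, 1.0], ["a", "b"]
            )
        assert any("regulation" in r.message for r in caplog.records)
        assert np.allclose(m.backward.sum(axis=1), 1.0)

    def test_bad_sizes(self):
        with pytest.raises(DomainError):
            backward_from_forward(np.eye(2), [1.0, 0.0], ["a", "b"])
        with pytest.raises(ValidationError):
            backward_from_forward([[0.5, 0.4], [0.5, 0.5]], [1, 1], ["a", "b"])


class TestMarginalisation:
    def test_two_binary_sites(self):
        space = TypeSpace([["0", "1"], ["0", "1"]])
        nu = PopulationMeasure(space, (1, 2), [0.1, 0.2, 0.3, 0.4])
        assert np.allclose(nu.marginal([1]).flat(), [0.3, 0.7])
        assert np.allclose(nu.marginal([2]).flat(), [0.4, 0.6])
        assert nu.marginal([1, 2]) is nu
        assert nu.marginal([]).table == pytest.approx(1.0)

    def test_not_a_subset(self):
        space = TypeSpace([["0", "1"], ["0", "1"]])
        nu = PopulationMeasure(space, (1,), [0.5, 0.5])
        with pytest.raises(DomainError):
            nu.marginal([2])

    def test_linear(self):
        rng = np.random.default_rng(0)
        space = TypeSpace([["0", "1"]] * 3)
        t1 = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
        t2 = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
        a, b = 0.3, 0.7
        mix = PopulationMeasure(space, (1, 2, 3), a * t1 + b * t2)
        m1 = PopulationMeasure(space, (1, 2, 3), t1).marginal([2])
        m2 = PopulationMeasure(space, (1, 2, 3), t2).marginal([2])
        assert np.allclose(mix.marginal([2]).table, a * m1.table + b * m2.table)

    def test_product_measure_factorises_under_marginal(self):
        """Marginalising a product of measures on disjoint site sets
        factorises blockwise (checked numerically on random tables)."""
        rng = np.random.default_rng(1)
        space = TypeSpace([["0", "1"]] * 4)
        nu_u = PopulationMeasure(space, (1, 3), rng.dirichlet(np.ones(4)).reshape(2, 2))
        nu_v = PopulationMeasure(space, (2, 4), rng.dirichlet(np.ones(4)).reshape(2, 2))
        prod = tensor([nu_u, nu_v])
        for w in [(1,), (2, 3), (1, 2, 4), (3, 4)]:
            lhs = prod.marginal(w)
            u_part = nu_u.marginal(set(w) & {1, 3})
            v_part = nu_v.marginal(set(w) & {2, 4})
            factors = [m for m in (u_part, v_part) if m.sites]
            rhs = tensor(factors) if len(factors) > 1 else factors[0]
            assert np.allclose(lhs.table, rhs.table, atol=1e-14)


class TestRecombinator:
    def test_single_block_returns_the_labelled_deme(self, small_cfg):
        mu = small_cfg.initial
        g = small_cfg.model.ground
        for d in mu.demes:
            out = recombinator(LabelledPartition([(g, d)]), mu)
            assert np.array_equal(out.table, mu(d).table)

    def test_all_singletons_is_product_of_marginals(self, small_cfg):
        mu = small_cfg.initial
        b = LabelledPartition([((1,), "d0"), ((2,), "d1"), ((3,), "d0")])
        out = recombinator(b, mu)
        expected = tensor(
            [mu("d0").marginal([1]), mu("d1").marginal([2]), mu("d0").marginal([3])]
        )
        assert np.allclose(out.table, expected.table)

    def test_splits_along_a_coarser_partition(self, small_cfg):
        """The recombinator of a labelled refinement factorises over the
        blocks of the coarser partition."""
        mu = small_cfg.initial
        delta = Partition([[1, 2], [3]])
        eps = LabelledPartition([((1,), "d1"), ((2,), "d0"), ((3,), "d1")])
        whole = recombinator(eps, mu)
        pieces = [
            recombinator(restrict(eps, d), mu.marginal(d)) for d in delta.blocks
        ]
        assert np.allclose(whole.table, tensor(pieces).table, atol=1e-14)

    def test_unknown_label(self, small_cfg):
        b = LabelledPartition([((1, 2, 3), "nope")])
        with pytest.raises(DomainError):
            recombinator(b, small_cfg.initial)


class TestMRProbabilities:
    def test_single_deme_reduces_to_r(self, nonmono_cfg):
        p = mr_probabilities(nonmono_cfg.model, "pop")
        r = nonmono_cfg.model.recombination
        for bdelta, val in p.probs.items():
            assert val == r[bdelta.base]
        assert p.total() == 1

    def test_worked_product(self):
        space = TypeSpace([["0", "1"], ["0", "1"]])
        g = space.sites
        r = RecombinationDistribution(
            g, {bottom(g): Fraction(1, 2), top(g): Fraction(1, 2)}
        )
        M = MigrationModel(["1", "2"], [[0.75, 0.25], [0.25, 0.75]])
        model = Model(space, r, M)
        p = mr_probabilities(model, "1")
        target = LabelledPartition([((1,), "1"), ((2,), "2")])
        assert p[target] == pytest.approx(3 / 32)
        assert p.total() == pytest.approx(1.0, abs=1e-12)

    def test_normalised_on_random_models(self, model_suite):
        for cfg in model_suite[:8]:
            for alpha in cfg.model.demes:
                p = mr_probabilities(cfg.model, alpha)
                assert float(p.total()) == pytest.approx(1.0, abs=1e-12)


class TestMarginalRecombination:
    def test_full_set_unchanged(self, small_cfg):
        r = small_cfg.model.recombination
        assert r.marginal(r.ground) == dict(r.weights)

    def test_single_site_is_unit_mass(self, small_cfg):
        r = small_cfg.model.recombination
        marg = r.marginal([2])
        assert marg == {Partition([[2]]): pytest.approx(1.0)}

    def test_pair_marginal_exact(self, nonmono_cfg):
        r = nonmono_cfg.model.recombination
        marg = r.marginal([1, 2])
        assert marg[Partition([[1, 2]])] == Fraction(1, 2)
        assert marg[Partition([[1], [2]])] == Fraction(1, 2)


class TestMarginalMRProbabilities:
    def test_full_set_equals_plain(self, small_cfg):
        m = small_cfg.model
        full = mr_probabilities(m, "d0").probs
        marg = marginal_mr_probabilities(m, m.ground, "d0").probs
        assert set(full) == set(marg)
        for k in full:
            assert float(full[k]) == pytest.approx(float(marg[k]), abs=1e-14)

    def test_single_deme_reduces_to_marginal_r(self, nonmono_cfg):
        m = nonmono_cfg.model
        p = marginal_mr_probabilities(m, (1, 2), "pop")
        rU = m.recombination.marginal((1, 2))
        for bdelta, val in p.probs.items():
            assert val == rU[bdelta.base]

    def test_equals_defining_sum_over_full_space(self, small_cfg):
        """The product form agrees with the brute-force sum of full-system
        probabilities over labelled partitions inducing the target."""
        m = small_cfg.model
        full = mr_probabilities(m, "d1").probs
        for U in [(1,), (1, 3), (2, 3)]:
            marg = marginal_mr_probabilities(m, U, "d1").probs
            brute: dict = {}
            for bdelta, val in full.items():
                key = restrict(bdelta, U)
                brute[key] = brute.get(key, 0.0) + float(val)
            assert set(marg) <= set(brute)
            for k, v in brute.items():
                assert float(marg.get(k, 0.0)) == pytest.approx(v, abs=1e-12)


class TestValidation:
    def test_bad_recombination(self):
        g = (1, 2)
        with pytest.raises(ValidationError):
            RecombinationDistribution(g, {top(g): 0.6, bottom(g): 0.6})
        with pytest.raises(ValidationError):
            RecombinationDistribution(g, {top(g): Fraction(3, 2), bottom(g): Fraction(-1, 2)})

    def test_bad_migration(self):
        with pytest.raises(ValidationError):
            MigrationModel(["a", "b"], [[0.5, 0.6], [0.5, 0.5]])

    def test_population_measure_shape_and_mass(self):
        space = TypeSpace([["0", "1"]])
        with pytest.raises(ValidationError):
            PopulationMeasure(space, (1,), [0.5, 0.6])
        with pytest.raises(ValidationError):
            PopulationMeasure(space, (1,), [0.5, 0.5, 0.0])

    def test_metapopulation_site_mismatch(self):
        space = TypeSpace([["0", "1"], ["0", "1"]])
        a = PopulationMeasure(space, (1,), [0.5, 0.5])
        b = PopulationMeasure(space, (2,), [0.5, 0.5])
        with pytest.raises(ValidationError):
            MetaPopulation(["x", "y"], [a, b])
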