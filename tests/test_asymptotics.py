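"""Limiting and quasi-limiting behaviour: stationary migration law,
separability, the forward limit, reachability, sojourn maxima, and the
quasi-limiting distributions with their exact matrix-power oracle."""

from fractions import Fraction

import numpy as np
import pytest

from migrec import (
    DomainError,
    MigrationModel,
    Partition,
    RecombinationDistribution,
    ValidationError,
    bottom,
    build_T,
    check_separability,
    collapse_clusters,
    conditional_law_exact,
    is_primitive,
    iterate,
    labelled_top,
    limiting_metapopulation,
    qlim_labelled,
    qlim_unlabelled,
    reachable_states,
    sojourn_eta_F,
    stationary_distribution,
    top,
)
from migrec.workbench import RandomModelSpec, generate_random_model

from conftest import exact_two_site_model


class TestPrimitivity:
    def test_identity_is_not_primitive(self):
        ok, k = is_primitive(np.eye(3))
        assert not ok and k is None

    def test_positive_matrix_is_primitive_at_one(self):
        ok, k = is_primitive(np.full((3, 3), 1 / 3))
        assert ok and k == 1

    def test_two_cycle_is_periodic(self):
        ok, _ = is_primitive(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert not ok

    def test_irreducible_aperiodic_needs_higher_power(self):
        M = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        ok, k = is_primitive(M)
        assert ok and k > 1


class TestStationaryDistribution:
    def test_doubly_stochastic_gives_uniform(self):
        M = MigrationModel(["a", "b", "c"],
                           [[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        q = stationary_distribution(M)
        assert np.allclose(q.q, 1 / 3)

    def test_two_state_closed_form(self):
        a, b = 0.2, 0.5
        M = MigrationModel(["x", "y"], [[1 - a, a], [b, 1 - b]])
        q = stationary_distribution(M)
        assert np.allclose(q.q, [b / (a + b), a / (a + b)])

    def test_left_fixed_point_residual(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            M = rng.dirichlet(np.ones(4) * 2, size=4)
            mm = MigrationModel(list("abcd"), M)
            q = stationary_distribution(mm)
            assert np.max(np.abs(q.q @ M - q.q)) < 1e-12
            assert np.all(q.q > 0)

    def test_non_primitive_raises(self):
        M = MigrationModel(["x", "y"], [[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValidationError):
            stationary_distribution(M)


class TestSeparability:
    def test_all_singleton_in_support_separates(self, small_cfg):
        ok, clusters = check_separability(small_cfg.model.recombination)
        assert ok

    def test_one_block_support_does_not(self):
        g = (1, 2, 3)
        r = RecombinationDistribution(g, {top(g): Fraction(1)})
        ok, clusters = check_separability(r)
        assert not ok and clusters == [(1, 2, 3)]

    def test_meet_over_the_fixture_support(self, nonmono_cfg):
        ok, _ = check_separability(nonmono_cfg.model.recombination)
        assert ok

    def test_collapse_clusters(self):
        g = (1, 2, 3)
        r = RecombinationDistribution(
            g,
            {
                top(g): Fraction(1, 2),
                Partition([[1, 2], [3]]): Fraction(1, 2),
            },
        )
        from migrec import Model, TypeSpace

        model = Model(TypeSpace([["0", "1"]] * 3), r, MigrationModel(["p"], [[1.0]]))
        reduced, _, clusters = collapse_clusters(model)
        assert clusters == [(1, 2), (3,)]
        assert reduced.space.n == 2
        assert len(reduced.space.alphabets[0]) == 4
        ok, _ = check_separability(reduced.recombination)
        assert ok


class TestForwardLimit:
    def test_single_deme_is_product_of_marginals(self, nonmono_cfg):
        mu0 = nonmono_cfg.initial
        lim = limiting_metapopulation(mu0, nonmono_cfg.model)
        from migrec import tensor

        expected = tensor([mu0("pop").marginal([i]) for i in range(1, 5)])
        assert np.allclose(lim("pop").table, expected.table)

    def test_limit_is_a_fixed_point(self, small_cfg):
        lim = limiting_metapopulation(small_cfg.initial, small_cfg.model)
        from migrec import mre_step

        assert mre_step(lim, small_cfg.model).sup_distance(lim) < 1e-13

    def test_orbit_converges_geometrically(self, small_cfg):
        lim = limiting_metapopulation(small_cfg.initial, small_cfg.model)
        traj = iterate(small_cfg.initial, small_cfg.model, 60, record=True)
        d60 = traj[60.0].sup_distance(lim)
        assert d60 <= 1e-8
        dists = np.array(
            [traj[float(t)].sup_distance(lim) for t in range(1, 31)]
        )
        assert np.all(np.diff(np.log(dists)) < 0)  # monotone decreasing
        slope = np.polyfit(np.arange(1, 31), np.log(dists), 1)[0]
        assert np.exp(slope) < 1.0

    def test_nonseparable_model_is_rejected(self):
        g = (1, 2)
        r = RecombinationDistribution(g, {top(g): Fraction(1)})
        from migrec import Model, TypeSpace

        model = Model(TypeSpace([["0", "1"]] * 2), r, MigrationModel(["p"], [[1.0]]))
        mu0 = iterate_mu0(model)
        with pytest.raises(ValidationError):
            limiting_metapopulation(mu0, model)


def iterate_mu0(model):
    from migrec import MetaPopulation, PopulationMeasure

    rng = np.random.default_rng(0)
    meas = [
        PopulationMeasure(
            model.space, model.ground,
            rng.dirichlet(np.ones(model.space.size())).reshape(model.space.shape()),
        )
        for _ in model.demes
    ]
    return MetaPopulation(model.demes, meas)


class TestReachability:
    def test_fixture_reachable_set(self, nonmono_cfg):
        r = nonmono_cfg.model.recombination
        got = reachable_states(r)
        expected = {
            top((1, 2, 3, 4)),
            Partition([[1, 2], [3, 4]]),
            Partition([[1, 2], [3], [4]]),
            Partition([[1], [2], [3, 4]]),
            bottom((1, 2, 3, 4)),
        }
        assert got == expected

    def test_absorbing_start(self, nonmono_cfg):
        r = nonmono_cfg.model.recombination
        z = bottom((1, 2, 3, 4))
        assert reachable_states(r, start=z) == {z}


class TestSojournMaxima:
    def test_two_site(self):
        model = exact_two_site_model(Fraction(1, 3), np.eye(2))
        eta, F, etap = sojourn_eta_F(model.recombination)
        assert eta == Fraction(2, 3)
        assert F == {top((1, 2))}
        assert etap is None

    def test_fixture_values_and_nonmonotone_path(self, nonmono_cfg):
        eta, F, etap = sojourn_eta_F(nonmono_cfg.model.recombination)
        assert eta == Fraction(1, 2)
        assert F == {Partition([[1, 2], [3], [4]]), Partition([[1], [2], [3, 4]])}
        assert etap == Fraction(2, 5)

    def test_all_mass_on_singletons_rejected(self):
        g = (1, 2)
        r = RecombinationDistribution(g, {bottom(g): Fraction(1)})
        with pytest.raises(ValidationError):
            sojourn_eta_F(r)

    def test_members_of_F_only_stay_or_absorb(self):
        """From a maximal-sojourn state the chain either stays or jumps
        straight to the absorbing state (checked across random models)."""
        from migrec import build_T_unlabelled

        for seed in range(20):
            cfg = generate_random_model(
                RandomModelSpec(seed=500 + seed, n=2 + seed % 3,
                                n_demes=1, support_size=2 + seed % 3)
            )
            r = cfg.model.recombination
            tul = build_T_unlabelled(r)
            eta, F, _ = sojourn_eta_F(r, tul=tul)
            z = tul.index[bottom(r.ground)]
            for d in F:
                i = tul.index[d]
                assert float(tul.matrix[i, i] + tul.matrix[i, z]) == pytest.approx(
                    1.0, abs=1e-12
                )


class TestQuasiLimiting:
    def test_two_site_is_unit_mass(self):
        model = exact_two_site_model(Fraction(1, 4), np.eye(2))
        law = qlim_unlabelled(model.recombination)
        assert law.unlabelled_law == {top((1, 2)): 1}

    def test_fixture_law_is_half_half(self, nonmono_cfg):
        law = qlim_unlabelled(nonmono_cfg.model.recombination)
        expected = {
            Partition([[1, 2], [3], [4]]): Fraction(1, 2),
            Partition([[1], [2], [3, 4]]): Fraction(1, 2),
        }
        assert law.unlabelled_law == expected

    def test_matches_conditional_law_at_large_t(self, nonmono_cfg):
        r = nonmono_cfg.model.recombination
        law = qlim_unlabelled(r)
        cond = conditional_law_exact(r, t=300)
        tv = 0.5 * sum(
            abs(float(law.unlabelled_law.get(p, 0)) - cond.get(p, 0.0))
            for p in set(law.unlabelled_law) | set(cond)
        )
        assert tv <= 1e-8

    def test_conditional_law_basics(self, nonmono_cfg):
        r = nonmono_cfg.model.recombination
        t0 = conditional_law_exact(r, t=0)
        assert t0 == {top((1, 2, 3, 4)): 1.0}
        model2 = exact_two_site_model(Fraction(1, 3), np.eye(2))
        for t in (0, 3, 10):
            law = conditional_law_exact(model2.recombination, t=t)
            assert law == {top((1, 2)): pytest.approx(1.0)}

    def test_absorbed_start_rejected(self, nonmono_cfg):
        with pytest.raises(DomainError):
            conditional_law_exact(
                nonmono_cfg.model.recombination, start=bottom((1, 2, 3, 4)), t=1
            )


class TestQuasiLimitingLabelled:
    def test_two_site_labelled_masses_are_q(self):
        model = exact_two_site_model(Fraction(1, 4), [[0.7, 0.3], [0.4, 0.6]])
        law = qlim_labelled(model)
        q = stationary_distribution(model.migration)
        for d in model.demes:
            assert law.labelled_law[labelled_top((1, 2), d)] == pytest.approx(q(d))

    def test_single_deme_reduces_to_unlabelled(self, nonmono_cfg):
        law = qlim_labelled(nonmono_cfg.model)
        for b, w in law.labelled_law.items():
            assert w == pytest.approx(float(law.unlabelled_law[b.base]))

    def test_product_form_matches_exact_labelled_conditional(
        self, nonmono_two_deme_model
    ):
        """Powering the labelled transition matrix and conditioning on
        non-absorption converges to the product of stationary labels and
        the unlabelled quasi-limiting law."""
        model = nonmono_two_deme_model
        T = build_T(model)
        live = [i for i, s in enumerate(T.states)
                if any(len(b) > 1 for b, _ in s)]
        Q = T.matrix[np.ix_(live, live)]
        start = labelled_top(model.ground, "a")
        v = np.zeros(len(live))
        v[live.index(T.index[start])] = 1.0
        t = 60
        for _ in range(t):
            v = v @ Q
        v = v / v.sum()
        law = qlim_labelled(model, "a")
        tv = 0.0
        for k, i in enumerate(live):
            tv += abs(v[k] - float(law.labelled_law.get(T.states[i], 0.0)))
        assert 0.5 * tv < 1e-4
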