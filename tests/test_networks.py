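"""Weights of the expression, mutation and integrative networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import random_calls, random_expression
from coremod import (ExpressionMatrix, ExpressionNetwork, MutationMatrix,
                     MutationNetwork, build_binary_mutation_matrix,
                     build_expression_network, build_mutation_network,
                     collapse_metagenes, compute_gene_universe,
                     coverage_weight, exclusivity_weight,
                     expression_edge_weight, influence_weight,
                     integrate_networks, mutation_ordered_expression)


def _universe(a, b):
    return compute_gene_universe(a, b)


def _expr(values, samples, genes):
    return ExpressionMatrix(pd.DataFrame(values, index=samples, columns=genes))


def _mut(data, samples):
    return MutationMatrix(indicator=pd.DataFrame(data, index=samples))


class TestMutationOrderedExpression:
    samples = ["s1", "s2", "s3", "s4"]

    def _fixture(self, mutated):
        col = [1 if s in mutated else 0 for s in self.samples]
        # a second, always-informative unit keeps the universe non-empty
        other = [1, 1, 0, 0]
        a = _mut({"g": col, "o": other}, self.samples)
        b = _expr(np.column_stack([[1, 2, 3, 4], [0, 0, 0, 0]]),
                  self.samples, ["g", "o"])
        return a, b, _universe(a, b)

    def test_mutated_block_comes_first(self):
        a, b, universe = self._fixture({"s3", "s4"})
        e = mutation_ordered_expression("g", a, b, universe)
        assert list(e) == [3, 4, 1, 2]

    def test_prefix_mutations_leave_order_unchanged(self):
        a, b, universe = self._fixture({"s1", "s2"})
        e = mutation_ordered_expression("g", a, b, universe)
        assert list(e) == [1, 2, 3, 4]

    def test_metagene_member_average(self):
        samples = ["s1", "s2"]
        df = pd.DataFrame({"g1": [1, 0], "g2": [1, 0], "o": [0, 1]}, index=samples)
        a = collapse_metagenes(MutationMatrix(indicator=df))
        b = _expr([[1, 3, 0], [3, 5, 0]], samples, ["g1", "g2", "o"])
        avg = np.array([2.0, 4.0])
        from coremod.networks import unit_expression

        got = unit_expression("g1/g2", a, b, _make_universe_over(a, b))
        np.testing.assert_allclose(got, avg)

    def test_unknown_unit_rejected(self):
        a, b, universe = self._fixture({"s3", "s4"})
        with pytest.raises(KeyError):
            mutation_ordered_expression("nope", a, b, universe)


def _make_universe_over(a, b):
    """Universe bypassing the group-size filter, for tiny fixtures."""
    from coremod.matrices import GeneUniverse

    samples = tuple(sorted(set(a.sample_ids) & set(b.sample_ids)))
    units = tuple(a.unit_ids)
    sub = a.indicator.loc[list(samples)]
    sizes = {u: (int(sub[u].sum()), len(samples) - int(sub[u].sum())) for u in units}
    return GeneUniverse(samples=samples, g0=units, units=units, group_sizes=sizes)


class TestInfluenceWeight:
    def test_zero_variance_everywhere_gives_zero(self):
        samples = [f"s{i}" for i in range(6)]
        a = _mut({"g": [1, 1, 1, 0, 0, 0]}, samples)
        # every expression gene constant -> every p_r = 1 -> f = 0
        b = _expr(np.ones((6, 3)), samples, ["g", "e2", "e3"])
        universe = _universe(a, b)
        assert influence_weight("g", a, b, universe) == pytest.approx(0.0)

    def test_matches_per_gene_ttest_oracle(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(20)]
        a = _mut({"g": rng.permutation([1] * 6 + [0] * 14)}, samples)
        b = random_expression(rng, 20, 7)
        universe = _make_universe_over(a, b)
        mask = a.indicator.loc[list(universe.samples), "g"].to_numpy() == 1
        expr = b.values.loc[list(universe.samples)].to_numpy()
        ps = [sps.ttest_ind(expr[mask, r], expr[~mask, r]).pvalue
              for r in range(expr.shape[1])]
        assert influence_weight("g", a, b, universe) == pytest.approx(
            1 - np.mean(ps), abs=1e-12)

    def test_welch_option_differs_from_pooled(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(30)]
        a = _mut({"g": rng.permutation([1] * 5 + [0] * 25)}, samples)
        vals = rng.normal(size=(30, 5))
        vals[:5] *= 6.0  # heteroscedastic
        b = _expr(vals, samples, [f"e{i}" for i in range(5)])
        universe = _make_universe_over(a, b)
        pooled = influence_weight("g", a, b, universe, ttest="pooled")
        welch = influence_weight("g", a, b, universe, ttest="welch")
        assert pooled != welch


class TestExpressionEdgeWeight:
    def _pair(self, e1, e2, col1=None, col2=None):
        n = len(e1)
        samples = [f"s{i}" for i in range(n)]
        col1 = col1 or [1, 1] + [0] * (n - 2)
        col2 = col2 or [0, 0, 1, 1] + [0] * (n - 4)
        a = _mut({"g1": col1, "g2": col2}, samples)
        b = _expr(np.column_stack([e1, e2]), samples, ["g1", "g2"])
        return a, b, _make_universe_over(a, b)

    def test_identical_profiles_give_one(self):
        e = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        a, b, u = self._pair(e, e, col1=[1, 1, 0, 0, 0, 0], col2=[1, 1, 0, 0, 0, 0])
        assert expression_edge_weight("g1", "g2", a, b, u) == pytest.approx(1.0)

    def test_anticorrelation_gives_one(self):
        e = np.arange(6.0)
        a, b, u = self._pair(e, -e, col1=[1, 1, 0, 0, 0, 0], col2=[1, 1, 0, 0, 0, 0])
        assert expression_edge_weight("g1", "g2", a, b, u) == pytest.approx(1.0)

    def test_constant_profile_gives_zero(self):
        a, b, u = self._pair([1.0] * 6, list(np.arange(6.0)),
                             col1=[1, 1, 0, 0, 0, 0], col2=[0, 0, 1, 1, 0, 0])
        assert expression_edge_weight("g1", "g2", a, b, u) == 0.0

    def test_self_edge_rejected(self):
        a, b, u = self._pair(list(range(6)), list(range(6)),
                             col1=[1, 1, 0, 0, 0, 0], col2=[0, 0, 1, 1, 0, 0])
        with pytest.raises(ValueError):
            expression_edge_weight("g1", "g1", a, b, u)

    def test_ordered_mode_depends_on_mutation_order(self):
        rng = np.random.default_rng(8)
        e1, e2 = rng.normal(size=6), rng.normal(size=6)
        a, b, u = self._pair(list(e1), list(e2),
                             col1=[1, 0, 1, 0, 0, 0], col2=[0, 0, 0, 1, 0, 1])
        ordered = expression_edge_weight("g1", "g2", a, b, u, edge_mode="ordered")
        plain = expression_edge_weight("g1", "g2", a, b, u, edge_mode="plain")
        assert ordered != pytest.approx(plain)


class TestMutationWeights:
    def test_coverage_toy(self, toy_mutation):
        assert coverage_weight("g3", toy_mutation) == pytest.approx(0.6)
        assert coverage_weight("g1", toy_mutation) == pytest.approx(0.4)

    def test_exclusivity_toy_enumeration(self, toy_mutation):
        assert exclusivity_weight("g1", "g2", toy_mutation) == pytest.approx(1.0)
        assert exclusivity_weight("g1", "g3", toy_mutation) == pytest.approx(0.75)

    def test_identical_columns_have_zero_exclusivity(self):
        a = _mut({"g1": [1, 1, 0], "g2": [1, 1, 0]}, ["s1", "s2", "s3"])
        assert exclusivity_weight("g1", "g2", a) == 0.0

    def test_never_altered_pair_is_zero(self):
        a = _mut({"g1": [0, 0], "g2": [0, 0]}, ["s1", "s2"])
        assert exclusivity_weight("g1", "g2", a) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_build_matches_pairwise_functions(self, seed):
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, 12, 6, p=0.4)
        a = MutationMatrix(indicator=calls.indicator)
        b = random_expression(rng, 12, 6)
        universe = _make_universe_over(a, b)
        mn = build_mutation_network(a, universe)
        for i in universe.units:
            assert mn.vertex_weight[i] == pytest.approx(coverage_weight(i, a))
            for j in universe.units:
                if i < j:
                    assert mn.edge_weight.loc[i, j] == pytest.approx(
                        exclusivity_weight(i, j, a))

    def test_sample_permutation_invariance(self, toy_mutation):
        perm = ["s4", "s1", "s5", "s2", "s3"]
        shuffled = MutationMatrix(indicator=toy_mutation.indicator.loc[perm])
        for i, j in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]:
            assert exclusivity_weight(i, j, shuffled) == pytest.approx(
                exclusivity_weight(i, j, toy_mutation))
        for g in toy_mutation.unit_ids:
            assert coverage_weight(g, shuffled) == pytest.approx(
                coverage_weight(g, toy_mutation))


def _toy_networks(f, u, h, v):
    units = list(f.keys())
    fser = pd.Series(f)
    hser = pd.Series(h)
    umat = pd.DataFrame(u, index=units, columns=units)
    vmat = pd.DataFrame(v, index=units, columns=units)
    en = ExpressionNetwork(units=tuple(units), vertex_weight=fser,
                           edge_weight=umat, d=10)
    mn = MutationNetwork(units=tuple(units), vertex_weight=hser,
                         edge_weight=vmat, m=10,
                         m_i=(hser * 10).astype(int))
    return en, mn


class TestIntegrateNetworks:
    def test_delta_from_maxima(self):
        en, mn = _toy_networks(f={"a": 1.0, "b": 0.5}, u=[[0, 0.8], [0.8, 0]],
                               h={"a": 0.5, "b": 0.2}, v=[[0, 1.0], [1.0, 0]])
        net = integrate_networks(en, mn, k=1.0)
        assert net.constants["delta"] == pytest.approx(1.25)

    def test_edge_weight_formula(self):
        # delta = 1.25 with u=0.8, v=1.0; an edge with u_ij=0.4, v_ij=0.75
        en, mn = _toy_networks(
            f={"a": 1.0, "b": 0.5, "c": 0.2},
            u=[[0, 0.8, 0.1], [0.8, 0, 0.4], [0.1, 0.4, 0]],
            h={"a": 0.5, "b": 0.2, "c": 0.3},
            v=[[0, 1.0, 0.2], [1.0, 0, 0.75], [0.2, 0.75, 0]])
        net = integrate_networks(en, mn, k=1.0)
        assert net.edge_weight.loc["b", "c"] == pytest.approx(1.25 * 0.4 + 0.75)

    def test_k_scales_delta_and_expression_terms(self):
        en, mn = _toy_networks(f={"a": 1.0, "b": 0.5}, u=[[0, 0.8], [0.8, 0]],
                               h={"a": 0.5, "b": 0.2}, v=[[0, 1.0], [1.0, 0]])
        net1 = integrate_networks(en, mn, k=1.0)
        net2 = integrate_networks(en, mn, k=2.0)
        assert net2.constants["delta"] == pytest.approx(2 * net1.constants["delta"])
        d1 = net1.edge_weight - mn.edge_weight
        d2 = net2.edge_weight - mn.edge_weight
        np.testing.assert_allclose(d2.to_numpy(), 2 * d1.to_numpy())

    @pytest.mark.parametrize("seed", range(3))
    def test_balancing_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        units = [f"g{i}" for i in range(n)]
        u = np.abs(rng.normal(size=(n, n)))
        u = (u + u.T) / (2 * u.max())
        np.fill_diagonal(u, 0)
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        en, mn = _toy_networks(
            f=dict(zip(units, rng.random(n))), u=u,
            h=dict(zip(units, rng.random(n) + 0.01)), v=v)
        k = 1.7
        net = integrate_networks(en, mn, k=k)
        delta = net.constants["delta"]
        assert delta * u.max() / v.max() == pytest.approx(k)
        xi, eta = net.constants["xi"], net.constants["eta"]
        assert xi * en.vertex_weight.max() == pytest.approx(u.max())
        assert eta * mn.vertex_weight.max() == pytest.approx(v.max())
        assert (net.edge_weight.to_numpy() >= 0).all()
        assert (net.vertex_weight.to_numpy() >= 0).all()
        np.testing.assert_allclose(net.edge_weight.to_numpy(),
                                   net.edge_weight.to_numpy().T)

    def test_mutation_only_mode_drops_expression_terms(self):
        en, mn = _toy_networks(f={"a": 1.0, "b": 0.5}, u=[[0, 0.8], [0.8, 0]],
                               h={"a": 0.5, "b": 0.2}, v=[[0, 1.0], [1.0, 0]])
        net = integrate_networks(None, mn, source="mutation_only")
        assert net.constants["delta"] == 0.0
        np.testing.assert_allclose(net.edge_weight.to_numpy(),
                                   mn.edge_weight.to_numpy())
        eta = net.constants["eta"]
        np.testing.assert_allclose(net.vertex_weight.to_numpy(),
                                   eta * mn.vertex_weight.to_numpy())

    def test_degenerate_weights_rejected(self):
        en, mn = _toy_networks(f={"a": 0.0, "b": 0.0}, u=[[0, 0.8], [0.8, 0]],
                               h={"a": 0.5, "b": 0.2}, v=[[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            integrate_networks(en, mn)


class TestEndToEndNetworkBuild:
    def test_full_build_on_synthetic_data(self, small_universe):
        a, expression, universe = small_universe
        en = build_expression_network(a, expression, universe)
        mn = build_mutation_network(a, universe)
        net = integrate_networks(en, mn)
        assert tuple(net.units) == tuple(universe.units)
        assert en.d == len(expression.gene_ids)
        assert (en.vertex_weight.between(0, 1)).all()
        assert ((en.edge_weight.to_numpy() >= 0)
                & (en.edge_weight.to_numpy() <= 1)).all()
        assert ((mn.edge_weight.to_numpy() >= 0)
                & (mn.edge_weight.to_numpy() <= 1)).all()
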