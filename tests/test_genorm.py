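"""geNorm M values, stepwise exclusion, NF_n, V_n/n+1 and the optimal-n rule.

Brute-force oracles here are written directly from the definitions
(explicit loops over gene pairs / subsets) and kept independent of the
vectorised implementation they check.
"""

import itertools
import statistics

import numpy as np
import pytest

from refstab.genorm import (
    GenormRanking,
    genorm_analysis,
    m_values,
    normalization_factors,
    optimal_n,
    pairwise_variation,
    stability_order,
    stepwise_ranking,
)
from refstab.quantities import to_expression

from conftest import make_table, random_table


def brute_force_m(expr):
    """Mean over partners of stdev of pairwise value differences."""
    out = {}
    for j, gj in enumerate(expr.genes):
        sds = []
        for k, gk in enumerate(expr.genes):
            if k == j:
                continue
            diffs = [expr.values[j, s] - expr.values[k, s] for s in range(expr.n_samples)]
            sds.append(statistics.stdev(diffs))
        out[gj] = sum(sds) / len(sds)
    return out


class TestMValues:
    def test_co_regulated_pair_has_zero_m(self):
        vals = np.array([[20.0, 21.0, 23.0], [25.0, 26.0, 28.0]])  # constant offset
        m = m_values(to_expression(make_table(vals)))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in m.values())

    def test_two_gene_panel_symmetric(self):
        rng = np.random.default_rng(0)
        m = m_values(to_expression(random_table(rng, 2, 6)))
        (a, b) = m.values()
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("k,n", [(3, 4), (5, 8), (13, 12)])
    def test_matches_brute_force(self, k, n):
        rng = np.random.default_rng(k * 100 + n)
        expr = to_expression(random_table(rng, k, n))
        m = m_values(expr)
        bf = brute_force_m(expr)
        for g in expr.genes:
            assert m[g] == pytest.approx(bf[g], abs=1e-10)

    def test_invariances(self):
        rng = np.random.default_rng(9)
        expr = to_expression(random_table(rng, 5, 8))
        base = m_values(expr)
        # per-gene constants
        expr.values = expr.values + rng.uniform(-3, 3, size=(5, 1))
        for g, v in m_values(expr).items():
            assert v == pytest.approx(base[g], abs=1e-10)
        # sample permutation
        perm = rng.permutation(expr.n_samples)
        expr.values = expr.values[:, perm]
        for g, v in m_values(expr).items():
            assert v == pytest.approx(base[g], abs=1e-10)

    def test_single_sample_rejected(self):
        vals = np.array([[20.0, 21.0], [22.0, 23.0]])
        expr = to_expression(make_table(vals))
        expr.values = expr.values[:, :1]
        expr.samples = expr.samples[:1]
        with pytest.raises(ValueError):
            m_values(expr)


class TestStepwise:
    def test_three_genes_single_exclusion(self):
        rng = np.random.default_rng(1)
        r = stepwise_ranking(to_expression(random_table(rng, 3, 6)))
        assert len(r.exclusion_order) == 1 and len(r.final_pair) == 2

    def test_ranks_mirror_exclusion_order(self):
        rng = np.random.default_rng(2)
        r = stepwise_ranking(to_expression(random_table(rng, 6, 8)))
        for pos, g in enumerate(r.exclusion_order):
            assert r.ranks[g] == 6 - pos
        assert all(r.ranks[g] == 1.5 for g in r.final_pair)
        assert sorted(r.ranks.values()) == [1.5, 1.5, 3, 4, 5, 6]

    def test_noisy_gene_removed_first(self):
        # one gene with independent SD-2 noise on top of a quiet panel
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = 20 + rng.normal(0, 0.2, size=(5, 10))
            vals[0] += rng.normal(0, 2.0, size=10)
            r = stepwise_ranking(to_expression(make_table(vals)))
            hits += r.exclusion_order[0] == "G1"
        assert hits >= 18

    def test_tie_broken_by_name(self):
        # mirror-image noisy genes (base +/- n) around an identical quiet
        # pair have bitwise-equal max M; lexicographic removal picks 'A'
        rng = np.random.default_rng(3)
        base = 25 + rng.normal(0, 0.01, size=6)
        noise = rng.normal(0, 1, size=6)
        vals = np.vstack([base + noise, base - noise, base, base.copy()])
        r = stepwise_ranking(
            to_expression(make_table(vals, genes=["B", "A", "Y", "Z"]))
        )
        assert r.exclusion_order[0] == "A"


class TestNormalizationFactors:
    def test_nf2_is_root_of_product(self):
        vals = np.array(
            [[20.0, 21.0, 22.0], [25.0, 25.5, 27.0], [30.0, 33.0, 30.5]]
        )
        expr = to_expression(make_table(vals))
        ranking = stepwise_ranking(expr)
        nf = normalization_factors(expr, ranking)
        q = expr.quantities()
        top2 = [expr.genes.index(g) for g in stability_order(ranking)[:2]]
        np.testing.assert_allclose(
            nf.loc[2].to_numpy(), np.sqrt(q[top2[0]] * q[top2[1]]), atol=1e-12
        )

    def test_nf_full_panel_uses_all_genes(self):
        rng = np.random.default_rng(4)
        expr = to_expression(random_table(rng, 5, 6))
        nf = normalization_factors(expr, stepwise_ranking(expr))
        q = expr.quantities()
        np.testing.assert_allclose(
            nf.loc[5].to_numpy(), np.prod(q, axis=0) ** (1 / 5), atol=1e-12
        )
        assert list(nf.index) == [2, 3, 4, 5]


class TestPairwiseVariation:
    def test_identical_nf_gives_zero_v(self):
        vals = np.array([[20.0, 21.0, 22.0]] * 3)  # all genes identical
        expr = to_expression(make_table(vals, genes=["A", "B", "C"]))
        v = pairwise_variation(normalization_factors(expr, stepwise_ranking(expr)))
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_log_ratio_sd(self):
        rng = np.random.default_rng(5)
        expr = to_expression(random_table(rng, 4, 7))
        ranking = stepwise_ranking(expr)
        nf = normalization_factors(expr, ranking)
        v = pairwise_variation(nf)
        order = stability_order(ranking)
        q = {g: expr.quantities()[expr.genes.index(g)] for g in expr.genes}
        for n in (2, 3):
            nf_n = [
                statistics.geometric_mean([q[g][s] for g in order[:n]])
                for s in range(expr.n_samples)
            ]
            nf_n1 = [
                statistics.geometric_mean([q[g][s] for g in order[: n + 1]])
                for s in range(expr.n_samples)
            ]
            ratios = [np.log2(a / b) for a, b in zip(nf_n, nf_n1)]
            assert v[n] == pytest.approx(statistics.stdev(ratios), abs=1e-10)
            assert v[n] >= 0


class TestOptimalN:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ({2: 0.068, 3: 0.062}, 2),  # two genes suffice
            ({2: 0.2, 3: 0.2}, "undetermined"),
            ({2: 0.16, 3: 0.01}, 3),
        ],
    )
    def test_decision_rule(self, v, expected):
        assert optimal_n(v, threshold=0.15) == expected

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            optimal_n({2: 0.1}, threshold=0.0)
        with pytest.raises(ValueError):
            optimal_n({}, threshold=0.15)


def test_full_analysis_on_stable_panel_flags_nothing(fungal_dev_candidates):
    _, expr, _ = fungal_dev_candidates
    res = genorm_analysis(expr)
    assert max(res.m_values.values()) < 1.5 and res.flagged == []
    assert res.optimal_n == 2
    assert all(v >= 0 for v in res.v_values.values())


def test_exchangeable_genes_first_removal_uniform():
    """First-removed gene of an i.i.d. panel is uniform over genes."""
    from scipy.stats import chisquare

    k, runs = 4, 200
    counts = {f"G{i + 1}": 0 for i in range(k)}
    for seed in range(runs):
        rng = np.random.default_rng(seed)
        vals = 20 + rng.normal(0, 0.5, size=(k, 8))
        r = stepwise_ranking(to_expression(make_table(vals)))
        counts[r.exclusion_order[0]] += 1
    _, p = chisquare(list(counts.values()))
    assert p > 0.001
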