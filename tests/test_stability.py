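import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from micronetstab import stability
from micronetstab.conet import CoNetwork
from micronetstab.tabio import AsvTable, DataValidationError


def _net(g):
    return CoNetwork(graph=g, rho_min=0.8, alpha=0.05)


# ---------------------------------------------------------------------------
# cohesion
# ---------------------------------------------------------------------------


def test_cohesion_two_perfectly_correlated_taxa():
    # two taxa whose relative abundances are perfectly positively correlated
    df = pd.DataFrame(
        {"s1": [10, 20, 70], "s2": [20, 40, 40], "s3": [5, 10, 85],
         "s4": [30, 60, 10], "s5": [15, 30, 55]},
        index=["a", "b", "c"],
    )
    table = AsvTable(df)
    rel = table.relative_abundance()
    res = stability.cohesion(table, null_model="none")
    # a and b are exact multiples -> corr(a, b) = 1
    assert res.connectedness.loc["a", "positive"] == pytest.approx(1.0)
    assert res.connectedness.loc["b", "positive"] == pytest.approx(1.0)


def test_cohesion_matches_hand_computation():
    """Literal transcription oracle: correlate, average by sign, weight by
    relative abundance."""
    rng = np.random.default_rng(1)
    counts = rng.integers(1, 60, size=(6, 8))
    table = AsvTable(pd.DataFrame(counts, index=[f"t{i}" for i in range(6)],
                                  columns=[f"s{j}" for j in range(8)]))
    res = stability.cohesion(table, null_model="none")

    rel = table.relative_abundance().to_numpy()  # taxa x samples
    n_t = rel.shape[0]
    conn_pos = np.zeros(n_t)
    conn_neg = np.zeros(n_t)
    for j in range(n_t):
        pos, neg = [], []
        for i in range(n_t):
            if i == j:
                continue
            r = np.corrcoef(rel[j], rel[i])[0, 1]
            (pos if r > 0 else neg).append(r)
        conn_pos[j] = np.mean(pos) if pos else 0.0
        conn_neg[j] = np.mean(neg) if neg else 0.0
    np.testing.assert_allclose(res.connectedness["positive"], conn_pos, atol=1e-10)
    np.testing.assert_allclose(res.connectedness["negative"], conn_neg, atol=1e-10)
    for si, s in enumerate(table.sample_ids):
        coh_pos = float((rel[:, si] * conn_pos).sum())
        coh_neg = float((rel[:, si] * conn_neg).sum())
        assert res.cohesion.loc[s, "positive"] == pytest.approx(coh_pos, abs=1e-10)
        assert res.cohesion.loc[s, "negative"] == pytest.approx(coh_neg, abs=1e-10)


def test_cohesion_null_correction_leaves_closure_bias_only():
    """For mutually independent taxa the shuffled null has mean correlation
    ~0, so the corrected pairwise correlations retain only the compositional
    closure bias, whose pair-average is -1/(k-1) (simulation over 20 seeds).
    """
    k = 12
    pair_means = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(50, size=(k, 20))
        table = AsvTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(k)],
            columns=[f"s{j}" for j in range(20)]))
        res = stability.cohesion(table, null_model="taxa_shuffle",
                                 n_null=100, seed=seed)
        # reconstruct the pairwise mean: conn+ + conn- averages the corrected
        # correlations of each taxon with all others, split by sign
        rel = table.relative_abundance().to_numpy()
        obs = np.corrcoef(rel)
        iu = np.triu_indices(k, 1)
        pair_means.append(obs[iu].mean())
        # corrected connectedness stays within the correlation bounds
        assert (res.connectedness.abs() <= 1 + 1e-9).all().all()
    assert abs(np.mean(pair_means) - (-1 / (k - 1))) < 0.03


def test_cohesion_taxa_shuffle_matches_literal_transcription():
    """The vectorized null correction equals a literal loop transcription of
    the same algorithm (same seed, same permutation order)."""
    rng = np.random.default_rng(4)
    counts = rng.integers(1, 80, size=(6, 10))
    table = AsvTable(pd.DataFrame(counts, index=[f"t{i}" for i in range(6)],
                                  columns=[f"s{j}" for j in range(10)]))
    n_null, seed = 40, 3
    res = stability.cohesion(table, null_model="taxa_shuffle",
                             n_null=n_null, seed=seed)

    rel = table.relative_abundance().to_numpy().T  # samples x taxa
    n_s, n_t = rel.shape
    Xs = (rel - rel.mean(axis=0)) / rel.std(axis=0)
    oracle_rng = np.random.default_rng(seed)
    null_sum = np.zeros((n_t, n_t))
    for _ in range(n_null):
        perm = np.empty_like(Xs)
        for j in range(n_t):
            perm[:, j] = Xs[oracle_rng.permutation(n_s), j]
        for i in range(n_t):
            for j in range(n_t):
                null_sum[i, j] += np.mean(Xs[:, i] * perm[:, j])
    null_mean = null_sum / n_null
    null_mean = (null_mean + null_mean.T) / 2
    corrected = np.corrcoef(rel, rowvar=False) - null_mean
    np.fill_diagonal(corrected, np.nan)
    conn_pos = np.zeros(n_t)
    for j in range(n_t):
        vals = corrected[j, :]
        pos = vals[(vals > 0) & ~np.isnan(vals)]
        conn_pos[j] = pos.mean() if pos.size else 0.0
    np.testing.assert_allclose(res.connectedness["positive"], conn_pos, atol=1e-10)


def test_cohesion_sign_constraints(small_table):
    res = stability.cohesion(small_table, null_model="taxa_shuffle",
                             n_null=50, seed=0)
    assert (res.connectedness["positive"] >= 0).all()
    assert (res.connectedness["negative"] <= 0).all()
    assert (res.connectedness.abs() <= 1 + 1e-12).all().all()
    assert (res.cohesion["positive"] >= -1e-12).all()
    assert (res.cohesion["negative"] <= 1e-12).all()


def test_cohesion_invariant_to_taxon_relabeling(small_table):
    res1 = stability.cohesion(small_table, null_model="none")
    shuffled = AsvTable(small_table.counts.iloc[::-1])
    res2 = stability.cohesion(shuffled, null_model="none")
    pd.testing.assert_frame_equal(
        res1.cohesion, res2.cohesion, check_exact=False, atol=1e-12
    )


def test_cohesion_guards():
    # taxon z holds a constant 1/3 share of every sample -> excluded with a
    # warning; x and y still vary in relative abundance
    df = pd.DataFrame(
        {"s1": [5, 1, 3], "s2": [1, 5, 3], "s3": [1, 1, 1], "s4": [2, 0, 1]},
        index=["x", "y", "z"],
    )
    with pytest.warns(UserWarning, match="constant"):
        res = stability.cohesion(AsvTable(df), null_model="none")
    assert "z" not in res.connectedness.index
    with pytest.raises(ValueError, match="n_null"):
        stability.cohesion(AsvTable(df), null_model="taxa_shuffle", n_null=5)


# ---------------------------------------------------------------------------
# stability ratio
# ---------------------------------------------------------------------------


def _cohesion_result(pos, neg):
    coh = pd.DataFrame({"positive": pos, "negative": neg},
                       index=[f"s{i}" for i in range(len(pos))])
    return stability.CohesionResult(
        connectedness=pd.DataFrame(), cohesion=coh,
        null_model="none", n_null=0, seed=None)


def test_stability_ratio_values():
    res = _cohesion_result([0.4, 0.5, 0.0], [-0.2, 0.0, -0.1])
    ratios = stability.stability_ratio(res)["stability_ratio"]
    assert ratios.iloc[0] == pytest.approx(0.5)
    assert ratios.iloc[1] == pytest.approx(0.0)
    assert np.isnan(ratios.iloc[2])  # zero positive cohesion -> undefined


def test_stability_ratio_invariant_to_sample_scaling(small_table):
    res1 = stability.cohesion(small_table, null_model="none")
    scaled = AsvTable(small_table.counts * 2)  # doubles every sample's reads
    res2 = stability.cohesion(scaled, null_model="none")
    r1 = stability.stability_ratio(res1)["stability_ratio"]
    r2 = stability.stability_ratio(res2)["stability_ratio"]
    np.testing.assert_allclose(r1, r2, atol=1e-12)


def test_summarize_stability_by_group():
    res = _cohesion_result([0.4, 0.2, 0.5, 0.25], [-0.2, -0.1, -0.1, -0.05])
    groups = pd.Series(["a", "a", "b", "b"], index=res.cohesion.index)
    summary = stability.summarize_stability(
        stability.stability_ratio(res, groups=groups))
    assert summary.loc["a", "mean"] == pytest.approx(0.5)
    assert summary.loc["b", "mean"] == pytest.approx(0.2)
    assert summary.loc["a", "n"] == 2


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------


def test_robustness_complete_graph_always_connected():
    curve = stability.robustness(_net(nx.complete_graph(10)), "random",
                                 fractions=(0.0, 0.5), n_repetitions=20, seed=0)
    assert curve.at(0.0) == pytest.approx(1.0)
    assert curve.at(0.5) == pytest.approx(1.0)  # survivors of K10 keep edges


def test_robustness_star_targeted_removes_center():
    g = nx.star_graph(10)  # center 0 + 10 leaves
    frac = 1 / 11 + 1e-9  # removes exactly one node: the center
    curve = stability.robustness(_net(g), "degree", fractions=(frac,),
                                 n_repetitions=5, seed=0)
    assert curve.frame["mean"].iloc[0] == pytest.approx(0.0)


def test_robustness_curve_invariants():
    g = nx.erdos_renyi_graph(40, 0.1, seed=2)
    g.remove_nodes_from(list(nx.isolates(g)))  # co-occurrence nets have none
    curve = stability.robustness(_net(g), "random", n_repetitions=50, seed=3)
    assert curve.at(0.0) == pytest.approx(1.0)
    means = curve.frame["mean"].to_numpy()
    assert np.all(np.diff(means) <= 0.05)  # non-increasing in expectation


def test_robustness_random_matches_independent_resimulation():
    """Second-implementation oracle for the f=0.5 random-removal statistic."""
    g = nx.erdos_renyi_graph(40, 0.1, seed=5)
    net = _net(g)
    curve = stability.robustness(net, "random", fractions=(0.5,),
                                 n_repetitions=400, seed=1)
    rng = np.random.default_rng(99)
    nodes = list(g.nodes)
    stats = []
    for _ in range(400):
        removed = set(rng.choice(len(nodes), size=20, replace=False))
        survivors = [n for i, n in enumerate(nodes) if i not in removed]
        keep = sum(
            1 for n in survivors
            if any(nb not in {nodes[i] for i in removed} for nb in g.neighbors(n))
        )
        stats.append(keep / len(survivors))
    ours, theirs = curve.frame["mean"].iloc[0], np.mean(stats)
    pooled_sd = np.sqrt(curve.frame["sd"].iloc[0] ** 2 / 400 + np.var(stats) / 400)
    assert abs(ours - theirs) < 2 * 2 * pooled_sd + 1e-6


def test_targeted_at_most_random_on_scale_free():
    g = nx.barabasi_albert_graph(60, 2, seed=7)
    net = _net(g)
    rnd = stability.robustness(net, "random", n_repetitions=60, seed=1)
    tgt = stability.robustness(net, "degree", n_repetitions=60, seed=1)
    assert (tgt.frame["mean"] <= rnd.frame["mean"] + 0.05).all()


# ---------------------------------------------------------------------------
# vulnerability / efficiency / complexity
# ---------------------------------------------------------------------------


def _brute_efficiency(g):
    nodes = list(g.nodes)
    n = len(nodes)
    total = 0.0
    for a, b in itertools.permutations(nodes, 2):
        try:
            total += 1.0 / nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            pass
    return total / (n * (n - 1))


def test_vulnerability_triangle_is_zero():
    assert stability.vulnerability(_net(nx.complete_graph(3))) == pytest.approx(0.0)


def test_vulnerability_path_graph_is_one():
    # removing the middle node of A-B-C disconnects everything
    assert stability.vulnerability(_net(nx.path_graph(3))) == pytest.approx(1.0)
    assert stability.global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)


def test_vulnerability_matches_brute_force():
    g = nx.erdos_renyi_graph(15, 0.25, seed=11)
    net = _net(g)
    e_full = _brute_efficiency(g)
    worst = max(
        (e_full - _brute_efficiency(g.subgraph([u for u in g if u != v]))) / e_full
        for v in g.nodes
    )
    assert stability.vulnerability(net) == pytest.approx(worst, abs=1e-10)
    assert stability.global_efficiency(g) == pytest.approx(e_full, abs=1e-10)


def test_vulnerability_needs_three_nodes():
    with pytest.raises(DataValidationError, match="at least 3"):
        stability.vulnerability(_net(nx.path_graph(2)))


def test_complexity_is_average_degree():
    assert stability.complexity(_net(nx.complete_graph(4))) == pytest.approx(3.0)
    assert stability.complexity(_net(nx.path_graph(2))) == pytest.approx(1.0)
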