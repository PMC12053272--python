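"""Gaussian graphical model: estimation, pruning, fit, communities, etc."""

import numpy as np
import pandas as pd
import pytest

from conftest import exact_moment_data

from efbattery.cohort import default_cohort_model, planted_precision, sample_scores
from efbattery.network import (
    GaussianGraphicalModel,
    bootstrap_edges,
    centrality,
    concurrent_correlations,
    effect_size_label,
    invariance_ladder,
    spinglass_communities,
)


def planted_sigma(K: pd.DataFrame) -> np.ndarray:
    return np.linalg.inv(K.to_numpy())


@pytest.fixture(scope="module")
def small_planted():
    variables = ["x", "y", "z"]
    K = planted_precision(variables, {"a": variables}, 0.25, 0.0, [])
    return variables, K


def test_saturated_matches_closed_form(small_planted, rng):
    """With sample moments equal to the planted ones, the estimated edges
    equal -K_ij / sqrt(K_ii K_jj) to 1e-8."""
    variables, K = small_planted
    sigma = planted_sigma(K)
    data = pd.DataFrame(exact_moment_data(np.zeros(3), sigma, 200, rng),
                        columns=variables)
    res = GaussianGraphicalModel(data).fit()
    Km = K.to_numpy()
    d = np.sqrt(np.diag(Km))
    target = -Km / np.outer(d, d)
    np.fill_diagonal(target, 0.0)
    assert np.abs(res.omega().to_numpy() - target).max() < 1e-8


def test_independent_columns_near_zero_edges(rng):
    data = pd.DataFrame(rng.standard_normal((5000, 4)),
                        columns=list("abcd"))
    res = GaussianGraphicalModel(data).fit()
    off = res.omega().to_numpy()[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 0.05


def test_fiml_optimizer_equals_analytic_on_complete_data(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 300, rng)
    ggm = GaussianGraphicalModel(data)
    analytic = ggm.fit()
    full_mask = ~np.eye(ggm.p, dtype=bool)
    numeric = ggm._fit_constrained(full_mask, False, False, False)
    assert np.abs(numeric.omega().to_numpy()
                  - analytic.omega().to_numpy()).max() < 1e-6
    assert numeric.loglike == pytest.approx(analytic.loglike, abs=1e-5)


def test_fiml_handles_missing_at_random(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 800, rng)
    lossy = data.mask(rng.uniform(size=data.shape) < 0.15)
    res = GaussianGraphicalModel(lossy).fit()
    complete = GaussianGraphicalModel(data).fit()
    # FIML estimates stay close to the complete-data estimates
    assert np.abs(res.omega().to_numpy()
                  - complete.omega().to_numpy()).max() < 0.12
    listwise = GaussianGraphicalModel(lossy, missing="listwise")
    assert listwise.n_total < res.model.n_total


def test_collinear_pair_reported():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    data = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(100)})
    with pytest.raises(ValueError, match="'a' and 'b'"):
        GaussianGraphicalModel(data)


def test_prune_alpha_extremes(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 400, rng)
    sat = GaussianGraphicalModel(data).fit()
    unchanged = sat.prune_and_refit(alpha=1.0)
    assert unchanged.n_edges() == 45
    assert np.allclose(unchanged.omega().to_numpy(), sat.omega().to_numpy(),
                       atol=1e-6)
    empty = sat.prune_and_refit(alpha=1e-300)
    assert empty.n_edges() == 0
    assert np.allclose(empty.omega().to_numpy(), 0.0)
    # the empty model is a valid independence model with finite likelihood
    assert np.isfinite(empty.loglike)


def test_saturated_fit_indices_identity(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 200, rng)
    fi = GaussianGraphicalModel(data).fit().fit_indices()
    assert fi.chi2 == 0.0 and fi.df == 0
    assert fi.cfi == 1.0 and fi.rmsea == 0.0 and not fi.rmsea_defined


def test_nested_information_criteria_algebra(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 400, rng)
    sat = GaussianGraphicalModel(data).fit()
    pruned = sat.prune_and_refit()
    fi_s, fi_p = sat.fit_indices(), pruned.fit_indices()
    dk = fi_s.n_params - fi_p.n_params
    assert fi_p.aic - fi_s.aic == pytest.approx(fi_p.chi2 - 2 * dk, abs=1e-6)
    assert fi_p.bic - fi_s.bic == pytest.approx(
        fi_p.chi2 - dk * np.log(len(data)), abs=1e-6)


def test_omega_scale_invariance(rng):
    """Partial correlations are invariant to linear rescaling of variables."""
    model = default_cohort_model()
    data, _ = sample_scores(model, 300, rng)
    res1 = GaussianGraphicalModel(data).fit()
    scaled = data.copy()
    scaled["stroop"] = scaled["stroop"] * 7.0 + 3.0
    scaled["boxed"] = scaled["boxed"] * 0.01
    res2 = GaussianGraphicalModel(scaled).fit()
    assert np.abs(res1.omega().to_numpy() - res2.omega().to_numpy()).max() < 1e-10


def test_pruned_model_reproduces_retained_sample_structure(rng):
    """At the constrained optimum the implied covariance matches the sample
    covariance on retained-edge entries (stationarity of the likelihood)."""
    model = default_cohort_model()
    data, _ = sample_scores(model, 600, rng)
    pruned = GaussianGraphicalModel(data).fit().prune_and_refit()
    from efbattery.network import _sigma_from
    sigma_hat = _sigma_from(pruned._omega["all"], pruned._delta["all"])
    S = np.cov(data.to_numpy(), rowvar=False, bias=True)
    mask = pruned.mask | np.eye(10, dtype=bool)
    assert np.abs((sigma_hat - S))[mask].max() < 5e-3


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------


def make_results_from_omega(omega: pd.DataFrame):
    """Wrap a known edge matrix in a results object via exact-moment data."""
    p = len(omega)
    ImO = np.eye(p) - omega.to_numpy()
    sigma = np.linalg.inv(ImO)
    rng = np.random.default_rng(0)
    data = pd.DataFrame(exact_moment_data(np.zeros(p), sigma, 25 * p, rng),
                        columns=omega.columns)
    return GaussianGraphicalModel(data).fit().prune_and_refit(alpha=0.05)


def test_disjoint_cliques_found_exactly():
    names = [f"v{i}" for i in range(6)]
    om = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        om[i, j] = om[j, i] = 0.35
    res = make_results_from_omega(pd.DataFrame(om, index=names, columns=names))
    part = spinglass_communities(res, n_reps=25, rng=np.random.default_rng(1))
    assert part.frequency == 1.0
    assert part.as_sets() == [{"v0", "v1", "v2"}, {"v3", "v4", "v5"}]


def test_single_edge_pair_one_community():
    names = ["a", "b", "c"]
    om = np.zeros((3, 3))
    om[0, 1] = om[1, 0] = 0.4
    res = make_results_from_omega(pd.DataFrame(om, index=names, columns=names))
    part = spinglass_communities(res, n_reps=10, rng=np.random.default_rng(2))
    assert part.labels["a"] == part.labels["b"]
    assert part.labels["c"] != part.labels["a"]   # isolated node on its own


def test_spinglass_reproducible():
    model = default_cohort_model()
    data, _ = sample_scores(model, 500, np.random.default_rng(4))
    pruned = GaussianGraphicalModel(data).fit().prune_and_refit()
    p1 = spinglass_communities(pruned, n_reps=30, rng=np.random.default_rng(5))
    p2 = spinglass_communities(pruned, n_reps=30, rng=np.random.default_rng(5))
    assert p1.labels == p2.labels and p1.frequency == p2.frequency


# ---------------------------------------------------------------------------
# Bootstrap, centrality, concurrent correlations
# ---------------------------------------------------------------------------


def test_bootstrap_deterministic_replay(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 150, rng)
    b1 = bootstrap_edges(data, n_boot=2, rng=np.random.default_rng(6))
    b2 = bootstrap_edges(data, n_boot=2, rng=np.random.default_rng(6))
    pd.testing.assert_frame_equal(b1, b2)


def test_bootstrap_edge_ci_coverage():
    """Coverage oracle over repeated experiments: the percentile CI of a
    strong planted edge (0.4 at n=600) excludes zero essentially always,
    and covers zero for a true-zero edge at roughly the nominal 95% rate."""
    variables = ["a", "b", "c", "d"]
    K = planted_precision(variables, {"g": variables[:2], "h": variables[2:]},
                          0.4, 0.0, [])
    sigma = np.linalg.inv(K.to_numpy())
    rng = np.random.default_rng(7)
    strong_excludes = zero_covers = 0
    n_exp = 40
    for _ in range(n_exp):
        data = pd.DataFrame(
            rng.multivariate_normal(np.zeros(4), sigma, size=600),
            columns=variables)
        boot = bootstrap_edges(data, n_boot=100, rng=rng) \
            .set_index(["node_i", "node_j"])
        strong = boot.loc[("a", "b")]
        strong_excludes += strong["ci_low"] > 0
        zero = boot.loc[("a", "c")]
        zero_covers += zero["ci_low"] <= 0 <= zero["ci_high"]
    assert strong_excludes >= int(0.95 * n_exp)
    assert 0.80 <= zero_covers / n_exp <= 1.0


def test_star_graph_centralities():
    names = ["hub"] + [f"leaf{i}" for i in range(4)]
    om = np.zeros((5, 5))
    for i in range(1, 5):
        om[0, i] = om[i, 0] = 0.2
    res = make_results_from_omega(pd.DataFrame(om, index=names, columns=names))
    cent = centrality(res)
    assert cent.loc["hub", "strength"] == pytest.approx(4 * 0.2, abs=0.02)
    # every leaf-to-leaf shortest path passes through the hub: 4 choose 2
    assert cent.loc["hub", "betweenness"] == pytest.approx(6.0)


def test_negative_edges_expected_influence():
    names = ["a", "b", "c"]
    om = np.zeros((3, 3))
    om[0, 1] = om[1, 0] = -0.3
    om[0, 2] = om[2, 0] = -0.2
    res = make_results_from_omega(pd.DataFrame(om, index=names, columns=names))
    cent = centrality(res)
    assert cent.loc["a", "expected_influence"] == pytest.approx(
        -cent.loc["a", "strength"], abs=1e-10)


def test_betweenness_matches_brute_force(rng):
    """Random small weighted graphs against an all-pairs path enumeration."""
    import itertools

    import networkx as nx

    for trial in range(5):
        r = np.random.default_rng(trial)
        p = 5
        om = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if r.uniform() < 0.6:
                    om[i, j] = om[j, i] = r.uniform(0.1, 0.4)
        names = [f"v{i}" for i in range(p)]
        gr = nx.Graph()
        gr.add_nodes_from(names)
        for i in range(p):
            for j in range(i + 1, p):
                if om[i, j]:
                    gr.add_edge(names[i], names[j], distance=1 / abs(om[i, j]))
        expected = {v: 0.0 for v in names}
        for s, t in itertools.combinations(names, 2):
            try:
                paths = list(nx.all_shortest_paths(gr, s, t, weight="distance"))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    expected[v] += 1.0 / len(paths)
        got = nx.betweenness_centrality(gr, weight="distance", normalized=False)
        for v in names:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


def test_concurrent_correlations_basics():
    rng = np.random.default_rng(8)
    a = pd.DataFrame({"t1": rng.normal(size=50), "t2": rng.normal(size=50)})
    out = concurrent_correlations(a, a.copy())
    assert np.allclose(out["r"], 1.0)
    assert set(out["label"]) == {"large"}
    tiny = pd.DataFrame({"t1": [1.0, 2.0, 4.0]})
    res = concurrent_correlations(tiny, tiny * 2 + 1)
    assert len(res) == 1 and np.isfinite(res["p"].iloc[0])


def test_effect_size_labels():
    assert effect_size_label(0.05) == "negligible"
    assert effect_size_label(-0.2) == "small"
    assert effect_size_label(0.35) == "moderate"
    assert effect_size_label(-0.62) == "large"


# ---------------------------------------------------------------------------
# Invariance
# ---------------------------------------------------------------------------


def test_duplicated_group_gives_zero_deltas(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 300, rng)
    doubled = pd.concat([data, data], ignore_index=True)
    doubled.index = [f"p{i}" for i in range(len(doubled))]
    groups = pd.Series(["a"] * len(data) + ["b"] * len(data),
                       index=doubled.index)
    inv = invariance_ladder(doubled, groups)
    deltas = inv.table["delta_chi2"].iloc[1:]
    assert (deltas.abs() < 0.05).all()


def test_invariance_group_too_small(rng):
    model = default_cohort_model()
    data, _ = sample_scores(model, 40, rng)
    groups = pd.Series(["a"] * 35 + ["b"] * 5, index=data.index)
    with pytest.raises(ValueError, match="n="):
        invariance_ladder(data, groups)
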