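"""Codon site models: rate matrix, pruning likelihood, fits, LRTs, site posteriors."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gramevol._codons import codon_index, substitution_masks
from gramevol.cli import fit_model_battery
from gramevol.simulate import CodonSimParams, simulate_codon_alignment
from gramevol.sitemodels import (
    CodonLikelihood,
    SiteModelSpec,
    aggregate_omega_stats,
    build_q,
    classify_sites,
    discretize_beta,
    fit,
    lrt,
    summarize_ogc_battery,
    uniform_codon_freqs,
)

PI = uniform_codon_freqs()


# ---------------------------------------------------------------------------
# rate matrix


def test_q_rows_sum_to_zero_and_reversible():
    rm = build_q(2.0, 0.5, PI)
    assert np.abs(rm.Q.sum(axis=1)).max() < 1e-10
    flux = PI[:, None] * rm.Q
    assert np.abs(flux - flux.T).max() < 1e-12


def test_omega_zero_kills_nonsynonymous_rates():
    rm = build_q(2.0, 0.0, PI)
    _, _, nonsyn_ts, nonsyn_tv = substitution_masks()
    assert np.all(rm.Q[nonsyn_ts | nonsyn_tv] == 0.0)


def test_no_multi_nucleotide_rates():
    rm = build_q(2.0, 0.7, PI)
    syn_ts, syn_tv, nonsyn_ts, nonsyn_tv = substitution_masks()
    single = syn_ts | syn_tv | nonsyn_ts | nonsyn_tv
    off_diag = ~np.eye(61, dtype=bool)
    assert np.all(rm.Q[off_diag & ~single] == 0.0)


def test_kappa_one_omega_one_uniform_rates_follow_adjacency():
    rm = build_q(1.0, 1.0, PI)
    syn_ts, syn_tv, nonsyn_ts, nonsyn_tv = substitution_masks()
    allowed = syn_ts | syn_tv | nonsyn_ts | nonsyn_tv
    vals = rm.Q[allowed]
    assert np.allclose(vals, vals[0])


@pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
def test_transition_matrix_is_stochastic(t):
    P = build_q(2.0, 0.5, PI).transition_matrix(t)
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
    assert P.min() > -1e-12


def test_invalid_simplex_rejected():
    with pytest.raises(ValueError):
        build_q(2.0, 0.5, np.ones(61))


# ---------------------------------------------------------------------------
# likelihood


def brute_force_lnl(aln, branch_lengths, kappa, omega, pi):
    """Exhaustive root-state sum for a star tree (independent leaves)."""
    idx = codon_index()
    Ps = {t: build_q(kappa, omega, pi).transition_matrix(t) for t in set(branch_lengths.values())}
    total = 0.0
    for site in range(aln.n_codons):
        s = 0.0
        for r in range(61):
            term = pi[r]
            for taxon in aln.taxa:
                term *= Ps[branch_lengths[taxon]][r, idx[aln.row(taxon)[site]]]
            s += term
        total += math.log(s)
    return total


def brute_force_lnl_internal(aln, kappa, omega, pi, t_leaf, t_internal):
    """4-taxon balanced tree, explicit sum over both internal states."""
    idx = codon_index()
    rm = build_q(kappa, omega, pi)
    Pl = rm.transition_matrix(t_leaf)
    Pi_ = rm.transition_matrix(t_internal)
    total = 0.0
    for site in range(aln.n_codons):
        x = [idx[aln.row(t)[site]] for t in aln.taxa]
        s = 0.0
        for u in range(61):
            left = sum(Pi_[u, v] * Pl[v, x[0]] * Pl[v, x[1]] for v in range(61))
            right = sum(Pi_[u, w] * Pl[w, x[2]] * Pl[w, x[3]] for w in range(61))
            s += pi[u] * left * right
        total += math.log(s)
    return total


def test_pruning_matches_star_tree_oracle():
    tree = "(a:0.2,b:0.3,c:0.1);"
    aln = simulate_codon_alignment(
        CodonSimParams(tree=tree, kappa=2.0, site_classes=[(1.0, 0.5)], n_codons=8, seed=3)
    )
    eng = CodonLikelihood(aln, tree, pi=PI)
    lnl = eng.loglik(SiteModelSpec("M0"), {"omega": 0.5}, kappa=2.0)
    oracle = brute_force_lnl(aln, {"a": 0.2, "b": 0.3, "c": 0.1}, 2.0, 0.5, PI)
    assert lnl == pytest.approx(oracle, abs=1e-8)


def test_pruning_matches_internal_state_sum_oracle():
    tree = "((a:0.15,b:0.15):0.05,(c:0.15,d:0.15):0.05);"
    aln = simulate_codon_alignment(
        CodonSimParams(tree=tree, kappa=1.5, site_classes=[(1.0, 0.3)], n_codons=10, seed=5)
    )
    eng = CodonLikelihood(aln, tree, pi=PI)
    lnl = eng.loglik(SiteModelSpec("M0"), {"omega": 0.3}, kappa=1.5)
    # dendropy roots the 4-taxon newick at the first split: internal edges 0.05+0.05
    oracle = brute_force_lnl_internal(aln, 1.5, 0.3, PI, 0.15, 0.05)
    assert lnl == pytest.approx(oracle, abs=1e-8)


def test_root_placement_irrelevant_by_reversibility(tree4):
    """Pulley principle: rerooting the tree leaves the likelihood unchanged."""
    import dendropy

    aln = simulate_codon_alignment(
        CodonSimParams(tree=tree4, kappa=2.0, site_classes=[(1.0, 0.4)], n_codons=20, seed=2)
    )
    lnl = CodonLikelihood(aln, tree4, pi=PI).loglik(SiteModelSpec("M0"), {"omega": 0.4}, kappa=2.0)
    tree = dendropy.Tree.get(data=tree4, schema="newick")
    leaf_c = [l for l in tree.leaf_node_iter() if l.taxon.label == "c"][0]
    tree.reroot_at_edge(leaf_c.edge, length1=0.1, length2=0.2, update_bipartitions=False)
    lnl2 = CodonLikelihood(aln, tree, pi=PI).loglik(SiteModelSpec("M0"), {"omega": 0.4}, kappa=2.0)
    assert lnl2 == pytest.approx(lnl, abs=1e-8)


def test_taxon_reordering_irrelevant(tree4):
    from gramevol.codon_align import CodonAlignment

    aln = simulate_codon_alignment(
        CodonSimParams(tree=tree4, kappa=2.0, site_classes=[(1.0, 0.4)], n_codons=15, seed=9)
    )
    perm = [2, 0, 3, 1]
    shuffled = CodonAlignment(
        taxa=[aln.taxa[i] for i in perm], codons=[aln.codons[i] for i in perm]
    )
    spec = SiteModelSpec("M0")
    a = CodonLikelihood(aln, tree4, pi=PI).loglik(spec, {"omega": 0.4}, kappa=2.0)
    b = CodonLikelihood(shuffled, tree4, pi=PI).loglik(spec, {"omega": 0.4}, kappa=2.0)
    assert a == pytest.approx(b, abs=1e-9)


def test_zero_branch_limit_gives_stationary_probability():
    """Two identical 1-codon sequences at t -> 0: site likelihood -> pi(codon)."""
    from gramevol.codon_align import CodonAlignment

    aln = CodonAlignment(taxa=["a", "b"], codons=[["ATG"], ["ATG"]])
    eng = CodonLikelihood(aln, "(a:1e-9,b:1e-9);", pi=PI)
    lnl = eng.loglik(SiteModelSpec("M0"), {"omega": 1.0}, kappa=2.0)
    assert lnl == pytest.approx(math.log(PI[codon_index()["ATG"]]), abs=1e-6)


def test_gapped_column_rejected():
    from gramevol.codon_align import CodonAlignment

    aln = CodonAlignment(taxa=["a", "b"], codons=[["---"], ["AAA"]])
    with pytest.raises(ValueError, match="filter"):
        CodonLikelihood(aln, "(a:0.1,b:0.1);", pi=PI)


# ---------------------------------------------------------------------------
# beta discretization


def test_beta_categories_are_equal_probability_medians():
    cats = discretize_beta(2.0, 3.0, 10)
    assert len(cats) == 10 and np.all(np.diff(cats) > 0)
    assert np.all((0 < cats) & (cats < 1))
    # median of each decile: CDF at the category value is (2k+1)/20
    assert stats.beta.cdf(cats, 2.0, 3.0) == pytest.approx((2 * np.arange(10) + 1) / 20)


def test_beta_discretized_mean_converges_to_analytic():
    p, q = 0.7, 2.1
    m10 = discretize_beta(p, q, 10).mean()
    m100 = discretize_beta(p, q, 100).mean()
    exact = p / (p + q)
    assert abs(m100 - exact) < abs(m10 - exact)
    assert m100 == pytest.approx(exact, abs=5e-3)


# ---------------------------------------------------------------------------
# fitting, nesting, LRT


@pytest.fixture(scope="module")
def m0_alignment():
    tree = "((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);"
    aln = simulate_codon_alignment(
        CodonSimParams(tree=tree, kappa=2.0, site_classes=[(1.0, 0.3)], n_codons=150, seed=21)
    )
    return aln, tree


@pytest.fixture(scope="module")
def battery(m0_alignment):
    aln, tree = m0_alignment
    return fit_model_battery(aln, tree, ["M0", "M3", "M7", "M8a", "M8"], beta_categories=5, seed=0)


def test_m0_recovers_simulated_omega(m0_alignment):
    aln, tree = m0_alignment
    f = fit(aln, tree, SiteModelSpec("M0"), n_restarts=1, seed=0)
    assert f.converged
    assert 0.2 <= f.params["omega"] <= 0.4
    assert 1.0 <= f.kappa <= 4.0


def test_nesting_chain_lnl_monotone(battery):
    assert battery["M3"].lnl >= battery["M0"].lnl - 1e-6
    assert battery["M8a"].lnl >= battery["M7"].lnl - 1e-6
    assert battery["M8"].lnl >= battery["M8a"].lnl - 1e-6
    assert battery["M8"].lnl >= battery["M7"].lnl - 1e-6


def test_site_posteriors_sum_to_one(battery):
    for f in battery.values():
        assert np.abs(f.site_posteriors.sum(axis=1) - 1.0).max() < 1e-9


def test_lrt_df_rules(battery):
    assert lrt(battery["M0"], battery["M3"]).df == 4
    assert lrt(battery["M7"], battery["M8"]).df == 2
    assert lrt(battery["M8a"], battery["M8"]).df == 1


def test_lrt_identical_lnl_gives_p_one(battery):
    import copy

    null = copy.copy(battery["M7"])
    alt = copy.copy(battery["M8"])
    alt.lnl = null.lnl
    r = lrt(null, alt)
    assert r.two_delta_lnl == 0.0 and r.p_value == 1.0


def test_lrt_rejects_non_nested(battery):
    with pytest.raises(ValueError, match="not nested"):
        lrt(battery["M3"], battery["M7"])


def test_lrt_small_negative_clamped_large_negative_raises(battery):
    import copy

    null = copy.copy(battery["M7"])
    alt = copy.copy(battery["M8"])
    alt.lnl = null.lnl - 0.004
    with pytest.warns(UserWarning, match="clamped"):
        assert lrt(null, alt).two_delta_lnl == 0.0
    alt.lnl = null.lnl - 1.0
    with pytest.raises(ValueError, match="optimizer failure"):
        lrt(null, alt)


# ---------------------------------------------------------------------------
# site classification


def test_classify_rejects_models_without_positive_class(battery):
    for name in ("M0", "M7", "M8a"):
        with pytest.raises(ValueError, match="omega > 1"):
            classify_sites(battery[name])


def test_no_flags_when_positive_proportion_vanishes(battery):
    """M8 fitted to purifying data drives p1 (or omega_s) to its boundary and
    flags no sites — the all-empty selected-site column."""
    sel = classify_sites(battery["M8"], threshold=0.95)
    m8 = battery["M8"]
    effective_p1 = m8.params["p1"] if m8.params["omega_s"] > 1.0 else 0.0
    if effective_p1 < 0.02:
        assert not sel["selected"].any()


def test_uniform_posteriors_never_exceed_threshold(battery):
    import copy

    f = copy.copy(battery["M8"])
    k = f.site_posteriors.shape[1]
    f.site_posteriors = np.full_like(f.site_posteriors, 1.0 / k)
    sel = classify_sites(f, threshold=0.95)
    assert not sel["selected"].any()


# ---------------------------------------------------------------------------
# battery summary and aggregate statistics


def test_aggregate_omega_statistics_match_reference_values():
    omegas = [0.4033, 0.2076, 0.2758, 0.1082, 0.2206, 0.2023, 0.2902]
    s = aggregate_omega_stats(np.array(omegas))
    assert round(s["mean"], 4) == pytest.approx(0.2440)
    assert round(s["sd"], 4) == pytest.approx(0.0918)
    # t = (mean - 1) / (sd / sqrt(7)) ~ -21.8, hence p far below 0.01
    assert s["t"] == pytest.approx((s["mean"] - 1.0) / (s["sd"] / math.sqrt(7)))
    assert s["t"] == pytest.approx(-21.8, abs=0.1)
    assert s["p"] < 0.01


def test_aggregate_degenerate_when_all_equal():
    s = aggregate_omega_stats(np.array([0.3, 0.3, 0.3]))
    assert s["degenerate"] and math.isnan(s["t"])


def test_summarize_ogc_battery_shapes_report(battery, m0_alignment):
    table, summary = summarize_ogc_battery({"G1": battery, "G2": battery})
    assert set(table["group"]) == {"G1", "G2"}
    assert "2dlnl_m3_vs_m0" in table.columns and "selected_sites" in table.columns
    assert summary["degenerate"]  # identical omegas across the two groups
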