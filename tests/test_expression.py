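"""ddCt expression, ANOVA/Tukey letters, t-tests, haplotype binning and key sites."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gramevol.expression import (
    anova_tukey,
    bin_haplotypes,
    compact_letters,
    delta_delta_ct,
    key_site_report,
    log_fpkm,
    one_sample_t,
)
from gramevol.simulate import QpcrSimConfig, VariantSimConfig, simulate_qpcr, simulate_variants


# ---------------------------------------------------------------------------
# ddCt


def cq_table(rows):
    return pd.DataFrame(rows, columns=["condition", "gene", "replicate", "cq"])


def test_ddct_zero_gives_unit_expression():
    rows = [(c, g, r, 20.0 if g == "ref" else 25.0) for c in ("ctl", "trt") for g in ("ref", "tgt") for r in (1, 2, 3)]
    res = delta_delta_ct(cq_table(rows), "tgt", "ref", "ctl")
    assert np.allclose(res["relative_expression"], 1.0)
    assert res.loc[res["condition"] == "ctl", "ddct"].iloc[0] == 0.0


def test_ddct_minus_two_gives_four():
    rows = [("ctl", "ref", r, 20.0) for r in (1, 2)] + [("ctl", "tgt", r, 25.0) for r in (1, 2)]
    rows += [("trt", "ref", r, 20.0) for r in (1, 2)] + [("trt", "tgt", r, 23.0) for r in (1, 2)]
    res = delta_delta_ct(cq_table(rows), "tgt", "ref", "ctl")
    val = res.loc[res["condition"] == "trt", "relative_expression"].iloc[0]
    assert val == pytest.approx(4.0)


def test_ddct_missing_reference_rejected():
    rows = [("ctl", "tgt", 1, 25.0), ("ctl", "tgt", 2, 25.0)]
    with pytest.raises(ValueError, match="reference"):
        delta_delta_ct(cq_table(rows), "tgt", "ref", "ctl")


def test_ddct_simulator_roundtrip_exact():
    cfg = QpcrSimConfig(
        genes=["g1", "g2"], conditions=["control", "t6", "t12"],
        fold_changes={"control": 1.0, "t6": 4.0, "t12": 0.5}, noise_sd=0.0, seed=1,
    )
    cq = simulate_qpcr(cfg)
    for gene in ("g1", "g2"):
        res = delta_delta_ct(cq, gene, "reference", "control").set_index("condition")
        assert res.loc["t6", "relative_expression"] == pytest.approx(4.0)
        assert res.loc["t12", "relative_expression"] == pytest.approx(0.5)
        assert res.loc["t6", "dct_sd"] == pytest.approx(0.0)


@pytest.mark.parametrize("x,expected", [(0, 0), (1, 1), (7, 3)])
def test_log_fpkm_values(x, expected):
    assert log_fpkm([x])[0] == pytest.approx(expected)


def test_log_fpkm_rejects_negative():
    with pytest.raises(ValueError):
        log_fpkm([-1.0])


# ---------------------------------------------------------------------------
# ANOVA / Tukey / letters


def test_identical_groups_share_letter():
    comp = anova_tukey({"g1": [1.0, 1.0, 1.0], "g2": [1.0, 1.0, 1.0]})
    assert comp.degenerate
    assert comp.letters == {"g1": "a", "g2": "a"}
    assert comp.anova_f == 0.0


def test_strong_separation_gets_distinct_letter(rng):
    groups = {
        "a": rng.normal(0, 1, 20),
        "b": rng.normal(0, 1, 20),
        "c": rng.normal(5, 1, 20),
    }
    comp = anova_tukey(groups)
    assert comp.anova_p < 1e-6
    assert set(comp.letters["a"]) & set(comp.letters["b"])
    assert not set(comp.letters["c"]) & set(comp.letters["a"])
    assert not set(comp.letters["c"]) & set(comp.letters["b"])


def test_letters_consistent_with_tukey_p(rng):
    """Pairs sharing a letter have Tukey p >= alpha; pairs sharing none have
    p < alpha (the compact-letter-display contract)."""
    groups = {
        "a": rng.normal(0.0, 1, 15),
        "b": rng.normal(0.8, 1, 12),
        "c": rng.normal(2.0, 1, 18),
        "d": rng.normal(5.0, 1, 10),
    }
    comp = anova_tukey(groups, alpha=0.05)
    for g1 in groups:
        for g2 in groups:
            if g1 >= g2:
                continue
            share = bool(set(comp.letters[g1]) & set(comp.letters[g2]))
            p = comp.tukey_p.loc[g1, g2]
            assert share == (p >= 0.05), (g1, g2, p, comp.letters)


def test_tukey_pairwise_p_against_permutation_oracle(rng):
    """Tukey p for the extreme pair vs a permutation distribution of the
    studentized range statistic (Monte-Carlo agreement)."""
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(1.0, 1, 10), "c": rng.normal(0.4, 1, 10)}
    comp = anova_tukey(groups)
    p_tukey = comp.tukey_p.loc["a", "b"]

    data = np.concatenate(list(groups.values()))
    labels = np.repeat([0, 1, 2], 10)

    def q_stat(values, labels):
        means = [values[labels == k].mean() for k in range(3)]
        sse = sum(((values[labels == k] - means[k]) ** 2).sum() for k in range(3))
        mse = sse / (30 - 3)
        return (max(means) - min(means)) / math.sqrt(mse / 10)

    observed_pair = abs(groups["a"].mean() - groups["b"].mean()) / math.sqrt(
        (sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / 27) / 10
    )
    perm_rng = np.random.default_rng(0)
    exceed = 0
    n_perm = 3000
    for _ in range(n_perm):
        perm = perm_rng.permutation(labels)
        if q_stat(data, perm) >= observed_pair:
            exceed += 1
    p_perm = exceed / n_perm
    assert abs(p_perm - p_tukey) < 0.08  # Monte-Carlo + studentized-range approximation


def test_anova_validates_group_sizes():
    with pytest.raises(ValueError):
        anova_tukey({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


def test_compact_letters_all_different():
    sig = {frozenset(p): True for p in (("a", "b"), ("a", "c"), ("b", "c"))}
    letters = compact_letters(["a", "b", "c"], sig)
    assert len({letters[g] for g in "abc"}) == 3


# ---------------------------------------------------------------------------
# one-sample t


def test_symmetric_values_give_t_zero():
    t, p = one_sample_t([0.8, 1.2, 0.9, 1.1], mu=1.0)
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_t_test_matches_formula():
    vals = [0.4033, 0.2076, 0.2758, 0.1082, 0.2206, 0.2023, 0.2902]
    t, p = one_sample_t(vals, mu=1.0)
    mean, sd = np.mean(vals), np.std(vals, ddof=1)
    assert t == pytest.approx((mean - 1.0) / (sd / math.sqrt(7)))
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 6))
    assert p < 0.01


def test_t_test_rejects_degenerate_input():
    with pytest.raises(ValueError):
        one_sample_t([1.0], mu=0.0)
    with pytest.raises(ValueError):
        one_sample_t([2.0, 2.0, 2.0], mu=0.0)


# ---------------------------------------------------------------------------
# haplotype binning


def test_all_identical_one_group():
    geno = pd.DataFrame([["A", "C"]] * 5, index=[f"s{i}" for i in range(5)], columns=["x", "y"])
    groups, dropped = bin_haplotypes(geno)
    assert len(groups) == 1 and groups[0].size == 5 and not dropped


def test_singleton_group_retained():
    geno = pd.DataFrame([["A"], ["A"], ["C"]], index=["s0", "s1", "s2"], columns=["x"])
    groups, _ = bin_haplotypes(geno)
    assert [(g.haplotype, g.size) for g in groups] == [("Hap1", 2), ("Hap2", 1)]


def test_groups_ordered_by_size_then_first_seen():
    geno = pd.DataFrame(
        [["C"], ["A"], ["A"], ["G"]], index=["s0", "s1", "s2", "s3"], columns=["x"]
    )
    groups, _ = bin_haplotypes(geno)
    assert [g.alleles[0] for g in groups] == ["A", "C", "G"]


def test_missing_samples_dropped_and_conserved():
    geno = pd.DataFrame(
        [["A", "A"], ["A", "."], ["C", "C"]], index=["s0", "s1", "s2"], columns=["x", "y"]
    )
    groups, dropped = bin_haplotypes(geno)
    assert dropped == ["s1"]
    assert sum(g.size for g in groups) + len(dropped) == 3


def test_impute_major_policy():
    geno = pd.DataFrame(
        [["A"], ["A"], ["."], ["C"]], index=[f"s{i}" for i in range(4)], columns=["x"]
    )
    groups, dropped = bin_haplotypes(geno, missing_policy="impute_major")
    assert not dropped and groups[0].size == 3


def test_heterozygous_calls_treated_as_missing():
    geno = pd.DataFrame(
        [["A/A"], ["A/C"], ["C|C"]], index=["s0", "s1", "s2"], columns=["x"]
    )
    groups, dropped = bin_haplotypes(geno)
    assert dropped == ["s1"]
    assert sorted(g.alleles[0] for g in groups) == ["A", "C"]


def test_binning_invariant_to_sample_and_site_order(rng):
    cfg = VariantSimConfig(
        n_sites=8,
        haplotype_defs=[("AAAAAAAA", 6), ("CCCCCCCC", 3), ("GGGGGGGG", 2)],
        phenotype_means=[0, 1, 2], seed=1,
    )
    geno, _ = simulate_variants(cfg)
    base, _ = bin_haplotypes(geno)
    shuffled = geno.sample(frac=1, random_state=5)[list(rng.permutation(geno.columns))]
    perm, _ = bin_haplotypes(shuffled)
    assert [(g.size, set(g.members)) for g in base] == [(g.size, set(g.members)) for g in perm]


def test_planted_reference_design_recovered():
    """Five haplotypes with the reference panel's group sizes re-bin exactly."""
    sizes = (189, 43, 6, 4, 3)
    strings = ["A" * 50, "C" * 50, "G" * 50, "T" * 50, "AC" * 25]
    cfg = VariantSimConfig(
        n_sites=50, haplotype_defs=list(zip(strings, sizes)),
        phenotype_means=[1, 2, 3, 4, 5], seed=2,
    )
    geno, _ = simulate_variants(cfg)
    groups, dropped = bin_haplotypes(geno)
    assert not dropped
    assert [g.size for g in groups] == sorted(sizes, reverse=True)
    assert sum(g.size for g in groups) == 245


# ---------------------------------------------------------------------------
# key sites


def test_key_sites_unique_to_focal():
    geno = pd.DataFrame(
        {
            "s1": list("ACGT"), "s2": list("ACGT"), "s3": list("TCGA"),
        }
    ).T
    geno.columns = [f"site_{i}" for i in range(1, 5)]
    groups, _ = bin_haplotypes(geno)
    focal = [g.haplotype for g in groups if g.size == 1][0]
    report = key_site_report(groups, focal)
    assert list(report["site"]) == ["site_1", "site_4"]


def test_focal_duplicate_warns_and_empty():
    geno = pd.DataFrame([["A"], ["A"], ["A"]], index=["s0", "s1", "s2"], columns=["x"])
    groups, _ = bin_haplotypes(geno)
    with pytest.raises(ValueError):
        key_site_report(groups, "Hap1")


def test_coding_substitution_reports_amino_acid_change():
    """A planted G->A at the second position of an AGG codon: Arg -> Lys."""
    cds = "ATG" + "AGG" + "TTT"
    geno = pd.DataFrame(
        [["G"], ["G"], ["A"]], index=["s0", "s1", "s2"], columns=["v1"]
    )
    groups, _ = bin_haplotypes(geno)
    focal = [g.haplotype for g in groups if g.alleles == ("A",)][0]
    report = key_site_report(groups, focal, site_positions=[5], cds=cds)
    assert report.iloc[0]["aa_change"] == "Arg->Lys"


def test_promoter_positions_have_no_aa_change():
    geno = pd.DataFrame([["C"], ["T"]], index=["s0", "s1"], columns=["v1"])
    groups, _ = bin_haplotypes(geno)
    report = key_site_report(groups, "Hap1", site_positions=[-1869], cds="ATGAAA")
    assert report.iloc[0]["aa_change"] is None
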