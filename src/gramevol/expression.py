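"""qPCR relative expression, group comparisons, and haplotype association.

The 2^-ddCt method assumes doubling per cycle: dCt is the target-minus-
reference Cq difference per condition, ddCt subtracts the calibrator
condition's dCt, and relative expression is 2^-ddCt. Group comparisons use
one-way ANOVA with Tukey HSD (Tukey–Kramer for unequal n) and a compact
letter display. Haplotype binning groups samples by exact allele-string
equality over the variant sites (complete-case by default, matching the
selfing-japonica assumption: heterozygous calls are treated as missing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._codons import translate_codon
from .simulate import MISSING_ALLELE

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}


# ---------------------------------------------------------------------------
# qPCR


def delta_delta_ct(
    cq: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression of ``target`` per condition.

    ``cq`` is long-format with columns condition, gene, replicate, cq.
    dCt replicates are paired by replicate id (target minus reference);
    the replicate SD of dCt is reported (NaN when fewer than 2 pairs).
    """
    for col in ("condition", "gene", "replicate", "cq"):
        if col not in cq.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    conditions = list(dict.fromkeys(cq["condition"]))
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    dct_by_cond = {}
    for cond in conditions:
        sub = cq[cq["condition"] == cond]
        tgt = sub[sub["gene"] == target].set_index("replicate")["cq"]
        ref = sub[sub["gene"] == reference].set_index("replicate")["cq"]
        if ref.empty:
            raise ValueError(f"reference gene {reference!r} missing in condition {cond!r}")
        if tgt.empty:
            raise ValueError(f"target gene {target!r} missing in condition {cond!r}")
        paired = pd.DataFrame({"t": tgt, "r": ref}).dropna()
        dct = paired["t"] - paired["r"]
        dct_by_cond[cond] = dct
    cal_dct = float(dct_by_cond[calibrator].mean())
    for cond in conditions:
        dct = dct_by_cond[cond]
        ddct = float(dct.mean()) - cal_dct
        sd = float(dct.std(ddof=1)) if len(dct) >= 2 else math.nan
        rows.append(
            {
                "condition": cond,
                "gene": target,
                "dct": float(dct.mean()),
                "ddct": ddct,
                "relative_expression": 2.0 ** (-ddct),
                "dct_sd": sd,
                "n_replicates": len(dct),
            }
        )
    return pd.DataFrame(rows)


def log_fpkm(values):
    """log2(FPKM + 1) normalization; rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative expression values")
    return np.log2(arr + 1.0)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letters


@dataclass
class PhenoComparison:
    phenotype: str
    group_stats: pd.DataFrame    # mean/sd/n per group
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame        # symmetric pairwise p-value matrix
    letters: dict[str, str]
    degenerate: bool = False     # all groups constant and equal


def compact_letters(groups: list[str], significant: dict[frozenset, bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    non-significant pair shares at least one letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not significant.get(frozenset((a, b)), False):
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for cand in (sa, sb):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # absorb duplicates/subsets, keep deterministic order by first group
    letter_sets = [s for s in letter_sets if s]
    letter_sets.sort(key=lambda s: [groups.index(g) for g in sorted(s, key=groups.index)])
    out = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05, phenotype: str = "phenotype") -> PhenoComparison:
    """One-way ANOVA with Tukey HSD pairwise tests and compact letters.

    Requires at least 2 groups with n >= 2 each. Unequal group sizes use the
    Tukey–Kramer correction (as implemented in statsmodels). When every
    group is constant and identical the comparison is flagged degenerate.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs n >= 2")
    values = np.concatenate([arrays[g] for g in names])
    labels = np.concatenate([[g] * len(arrays[g]) for g in names])
    stats_df = pd.DataFrame(
        {
            "group": names,
            "n": [len(arrays[g]) for g in names],
            "mean": [float(arrays[g].mean()) for g in names],
            "sd": [float(arrays[g].std(ddof=1)) for g in names],
        }
    ).set_index("group")
    pooled_var = float(np.concatenate([arrays[g] - arrays[g].mean() for g in names]).var(ddof=0))
    degenerate = pooled_var == 0.0
    if degenerate and len({round(m, 12) for m in stats_df["mean"]}) == 1:
        tukey_p = pd.DataFrame(1.0, index=names, columns=names)
        letters = {g: "a" for g in names}
        return PhenoComparison(phenotype, stats_df, 0.0, 1.0, tukey_p, letters, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*[arrays[g] for g in names])
    if math.isnan(f):
        f, p = 0.0, 1.0
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_p = pd.DataFrame(1.0, index=names, columns=names)
    significant: dict[frozenset, bool] = {}
    table = np.asarray(res._results_table.data[1:], dtype=object)
    for row in table:
        g1, g2, pval, reject = str(row[0]), str(row[1]), float(row[3]), bool(row[6])
        tukey_p.loc[g1, g2] = tukey_p.loc[g2, g1] = pval
        significant[frozenset((g1, g2))] = reject
    letters = compact_letters(names, significant)
    return PhenoComparison(phenotype, stats_df, float(f), float(p), tukey_p, letters)


def one_sample_t(values, mu: float) -> tuple[float, float]:
    """Two-sided one-sample t-test: t = (mean - mu) / (sd / sqrt(n))."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if arr.std(ddof=1) == 0.0:
        raise ValueError("zero standard deviation")
    t, p = stats.ttest_1samp(arr, popmean=mu)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class HaplotypeGroup:
    haplotype: str
    alleles: tuple[str, ...]
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def bin_haplotypes(
    genotypes: pd.DataFrame,
    min_group_size: int = 1,
    missing_policy: str = "drop",
    sites: list[str] | None = None,
    heterozygous_as_missing: bool = True,
) -> tuple[list[HaplotypeGroup], list[str]]:
    """Group samples by exact allele-string equality over the retained sites.

    ``genotypes`` is samples x sites; ``sites`` restricts to a subset of
    columns. Missing calls (the ``.`` sentinel) drop the sample under the
    default policy or are imputed to the site's major allele under
    ``impute_major``. Heterozygous calls (containing ``/`` or ``|``) are
    treated as missing by default. Groups are ordered by size descending,
    ties by first appearance, and named Hap1, Hap2, ...; returns the groups
    (size >= min_group_size) and the list of dropped samples.
    """
    if genotypes.empty:
        raise ValueError("empty genotype table")
    geno = genotypes[sites] if sites is not None else genotypes
    geno = geno.astype(str)
    if heterozygous_as_missing:
        het = geno.apply(lambda col: col.str.contains(r"[/|]") & (col.str.split(r"[/|]").str[0] != col.str.split(r"[/|]").str[1]))
        geno = geno.mask(het, MISSING_ALLELE)
        geno = geno.apply(lambda col: col.str.split(r"[/|]").str[0])
    has_missing = (geno == MISSING_ALLELE).any(axis=1)
    dropped: list[str] = []
    if missing_policy == "drop":
        dropped = list(geno.index[has_missing])
        geno = geno[~has_missing]
    elif missing_policy == "impute_major":
        for col in geno.columns:
            observed = geno.loc[geno[col] != MISSING_ALLELE, col]
            if observed.empty:
                raise ValueError(f"site {col!r} entirely missing")
            major = observed.mode().iloc[0]
            geno.loc[geno[col] == MISSING_ALLELE, col] = major
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    order: dict[tuple, int] = {}
    members: dict[tuple, list[str]] = {}
    for sample, row in zip(geno.index, geno.itertuples(index=False)):
        key = tuple(row)
        if key not in order:
            order[key] = len(order)
        members.setdefault(key, []).append(sample)
    ranked = sorted(members, key=lambda k: (-len(members[k]), order[k]))
    groups = [
        HaplotypeGroup(haplotype=f"Hap{i + 1}", alleles=key, members=members[key])
        for i, key in enumerate(ranked)
        if len(members[key]) >= min_group_size
    ]
    return groups, dropped


def key_site_report(
    groups: list[HaplotypeGroup],
    focal: str,
    site_names: list[str] | None = None,
    site_positions: list[int] | None = None,
    cds: str | None = None,
    genetic_code: int = 1,
) -> pd.DataFrame:
    """Sites where the focal haplotype's allele is unique among all groups.

    ``site_positions`` follow the promoter convention: negative positions
    are upstream of the ATG, position +1 is the A of ATG. For coding SNP
    positions (>= 1) with a ``cds`` supplied, the induced amino-acid change
    is reported under the standard genetic code. A focal haplotype that is
    identical to another group at every site yields an empty report with a
    duplicate-haplotype warning.
    """
    by_name = {g.haplotype: g for g in groups}
    if focal not in by_name:
        raise KeyError(f"focal haplotype {focal!r} not found")
    fg = by_name[focal]
    others = [g for g in groups if g.haplotype != focal]
    if not others:
        raise ValueError("need at least 2 haplotype groups")
    if any(g.alleles == fg.alleles for g in others):
        warnings.warn(f"{focal} duplicates another haplotype's allele string", stacklevel=2)
    n_sites = len(fg.alleles)
    names = site_names or [f"site_{i + 1}" for i in range(n_sites)]
    rows = []
    for i in range(n_sites):
        allele = fg.alleles[i]
        if all(g.alleles[i] != allele for g in others):
            row = {
                "site": names[i],
                "position": site_positions[i] if site_positions else None,
                "focal_allele": allele,
                "other_alleles": ",".join(sorted({g.alleles[i] for g in others})),
                "aa_change": None,
            }
            pos = site_positions[i] if site_positions else None
            if cds is not None and pos is not None and pos >= 1 and len(allele) == 1:
                row["aa_change"] = _aa_change(cds, pos, allele, genetic_code)
            rows.append(row)
    return pd.DataFrame(rows, columns=["site", "position", "focal_allele", "other_alleles", "aa_change"])


def _aa_change(cds: str, position: int, alt: str, genetic_code: int) -> str | None:
    cds = cds.upper().replace("U", "T")
    idx = position - 1
    if idx >= len(cds):
        return None
    codon_start = (idx // 3) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return None
    offset = idx - codon_start
    alt_codon = ref_codon[:offset] + alt.upper() + ref_codon[offset + 1 :]
    ref_aa = translate_codon(ref_codon, genetic_code) if ref_codon not in ("TAA", "TAG", "TGA") else "*"
    alt_aa = translate_codon(alt_codon, genetic_code) if alt_codon not in ("TAA", "TAG", "TGA") else "*"
    if ref_aa == alt_aa:
        return f"synonymous ({AA3[ref_aa]})"
    return f"{AA3[ref_aa]}->{AA3[alt_aa]}"
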