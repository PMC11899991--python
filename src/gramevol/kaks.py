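"""Pairwise Ka/Ks by Nei–Gojobori (1986) counting with Jukes–Cantor correction.

Sites are counted fractionally per codon (averaged over the two sequences);
differences are averaged with equal weight over all minimal mutational
pathways between differing codons, excluding pathways through stop codons.
A molecular-clock conversion of Ks into divergence time is provided
(T = Ks / (2 * rate), with the grass-standard synonymous rate
1.5e-8 substitutions/site/year by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._codons import codon_index, ng86_pathway_tables, ng86_site_fractions, stop_codons
from .codon_align import GAP_CODON, CodonAlignment

#: default synonymous-substitution clock, substitutions per site per year
DEFAULT_CLOCK_RATE = 1.5e-8


@dataclass
class PairwiseKaKs:
    """NG86 estimates for one sequence pair.

    ``ka``/``ks`` are substitutions per nonsynonymous/synonymous site after
    Jukes–Cantor correction; ``ratio`` is NaN with ``undefined_ratio`` set
    when ks = 0, and ``saturated`` flags p >= 3/4 where the correction is
    undefined (the corresponding distance is NaN).
    """

    ka: float
    ks: float
    ratio: float
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    n_codons: int
    undefined_ratio: bool = False
    saturated: bool = False


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _clean_pair(a: str, b: str, code_id: int) -> tuple[list[str], list[str]]:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    kept_a, kept_b = [], []
    stops = stop_codons(code_id)
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if set(ca) - set("ACGT") or set(cb) - set("ACGT"):
            continue  # pairwise deletion of ambiguous codons
        if ca in stops or cb in stops:
            raise ValueError(f"stop codon at codon {i // 3 + 1}")
        kept_a.append(ca)
        kept_b.append(cb)
    return kept_a, kept_b


def ng86(seq_a: str, seq_b: str, genetic_code: int = 1) -> PairwiseKaKs:
    """NG86 Ka, Ks and their ratio for two in-frame codon sequences.

    Codons containing gaps or ambiguity in either sequence are dropped
    pairwise before counting.
    """
    codons_a, codons_b = _clean_pair(seq_a, seq_b, genetic_code)
    if not codons_a:
        raise ValueError("no comparable codons after pairwise deletion")
    idx = codon_index(genetic_code)
    frac = ng86_site_fractions(genetic_code)
    sd_tab, nd_tab = ng86_pathway_tables(genetic_code)
    ia = np.array([idx[c] for c in codons_a])
    ib = np.array([idx[c] for c in codons_b])
    s_sites = float((frac[ia] + frac[ib]).sum() / 2.0)
    n_sites = 3.0 * len(codons_a) - s_sites
    s_diffs = float(sd_tab[ia, ib].sum())
    n_diffs = float(nd_tab[ia, ib].sum())
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    undefined = (not saturated) and ks == 0.0
    ratio = math.nan if (saturated or undefined) else ka / ks
    return PairwiseKaKs(
        ka=ka,
        ks=ks,
        ratio=ratio,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        n_codons=len(codons_a),
        undefined_ratio=undefined,
        saturated=saturated,
    )


def pooled_ng86(aln: CodonAlignment) -> PairwiseKaKs:
    """Pooled NG86 over all sequence pairs of an alignment.

    Site and difference counts are summed across pairs before the distance
    correction; used for the neutrality diagnostics on simulated data.
    """
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    n_codons = 0
    for a, b in combinations(aln.taxa, 2):
        r = ng86(aln.sequence(a), aln.sequence(b), aln.genetic_code)
        s_sites += r.s_sites
        n_sites += r.n_sites
        s_diffs += r.s_diffs
        n_diffs += r.n_diffs
        n_codons += r.n_codons
    ks = _jc_correct(s_diffs / s_sites)
    ka = _jc_correct(n_diffs / n_sites)
    saturated = math.isnan(ks) or math.isnan(ka)
    undefined = (not saturated) and ks == 0.0
    return PairwiseKaKs(
        ka=ka,
        ks=ks,
        ratio=math.nan if (saturated or undefined) else ka / ks,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        n_codons=n_codons,
        undefined_ratio=undefined,
        saturated=saturated,
    )


def divergence_time(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Divergence time in million years: T = Ks / (2 * rate) * 1e-6."""
    if ks < 0:
        raise ValueError("negative Ks")
    return ks / (2.0 * rate) * 1e-6


def recompute_pair_table(table: pd.DataFrame, rate: float = DEFAULT_CLOCK_RATE) -> pd.DataFrame:
    """Recompute ratio and MYA columns from a (pair, Ka, Ks) table.

    Adds ``ratio`` (Ka/Ks, 4 dp), ``mya`` (2 dp) and ``positive_selection``
    (ratio > 1) columns; input needs ``ka`` and ``ks`` columns.
    """
    out = table.copy()
    out["ratio"] = (out["ka"] / out["ks"]).round(4)
    out["mya"] = out["ks"].map(lambda ks: round(divergence_time(ks, rate), 2))
    out["positive_selection"] = out["ratio"] > 1.0
    return out


def kaks_table(aln: CodonAlignment, pairs: list[tuple[str, str]], rate: float = DEFAULT_CLOCK_RATE) -> pd.DataFrame:
    """NG86 table for named pairs of an alignment (Seq_1, Seq_2, Ka, Ks, Ka/Ks, MYA)."""
    rows = []
    for a, b in pairs:
        r = ng86(aln.sequence(a), aln.sequence(b), aln.genetic_code)
        rows.append(
            {
                "seq_1": a,
                "seq_2": b,
                "ka": r.ka,
                "ks": r.ks,
                "ratio": r.ratio,
                "mya": math.nan if math.isnan(r.ks) else divergence_time(r.ks, rate),
                "saturated": r.saturated,
            }
        )
    return pd.DataFrame(rows)
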