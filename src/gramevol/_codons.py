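"""Shared genetic-code tables for the 61-state sense-codon space.

The standard nuclear code is the default throughout (all six grass genomes
are nuclear plant genes); an alternative ``Bio.Data.CodonTable`` id can be
injected where the public APIs expose a ``genetic_code`` argument.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def _table(code_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


@lru_cache(maxsize=None)
def sense_codons(code_id: int = 1) -> tuple[str, ...]:
    """Sense codons in TCAG order (the conventional 61 for the standard code)."""
    stops = set(_table(code_id).stop_codons)
    return tuple(
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if a + b + c not in stops
    )


@lru_cache(maxsize=None)
def codon_index(code_id: int = 1) -> dict[str, int]:
    return {c: i for i, c in enumerate(sense_codons(code_id))}


@lru_cache(maxsize=None)
def stop_codons(code_id: int = 1) -> frozenset[str]:
    return frozenset(_table(code_id).stop_codons)


def translate_codon(codon: str, code_id: int = 1) -> str:
    """One-letter amino acid for a sense codon, ``*`` for a stop."""
    if codon in stop_codons(code_id):
        return "*"
    return _table(code_id).forward_table[codon]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T single-nucleotide exchange."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@lru_cache(maxsize=None)
def substitution_masks(code_id: int = 1):
    """Boolean 61x61 masks over single-nucleotide codon changes.

    Returns (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv); multi-nucleotide changes
    are False everywhere (they are instantaneous-rate zeros in the model).
    """
    codons = sense_codons(code_id)
    n = len(codons)
    syn_ts = np.zeros((n, n), dtype=bool)
    syn_tv = np.zeros((n, n), dtype=bool)
    nonsyn_ts = np.zeros((n, n), dtype=bool)
    nonsyn_tv = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ts = is_transition(ci[k], cj[k])
            syn = translate_codon(ci, code_id) == translate_codon(cj, code_id)
            if syn and ts:
                syn_ts[i, j] = True
            elif syn:
                syn_tv[i, j] = True
            elif ts:
                nonsyn_ts[i, j] = True
            else:
                nonsyn_tv[i, j] = True
    return syn_ts, syn_tv, nonsyn_ts, nonsyn_tv


@lru_cache(maxsize=None)
def ng86_site_fractions(code_id: int = 1) -> np.ndarray:
    """Synonymous site count per sense codon (NG86 counting).

    Each codon position is one site, split between synonymous and
    nonsynonymous in proportion to the single-base changes at that position
    that do not create a stop codon (nonsense mutations are disregarded, the
    classic NG86 convention). The synonymous and nonsynonymous site counts
    of a codon therefore always sum to exactly 3.
    """
    out = np.zeros(len(sense_codons(code_id)))
    for i, codon in enumerate(sense_codons(code_id)):
        s = 0.0
        aa = translate_codon(codon, code_id)
        for pos in range(3):
            syn = viable = 0
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1 :]
                if mutant in stop_codons(code_id):
                    continue
                viable += 1
                if translate_codon(mutant, code_id) == aa:
                    syn += 1
            if viable:
                s += syn / viable
        out[i] = s
    return out


def _pathway_steps(a: str, b: str, code_id: int):
    """(syn, nonsyn) step counts averaged over stop-free minimal pathways.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded (classic NG86 convention). If every
    pathway is blocked, all pathways are used instead so the difference count
    is never silently dropped.
    """
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    stops = stop_codons(code_id)
    paths = []
    for order in permutations(diffs):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in stops:
                blocked = True
            if translate_codon(cur, code_id) == translate_codon(nxt, code_id):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    open_paths = [(s, n) for blocked, s, n in paths if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in open_paths) / len(open_paths)
    nonsyn = sum(n for _, n in open_paths) / len(open_paths)
    return syn, nonsyn


@lru_cache(maxsize=None)
def ng86_pathway_tables(code_id: int = 1):
    """61x61 tables of pathway-averaged (synonymous, nonsynonymous) differences."""
    codons = sense_codons(code_id)
    n = len(codons)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i < j:
                s, ns = _pathway_steps(ci, cj, code_id)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = ns
    return sd, nd
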