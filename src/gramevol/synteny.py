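"""Tandem/segmental duplication classification via gene order and collinearity.

A homolog pair is *tandem* when both genes sit on one chromosome within a
small number of intervening genes (default 1, the adjacency-style rule);
overlapping tandem pairs merge into arrays, and an array of k genes counts
as one tandem *event*. A pair is *segmental* when it anchors a collinear
block: a chain of homolog anchor pairs whose order indices increase on the
first chromosome and are monotone (increasing or decreasing, allowing
inversions) on the second, with order-index gaps bounded on both sides
(MCScanX-style defaults: at least 5 anchors, gaps of at most 25 genes).
Everything operates on order indices; base-pair distances are not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass
class CollinearBlock:
    chromosome_a: str
    chromosome_b: str
    anchors: list[tuple[str, str]]  # ordered homolog pairs
    orientation: int  # +1 increasing on B, -1 decreasing

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def rank_loci(annotation: pd.DataFrame) -> pd.DataFrame:
    """Add per-chromosome ``order_index`` (rank by start) to an annotation.

    Expects columns gene_id, chromosome, start, end (1-based inclusive).
    """
    ann = annotation.copy()
    if (ann["start"] > ann["end"]).any():
        raise ValueError("locus with start > end")
    ann["order_index"] = ann.groupby("chromosome")["start"].rank(method="first").astype(int)
    if ann.duplicated("gene_id").any():
        raise ValueError("duplicate gene ids in annotation")
    return ann


def _locus_map(loci: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {r.gene_id: (r.chromosome, r.order_index) for r in loci.itertuples()}


def detect_tandem(
    loci: pd.DataFrame,
    homolog_pairs: list[tuple[str, str]],
    max_intervening: int = 1,
) -> tuple[list[tuple[str, str]], list[list[str]]]:
    """Tandem pairs and their merged arrays.

    A pair is tandem iff both genes share a chromosome and differ by at most
    ``max_intervening + 1`` in order index. Pairs sharing genes merge into
    arrays (connected components), each array being one duplication event.
    """
    pos = _locus_map(loci)
    calls = []
    for a, b in homolog_pairs:
        for g in (a, b):
            if g not in pos:
                raise KeyError(f"unknown gene id {g!r}")
        (ca, ia), (cb, ib) = pos[a], pos[b]
        if a != b and ca == cb and abs(ia - ib) <= max_intervening + 1:
            calls.append((a, b))
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in calls:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for g in parent:
        groups.setdefault(find(g), []).append(g)
    arrays = sorted(
        (sorted(members, key=lambda g: pos[g][1]) for members in groups.values()),
        key=lambda arr: (pos[arr[0]][0], pos[arr[0]][1]),
    )
    return calls, arrays


def chain_collinear(
    homolog_pairs: list[tuple[str, str]],
    loci: pd.DataFrame,
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Dynamic-programming anchor chaining into collinear blocks.

    Anchors on each chromosome pair are chained greedily by best DP chain
    (ties broken toward the lowest first-chromosome order), used anchors
    removed, repeating until no chain reaches ``min_anchors``. Both
    orientations are attempted; each anchor belongs to at most one block.
    """
    pos = _locus_map(loci)
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in homolog_pairs:
        if a not in pos or b not in pos:
            raise KeyError(f"unknown gene id in pair ({a}, {b})")
        (ca, ia), (cb, ib) = pos[a], pos[b]
        if ca == cb and a == b:
            continue
        key = (ca, cb) if ca <= cb else (cb, ca)
        if key == (ca, cb):
            by_chrom_pair.setdefault(key, []).append((ia, ib, a, b))
        else:
            by_chrom_pair.setdefault(key, []).append((ib, ia, b, a))
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_chrom_pair.items()):
        pool = sorted(set(anchors))
        while True:
            best_chain, best_orient = _best_chain(pool, max_gap)
            if best_chain is None or len(best_chain) < min_anchors:
                break
            blocks.append(
                CollinearBlock(
                    chromosome_a=ca,
                    chromosome_b=cb,
                    anchors=[(a, b) for _, _, a, b in best_chain],
                    orientation=best_orient,
                )
            )
            used = set(best_chain)
            pool = [x for x in pool if x not in used]
    return blocks


def _best_chain(anchors: list[tuple[int, int, str, str]], max_gap: int):
    """Best chain over anchors for either orientation; deterministic ties."""
    best, best_orient = None, 0
    for orient in (1, -1):
        pts = sorted(anchors, key=lambda x: (x[0], orient * x[1]))
        n = len(pts)
        if n == 0:
            continue
        score = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                da = pts[i][0] - pts[j][0]
                db = orient * (pts[i][1] - pts[j][1])
                if 0 < da <= max_gap + 1 and 0 < db <= max_gap + 1:
                    if score[j] + 1 > score[i]:
                        score[i] = score[j] + 1
                        prev[i] = j
        i_best = max(range(n), key=lambda i: (score[i], -pts[i][0]))
        chain = []
        i = i_best
        while i >= 0:
            chain.append(pts[i])
            i = prev[i]
        chain.reverse()
        if best is None or len(chain) > len(best):
            best, best_orient = chain, orient
    return best, best_orient


def classify_duplications(
    family_pairs: list[tuple[str, str]],
    tandem_calls: list[tuple[str, str]],
    blocks: list[CollinearBlock],
) -> pd.DataFrame:
    """tandem > segmental > dispersed classification of family pairs."""
    tandem = {frozenset(p) for p in tandem_calls}
    anchored = {frozenset(p) for blk in blocks for p in blk.anchors}
    rows = []
    for a, b in family_pairs:
        key = frozenset((a, b))
        if key in tandem:
            cls = "tandem"
        elif key in anchored:
            cls = "segmental"
        else:
            cls = "dispersed"
        rows.append({"gene_a": a, "gene_b": b, "class": cls})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])


def aggregate_counts(
    segmental_pairs: dict[str, list[tuple[str, str]]],
    tandem_events: dict[str, list[list[str]]],
) -> pd.DataFrame:
    """Per-species and total duplication bookkeeping.

    Segmental duplications are counted as *pairs*; tandem duplications as
    *events* (an array of k genes is one event).
    """
    species = sorted(set(segmental_pairs) | set(tandem_events))
    rows = [
        {
            "species": sp,
            "segmental_pairs": len(segmental_pairs.get(sp, [])),
            "tandem_events": len(tandem_events.get(sp, [])),
        }
        for sp in species
    ]
    out = pd.DataFrame(rows, columns=["species", "segmental_pairs", "tandem_events"])
    total = {
        "species": "total",
        "segmental_pairs": int(out["segmental_pairs"].sum()),
        "tandem_events": int(out["tandem_events"].sum()),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def cross_species_pairs(
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
    homolog_pairs: list[tuple[str, str]],
    family_ids: set[str] | None = None,
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[tuple[str, str]]:
    """Family homolog pairs anchoring accepted blocks between two genomes.

    Blocks are chained from the full homolog-pair set; the returned pairs
    are those anchors whose genes belong to ``family_ids`` families (all
    pairs if None). Gene ids must be disjoint between the two genomes.
    """
    loci = rank_loci(pd.concat([annotation_a, annotation_b], ignore_index=True))
    chroms_a = set(annotation_a["chromosome"])
    blocks = [
        blk
        for blk in chain_collinear(homolog_pairs, loci, min_anchors, max_gap)
        if (blk.chromosome_a in chroms_a) != (blk.chromosome_b in chroms_a)
    ]
    fam_of = dict(zip(loci["gene_id"], loci.get("family", pd.Series(dtype=str))))
    out = []
    for blk in blocks:
        for a, b in blk.anchors:
            if family_ids is None or (fam_of.get(a) in family_ids or fam_of.get(b) in family_ids):
                out.append((a, b))
    return sorted(set(map(tuple, (sorted(p) for p in out))))
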