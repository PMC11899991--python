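"""Neighbor-joining trees, bootstrap supports, and orthologous gene clusters.

Distances are p, Poisson-corrected (-ln(1-p), the default) or gamma-
corrected protein distances with pairwise deletion of gapped columns.
NJ is the Saitou–Nei agglomeration with the standard Q criterion,
deterministic lexicographic tie-breaking, and negative branch lengths
clamped to zero. Orthologous gene clusters (OGCs) are read off a rooted
gene tree with the species-overlap rule: an internal node is a duplication
iff its children's species sets intersect; OGC roots are the first
non-duplication nodes below an all-duplication ancestry, so each OGC
stands for one gene in the species' common ancestor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# distances


def protein_distance(
    aligned: list[tuple[str, str]],
    model: str = "poisson",
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Pairwise distance matrix from an aligned protein set.

    ``p`` is the mismatch proportion over columns where both rows are
    non-gap; ``poisson`` applies -ln(1-p); ``gamma`` applies
    alpha*((1-p)^(-1/alpha) - 1). Saturated pairs (p = 1 under a corrected
    model) get infinite distance with a warning.
    """
    names = [n for n, _ in aligned]
    seqs = [s.upper() for _, s in aligned]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("ragged alignment")
    arr = np.array([list(s) for s in seqs])
    nongap = arr != "-"
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            if not both.any():
                raise ValueError(f"{names[i]}/{names[j]}: no comparable columns")
            p = float(((arr[i] != arr[j]) & both).sum() / both.sum())
            if model == "p":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    warnings.warn(f"{names[i]}/{names[j]}: saturated (p=1)", stacklevel=2)
                    d = math.inf
                else:
                    d = -math.log1p(-p)
            elif model == "gamma":
                if p >= 1.0:
                    warnings.warn(f"{names[i]}/{names[j]}: saturated (p=1)", stacklevel=2)
                    d = math.inf
                else:
                    d = alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
            else:
                raise ValueError(f"unknown model {model!r}")
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbor joining


def nj(matrix: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining of a symmetric distance matrix.

    Ties in the Q criterion break toward the lexicographically smallest
    taxon-name pair; negative branch-length estimates are clamped to 0 with
    a warning. Returns an unrooted dendropy tree.
    """
    names = list(matrix.index)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    D = {a: {b: float(matrix.at[a, b]) for b in names} for a in names}
    newick = {a: a for a in names}
    active = list(names)
    clamped = False
    k = 0
    while len(active) > 3:
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        n_act = len(active)
        best, best_q = None, math.inf
        for a, b in ((a, b) for i, a in enumerate(active) for b in active[i + 1 :]):
            q = (n_act - 2) * D[a][b] - r[a] - r[b]
            key = tuple(sorted((a, b)))
            if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and key < tuple(sorted(best))):
                best, best_q = (a, b), q
        a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2.0 * (n_act - 2))
        lb = D[a][b] - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"__node{k}"
        k += 1
        newick[new] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = D[c][new] = max(d, 0.0)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = sorted(active)
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    if min(la, lb, lc) < 0:
        clamped = True
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative branch length estimate(s) clamped to 0", stacklevel=2)
    text = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    return dendropy.Tree.get(data=text, schema="newick")


def _bipartitions(tree: dendropy.Tree, taxa: set[str]) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree as smaller-side leaf sets."""
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(taxa - side)
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap(
    aligned: list[tuple[str, str]],
    b: int = 1000,
    seed: int = 0,
    model: str = "poisson",
    alpha: float = 1.0,
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports on internal nodes.

    Replicate r uses its own child generator seeded from (seed, r) so that
    supports do not depend on taxon order. Supports (percent of replicates
    containing each internal bipartition) are stored as internal node labels
    and in ``node.support``.
    """
    if b < 1:
        raise ValueError("need at least one replicate")
    n_cols = len(aligned[0][1])
    if n_cols < 2:
        raise ValueError("alignment needs at least 2 columns")
    tree = nj(protein_distance(aligned, model, alpha))
    taxa = {n for n, _ in aligned}
    counts: dict[frozenset[str], int] = {}
    for r in range(b):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = [(name, "".join(s[c] for c in cols)) for name, s in aligned]
        try:
            rep = nj(protein_distance(resampled, model, alpha))
        except ValueError:
            continue
        for split in _bipartitions(rep, taxa):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(taxa - side)
        if len(side) < 2 or len(other) < 2:
            continue
        split = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        support = 100.0 * counts.get(split, 0) / b
        node.label = f"{support:.0f}"
        node.support = support
    return tree


# ---------------------------------------------------------------------------
# orthologous gene clusters


@dataclass
class OgcPartition:
    clusters: dict[str, str]  # gene -> OGC id
    counts: pd.DataFrame      # OGC x species gene counts
    duplications: pd.Series   # per species
    losses: pd.Series         # per species


def duplication_loss_from_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-species duplication/loss bookkeeping from an OGC x species table.

    Duplications: sum over OGCs of max(0, count - 1); losses: number of
    OGCs where the species has no gene.
    """
    dups = counts.apply(lambda col: (col - 1).clip(lower=0).sum())
    losses = (counts == 0).sum()
    return dups.astype(int), losses.astype(int)


def assign_ogcs(
    gene_tree: dendropy.Tree,
    gene_to_species: dict[str, str],
    species: list[str],
    rooted: bool = False,
) -> OgcPartition:
    """Partition a gene tree into OGCs with the species-overlap rule.

    The tree is midpoint-rooted unless ``rooted``. Internal nodes whose
    children share species are duplications; descending from the root,
    the first node that is not a duplication roots one OGC. OGCs are
    numbered in the order encountered.
    """
    tree = gene_tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in gene_to_species:
            raise KeyError(f"gene {leaf.taxon.label!r} has no species mapping")
    if not rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)

    def species_set(node):
        return {gene_to_species[l.taxon.label] for l in node.leaf_iter()}

    def is_duplication(node):
        kids = node.child_nodes()
        if len(kids) < 2:
            return False
        sets = [species_set(k) for k in kids]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    return True
        return False

    ogc_roots = []

    def descend(node):
        if not node.is_leaf() and is_duplication(node):
            for k in node.child_nodes():
                descend(k)
        else:
            ogc_roots.append(node)

    descend(tree.seed_node)
    clusters = {}
    rows = []
    for i, root in enumerate(ogc_roots, start=1):
        ogc = f"OGC{i}"
        genes = [l.taxon.label for l in root.leaf_iter()]
        for g in genes:
            clusters[g] = ogc
        row = {sp: 0 for sp in species}
        for g in genes:
            row[gene_to_species[g]] += 1
        rows.append(pd.Series(row, name=ogc))
    counts = pd.DataFrame(rows)
    dups, losses = duplication_loss_from_counts(counts)
    return OgcPartition(clusters=clusters, counts=counts, duplications=dups, losses=losses)
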