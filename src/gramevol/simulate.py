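"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here at desk
scale: codon alignments evolved under a known omega-class mixture on a
tree, gene families with planted tandem arrays and collinear segments on
synthetic chromosomes, genotype matrices with planted haplotypes and a
haplotype -> phenotype effect, and qPCR Cq tables encoding a known
fold-change. All randomness flows from one ``numpy`` generator seeded per
call; identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._codons import sense_codons
from .codon_align import CodonAlignment
from .sitemodels import _decompose, _unnormalized_q, CodonRateMatrix

MISSING_ALLELE = "."


# ---------------------------------------------------------------------------
# codon alignments


@dataclass
class CodonSimParams:
    """Simulation settings for a codon alignment under a site-class mixture.

    ``tree`` branch lengths are expected substitutions per codon under the
    mixture; ``site_classes`` is a list of (proportion, omega) pairs whose
    proportions sum to 1. Site classes are drawn i.i.d. per column and fixed
    along the tree. The root sequence is sampled from ``codon_freqs``
    (stationarity assumed).
    """

    tree: str
    kappa: float
    site_classes: list[tuple[float, float]]
    n_codons: int
    codon_freqs: np.ndarray | None = None  # defaults to uniform over 61
    seed: int = 0
    genetic_code: int = 1

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        props = np.array([p for p, _ in self.site_classes], dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("site-class proportions must sum to 1")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omega must be >= 0")
        n = len(sense_codons(self.genetic_code))
        if self.codon_freqs is None:
            self.codon_freqs = np.full(n, 1.0 / n)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (n,) or abs(self.codon_freqs.sum() - 1.0) > 1e-12 or np.any(self.codon_freqs < 0):
            raise ValueError(f"codon_freqs must be a {n}-simplex")


def _sample_markov_step(states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(states))
    return (u[:, None] > cum[states]).sum(axis=1)


def simulate_codon_alignment(params: CodonSimParams) -> CodonAlignment:
    """Evolve codons along a tree under the configured omega mixture.

    Returns a gap-free, stop-free alignment with one row per tree leaf and
    the true per-site class assignment recorded in ``site_classes``.
    """
    tree = dendropy.Tree.get(data=params.tree, schema="newick")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = np.random.default_rng(params.seed)
    props = np.array([p for p, _ in params.site_classes])
    omegas = np.array([w for _, w in params.site_classes])
    pi = params.codon_freqs
    Qs = [_unnormalized_q(params.kappa, w, pi, params.genetic_code) for w in omegas]
    rates = np.array([-float(pi @ np.diag(Q)) for Q in Qs])
    mean_rate = float(props @ rates)
    matrices = []
    for Q in Qs:
        Qn = Q / mean_rate if mean_rate > 0 else Q
        w, left, right = _decompose(Qn, pi)
        matrices.append(CodonRateMatrix(kappa=params.kappa, omega=0.0, pi=pi, Q=Qn, _eigvals=w, _left=left, _right=right))
    site_class = rng.choice(len(props), size=params.n_codons, p=props)
    root_states = rng.choice(len(pi), size=params.n_codons, p=pi)
    states = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = float(node.edge.length or 0.0)
        parent_states = states[id(node.parent_node)]
        if t == 0.0:
            states[id(node)] = parent_states.copy()
        else:
            out = np.empty_like(parent_states)
            for k, rm in enumerate(matrices):
                mask = site_class == k
                if not mask.any():
                    continue
                P = rm.transition_matrix(t)
                out[mask] = _sample_markov_step(parent_states[mask], P, rng)
            states[id(node)] = out
    codons = sense_codons(params.genetic_code)
    rows = []
    for leaf in tree.leaf_node_iter():
        rows.append([codons[s] for s in states[id(leaf)]])
    return CodonAlignment(
        taxa=leaves, codons=rows, genetic_code=params.genetic_code,
        site_classes=[int(c) for c in site_class],
    )


# ---------------------------------------------------------------------------
# gene families on synthetic chromosomes


@dataclass
class PlantedArray:
    species: str
    chromosome: int
    size: int
    gap: int = 0  # background genes between consecutive array members

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("tandem array size must be >= 2")


@dataclass
class PlantedSegment:
    species_a: str
    chromosome_a: int
    species_b: str
    chromosome_b: int
    n_anchors: int
    spacing: int = 2  # background genes between consecutive anchors

    def __post_init__(self):
        if self.n_anchors < 1:
            raise ValueError("anchor count must be >= 1")


@dataclass
class FamilySimConfig:
    """Gene-family birth–death simulation plus synthetic genome layout."""

    species_tree: str
    n_families: int = 1
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 30
    planted_tandem_arrays: list[PlantedArray] = field(default_factory=list)
    planted_collinear_segments: list[PlantedSegment] = field(default_factory=list)
    seed: int = 0
    retry_cap: int = 20

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


class FamilyExtinct(RuntimeError):
    """All copies of a family were lost in every species despite retries."""


def _evolve_gene_branch(t: float, dup: float, loss: float, rng, events: list, branch: str) -> int:
    """Number of surviving descendants of one gene lineage after time t."""
    total = dup + loss
    if total == 0.0:
        return 1
    remaining = t
    while True:
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            return 1
        remaining -= wait
        if rng.random() < dup / total:
            events.append(("duplication", branch))
            # two independent daughter lineages for the remaining time
            return _evolve_gene_branch(remaining, dup, loss, rng, events, branch) + _evolve_gene_branch(
                remaining, dup, loss, rng, events, branch
            )
        events.append(("loss", branch))
        return 0


def _branch_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "|".join(leaves)


def simulate_gene_family(config: FamilySimConfig):
    """Simulate gene families and lay their genes on synthetic chromosomes.

    Returns ``(counts, event_log, annotation, truth)``: per-family
    per-species gene counts (DataFrame), the duplication/loss event log,
    a gene-coordinate annotation with planted tandem arrays and collinear
    anchor runs, and a ground-truth dict listing the planted structures.
    """
    tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    rng = np.random.default_rng(config.seed)
    event_rows = []
    count_rows = []
    for fam in range(config.n_families):
        for attempt in range(config.retry_cap + 1):
            events: list[tuple[str, str]] = []
            copies = {id(tree.seed_node): 1}
            leaf_counts = {}
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                n_in = copies[id(node.parent_node)]
                label = _branch_label(node)
                n_out = 0
                for _ in range(n_in):
                    n_out += _evolve_gene_branch(
                        float(node.edge.length or 0.0), config.dup_rate, config.loss_rate, rng, events, label
                    )
                copies[id(node)] = n_out
                if node.is_leaf():
                    leaf_counts[node.taxon.label] = n_out
            if sum(leaf_counts.values()) > 0:
                break
        else:
            raise FamilyExtinct(f"family {fam} extinct after {config.retry_cap} retries")
        for ev, branch in events:
            event_rows.append({"family": f"fam{fam}", "event": ev, "branch": branch})
        row = {"family": f"fam{fam}"}
        row.update({sp: leaf_counts.get(sp, 0) for sp in species})
        count_rows.append(row)
    counts = pd.DataFrame(count_rows).set_index("family")
    event_log = pd.DataFrame(event_rows, columns=["family", "event", "branch"])
    annotation, truth = _build_annotation(config, species, counts, rng)
    return counts, event_log, annotation, truth


def _build_annotation(config: FamilySimConfig, species: list[str], counts: pd.DataFrame, rng) -> tuple[pd.DataFrame, dict]:
    chrom_genes: dict[tuple[str, int], list[tuple[str, str]]] = {}
    bg = 0
    for sp in species:
        for c in range(1, config.n_chromosomes + 1):
            genes = []
            for _ in range(config.genes_per_chromosome):
                genes.append((f"{sp}_bg{bg}", f"bg{bg}"))
                bg += 1
            chrom_genes[(sp, c)] = genes
    # scatter the simulated family members across chromosomes
    for fam, row in counts.iterrows():
        for sp in species:
            for k in range(int(row[sp])):
                c = int(rng.integers(1, config.n_chromosomes + 1))
                genes = chrom_genes[(sp, c)]
                pos = int(rng.integers(0, len(genes) + 1))
                genes.insert(pos, (f"{fam}_{sp}_{k}", str(fam)))
    truth = {"tandem_arrays": [], "collinear_segments": []}
    for a_i, arr in enumerate(config.planted_tandem_arrays):
        genes = chrom_genes[(arr.species, arr.chromosome)]
        fam = f"tandem{a_i}"
        members = [f"{fam}_{arr.species}_{m}" for m in range(arr.size)]
        pos = len(genes) // 2
        block: list[tuple[str, str]] = []
        for m, gid in enumerate(members):
            block.append((gid, fam))
            if m < arr.size - 1:
                for g in range(arr.gap):
                    block.append((f"{arr.species}_bg{bg}", f"bg{bg}"))
                    bg += 1
        genes[pos:pos] = block
        truth["tandem_arrays"].append({"family": fam, "genes": members, "chromosome": f"{arr.species}_chr{arr.chromosome}"})
    for s_i, seg in enumerate(config.planted_collinear_segments):
        fam_base = f"seg{s_i}"
        pairs = []
        for side, (sp, c) in enumerate([(seg.species_a, seg.chromosome_a), (seg.species_b, seg.chromosome_b)]):
            genes = chrom_genes[(sp, c)]
            pos = 1
            for a in range(seg.n_anchors):
                gid = f"{fam_base}a{a}_{sp}_{side}"
                genes.insert(min(pos, len(genes)), (gid, f"{fam_base}a{a}"))
                pos += 1 + seg.spacing
                if side == 0:
                    pairs.append([gid])
                else:
                    pairs[a].append(gid)
        truth["collinear_segments"].append(
            {
                "chromosome_a": f"{seg.species_a}_chr{seg.chromosome_a}",
                "chromosome_b": f"{seg.species_b}_chr{seg.chromosome_b}",
                "anchor_pairs": [tuple(p) for p in pairs],
            }
        )
    rows = []
    for (sp, c), genes in chrom_genes.items():
        for i, (gid, fam) in enumerate(genes):
            start = i * 1000 + 1
            rows.append(
                {
                    "gene_id": gid,
                    "species": sp,
                    "chromosome": f"{sp}_chr{c}",
                    "start": start,
                    "end": start + 599,
                    "strand": "+",
                    "family": fam,
                }
            )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# genotype matrices with planted haplotypes


@dataclass
class VariantSimConfig:
    """Planted-haplotype genotype simulation with a phenotype effect.

    ``haplotype_defs`` lists (allele string over all sites, group size);
    group sizes must sum to ``n_samples`` and allele strings must be unique.
    Phenotypes are drawn as the haplotype mean plus Gaussian noise; multiple
    phenotype columns are supported by passing a mapping of
    name -> per-haplotype means.
    """

    n_sites: int
    haplotype_defs: list[tuple[str, int]]
    phenotype_means: dict[str, list[float]] | list[float]
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        strings = [s for s, _ in self.haplotype_defs]
        if len(set(strings)) != len(strings):
            raise ValueError("duplicate allele strings across haplotype_defs")
        if any(len(s) != self.n_sites for s in strings):
            raise ValueError("allele strings must all have length n_sites")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not isinstance(self.phenotype_means, dict):
            self.phenotype_means = {"phenotype": list(self.phenotype_means)}
        for name, means in self.phenotype_means.items():
            if len(means) != len(self.haplotype_defs):
                raise ValueError(f"{name}: one mean per haplotype required")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.haplotype_defs)


def simulate_variants(config: VariantSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype matrix (samples x sites) and phenotype table.

    Missing calls use the sentinel ``.``. Site columns are named ``site_1``
    .. ``site_n``; true haplotype membership is recorded in the phenotype
    table's ``true_haplotype`` column.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids, hap_of_sample, geno_rows = [], [], []
    for h, (alleles, size) in enumerate(config.haplotype_defs):
        for k in range(size):
            sample_ids.append(f"hap{h + 1}_s{k}")
            hap_of_sample.append(h)
            geno_rows.append(list(alleles))
    geno = pd.DataFrame(geno_rows, index=sample_ids, columns=[f"site_{i + 1}" for i in range(config.n_sites)])
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno = geno.mask(mask, MISSING_ALLELE)
    pheno = pd.DataFrame({"sample": sample_ids, "true_haplotype": [f"Hap{h + 1}" for h in hap_of_sample]})
    for name, means in config.phenotype_means.items():
        mu = np.array([means[h] for h in hap_of_sample], dtype=float)
        pheno[name] = mu + rng.normal(0.0, config.noise_sd, size=len(mu))
    return geno, pheno.set_index("sample")


# ---------------------------------------------------------------------------
# qPCR Cq tables


@dataclass
class QpcrSimConfig:
    """qPCR Cq simulation under the doubling-per-cycle assumption.

    A true fold-change f in a condition shifts the target gene's Cq by
    -log2(f) relative to the calibrator condition while the reference gene
    stays flat, so the 2^-ddCt analysis recovers f exactly at zero noise.
    """

    genes: list[str]
    conditions: list[str]
    fold_changes: dict[str, float]  # per condition; calibrator must be 1.0
    calibrator: str = "control"
    replicates: int = 3
    noise_sd: float = 0.0
    reference_gene: str = "reference"
    reference_baseline_cq: float = 20.0
    target_baseline_cq: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold-changes must be > 0")
        if self.calibrator not in self.conditions:
            raise ValueError("calibrator condition missing from conditions")
        self.fold_changes.setdefault(self.calibrator, 1.0)


def simulate_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Long-format Cq table: condition, gene, replicate, cq."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond in config.conditions:
        fold = config.fold_changes.get(cond, 1.0)
        for gene in list(config.genes) + [config.reference_gene]:
            for rep in range(1, config.replicates + 1):
                if gene == config.reference_gene:
                    cq = config.reference_baseline_cq
                else:
                    cq = config.target_baseline_cq - np.log2(fold)
                rows.append(
                    {
                        "condition": cond,
                        "gene": gene,
                        "replicate": rep,
                        "cq": cq + rng.normal(0.0, config.noise_sd),
                    }
                )
    return pd.DataFrame(rows)
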