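# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each stage of the pipeline, in the order data flows
through it.

## Codon alignments

Back-translation maps each aligned protein column to the codon that
encodes it (gap → `---`), after normalizing case and U→T and silently
stripping a terminal stop codon. Internal stops are hard errors: they
would corrupt the 61-state models downstream. The CDS must translate
exactly to the ungapped protein row; the first discordant residue is
reported. Only the standard nuclear code is used by default (all six
species are nuclear plant genes); a Biopython code-table id can be
injected. Column filtering offers `any_gap` (complete columns only — what
the likelihood engine requires), `ambiguity` (additionally drops non-ACGT
columns) and `none`; the original column indices are retained so site
reports can refer back to the unfiltered alignment. Filtering is
idempotent.

## Ka/Ks (NG86)

Sites: each codon position counts as one site, split between synonymous
and nonsynonymous in proportion to the single-base changes at that
position that do not create a stop codon ("nonsense mutations
disregarded"). This keeps S + N = 3 × codons exactly while not charging
nonsynonymous capacity for mutations the sense-codon state space cannot
realize. Differences: equal-weight averages over all orderings of the
differing positions, excluding pathways through stop codons (all pathways
are used if every one is blocked, so differences are never dropped).
Distances use the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is reported as saturated (NaN, flagged), and Ks = 0 makes the
ratio undefined (NaN, flagged) rather than infinite. Codons with gaps or
ambiguity in either sequence are deleted pairwise.

A point worth knowing: under a transition/transversion bias (κ > 1) NG86
is biased *below* 1 for neutrally evolving sequences, because synonymous
changes are enriched among transitions while the site counting weights
all changes equally. Our simulations measure pooled neutral Ka/Ks of
≈ 0.83–0.91 at κ = 2 versus ≈ 0.94–1.04 at κ = 1 (2000 codons, 8 taxa).
The neutrality identity is therefore asserted at κ = 1; the κ = 2 bias is
asserted as a property in its own right. Conclusions about purifying
selection are conservative under this bias (estimates are pushed down at
most ~15% at realistic κ, far from the ω ≈ 0.2 signals of interest).

Divergence times use T = Ks / (2λ) × 10⁻⁶ MYA with
λ = 1.5×10⁻⁸ synonymous substitutions/site/year (the grass-standard
clock), overridable everywhere it appears.

The bundled 55-pair reference table stores the published Ka, Ks, ratio and
MYA values at their printed precision. Ratio and MYA are *recomputed* from
the printed Ka/Ks and compared at each row's printed precision plus the
first-order error propagated from the inputs' own printed rounding; the
published Ka/Ks values themselves are not recomputed from sequence (the
original tool's estimator is unspecified, and NG86 was chosen here as the
simplest estimator with an exact enumeration oracle).

## Codon site models

The engine is a reversible Goldman–Yang-style model on the 61 sense
codons: qᵢⱼ = 0 for multi-nucleotide changes and ∝ πⱼ·{1, κ, ω, κω} for
synonymous transversions/transitions and nonsynonymous
transversions/transitions. Transition probabilities come from the
symmetric eigendecomposition of D^{1/2} Q D^{-1/2} (exact, stable, cheap
at 61×61). Codon frequencies default to F3x4 computed from the alignment
(PAML's convention); tests use equal frequencies for analytic
tractability.

Site-to-site ω variation is a finite mixture, fixed along the tree and
i.i.d. across sites:

- **M0** — one ω (1 free parameter).
- **M3(K)** — K discrete classes; proportions parameterized by
  stick-breaking (2K−1 free).
- **M7** — beta(p, q) on (0,1), discretized into K = 10 equal-probability
  categories at category medians (PAML's default behavior; 2 free).
- **M8** — M7 plus a class with ω ≥ 1 and weight p1 (4 free).
- **M8a** — M8 with ω fixed at 1 (3 free).

Class matrices are scaled jointly so the mixture's expected rate is one
substitution per codon per unit branch length. Likelihoods use Felsenstein
pruning with site-pattern compression; gapped/ambiguous columns must be
filtered first. Branch lengths of the input tree are multiplied by one
free scale factor per fit rather than re-optimized individually — a
deliberate simplification relative to codeml that keeps desk-scale fits in
seconds; with trees estimated on the same data the residual error enters
all compared models equally and largely cancels in LRTs.

Optimization is bounded L-BFGS-B with a curated default start plus
seeded random restarts; parameters landing on a bound are reported in the
fit's `boundary` list (ω = 999-type artifacts are thus surfaced
explicitly rather than silently reported as estimates). Nested fits can be
warm-started from the null's optimum (M8 from M7 at p1 ≈ 0, ωs = 1),
which enforces the nesting inequality up to optimizer tolerance.

LRTs compare 2ΔlnL to χ² with df equal to the difference in free
ω-distribution parameters: M0 vs M3(3) → 4, M7 vs M8 → 2, M8a vs M8 → 1
(the naive χ²₁ convention for the boundary case; the 50:50 mixture
refinement is noted but not default). Small negative 2ΔlnL within 0.01 is
clamped to 0 with a warning — exactly the kind of −0.0001 values
optimizer noise produces; anything more negative raises, flagging a failed
alternative fit. For the M7-vs-M8 comparison the null places p1 on the
boundary of the parameter space, so the χ²₂ reference is conservative:
null-simulation rejection rates measured here are well below the nominal
5% (0/20 in the shipped suite).

Site classification reports NEB (plug-in MLE) posteriors of the ω > 1
class per site, flagging sites above 0.95. A coarse grid approximation in
the spirit of BEB (flat prior over an 11×7 grid on (p1, ωs), posterior
averaged with data-likelihood weights) is available behind a flag; the
exact Yang–Wong–Nielsen integration is out of scope and NEB is the tested
default. On data simulated with a planted ω = 4 class (p1 = 0.1,
8 taxa × 500 codons) the 0.95 threshold recovers ~60–80% of the true sites
with under 1% false flags.

## Duplication classification

Everything runs on per-chromosome order indices (rank by start; 1-based
inclusive GFF-style coordinates); base-pair distances are not used. A
homolog pair is **tandem** iff same chromosome and |Δorder| ≤
max_intervening + 1 (default max_intervening = 1, the
adjacent-or-one-gene-between rule); overlapping pairs merge into arrays
via union-find, and an array of k genes counts as **one** tandem event —
which is why a 3-gene array plus a 2-gene array yields 2 events, not 5
pairs. **Segmental** pairs are anchors of accepted collinear blocks:
chains of anchor pairs strictly increasing on chromosome A and monotone
(either direction, allowing inversions) on B, both gaps ≤ max_gap
(default 25 genes), at least min_anchors (default 5) — MCScanX-style
defaults. Chaining is O(n²) DP per chromosome pair with deterministic
tie-breaking (lowest A-order), greedily extracting the best chain and
repeating on the remainder; anchors belong to at most one block.
Classification precedence is tandem > segmental > dispersed, so the three
classes partition the input pairs. Anchor homolog pairs are an explicit
input (the upstream all-vs-all search is not re-implemented).

## NJ trees and orthologous gene clusters

Protein distances: p (mismatch share over columns where both rows are
non-gap), Poisson −ln(1−p) (default), or gamma α[(1−p)^{−1/α} − 1];
saturated pairs (p = 1) get infinite distance with a warning.
JTT maximum-likelihood distances are not re-implemented — a documented
deviation from the original MEGA workflow; Poisson distances preserve the
topological signal NJ needs at family-level divergences. NJ is the
Saitou–Nei agglomeration with the standard Q criterion, lexicographic
tie-breaking for determinism, and negative branch estimates clamped to 0
with a warning. On additive matrices NJ is exact; the tests verify exact
recovery on 50 random 5–10 taxon trees.

Bootstrap resamples alignment columns with replacement; replicate r draws
from a child generator spawned from (seed, r), so supports are invariant
to taxon order. Supports are the percentage of replicates containing each
internal bipartition.

OGC assignment midpoint-roots the gene tree (outgroup override available)
and labels an internal node a duplication iff any two children's species
sets intersect (species overlap — chosen over full reconciliation because
it matches per-cluster counting and stays testable). Descending from the
root, the first non-duplication node encountered roots one OGC; each OGC
therefore stands for one gene in the species' common ancestor.
Bookkeeping per species: duplications = Σ_OGC max(0, count − 1), losses =
number of OGCs with zero genes. Published per-species duplication totals
in this family are not consistent with any per-gene counting rule we
could reconstruct, so the module documents its own rule and the tests
assert it on fixtures and simulated families with logged events.

## Promoter scanning

Promoters are the `length` (default 2000) bases immediately 5′ of the
translation start — ATG-anchored, the common PlantCARE workflow, since
TSS annotations are rarely reliable in these genomes — reverse-
complemented for minus-strand genes and truncated with a flag at
chromosome edges. The bundled catalog holds ~20 widely used consensus
patterns (ABRE, ARE, MBS, G-box, CGTCA/TGACG, P-box, TC-rich repeats,
CAT-box, LTR, WUN-motif, NON-box, RY-element, …) grouped into
phytohormone/light/stress/development categories. Matching is exact
degenerate IUPAC matching on both strands with all overlapping hits
reported (regex lookahead); no mismatches, no PWMs. PlantCARE's internal
patterns are not public, so per-gene counts from the original database
are not reproduction targets — planted-motif recovery on synthetic
promoters is the tested property.

## Expression and haplotypes

2^−ΔΔCT assumes doubling per cycle (amplification efficiency fixed at 2;
Pfaffl-style efficiency correction is out of scope). ΔCt replicates are
paired by replicate id (target − reference), ΔΔCt subtracts the
calibrator condition's mean ΔCt, and the replicate SD of ΔCt is
propagated (missing when n < 2). Tissue expression uses log₂(FPKM+1).

Group comparisons: one-way ANOVA, Tukey HSD on the pooled MSE with the
Tukey–Kramer adjustment for unequal n (the reference panel's groups of
189/43/6/4/3 are highly unbalanced), and a compact letter display built
by insert-and-absorb — groups share a letter iff not significantly
different, a contract the tests verify pairwise, including against a
permutation oracle for the studentized-range p-value. All-constant,
all-equal groups short-circuit to a degenerate flagged result.

Haplotype binning groups samples by exact allele-string equality over the
retained sites (a site-subset parameter exists because a full segregating
site set generically yields more distinct strings than named haplotypes).
Missing calls (sentinel `.`) drop the sample by default (DnaSP-like
complete case; counts reported) or are imputed to the site's major allele
behind a flag. Heterozygous calls are treated as missing by default — the
selfing-*japonica* assumption — and groups are ordered by size then first
appearance (Hap1, Hap2, …). Key-site reports list the sites where the
focal haplotype's allele differs from *every* other group; for coding
positions (≥ 1, with +1 = the A of ATG; promoter positions negative) the
induced amino-acid change is computed under the standard code.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every property test. Codon
simulation assumes stationarity (root drawn from the equilibrium
frequencies), i.i.d. site classes fixed along the tree, and no indels —
matching the site-model assumptions — so passing tests demonstrate
estimator correctness under the model, not robustness to alignment error,
recombination or selection regimes changing along lineages. Gene-family
simulation is a per-lineage birth–death process on the species tree with
an analytic pure-birth mean used as the Monte-Carlo oracle; planted
tandem arrays and collinear segments are constructed, not evolved, so
their recovery tests detector logic, not evolutionary realism. Variant
simulation plants haplotypes exactly (no recombination or linkage beyond
the planted strings) with Gaussian phenotype noise; the default design
mirrors the reference panel (5 haplotypes of 189/43/6/4/3 samples over
4 + 46 = 50 sites). qPCR simulation encodes a fold-change f as a target
Cq shift of −log₂(f) with a flat reference gene, so ΔΔCt recovery is
exact at zero noise. Every generator draws from a single seeded
generator per call; identical configurations give byte-identical outputs.

## Problem sizes and numerics

Shipped test and acceptance problem sizes (8 taxa × 500 codons for ω
recovery, 20 replicates of 6 taxa × 100 codons with 5 beta categories for
the null LRT suite, 2000 codons for neutrality, 50 random trees for NJ)
were chosen as the smallest sizes at which each property is comfortably
away from its decision boundary; they keep the whole suite under a few
minutes on one core. Optimizer tolerance is 1e-9 on the scaled objective
with maxiter 200; likelihood floors at 1e-300 guard log-underflow (no
per-node rescaling — adequate at ≤ ~20 taxa; larger trees would need it).
pI is solved by Biopython's Bjellqvist bisection; note the terminal
residues carry their own pKa, so pI is invariant only to interior
permutations. Published physicochemical values are treated as
approximately comparable (tool-version dependent) and summarized, not
re-asserted per protein.

## Known limitations

- NG86's transition bias (above); no YN00/ML pairwise estimator.
- One global branch-scale factor instead of per-branch optimization;
  exact codeml reproduction is a non-goal.
- BEB is a coarse grid approximation; NEB is the tested default.
- Species-overlap duplication labeling can over-call duplications under
  incomplete lineage sorting; no reconciliation.
- Promoter scanning is consensus-exact; degenerate biological matches
  below consensus stringency are missed by design.
- The pipeline assumes desk-scale inputs (hundreds of genes, tens of
  taxa); none of the algorithms are tuned for genome-scale anchor sets.
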