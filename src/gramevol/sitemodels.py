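"""Codon substitution site models: M0, M3, M7, M8, M8a, with LRTs.

The engine is a Goldman–Yang-style 61-state codon model. The instantaneous
rate from codon i to j is 0 for multi-nucleotide changes and otherwise
proportional to pi_j times 1, kappa, omega or kappa*omega according to
whether the change is a synonymous transversion, synonymous transition,
nonsynonymous transversion or nonsynonymous transition. Site-to-site
variation in omega is a finite mixture: one class (M0), K discrete classes
(M3), a discretized beta on (0,1) (M7), beta plus one class with
omega >= 1 free (M8) or fixed at 1 (M8a). Likelihoods come from
Felsenstein pruning over a fixed input topology whose branch lengths are
jointly rescaled by one free factor per fit; nested fits are compared with
chi-squared likelihood-ratio tests (df = difference in free parameters:
M0 vs M3(3) -> 4, M7 vs M8 -> 2, M8a vs M8 -> 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import eigh
from scipy.special import betaincinv

from ._codons import codon_index, sense_codons, substitution_masks
from .codon_align import GAP_CODON, CodonAlignment

N_STATES = 61


# ---------------------------------------------------------------------------
# rate matrix


@dataclass
class CodonRateMatrix:
    """A reversible 61-state codon rate matrix with its spectral decomposition."""

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{1/2} V
    _right: np.ndarray = field(repr=False, default=None)  # V^T D^{-1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition."""
        if t < 0:
            raise ValueError("negative branch length")
        return (self._left * np.exp(self._eigvals * t)) @ self._right


def _unnormalized_q(kappa: float, omega: float, pi: np.ndarray, code_id: int = 1) -> np.ndarray:
    syn_ts, syn_tv, nonsyn_ts, nonsyn_tv = substitution_masks(code_id)
    rates = syn_tv * 1.0 + syn_ts * kappa + nonsyn_tv * omega + nonsyn_ts * (kappa * omega)
    Q = rates * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _decompose(Q: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sqrt_pi = np.sqrt(pi)
    B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    B = (B + B.T) / 2.0  # symmetric up to round-off by reversibility
    w, V = eigh(B)
    left = V / sqrt_pi[:, None]
    right = V.T * sqrt_pi[None, :]
    return w, left, right


def build_q(kappa: float, omega: float, pi: np.ndarray, normalize: bool = True, genetic_code: int = 1) -> CodonRateMatrix:
    """Build the codon rate matrix for one omega class.

    With ``normalize`` the matrix is scaled to one expected substitution per
    codon per unit time at stationarity; mixture models instead rescale their
    class matrices jointly so the *mixture* has unit expected rate.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_STATES,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be a 61-simplex")
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    Q = _unnormalized_q(kappa, omega, pi, genetic_code)
    if normalize:
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q = Q / rate
    w, left, right = _decompose(Q, pi)
    return CodonRateMatrix(kappa=kappa, omega=omega, pi=pi, Q=Q, _eigvals=w, _left=left, _right=right)


def uniform_codon_freqs(genetic_code: int = 1) -> np.ndarray:
    return np.full(N_STATES, 1.0 / N_STATES)


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from the alignment's per-position nucleotide counts."""
    counts = np.zeros((3, 4))
    order = {nt: k for k, nt in enumerate("TCAG")}
    for row in aln.codons:
        for cell in row:
            if cell == GAP_CODON or set(cell) - set("ACGT"):
                continue
            for pos, nt in enumerate(cell):
                counts[pos, order[nt]] += 1
    counts = counts / counts.sum(axis=1, keepdims=True)
    codons = sense_codons(aln.genetic_code)
    freqs = np.array([counts[0, order[c[0]]] * counts[1, order[c[1]]] * counts[2, order[c[2]]] for c in codons])
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# model specifications


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """K equal-probability beta(p, q) categories represented by their medians."""
    if p <= 0 or q <= 0 or k < 1:
        raise ValueError("p, q must be positive and k >= 1")
    quantiles = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    return betaincinv(p, q, quantiles)


@dataclass
class SiteModelSpec:
    """One of the supported site models and its free-parameter layout.

    Free parameters exclude the shared kappa and tree-scale factor, which are
    always estimated alongside; ``n_free`` counts only the omega-distribution
    parameters so that LRT degrees of freedom follow the standard rules.
    """

    name: str
    n_classes: int = 3  # K for M3
    n_beta_categories: int = 10

    _LAYOUT = {"M0": 1, "M7": 2, "M8a": 3, "M8": 4}

    def __post_init__(self):
        if self.name not in ("M0", "M3", "M7", "M8", "M8a"):
            raise ValueError(f"unknown site model {self.name!r}")

    @property
    def n_free(self) -> int:
        if self.name == "M3":
            return 2 * self.n_classes - 1
        return self._LAYOUT[self.name]

    def parameter_names(self) -> list[str]:
        if self.name == "M0":
            return ["omega"]
        if self.name == "M3":
            return [f"v{i}" for i in range(1, self.n_classes)] + [
                f"omega{i}" for i in range(self.n_classes)
            ]
        if self.name == "M7":
            return ["p", "q"]
        if self.name == "M8a":
            return ["p", "q", "p1"]
        return ["p", "q", "p1", "omega_s"]

    def bounds(self) -> list[tuple[float, float]]:
        if self.name == "M0":
            return [(1e-4, 20.0)]
        if self.name == "M3":
            return [(1e-3, 1 - 1e-3)] * (self.n_classes - 1) + [(1e-4, 20.0)] * self.n_classes
        pq = [(0.05, 99.0), (0.05, 99.0)]
        if self.name == "M7":
            return pq
        if self.name == "M8a":
            return pq + [(1e-6, 1 - 1e-6)]
        return pq + [(1e-6, 1 - 1e-6), (1.0, 999.0)]

    def mixture(self, params: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """(proportions, omegas) of the site classes under ``params``."""
        if self.name == "M0":
            return np.array([1.0]), np.array([params["omega"]])
        if self.name == "M3":
            props = []
            rest = 1.0
            for i in range(1, self.n_classes):
                v = params[f"v{i}"]
                props.append(rest * v)
                rest *= 1.0 - v
            props.append(rest)
            omegas = np.array([params[f"omega{i}"] for i in range(self.n_classes)])
            return np.array(props), omegas
        betas = discretize_beta(params["p"], params["q"], self.n_beta_categories)
        if self.name == "M7":
            return np.full(self.n_beta_categories, 1.0 / self.n_beta_categories), betas
        p1 = params["p1"]
        props = np.append(np.full(self.n_beta_categories, (1.0 - p1) / self.n_beta_categories), p1)
        omega_s = 1.0 if self.name == "M8a" else params["omega_s"]
        return props, np.append(betas, omega_s)


# ---------------------------------------------------------------------------
# tree handling and pruning


class _TreeStructure:
    """Fixed postorder skeleton of an unrooted-as-rooted dendropy tree."""

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        tree = tree.clone(depth=1)
        nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = []
        self.lengths: list[float] = []
        self.leaf_taxon: list[str | None] = []
        for n in nodes:
            self.children.append([self.index[id(c)] for c in n.child_nodes()])
            self.lengths.append(float(n.edge.length or 0.0))
            self.leaf_taxon.append(n.taxon.label if n.is_leaf() else None)
        self.root = len(nodes) - 1
        leaf_labels = {t for t in self.leaf_taxon if t is not None}
        missing = leaf_labels - set(taxa)
        if missing:
            raise ValueError(f"tree leaves not in alignment: {sorted(missing)}")


def _encode_patterns(aln: CodonAlignment, taxa_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression: (codes matrix taxa x patterns, pattern counts)."""
    idx = codon_index(aln.genetic_code)
    mat = np.empty((len(taxa_order), aln.n_codons), dtype=np.int64)
    for r, taxon in enumerate(taxa_order):
        row = aln.row(taxon)
        for c, cell in enumerate(row):
            if cell == GAP_CODON or cell not in idx:
                raise ValueError(
                    f"{taxon}: gap or ambiguous codon at column {c}; filter columns first"
                )
            mat[r, c] = idx[cell]
    patterns, inverse, counts = np.unique(mat, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts, inverse


def _class_site_likelihoods(struct: _TreeStructure, rm: CodonRateMatrix, scale: float, codes: np.ndarray, taxa_pos: dict[str, int]) -> np.ndarray:
    """Per-pattern likelihood under one omega class by postorder pruning."""
    n_patterns = codes.shape[1]
    partials: list[np.ndarray | None] = [None] * (struct.root + 1)
    for i, kids in enumerate(struct.children):
        if not kids:
            continue
        acc = np.ones((n_patterns, N_STATES))
        for c in kids:
            P = rm.transition_matrix(struct.lengths[c] * scale)
            taxon = struct.leaf_taxon[c]
            if taxon is not None:
                acc *= P[:, codes[taxa_pos[taxon]]].T
            else:
                acc *= partials[c] @ P.T
            partials[c] = None
        partials[i] = acc
    return partials[struct.root] @ rm.pi


class CodonLikelihood:
    """Pruning likelihood for one alignment/tree pair, reused across models.

    Codon frequencies default to F3x4 computed from the alignment; pass
    ``pi`` (e.g. :func:`uniform_codon_freqs`) to override. Branch lengths of
    the input tree are multiplied by a single free scale factor per
    evaluation rather than re-optimized individually.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree | str, pi: np.ndarray | None = None):
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick")
        self.aln = aln
        self.struct = _TreeStructure(tree, aln.taxa)
        self.codes, self.counts, self.pattern_of_site = _encode_patterns(aln, aln.taxa)
        self.taxa_pos = {t: i for i, t in enumerate(aln.taxa)}
        if pi is None:
            pi = f3x4_frequencies(aln)
        pi = np.maximum(np.asarray(pi, dtype=float), 1e-10)
        self.pi = pi / pi.sum()
        self.genetic_code = aln.genetic_code

    def class_site_likelihoods(self, props: np.ndarray, omegas: np.ndarray, kappa: float, scale: float) -> np.ndarray:
        """Per-pattern likelihood of each class, (n_classes, n_patterns).

        Class matrices are scaled jointly so the mixture's expected rate is
        one substitution per codon per unit branch length.
        """
        Qs = [_unnormalized_q(kappa, w, self.pi, self.genetic_code) for w in omegas]
        rates = np.array([-float(self.pi @ np.diag(Q)) for Q in Qs])
        mean_rate = float(props @ rates)
        if mean_rate <= 0:
            mean_rate = 1.0
        out = np.zeros((len(props), self.codes.shape[1]))
        for k, Q in enumerate(Qs):
            w, left, right = _decompose(Q / mean_rate, self.pi)
            rm = CodonRateMatrix(kappa=kappa, omega=omegas[k], pi=self.pi, Q=Q / mean_rate, _eigvals=w, _left=left, _right=right)
            out[k] = _class_site_likelihoods(self.struct, rm, scale, self.codes, self.taxa_pos)
        return out

    def loglik(self, spec: SiteModelSpec, params: dict[str, float], kappa: float, scale: float = 1.0) -> float:
        props, omegas = spec.mixture(params)
        class_lik = self.class_site_likelihoods(props, omegas, kappa, scale)
        site_lik = np.maximum(props @ class_lik, 1e-300)
        return float(self.counts @ np.log(site_lik))


def loglik(
    aln: CodonAlignment,
    tree: dendropy.Tree | str,
    spec: SiteModelSpec,
    params: dict[str, float],
    kappa: float,
    scale: float = 1.0,
    pi: np.ndarray | None = None,
) -> float:
    """Mixture log-likelihood of the alignment under ``spec`` at ``params``."""
    return CodonLikelihood(aln, tree, pi).loglik(spec, params, kappa, scale)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SiteModelFit:
    """Maximized fit of one site model."""

    spec: SiteModelSpec
    lnl: float
    params: dict[str, float]
    kappa: float
    scale: float
    proportions: np.ndarray
    omegas: np.ndarray
    site_posteriors: np.ndarray  # (n_sites, n_classes), NEB
    converged: bool
    boundary: list[str]
    engine: CodonLikelihood = field(repr=False, default=None)

    @property
    def n_free(self) -> int:
        return self.spec.n_free


_KAPPA_BOUNDS = (0.1, 50.0)
_SCALE_BOUNDS = (1e-3, 100.0)


def _default_start(spec: SiteModelSpec) -> list[float]:
    if spec.name == "M0":
        return [0.3]
    if spec.name == "M3":
        k = spec.n_classes
        return [1.0 / (k - i) for i in range(1, k)] + list(np.linspace(0.05, 1.0, k))
    if spec.name == "M7":
        return [0.5, 1.5]
    if spec.name == "M8a":
        return [0.5, 1.5, 0.1]
    return [0.5, 1.5, 0.1, 2.0]


def fit(
    aln: CodonAlignment,
    tree: dendropy.Tree | str,
    spec: SiteModelSpec,
    pi: np.ndarray | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    maxiter: int = 200,
    engine: CodonLikelihood | None = None,
    warm_start: SiteModelFit | dict | None = None,
) -> SiteModelFit:
    """Maximize the site-model likelihood with bounded L-BFGS-B multistart.

    ``n_restarts`` additional random starts are drawn uniformly within the
    bounds from a generator seeded with ``seed``; the best local optimum is
    returned, with parameters lying on a bound listed in ``boundary``.
    ``warm_start`` seeds an extra start from a fit of a nested model (e.g.
    an M7 fit warm-starts M8 at p1 ~ 0, omega_s = 1, which guarantees the
    nested-model likelihood inequality up to optimizer tolerance).
    """
    eng = engine or CodonLikelihood(aln, tree, pi)
    names = spec.parameter_names()
    bounds = spec.bounds() + [_KAPPA_BOUNDS, _SCALE_BOUNDS]
    rng = np.random.default_rng(seed)

    def unpack(x):
        return dict(zip(names, x[:-2])), float(x[-2]), float(x[-1])

    def objective(x):
        params, kappa, scale = unpack(x)
        try:
            return -eng.loglik(spec, params, kappa, scale)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    starts = [np.array(_default_start(spec) + [2.0, 1.0])]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if warm_start is not None:
        src = dict(warm_start.params, kappa=warm_start.kappa, scale=warm_start.scale) \
            if isinstance(warm_start, SiteModelFit) else dict(warm_start)
        defaults = dict(zip(names, _default_start(spec)), kappa=2.0, scale=1.0)
        defaults.update({"p1": 1e-6, "omega_s": 1.0})  # nested-at-boundary values
        vec = [src.get(n, defaults[n]) for n in names] + [src.get("kappa", 2.0), src.get("scale", 1.0)]
        starts.insert(0, np.array(vec, dtype=float))
    # random restarts sample log-uniformly for scale-like params, uniformly otherwise
    for _ in range(n_restarts):
        u = rng.random(len(bounds))
        starts.append(lo + u * (np.minimum(hi, 10.0) - lo))
    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(
            objective, np.clip(x0, lo, hi), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params, kappa, scale = unpack(best.x)
    props, omegas = spec.mixture(params)
    class_lik = eng.class_site_likelihoods(props, omegas, kappa, scale)
    weighted = props[:, None] * class_lik
    post_patterns = weighted / np.maximum(weighted.sum(axis=0, keepdims=True), 1e-300)
    site_posteriors = post_patterns[:, eng.pattern_of_site].T
    at_bound = [
        n for n, v, (blo, bhi) in zip(names + ["kappa", "scale"], best.x, bounds)
        if v <= blo + 1e-8 or v >= bhi - 1e-8
    ]
    if n_converged == 0:
        warnings.warn(f"{spec.name}: no optimizer start converged; fit flagged", stacklevel=2)
    return SiteModelFit(
        spec=spec, lnl=-float(best.fun), params=params, kappa=kappa, scale=scale,
        proportions=props, omegas=omegas, site_posteriors=site_posteriors,
        converged=n_converged > 0, boundary=at_bound, engine=eng,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests


@dataclass
class LrtResult:
    two_delta_lnl: float
    df: int
    p_value: float
    null_name: str
    alt_name: str


_NESTED = {("M0", "M3"), ("M7", "M8"), ("M8a", "M8"), ("M7", "M8a")}


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit, tolerance: float = 0.01) -> LrtResult:
    """Chi-squared LRT of two nested site-model fits.

    df is the difference in free omega-distribution parameters (M0 vs
    M3(K=3): 4; M7 vs M8: 2; M8a vs M8: 1). A small negative 2*dlnL within
    ``tolerance`` is clamped to 0 with a warning (optimizer noise); a larger
    negative value raises, flagging optimizer failure on the alternative.
    """
    pair = (null_fit.spec.name, alt_fit.spec.name)
    if pair not in _NESTED:
        raise ValueError(f"{pair[0]} is not nested in {pair[1]}")
    df = alt_fit.n_free - null_fit.n_free
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < 0:
        if stat < -tolerance:
            raise ValueError(
                f"2*dlnL = {stat:.4f} < -{tolerance}: alternative fit worse than null; optimizer failure"
            )
        warnings.warn(f"negative 2*dlnL {stat:.4g} clamped to 0", stacklevel=2)
        stat = 0.0
    return LrtResult(
        two_delta_lnl=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
        null_name=null_fit.spec.name, alt_name=alt_fit.spec.name,
    )


# ---------------------------------------------------------------------------
# site classification


def classify_sites(fit_result: SiteModelFit, threshold: float = 0.95, beb_grid: bool = False) -> pd.DataFrame:
    """Posterior membership of the omega > 1 class(es) per site.

    NEB (naive empirical Bayes, plug-in MLEs) is the default; ``beb_grid``
    averages the M8 positive-class posterior over a coarse grid prior on
    (p1, omega_s), a cheap approximation in the spirit of Bayes empirical
    Bayes. Sites with posterior above ``threshold`` are flagged. Models with
    no omega > 1 class (M0, M7, M8a) are rejected.
    """
    spec = fit_result.spec
    if spec.name in ("M0", "M7", "M8a"):
        raise ValueError(f"{spec.name} has no omega > 1 class")
    positive = fit_result.omegas > 1.0
    if spec.name == "M8":
        positive = np.zeros_like(positive)
        positive[-1] = fit_result.omegas[-1] > 1.0
    post = fit_result.site_posteriors[:, positive].sum(axis=1)
    if beb_grid and spec.name == "M8":
        post = _beb_grid_posterior(fit_result)
    n_sites = len(post)
    return pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "posterior": post,
            "selected": post > threshold,
        }
    )


def _beb_grid_posterior(fit_result: SiteModelFit, n_p1: int = 11, omega_grid=(1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 10.0)) -> np.ndarray:
    """Average the positive-class posterior over a flat (p1, omega_s) grid."""
    eng = fit_result.engine
    spec = fit_result.spec
    p1_grid = np.linspace(0.0, 0.5, n_p1)
    acc = np.zeros(eng.codes.shape[1])
    total_weight = 0.0
    for omega_s in omega_grid:
        params = dict(fit_result.params, omega_s=omega_s)
        for p1 in p1_grid:
            params["p1"] = max(p1, 1e-9)
            props, omegas = spec.mixture(params)
            class_lik = eng.class_site_likelihoods(props, omegas, fit_result.kappa, fit_result.scale)
            site_lik = np.maximum(props @ class_lik, 1e-300)
            lnl = float(eng.counts @ np.log(site_lik))
            weight = math.exp(lnl - fit_result.lnl) if lnl - fit_result.lnl > -700 else 0.0
            if weight == 0.0:
                continue
            acc += weight * (props[-1] * class_lik[-1]) / site_lik
            total_weight += weight
    if total_weight == 0.0:
        return np.zeros(len(eng.pattern_of_site))
    return (acc / total_weight)[eng.pattern_of_site]


# ---------------------------------------------------------------------------
# battery over orthologous gene clusters


def summarize_ogc_battery(fits_by_group: dict[str, dict[str, SiteModelFit]], threshold: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Selection-test report across gene clusters plus aggregate M0 statistics.

    ``fits_by_group`` maps a cluster name to its fits keyed by model name
    (at least M0/M3/M7/M8/M8a). Returns the per-cluster table and a summary
    with mean, sample SD and a one-sample t-test of the M0 omegas against 1.
    """
    if len(fits_by_group) < 2:
        raise ValueError("need at least 2 group fits for aggregate statistics")
    rows = []
    m0_omegas = []
    for group, fits in fits_by_group.items():
        m0 = fits["M0"]
        m0_omegas.append(m0.params["omega"])
        row = {"group": group, "n_taxa": m0.engine.aln.n_taxa if m0.engine else None, "omega_m0": m0.params["omega"]}
        for null, alt, label in (("M0", "M3", "m3_vs_m0"), ("M7", "M8", "m8_vs_m7"), ("M8a", "M8", "m8_vs_m8a")):
            if null in fits and alt in fits:
                stat = 2.0 * (fits[alt].lnl - fits[null].lnl)
                row[f"2dlnl_{label}"] = stat
                df = fits[alt].n_free - fits[null].n_free
                row[f"p_{label}"] = float(stats.chi2.sf(max(stat, 0.0), df))
        if "M8" in fits:
            m8 = fits["M8"]
            row["m8_p1"] = m8.params["p1"]
            row["m8_omega_s"] = m8.params["omega_s"]
            row["m8_beta_p"] = m8.params["p"]
            row["m8_beta_q"] = m8.params["q"]
            sel = classify_sites(m8, threshold=threshold)
            flagged = sel.loc[sel["selected"], "site"].tolist()
            row["selected_sites"] = ",".join(map(str, flagged)) if flagged else "NAN"
            row["m8_boundary"] = ",".join(m8.boundary) if m8.boundary else ""
        rows.append(row)
    m0_omegas = np.asarray(m0_omegas, dtype=float)
    summary = aggregate_omega_stats(m0_omegas)
    return pd.DataFrame(rows), summary


def aggregate_omega_stats(omegas: np.ndarray) -> dict:
    """Mean, sample SD and one-sample t-test against 1 for a set of M0 omegas."""
    omegas = np.asarray(omegas, dtype=float)
    if omegas.size < 2:
        raise ValueError("need at least 2 omega values")
    mean = float(np.mean(omegas))
    sd = float(np.std(omegas, ddof=1))
    if sd == 0.0:
        return {"mean": mean, "sd": 0.0, "t": math.nan, "p": math.nan, "degenerate": True}
    t, p = stats.ttest_1samp(omegas, popmean=1.0)
    return {"mean": mean, "sd": sd, "t": float(t), "p": float(p), "degenerate": False}
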