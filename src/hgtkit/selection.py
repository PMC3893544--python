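"""Codon substitution models (GY94 family) and LRTs for positive selection.

Implements the standard site-model ladder M0, M3(k), M1a/M2a, M7/M8 and
branch-site model A (with its omega2=1 null), a Felsenstein pruning
likelihood over the 61 sense codons of the universal code, nested
likelihood-ratio tests, and naive empirical Bayes (NEB) site posteriors.

Branch lengths are estimated once under M0 and held fixed for all other
models; this is the package's main simplification relative to per-model
re-optimisation and is documented in the methods note.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.stats
from scipy.linalg import eigh
from scipy.stats import chi2

import dendropy

from .io import MSA
from .trees import TreeArrays, set_branch_lengths, tree_to_arrays

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Genetic code (universal), 61 sense codons
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_CODE = {}
_AA_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_a + _b + _c] = _AA_TABLE[_i]

STOP_CODONS = tuple(sorted(c for c, aa in _CODE.items() if aa == "*"))
CODONS: tuple[str, ...] = tuple(sorted(c for c, aa in _CODE.items() if aa != "*"))
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = np.array([_CODE[c] for c in CODONS])

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _single_nt_pairs():
    """Index arrays over codon pairs differing at exactly one position."""
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(*diffs[0]))
            syn.append(_CODE[ci] == _CODE[cj])
    return (np.array(ii), np.array(jj), np.array(ts, bool), np.array(syn, bool))


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _single_nt_pairs()


def equal_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_freqs(codon_rows: Sequence[str]) -> np.ndarray:
    """F3x4 codon frequencies from per-position nucleotide compositions.

    ``codon_rows`` are gap-free coding sequences (length divisible by 3);
    stop-codon cells are zeroed and the vector renormalised.
    """
    counts = np.zeros((3, 4))
    base_idx = {b: k for k, b in enumerate("TCAG")}
    for row in codon_rows:
        for p in range(0, len(row) - len(row) % 3, 3):
            codon = row[p:p + 3]
            for k, b in enumerate(codon):
                if b in base_idx:
                    counts[k, base_idx[b]] += 1
    counts += 1e-9
    pos = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.empty(N_CODONS)
    for i, c in enumerate(CODONS):
        freqs[i] = pos[0, base_idx[c[0]]] * pos[1, base_idx[c[1]]] * pos[2, base_idx[c[2]]]
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_Q(kappa: float, omega: float, freqs: np.ndarray,
            normalize: bool = True) -> np.ndarray:
    """GY94-style 61x61 generator.

    Off-diagonal rate to codon j (one nucleotide change away) is
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; multi-nucleotide
    changes have rate 0.  With ``normalize`` the matrix is scaled so the
    expected number of substitutions per codon per time unit is 1.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    freqs = np.asarray(freqs, float)
    if freqs.shape != (N_CODONS,) or not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise ValueError("freqs must be a probability vector over the 61 sense codons")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = freqs[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -(freqs * np.diag(Q)).sum()
        if mu > 0:
            Q /= mu
    return Q


class CodonRateMatrix:
    """Eigendecomposed reversible generator; fast P(t) for many branches."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        self.Q = Q
        self.freqs = freqs
        sp = np.sqrt(freqs)
        sym = (Q * sp[:, None]) / sp[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, U = eigh(sym)
        self._lam = lam
        self._left = U / sp[:, None]          # D^-1 U
        self._right = U.T * sp[None, :]       # U^T D

    def transition(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

SITE_MODELS = ("M0", "M3", "M1a", "M2a", "M7", "M8")
BRANCH_SITE_MODELS = ("bsA", "bsA_null")


@dataclass
class CodonModelSpec:
    """A concrete codon model: site classes with proportions and omegas.

    For branch-site models ``fg_omegas`` gives each class's omega on
    foreground branches (identical to ``omegas`` for site models).
    """

    model: str
    kappa: float
    freqs: np.ndarray
    omegas: np.ndarray
    proportions: np.ndarray
    fg_omegas: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omegas = np.atleast_1d(np.asarray(self.omegas, float))
        self.proportions = np.atleast_1d(np.asarray(self.proportions, float))
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-8):
            raise ValueError("class proportions must sum to 1")
        if (self.omegas < 0).any():
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def n_classes(self) -> int:
        return len(self.omegas)


def discretize_beta(p: float, q: float, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """K equal-probability categories of Beta(p, q); category means as omegas."""
    edges = scipy.stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
    upper = scipy.stats.beta.cdf(edges, p + 1, q)
    means = (upper[1:] - upper[:-1]) * (p / (p + q)) * k
    means = np.clip(means, 1e-8, 1.0)
    return means, np.full(k, 1.0 / k)


# ---------------------------------------------------------------------------
# Alignment encoding
# ---------------------------------------------------------------------------

@dataclass
class CodonData:
    """Pattern-compressed codon alignment bound to a tree's leaf order."""

    patterns: np.ndarray      # (n_leaves, n_patterns) codon state, -1 = missing
    weights: np.ndarray       # (n_patterns,)
    site_to_pattern: np.ndarray  # (n_sites,)
    labels: list[str]
    n_sites: int
    excluded_sites: list[int]
    freqs_f3x4: np.ndarray


def encode_codon_msa(msa: MSA, drop_gapped: bool = True) -> CodonData:
    """Translate an in-frame nucleotide alignment to codon states.

    Codon columns containing a gap or stop codon in any row are excluded
    (logged); codons with ambiguity characters become missing data for that
    row only.
    """
    if msa.n_cols % 3 != 0:
        raise ValueError("codon alignment length must be divisible by 3")
    n_sites = msa.n_cols // 3
    labels = msa.ids
    states = np.full((len(labels), n_sites), -1, dtype=np.int64)
    has_gap = np.zeros(n_sites, bool)
    has_stop = np.zeros(n_sites, bool)
    for r, rec in enumerate(msa.records):
        for s in range(n_sites):
            codon = rec.seq[3 * s:3 * s + 3]
            if "-" in codon:
                has_gap[s] = True
            elif codon in CODON_INDEX:
                states[r, s] = CODON_INDEX[codon]
            elif codon in STOP_CODONS:
                has_stop[s] = True
            # else ambiguity -> missing
    keep = ~(has_gap | has_stop) if drop_gapped else ~has_stop
    excluded = list(np.nonzero(~keep)[0])
    if excluded:
        logger.info("excluded %d gapped/stop codon columns", len(excluded))
    states = states[:, keep]
    rows = ["".join(CODONS[s] if s >= 0 else "NNN" for s in row) for row in states]
    freqs = f3x4_freqs(rows)
    pat, site_to_pat, counts = np.unique(states, axis=1,
                                         return_inverse=True, return_counts=True)
    return CodonData(pat, counts.astype(float), site_to_pat, labels,
                     int(keep.sum()), excluded, freqs)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _class_transition_stack(spec: CodonModelSpec, tarr: TreeArrays,
                            blens: np.ndarray,
                            foreground_edges: set[int] | None,
                            cache: dict | None = None) -> np.ndarray:
    """P matrices, shape (n_classes, n_nodes, 61, 61); root slot unused."""
    cache = cache if cache is not None else {}

    def matrix_for(omega: float) -> CodonRateMatrix:
        key = (round(spec.kappa, 12), round(omega, 12))
        if key not in cache:
            cache[key] = CodonRateMatrix(build_Q(spec.kappa, omega, spec.freqs), spec.freqs)
        return cache[key]

    C = spec.n_classes
    P = np.empty((C, tarr.n_nodes, N_CODONS, N_CODONS))
    fg = foreground_edges or set()
    for c in range(C):
        bg_m = matrix_for(spec.omegas[c])
        fg_m = matrix_for(spec.fg_omegas[c]) if spec.fg_omegas is not None else bg_m
        for node in tarr.edges():
            m = fg_m if node in fg else bg_m
            P[c, node] = m.transition(max(blens[node], 1e-12))
    return P


def pruning_lnl(data: CodonData, tarr: TreeArrays, spec: CodonModelSpec,
                blens: np.ndarray | None = None,
                foreground_edges: set[int] | None = None,
                cache: dict | None = None,
                return_site: bool = False):
    """Mixture log-likelihood by Felsenstein pruning over 61 codon states.

    Returns lnL, or with ``return_site`` a tuple
    ``(lnL, per_class_site_loglik (C, n_patterns), pattern log-likelihoods)``.
    """
    blens = tarr.branch_lengths if blens is None else blens
    P = _class_transition_stack(spec, tarr, blens, foreground_edges, cache)
    C = spec.n_classes
    npat = data.patterns.shape[1]
    leaf_of = tarr.leaf_index
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for node in range(tarr.n_nodes):
        kids = tarr.children[node]
        if not kids:
            lab_row = data.labels.index(tarr.labels[node]) if tarr.labels[node] in data.labels else None
            if lab_row is None:
                raise ValueError(f"tree leaf {tarr.labels[node]!r} not in alignment")
            states = data.patterns[lab_row]
            L = np.zeros((C, N_CODONS, npat))
            obs = states >= 0
            L[:, :, ~obs] = 1.0
            L[:, states[obs], np.nonzero(obs)[0]] = 1.0
            partial[node] = L
        else:
            L = np.ones((C, N_CODONS, npat))
            for ch in kids:
                L *= np.einsum("cij,cjp->cip", P[:, ch], partial.pop(ch))
            if node != tarr.root:
                m = L.max(axis=(0, 1))
                m[m == 0] = 1.0
                L /= m
                logscale += np.log(m)
            partial[node] = L
    Lroot = partial[tarr.root]
    class_site = np.einsum("j,cjp->cp", spec.freqs, Lroot)
    mix = spec.proportions @ class_site
    mix = np.clip(mix, 1e-300, None)
    pat_loglik = np.log(mix) + logscale
    lnl = float(pat_loglik @ data.weights)
    if return_site:
        return lnl, class_site, pat_loglik
    return lnl


# ---------------------------------------------------------------------------
# Model construction from free parameters
# ---------------------------------------------------------------------------

def _stick(qs: Sequence[float]) -> np.ndarray:
    """Stick-breaking fractions -> proportions over len(qs)+1 classes."""
    props = []
    rest = 1.0
    for q in qs:
        props.append(rest * q)
        rest *= (1 - q)
    props.append(rest)
    return np.asarray(props)


_EPS = 1e-6


def _model_parameterization(model: str, freqs: np.ndarray, k_m3: int = 3,
                            k_beta: int = 10):
    """Free-parameter layout: (names, bounds, default inits, builder)."""
    if model == "M0":
        names = ["kappa", "omega"]
        bounds = [(1e-4, 99.0), (1e-4, 99.0)]
        inits = [[2.0, 0.4], [1.0, 0.1], [4.0, 1.5]]

        def build(x):
            return CodonModelSpec("M0", x[0], freqs, [x[1]], [1.0],
                                  params={"kappa": x[0], "omega": x[1]})
    elif model == "M3":
        names = ["kappa"] + [f"omega{i}" for i in range(k_m3)] + \
                [f"q{i}" for i in range(k_m3 - 1)]
        bounds = [(1e-4, 99.0)] + [(1e-4, 99.0)] * k_m3 + [(_EPS, 1 - _EPS)] * (k_m3 - 1)
        inits = [[2.0] + list(np.linspace(0.05, 1.5, k_m3)) + [1.0 / (k_m3 - i) for i in range(k_m3 - 1)],
                 [1.0] + list(np.linspace(0.2, 3.0, k_m3)) + [0.6] * (k_m3 - 1)]

        def build(x):
            omegas = np.array(x[1:1 + k_m3])
            props = _stick(x[1 + k_m3:])
            return CodonModelSpec("M3", x[0], freqs, omegas, props,
                                  params={"kappa": x[0], "omegas": omegas, "proportions": props})
    elif model == "M1a":
        names = ["kappa", "omega0", "p0"]
        bounds = [(1e-4, 99.0), (1e-4, 1 - 1e-6), (_EPS, 1 - _EPS)]
        inits = [[2.0, 0.2, 0.8], [2.0, 0.5, 0.5], [1.0, 0.05, 0.95]]

        def build(x):
            return CodonModelSpec("M1a", x[0], freqs, [x[1], 1.0], [x[2], 1 - x[2]],
                                  params={"kappa": x[0], "omega0": x[1], "p0": x[2]})
    elif model == "M2a":
        names = ["kappa", "omega0", "p0", "p1_frac", "omega2"]
        bounds = [(1e-4, 99.0), (1e-4, 1 - 1e-6), (_EPS, 1 - _EPS), (_EPS, 1 - _EPS),
                  (1.0, 99.0)]
        inits = [[2.0, 0.2, 0.7, 0.8, 2.0], [2.0, 0.5, 0.45, 0.5, 4.0]]

        def build(x):
            props = _stick([x[2], x[3]])  # p0, p1, p2
            return CodonModelSpec("M2a", x[0], freqs, [x[1], 1.0, x[4]], props,
                                  params={"kappa": x[0], "omega0": x[1],
                                          "proportions": props, "omega2": x[4]})
    elif model == "M7":
        names = ["kappa", "p", "q"]
        bounds = [(1e-4, 99.0), (5e-3, 99.0), (5e-3, 99.0)]
        inits = [[2.0, 0.5, 1.5], [2.0, 2.0, 2.0]]

        def build(x):
            omegas, props = discretize_beta(x[1], x[2], k_beta)
            return CodonModelSpec("M7", x[0], freqs, omegas, props,
                                  params={"kappa": x[0], "p": x[1], "q": x[2]})
    elif model == "M8":
        names = ["kappa", "p", "q", "p0", "omega_s"]
        bounds = [(1e-4, 99.0), (5e-3, 99.0), (5e-3, 99.0), (_EPS, 1 - _EPS), (1.0, 99.0)]
        inits = [[2.0, 0.5, 1.5, 0.9, 2.0], [2.0, 2.0, 2.0, 0.7, 4.0]]

        def build(x):
            omegas, props = discretize_beta(x[1], x[2], k_beta)
            omegas = np.append(omegas, x[4])
            props = np.append(props * x[3], 1 - x[3])
            return CodonModelSpec("M8", x[0], freqs, omegas, props,
                                  params={"kappa": x[0], "p": x[1], "q": x[2],
                                          "p0": x[3], "omega_s": x[4]})
    elif model in ("bsA", "bsA_null"):
        fixed_w2 = model == "bsA_null"
        names = ["kappa", "omega0", "p0", "p1_frac"] + ([] if fixed_w2 else ["omega2"])
        bounds = [(1e-4, 99.0), (1e-4, 1 - 1e-6), (_EPS, 1 - _EPS), (_EPS, 1 - _EPS)]
        inits_base = [[2.0, 0.2, 0.7, 0.8], [2.0, 0.5, 0.5, 0.5]]
        if fixed_w2:
            inits = inits_base
        else:
            bounds = bounds + [(1.0, 99.0)]
            inits = [b + [2.0] for b in inits_base] + [[2.0, 0.2, 0.7, 0.8, 6.0]]

        def build(x):
            w2 = 1.0 if fixed_w2 else x[4]
            p0, p1f = x[2], x[3]
            p01 = _stick([p0, p1f])     # p0, p1, p2-total
            pa, pb, p2 = p01
            # class 2 split between 2a (background omega0) and 2b (background 1)
            # proportionally to p0:p1, per the standard model A layout
            denom = pa + pb
            p2a = p2 * (pa / denom)
            p2b = p2 * (pb / denom)
            omegas = np.array([x[1], 1.0, x[1], 1.0])
            fg = np.array([x[1], 1.0, w2, w2])
            props = np.array([pa, pb, p2a, p2b])
            return CodonModelSpec(model, x[0], freqs, omegas, props, fg_omegas=fg,
                                  params={"kappa": x[0], "omega0": x[1],
                                          "proportions": props, "omega2": w2})
    else:
        raise ValueError(f"unknown model {model!r}")
    return names, bounds, inits, build


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    lnl: float
    params: dict
    spec: CodonModelSpec
    converged: bool
    branch_lengths: np.ndarray
    tree: dendropy.Tree
    data: CodonData
    tarr: TreeArrays
    foreground_edges: set[int] | None = None
    n_evaluations: int = 0


def foreground_edges_for(tree: dendropy.Tree, tarr: TreeArrays,
                         leaves: Sequence[str], clade: bool = False) -> set[int]:
    """Edge set for a branch-site foreground.

    Default: the stem edge above the MRCA of ``leaves`` (a single leaf gives
    its terminal edge).  With ``clade`` every edge inside the clade is
    foreground as well.
    """
    import warnings

    taxa = [t for t in tree.taxon_namespace if t.label in set(leaves)]
    if len(taxa) != len(set(leaves)):
        raise ValueError("foreground leaves not all present in tree")
    with warnings.catch_warnings():
        # the MRCA is taken relative to the stored rooting on purpose
        warnings.simplefilter("ignore", UserWarning)
        mrca = tree.mrca(taxa=taxa)
    nodes = {id(mrca)}
    if clade:
        for nd in mrca.preorder_iter():
            nodes.add(id(nd))
    index = {id(nd): i for i, nd in enumerate(tree.postorder_node_iter())}
    return {index[n] for n in nodes if index[n] != tarr.root}


def _fit_m0_with_branch_lengths(data: CodonData, tree: dendropy.Tree,
                                tarr: TreeArrays, freqs: np.ndarray,
                                init_blen: float = 0.2) -> tuple[FitResult, np.ndarray]:
    edges = tarr.edges()
    b0 = np.array([tarr.branch_lengths[e] if tarr.branch_lengths[e] > 0 else init_blen
                   for e in edges])
    x0 = np.concatenate([[np.log(2.0), np.log(0.4)], np.log(np.clip(b0, 1e-5, 20))])
    bounds = [(np.log(1e-4), np.log(99.0))] * 2 + [(np.log(1e-7), np.log(20.0))] * len(edges)
    cache: dict = {}
    nev = [0]

    def neg(x):
        nev[0] += 1
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        blens = np.zeros(tarr.n_nodes)
        blens[edges] = np.exp(x[2:])
        spec = CodonModelSpec("M0", kappa, freqs, [omega], [1.0])
        return -pruning_lnl(data, tarr, spec, blens=blens, cache=cache)

    res = scipy.optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                  options={"maxiter": 200, "ftol": 1e-9})
    kappa, omega = np.exp(res.x[0]), np.exp(res.x[1])
    blens = np.zeros(tarr.n_nodes)
    blens[edges] = np.exp(res.x[2:])
    spec = CodonModelSpec("M0", kappa, freqs, [omega], [1.0],
                          params={"kappa": kappa, "omega": omega})
    fit = FitResult("M0", -res.fun, {"kappa": kappa, "omega": omega}, spec,
                    bool(res.success), blens, tree, data, tarr,
                    n_evaluations=nev[0])
    return fit, blens


def fit_model(msa: MSA, tree: dendropy.Tree, model: str = "M0",
              foreground_leaves: Sequence[str] | None = None,
              foreground_clade: bool = False,
              freqs: str | np.ndarray = "f3x4",
              branch_lengths: np.ndarray | None = None,
              k_m3: int = 3, k_beta: int = 10,
              n_starts: int | None = None,
              extra_starts: Sequence[Sequence[float]] | None = None) -> FitResult:
    """Fit a codon model by bounded multi-start quasi-Newton.

    Branch lengths: if ``branch_lengths`` is given (postorder edge array from
    a previous M0 fit) they are held fixed; otherwise they are estimated
    jointly under M0 first and then fixed for the requested model.
    """
    tarr = tree_to_arrays(tree, default_blen=0.1)
    data = encode_codon_msa(msa)
    freq_vec = data.freqs_f3x4 if isinstance(freqs, str) and freqs == "f3x4" else (
        equal_codon_freqs() if isinstance(freqs, str) else np.asarray(freqs))

    if branch_lengths is None:
        m0_fit, blens = _fit_m0_with_branch_lengths(data, tree, tarr, freq_vec)
        if model == "M0":
            set_branch_lengths(tree, tarr, blens)
            return m0_fit
    else:
        blens = np.asarray(branch_lengths, float)
        if model == "M0":
            # M0 with fixed branch lengths: fall through to generic path
            pass

    fg_edges = None
    if model in BRANCH_SITE_MODELS:
        if not foreground_leaves:
            raise ValueError("branch-site models need foreground_leaves")
        fg_edges = foreground_edges_for(tree, tarr, foreground_leaves, foreground_clade)

    names, bounds, inits, build = _model_parameterization(model, freq_vec, k_m3, k_beta)
    cache: dict = {}
    nev = [0]

    def neg(x):
        nev[0] += 1
        try:
            spec = build(list(x))
        except ValueError:
            return 1e12
        return -pruning_lnl(data, tarr, spec, blens=blens,
                            foreground_edges=fg_edges, cache=cache)

    if n_starts is not None:
        inits = inits[:n_starts]
    if extra_starts:
        inits = list(inits) + [list(s) for s in extra_starts]
    best = None
    for x0 in inits:
        res = scipy.optimize.minimize(neg, np.asarray(x0, float), method="L-BFGS-B",
                                      bounds=bounds,
                                      options={"maxiter": 300, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    spec = build(list(best.x))
    fit = FitResult(model, -best.fun, dict(spec.params), spec, bool(best.success),
                    blens, tree, data, tarr, foreground_edges=fg_edges,
                    n_evaluations=nev[0])
    if not best.success:
        logger.warning("%s fit flagged non-converged (best lnL %.4f returned)",
                       model, fit.lnl)
    return fit


def refine_from(fit_null: FitResult, model: str, extra_init: Sequence[float]) -> list[float]:
    """Starting point for an alternative model seeded at a null fit's MLE."""
    p = fit_null.params
    if model == "M2a" and fit_null.model == "M1a":
        # p2 -> 0, omega2 -> 1: the alternative contains the null
        return [p["kappa"], p["omega0"], p["p0"] * (1 - 1e-4), 1 - 1e-4, 1.0 + 1e-6]
    if model == "bsA" and fit_null.model == "bsA_null":
        pr = p["proportions"]
        p0 = pr[0] + pr[2]
        p1 = pr[1] + pr[3]
        return [p["kappa"], p["omega0"], p0 / (p0 + p1) if p0 + p1 > 0 else 0.5,
                1 - 1e-4, 1.0 + 1e-6]
    return list(extra_init)


# ---------------------------------------------------------------------------
# LRT and site posteriors
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float


def lrt(fit_null: FitResult, fit_alt: FitResult, df: int) -> LrtResult:
    """Likelihood-ratio test 2*(lnL_alt - lnL_null) against chi2(df).

    Small negative differences within optimizer tolerance are clamped to 0
    with a warning; larger violations raise.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = fit_alt.lnl - fit_null.lnl
    if delta < -0.5:
        raise ValueError(f"alternative lnL below null by {-delta:.3f}; models not nested "
                         "or optimisation failed")
    if delta < 0:
        if delta < -1e-6:
            logger.warning("lnL_alt < lnL_null by %.2e (optimizer tolerance); clamped", -delta)
        delta = 0.0
    stat = 2.0 * delta
    return LrtResult(stat, df, float(chi2.sf(stat, df)))


STANDARD_TESTS = {
    ("M0", "M3"): 4,       # k=3 categories: 2 extra omegas + 2 proportions
    ("M1a", "M2a"): 2,
    ("M7", "M8"): 2,
    ("bsA_null", "bsA"): 1,
}


@dataclass
class SitePosteriors:
    posteriors: np.ndarray       # (n_sites, n_classes)
    class_omegas: np.ndarray
    positive_sites: list[tuple[int, float]]   # (0-based site, posterior)


def site_posteriors(fit: FitResult, threshold: float = 0.75) -> SitePosteriors:
    """Naive empirical Bayes class posteriors at the MLEs.

    Sites whose posterior probability of belonging to a positively selected
    class (omega > 1, or the foreground omega2 classes of branch-site A)
    exceeds ``threshold`` are flagged.
    """
    if fit.spec.n_classes < 2:
        raise ValueError("site posteriors require a mixture model (M0 has one class)")
    _, class_site, _ = pruning_lnl(fit.data, fit.tarr, fit.spec,
                                   blens=fit.branch_lengths,
                                   foreground_edges=fit.foreground_edges,
                                   return_site=True)
    joint = fit.spec.proportions[:, None] * class_site
    denom = joint.sum(axis=0, keepdims=True)
    denom[denom == 0] = 1.0
    post_pat = (joint / denom).T                     # (n_patterns, C)
    post = post_pat[fit.data.site_to_pattern]        # (n_sites, C)
    if fit.spec.fg_omegas is not None:
        pos_mask = fit.spec.fg_omegas > 1.0
    else:
        pos_mask = fit.spec.omegas > 1.0
    p_pos = post[:, pos_mask].sum(axis=1) if pos_mask.any() else np.zeros(len(post))
    flagged = [(int(i), float(p_pos[i])) for i in np.nonzero(p_pos > threshold)[0]]
    flagged.sort(key=lambda t: -t[1])
    return SitePosteriors(post, fit.spec.omegas, flagged)
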