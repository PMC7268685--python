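"""Substitution models, discrete-gamma rate variation, and Felsenstein
pruning on fixed trees.

The engine is deliberately small: time-reversible models built from an
exchangeability matrix S and equilibrium frequencies pi, with
Q = S.diag(pi) rescaled to one expected substitution per unit branch length,
plus equal-probability discrete-gamma rate categories (category means).
Transition matrices come from the symmetric eigendecomposition of
diag(pi)^(1/2) Q diag(pi)^(-1/2), which is numerically stable for
reversible Q.  Non-reversible generators (needed for ARD Mk models) can be
plugged into the same pruning code through the ``transition`` protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .errors import UnknownTaxonError
from .seqio import Alphabet, PartitionedAlignment, Phylogeny

__all__ = [
    "SubstitutionModel",
    "LikelihoodResult",
    "poisson_model",
    "jc_model",
    "gtr_model",
    "read_paml_rates",
    "empirical_freqs",
    "discrete_gamma_rates",
    "transition_matrix",
    "pruning_loglik",
    "loglik_codes",
    "TreeIndex",
]

_FREQ_TOL = 1e-12
_TINY = 1e-300


@dataclass
class SubstitutionModel:
    """Time-reversible CTMC over a finite state alphabet.

    Attributes
    ----------
    alphabet:
        :class:`~phyloscreen.seqio.Alphabet`; fixes the state order.
    exchangeability:
        Symmetric non-negative matrix S with zero diagonal.
    freqs:
        Equilibrium frequencies pi (sum to 1).
    alpha:
        Shape of the discrete-gamma rate distribution, or None for a single
        rate class.
    n_cat:
        Number of gamma categories (default 4).
    """

    alphabet: Alphabet
    exchangeability: np.ndarray
    freqs: np.ndarray
    alpha: float | None = None
    n_cat: int = 4
    name: str = "custom"
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        k = len(self.alphabet.states)
        S = np.asarray(self.exchangeability, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if S.shape != (k, k):
            raise ValueError(f"exchangeability must be {k}x{k}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0) or np.any(np.diag(S) != 0):
            raise ValueError("exchangeabilities must be >=0 with zero diagonal")
        if abs(pi.sum() - 1.0) > 1e-6 or np.any(pi <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()
        assert abs(pi.sum() - 1.0) < _FREQ_TOL
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self.exchangeability = S
        self.freqs = pi

    @property
    def k(self) -> int:
        return len(self.alphabet.states)

    @property
    def Q(self) -> np.ndarray:
        """Rate matrix scaled to one expected substitution per unit time."""
        Q = self.exchangeability * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(self.freqs @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate model: zero total substitution rate")
        return Q / mu

    def _spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._eig is None:
            sq = np.sqrt(self.freqs)
            B = (sq[:, None] * self.Q) / sq[None, :]
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U.T * sq[None, :]        # U^T diag(sqrt(pi))
            right = (1.0 / sq)[:, None] * U  # diag(1/sqrt(pi)) U
            self._eig = (w, right, left)
        return self._eig

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left = self._spectral()
        P = (right * np.exp(w * t * rate)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_multi(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked transition matrices, one per rate multiplier: (C, k, k)."""
        return self.transition_batch(np.array([t]), np.asarray(rates))[0]

    def transition_batch(self, ts: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """Transition matrices for every (branch length, rate) pair:
        shape (len(ts), len(rates), k, k)."""
        if np.any(ts < 0):
            raise ValueError("branch length must be non-negative")
        w, right, left = self._spectral()
        scale = ts[:, None] * rates[None, :]  # (B, C)
        E = np.exp(scale[:, :, None] * w[None, None, :])  # (B, C, k)
        P = np.matmul(right[None, None, :, :] * E[:, :, None, :], left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=3, keepdims=True)
        return P

    def rates(self) -> np.ndarray:
        if self.alpha is None or self.n_cat <= 1:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cat)


def transition_matrix(model, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition probabilities over branch length ``t`` at a rate multiplier."""
    return model.transition(t, rate)


def poisson_model(
    alphabet: Alphabet,
    freqs: np.ndarray | None = None,
    alpha: float | None = None,
    n_cat: int = 4,
) -> SubstitutionModel:
    """Uniform exchangeabilities (the 'poisson' model); default equal pi."""
    k = len(alphabet.states)
    S = np.ones((k, k)) - np.eye(k)
    pi = np.full(k, 1.0 / k) if freqs is None else np.asarray(freqs, float)
    return SubstitutionModel(alphabet, S, pi, alpha, n_cat, name="poisson")


def jc_model(alpha: float | None = None, n_cat: int = 4) -> SubstitutionModel:
    """Jukes-Cantor: poisson exchangeabilities and equal frequencies on NT."""
    m = poisson_model(Alphabet.NT, alpha=alpha, n_cat=n_cat)
    m.name = "jc"
    return m


def gtr_model(
    exchangeability: np.ndarray,
    freqs: np.ndarray,
    alpha: float | None = None,
    n_cat: int = 4,
    name: str = "gtr",
) -> SubstitutionModel:
    return SubstitutionModel(
        Alphabet.NT, np.asarray(exchangeability, float), np.asarray(freqs, float),
        alpha, n_cat, name=name,
    )


def read_paml_rates(
    path: str | Path,
    alphabet: Alphabet = Alphabet.AA,
    alpha: float | None = None,
    n_cat: int = 4,
) -> SubstitutionModel:
    """Load an empirical rate matrix in PAML .dat layout.

    The file holds the strictly-lower-triangular exchangeabilities row by row
    (k-1 rows) followed by the k equilibrium frequencies; comments after the
    frequency block are ignored.
    """
    k = len(alphabet.states)
    numbers: list[float] = []
    need = k * (k - 1) // 2 + k
    for line in Path(path).read_text().splitlines():
        for tok in line.split():
            try:
                numbers.append(float(tok))
            except ValueError:
                break
        if len(numbers) >= need:
            break
    if len(numbers) < need:
        raise ValueError(f"expected at least {need} numbers in PAML file {path}")
    S = np.zeros((k, k))
    pos = 0
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[pos]
            pos += 1
    pi = np.array(numbers[pos : pos + k])
    return SubstitutionModel(alphabet, S, pi, alpha, n_cat, name=Path(path).stem)


def empirical_freqs(
    aln: PartitionedAlignment,
    rows: np.ndarray | None = None,
    columns: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """State frequencies counted from the data, with a pseudocount per state.

    The pseudocount keeps every frequency positive even on tiny
    sub-alignments (e.g. the four rows of one quartet).
    """
    sub = aln.matrix
    if rows is not None:
        sub = sub[rows]
    if columns is not None:
        sub = sub[:, columns]
    states = list(aln.alphabet.states)
    counts = np.array([(sub == s).sum() for s in states], dtype=float)
    counts += pseudocount
    return counts / counts.sum()


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability gamma categories (mean-1 gamma).

    Category boundaries are gamma quantiles; each category's rate is its
    conditional mean, renormalized so the average multiplier is exactly 1.
    """
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1 or not np.isfinite(alpha):
        return np.ones(k)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], alpha * edges, [np.inf]])
    upper = gammainc(alpha + 1, cuts[1:])
    lower = gammainc(alpha + 1, cuts[:-1])
    rates = k * (upper - lower)
    rates /= rates.mean()
    return rates


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods (nats)."""

    loglik: float
    site_logliks: np.ndarray
    n_patterns: int

    def __post_init__(self) -> None:
        assert abs(self.site_logliks.sum() - self.loglik) < 1e-9 * max(
            1.0, abs(self.loglik)
        )


class TreeIndex:
    """Array representation of a rooted tree for fast pruning.

    Nodes are numbered in postorder; leaves carry alignment row indices.
    """

    def __init__(self, tree: Phylogeny, taxa: list[str]):
        taxon_row = {t: i for i, t in enumerate(taxa)}
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.children: list[list[int]] = []
        self.branch_lengths: list[list[float]] = []
        self.leaf_rows: list[int | None] = []
        self.leaf_labels: list[str | None] = []
        for nd in self.nodes:
            kids = nd.child_nodes()
            self.children.append([self.index[id(c)] for c in kids])
            self.branch_lengths.append(
                [c.edge.length if c.edge.length is not None else 0.0 for c in kids]
            )
            if not kids:
                label = nd.taxon.label if nd.taxon is not None else None
                if label is None or label not in taxon_row:
                    raise UnknownTaxonError(
                        f"tree leaf {label!r} has no sequence in the alignment"
                    )
                self.leaf_rows.append(taxon_row[label])
                self.leaf_labels.append(label)
            else:
                self.leaf_rows.append(None)
                self.leaf_labels.append(None)
        self.root = self.n_nodes - 1

    def edge_list(self) -> list[tuple[int, int, float]]:
        """(parent, child, length) triples in postorder of the child."""
        out = []
        for p, kids in enumerate(self.children):
            for c, t in zip(kids, self.branch_lengths[p]):
                out.append((p, c, t))
        return out


def _tip_partials(codes: np.ndarray, k: int) -> np.ndarray:
    """(n_rows, n_patterns, k) partials; missing (-1) is all-ones."""
    n_rows, n_pat = codes.shape
    L = np.zeros((n_rows, n_pat, k))
    miss = codes < 0
    L[np.where(miss)[0], np.where(miss)[1], :] = 1.0
    obs = np.where(~miss)
    L[obs[0], obs[1], codes[obs]] = 1.0
    return L


def pruning_partials(
    ti: TreeIndex,
    tips: np.ndarray,
    model,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial likelihoods at every node for one rate category.

    Returns (partials[n_nodes, n_pat, k], logscale[n_pat]) where logscale
    accumulates the per-pattern scaling applied at internal nodes.
    """
    k = tips.shape[2]
    n_pat = tips.shape[1]
    partials = np.empty((ti.n_nodes, n_pat, k))
    logscale = np.zeros(n_pat)
    for i in range(ti.n_nodes):
        kids = ti.children[i]
        if not kids:
            partials[i] = tips[ti.leaf_rows[i]]
            continue
        acc = np.ones((n_pat, k))
        for c, t in zip(kids, ti.branch_lengths[i]):
            P = model.transition(t, rate)
            acc *= partials[c] @ P.T
        scale = acc.max(axis=1)
        scale[scale == 0.0] = _TINY
        partials[i] = acc / scale[:, None]
        logscale += np.log(scale)
    return partials, logscale


def loglik_codes(
    ti,
    codes: np.ndarray,
    model,
    root_freqs: np.ndarray | None = None,
    k: int | None = None,
) -> LikelihoodResult:
    """Pruning log-likelihood from a TreeIndex(-like) and integer site codes.

    ``codes`` has one row per tip-array slot referenced by ``ti.leaf_rows``;
    -1 marks missing data (all-ones partials).  This is the shared engine
    behind both sequence likelihoods and Mk character likelihoods.
    """
    if k is None:
        k = model.k if hasattr(model, "k") else len(model.freqs)
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    tips = _tip_partials(patterns.T, k)
    pi = np.asarray(root_freqs if root_freqs is not None else model.freqs, float)
    rates = model.rates()
    per_cat = np.empty((len(rates), tips.shape[1]))
    for ci, r in enumerate(rates):
        partials, logscale = pruning_partials(ti, tips, model, r)
        lik = partials[ti.root] @ pi
        lik[lik <= 0.0] = _TINY
        per_cat[ci] = np.log(lik) + logscale
    pat_log = logsumexp(per_cat, axis=0) - np.log(len(rates))
    site_log = pat_log[inverse]
    return LikelihoodResult(
        loglik=float(site_log.sum()), site_logliks=site_log, n_patterns=len(counts)
    )


def pruning_loglik(
    tree: Phylogeny,
    aln: PartitionedAlignment,
    model,
    root_freqs: np.ndarray | None = None,
) -> LikelihoodResult:
    """Felsenstein-pruning log-likelihood of an alignment on a fixed tree.

    Missing states contribute all-ones tip partials; the root is weighted by
    the model's equilibrium frequencies (or ``root_freqs``); gamma rate
    variation is a uniform mixture over categories.  Reversibility makes the
    result independent of root placement.
    """
    ti = TreeIndex(tree, aln.taxa)
    codes = aln.encode()
    rows = sorted({r for r in ti.leaf_rows if r is not None})
    row_map = np.full(aln.n_taxa, -1)
    for new, old in enumerate(rows):
        row_map[old] = new
    remapped = TreeIndexView(ti, row_map)
    return loglik_codes(remapped, codes[rows], model, root_freqs)


class TreeIndexView:
    """A TreeIndex with leaf rows remapped onto a compacted tip array."""

    def __init__(self, ti: TreeIndex, row_map: np.ndarray):
        self.n_nodes = ti.n_nodes
        self.children = ti.children
        self.branch_lengths = ti.branch_lengths
        self.leaf_rows = [
            None if r is None else int(row_map[r]) for r in ti.leaf_rows
        ]
        self.root = ti.root
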