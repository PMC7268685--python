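"""Ancestral reconstruction of discrete characters on a fixed tree.

Three complementary layers:

* **Sankoff parsimony** — minimum-change reconstruction with the union of
  states over all most-parsimonious reconstructions per node, and a list of
  branches whose state change is unambiguous (an apomorphy list).
* **Mk maximum likelihood** — continuous-time Markov models over the
  character's states with equal-rates (ER), symmetric (SYM) or
  all-rates-different (ARD) parameterizations, fitted by maximizing the
  pruning likelihood; AIC/AICc for model choice.  Branch lengths may be in
  any units (e.g. millions of years on a chronogram); the rate absorbs the
  scale.
* **Stochastic character mapping (SCM)** — full character histories (joint
  node states plus substitution paths along branches) sampled conditional on
  the tips under a fitted Mk model.  Node-state frequencies over many
  histories estimate posterior ancestral-state probabilities; the exact
  marginal reconstruction is available as an oracle for them.

Path sampling is rejection-first (forward simulation conditioned by
acceptance of the end state) with a uniformization bridge as fallback when a
branch's endpoint combination is too improbable for rejection to be cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import poisson

from .errors import StateError
from .models import TreeIndex, loglik_codes
from .seqio import CharacterMatrix, MISSING_CODES, Phylogeny

__all__ = [
    "MkModel",
    "ParsimonyResult",
    "SCMResult",
    "sankoff",
    "sankoff_matrix",
    "fitch_count",
    "mk_fit",
    "mk_model_select",
    "marginal_ancestral",
    "scm_sample",
]

_STRUCTURES = ("ER", "SYM", "ARD")
_LOG_RATE_MIN, _LOG_RATE_MAX = np.log(1e-9), np.log(1e3)


# ---------------------------------------------------------------------------
# tree / character plumbing
# ---------------------------------------------------------------------------


def _leaf_labels(tree: Phylogeny) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _tree_index(tree: Phylogeny) -> tuple[TreeIndex, list[str]]:
    taxa = _leaf_labels(tree)
    ti = TreeIndex(tree, taxa)
    labels = []
    for i, nd in enumerate(ti.nodes):
        if ti.leaf_rows[i] is not None:
            labels.append(ti.leaf_labels[i])
        else:
            labels.append(nd.label if nd.label else f"N{i}")
    return ti, labels


def _encode_character(
    character: dict[str, str], taxa: list[str], states: tuple[str, ...]
) -> np.ndarray:
    """Integer codes per taxon; -1 for missing; errors on undeclared states."""
    lookup = {s: i for i, s in enumerate(states)}
    codes = np.empty(len(taxa), dtype=np.int16)
    for i, t in enumerate(taxa):
        s = character.get(t, "?")
        if s in MISSING_CODES:
            codes[i] = -1
        elif s in lookup:
            codes[i] = lookup[s]
        else:
            raise StateError(f"state {s!r} of taxon {t!r} not in {states}")
    return codes


def _infer_states(character: dict[str, str]) -> tuple[str, ...]:
    return tuple(sorted(set(character.values()) - set(MISSING_CODES)))


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------


@dataclass
class ParsimonyResult:
    character: str
    states: tuple[str, ...]
    min_changes: float
    node_states: dict[str, frozenset]
    changes: list[tuple[str, str, str]]  # (child node label, from, to)

    def __post_init__(self) -> None:
        assert self.min_changes >= 0
        assert all(len(s) > 0 for s in self.node_states.values())


def sankoff(
    tree: Phylogeny,
    character: dict[str, str],
    states: tuple[str, ...] | None = None,
    cost: np.ndarray | None = None,
    name: str = "char",
) -> ParsimonyResult:
    """Sankoff dynamic-programming parsimony for one discrete character.

    Missing tips allow every state.  ``node_states`` holds, per node, the
    states attained in at least one most-parsimonious reconstruction; a
    branch appears in ``changes`` only when parent and child sets are
    disjoint singletons, i.e. every MPR implies the same change.
    """
    if states is None:
        states = _infer_states(character)
    k = len(states)
    if k == 0:
        raise StateError("character has no observed states")
    C = cost if cost is not None else (1.0 - np.eye(k))
    ti, labels = _tree_index(tree)
    codes = _encode_character(character, [t or "" for t in ti.leaf_labels], states)
    INF = np.inf
    cost_vec = np.zeros((ti.n_nodes, k))
    for i in range(ti.n_nodes):
        kids = ti.children[i]
        if not kids:
            c = codes[i]
            if c >= 0:
                cost_vec[i] = INF
                cost_vec[i, c] = 0.0
            continue
        total = np.zeros(k)
        for ch in kids:
            # min over child states t of cost_vec[ch][t] + C[s, t]
            total += (C + cost_vec[ch][None, :]).min(axis=1)
        cost_vec[i] = total
    root = ti.root
    min_changes = float(cost_vec[root].min())
    allowed: list[set[int]] = [set() for _ in range(ti.n_nodes)]
    allowed[root] = set(np.flatnonzero(cost_vec[root] == cost_vec[root].min()))
    for i in reversed(range(ti.n_nodes)):  # preorder
        for ch in ti.children[i]:
            opts = C + cost_vec[ch][None, :]  # (parent s, child t)
            best = opts.min(axis=1)
            for s in allowed[i]:
                allowed[ch] |= set(np.flatnonzero(opts[s] == best[s]))
    node_states = {
        labels[i]: frozenset(states[s] for s in allowed[i])
        for i in range(ti.n_nodes)
    }
    changes = []
    for p, c, _t in ti.edge_list():
        ps, cs = allowed[p], allowed[c]
        if len(ps) == 1 and len(cs) == 1 and ps != cs:
            changes.append(
                (labels[c], states[next(iter(ps))], states[next(iter(cs))])
            )
    return ParsimonyResult(
        character=name,
        states=states,
        min_changes=min_changes,
        node_states=node_states,
        changes=changes,
    )


def sankoff_matrix(
    tree: Phylogeny, cm: CharacterMatrix
) -> tuple[list[ParsimonyResult], pd.DataFrame]:
    """Run Sankoff on every character of a matrix; stacked apomorphy table."""
    results = []
    rows = []
    for name in cm.characters:
        res = sankoff(tree, cm.column(name), states=cm.state_lists[name], name=name)
        results.append(res)
        for child, frm, to in res.changes:
            rows.append({"character": name, "branch_to": child, "from": frm, "to": to})
    return results, pd.DataFrame(rows, columns=["character", "branch_to", "from", "to"])


def fitch_count(tree: Phylogeny, character: dict[str, str]) -> int:
    """Fitch pass change count (binary trees, unit costs); cross-check only."""
    states = _infer_states(character)
    full = set(states)
    changes = 0

    def post(nd) -> set:
        nonlocal changes
        if nd.is_leaf():
            s = character.get(nd.taxon.label, "?")
            return full.copy() if s in MISSING_CODES else {s}
        sets = [post(c) for c in nd.child_nodes()]
        acc = sets[0]
        for s in sets[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        return acc

    post(tree.seed_node)
    return changes


# ---------------------------------------------------------------------------
# Mk models
# ---------------------------------------------------------------------------


@dataclass
class MkModel:
    """Mk rate model over a character's states.

    ``rates`` holds the free off-diagonal parameters: 1 value for ER,
    k(k-1)/2 for SYM (upper triangle, row-major), k(k-1) for ARD (row-major
    off-diagonal).  The root prior defaults to uniform.
    """

    states: tuple[str, ...]
    structure: str
    rate_params: np.ndarray
    root_prior: np.ndarray | None = None
    loglik: float | None = None
    aic: float | None = None
    aicc: float | None = None
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        k = len(self.states)
        expected = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[
            self.structure
        ]
        self.rate_params = np.asarray(self.rate_params, dtype=float)
        if self.rate_params.shape != (expected,):
            raise ValueError(
                f"{self.structure} with {k} states needs {expected} rates"
            )
        if np.any(self.rate_params <= 0):
            raise ValueError("rates must be positive")
        if self.root_prior is None:
            self.root_prior = np.full(k, 1.0 / k)

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return len(self.rate_params)

    @property
    def freqs(self) -> np.ndarray:
        return self.root_prior

    @property
    def Q(self) -> np.ndarray:
        k = self.k
        Q = np.zeros((k, k))
        if self.structure == "ER":
            Q[:] = self.rate_params[0]
        elif self.structure == "SYM":
            iu = np.triu_indices(k, 1)
            Q[iu] = self.rate_params
            Q.T[iu] = self.rate_params
        else:  # ARD
            mask = ~np.eye(k, dtype=bool)
            Q[mask] = self.rate_params
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = expm(self.Q * (t * rate))
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def rates(self) -> np.ndarray:
        return np.ones(1)


def _char_code_matrix(
    ti: TreeIndex,
    characters: list[dict[str, str]],
    states: tuple[str, ...],
) -> np.ndarray:
    cols = [
        _encode_character(ch, [t or "" for t in ti.leaf_labels], states)
        for ch in characters
    ]
    return np.stack(cols, axis=1)  # (n_nodes-slots, n_chars); internal rows unused


class _MkTreeView:
    """TreeIndex facade mapping tip slots straight onto code-matrix rows."""

    def __init__(self, ti: TreeIndex):
        self.n_nodes = ti.n_nodes
        self.children = ti.children
        self.branch_lengths = ti.branch_lengths
        self.leaf_rows = [
            i if r is not None else None for i, r in enumerate(ti.leaf_rows)
        ]
        self.root = ti.root


def _as_characters(
    data: dict[str, str] | CharacterMatrix,
) -> tuple[list[dict[str, str]], tuple[str, ...], str]:
    if isinstance(data, CharacterMatrix):
        chars = [data.column(c) for c in data.characters]
        states = tuple(
            sorted(set().union(*(set(s) for s in data.state_lists.values())))
        )
        return chars, states, "+".join(data.characters)
    states = _infer_states(data)
    return [data], states, "char"


def mk_fit(
    tree: Phylogeny,
    data: dict[str, str] | CharacterMatrix,
    structure: str = "ER",
    states: tuple[str, ...] | None = None,
    root_prior: np.ndarray | None = None,
    init_rates: np.ndarray | None = None,
) -> MkModel:
    """Maximum-likelihood Mk fit on a fixed tree with branch lengths.

    A CharacterMatrix is treated as independent characters sharing one rate
    matrix (the joint likelihood is the product over characters).  Rates are
    optimized in log space; ``at_bound`` flags an MLE pinned at the search
    bounds (e.g. constant characters, where the likelihood is monotone in
    the rate).
    """
    characters, inferred, _ = _as_characters(data)
    states = states or inferred
    k = len(states)
    if k < 2:
        raise StateError("Mk needs at least two observed states")
    ti, _ = _tree_index(tree)
    view = _MkTreeView(ti)
    codes = _char_code_matrix(ti, characters, states)
    n_par = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]
    tree_len = sum(t for _, _, t in ti.edge_list()) or 1.0
    prior = root_prior if root_prior is not None else np.full(k, 1.0 / k)

    def negloglik(x: np.ndarray) -> float:
        model = MkModel(states, structure, np.exp(x), root_prior=prior)
        return -loglik_codes(view, codes, model, root_freqs=prior, k=k).loglik

    starts = []
    if init_rates is not None:
        starts.append(np.log(np.asarray(init_rates, float)))
    for scale in (1.0, 10.0, 0.1):
        starts.append(np.full(n_par, np.log(scale / tree_len)))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            negloglik,
            np.clip(x0, _LOG_RATE_MIN + 1, _LOG_RATE_MAX - 1),
            method="L-BFGS-B",
            bounds=[(_LOG_RATE_MIN, _LOG_RATE_MAX)] * n_par,
            options={"ftol": 1e-10, "maxiter": 500},
        )
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    logl = -best_f
    at_bound = bool(
        np.any(best_x <= _LOG_RATE_MIN + 1e-6) or np.any(best_x >= _LOG_RATE_MAX - 1e-6)
    )
    n_obs = codes.shape[1]
    aic = 2 * n_par - 2 * logl
    denom = n_obs - n_par - 1
    aicc = aic + (2 * n_par * (n_par + 1) / denom) if denom > 0 else np.inf
    return MkModel(
        states,
        structure,
        np.exp(best_x),
        root_prior=prior,
        loglik=logl,
        aic=aic,
        aicc=float(aicc),
        at_bound=at_bound,
    )


def mk_model_select(
    tree: Phylogeny,
    data: dict[str, str] | CharacterMatrix,
    structures: tuple[str, ...] = _STRUCTURES,
    **kwargs,
) -> dict[str, MkModel]:
    """Fit nested Mk structures, seeding each from the previous optimum.

    Chaining the initializations (ER -> SYM -> ARD) guarantees the fitted
    log-likelihoods respect the nesting order.
    """
    fits: dict[str, MkModel] = {}
    prev: MkModel | None = None
    for structure in structures:
        init = None
        if prev is not None:
            k = len(prev.states)
            Qprev = prev.Q
            if structure == "SYM":
                iu = np.triu_indices(k, 1)
                init = (Qprev[iu] + Qprev.T[iu]) / 2.0
            elif structure == "ARD":
                init = Qprev[~np.eye(k, dtype=bool)]
        init = None if init is None else np.maximum(init, 1e-9)
        fits[structure] = mk_fit(tree, data, structure, init_rates=init, **kwargs)
        prev = fits[structure]
    return fits


# ---------------------------------------------------------------------------
# exact marginal ancestral states
# ---------------------------------------------------------------------------


def _inside_outside(
    ti, codes: np.ndarray, model: MkModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Below/above partial likelihoods and node posteriors for one character.

    Returns (below, above, posterior) arrays of shape (n_nodes, k) plus the
    per-branch transition matrices used.
    """
    k = model.k
    below = np.zeros((ti.n_nodes, k))
    P: dict[int, np.ndarray] = {}
    for i in range(ti.n_nodes):
        kids = ti.children[i]
        if not kids:
            c = codes[ti.leaf_rows[i]] if ti.leaf_rows[i] is not None else -1
            below[i] = 1.0 if c < 0 else 0.0
            if c >= 0:
                below[i, c] = 1.0
            continue
        acc = np.ones(k)
        for ch, t in zip(kids, ti.branch_lengths[i]):
            P[ch] = model.transition(t)
            acc = acc * (P[ch] @ below[ch])
        m = acc.max()
        below[i] = acc / m if m > 0 else acc
    above = np.zeros((ti.n_nodes, k))
    above[ti.root] = model.root_prior
    for i in reversed(range(ti.n_nodes)):
        kids = ti.children[i]
        if not kids:
            continue
        msgs = {ch: P[ch] @ below[ch] for ch in kids}
        for ch in kids:
            others = np.ones(k)
            for sib in kids:
                if sib != ch:
                    others = others * msgs[sib]
            above[ch] = (above[i] * others) @ P[ch]
            m = above[ch].max()
            if m > 0:
                above[ch] /= m
    post = above * below
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm
    return below, above, post


def marginal_ancestral(
    tree: Phylogeny, character: dict[str, str], model: MkModel
) -> pd.DataFrame:
    """Exact marginal posterior state probabilities at every node.

    Standard inside-outside reconstruction: each node's posterior is
    conditioned on all tips and the root prior.  Tip rows are point masses on
    the observed state (or the tip's conditional posterior when missing).
    """
    ti, labels = _tree_index(tree)
    codes = _encode_character(
        character, [t or "" for t in ti.leaf_labels], model.states
    )
    view = _MkTreeView(ti)
    _, _, post = _inside_outside(view, codes, model)[:3]
    return pd.DataFrame(post, index=labels, columns=list(model.states))


# ---------------------------------------------------------------------------
# stochastic character mapping
# ---------------------------------------------------------------------------


@dataclass
class SCMResult:
    """Summaries of sampled character histories."""

    character: str
    states: tuple[str, ...]
    n_histories: int
    node_freqs: pd.DataFrame  # nodes x states, rows sum to 1
    transitions: pd.DataFrame  # branch_to, from, to, expected count per history
    dwell: pd.Series  # expected total time per state per history
    seed: int
    n_fallback: int = 0

    def __post_init__(self) -> None:
        sums = self.node_freqs.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-8)

    @property
    def expected_changes(self) -> float:
        return float(self.transitions["count"].sum())


def _forward_path(Q, jump_cum, exit_rates, a, t, rng):
    """Simulate one unconditioned CTMC path; returns (end, counts, dwell)."""
    k = Q.shape[0]
    counts = np.zeros((k, k))
    dwell = np.zeros(k)
    s, elapsed = a, 0.0
    while True:
        rate = exit_rates[s]
        if rate <= 0:
            dwell[s] += t - elapsed
            return s, counts, dwell
        dt = rng.exponential(1.0 / rate)
        if elapsed + dt >= t:
            dwell[s] += t - elapsed
            return s, counts, dwell
        dwell[s] += dt
        elapsed += dt
        s2 = int(np.searchsorted(jump_cum[s], rng.random()))
        counts[s, s2] += 1.0
        s = s2


def _uniformization_bridge(Q, a, b, t, rng, max_terms=512):
    """Sample a path conditioned on both endpoints via uniformization."""
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    counts = np.zeros((k, k))
    dwell = np.zeros(k)
    if mu <= 0:
        dwell[a] += t
        return counts, dwell
    R = np.eye(k) + Q / mu
    Rpow = [np.eye(k)]
    weights = []
    total_target = None
    pa_b = expm(Q * t)[a, b]
    for n in range(max_terms):
        if n > 0:
            Rpow.append(Rpow[-1] @ R)
        w = poisson.pmf(n, mu * t) * Rpow[n][a, b]
        weights.append(w)
        if n > mu * t + 10 and sum(weights) > 0.9999 * pa_b:
            break
    weights = np.array(weights)
    if weights.sum() <= 0:
        dwell[a] += t
        return counts, dwell
    n_jumps = int(rng.choice(len(weights), p=weights / weights.sum()))
    seq = [a]
    for i in range(1, n_jumps):
        prev = seq[-1]
        probs = R[prev] * Rpow[n_jumps - i][:, b]
        ssum = probs.sum()
        probs = probs / ssum if ssum > 0 else np.full(k, 1.0 / k)
        seq.append(int(rng.choice(k, p=probs)))
    if n_jumps > 0:
        seq.append(b)
    times = np.sort(rng.random(n_jumps)) * t
    bounds = np.concatenate([[0.0], times, [t]])
    for i, s in enumerate(seq):
        dwell[s] += bounds[i + 1] - bounds[i]
        if i + 1 < len(seq) and seq[i + 1] != s:
            counts[s, seq[i + 1]] += 1.0
    return counts, dwell


def scm_sample(
    tree: Phylogeny,
    character: dict[str, str],
    model: MkModel,
    n_histories: int = 10000,
    seed: int = 0,
    rejection_cap: int = 1000,
    name: str = "char",
) -> SCMResult:
    """Stochastic character mapping: sample full histories given the tips.

    Node states are drawn jointly (root from its posterior, then pre-order
    conditional sampling); each branch's substitution path is then sampled
    conditioned on its endpoints, by rejection with a uniformization-bridge
    fallback after ``rejection_cap`` failed attempts per endpoint group.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ti, labels = _tree_index(tree)
    codes = _encode_character(
        character, [t or "" for t in ti.leaf_labels], model.states
    )
    view = _MkTreeView(ti)
    below, _, _ = _inside_outside(view, codes, model)
    k = model.k
    Q = model.Q
    exit_rates = -np.diag(Q)
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    row_sums = jump.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    jump_cum = np.cumsum(jump / row_sums, axis=1)

    # joint node-state sampling, vectorized across histories
    node_states = np.empty((ti.n_nodes, n_histories), dtype=np.int64)
    root_post = model.root_prior * below[ti.root]
    root_post = root_post / root_post.sum()
    node_states[ti.root] = rng.choice(k, size=n_histories, p=root_post)
    P_branch: dict[int, np.ndarray] = {}
    branch_parent: dict[int, int] = {}
    branch_len: dict[int, float] = {}
    for i in reversed(range(ti.n_nodes)):
        for ch, t in zip(ti.children[i], ti.branch_lengths[i]):
            P = model.transition(t)
            P_branch[ch], branch_parent[ch], branch_len[ch] = P, i, t
            cond = P * below[ch][None, :]
            csum = cond.sum(axis=1, keepdims=True)
            csum[csum == 0] = 1.0
            cond_cum = np.cumsum(cond / csum, axis=1)
            u = rng.random(n_histories)
            parents = node_states[i]
            node_states[ch] = (
                u[:, None] > cond_cum[parents]
            ).sum(axis=1)

    # branch path sampling, grouped by (start, end) per branch
    trans_acc: dict[int, np.ndarray] = {
        ch: np.zeros((k, k)) for ch in P_branch
    }
    dwell_acc = np.zeros(k)
    n_fallback = 0
    for ch, P in P_branch.items():
        t = branch_len[ch]
        starts = node_states[branch_parent[ch]]
        ends = node_states[ch]
        pairs, counts_per_pair = np.unique(
            np.stack([starts, ends]), axis=1, return_counts=True
        )
        for (a, b), m in zip(pairs.T, counts_per_pair):
            a, b, m = int(a), int(b), int(m)
            if t == 0.0 or exit_rates[a] == 0.0:
                dwell_acc[a] += t * m
                continue
            remaining = m
            attempts = 0
            budget = rejection_cap * m
            while remaining > 0 and attempts < budget:
                attempts += 1
                end, c_path, d_path = _forward_path(
                    Q, jump_cum, exit_rates, a, t, rng
                )
                if end == b:
                    trans_acc[ch] += c_path
                    dwell_acc += d_path
                    remaining -= 1
            for _ in range(remaining):
                n_fallback += 1
                c_path, d_path = _uniformization_bridge(Q, a, b, t, rng)
                trans_acc[ch] += c_path
                dwell_acc += d_path

    # summaries
    freq = np.zeros((ti.n_nodes, k))
    for i in range(ti.n_nodes):
        freq[i] = np.bincount(node_states[i], minlength=k) / n_histories
    node_freqs = pd.DataFrame(freq, index=labels, columns=list(model.states))
    rows = []
    for ch, mat in trans_acc.items():
        for a in range(k):
            for b in range(k):
                if a != b and mat[a, b] > 0:
                    rows.append(
                        {
                            "branch_to": labels[ch],
                            "from": model.states[a],
                            "to": model.states[b],
                            "count": mat[a, b] / n_histories,
                        }
                    )
    transitions = pd.DataFrame(rows, columns=["branch_to", "from", "to", "count"])
    dwell = pd.Series(dwell_acc / n_histories, index=list(model.states))
    return SCMResult(
        character=name,
        states=model.states,
        n_histories=n_histories,
        node_freqs=node_freqs,
        transitions=transitions,
        dwell=dwell,
        seed=seed,
        n_fallback=n_fallback,
    )
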