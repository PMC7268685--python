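"""Quartet support of a fixed species tree against a set of gene trees.

Every internal edge of a binary (unrooted) species tree defines a
quadripartition A|B|C|D of the leaves: the four leaf sets hanging off the
edge's two endpoints.  For sampled quartets (one leaf per part), each gene
tree containing all four leaves induces one of three arrangements:

    1: AB|CD (agrees with the species tree)   2: AC|BD   3: AD|BC

q1, q2, q3 are the frequencies of the arrangements among resolved
observations (gene tree x quartet), the per-internode quartet-support values
drawn as pie charts on coalescent species trees.  This is a scoring
re-implementation only: no species-tree search, and sampling (cap per edge)
replaces the full weighted tally, so the numbers are estimates of the same
quantities rather than an exact replica of any particular program's output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Phylogeny

__all__ = [
    "EdgeQuartetSupport",
    "quadripartitions",
    "edge_quartet_support",
    "annotate_species_tree",
]


@dataclass
class EdgeQuartetSupport:
    """Quartet frequencies around one internal species-tree edge."""

    edge_id: int
    parts: tuple[frozenset, frozenset, frozenset, frozenset]
    q: tuple[float, float, float] | None
    n_quartets: int
    n_observations: int
    n_resolved: int
    n_unresolved: int
    n_missing: int
    n_gene_trees: int

    def __post_init__(self) -> None:
        if self.q is not None:
            assert abs(sum(self.q) - 1.0) < 1e-10
            assert all(0.0 <= x <= 1.0 for x in self.q)


# ---------------------------------------------------------------------------
# species-tree quadripartitions
# ---------------------------------------------------------------------------


def _adjacency(tree: Phylogeny) -> tuple[dict, dict]:
    """Unrooted adjacency map {node: [neighbors]} and {node: leaf label}."""
    adj: dict = {}
    leaf: dict = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            adj[nd].append(ch)
            adj.setdefault(ch, []).append(nd)
        if nd.is_leaf():
            leaf[nd] = nd.taxon.label
    # suppress a degree-2 root so the tree is treated as unrooted
    for nd in list(adj):
        if nd not in leaf and len(adj[nd]) == 2:
            a, b = adj[nd]
            adj[a] = [x if x is not nd else b for x in adj[a]]
            adj[b] = [x if x is not nd else a for x in adj[b]]
            del adj[nd]
    return adj, leaf


def _leaves_behind(adj: dict, leaf: dict, start, avoid) -> frozenset:
    """Leaf labels reachable from ``start`` without crossing into ``avoid``."""
    out, stack, seen = [], [start], {avoid, start}
    while stack:
        nd = stack.pop()
        if nd in leaf:
            out.append(leaf[nd])
            continue
        for nb in adj[nd]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(out)


def quadripartitions(
    species_tree: Phylogeny,
) -> list[tuple[int, tuple[frozenset, frozenset, frozenset, frozenset]]]:
    """One quadripartition per binary internal edge of the unrooted tree.

    Edges incident to a polytomy are skipped with a warning; a star tree
    yields an empty list.
    """
    adj, leaf = _adjacency(species_tree)
    out = []
    seen_pairs = set()
    edge_id = 0
    for u in adj:
        if u in leaf:
            continue
        for v in adj[u]:
            if v in leaf or (id(v), id(u)) in seen_pairs:
                continue
            seen_pairs.add((id(u), id(v)))
            u_rest = [x for x in adj[u] if x is not v]
            v_rest = [x for x in adj[v] if x is not u]
            if len(u_rest) != 2 or len(v_rest) != 2:
                warnings.warn(
                    f"skipping internal edge at a polytomy "
                    f"(degrees {len(u_rest) + 1}, {len(v_rest) + 1})"
                )
                continue
            parts = (
                _leaves_behind(adj, leaf, u_rest[0], u),
                _leaves_behind(adj, leaf, u_rest[1], u),
                _leaves_behind(adj, leaf, v_rest[0], v),
                _leaves_behind(adj, leaf, v_rest[1], v),
            )
            out.append((edge_id, parts))
            edge_id += 1
    if not out:
        warnings.warn("species tree has no binary internal edge (star tree?)")
    return out


# ---------------------------------------------------------------------------
# gene-tree quartet classification
# ---------------------------------------------------------------------------


def _gene_tree_splits(tree: Phylogeny) -> tuple[set, list[frozenset]]:
    """The tree's taxon set and its non-trivial splits (child-side leaf sets)."""
    taxa: set = set()
    below: dict = {}
    splits: list[frozenset] = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
            taxa.add(nd.taxon.label)
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    n = len(taxa)
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        s = below[nd]
        if 1 < len(s) < n - 1:
            splits.append(s)
    return taxa, splits


def _classify_quartet(
    taxa: set, splits: list[frozenset], quartet: tuple[str, str, str, str]
) -> int | None:
    """Arrangement 1/2/3 of the quartet in the gene tree, 0 if unresolved,
    None if any leaf is missing."""
    a, b, c, d = quartet
    if not {a, b, c, d} <= taxa:
        return None
    for s in splits:
        inside = (a in s) + (b in s) + (c in s) + (d in s)
        if inside not in (2,):
            continue
        pair = frozenset(x for x in quartet if x in s)
        if pair == frozenset((a, b)) or pair == frozenset((c, d)):
            return 1
        if pair == frozenset((a, c)) or pair == frozenset((b, d)):
            return 2
        if pair == frozenset((a, d)) or pair == frozenset((b, c)):
            return 3
    return 0


def _sample_quartets(
    parts: tuple[frozenset, ...], cap: int, rng: np.random.Generator
) -> list[tuple[str, str, str, str]]:
    lists = [sorted(p) for p in parts]
    sizes = [len(p) for p in lists]
    total = int(np.prod(sizes))
    if total <= cap:
        return list(itertools.product(*lists))
    chosen: set[int] = set()
    while len(chosen) < cap:
        draw = rng.integers(0, total, size=cap - len(chosen))
        chosen.update(int(x) for x in draw)
    quartets = []
    for code in sorted(chosen):
        idx = []
        for s in reversed(sizes):
            idx.append(code % s)
            code //= s
        idx.reverse()
        quartets.append(tuple(lists[g][i] for g, i in enumerate(idx)))
    return quartets


def edge_quartet_support(
    species_tree: Phylogeny,
    gene_trees: list[Phylogeny],
    cap_per_edge: int = 1000,
    seed: int = 0,
) -> list[EdgeQuartetSupport]:
    """q1/q2/q3 for every internal species-tree edge from a gene-tree set.

    Per edge, up to ``cap_per_edge`` quartets are drawn (full enumeration when
    possible).  Observations are (gene tree, quartet) pairs; gene trees
    lacking a quartet taxon count as missing, polytomies as unresolved;
    unresolved observations are excluded from the q denominator.
    """
    rng = np.random.default_rng(seed)
    gt = [_gene_tree_splits(t) for t in gene_trees]
    out: list[EdgeQuartetSupport] = []
    for edge_id, parts in quadripartitions(species_tree):
        quartets = _sample_quartets(parts, cap_per_edge, rng)
        counts = [0, 0, 0]
        unresolved = missing = 0
        for q in quartets:
            for taxa, splits in gt:
                cls = _classify_quartet(taxa, splits, q)
                if cls is None:
                    missing += 1
                elif cls == 0:
                    unresolved += 1
                else:
                    counts[cls - 1] += 1
        resolved = sum(counts)
        q_vals = (
            tuple(c / resolved for c in counts) if resolved > 0 else None
        )
        out.append(
            EdgeQuartetSupport(
                edge_id=edge_id,
                parts=parts,
                q=q_vals,
                n_quartets=len(quartets),
                n_observations=resolved + unresolved + missing,
                n_resolved=resolved,
                n_unresolved=unresolved,
                n_missing=missing,
                n_gene_trees=len(gene_trees),
            )
        )
    return out


def support_table(supports: list[EdgeQuartetSupport]) -> pd.DataFrame:
    rows = []
    for s in supports:
        rows.append(
            {
                "edge": s.edge_id,
                "part_a": ",".join(sorted(s.parts[0])),
                "part_b": ",".join(sorted(s.parts[1])),
                "part_c": ",".join(sorted(s.parts[2])),
                "part_d": ",".join(sorted(s.parts[3])),
                "q1": s.q[0] if s.q else np.nan,
                "q2": s.q[1] if s.q else np.nan,
                "q3": s.q[2] if s.q else np.nan,
                "n_quartets": s.n_quartets,
                "n_resolved": s.n_resolved,
                "n_unresolved": s.n_unresolved,
                "n_missing": s.n_missing,
            }
        )
    return pd.DataFrame(rows)


def annotate_species_tree(
    species_tree: Phylogeny, supports: list[EdgeQuartetSupport]
) -> str:
    """Newick with q1/q2/q3 attached as labels of matching internal nodes.

    An edge is matched to the internal node whose below-edge leaf set equals
    one side (A+B or C+D) of the quadripartition.
    """
    below: dict = {}
    all_taxa: set = set()
    for nd in species_tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
            all_taxa.add(nd.taxon.label)
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    by_side = {}
    for s in supports:
        if s.q is None:
            continue
        side = s.parts[0] | s.parts[1]
        by_side[side] = s
        by_side[frozenset(all_taxa) - side] = s
    for nd in species_tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        s = by_side.get(below[nd])
        if s is not None:
            nd.label = f"q1={s.q[0]:.4f}|q2={s.q[1]:.4f}|q3={s.q[2]:.4f}"
    return species_tree.as_string(schema="newick", unquoted_underscores=True)
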