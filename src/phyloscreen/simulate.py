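"""Synthetic data with the statistical structure the diagnostics assume.

The generator produces every input class the pipeline consumes — partitioned
alignments, species and gene trees, discrete character matrices — so all
stages are testable without external downloads.  It deliberately emulates the
data pathologies the analyses screen for:

* lineage-specific compositional heterogeneity, as a frequency switch on the
  branches leading to a designated taxon set (the simplest violation of the
  stationarity/homogeneity assumptions that a matched-pairs symmetry test
  should detect);
* non-random taxon-by-partition occupancy (whole blocks of missing data),
  plus optional per-site dropout;
* gamma rate variation across sites;
* gene-tree discordance, as species trees perturbed by a random
  nearest-neighbor interchange with probability epsilon (an NNI stand-in for
  coalescent discordance, sufficient to exercise quartet scoring);
* discrete characters evolved under an Mk process on a chronogram.

All randomness derives from one master seed through named substreams, so
every output is byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .charmap import MkModel
from .models import SubstitutionModel, poisson_model
from .seqio import (
    Alphabet,
    CharacterMatrix,
    PartitionEntry,
    PartitionScheme,
    PartitionedAlignment,
    Phylogeny,
)

__all__ = [
    "CompositionShift",
    "OccupancySpec",
    "MkSpec",
    "SimulationSpec",
    "simulate_tree",
    "simulate_alignment",
    "simulate_gene_trees",
    "simulate_characters",
    "grouping_from_tree",
    "set_split_length",
    "substream",
    "default_shift_target",
]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from the master seed."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def default_shift_target(alphabet: Alphabet) -> tuple[float, ...]:
    """A strongly skewed frequency vector for compositional-shift scenarios:
    90% of the mass on a quarter of the states (e.g. a GC-rich-like bias on
    nucleotides)."""
    k = len(alphabet.states)
    boosted = max(2, k // 4)
    target = np.full(k, 0.1 / (k - boosted))
    target[:boosted] = 0.9 / boosted
    return tuple(target / target.sum())


@dataclass(frozen=True)
class CompositionShift:
    """Frequency switch applied on the branches leading to ``taxa``.

    On every branch whose descendant leaves all belong to ``taxa``, the
    substitution process uses perturbed equilibrium frequencies
    (1 - weight) * pi + weight * target.
    """

    taxa: tuple[str, ...]
    target_freqs: tuple[float, ...]
    weight: float = 0.5
    partitions: tuple[str, ...] | None = None  # None: all partitions

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("mixing weight must lie in [0, 1]")
        if abs(sum(self.target_freqs) - 1.0) > 1e-9:
            raise ValueError("target frequencies must sum to 1")


@dataclass(frozen=True)
class OccupancySpec:
    """Taxon-by-partition retention: a cell survives with its taxon/partition
    probability; surviving cells may additionally drop per site."""

    retention: float = 1.0  # baseline P(taxon has a partition)
    per_taxon: dict[str, float] = field(default_factory=dict)
    site_dropout: float = 0.0

    def prob(self, taxon: str) -> float:
        return self.per_taxon.get(taxon, self.retention)


@dataclass(frozen=True)
class MkSpec:
    n_characters: int = 20
    states: tuple[str, ...] = ("0", "1")
    rate: float = 0.5  # ER rate per unit branch length
    root_prior: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic study.

    Defaults mirror a desk-scale version of a phylogenomic supermatrix
    screen: 20 taxa, four amino-acid partitions of 300 sites under a poisson
    model with gamma(alpha=1) rate variation, a compositional shift on three
    taxa, block-wise missing data, 200 gene trees with 20% NNI discordance,
    and 20 binary Mk characters.
    """

    n_taxa: int = 20
    birth_rate: float = 1.0
    tree_height: float = 0.5  # expected substitutions per site, root to tip
    alphabet: Alphabet = Alphabet.AA
    n_partitions: int = 4
    partition_length: int = 300
    gamma_alpha: float | None = 1.0
    n_rate_categories: int = 4
    shift: CompositionShift | None = None
    occupancy: OccupancySpec = field(default_factory=OccupancySpec)
    epsilon: float = 0.2
    n_gene_trees: int = 200
    mk: MkSpec = field(default_factory=MkSpec)
    seed: int = 0


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> Phylogeny:
    """Yule (pure-birth) topology with exponential waiting times.

    Branch lengths are rescaled so the maximum root-to-tip depth equals
    ``spec.tree_height``.
    """
    rng = rng if rng is not None else substream(spec.seed, "tree")
    n = spec.n_taxa
    if n < 2:
        raise ValueError("need at least two taxa")
    taxa = [f"t{i + 1:02d}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    tips = [first, second]
    depth = {first: 0.0, second: 0.0}
    now = 0.0
    while len(tips) < n:
        now += rng.exponential(1.0 / (spec.birth_rate * len(tips)))
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        parent.edge.length = now - depth[parent]
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        depth[a] = depth[b] = now
        tips.extend([a, b])
    now += rng.exponential(1.0 / (spec.birth_rate * len(tips)))
    order = rng.permutation(n)
    for i, tip in enumerate(tips):
        tip.edge.length = now - depth[tip]
        tip.taxon = tns[int(order[i])]
    scale = spec.tree_height / now if now > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def _shifted_branches(tree: Phylogeny, taxa: set[str]) -> set[int]:
    """ids of nodes whose subtending branch lies entirely within ``taxa``."""
    shifted: set[int] = set()
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = {nd.taxon.label}
        else:
            below[nd] = set().union(*(below[c] for c in nd.child_nodes()))
        if nd.parent_node is not None and below[nd] <= taxa:
            shifted.add(id(nd))
    return shifted


# ---------------------------------------------------------------------------
# sequence alignments
# ---------------------------------------------------------------------------


def _evolve_partition(
    tree: Phylogeny,
    model: SubstitutionModel,
    shift_model: SubstitutionModel | None,
    shifted: set[int],
    length: int,
    rng: np.random.Generator,
    taxa_order: list[str],
) -> np.ndarray:
    k = model.k
    rates = model.rates()
    cat = rng.integers(len(rates), size=length)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(k, size=length, p=model.freqs)
    out = np.empty((len(taxa_order), length), dtype=np.int64)
    row = {t: i for i, t in enumerate(taxa_order)}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            parent_states = states[id(nd)]
        else:
            t = nd.edge.length or 0.0
            m = shift_model if (shift_model is not None and id(nd) in shifted) else model
            parent = states[id(nd.parent_node)]
            child = np.empty(length, dtype=np.int64)
            for ci, r in enumerate(rates):
                idx = np.flatnonzero(cat == ci)
                if idx.size == 0:
                    continue
                P = m.transition(t, r)
                cum = np.cumsum(P, axis=1)
                u = rng.random(idx.size)
                child[idx] = (u[:, None] > cum[parent[idx]]).sum(axis=1)
            states[id(nd)] = child
            parent_states = child
        if nd.is_leaf():
            out[row[nd.taxon.label]] = parent_states
    return out


def simulate_alignment(
    tree: Phylogeny,
    spec: SimulationSpec,
    model: SubstitutionModel | None = None,
    rng: np.random.Generator | None = None,
) -> PartitionedAlignment:
    """Evolve a partitioned alignment along the tree.

    Sites evolve independently given their gamma rate category.  Branches in
    the compositional-shift set use the perturbed-frequency model
    (a non-stationary switch); the occupancy mask is applied afterwards by
    overwriting masked cells with '-'.
    """
    rng = rng if rng is not None else substream(spec.seed, "alignment")
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if model is None:
        model = poisson_model(
            spec.alphabet, alpha=spec.gamma_alpha, n_cat=spec.n_rate_categories
        )
    shift_model = None
    shifted: set[int] = set()
    if spec.shift is not None:
        mix = np.asarray(spec.shift.target_freqs, float)
        pi = (1.0 - spec.shift.weight) * model.freqs + spec.shift.weight * mix
        shift_model = SubstitutionModel(
            model.alphabet, model.exchangeability, pi,
            model.alpha, model.n_cat, name=model.name + "+shift",
        )
        shifted = _shifted_branches(tree, set(spec.shift.taxa))
    state_symbols = np.array(list(spec.alphabet.states))
    blocks, entries, offset = [], [], 0
    for p in range(spec.n_partitions):
        name = f"p{p + 1}"
        use_shift = shift_model is not None and (
            spec.shift.partitions is None or name in spec.shift.partitions
        )
        codes = _evolve_partition(
            tree,
            model,
            shift_model if use_shift else None,
            shifted,
            spec.partition_length,
            rng,
            taxa,
        )
        blocks.append(state_symbols[codes])
        entries.append(
            PartitionEntry(name, ((offset, offset + spec.partition_length),))
        )
        offset += spec.partition_length
    matrix = np.concatenate(blocks, axis=1).astype("<U1")
    # occupancy mask
    occ = spec.occupancy
    for p, entry in enumerate(entries):
        lo, hi = entry.ranges[0]
        for i, t in enumerate(taxa):
            if rng.random() >= occ.prob(t):
                matrix[i, lo:hi] = "-"
    if occ.site_dropout > 0:
        drop = rng.random(matrix.shape) < occ.site_dropout
        matrix[drop] = "-"
    return PartitionedAlignment(
        taxa=taxa,
        matrix=matrix,
        alphabet=spec.alphabet,
        partitions=PartitionScheme(tuple(entries)),
    )


def grouping_from_tree(tree: Phylogeny, label: str = "split"):
    """A four-group hypothesis conformal with the tree's most balanced
    internal split: the four quadripartition parts around that edge."""
    from .genetree import quadripartitions
    from .seqio import TaxonGrouping

    qps = quadripartitions(tree)
    if not qps:
        raise ValueError("tree has no internal edge to build a hypothesis from")
    _, parts = max(qps, key=lambda x: min(len(p) for p in x[1]))
    return TaxonGrouping(
        label=label,
        group_names=("g1", "g2", "g3", "g4"),
        groups=tuple(tuple(sorted(p)) for p in parts),  # type: ignore[arg-type]
    )


def set_split_length(tree: Phylogeny, side: frozenset, length: float) -> None:
    """Set the length of the internal edge whose below-edge leaf set equals
    ``side`` (or its complement)."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    targets = {frozenset(side), all_taxa - frozenset(side)}
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
        if nd.parent_node is not None and below[nd] in targets:
            nd.edge.length = length
            return
    raise ValueError("no internal edge matches the requested split")


# ---------------------------------------------------------------------------
# gene trees and characters
# ---------------------------------------------------------------------------


def _random_nni(tree: Phylogeny, rng: np.random.Generator) -> Phylogeny:
    """One uniformly chosen nearest-neighbor interchange (topology only)."""
    candidates = [
        nd
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf()
        and nd.parent_node is not None
        and len(nd.parent_node.child_nodes()) >= 2
    ]
    if not candidates:
        return tree
    c = candidates[int(rng.integers(len(candidates)))]
    p = c.parent_node
    siblings = [x for x in p.child_nodes() if x is not c]
    sib = siblings[int(rng.integers(len(siblings)))]
    kids = c.child_nodes()
    child = kids[int(rng.integers(len(kids)))]
    c.remove_child(child)
    p.remove_child(sib)
    c.add_child(sib)
    p.add_child(child)
    return tree


def simulate_gene_trees(
    species_tree: Phylogeny, epsilon: float, n: int, seed: int
) -> list[Phylogeny]:
    """Gene trees: the species tree, or (probability epsilon) a random NNI
    neighbor of it."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        gt = species_tree.clone(depth=1)
        if rng.random() < epsilon:
            _random_nni(gt, rng)
        out.append(gt)
    return out


def simulate_characters(
    tree: Phylogeny,
    model: MkModel | np.ndarray,
    n: int,
    seed: int,
    states: tuple[str, ...] | None = None,
) -> CharacterMatrix:
    """Evolve ``n`` independent discrete characters down the tree by CTMC
    sampling from the root prior."""
    rng = np.random.default_rng(seed)
    if isinstance(model, MkModel):
        Q = model.Q
        prior = model.root_prior
        states = states or model.states
    else:
        Q = np.asarray(model, float)
        k = Q.shape[0]
        prior = np.full(k, 1.0 / k)
        states = states or tuple(str(i) for i in range(k))
    k = Q.shape[0]
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    row = {t: i for i, t in enumerate(taxa)}
    out = np.empty((len(taxa), n), dtype="<U8")
    vals: dict[int, np.ndarray] = {}
    vals[id(tree.seed_node)] = rng.choice(k, size=n, p=prior)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            t = nd.edge.length or 0.0
            from scipy.linalg import expm

            P = expm(Q * t)
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            parent = vals[id(nd.parent_node)]
            u = rng.random(n)
            vals[id(nd)] = (u[:, None] > cum[parent]).sum(axis=1)
        if nd.is_leaf():
            out[row[nd.taxon.label]] = np.array(states)[vals[id(nd)]]
    return CharacterMatrix(
        taxa=taxa,
        characters=[f"c{i + 1:03d}" for i in range(n)],
        states=out,
    )
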