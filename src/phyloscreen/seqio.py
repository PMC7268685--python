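"""Input/output and validation for alignments, partitions, trees, character
matrices, and taxon-group files.

Conventions
-----------
* Partition files use the RAxML charset dialect with 1-based inclusive
  intervals ("WAG, p1 = 1-100"); internally every range is stored 0-based,
  half-open.  The conversion happens in exactly one place (`_parse_range` /
  `format_partitions`).
* Alignment characters are upper-cased on input.  Each alphabet declares a
  canonical state set and an ambiguity set; ambiguous symbols are treated as
  missing data by every downstream statistic.
* Parsing is strict by default: a symbol outside states+ambiguity raises
  :class:`~phyloscreen.errors.AlphabetError`.  With ``strict=False`` unknown
  symbols are coerced to ``?``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    DisjointnessError,
    DuplicateTaxonError,
    EmptyAlignmentError,
    FrameError,
    LengthMismatchError,
    PartitionBoundsError,
    PartitionOverlapError,
    PartitionError,
    UnknownTaxonError,
)

__all__ = [
    "Alphabet",
    "PartitionEntry",
    "PartitionScheme",
    "PartitionedAlignment",
    "CharacterMatrix",
    "TaxonGrouping",
    "Phylogeny",
    "read_alignment",
    "write_alignment",
    "read_partitions",
    "write_partitions",
    "format_partitions",
    "extract_codon_positions",
    "read_tree",
    "read_trees",
    "write_tree",
    "read_character_matrix",
    "write_character_matrix",
    "read_grouping",
    "write_grouping",
]

AA_STATES = "ACDEFGHIKLMNPQRSTVWY"
NT_STATES = "ACGT"
AA_AMBIGUOUS = frozenset("X-?*")
NT_AMBIGUOUS = frozenset("N-?")
IUPAC_PARTIAL = frozenset("RYSWKMBDHVU")
MISSING_CODES = frozenset("?-")


class Alphabet(str, Enum):
    """Sequence alphabet: amino acids or nucleotides."""

    AA = "aa"
    NT = "nt"

    @property
    def states(self) -> str:
        return AA_STATES if self is Alphabet.AA else NT_STATES

    def default_ambiguity(self, iupac_as_missing: bool = True) -> frozenset[str]:
        if self is Alphabet.AA:
            return AA_AMBIGUOUS
        amb = NT_AMBIGUOUS
        if iupac_as_missing:
            amb = amb | IUPAC_PARTIAL
        return amb


@dataclass(frozen=True)
class PartitionEntry:
    """One partition: a name, 0-based half-open ranges, optional codon stride.

    With ``codon_stride=k`` each range contributes every k-th site starting at
    the range's first site (the RAxML ``a-b\\k`` dialect).  The model token
    from the partition file is kept as an annotation only.
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    codon_stride: int | None = None
    model: str | None = None

    def sites(self) -> np.ndarray:
        """0-based column indices covered by this entry, in file order."""
        step = self.codon_stride or 1
        idx: list[np.ndarray] = [np.arange(lo, hi, step) for lo, hi in self.ranges]
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    @property
    def n_sites(self) -> int:
        return int(self.sites().size)


@dataclass(frozen=True)
class PartitionScheme:
    entries: tuple[PartitionEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise PartitionError(f"duplicate partition names in {names}")
        occupied: set[int] = set()
        for e in self.entries:
            s = set(e.sites().tolist())
            clash = occupied & s
            if clash:
                raise PartitionOverlapError(
                    f"partition {e.name!r} overlaps earlier partitions at "
                    f"1-based sites {sorted(x + 1 for x in list(clash)[:5])}..."
                )
            occupied |= s

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def entry(self, name: str) -> PartitionEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def validate_against(self, n_sites: int) -> None:
        for e in self.entries:
            for lo, hi in e.ranges:
                if lo < 0 or hi > n_sites:
                    raise PartitionBoundsError(
                        f"partition {e.name!r} range {lo + 1}-{hi} exceeds "
                        f"alignment length {n_sites}"
                    )


def single_partition(n_sites: int, name: str = "all") -> PartitionScheme:
    return PartitionScheme((PartitionEntry(name, ((0, n_sites),)),))


@dataclass
class PartitionedAlignment:
    """A taxa x sites character matrix with a partition map and alphabet.

    ``matrix`` holds upper-case single characters; cells whose symbol is in
    ``ambiguity`` count as missing everywhere downstream.
    """

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites), dtype '<U1'
    alphabet: Alphabet
    partitions: PartitionScheme | None = None
    ambiguity: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise DuplicateTaxonError(f"duplicate taxon labels: {sorted(dupes)}")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise LengthMismatchError("matrix shape does not match taxon list")
        if self.n_sites == 0:
            raise EmptyAlignmentError("alignment has no sites")
        if not self.ambiguity:
            self.ambiguity = self.alphabet.default_ambiguity()
        if self.partitions is not None:
            self.partitions.validate_against(self.n_sites)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise UnknownTaxonError(f"taxon {label!r} not in alignment") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_sites) array; True where the cell is missing."""
        return ~np.isin(self.matrix, list(self.alphabet.states))

    def effective_partitions(self) -> PartitionScheme:
        """The declared scheme, or a single all-sites partition."""
        if self.partitions is not None and len(self.partitions) > 0:
            return self.partitions
        return single_partition(self.n_sites)

    def sequence(self, label: str) -> str:
        return "".join(self.matrix[self.taxon_index(label)])

    def subset_taxa(self, labels: Sequence[str]) -> "PartitionedAlignment":
        idx = [self.taxon_index(t) for t in labels]
        return replace(
            self, taxa=list(labels), matrix=self.matrix[idx], partitions=self.partitions
        )

    def subset_columns(
        self, columns: np.ndarray, partitions: PartitionScheme | None = None
    ) -> "PartitionedAlignment":
        if len(columns) == 0:
            raise EmptyAlignmentError("column subset is empty")
        return replace(
            self, matrix=self.matrix[:, columns], partitions=partitions
        )

    def encode(self, extra_taxa_ok: bool = True) -> np.ndarray:
        """Integer codes: index into alphabet.states, -1 for missing."""
        states = np.array(list(self.alphabet.states))
        codes = np.full(self.matrix.shape, -1, dtype=np.int16)
        for i, s in enumerate(states):
            codes[self.matrix == s] = i
        return codes


# ---------------------------------------------------------------------------
# alignment reading / writing
# ---------------------------------------------------------------------------


def _validate_symbols(
    matrix: np.ndarray, alphabet: Alphabet, ambiguity: frozenset[str], strict: bool
) -> np.ndarray:
    legal = set(alphabet.states) | set(ambiguity)
    present = set(np.unique(matrix).tolist())
    illegal = present - legal
    if illegal:
        if strict:
            raise AlphabetError(
                f"illegal symbols {sorted(illegal)} for {alphabet.value} alphabet"
            )
        matrix = matrix.copy()
        matrix[np.isin(matrix, sorted(illegal))] = "?"
    return matrix


def _records_to_alignment(
    records: list[tuple[str, str]],
    alphabet: Alphabet,
    strict: bool,
    ambiguity: frozenset[str] | None,
) -> PartitionedAlignment:
    if not records:
        raise EmptyAlignmentError("no sequences in file")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise LengthMismatchError(f"sequence lengths differ: {sorted(lengths)}")
    amb = ambiguity if ambiguity is not None else alphabet.default_ambiguity()
    matrix = np.array([list(s.upper()) for _, s in records], dtype="<U1")
    matrix = _validate_symbols(matrix, alphabet, amb, strict)
    return PartitionedAlignment(
        taxa=[n for n, _ in records], matrix=matrix, alphabet=alphabet, ambiguity=amb
    )


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet = Alphabet.AA,
    strict: bool = True,
    ambiguity: frozenset[str] | None = None,
) -> PartitionedAlignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Parameters
    ----------
    format:
        ``"fasta"`` or ``"phylip"`` (relaxed, sequential).
    strict:
        If True (default), symbols outside the alphabet's state and ambiguity
        sets raise :class:`AlphabetError`; otherwise they are coerced to ``?``.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        records = [(r.id, str(r.seq)) for r in aln]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    return _records_to_alignment(records, alphabet, strict, ambiguity)


def write_alignment(
    aln: PartitionedAlignment, path: str | Path, format: str = "fasta"
) -> None:
    """Write in canonical form: FASTA as 2-line records, PHYLIP relaxed."""
    path = Path(path)
    rows = ["".join(r) for r in aln.matrix]
    if format == "fasta":
        with open(path, "w") as fh:
            for name, seq in zip(aln.taxa, rows):
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=n, description="") for n, s in zip(aln.taxa, rows)]
        )
        with open(path, "w") as fh:
            AlignIO.write(msa, fh, "phylip-relaxed")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


# ---------------------------------------------------------------------------
# partition files (RAxML charset dialect)
# ---------------------------------------------------------------------------

_PART_LINE = re.compile(
    r"""^\s*(?:(?P<model>[^,=]+?)\s*,)?\s*      # optional "MODEL,"
         (?P<name>[\w.+-]+)\s*=\s*
         (?P<ranges>[0-9][0-9\s,\\-]*)\s*$""",
    re.VERBOSE,
)
_RANGE = re.compile(r"^(\d+)\s*-\s*(\d+)(?:\\(\d))?$")


def _parse_ranges(text: str) -> tuple[tuple[tuple[int, int], ...], int | None]:
    ranges: list[tuple[int, int]] = []
    stride: int | None = None
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _RANGE.match(chunk)
        if not m:
            raise PartitionError(f"cannot parse range {chunk!r}")
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo < 1 or hi < lo:
            raise PartitionError(f"invalid 1-based range {chunk!r}")
        if m.group(3):
            stride = int(m.group(3))
            if stride not in (1, 2, 3):
                raise PartitionError(f"codon stride must be 1-3, got {stride}")
        ranges.append((lo - 1, hi))  # to 0-based half-open
    return tuple(ranges), stride


def read_partitions(path: str | Path) -> PartitionScheme:
    """Parse a RAxML-style partition file ("WAG, p1 = 1-100, 200-300\\3")."""
    entries: list[PartitionEntry] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _PART_LINE.match(line)
        if not m:
            raise PartitionError(f"cannot parse partition line {raw!r}")
        ranges, stride = _parse_ranges(m.group("ranges"))
        model = m.group("model")
        entries.append(
            PartitionEntry(
                name=m.group("name"),
                ranges=ranges,
                codon_stride=stride,
                model=model.strip() if model else None,
            )
        )
    return PartitionScheme(tuple(entries))


def format_partitions(scheme: PartitionScheme) -> str:
    lines = []
    for e in scheme:
        suffix = f"\\{e.codon_stride}" if e.codon_stride else ""
        ranges = ", ".join(f"{lo + 1}-{hi}{suffix}" for lo, hi in e.ranges)
        model = e.model or "AUTO"
        lines.append(f"{model}, {e.name} = {ranges}")
    return "\n".join(lines) + "\n"


def write_partitions(scheme: PartitionScheme, path: str | Path) -> None:
    Path(path).write_text(format_partitions(scheme))


def extract_codon_positions(
    aln: PartitionedAlignment, position: int
) -> PartitionedAlignment:
    """Keep only the requested codon position (1, 2 or 3) of every partition.

    Every partition's site count must be divisible by 3 and its reading frame
    is assumed to start at its first site.  The returned scheme is re-indexed
    to contiguous blocks in partition order.
    """
    if aln.alphabet is not Alphabet.NT:
        raise AlphabetError("codon positions are only defined for NT alignments")
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    blocks: list[np.ndarray] = []
    new_entries: list[PartitionEntry] = []
    offset = 0
    for e in aln.effective_partitions():
        if e.codon_stride is not None:
            raise FrameError(f"partition {e.name!r} already has a codon stride")
        sites = e.sites()
        if sites.size % 3 != 0:
            raise FrameError(
                f"partition {e.name!r} has {sites.size} sites, not divisible by 3"
            )
        keep = sites[position - 1 :: 3]
        blocks.append(keep)
        new_entries.append(
            PartitionEntry(e.name, ((offset, offset + keep.size),), model=e.model)
        )
        offset += keep.size
    columns = np.concatenate(blocks)
    return PartitionedAlignment(
        taxa=list(aln.taxa),
        matrix=aln.matrix[:, columns],
        alphabet=aln.alphabet,
        partitions=PartitionScheme(tuple(new_entries)),
        ambiguity=aln.ambiguity,
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

Phylogeny = dendropy.Tree  # leaf labels unique; branch lengths >= 0 where set


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = {t for t in labels if labels.count(t) > 1}
        raise DuplicateTaxonError(f"duplicate leaf labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def read_tree(path: str | Path) -> Phylogeny:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _validate_tree(tree)


def read_trees(path: str | Path) -> list[Phylogeny]:
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return [_validate_tree(t) for t in trees]


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tree_from_newick(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _validate_tree(tree)


# ---------------------------------------------------------------------------
# discrete character matrices
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x characters table of discrete states; '?' and '-' are missing."""

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # (n_taxa, n_characters), dtype '<U1' (or small str)
    state_lists: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise DuplicateTaxonError("duplicate taxa in character matrix")
        if not self.state_lists:
            self.state_lists = {
                c: tuple(
                    sorted(
                        set(self.states[:, j].tolist()) - MISSING_CODES
                    )
                )
                for j, c in enumerate(self.characters)
            }
        from .errors import StateError

        for j, c in enumerate(self.characters):
            legal = set(self.state_lists[c]) | MISSING_CODES
            seen = set(self.states[:, j].tolist())
            if seen - legal:
                raise StateError(
                    f"character {c!r} has undeclared states {sorted(seen - legal)}"
                )

    def column(self, character: str) -> dict[str, str]:
        j = self.characters.index(character)
        return {t: self.states[i, j] for i, t in enumerate(self.taxa)}


def read_character_matrix(path: str | Path) -> CharacterMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, comment="#")
    states = df.to_numpy(dtype="<U8")
    states[pd.isna(df).to_numpy()] = "?"
    return CharacterMatrix(
        taxa=[str(t) for t in df.index],
        characters=[str(c) for c in df.columns],
        states=states,
    )


def write_character_matrix(cm: CharacterMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.states, index=cm.taxa, columns=cm.characters)
    df.to_csv(path, sep="\t", index_label="taxon")


# ---------------------------------------------------------------------------
# taxon groupings for four-cluster likelihood mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonGrouping:
    """Four named, disjoint, non-empty taxon sets plus a hypothesis label."""

    label: str
    group_names: tuple[str, str, str, str]
    groups: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.groups) != 4 or any(len(g) == 0 for g in self.groups):
            raise DisjointnessError("exactly four non-empty groups are required")
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen & set(g)
            if overlap:
                raise DisjointnessError(f"groups overlap on {sorted(overlap)}")
            seen |= set(g)

    def validate_against(self, aln: PartitionedAlignment) -> None:
        missing = set().union(*map(set, self.groups)) - set(aln.taxa)
        if missing:
            raise UnknownTaxonError(
                f"grouping taxa absent from alignment: {sorted(missing)}"
            )


def read_grouping(
    path: str | Path, aln: PartitionedAlignment | None = None
) -> TaxonGrouping:
    """Read a 2-column TSV (group<TAB>taxon); optional '#label=...' header."""
    label = Path(path).stem
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*label\s*=\s*(.+)", line)
            if m:
                label = m.group(1).strip()
            continue
        parts = re.split(r"\t+", line)
        if len(parts) != 2:
            raise ValueError(f"expected 'group<TAB>taxon', got {raw!r}")
        g, t = parts[0].strip(), parts[1].strip()
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(t)
    if len(order) != 4:
        raise DisjointnessError(f"grouping file defines {len(order)} groups, need 4")
    grouping = TaxonGrouping(
        label=label,
        group_names=tuple(order),  # type: ignore[arg-type]
        groups=tuple(tuple(groups[g]) for g in order),  # type: ignore[arg-type]
    )
    if aln is not None:
        grouping.validate_against(aln)
    return grouping


def write_grouping(grouping: TaxonGrouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={grouping.label}\n")
        for name, taxa in zip(grouping.group_names, grouping.groups):
            for t in taxa:
                fh.write(f"{name}\t{t}\n")
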