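"""Shared fixtures: tiny hand-built alignments and trees."""

from __future__ import annotations

import numpy as np
import pytest

from phyloscreen.seqio import (
    Alphabet,
    PartitionEntry,
    PartitionScheme,
    PartitionedAlignment,
    tree_from_newick,
)


def aln_from_strings(
    rows: dict[str, str],
    alphabet: Alphabet = Alphabet.AA,
    partitions: PartitionScheme | None = None,
) -> PartitionedAlignment:
    taxa = list(rows)
    matrix = np.array([list(rows[t]) for t in taxa], dtype="<U1")
    return PartitionedAlignment(taxa, matrix, alphabet, partitions)


@pytest.fixture
def balanced_quartet_tree():
    return tree_from_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);")


@pytest.fixture
def two_state_quartet_aln():
    return aln_from_strings(
        {"A": "AAAC", "B": "CCCC", "C": "ACAC", "D": "CCCA"}, Alphabet.AA
    )


@pytest.fixture
def partitioned_nt_aln():
    scheme = PartitionScheme(
        (PartitionEntry("p1", ((0, 6),)), PartitionEntry("p2", ((6, 12),)))
    )
    return aln_from_strings(
        {
            "A": "ACGTACGTACGT",
            "B": "ACGTACTTACGA",
            "C": "ACGAACGTACGT",
            "D": "TCGTACGTAGGT",
        },
        Alphabet.NT,
        scheme,
    )
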