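"""Signal-destroying alignment permutations.

Each scheme scrambles the data while preserving a chosen confounding
structure, so that re-running four-cluster likelihood mapping on the permuted
matrix isolates how much apparent support that structure alone can generate:

* ``scheme_columnwise`` — within every partition, each column's observed
  residues are shuffled among the taxa covered in that column.  Preserves the
  missing-data mask and every column's state multiset (hence the site-rate
  profile); destroys tree signal and lineage-specific composition.
* ``scheme_rowwise`` — within every partition, each taxon's observed residues
  are shuffled across its own covered sites.  Preserves the mask and each
  taxon's per-partition composition (hence SRH-violation structure); destroys
  shared site patterns.
* ``scheme_mask_only`` — every observed cell is redrawn i.i.d. from the
  partition-wide pooled state frequencies.  Preserves only the coverage
  pattern.

All schemes leave shape, taxon order, partition scheme, and missing-cell
coordinates bit-identical to the input, and are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .seqio import PartitionedAlignment

__all__ = ["scheme_columnwise", "scheme_rowwise", "scheme_mask_only", "SCHEMES"]


def _prepare(aln: PartitionedAlignment, seed: int):
    rng = np.random.default_rng(seed)
    matrix = aln.matrix.copy()
    observed = ~aln.missing_mask()
    return rng, matrix, observed


def scheme_columnwise(aln: PartitionedAlignment, seed: int) -> PartitionedAlignment:
    """Permute each column's observed residues among its covered taxa."""
    rng, matrix, observed = _prepare(aln, seed)
    for entry in aln.effective_partitions():
        for col in entry.sites():
            rows = np.flatnonzero(observed[:, col])
            if rows.size > 1:
                matrix[rows[rng.permutation(rows.size)], col] = matrix[rows, col]
    return replace(aln, matrix=matrix)


def scheme_rowwise(aln: PartitionedAlignment, seed: int) -> PartitionedAlignment:
    """Permute each taxon's observed residues across its covered sites,
    independently within every partition."""
    rng, matrix, observed = _prepare(aln, seed)
    for entry in aln.effective_partitions():
        cols = entry.sites()
        for row in range(aln.n_taxa):
            covered = cols[observed[row, cols]]
            if covered.size > 1:
                matrix[row, covered[rng.permutation(covered.size)]] = matrix[
                    row, covered
                ]
    return replace(aln, matrix=matrix)


def scheme_mask_only(aln: PartitionedAlignment, seed: int) -> PartitionedAlignment:
    """Replace observed cells by i.i.d. draws from pooled partition frequencies."""
    rng, matrix, observed = _prepare(aln, seed)
    states = np.array(list(aln.alphabet.states))
    for entry in aln.effective_partitions():
        cols = entry.sites()
        sub = matrix[:, cols]
        obs = observed[:, cols]
        values = sub[obs]
        counts = np.array([(values == s).sum() for s in states], dtype=float)
        if counts.sum() == 0:
            continue
        freqs = counts / counts.sum()
        draws = states[rng.choice(len(states), size=values.size, p=freqs)]
        sub[obs] = draws
        matrix[:, cols] = sub
    return replace(aln, matrix=matrix)


SCHEMES = {
    "columnwise": scheme_columnwise,
    "rowwise": scheme_rowwise,
    "maskonly": scheme_mask_only,
}
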