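"""Supermatrix diagnostics: matched-pairs symmetry tests, compositional
heterogeneity (RCFV), completeness scores, and the masking/filter rules built
on them.

Bowker's test of symmetry compares the pairwise divergence table of two
sequences; under stationary, reversible, homogeneous (SRH) evolution the
table is expected to be symmetric, so a rejection flags an SRH violation.
RCFV (relative composition frequency variation) scores how far per-taxon
state frequencies stray from the across-taxa mean within one partition;
partitions at or above a threshold (default 0.1) are masked.  The decisive
filter keeps partitions where every taxon has data, ambiguous cells are rare,
and the partition is long enough to carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import EmptyAlignmentError
from .seqio import (
    PartitionEntry,
    PartitionScheme,
    PartitionedAlignment,
)

__all__ = [
    "SymmetryTestResult",
    "PairwiseSymmetrySummary",
    "CompositionReport",
    "CompletenessReport",
    "FilterCriteria",
    "bowker_test",
    "pairwise_symmetry",
    "rcfv",
    "rcfv_all",
    "mask_by_rcfv",
    "completeness",
    "decisive_filter",
]


@dataclass(frozen=True)
class SymmetryTestResult:
    """Bowker's matched-pairs test for one taxon pair.

    ``p`` is None when no comparable sites exist (insufficient data); with
    comparable sites but no informative off-diagonal cell pair (df = 0) the
    convention is B = 0, p = 1.
    """

    taxon_i: str
    taxon_j: str
    B: float
    df: int
    p: float | None
    n_sites: int

    def __post_init__(self) -> None:
        assert self.B >= 0 and self.df >= 0
        if self.df == 0 and self.n_sites > 0:
            assert self.B == 0.0


@dataclass
class PairwiseSymmetrySummary:
    results: list[SymmetryTestResult]
    p_matrix: pd.DataFrame
    median_p: float | None
    n_undefined: int


@dataclass
class CompositionReport:
    partition: str
    rcfv: float
    deviations: pd.DataFrame  # taxa x states |A_sj - mean_s|; NaN rows: no data
    n_taxa_with_data: int
    masked: bool
    insufficient: bool = False


@dataclass
class CompletenessReport:
    c_overall: float
    c_per_taxon: pd.Series
    c_pairwise: pd.DataFrame


@dataclass(frozen=True)
class FilterCriteria:
    """Masking and decisiveness thresholds.

    ``max_ambiguous_fraction`` is a strict upper bound; ``min_sites`` and
    ``rcfv_threshold`` are inclusive.
    """

    require_all_taxa: bool = True
    max_ambiguous_fraction: float = 0.30
    min_sites: int = 500
    rcfv_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_ambiguous_fraction <= 1.0):
            raise ValueError("max_ambiguous_fraction must lie in [0, 1]")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


# ---------------------------------------------------------------------------
# Bowker's test of symmetry
# ---------------------------------------------------------------------------


def _bowker_from_codes(
    codes: np.ndarray, i: int, j: int, k: int, taxon_i: str, taxon_j: str
) -> SymmetryTestResult:
    a, b = codes[i], codes[j]
    ok = (a >= 0) & (b >= 0)
    table = np.bincount(a[ok] * k + b[ok], minlength=k * k).reshape(k, k)
    n_sites = int(ok.sum())
    if n_sites == 0:
        return SymmetryTestResult(taxon_i, taxon_j, 0.0, 0, None, 0)
    iu = np.triu_indices(table.shape[0], k=1)
    n_ab = table[iu].astype(float)
    n_ba = table.T[iu].astype(float)
    tot = n_ab + n_ba
    informative = tot > 0
    df = int(informative.sum())
    if df == 0:
        return SymmetryTestResult(taxon_i, taxon_j, 0.0, 0, 1.0, n_sites)
    B = float(((n_ab - n_ba)[informative] ** 2 / tot[informative]).sum())
    p = float(chi2.sf(B, df))
    return SymmetryTestResult(taxon_i, taxon_j, B, df, p, n_sites)


def bowker_test(
    aln: PartitionedAlignment, taxon_i: str, taxon_j: str
) -> SymmetryTestResult:
    """Bowker's chi-square test of symmetry on the pairwise divergence table.

    Only columns where both taxa are non-missing are compared (pairwise
    deletion).  B sums (n_ab - n_ba)^2 / (n_ab + n_ba) over unordered state
    pairs with at least one observation; df counts those pairs; the p-value
    is the upper chi-square tail.
    """
    i = aln.taxon_index(taxon_i)
    j = aln.taxon_index(taxon_j)
    return _bowker_from_codes(
        aln.encode(), i, j, len(aln.alphabet.states), taxon_i, taxon_j
    )


def pairwise_symmetry(aln: PartitionedAlignment) -> PairwiseSymmetrySummary:
    """Bowker's test for all unordered taxon pairs, plus the median p-value.

    The median is taken over defined p-values only; pairs with no comparable
    sites are counted in ``n_undefined``.
    """
    if aln.n_taxa < 2:
        raise ValueError("pairwise symmetry needs at least two taxa")
    results: list[SymmetryTestResult] = []
    n = aln.n_taxa
    k = len(aln.alphabet.states)
    codes = aln.encode()
    pmat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            res = _bowker_from_codes(codes, i, j, k, aln.taxa[i], aln.taxa[j])
            results.append(res)
            if res.p is not None:
                pmat[i, j] = pmat[j, i] = res.p
    defined = [r.p for r in results if r.p is not None]
    return PairwiseSymmetrySummary(
        results=results,
        p_matrix=pd.DataFrame(pmat, index=aln.taxa, columns=aln.taxa),
        median_p=float(np.median(defined)) if defined else None,
        n_undefined=len(results) - len(defined),
    )


# ---------------------------------------------------------------------------
# RCFV and masking
# ---------------------------------------------------------------------------


def _partition_entry(
    aln: PartitionedAlignment, partition: str | PartitionEntry | None
) -> PartitionEntry:
    scheme = aln.effective_partitions()
    if partition is None:
        if len(scheme) != 1:
            raise ValueError("partition name required for a multi-partition matrix")
        return scheme.entries[0]
    if isinstance(partition, PartitionEntry):
        return partition
    return scheme.entry(partition)


def rcfv(
    aln: PartitionedAlignment,
    partition: str | PartitionEntry | None = None,
    threshold: float = 0.1,
) -> CompositionReport:
    """Relative composition frequency variation of one partition.

    With A_sj the relative frequency of state s among taxon j's observed
    characters in the partition and mean_s the average over the n taxa with
    data, RCFV = sum_s sum_j |A_sj - mean_s| / n.  Taxa with no data in the
    partition are excluded from n.  ``masked`` is True when RCFV >=
    ``threshold`` (inclusive bound).
    """
    entry = _partition_entry(aln, partition)
    cols = entry.sites()
    states = list(aln.alphabet.states)
    sub = aln.matrix[:, cols]
    counts = np.stack([(sub == s).sum(axis=1) for s in states], axis=1).astype(float)
    totals = counts.sum(axis=1)
    has_data = totals > 0
    n = int(has_data.sum())
    dev = np.full((aln.n_taxa, len(states)), np.nan)
    if n == 0:
        return CompositionReport(
            partition=entry.name,
            rcfv=float("nan"),
            deviations=pd.DataFrame(dev, index=aln.taxa, columns=states),
            n_taxa_with_data=0,
            masked=False,
            insufficient=True,
        )
    freqs = counts[has_data] / totals[has_data, None]
    mean = freqs.mean(axis=0)
    dev[has_data] = np.abs(freqs - mean[None, :])
    value = float(np.nansum(dev[has_data]) / n)
    return CompositionReport(
        partition=entry.name,
        rcfv=value,
        deviations=pd.DataFrame(dev, index=aln.taxa, columns=states),
        n_taxa_with_data=n,
        masked=value >= threshold,
    )


def rcfv_all(
    aln: PartitionedAlignment, threshold: float = 0.1
) -> list[CompositionReport]:
    return [rcfv(aln, e, threshold) for e in aln.effective_partitions()]


@dataclass
class MaskReport:
    masked_partitions: list[str]
    masked_sites: int
    surviving_partitions: list[str]
    rcfv_values: pd.Series


def mask_by_rcfv(
    aln: PartitionedAlignment, criteria: FilterCriteria = FilterCriteria()
) -> tuple[PartitionedAlignment, MaskReport]:
    """Drop every partition whose RCFV meets the threshold; re-index survivors.

    Raises :class:`EmptyAlignmentError` when no partition survives.
    """
    reports = rcfv_all(aln, criteria.rcfv_threshold)
    keep = [r for r in reports if not r.masked and not r.insufficient]
    drop = [r for r in reports if r.masked or r.insufficient]
    if not keep:
        raise EmptyAlignmentError("all partitions masked by the RCFV rule")
    scheme = aln.effective_partitions()
    blocks, new_entries, offset = [], [], 0
    for r in keep:
        entry = scheme.entry(r.partition)
        sites = entry.sites()
        blocks.append(sites)
        new_entries.append(
            PartitionEntry(entry.name, ((offset, offset + sites.size),),
                           model=entry.model)
        )
        offset += sites.size
    columns = np.concatenate(blocks)
    masked_sites = aln.n_sites - len(columns) if aln.partitions is None else int(
        sum(scheme.entry(r.partition).n_sites for r in drop)
    )
    out = PartitionedAlignment(
        taxa=list(aln.taxa),
        matrix=aln.matrix[:, columns],
        alphabet=aln.alphabet,
        partitions=PartitionScheme(tuple(new_entries)),
        ambiguity=aln.ambiguity,
    )
    report = MaskReport(
        masked_partitions=[r.partition for r in drop],
        masked_sites=masked_sites,
        surviving_partitions=[r.partition for r in keep],
        rcfv_values=pd.Series({r.partition: r.rcfv for r in reports}),
    )
    return out, report


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------


def completeness(aln: PartitionedAlignment) -> CompletenessReport:
    """Proportion of non-ambiguous characters: overall, per taxon, per pair.

    The pairwise score C_ij is the fraction of alignment columns where both
    taxa are non-ambiguous.
    """
    present = ~aln.missing_mask()
    c_overall = float(present.mean())
    c_taxon = pd.Series(present.mean(axis=1), index=aln.taxa)
    both = (present.astype(float) @ present.T.astype(float)) / aln.n_sites
    return CompletenessReport(
        c_overall=c_overall,
        c_per_taxon=c_taxon,
        c_pairwise=pd.DataFrame(both, index=aln.taxa, columns=aln.taxa),
    )


# ---------------------------------------------------------------------------
# decisive filtering
# ---------------------------------------------------------------------------


def decisive_filter(
    aln: PartitionedAlignment, criteria: FilterCriteria = FilterCriteria()
) -> list[str]:
    """Names of partitions that satisfy the decisiveness rules.

    A partition survives when (a) every taxon has at least one non-missing
    character in it, (b) its ambiguous-cell fraction is strictly below
    ``max_ambiguous_fraction``, and (c) it spans at least ``min_sites`` sites.
    """
    missing = aln.missing_mask()
    survivors: list[str] = []
    for entry in aln.effective_partitions():
        cols = entry.sites()
        sub_missing = missing[:, cols]
        if criteria.require_all_taxa and sub_missing.all(axis=1).any():
            continue
        if sub_missing.mean() >= criteria.max_ambiguous_fraction:
            continue
        if cols.size < criteria.min_sites:
            continue
        survivors.append(entry.name)
    return survivors
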