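"""Four-cluster likelihood mapping (FcLM).

For four predefined taxon groups, every sampled quartet (one taxon per
group) is evaluated under the three unrooted quartet topologies

    T1 = (g1,g2 | g3,g4),   T2 = (g1,g3 | g2,g4),   T3 = (g1,g4 | g2,g3),

each with its five branch lengths optimized by maximum likelihood.  The
normalized support vector p = softmax(l1,l2,l3) lives on the 2-simplex and is
assigned to one of seven regions: three corners (resolved support for one
topology), three edges (two-way ambiguity) and the center (star-like signal).
Region occupancy over many quartets summarizes how decisively the data speak
for a hypothesis; re-running the analysis on permuted matrices shows how much
of that support survives once phylogenetic signal is destroyed.

Region geometry is a nearest-prototype partition of the simplex (corner,
edge-midpoint and center prototypes), a convex approximation of the classic
likelihood-mapping figure; the headline "% of quartets supporting topology i"
counts corner regions only.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import DisjointnessError
from .models import SubstitutionModel, empirical_freqs, poisson_model
from .seqio import PartitionedAlignment, TaxonGrouping

__all__ = [
    "FcLMOptions",
    "QuartetEvaluation",
    "FcLMSummary",
    "enumerate_quartets",
    "evaluate_quartet",
    "assign_region",
    "run_hypothesis",
    "estimate_alpha",
    "REGIONS",
]

REGIONS = ("C1", "C2", "C3", "E12", "E13", "E23", "CTR")
_PROTOTYPES = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.5, 0.5, 0.0],
        [0.5, 0.0, 0.5],
        [0.0, 0.5, 0.5],
        [1 / 3, 1 / 3, 1 / 3],
    ]
)
# topology -> (pair at node u, pair at node v), indices into the quartet tuple
_TOPOLOGIES = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

_LOG_BL_MIN, _LOG_BL_MAX = np.log(1e-8), np.log(10.0)


@dataclass(frozen=True)
class FcLMOptions:
    """Knobs for quartet evaluation.

    min_sites: minimum usable (complete) columns per quartet; below it the
    quartet is skipped.  n_restarts: branch-length optimizations per topology
    from different starting points.  alpha: gamma shape; None means estimate
    it once on a random subsample of quartets and keep it fixed.
    """

    min_sites: int = 30
    n_restarts: int = 3
    n_cat: int = 4
    alpha: float | None = None
    alpha_subsample: int = 50
    ftol: float = 1e-6
    freq_pseudocount: float = 1.0


@dataclass
class QuartetEvaluation:
    taxa: tuple[str, str, str, str]
    n_sites: int
    logliks: tuple[float, float, float] | None
    weights: tuple[float, float, float] | None
    region: str | None
    skipped: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.skipped and self.weights is not None:
            assert abs(sum(self.weights) - 1.0) < 1e-10


@dataclass
class FcLMSummary:
    """Aggregate of one FcLM hypothesis run.

    ``region_percent`` covers all seven regions and sums to 100 over
    evaluated quartets; ``topology_percent`` renormalizes the three corner
    counts (the headline '% of quartets supporting topology i').
    """

    label: str
    group_names: tuple[str, str, str, str]
    n_sampled: int
    n_evaluated: int
    n_skipped: int
    region_counts: dict[str, int]
    region_percent: dict[str, float]
    topology_percent: tuple[float, float, float] | None
    evaluations: list[QuartetEvaluation] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.label,
            "groups": list(self.group_names),
            "n_sampled": self.n_sampled,
            "n_evaluated": self.n_evaluated,
            "n_skipped": self.n_skipped,
            "region_counts": self.region_counts,
            "region_percent": self.region_percent,
            "topology_percent": list(self.topology_percent)
            if self.topology_percent
            else None,
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            rows.append(
                {
                    "t1": ev.taxa[0],
                    "t2": ev.taxa[1],
                    "t3": ev.taxa[2],
                    "t4": ev.taxa[3],
                    "n_sites": ev.n_sites,
                    "l1": ev.logliks[0] if ev.logliks else np.nan,
                    "l2": ev.logliks[1] if ev.logliks else np.nan,
                    "l3": ev.logliks[2] if ev.logliks else np.nan,
                    "p1": ev.weights[0] if ev.weights else np.nan,
                    "p2": ev.weights[1] if ev.weights else np.nan,
                    "p3": ev.weights[2] if ev.weights else np.nan,
                    "region": ev.region or "",
                    "skipped": ev.skipped,
                    "reason": ev.reason or "",
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quartet sampling
# ---------------------------------------------------------------------------


def enumerate_quartets(
    grouping: TaxonGrouping, cap: int = 20000, seed: int = 0
) -> list[tuple[str, str, str, str]]:
    """All group-respecting quartets, or a seeded uniform sample of ``cap``.

    The full Cartesian product is returned when its size is at most ``cap``;
    otherwise ``cap`` distinct quartets are drawn without replacement.
    """
    sizes = [len(g) for g in grouping.groups]
    total = int(np.prod(sizes))
    if total <= cap:
        return list(itertools.product(*grouping.groups))
    rng = np.random.default_rng(seed)
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
        quartets.append(tuple(grouping.groups[g][i] for g, i in enumerate(idx)))
    return quartets


# ---------------------------------------------------------------------------
# per-quartet likelihood
# ---------------------------------------------------------------------------


class _QuartetLikelihood:
    """Likelihood of a 4-taxon alignment under one quartet topology.

    Precomputes site patterns once; evaluation takes the five branch lengths
    (four terminal in quartet order, then the internal branch) and mixes over
    gamma categories.
    """

    def __init__(self, codes: np.ndarray, model: SubstitutionModel):
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.pat = patterns.T  # (4, n_pat)
        self.counts = counts.astype(float)
        self.model = model
        self.rates = model.rates()
        self.pi = model.freqs

    def loglik(self, topology: int, lengths: np.ndarray) -> float:
        (i, j), (m, n) = _TOPOLOGIES[topology]
        # (5, C, k, k): all branches x gamma categories in one shot
        P = self.model.transition_batch(lengths, self.rates)
        mi = P[i][:, :, self.pat[i]].transpose(0, 2, 1)  # (C, n_pat, k)
        mj = P[j][:, :, self.pat[j]].transpose(0, 2, 1)
        mm = P[m][:, :, self.pat[m]].transpose(0, 2, 1)
        mn = P[n][:, :, self.pat[n]].transpose(0, 2, 1)
        Lu = mi * mj
        mu = np.matmul(Lu, P[4].transpose(0, 2, 1))
        Lv = mm * mn * mu
        lik = Lv @ self.pi  # (C, n_pat)
        lik = np.maximum(lik, 1e-300)
        # mixture over equal-probability categories, in log space
        top = lik.max(axis=0)
        pat_log = np.log((lik / top).sum(axis=0)) + np.log(top) - np.log(
            lik.shape[0]
        )
        return float(pat_log @ self.counts)


def _optimize_topology(
    ql: _QuartetLikelihood, topology: int, starts: list[np.ndarray], ftol: float
) -> float | None:
    best = None
    for x0 in starts:
        res = minimize(
            lambda x: -ql.loglik(topology, np.exp(x)),
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_BL_MIN, _LOG_BL_MAX)] * 5,
            options={"ftol": ftol, "maxiter": 200},
        )
        val = -float(res.fun)
        if res.success or np.isfinite(val):
            if best is None or val > best:
                best = val
    return best


def _quartet_seed(taxa: tuple[str, ...], seed: int) -> int:
    key = "|".join(sorted(taxa))
    return (zlib.crc32(key.encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def _starting_points(taxa, opts: FcLMOptions, seed: int) -> list[np.ndarray]:
    # symmetric starts (one value for tips, one for the internal branch) keep
    # results exactly invariant under group relabeling
    starts = [np.log(np.full(5, 0.1))]
    rng = np.random.default_rng(_quartet_seed(taxa, seed))
    for _ in range(max(0, opts.n_restarts - 1)):
        tip = rng.uniform(np.log(0.01), np.log(1.0))
        internal = rng.uniform(np.log(0.01), np.log(1.0))
        starts.append(np.array([tip, tip, tip, tip, internal]))
    return starts[: max(1, opts.n_restarts)]


def evaluate_quartet(
    aln: PartitionedAlignment,
    quartet: tuple[str, str, str, str],
    model: SubstitutionModel,
    opts: FcLMOptions = FcLMOptions(),
    seed: int = 0,
) -> QuartetEvaluation:
    """Evaluate one quartet under the three topologies.

    Columns where any of the four taxa is missing are dropped (per-quartet
    complete deletion); quartets with fewer than ``opts.min_sites`` usable
    columns are skipped.
    """
    rows = [aln.taxon_index(t) for t in quartet]
    codes = aln.encode()[rows]
    usable = (codes >= 0).all(axis=0)
    n_sites = int(usable.sum())
    if n_sites < opts.min_sites:
        return QuartetEvaluation(
            taxa=tuple(quartet), n_sites=n_sites, logliks=None, weights=None,
            region=None, skipped=True, reason="insufficient sites",
        )
    ql = _QuartetLikelihood(codes[:, usable], model)
    starts = _starting_points(tuple(quartet), opts, seed)
    ls = []
    for topo in range(3):
        val = _optimize_topology(ql, topo, starts, opts.ftol)
        if val is None:
            return QuartetEvaluation(
                taxa=tuple(quartet), n_sites=n_sites, logliks=None, weights=None,
                region=None, skipped=True, reason="optimizer failed",
            )
        ls.append(val)
    l = np.array(ls)
    w = np.exp(l - logsumexp(l))
    w /= w.sum()
    region = assign_region(*w)
    return QuartetEvaluation(
        taxa=tuple(quartet),
        n_sites=n_sites,
        logliks=tuple(float(x) for x in l),
        weights=tuple(float(x) for x in w),
        region=region,
    )


def assign_region(p1: float, p2: float, p3: float) -> str:
    """Nearest-prototype assignment of a simplex point to one of 7 regions.

    Prototypes are the three corners, the three edge midpoints, and the
    center; ties break in the order C1, C2, C3, E12, E13, E23, CTR.
    """
    p = np.array([p1, p2, p3], dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-9):
        raise ValueError(f"weights {p} are not on the simplex")
    d = np.linalg.norm(_PROTOTYPES - p[None, :], axis=1)
    return REGIONS[int(np.argmin(np.round(d, 12)))]


# ---------------------------------------------------------------------------
# hypothesis-level run
# ---------------------------------------------------------------------------


def default_model(
    aln: PartitionedAlignment,
    alpha: float | None,
    n_cat: int = 4,
    pseudocount: float = 1.0,
) -> SubstitutionModel:
    """Poisson exchangeabilities with alignment-wide empirical frequencies."""
    freqs = empirical_freqs(aln, pseudocount=pseudocount)
    return poisson_model(aln.alphabet, freqs=freqs, alpha=alpha, n_cat=n_cat)


def estimate_alpha(
    aln: PartitionedAlignment,
    quartets: list[tuple[str, str, str, str]],
    opts: FcLMOptions,
    seed: int = 0,
) -> float:
    """Profile the gamma shape on a quartet subsample (T1 topology only).

    A cheap one-dimensional search: for each candidate shape, branch lengths
    of each subsample quartet are re-optimized and the summed log-likelihood
    is maximized over a log-spaced grid refined once around the best point.
    """
    rng = np.random.default_rng(seed)
    n_sub = min(opts.alpha_subsample, len(quartets))
    idx = rng.choice(len(quartets), size=n_sub, replace=False)
    sample = [quartets[i] for i in idx]
    codes_all = aln.encode()
    sub_opts = FcLMOptions(
        min_sites=opts.min_sites, n_restarts=1, n_cat=opts.n_cat, ftol=1e-4
    )

    def objective(alpha: float) -> float:
        model = default_model(aln, alpha, opts.n_cat, opts.freq_pseudocount)
        total = 0.0
        for q in sample:
            rows = [aln.taxon_index(t) for t in q]
            codes = codes_all[rows]
            usable = (codes >= 0).all(axis=0)
            if usable.sum() < opts.min_sites:
                continue
            ql = _QuartetLikelihood(codes[:, usable], model)
            val = _optimize_topology(
                ql, 0, _starting_points(tuple(q), sub_opts, seed), sub_opts.ftol
            )
            if val is not None:
                total += val
        return total

    grid = np.exp(np.linspace(np.log(0.2), np.log(5.0), 7))
    scores = [objective(a) for a in grid]
    best = int(np.argmax(scores))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    fine = np.exp(np.linspace(np.log(lo), np.log(hi), 5))
    fine_scores = [objective(a) for a in fine]
    return float(fine[int(np.argmax(fine_scores))])


def run_hypothesis(
    aln: PartitionedAlignment,
    grouping: TaxonGrouping,
    model: SubstitutionModel | None = None,
    cap: int = 20000,
    seed: int = 0,
    opts: FcLMOptions = FcLMOptions(),
) -> FcLMSummary:
    """Evaluate one FcLM hypothesis and aggregate region occupancy.

    With ``model=None`` a default model is built from the alignment
    (empirical frequencies, poisson exchangeabilities, gamma rates with the
    shape either given in ``opts.alpha`` or estimated once on a subsample).
    Deterministic for a fixed seed.
    """
    grouping.validate_against(aln)
    if any(len(g) == 0 for g in grouping.groups):
        raise DisjointnessError("empty taxon group")
    quartets = enumerate_quartets(grouping, cap=cap, seed=seed)
    if model is None:
        alpha = opts.alpha
        if alpha is None:
            alpha = estimate_alpha(aln, quartets, opts, seed=seed + 1)
        model = default_model(aln, alpha, opts.n_cat, opts.freq_pseudocount)
    evaluations = [
        evaluate_quartet(aln, q, model, opts=opts, seed=seed) for q in quartets
    ]
    kept = [e for e in evaluations if not e.skipped]
    counts = {r: 0 for r in REGIONS}
    for e in kept:
        counts[e.region] += 1
    n_eval = len(kept)
    percent = {
        r: (100.0 * c / n_eval if n_eval else 0.0) for r, c in counts.items()
    }
    corner_total = counts["C1"] + counts["C2"] + counts["C3"]
    topo = (
        tuple(100.0 * counts[c] / corner_total for c in ("C1", "C2", "C3"))
        if corner_total
        else None
    )
    return FcLMSummary(
        label=grouping.label,
        group_names=grouping.group_names,
        n_sampled=len(quartets),
        n_evaluated=n_eval,
        n_skipped=len(quartets) - n_eval,
        region_counts=counts,
        region_percent=percent,
        topology_percent=topo,
        evaluations=evaluations,
    )


def plot_simplex(summary: FcLMSummary, path: str) -> None:
    """Scatter the quartet support vectors in the 2-simplex (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # barycentric -> cartesian with corners C1 top, C2 bottom-left, C3 bottom-right
    corners = np.array([[0.5, np.sqrt(3) / 2], [0.0, 0.0], [1.0, 0.0]])
    pts = np.array([e.weights for e in summary.evaluations if not e.skipped])
    fig, ax = plt.subplots(figsize=(5, 5))
    tri = np.vstack([corners, corners[0]])
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
    if len(pts):
        xy = pts @ corners
        ax.scatter(xy[:, 0], xy[:, 1], s=8, alpha=0.5)
    for label, (x, y) in zip(("T1", "T2", "T3"), corners):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(0, 4),
                    ha="center")
    ax.set_axis_off()
    ax.set_title(summary.label)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
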