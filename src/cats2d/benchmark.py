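"""Retrospective screening benchmark: BEDROC enrichment, scaffold-hopping
diversity, and descriptor-comparison statistics.

For every eligible target (at least ``min_actives_per_target`` annotated
ligands) each active is used as a query in turn against the remaining pool,
giving one ranked list per (representation, query). Early enrichment is scored
with BEDROC(alpha) (Truchon & Bailey's exponentially weighted ROC relative);
scaffold-hopping potential with the relative scaffold diversity r = s/n, the
ratio of distinct Murcko scaffolds s to retrieved actives n among the top
fraction of each list. Descriptor families are compared with pairwise
one-sided Wilcoxon rank-sum tests and Ward clustering of the resulting
p-value structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import brentq
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .chemio import Compound, murcko_scaffold
from .simsearch import DescriptorSpec, RankedRetrieval, get_representation, scores_against, sort_entries

log = logging.getLogger(__name__)

__all__ = [
    "BenchmarkConfig",
    "QueryResult",
    "DescriptorComparison",
    "bedroc",
    "alpha_for_contribution",
    "scaffold_diversity",
    "run_benchmark",
    "compare_descriptors",
    "results_frame",
    "summarize",
    "plot_distributions",
]

#: BEDROC exponent at which the top 1% of a ranked list contributes 80% of
#: the score mass (see alpha_for_contribution).
DEFAULT_ALPHA = 160.9


@dataclass
class BenchmarkConfig:
    alpha: float = DEFAULT_ALPHA
    top_fraction: float = 0.01
    min_actives_per_target: int = 20

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class QueryResult:
    query_id: str
    target_id: str
    bedroc: float
    n: int                      # actives retrieved within the top fraction
    s: int                      # distinct Murcko scaffolds among them
    r: float | None             # s / n, absent when n == 0


@dataclass
class DescriptorComparison:
    descriptors: list[str]
    p_matrix: pd.DataFrame      # one-sided rank-sum p for "row > column"
    linkage_matrix: np.ndarray  # scipy Ward merge tree, n-1 rows
    distance_transform: str = "1 - 2*min(p_ij, p_ji)"

    def to_newick(self) -> str:
        """Newick rendering of the Ward merge tree (merge heights as lengths)."""
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
            if node.is_leaf():
                return f"{self.descriptors[node.id]}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# BEDROC
# ---------------------------------------------------------------------------

def bedroc(ranked: RankedRetrieval, alpha: float = DEFAULT_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC, bounded in [0, 1].

    With N candidates, n actives at 1-based ranks r_i and Ra = n/N:

        RIE    = (1/n) * sum_i exp(-alpha*r_i/N)
                 / [(1/N) * (1 - exp(-alpha)) / (exp(alpha/N) - 1)]
        BEDROC = RIE * Ra*sinh(alpha/2) / (cosh(alpha/2) - cosh(alpha/2 - alpha*Ra))
                 + 1 / (1 - exp(alpha*(1 - Ra)))
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    ranks = np.asarray(ranked.active_ranks(), dtype=float)
    N = ranked.n
    n = len(ranks)
    if n == 0 or n == N:
        raise ValueError("ranking must contain at least one active and one inactive")
    ra = n / N
    s = float(np.sum(np.exp(-alpha * ranks / N)))
    rie = (s / n) / ((1.0 / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0))
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    constant = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return rie * factor + constant


def random_bedroc_expectation(n_total: int, n_actives: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Expected BEDROC of a uniformly random ranking (RIE expectation = 1)."""
    ra = n_actives / n_total
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    return factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))


def alpha_for_contribution(top_fraction: float, contribution: float) -> float:
    """Solve for the BEDROC exponent giving the stated early score contribution.

    Finds alpha with (1 - exp(-alpha*z)) / (1 - exp(-alpha)) = f by bracketed
    root finding; e.g. z = 0.01, f = 0.8 yields alpha ~= 160.9, the exponent at
    which the top 1% of the list carries 80% of the exponential weight.
    """
    z, f = top_fraction, contribution
    if not (0 < z < 1) or not (0 < f < 1):
        raise ValueError("top_fraction and contribution must be in (0, 1)")

    def g(a: float) -> float:
        return (1.0 - math.exp(-a * z)) / (1.0 - math.exp(-a)) - f

    lo, hi = 1e-6, 1e4
    if g(lo) * g(hi) > 0:
        raise ValueError(f"no alpha in ({lo}, {hi}) satisfies the contribution equation")
    return float(brentq(g, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Scaffold diversity
# ---------------------------------------------------------------------------

def scaffold_diversity(
    ranked: RankedRetrieval,
    top_fraction: float,
    scaffolds: dict[str, str],
) -> tuple[int, int, float | None]:
    """(n, s, r) among the top fraction of one ranked list.

    n = actives within the top ceil(top_fraction * |pool|) entries, s = number
    of distinct Murcko scaffold keys among them, r = s/n (None when n = 0).
    The ceiling guarantees a nonempty cut for any nonempty pool.
    """
    cut = math.ceil(top_fraction * ranked.n)
    top_actives = [e.candidate_id for e in ranked.entries[:cut] if e.is_active]
    n = len(top_actives)
    if n == 0:
        return 0, 0, None
    missing = [cid for cid in top_actives if cid not in scaffolds]
    if missing:
        raise KeyError(f"no scaffold key for active(s) {missing}")
    s = len({scaffolds[cid] for cid in top_actives})
    return n, s, s / n


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

def eligible_targets(pool: Sequence[Compound], min_actives: int) -> dict[str, list[str]]:
    """target -> sorted ligand ids, restricted to targets meeting the threshold."""
    by_target: dict[str, list[str]] = {}
    for c in pool:
        for t in c.targets:
            by_target.setdefault(t, []).append(c.id)
    eligible = {t: sorted(ids) for t, ids in by_target.items() if len(ids) >= min_actives}
    for t in sorted(set(by_target) - set(eligible)):
        log.info("target %s has %d < %d actives; skipped", t, len(by_target[t]), min_actives)
    return dict(sorted(eligible.items()))


def run_benchmark(
    pool: Sequence[Compound],
    representations: Sequence[str | DescriptorSpec],
    config: BenchmarkConfig | None = None,
) -> dict[str, list[QueryResult]]:
    """Leave-one-out retrospective screening over all eligible targets.

    For each representation, each ligand of each eligible target is used as a
    query against all remaining pool compounds; actives are the other ligands
    annotated to the same target (multi-target compounds are active in each of
    their targets' runs). Returns per-representation QueryResult lists in a
    deterministic (target, query) order.
    """
    config = config or BenchmarkConfig()
    targets = eligible_targets(pool, config.min_actives_per_target)
    if not targets:
        raise ValueError(
            f"no target has >= {config.min_actives_per_target} annotated actives"
        )
    ids = [c.id for c in pool]
    index_of = {cid: i for i, cid in enumerate(ids)}
    scaffolds = {c.id: murcko_scaffold(c) for c in pool}

    results: dict[str, list[QueryResult]] = {}
    for rep in representations:
        spec = get_representation(rep)
        features = spec.featurize(list(pool))
        per_rep: list[QueryResult] = []
        for target, ligands in targets.items():
            actives = set(ligands)
            for query_id in ligands:
                qi = index_of[query_id]
                scores = scores_against(features, qi, spec.metric)
                keep = [k for k in range(len(ids)) if k != qi]
                entries = sort_entries([ids[k] for k in keep],
                                       [scores[k] for k in keep],
                                       actives - {query_id}, spec.metric)
                ranked = RankedRetrieval(query_id, entries, spec.metric)
                try:
                    score = bedroc(ranked, config.alpha)
                except ValueError as exc:
                    log.warning("query %s/%s skipped: %s", target, query_id, exc)
                    continue
                n, s, r = scaffold_diversity(ranked, config.top_fraction, scaffolds)
                per_rep.append(QueryResult(query_id, target, score, n, s, r))
        results[spec.name] = per_rep
    return results


def results_frame(results: dict[str, list[QueryResult]]) -> pd.DataFrame:
    rows = [
        {"representation": rep, "query_id": q.query_id, "target_id": q.target_id,
         "bedroc": q.bedroc, "n": q.n, "s": q.s, "r": q.r}
        for rep, qs in results.items() for q in qs
    ]
    return pd.DataFrame(rows)


def summarize(results: dict[str, list[QueryResult]], statistic: str = "bedroc") -> pd.DataFrame:
    """Median and quartiles per representation (inclusive quantile definition)."""
    df = results_frame(results).dropna(subset=[statistic])
    return (
        df.groupby("representation")[statistic]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
    )


# ---------------------------------------------------------------------------
# Descriptor comparison (rank-sum tests + Ward clustering)
# ---------------------------------------------------------------------------

def _statistic_values(qs: Sequence[QueryResult], statistic: str,
                      aggregate: str = "pooled") -> np.ndarray:
    if aggregate == "per_target":
        by_target: dict[str, list[float]] = {}
        for q in qs:
            v = getattr(q, statistic)
            if v is not None:
                by_target.setdefault(q.target_id, []).append(v)
        return np.asarray([float(np.mean(v)) for _, v in sorted(by_target.items())])
    vals = [getattr(q, statistic) for q in qs]
    return np.asarray([v for v in vals if v is not None], dtype=float)


def compare_descriptors(
    results: dict[str, list[QueryResult]],
    statistic: str = "bedroc",
    aggregate: str = "pooled",
) -> DescriptorComparison:
    """Pairwise one-sided Wilcoxon rank-sum tests plus Ward clustering.

    p_matrix[i, j] is the one-sided rank-sum p-value for "distribution i is
    stochastically greater than distribution j". Ward linkage runs on the
    symmetrized distance d(i, j) = 1 - 2*min(p_ij, p_ji): identical
    distributions (both p ~ 0.5) map to d ~ 0, fully separated ones to d ~ 1.

    By default per-query scores are pooled over all targets;
    ``aggregate="per_target"`` first averages scores within each target and
    tests the per-target means instead.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need >= 2 representations to compare")
    samples = {name: _statistic_values(results[name], statistic, aggregate)
               for name in names}
    for name, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"representation {name!r} has < 2 results")

    k = len(names)
    p = np.full((k, k), 0.5)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            xi, xj = samples[names[i]], samples[names[j]]
            if np.ptp(xi) == 0 and np.ptp(xj) == 0 and xi[0] == xj[0]:
                log.warning("degenerate constant distributions %s vs %s; p := 0.5",
                            names[i], names[j])
                continue
            p[i, j] = mannwhitneyu(xi, xj, alternative="greater").pvalue

    dist = 1.0 - 2.0 * np.minimum(p, p.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    lm = linkage(squareform(dist, checks=False), method="ward")
    return DescriptorComparison(names, pd.DataFrame(p, index=names, columns=names), lm)


def plot_distributions(results: dict[str, list[QueryResult]], statistic: str,
                       path: str) -> None:
    """Violin plot of per-query statistic distributions, one violin per
    representation, with median and quartile markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(results)
    data = [_statistic_values(results[n], statistic) for n in names]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.violinplot(data, showmedians=True, quantiles=[[0.25, 0.75]] * len(names))
    ax.set_xticks(range(1, len(names) + 1), names, rotation=45, ha="right")
    ax.set_ylabel(statistic)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
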