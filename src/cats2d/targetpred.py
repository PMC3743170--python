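"""SOM-co-clustering ligand-based target prediction with empirical p-values.

A query (e.g. a virtual combinatorial product) is projected onto a SOM trained
on the union of annotated reference compounds and queries. Only targets of
reference compounds sharing the query's cell are considered candidates — a
conservative application domain that reduces false-positive predictions. Each
(query, target) candidate is scored by the minimal descriptor distance from
the query to a co-clustered ligand of that target, and converted to an
empirical p-value against the null distribution of distances between reference
ligands binding to *different* targets. The p-value estimates the probability
of a false-positive (type-I) prediction: how often two unrelated ligands come
out at least this similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import Compound

log = logging.getLogger(__name__)

__all__ = [
    "NullScoreDistribution",
    "TargetPrediction",
    "build_null",
    "empirical_p",
    "predict_targets",
    "library_target_profile",
    "joint_target_rank",
]


@dataclass
class NullScoreDistribution:
    metric: str
    scores: np.ndarray          # sorted ascending
    n_pairs_sampled: int
    seed: int

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TargetPrediction:
    compound_id: str
    target_id: str
    cell: tuple[int, int]
    n_cocluster_refs: int
    score: float
    p_value: float
    rank: int


def build_null(
    references: Sequence[Compound],
    matrix: np.ndarray,
    max_pairs: int = 10**6,
    seed: int = 7,
) -> NullScoreDistribution:
    """Null distances between reference ligands with disjoint target sets.

    Enumerates all unordered pairs of annotated references whose target-id
    sets are disjoint, subsamples up to ``max_pairs`` of them without
    replacement (seeded), and stores their Euclidean descriptor distances
    sorted ascending.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(references):
        raise ValueError("matrix rows must match references")
    annotated = [i for i, c in enumerate(references) if c.targets]
    pairs = [
        (i, j)
        for i, j in combinations(annotated, 2)
        if references[i].targets.isdisjoint(references[j].targets)
    ]
    if len(pairs) < 2:
        raise ValueError("need >= 2 reference pairs with disjoint target sets")
    rng = np.random.default_rng(seed)
    if len(pairs) > max_pairs:
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    dists = np.sqrt(((matrix[ii] - matrix[jj]) ** 2).sum(axis=1))
    return NullScoreDistribution("euclidean_distance", np.sort(dists), len(pairs), seed)


def empirical_p(score: float, null: NullScoreDistribution) -> float:
    """Add-one empirical p-value of a distance score against the null.

    Smaller distance = more similar, so p = (1 + #{null <= score}) / (1 + M).
    The pseudo-count keeps p in (0, 1] for any finite null sample.
    """
    if len(null) == 0:
        raise ValueError("empty null distribution")
    count = int(np.searchsorted(null.scores, score, side="right"))
    return (1 + count) / (1 + len(null))


def predict_targets(
    model,
    references: Sequence[Compound],
    ref_matrix: np.ndarray,
    queries: Sequence[Compound],
    query_matrix: np.ndarray,
    null: NullScoreDistribution,
) -> list[TargetPrediction]:
    """Predict targets for queries via SOM co-clustering.

    For each query, candidate targets are the union of annotations of
    references assigned to the query's cell. The per-(query, target) score is
    the minimal Euclidean descriptor distance from the query to a co-clustered
    ligand of that target; predictions are sorted per query by p ascending
    (ties by target id) and ranked 1..k. Queries landing in cells without
    annotated references get no predictions (logged).
    """
    ref_matrix = np.asarray(ref_matrix, dtype=float)
    query_matrix = np.asarray(query_matrix, dtype=float)
    if ref_matrix.shape[0] != len(references) or query_matrix.shape[0] != len(queries):
        raise ValueError("descriptor matrices must match compound lists")

    refs_by_cell: dict[tuple[int, int], list[int]] = {}
    for i, ref in enumerate(references):
        cell = model.cell_of(ref.id)
        refs_by_cell.setdefault(cell, []).append(i)

    predictions: list[TargetPrediction] = []
    for qi, query in enumerate(queries):
        cell = model.cell_of(query.id)
        co_refs = [i for i in refs_by_cell.get(cell, []) if references[i].targets]
        if not co_refs:
            log.info("query %s: no annotated references in cell %s", query.id, cell)
            continue
        candidates: dict[str, list[int]] = {}
        for i in co_refs:
            for t in references[i].targets:
                candidates.setdefault(t, []).append(i)
        scored = []
        for target, ref_idx in candidates.items():
            d = np.sqrt(((ref_matrix[ref_idx] - query_matrix[qi]) ** 2).sum(axis=1))
            score = float(d.min())
            scored.append((empirical_p(score, null), target, score, len(ref_idx)))
        scored.sort(key=lambda rec: (rec[0], rec[1]))
        for rank, (p, target, score, n_refs) in enumerate(scored, 1):
            predictions.append(
                TargetPrediction(query.id, target, cell, n_refs, score, p, rank)
            )
    return predictions


def library_target_profile(
    predictions: Sequence[TargetPrediction],
    p_threshold: float = 0.01,
    all_query_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Library-level target profile: targets whose mean p over the compounds
    predicted for them is strictly below the threshold, sorted ascending.

    By default the mean runs over predicted members only. Passing
    ``all_query_ids`` switches to averaging over the whole query library,
    counting members without a prediction for the target at p = 1.

    Returns a DataFrame indexed by target_id with columns mean_p and
    n_compounds (compounds carrying a prediction for that target).
    """
    if not predictions:
        raise ValueError("no predictions to profile")
    df = pd.DataFrame(
        {"target_id": p.target_id, "p_value": p.p_value, "compound_id": p.compound_id}
        for p in predictions
    )
    profile = df.groupby("target_id").agg(
        mean_p=("p_value", "mean"), n_compounds=("compound_id", "nunique")
    )
    if all_query_ids is not None:
        n_total = len(set(all_query_ids))
        # members without a prediction enter the average at p = 1
        profile["mean_p"] = (
            profile["mean_p"] * profile["n_compounds"] + (n_total - profile["n_compounds"])
        ) / n_total
    return (
        profile.query("mean_p < @p_threshold").sort_values(["mean_p", "target_id"])
    )


def joint_target_rank(
    predictions: Sequence[TargetPrediction],
    targets: tuple[str, str],
) -> list[tuple[str, float, float]]:
    """Rank compounds predicted for *both* targets by worst-case confidence.

    Keeps compounds carrying predictions for both targets and sorts them
    ascending by max(p_target1, p_target2) — both predictions must be
    confident — with ties broken by compound id. Returns
    (compound_id, p_target1, p_target2) triples.
    """
    t1, t2 = targets
    present = {p.target_id for p in predictions}
    for t in (t1, t2):
        if t not in present:
            raise ValueError(f"target {t!r} absent from predictions")
    by_compound: dict[str, dict[str, float]] = {}
    for p in predictions:
        if p.target_id in (t1, t2):
            by_compound.setdefault(p.compound_id, {})[p.target_id] = p.p_value
    rows = [
        (cid, ps[t1], ps[t2])
        for cid, ps in by_compound.items()
        if t1 in ps and t2 in ps
    ]
    if not rows:
        log.warning("no compound has predictions for both %s and %s", t1, t2)
        return []
    rows.sort(key=lambda rec: (max(rec[1], rec[2]), rec[0]))
    return rows
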