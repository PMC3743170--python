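"""Similarity search: metrics, molecular representations, and ranked retrieval.

Metric descriptors (CATS vectors) are compared by Euclidean distance, binary
fingerprints (Morgan, MACCS, Daylight-like path fingerprint) by the Tanimoto
coefficient. Rankings are fully deterministic: best score first, ties broken
by candidate id ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .cats import cats_matrix
from .chemio import Compound

log = logging.getLogger(__name__)

__all__ = [
    "Entry",
    "RankedRetrieval",
    "euclidean",
    "tanimoto",
    "DescriptorSpec",
    "get_representation",
    "REPRESENTATIONS",
    "rank_pool",
]


class Entry(NamedTuple):
    candidate_id: str
    score: float
    is_active: bool


@dataclass
class RankedRetrieval:
    """A query's score-sorted candidate list with active/inactive labels."""

    query_id: str
    entries: list[Entry]
    metric: str  # "euclidean_distance" | "tanimoto_similarity"

    def active_ranks(self) -> list[int]:
        """1-based ranks of the active entries."""
        return [i for i, e in enumerate(self.entries, 1) if e.is_active]

    @property
    def n(self) -> int:
        return len(self.entries)


def euclidean(u: Sequence[float], v: Sequence[float]) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a&b| / |a|b| for bit vectors or index sets.

    Two empty bit sets compare as 1.0 (featureless objects are
    indistinguishable); this degenerate case is logged.
    """
    if isinstance(a, (set, frozenset)) or isinstance(b, (set, frozenset)):
        a, b = set(a), set(b)
        union = a | b
        if not union:
            log.warning("Tanimoto of two empty bit sets; returning 1.0")
            return 1.0
        return len(a & b) / len(union)
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError("fingerprint universe sizes differ")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        log.warning("Tanimoto of two empty fingerprints; returning 1.0")
        return 1.0
    return float(DataStructs.TanimotoSimilarity(a, b))


# ---------------------------------------------------------------------------
# Representations
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSpec:
    """A named molecular representation with its associated metric.

    ``featurize`` maps a compound list to either a real matrix (metric
    ``euclidean_distance``) or a list of RDKit bit vectors (metric
    ``tanimoto_similarity``).
    """

    name: str
    metric: str
    featurize: Callable[[Sequence[Compound]], object]


def _morgan(compounds: Sequence[Compound]):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return [gen.GetFingerprint(c.mol) for c in compounds]


def _maccs(compounds: Sequence[Compound]):
    return [MACCSkeys.GenMACCSKeys(c.mol) for c in compounds]


def _pathfp(compounds: Sequence[Compound]):
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
    return [gen.GetFingerprint(c.mol) for c in compounds]


REPRESENTATIONS: dict[str, DescriptorSpec] = {
    "cats1": DescriptorSpec("cats1", "euclidean_distance",
                            lambda cs: cats_matrix(cs, "cats1", "types")),
    "cats2": DescriptorSpec("cats2", "euclidean_distance",
                            lambda cs: cats_matrix(cs, "cats2", "types")),
    "morgan": DescriptorSpec("morgan", "tanimoto_similarity", _morgan),
    "maccs": DescriptorSpec("maccs", "tanimoto_similarity", _maccs),
    "pathfp": DescriptorSpec("pathfp", "tanimoto_similarity", _pathfp),
}


def get_representation(representation: str | DescriptorSpec) -> DescriptorSpec:
    if isinstance(representation, DescriptorSpec):
        return representation
    try:
        return REPRESENTATIONS[representation]
    except KeyError:
        raise ValueError(
            f"unknown representation {representation!r}; "
            f"choose from {sorted(REPRESENTATIONS)}"
        ) from None


def scores_against(features, query_index: int, metric: str) -> np.ndarray:
    """Score every row/fingerprint against the one at query_index."""
    if metric == "euclidean_distance":
        mat = np.asarray(features, dtype=float)
        return np.sqrt(np.sum((mat - mat[query_index]) ** 2, axis=1))
    sims = DataStructs.BulkTanimotoSimilarity(features[query_index], list(features))
    return np.asarray(sims, dtype=float)


def sort_entries(ids: Sequence[str], scores: Sequence[float], actives: set[str],
                 metric: str) -> list[Entry]:
    """Deterministic best-first ordering with id tie-break."""
    reverse = metric == "tanimoto_similarity"
    order = sorted(range(len(ids)),
                   key=lambda k: (-scores[k] if reverse else scores[k], ids[k]))
    return [Entry(ids[k], float(scores[k]), ids[k] in actives) for k in order]


def rank_pool(
    query: Compound,
    pool: Sequence[Compound],
    representation: str | DescriptorSpec = "cats2",
    actives: set[str] | None = None,
) -> RankedRetrieval:
    """Rank a screening pool against one query compound.

    The query must not be part of the pool. Entries are sorted best-first
    (ascending distance or descending similarity) with ties broken by
    candidate id.
    """
    if not pool:
        raise ValueError("empty screening pool")
    if any(c.id == query.id for c in pool):
        raise ValueError(f"query {query.id!r} must not be in the pool")
    actives = actives or set()
    spec = get_representation(representation)

    features = spec.featurize([query, *pool])
    scores = scores_against(features, 0, spec.metric)[1:]
    ids = [c.id for c in pool]
    return RankedRetrieval(query.id, sort_entries(ids, scores, actives, spec.metric),
                           spec.metric)
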