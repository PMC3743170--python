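"""CATS topological pharmacophore-pair descriptors.

The descriptor reduces a molecule to its heavy-atom graph, assigns abstract
pharmacophore feature types to atoms by substructure rules, counts atom pairs
per unordered feature-type pair at each topological (shortest-path, bond-count)
distance, and optionally normalizes each pair block by the summed occurrence
counts of the two feature types ("types scaling", lambda).

Two variants are supported:

* ``cats1`` — five feature types (donor D, acceptor A, positive P, negative N,
  lipophilic L); aromatic carbons satisfying the lipophilic rule count as L.
* ``cats2`` — adds the aromatic type R; aromatic atoms are typed R and
  excluded from L, yielding 21 type pairs instead of 15.

With the default maximal correlation distance of 10 bonds (bins d = 0..9) the
vectors have the canonical dimensionalities 150 (CATS1) and 210 (CATS2).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem

from .chemio import Compound

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RULES",
    "VARIANT_TYPES",
    "FeatureTyping",
    "CATSVector",
    "assign_features",
    "cats_vector",
    "cats_matrix",
    "vector_labels",
    "load_rules",
    "rules_hash",
    "write_matrix",
]

# Feature-typing rule table as SMARTS lists. The published CATS scheme names
# the roles (donor, acceptor, positive, negative, lipophilic, aromatic) but not
# the exact patterns; this table follows common pharmacophore conventions and
# is config-overridable (see load_rules).
DEFAULT_RULES: dict[str, list[str]] = {
    # O or N bearing at least one hydrogen
    "D": ["[#7;!H0]", "[#8;!H0]"],
    # any O; N without H that retains a lone pair (not quaternary, not amide)
    "A": ["[#8]", "[#7;H0;+0;!X4;!$([#7][#6,#16,#15]=[O,S])]"],
    # protonatable: formal positive charge, basic aliphatic amines, guanidine
    "P": [
        "[*;+;!$([*;+]~[*;-])]",
        "[NX3;H2,H1;+0;$(N[CX4]);!$(N[a]);!$(N[#6]=[O,S,N])]",
        "[NX3;H0;+0;$(N([CX4])([CX4])[CX4])]",
        "[NX3;$([NX3][CX3](=[NX2])[NX3])]",
        "[NX2;$([NX2]=[CX3]([NX3])[NX3])]",
    ],
    # deprotonatable/anionic: formal negative charge, carboxylic/sulfonic/
    # phosphonic acid oxygens
    "N": [
        "[*;-;!$([*;-]~[*;+])]",
        "[OX1]=[CX3][OX2H1]",
        "[OX2H1][CX3]=[OX1]",
        "[OX1,OX2H1;$([OX1,OX2H1][SX4](=[OX1])=[OX1])]",
        "[OX1,OX2H1;$([OX1,OX2H1][PX4]=[OX1])]",
    ],
    # C or S whose heavy neighbors are all C or S (requires >= 1 heavy neighbor)
    "L": ["[#6,#16;!$([#6,#16]~[!#6;!#16;!#1]);!D0]"],
    # toolkit aromaticity flag (used by the cats2 variant only)
    "R": ["[a]"],
}

VARIANT_TYPES: dict[str, tuple[str, ...]] = {
    "cats1": ("D", "A", "P", "N", "L"),
    "cats2": ("D", "A", "P", "N", "L", "R"),
}


@dataclass
class FeatureTyping:
    """Map from atom index to the set of feature types assigned to it."""

    variant: str
    assignments: dict[int, frozenset[str]]

    def type_counts(self, types: Sequence[str]) -> dict[str, int]:
        return {t: sum(1 for s in self.assignments.values() if t in s) for t in types}


@dataclass
class CATSVector:
    variant: str
    scaling: str
    max_distance: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = len(type_pairs(self.variant)) * self.max_distance
        if self.values.shape != (expected,):
            raise ValueError(f"expected length {expected}, got {self.values.shape}")


def type_pairs(variant: str) -> list[tuple[str, str]]:
    """Unordered feature-type pairs in canonical order (15 for cats1, 21 for cats2)."""
    types = VARIANT_TYPES[variant]
    return list(combinations_with_replacement(types, 2))


def vector_labels(variant: str, max_distance: int = 10) -> list[str]:
    """Column labels ``"<T1><T2>.<d>"`` matching cats_vector element order."""
    return [f"{t1}{t2}.{d}" for (t1, t2) in type_pairs(variant) for d in range(max_distance)]


def load_rules(path: str | Path) -> dict[str, list[str]]:
    """Load an alternative feature rule table from YAML (type -> SMARTS list)."""
    with Path(path).open() as fh:
        rules = yaml.safe_load(fh)
    unknown = set(rules) - set(DEFAULT_RULES)
    if unknown:
        raise ValueError(f"unknown feature types in rule table: {sorted(unknown)}")
    for ftype, patterns in rules.items():
        for smarts in patterns:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid SMARTS for type {ftype}: {smarts!r}")
    return {k: list(v) for k, v in rules.items()}


def rules_hash(rules: dict[str, list[str]] | None = None) -> str:
    payload = json.dumps(rules or DEFAULT_RULES, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SMARTS_CACHE: dict[str, Chem.Mol] = {}


def _patterns(smarts_list: Iterable[str]) -> list[Chem.Mol]:
    out = []
    for s in smarts_list:
        if s not in _SMARTS_CACHE:
            patt = Chem.MolFromSmarts(s)
            if patt is None:
                raise ValueError(f"invalid SMARTS {s!r}")
            _SMARTS_CACHE[s] = patt
        out.append(_SMARTS_CACHE[s])
    return out


def assign_features(
    compound: Compound | Chem.Mol,
    variant: str = "cats2",
    rules: dict[str, list[str]] | None = None,
) -> FeatureTyping:
    """Assign pharmacophore feature types to every heavy atom.

    An atom may carry several types. Under ``cats1`` the aromatic type is never
    assigned (aromatic carbons may still satisfy the lipophilic rule); under
    ``cats2`` aromatic atoms are typed R and excluded from L.
    """
    if variant not in VARIANT_TYPES:
        raise ValueError(f"unknown variant {variant!r}")
    mol = compound.mol if isinstance(compound, Compound) else compound
    rules = rules or DEFAULT_RULES

    matched: dict[str, set[int]] = {}
    for ftype in VARIANT_TYPES[variant]:
        hits: set[int] = set()
        for patt in _patterns(rules.get(ftype, [])):
            for match in mol.GetSubstructMatches(patt, uniquify=True):
                hits.add(match[0])
        matched[ftype] = hits
    if variant == "cats2":
        matched["L"] -= matched.get("R", set())

    assignments: dict[int, frozenset[str]] = {}
    for ftype, atoms in matched.items():
        for idx in atoms:
            assignments[idx] = assignments.get(idx, frozenset()) | {ftype}
    return FeatureTyping(variant, assignments)


def cats_vector(
    compound: Compound | Chem.Mol,
    variant: str = "cats2",
    scaling: str = "types",
    max_distance: int = 10,
    rules: dict[str, list[str]] | None = None,
    binning: str = "d0",
    count_self_pairs: bool = True,
) -> CATSVector:
    """Compute one CATS descriptor vector.

    For every unordered type pair (T1, T2) and topological distance
    d in {0, .., max_distance-1}, counts heavy-atom pairs (i, j), i <= j, where
    one atom carries T1 and the other T2; each atom pair contributes at most
    once per type pair. The d = 0 bin counts single atoms carrying both types
    of a heterotypic pair. Distances use the hydrogen-suppressed graph; atom
    pairs in different fragments (infinite distance) are not counted.

    ``scaling="raw"`` leaves integer counts; ``scaling="types"`` divides each
    pair block by lambda(T1, T2) = occurrences(T1) + occurrences(T2) in the
    molecule (2x the count for homotypic pairs), with 0/0 defined as 0.

    Two conventions of the original implementation are not documented and are
    exposed as switches: ``binning="d1"`` maps bins to distances 1..max
    instead of 0..max-1 (no self-pair bin), and ``count_self_pairs=False``
    drops the d = 0 single-atom counts while keeping the bin layout.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if scaling not in ("raw", "types"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if binning not in ("d0", "d1"):
        raise ValueError(f"unknown binning {binning!r}")
    mol = compound.mol if isinstance(compound, Compound) else compound
    typing = assign_features(mol, variant, rules)

    pairs = type_pairs(variant)
    pair_index = {p: k for k, p in enumerate(pairs)}
    counts = np.zeros((len(pairs), max_distance), dtype=float)
    d_lo, d_hi = (0, max_distance - 1) if binning == "d0" else (1, max_distance)

    typed_atoms = sorted(typing.assignments)
    if binning == "d0" and count_self_pairs:
        # d = 0: single atoms carrying both members of a heterotypic pair
        for idx in typed_atoms:
            for t1, t2 in combinations(sorted(typing.assignments[idx]), 2):
                key = (t1, t2) if (t1, t2) in pair_index else (t2, t1)
                counts[pair_index[key], 0] += 1

    if len(typed_atoms) >= 2:
        dmat = Chem.GetDistanceMatrix(mol)
        for i, j in combinations(typed_atoms, 2):
            d = dmat[i, j]
            if not (max(d_lo, 1) <= d <= d_hi):  # excludes disconnected (1e8)
                continue
            d = int(d) - d_lo
            seen: set[tuple[str, str]] = set()
            for t1 in typing.assignments[i]:
                for t2 in typing.assignments[j]:
                    key = (t1, t2) if (t1, t2) in pair_index else (t2, t1)
                    seen.add(key)
            for key in seen:
                counts[pair_index[key], d] += 1

    if scaling == "types":
        occ = typing.type_counts(VARIANT_TYPES[variant])
        for k, (t1, t2) in enumerate(pairs):
            lam = occ[t1] + occ[t2]
            if lam > 0:
                counts[k] /= lam
            # lam == 0 implies an all-zero block; 0/0 -> 0

    return CATSVector(variant, scaling, max_distance, counts.ravel())


def cats_matrix(
    compounds: Sequence[Compound],
    variant: str = "cats2",
    scaling: str = "types",
    max_distance: int = 10,
    rules: dict[str, list[str]] | None = None,
) -> np.ndarray:
    """Stack per-compound CATS vectors into an (n_compounds, dim) matrix.

    Row order matches input order; a compound whose descriptor computation
    fails yields an all-zero row and a logged warning.
    """
    if not compounds:
        raise ValueError("need at least one compound")
    dim = len(type_pairs(variant)) * max_distance
    out = np.zeros((len(compounds), dim))
    for i, c in enumerate(compounds):
        try:
            out[i] = cats_vector(c, variant, scaling, max_distance, rules).values
        except Exception as exc:  # descriptor failure must not kill the batch
            log.warning("CATS failed for %s (%s); emitting zero row", c.id, exc)
    return out


def write_matrix(
    compounds: Sequence[Compound],
    matrix: np.ndarray,
    path: str | Path,
    variant: str,
    scaling: str,
    max_distance: int,
    rules: dict[str, list[str]] | None = None,
) -> None:
    """Write a descriptor matrix as CSV plus a JSON sidecar with provenance."""
    import pandas as pd

    path = Path(path)
    labels = vector_labels(variant, max_distance)
    df = pd.DataFrame(matrix, columns=labels)
    df.insert(0, "id", [c.id for c in compounds])
    df.to_csv(path, index=False)
    sidecar = {
        "variant": variant,
        "scaling": scaling,
        "max_distance": max_distance,
        "rule_table_hash": rules_hash(rules),
        "n_compounds": len(compounds),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
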