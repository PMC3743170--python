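"""Deterministic synthetic compound collections and building-block sets.

Emulates, at desk scale, an annotated reference collection of druglike
bioactives organized by target: each synthetic target family decorates a
small set of distinct ring scaffolds with side chains drawn from a
target-characteristic pharmacophore motif pool (one family enriched in
donor-acceptor chains, another in basic amines next to aromatics, and so
on), so that ligands of one target are close in topological pharmacophore
space while remaining spread over several Murcko scaffolds. Decoys combine
arbitrary scaffolds with arbitrary motifs. All randomness flows through one
seeded NumPy generator per call; identical specs produce byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import BlockRole, BuildingBlockSet, Compound

__all__ = [
    "FixtureSpec",
    "SCAFFOLD_VOCABULARY",
    "TARGET_MOTIF_POOLS",
    "generate_collection",
    "generate_building_blocks",
    "write_collection",
]

# ~30 common ring systems as SMILES templates with one substitution site.
# Includes the imidazo[1,2-a]pyridine core typical of GBB-type libraries.
SCAFFOLD_VOCABULARY: tuple[str, ...] = (
    "c1ccc({})cc1",                 # benzene
    "c1ccnc({})c1",                 # pyridine
    "c1cnc({})cn1",                 # pyrazine
    "c1ccc({})nn1",                 # pyridazine
    "c1ncnc({})c1",                 # pyrimidine
    "c1ccc({})o1",                  # furan
    "c1ccc({})s1",                  # thiophene
    "c1ccc({})[nH]1",               # pyrrole
    "c1cnc({})[nH]1",               # imidazole
    "c1cc({})[nH]n1",               # pyrazole
    "c1oc({})nc1",                  # oxazole
    "c1sc({})nc1",                  # thiazole
    "c1ccc2cc({})ccc2c1",           # naphthalene
    "c1ccc2[nH]c({})cc2c1",         # indole
    "c1ccc2[nH]c({})nc2c1",         # benzimidazole
    "c1ccc2oc({})cc2c1",            # benzofuran
    "c1ccc2sc({})cc2c1",            # benzothiophene
    "c1ccc2nc({})ccc2c1",           # quinoline
    "c1ccc2cnc({})cc2c1",           # isoquinoline
    "c1ccn2cc({})nc2c1",            # imidazo[1,2-a]pyridine
    "c1ccn2c({})cnc2c1",            # imidazo[1,2-a]pyridine, 3-subst.
    "C1CCC({})CC1",                 # cyclohexane
    "C1CCC({})C1",                  # cyclopentane
    "C1CCN({})CC1",                 # piperidine
    "C1CN({})CCN1",                 # piperazine
    "O1CCN({})CC1",                 # morpholine
    "C1COC({})C1",                  # tetrahydrofuran
    "C1CSC({})C1",                  # tetrahydrothiophene
    "C1CC({})CCO1",                 # tetrahydropyran
    "c1cc2ccccn2c({})1",            # indolizine
)

# Side-chain pools with distinct pharmacophore character; target family t
# draws from pool t mod len(pools).
TARGET_MOTIF_POOLS: tuple[tuple[str, ...], ...] = (
    # donor-acceptor pairs at 4-6 bond separations
    ("NCCCC(N)=O", "NCCCOC(C)=O", "OCCCNC(C)=O", "NCCCCC(N)=O", "OCCCCC(N)=O"),
    # aromatic rings paired with basic (positive) amines
    ("CCN(C)C", "CCCN(C)C", "CCN1CCCC1", "CCCNC", "CCN(CC)CC"),
    # acceptor-rich ether/ester chains
    ("COCCOC", "CCOC(C)=O", "COCCOCC", "CCOCCOC", "COCC(=O)OC"),
    # donor-rich hydroxy/amino chains
    ("NCCO", "OCCNCCO", "OCCCO", "NCCNCCO", "OCCCN"),
    # acidic (negative) chains
    ("CCC(=O)O", "CCCC(=O)O", "CCS(=O)(=O)O", "CCCS(=O)(=O)O", "CCOC(=O)CC(=O)O"),
    # mixed amide/sulfonamide chains
    ("CNC(C)=O", "CCNC(C)=O", "CN(C)C(C)=O", "CCNC(=O)CC", "CNCC(N)=O"),
)

_DECOY_EXTRAS: tuple[str, ...] = (
    "C", "CC", "CCC", "CC(C)C", "CCCC", "CCl", "CBr", "CF", "C(F)(F)F", "C#N",
)


@dataclass
class FixtureSpec:
    n_targets: int = 3
    ligands_per_target: int = 25
    scaffold_count_per_target: int = 4
    decoy_count: int = 100
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.ligands_per_target < 1:
            raise ValueError("need >= 1 target with >= 1 ligand")
        if self.scaffold_count_per_target < 1:
            raise ValueError("need >= 1 scaffold per target")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _make_smiles(template: str, side_chain: str) -> str | None:
    smiles = template.format(side_chain)
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def generate_collection(spec: FixtureSpec) -> list[Compound]:
    """Generate an annotated collection: planted target families plus decoys.

    Each ligand is annotated with exactly one target (``T1`` .. ``Tk``);
    decoys carry no annotation. Ligand ids are ``T<k>_L<i>``, decoy ids
    ``DEC_<i>``. Every emitted structure is valence-legal and round-trips
    through canonical SMILES.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = list(SCAFFOLD_VOCABULARY)
    compounds: list[Compound] = []

    for t in range(spec.n_targets):
        target_id = f"T{t + 1}"
        pool = TARGET_MOTIF_POOLS[t % len(TARGET_MOTIF_POOLS)]
        scaffold_idx = rng.choice(len(vocab),
                                  size=min(spec.scaffold_count_per_target, len(vocab)),
                                  replace=False)
        scaffolds = [vocab[i] for i in scaffold_idx]
        made = 0
        while made < spec.ligands_per_target:
            template = scaffolds[int(rng.integers(len(scaffolds)))]
            motif = pool[int(rng.integers(len(pool)))]
            smiles = _make_smiles(template, motif)
            if smiles is None:
                continue
            made += 1
            compounds.append(
                Compound.from_smiles(smiles, f"{target_id}_L{made}", {target_id})
            )

    all_motifs = [m for pool in TARGET_MOTIF_POOLS for m in pool] + list(_DECOY_EXTRAS)
    made = 0
    while made < spec.decoy_count:
        template = vocab[int(rng.integers(len(vocab)))]
        motif = all_motifs[int(rng.integers(len(all_motifs)))]
        smiles = _make_smiles(template, motif)
        if smiles is None:
            continue
        made += 1
        compounds.append(Compound.from_smiles(smiles, f"DEC_{made}"))
    return compounds


# Fragment cores for synthetic building blocks (trivial attachment assembler).
_FRAG_A = ("C", "CC", "CCC", "CCO", "CCN", "c1ccccc1", "C1CCCCC1", "CC(C)", "CCOC", "CCS")
# internal linkers for B blocks, open at both ends of the SMILES string
_FRAG_B = ("C", "CC", "CCC", "CN(C)C", "COC", "CSC", "CCNCC", "CC(C)C")
_FRAG_C = ("CO", "CN", "CCO", "CC", "C", "c1ccccc1", "CC(C)O", "CCN", "COC", "CCC")


def _unique_fragment(rng: np.random.Generator, make, seen: set[str]) -> str:
    """Draw fragments until a new canonical SMILES appears; after many
    collisions the maker's pad length grows, so the space is unbounded."""
    attempts = 0
    while True:
        smiles = make(rng, extra_pad=attempts // 50)
        attempts += 1
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            return canonical


def generate_building_blocks(
    n_a: int, n_b: int, n_c: int, seed: int = 1
) -> tuple[BuildingBlockSet, BuildingBlockSet, BuildingBlockSet]:
    """Three building-block sets with marked attachment points.

    A-blocks carry ``[*:1]``, B-blocks ``[*:1]`` and ``[*:2]``, C-blocks
    ``[*:2]``; all are compatible with the trivial attachment assembler.
    Deduplication may append extra methylenes, so arbitrarily large sets stay
    distinct.
    """
    if min(n_a, n_b, n_c) < 1:
        raise ValueError("all block counts must be >= 1")
    rng = np.random.default_rng(seed)

    def make_a(r: np.random.Generator, extra_pad: int = 0) -> str:
        core = _FRAG_A[int(r.integers(len(_FRAG_A)))]
        pad = "C" * (int(r.integers(0, 4)) + extra_pad)
        return f"{core}{pad}[*:1]"

    def make_b(r: np.random.Generator, extra_pad: int = 0) -> str:
        core = _FRAG_B[int(r.integers(len(_FRAG_B)))]
        pad1 = "C" * (int(r.integers(0, 4)) + extra_pad)
        pad2 = "C" * int(r.integers(0, 4))
        return f"[*:1]{pad1}{core}{pad2}[*:2]"

    def make_c(r: np.random.Generator, extra_pad: int = 0) -> str:
        core = _FRAG_C[int(r.integers(len(_FRAG_C)))]
        pad = "C" * (int(r.integers(0, 4)) + extra_pad)
        return f"[*:2]{pad}{core}"

    sets = []
    for role, count, make, prefix in (
        (BlockRole.component_A, n_a, make_a, "A"),
        (BlockRole.component_B, n_b, make_b, "B"),
        (BlockRole.component_C, n_c, make_c, "C"),
    ):
        seen: set[str] = set()
        members = []
        for i in range(count):
            smiles = _unique_fragment(rng, make, seen)
            members.append(Compound.from_smiles(smiles, f"{prefix}{i + 1:03d}"))
        sets.append(BuildingBlockSet(role, members))
    return tuple(sets)


def write_collection(compounds: Sequence[Compound], out_dir: str | Path,
                     spec: FixtureSpec | None = None) -> dict[str, Path]:
    """Write a collection as .smi + annotations CSV + manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    smi = out_dir / "collection.smi"
    ann = out_dir / "annotations.csv"
    manifest = out_dir / "manifest.json"
    with smi.open("w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles} {c.id}\n")
    with ann.open("w") as fh:
        fh.write("compound_id,target_id\n")
        for c in compounds:
            for t in sorted(c.targets):
                fh.write(f"{c.id},{t}\n")
    manifest.write_text(json.dumps(
        {"spec": asdict(spec) if spec else None, "n_compounds": len(compounds)},
        indent=2,
    ))
    return {"smi": smi, "annotations": ann, "manifest": manifest}
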