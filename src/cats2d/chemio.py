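"""Molecule I/O, Murcko scaffolds, monoisotopic masses, and combinatorial enumeration.

Compounds are thin wrappers around RDKit molecules carrying a unique id and an
optional set of target annotations. The enumeration machinery builds virtual
three-component libraries from building-block sets, with a pluggable assembly
rule; the shipped default is a Groebke-Blackburn-Bienaymé-type coupling of a
2-aminoazine, an aldehyde and an isocyanide into a 3-aminoimidazo[1,2-a]pyridine,
plus a trivial attachment-point assembler for synthetic fragment sets.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

log = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Da, mass of H+ for [M+H]+ adducts

__all__ = [
    "Compound",
    "BlockRole",
    "BuildingBlockSet",
    "LibraryProduct",
    "read_compounds",
    "read_annotations",
    "apply_annotations",
    "write_smi",
    "murcko_scaffold",
    "scaffold_table",
    "monoisotopic_mh",
    "AttachmentAssembler",
    "ReactionAssembler",
    "GBB_REACTION_SMARTS",
    "enumerate_library",
]


@dataclass
class Compound:
    """An identified molecular structure with optional target annotations."""

    id: str
    mol: Chem.Mol
    targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.mol is None or self.mol.GetNumAtoms() == 0:
            raise ValueError(f"compound {self.id!r}: structure must have >= 1 atom")
        if self.targets is None:
            self.targets = set()

    @classmethod
    def from_smiles(cls, smiles: str, cid: str, targets: Iterable[str] = ()) -> "Compound":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"compound {cid!r}: unparseable SMILES {smiles!r}")
        return cls(cid, mol, set(targets))

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


class BlockRole(str, Enum):
    component_A = "component_A"
    component_B = "component_B"
    component_C = "component_C"


@dataclass
class BuildingBlockSet:
    role: BlockRole
    members: list[Compound]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"building-block set {self.role} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LibraryProduct:
    id: str
    parents: tuple[str, str, str]
    mol: Chem.Mol

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "smiles"}:
        return "smi"
    if suffix in {"sdf", "mol"}:
        return "sdf"
    if suffix in {"csv", "tsv"}:
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_compounds(path: str | Path, fmt: str | None = None) -> list[Compound]:
    """Read compounds from .smi (``SMILES<ws>id``), SDF, or CSV (smiles,id[,targets]).

    Unparseable records are skipped with a logged warning. Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` when no record
    parses at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    compounds: list[Compound] = []
    n_skipped = 0

    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                log.warning("%s:%d: missing id field, record skipped", path.name, lineno)
                n_skipped += 1
                continue
            smiles, cid = parts[0], parts[1]
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                log.warning("%s:%d: unparseable SMILES %r, record skipped", path.name, lineno, smiles)
                n_skipped += 1
                continue
            compounds.append(Compound(cid, mol))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("%s: record %d unparseable, skipped", path.name, i)
                n_skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            compounds.append(Compound(name, mol))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                smiles = (row.get("smiles") or "").strip()
                cid = (row.get("id") or "").strip()
                targets = {t for t in (row.get("targets") or "").split(";") if t}
                mol = Chem.MolFromSmiles(smiles) if smiles else None
                if not cid or mol is None:
                    log.warning("%s: bad row %r, record skipped", path.name, row)
                    n_skipped += 1
                    continue
                compounds.append(Compound(cid, mol, targets))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if n_skipped:
        log.warning("%s: %d record(s) skipped", path.name, n_skipped)
    if not compounds:
        raise ValueError(f"{path}: no parseable records")
    seen: set[str] = set()
    for c in compounds:
        if c.id in seen:
            raise ValueError(f"{path}: duplicate compound id {c.id!r}")
        seen.add(c.id)
    return compounds


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a compound_id,target_id CSV into an id -> target-set mapping."""
    path = Path(path)
    table: dict[str, set[str]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            cid = row["compound_id"].strip()
            tid = row["target_id"].strip()
            if cid and tid:
                table.setdefault(cid, set()).add(tid)
    return table


def apply_annotations(compounds: Sequence[Compound], table: dict[str, set[str]]) -> None:
    for c in compounds:
        if c.id in table:
            c.targets |= table[c.id]


def write_smi(compounds: Iterable[Compound | LibraryProduct], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles} {c.id}\n")


# ---------------------------------------------------------------------------
# Murcko scaffolds
# ---------------------------------------------------------------------------

def murcko_scaffold(compound: Compound | Chem.Mol) -> str:
    """Canonical SMILES of the Murcko framework (ring systems plus linkers).

    Atom and bond types are retained; acyclic molecules map to the empty
    scaffold key ``""`` and are pooled as one scaffold class downstream.
    """
    mol = compound.mol if isinstance(compound, Compound) else compound
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(core)


def scaffold_table(compounds: Sequence[Compound]) -> dict[str, str]:
    return {c.id: murcko_scaffold(c) for c in compounds}


# ---------------------------------------------------------------------------
# Monoisotopic [M+H]+
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mh(formula: str) -> float:
    """Monoisotopic [M+H]+ m/z for a molecular formula, rounded to 4 decimals.

    Sums most-abundant-isotope masses and adds one proton (1.007276 Da),
    matching the convention of HRMS-ESI calculated values.
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"invalid molecular formula {formula!r}")
    pt = Chem.GetPeriodicTable()
    mass = 0.0
    for symbol, count in _FORMULA_TOKEN.findall(formula):
        if not symbol:
            continue
        try:
            atomic_number = pt.GetAtomicNumber(symbol)
        except Exception:
            atomic_number = 0
        if atomic_number == 0:
            raise ValueError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        mass += pt.GetMostCommonIsotopeMass(symbol) * (int(count) if count else 1)
    return round(mass + PROTON_MASS, 4)


def mol_formula(mol: Chem.Mol) -> str:
    """Molecular formula (Hill order, charge suffix stripped)."""
    return rdMolDescriptors.CalcMolFormula(mol)


# ---------------------------------------------------------------------------
# Library enumeration
# ---------------------------------------------------------------------------

Assembler = Callable[[Chem.Mol, Chem.Mol, Chem.Mol], Chem.Mol | None]


class AttachmentAssembler:
    """Joins three fragments at mapped dummy atoms: A carries ``[*:1]``,
    B carries ``[*:1]`` and ``[*:2]``, C carries ``[*:2]``."""

    def __call__(self, a: Chem.Mol, b: Chem.Mol, c: Chem.Mol) -> Chem.Mol | None:
        try:
            ab = Chem.molzip(a, b)
            abc = Chem.molzip(ab, c)
            Chem.SanitizeMol(abc)
        except Exception:
            return None
        if abc is None or len(Chem.GetMolFrags(abc)) != 1:
            return None
        return abc


#: Groebke-Blackburn-Bienaymé-type three-component coupling:
#: 2-aminopyridine + aldehyde + isocyanide -> 3-aminoimidazo[1,2-a]pyridine.
GBB_REACTION_SMARTS = (
    "[NH2:7][c:6]1[n:5][c:4][c:3][c:2][c:1]1."
    "[#6:8][CX3H1:9]=[OX1]."
    "[#6:10][N+:11]#[C-:12]"
    ">>[C:1]1=[C:2][C:3]=[C:4][N:5]2[C:6]1=[NH0:7][CH0+0:9]([#6:8])=[CH0+0:12]2[NH1+0:11][#6:10]"
)


class ReactionAssembler:
    """Assembles product structures with an RDKit reaction transform.

    The default SMARTS encodes the Ugi-type (GBB) three-component coupling used
    for imidazo[1,2-a]pyridine libraries; alternative transforms can be supplied
    as SMARTS strings via configuration.
    """

    def __init__(self, smarts: str = GBB_REACTION_SMARTS):
        self.rxn = AllChem.ReactionFromSmarts(smarts)
        self.rxn.Initialize()

    def __call__(self, a: Chem.Mol, b: Chem.Mol, c: Chem.Mol) -> Chem.Mol | None:
        try:
            outcomes = self.rxn.RunReactants((a, b, c))
        except Exception:
            return None
        products = set()
        for outcome in outcomes:
            mol = outcome[0]
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                continue
            products.add(Chem.MolToSmiles(mol))
        if not products:
            return None
        # deterministic choice when the transform matches in several ways
        return Chem.MolFromSmiles(sorted(products)[0])


def enumerate_library(
    a: BuildingBlockSet,
    b: BuildingBlockSet,
    c: BuildingBlockSet,
    assembler: Assembler | None = None,
) -> list[LibraryProduct]:
    """Enumerate the full |a| x |b| x |c| virtual combinatorial library.

    Products are ordered lexicographically by parent-id triple and identified
    as ``"Aid_Bid_Cid"``. Triples the assembler cannot couple are skipped with
    a logged warning; the skip count is logged at the end.
    """
    for block in (a, b, c):
        if not block.members:
            raise ValueError(f"empty building-block set {block.role}")
    if len({a.role, b.role, c.role}) != 3:
        raise ValueError("building-block sets must have three distinct roles")
    assembler = assembler or AttachmentAssembler()

    products: list[LibraryProduct] = []
    n_skipped = 0
    for ca in sorted(a.members, key=lambda m: m.id):
        for cb in sorted(b.members, key=lambda m: m.id):
            for cc in sorted(c.members, key=lambda m: m.id):
                mol = assembler(ca.mol, cb.mol, cc.mol)
                if mol is None:
                    log.warning("assembler failed on triple (%s, %s, %s), product skipped",
                                ca.id, cb.id, cc.id)
                    n_skipped += 1
                    continue
                pid = f"{ca.id}_{cb.id}_{cc.id}"
                products.append(LibraryProduct(pid, (ca.id, cb.id, cc.id), mol))
    if n_skipped:
        log.warning("library enumeration: %d triple(s) skipped", n_skipped)
    return products
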