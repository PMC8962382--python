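"""Chemical-structure registry, parsing, mass and drug-likeness computation.

The compound registry ships the curated structures of the MPC inhibitor
series (the cyanoacrylic acids BE1976..BE2623, the reference inhibitor
UK-5099) together with their ester and des-cyano negative controls.
Everything downstream — feature perception, screening, potency reporting —
resolves structures through this module.
"""

from __future__ import annotations

import functools
import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

_PERIODIC_TABLE = Chem.GetPeriodicTable()

# Ro5 bounds: MW <= 500 Da, logP <= 5, H-bond donors <= 5, acceptors <= 10
RO5_MW_MAX = 500.0
RO5_LOGP_MAX = 5.0
RO5_HBD_MAX = 5
RO5_HBA_MAX = 10

_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class RegistryLookupError(KeyError):
    """Raised when a compound id is not present in the registry."""


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a molecule."""


@dataclass(frozen=True)
class Molecule:
    """A valence-checked chemical graph with a canonical SMILES.

    ``rdmol`` holds the sanitized RDKit molecule (hydrogens implicit);
    ``atoms`` and ``bonds`` expose the plain-data view of the graph.
    """

    id: str
    smiles: str
    rdmol: Chem.Mol = field(compare=False, repr=False)

    @property
    def atoms(self) -> list[tuple[str, int, bool]]:
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float]]:
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.rdmol)


@dataclass
class Conformer:
    """3D coordinates (Å) for every atom of ``molecule``'s graph."""

    molecule: Molecule
    coords: np.ndarray  # (n_atoms, 3), Å
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.molecule.rdmol.GetNumAtoms(), 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{self.molecule.rdmol.GetNumAtoms()} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        return Conformer(
            self.molecule,
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            self.energy,
        )


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    smiles: str
    role: str  # active | inactive_control | decoy
    printed_ic50_nM: float | None = None
    printed_mz: int | None = None
    provisional: bool = False


@dataclass(frozen=True)
class DescriptorProfile:
    molecular_weight: float
    logp: float
    hbd: int
    hba: int
    rule_of_five_violations: int


@functools.lru_cache(maxsize=1)
def load_registry() -> dict[str, CompoundRecord]:
    """Load the shipped compound registry (curated SMILES + printed assay data)."""
    path = importlib.resources.files("mpcscreen").joinpath("data/registry.csv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    records: dict[str, CompoundRecord] = {}
    for row in df.itertuples(index=False):
        records[row.id] = CompoundRecord(
            id=row.id,
            smiles=row.smiles,
            role=row.role,
            printed_ic50_nM=None if pd.isna(row.printed_ic50_nM) else float(row.printed_ic50_nM),
            printed_mz=None if pd.isna(row.printed_mz) else int(row.printed_mz),
            provisional=(not pd.isna(row.provisional)) and str(row.provisional) == "provisional",
        )
    return records


def registry_actives() -> list[CompoundRecord]:
    return [r for r in load_registry().values() if r.role == "active" and r.id != "UK-5099"]


def registry_ester_negatives() -> list[CompoundRecord]:
    return [r for r in load_registry().values() if r.id.startswith("3")]


def parse_structure(spec: str, mol_id: str | None = None) -> Molecule:
    """Parse a SMILES string, or resolve a registry id to its curated structure.

    Raises :class:`StructureParseError` on malformed SMILES (the message names
    the offending input) and :class:`RegistryLookupError` for unknown ids.
    """
    registry = load_registry()
    if spec in registry:
        rec = registry[spec]
        return parse_structure(rec.smiles, mol_id=rec.id)
    mol = Chem.MolFromSmiles(spec, sanitize=False)
    if mol is None:
        # registry-id-shaped strings (BE1976, UK-5099, DEC00001, 3a) that
        # failed to parse are lookup errors, not SMILES errors
        if re.fullmatch(r"[A-Z]{2,}-?\w+|\d[a-z]", spec):
            raise RegistryLookupError(f"unknown compound id {spec!r}")
        raise StructureParseError(f"malformed SMILES: could not parse token {spec!r}")
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        detail = "; ".join(p.Message() for p in problems)
        raise StructureParseError(f"invalid structure {spec!r}: {detail}")
    Chem.SanitizeMol(mol)
    canonical = Chem.MolToSmiles(mol)
    return Molecule(id=mol_id or canonical, smiles=canonical, rdmol=mol)


def nominal_mass(m: Molecule) -> int:
    """Integer nominal mass: sum of most-abundant-isotope masses over all atoms."""
    total = 0
    for atom in m.rdmol.GetAtoms():
        total += round(_PERIODIC_TABLE.GetMostCommonIsotopeMass(atom.GetSymbol()))
        total += atom.GetTotalNumHs()  # 1H
    return int(total)


def esi_mz(m: Molecule, mode: int = +1) -> int:
    """Nominal m/z of the (M+1)+ or (M-1)- electrospray ion."""
    if mode not in (+1, -1):
        raise ValueError("mode must be +1 or -1")
    return nominal_mass(m) + mode


def lipinski_profile(m: Molecule) -> DescriptorProfile:
    """Rule-of-Five descriptors on the neutral (protonated-acid) form.

    logP is the Crippen atomic-contribution estimate; HBD/HBA are the
    classical Lipinski counts (OH+NH donors; N+O acceptors).
    """
    mol = m.rdmol
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hbd = rdMolDescriptors.CalcNumLipinskiHBD(mol)
    hba = rdMolDescriptors.CalcNumLipinskiHBA(mol)
    violations = sum(
        [mw > RO5_MW_MAX, logp > RO5_LOGP_MAX, hbd > RO5_HBD_MAX, hba > RO5_HBA_MAX]
    )
    return DescriptorProfile(mw, logp, hbd, hba, violations)


def deprotonate_acids(m: Molecule) -> Molecule:
    """Return the carboxylate anion form (each COOH -> COO-), as screened.

    Screening uses the ionization state relevant at physiological pH; the
    negative-ionizable pharmacophore feature sits on the carboxylate.
    """
    mol = Chem.RWMol(m.rdmol)
    for match in mol.GetSubstructMatches(_CARBOXYLIC_ACID):
        o_idx = match[2]  # the hydroxyl oxygen in the SMARTS
        atom = mol.GetAtomWithIdx(o_idx)
        atom.SetFormalCharge(-1)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Molecule(id=m.id, smiles=Chem.MolToSmiles(out), rdmol=out)


def embed_conformers(m: Molecule, n: int, seed: int) -> list[Conformer]:
    """Distance-geometry embed up to ``n`` conformers, MMFF-minimized.

    Deterministic for a fixed seed. Raises :class:`EmbeddingError` if no
    conformer can be produced after a random-coordinate retry.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    molh = Chem.AddHs(Chem.Mol(m.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(ids) == 0:
        raise EmbeddingError(f"could not embed conformers for molecule {m.id!r}")
    energies: dict[int, float] = {}
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
        for cid, (converged, energy) in zip(ids, results):
            energies[cid] = float(energy)
    except Exception:  # UFF fallback for MMFF-unsupported chemistry
        for cid in ids:
            ff = AllChem.UFFGetMoleculeForceField(molh, confId=cid)
            ff.Minimize(maxIts=500)
            energies[cid] = float(ff.CalcEnergy())
    heavy = Chem.RemoveHs(molh)
    out = []
    for cid in ids:
        conf = heavy.GetConformer(cid)
        coords = np.array(conf.GetPositions(), dtype=float)
        out.append(Conformer(m, coords, energies.get(cid)))
    return out


# ---------------------------------------------------------------------------
# Structure file I/O


def write_smiles_file(records: Iterable[CompoundRecord], path: str) -> None:
    """One record per line: SMILES<TAB>ID."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_smiles_file(path: str) -> list[Molecule]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else None
            out.append(parse_structure(smiles, mol_id=mol_id))
    return out


def write_sdf(conformers: Sequence[Conformer], path: str) -> None:
    """Write conformers as a multi-record V2000 SDF."""
    writer = Chem.SDWriter(path)
    writer.SetKekulize(True)
    try:
        for c in conformers:
            mol = Chem.Mol(c.molecule.rdmol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(c.coords):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.RemoveAllConformers()
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", c.molecule.id)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str) -> list[Conformer]:
    out = []
    for mol in Chem.SDMolSupplier(path, removeHs=True):
        if mol is None:
            raise StructureParseError(f"unreadable SDF record in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
        molecule = Molecule(id=name, smiles=Chem.MolToSmiles(mol), rdmol=mol)
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        out.append(Conformer(molecule, coords))
    return out
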