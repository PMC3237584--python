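"""Molecular representations: atom counts, physicochemical descriptors,
circular fingerprints (ECFP_4 / FCFP_4 folded to 1024 bits), and the public
166 structural keys.

Five descriptor sets are exposed under the names ``atom_counts``,
``pp_desc``, ``ecfp4``, ``fcfp4`` and ``mdl_keys``; every classifier in
:mod:`metspace.models` can be trained on any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .curation import MoleculeRecord

ATOM_COUNT_NAMES = (
    "H_Count",
    "C_Count",
    "N_Count",
    "O_Count",
    "F_Count",
    "P_Count",
    "S_Count",
    "Cl_Count",
)

PP_DESC_NAMES = ATOM_COUNT_NAMES + (
    "Molecular_Weight",
    "Num_Atoms",
    "ALogP",
    "LogD",
    "Num_H_Donors",
    "Num_H_Acceptors",
    "Num_RotatableBonds",
    "Num_Rings",
    "Num_AromaticRings",
    "Molecular_Solubility",
    "Molecular_PolarSurfaceArea",
    "Minimized_Energy",
)

DESCRIPTOR_KINDS = ("atom_counts", "pp_desc", "ecfp4", "fcfp4", "mdl_keys")
BINARY_KINDS = frozenset({"ecfp4", "fcfp4", "mdl_keys"})


@dataclass
class DescriptorVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


@dataclass
class SparseFingerprint:
    """Unhashed circular-fingerprint features (identifier -> multiplicity)."""

    features: dict[int, int]
    radius: int
    variant: str  # "atom_type" | "functional_class"

    @property
    def feature_ids(self) -> set[int]:
        return set(self.features)


@dataclass
class BitFingerprint:
    bits: np.ndarray
    scheme: str  # "ecfp4_folded" | "fcfp4_folded" | "structural_keys"
    mol_id: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)

    @property
    def length(self) -> int:
        return int(self.bits.size)

    def popcount(self) -> int:
        return int(self.bits.sum())


def atom_counts(record: MoleculeRecord) -> DescriptorVector:
    """H, C, N, O, F, P, S, Cl counts (hydrogens include implicit H)."""
    mol = record.mol()
    counts = dict.fromkeys(ATOM_COUNT_NAMES, 0)
    for atom in mol.GetAtoms():
        counts["H_Count"] += atom.GetTotalNumHs()
        key = f"{atom.GetSymbol()}_Count"
        if key in counts:
            counts[key] += 1
    return DescriptorVector(ATOM_COUNT_NAMES, np.array([counts[n] for n in ATOM_COUNT_NAMES]))


# pH 7.4 ionization penalties for the logD estimate: an acidic molecule is
# predominantly anionic, a basic aliphatic amine predominantly cationic.
_ACID_SMARTS = [
    Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),       # carboxylic acid
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1]"),   # sulfonic acid
    Chem.MolFromSmarts("[PX4](=O)([OX2H1])"),     # phosphoric acid/ester
]
_BASE_SMARTS = [
    Chem.MolFromSmarts("[NX3;H2,H1,H0;!$(NC=O);!$(N=*);!$(N[!#6;!#1]);!a]"),  # aliphatic amine
    Chem.MolFromSmarts("[NX3][CX3](=[NX2])"),     # amidine / guanidine
]


def _logd(mol: Chem.Mol, logp: float) -> float:
    if any(mol.HasSubstructMatch(q) for q in _ACID_SMARTS):
        return logp - 3.0
    if any(mol.HasSubstructMatch(q) for q in _BASE_SMARTS):
        return logp - 2.0
    return logp


def _esol_log_solubility(mol: Chem.Mol, logp: float, mw: float, rotb: int) -> float:
    """Delaney-style estimated aqueous log solubility (log mol/L)."""
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * ap


def _minimized_energy(mol: Chem.Mol, seed: int = 20211214) -> float:
    """MMFF94 energy of one embedded, minimized conformer (kcal/mol)."""
    m = Chem.AddHs(Chem.Mol(mol))
    if AllChem.EmbedMolecule(m, randomSeed=seed) != 0:
        return 0.0
    AllChem.MMFFOptimizeMolecule(m)
    props = AllChem.MMFFGetMoleculeProperties(m)
    if props is None:
        return 0.0
    ff = AllChem.MMFFGetMoleculeForceField(m, props)
    return float(ff.CalcEnergy()) if ff is not None else 0.0


def physchem(record: MoleculeRecord, compute_energy: bool = False) -> DescriptorVector:
    """The 20-entry PP_desc vector: atom counts + physicochemical properties.

    ``Minimized_Energy`` defaults to the sentinel 0.0 (conformer generation
    is expensive and the estimate noisy); pass ``compute_energy=True`` for
    an MMFF94 single-conformer value.
    """
    mol = record.mol()
    ac = atom_counts(record)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rotb = int(Descriptors.NumRotatableBonds(mol))
    values = list(ac.values) + [
        mw,
        mol.GetNumHeavyAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        logp,
        _logd(mol, logp),
        int(Lipinski.NumHDonors(mol)),
        int(Lipinski.NumHAcceptors(mol)),
        rotb,
        int(rdMolDescriptors.CalcNumRings(mol)),
        int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        _esol_log_solubility(mol, logp, mw, rotb),
        Descriptors.TPSA(mol),
        _minimized_energy(mol) if compute_energy else 0.0,
    ]
    return DescriptorVector(PP_DESC_NAMES, np.array(values, dtype=float))


def _morgan_generator(radius: int, variant: str):
    if variant == "functional_class":
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, atomInvariantsGenerator=inv
        )
    if variant != "atom_type":
        raise ValueError(f"unknown variant {variant!r}")
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius)


def circular_fingerprint(
    record: MoleculeRecord, diameter: int = 4, variant: str = "atom_type"
) -> SparseFingerprint:
    """Sparse extended-connectivity fingerprint of the given diameter.

    Iterative neighborhood identifiers for rounds 0..diameter/2; equivalent
    environments are deduplicated.  ``variant="functional_class"`` seeds
    the iteration from pharmacophoric atom classes (donor, acceptor,
    ionizable, aromatic, halogen) instead of element-based atom types.
    """
    if diameter < 0 or diameter % 2 != 0:
        raise ValueError("diameter must be even and >= 0")
    mol = record.mol()
    gen = _morgan_generator(diameter // 2, variant)
    sfp = gen.GetSparseCountFingerprint(mol)
    return SparseFingerprint(
        features=dict(sfp.GetNonzeroElements()), radius=diameter // 2, variant=variant
    )


def feature_environments(
    record: MoleculeRecord, diameter: int = 4, variant: str = "atom_type"
) -> dict[int, str]:
    """Map sparse-fingerprint feature ids to a SMILES of one generating environment."""
    if diameter < 0 or diameter % 2 != 0:
        raise ValueError("diameter must be even and >= 0")
    mol = record.mol()
    gen = _morgan_generator(diameter // 2, variant)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    envs: dict[int, str] = {}
    for fid, hits in ao.GetBitInfoMap().items():
        atom, radius = hits[0]
        if radius == 0:
            envs[fid] = mol.GetAtomWithIdx(atom).GetSymbol()
            continue
        bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
        atoms = {atom}
        for b in bond_ids:
            bond = mol.GetBondWithIdx(b)
            atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        envs[fid] = Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids), canonical=True
        )
    return envs


def fold(fp: SparseFingerprint, nbits: int = 1024) -> BitFingerprint:
    """Fold sparse features to a fixed-length bit vector (feature mod nbits, OR on collision)."""
    if nbits < 1:
        raise ValueError("nbits must be >= 1")
    bits = np.zeros(nbits, dtype=np.uint8)
    for feat in fp.features:
        bits[feat % nbits] = 1
    scheme = "ecfp4_folded" if fp.variant == "atom_type" else "fcfp4_folded"
    return BitFingerprint(bits=bits, scheme=scheme)


def structural_keys(record: MoleculeRecord) -> BitFingerprint:
    """166-bit public structural-key fingerprint (presence/absence of predefined substructures)."""
    mol = record.mol()
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, index 0 unused
    bits = np.array([fp.GetBit(i) for i in range(1, 167)], dtype=np.uint8)
    return BitFingerprint(bits=bits, scheme="structural_keys", mol_id=record.id)


def fingerprint(record: MoleculeRecord, kind: str, nbits: int = 1024) -> BitFingerprint:
    """Folded circular fingerprint or structural keys by descriptor-set name."""
    if kind == "ecfp4":
        bf = fold(circular_fingerprint(record, 4, "atom_type"), nbits)
    elif kind == "fcfp4":
        bf = fold(circular_fingerprint(record, 4, "functional_class"), nbits)
    elif kind == "mdl_keys":
        bf = structural_keys(record)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    bf.mol_id = record.id
    return bf


def descriptor_matrix(records, kind: str, compute_energy: bool = False) -> pd.DataFrame:
    """Descriptor matrix (one row per molecule id) for any of the five sets."""
    ids = [r.id for r in records]
    if kind == "atom_counts":
        rows = [atom_counts(r).values for r in records]
        return pd.DataFrame(rows, index=ids, columns=list(ATOM_COUNT_NAMES))
    if kind == "pp_desc":
        rows = [physchem(r, compute_energy=compute_energy).values for r in records]
        return pd.DataFrame(rows, index=ids, columns=list(PP_DESC_NAMES))
    if kind in BINARY_KINDS:
        rows = [fingerprint(r, kind).bits for r in records]
        ncol = len(rows[0]) if rows else (166 if kind == "mdl_keys" else 1024)
        cols = [f"bit_{i}" for i in range(ncol)]
        return pd.DataFrame(np.asarray(rows, dtype=np.uint8), index=ids, columns=cols)
    raise ValueError(f"unknown descriptor kind {kind!r}")
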