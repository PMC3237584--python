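"""Fragment enumeration and frequency analysis.

Five fragment kinds are enumerated per molecule:

* ``ring`` — each smallest ring;
* ``ring_assembly`` — each maximal fused ring system (rings sharing an
  atom, which covers both fused and spiro junctions, belong to one
  assembly);
* ``bridge_assembly`` — a pair of ring assemblies together with the
  shortest acyclic linker joining them;
* ``chain`` — each maximal connected acyclic fragment left after deleting
  all ring atoms;
* ``murcko`` — the scaffold: all ring systems plus connecting linkers,
  side chains pruned.

Frequency tables contrast two compound sets by per-molecule presence
(multiplicity within a molecule does not count), the standard way of
asking "what fraction of metabolites contain this fragment?".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import MoleculeRecord

FRAGMENT_KINDS = ("ring", "ring_assembly", "bridge_assembly", "chain", "murcko")


@dataclass
class FragmentRecord:
    kind: str
    structure: str
    heavy_atoms: int
    freq_a: float | None = None
    freq_b: float | None = None


def _induced_smiles(source: Chem.Mol, atoms: set[int]) -> str | None:
    bonds = [
        b.GetIdx()
        for b in source.GetBonds()
        if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
    ]
    try:
        smi = Chem.MolFragmentToSmiles(
            source, atomsToUse=sorted(atoms), bondsToUse=bonds, canonical=False
        )
    except Exception:
        return None
    frag = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(frag) if frag is not None else None


def _fragment_smiles(mol: Chem.Mol, atoms: set[int]) -> str | None:
    """Canonical SMILES of an induced subgraph; None if it cannot stand alone.

    Aromatic perception is tried first so that e.g. each ring of a fused
    aromatic comes out as benzene; fragments that cannot stand alone
    aromatically (partial ring systems) fall back to a kekulized copy.
    """
    if not atoms:
        return None
    smi = _induced_smiles(mol, atoms)
    if smi is not None:
        return smi
    km = Chem.Mol(mol)
    try:
        Chem.Kekulize(km, clearAromaticFlags=True)
    except Chem.KekulizeException:
        return None
    return _induced_smiles(km, atoms)


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Maximal fused ring systems as atom-index sets."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        keep = []
        for sys_ in systems:
            if merged & sys_:
                merged = merged | sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    return systems


def _bridge_assemblies(mol: Chem.Mol, systems: list[set[int]]) -> list[set[int]]:
    out: list[set[int]] = []
    for i in range(len(systems)):
        for j in range(i + 1, len(systems)):
            a_sys, b_sys = systems[i], systems[j]
            others = set().union(*(s for k, s in enumerate(systems) if k not in (i, j)))
            best: tuple[int, ...] | None = None
            for a in sorted(a_sys):
                for b in sorted(b_sys):
                    path = Chem.GetShortestPath(mol, a, b)
                    if not path:
                        continue
                    inner = set(path[1:-1])
                    if inner & (a_sys | b_sys | others):
                        continue  # not a simple bridge between exactly these two
                    if best is None or len(path) < len(best):
                        best = path
            if best is not None:
                out.append(a_sys | b_sys | set(best))
    return out


def _chains(mol: Chem.Mol) -> list[set[int]]:
    """Connected components of non-ring heavy atoms."""
    non_ring = {a.GetIdx() for a in mol.GetAtoms() if not a.IsInRing()}
    seen: set[int] = set()
    comps: list[set[int]] = []
    for start in sorted(non_ring):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                idx = nb.GetIdx()
                if idx in non_ring and idx not in comp:
                    comp.add(idx)
                    stack.append(idx)
        seen |= comp
        comps.append(comp)
    return comps


def generate_fragments(
    record: MoleculeRecord, kinds: Iterable[str] = FRAGMENT_KINDS
) -> list[FragmentRecord]:
    """Enumerate the requested fragment kinds; duplicates within the molecule collapse."""
    kinds = set(kinds)
    unknown = kinds - set(FRAGMENT_KINDS)
    if unknown:
        raise ValueError(f"unknown fragment kinds: {sorted(unknown)}")
    mol = record.mol()
    systems = _ring_systems(mol)
    found: dict[tuple[str, str], int] = {}

    def add(kind: str, atoms: set[int] | None = None, smiles: str | None = None) -> None:
        smi = smiles if smiles is not None else _fragment_smiles(mol, atoms)
        if smi is None:
            return
        frag = Chem.MolFromSmiles(smi)
        if frag is None or frag.GetNumHeavyAtoms() == 0:
            return
        found[(kind, smi)] = frag.GetNumHeavyAtoms()

    if "ring" in kinds:
        for ring in mol.GetRingInfo().AtomRings():
            add("ring", set(ring))
    if "ring_assembly" in kinds:
        for sys_ in systems:
            add("ring_assembly", sys_)
    if "bridge_assembly" in kinds:
        for atoms in _bridge_assemblies(mol, systems):
            add("bridge_assembly", atoms)
    if "chain" in kinds:
        for comp in _chains(mol):
            add("chain", comp)
    if "murcko" in kinds:
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        if scaffold is not None and scaffold.GetNumHeavyAtoms() > 0:
            add("murcko", smiles=Chem.MolToSmiles(scaffold))

    return [FragmentRecord(kind=k, structure=s, heavy_atoms=h) for (k, s), h in sorted(found.items())]


def fragment_frequency(
    set_a: Sequence[MoleculeRecord],
    set_b: Sequence[MoleculeRecord],
    kinds: Iterable[str] = FRAGMENT_KINDS,
    min_heavy: int = 4,
    top_k: int = 20,
) -> list[FragmentRecord]:
    """Top-k fragments of set A with presence frequencies in both sets.

    Frequency is the fraction of molecules containing the fragment at
    least once; fragments with fewer than ``min_heavy`` heavy atoms are
    excluded; ranking is by frequency in set A (descending), ties by
    canonical SMILES.
    """
    if not set_a or not set_b:
        raise ValueError("both compound sets must be non-empty")

    def presence(records) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], int]]:
        counts: dict[tuple[str, str], int] = {}
        heavies: dict[tuple[str, str], int] = {}
        for rec in records:
            for frag in generate_fragments(rec, kinds):
                key = (frag.kind, frag.structure)
                counts[key] = counts.get(key, 0) + 1
                heavies[key] = frag.heavy_atoms
        return counts, heavies

    counts_a, heavies_a = presence(set_a)
    counts_b, heavies_b = presence(set_b)
    heavies = {**heavies_b, **heavies_a}
    keys = [k for k in set(counts_a) | set(counts_b) if heavies[k] >= min_heavy]
    records = [
        FragmentRecord(
            kind=k[0],
            structure=k[1],
            heavy_atoms=heavies[k],
            freq_a=counts_a.get(k, 0) / len(set_a),
            freq_b=counts_b.get(k, 0) / len(set_b),
        )
        for k in keys
    ]
    records.sort(key=lambda r: (-r.freq_a, r.structure, r.kind))
    return records[:top_k]
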