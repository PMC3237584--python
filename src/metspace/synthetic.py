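"""Synthetic fixtures: labeled Bernoulli bit-fingerprints with a known
class-conditional structure, the analytic Bayes-optimal AUC for that
generator, and a deterministic toy pair of molecule collections.

The fingerprint generator draws each bit independently per class, which is
exactly the Naive Bayes assumption: the exact log-likelihood-ratio score
is then the Bayes-optimal classifier and its AUC — computable in closed
form by convolving the per-bit LLR distributions — provides a sharp target
that trained classifiers must recover.  The toy molecule sets emulate the
chemistry contrast seen between endogenous metabolites and synthetic
screening compounds (hydroxyl/carboxyl/phosphate/sugar-rich versus
amine/azole/thioether-rich), so that fragment tables and tree splits on
the fixture are predictable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curation import METABOLITE, NON_METABOLITE, MoleculeRecord, wash


@dataclass
class SyntheticSpec:
    n_per_class: int
    n_bits: int
    p_metab: np.ndarray
    p_background: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.p_metab = np.asarray(self.p_metab, dtype=float)
        self.p_background = np.asarray(self.p_background, dtype=float)
        for p in (self.p_metab, self.p_background):
            if p.shape != (self.n_bits,):
                raise ValueError("probability vectors must have length n_bits")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")


def default_spec(seed: int = 0, n_per_class: int = 500) -> SyntheticSpec:
    """Study conditions for parameter recovery: 64 bits, 24 informative
    (p1 = 0.62 vs p0 = 0.38), the rest uninformative at 0.5."""
    n_bits = 64
    p1 = np.full(n_bits, 0.5)
    p0 = np.full(n_bits, 0.5)
    p1[:24] = 0.62
    p0[:24] = 0.38
    return SyntheticSpec(n_per_class=n_per_class, n_bits=n_bits, p_metab=p1, p_background=p0, seed=seed)


def null_spec(seed: int = 0, n_per_class: int = 500) -> SyntheticSpec:
    """No-signal control: identical per-bit probabilities in both classes."""
    p = np.full(64, 0.5)
    return SyntheticSpec(n_per_class=n_per_class, n_bits=64, p_metab=p, p_background=p, seed=seed)


def gen_bernoulli_fingerprints(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact class counts; bit j of a class-c fingerprint ~ Bernoulli(p_c[j]).

    Returns (X, y) with X of shape (2 * n_per_class, n_bits) uint8 and
    y in {0, 1} (1 = metabolite-like class); reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    X0 = (rng.random((n, spec.n_bits)) < spec.p_background).astype(np.uint8)
    X1 = (rng.random((n, spec.n_bits)) < spec.p_metab).astype(np.uint8)
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return X, y


def _llr_weights(p1: np.ndarray, p0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bit LLR contributions for bit=1 and bit=0 (inf-safe)."""
    with np.errstate(divide="ignore"):
        w1 = np.log(p1) - np.log(p0)
        w0 = np.log1p(-p1) - np.log1p(-p0)
    return w1, w0


def llr_scores(X: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Exact log-likelihood-ratio score of each fingerprint (Bayes-optimal)."""
    w1, w0 = _llr_weights(spec.p_metab, spec.p_background)
    X = np.asarray(X, dtype=float)
    terms = X * np.where(np.isfinite(w1), w1, 0.0) + (1 - X) * np.where(np.isfinite(w0), w0, 0.0)
    score = terms.sum(axis=1)
    # deterministic bits: +/- inf contributions dominate
    for j in np.flatnonzero(~np.isfinite(w1)):
        score = np.where(X[:, j] == 1, score + w1[j], score)
    for j in np.flatnonzero(~np.isfinite(w0)):
        score = np.where(X[:, j] == 0, score + w0[j], score)
    return score


def _auc_from_distributions(v1, p1, v0, p0) -> float:
    """AUC = P(S1 > S0) + 0.5 P(S1 = S0) for discrete score distributions."""
    v0 = np.asarray(v0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    order = np.argsort(v0)
    v0, p0 = v0[order], p0[order]
    cum = np.cumsum(p0)
    auc = 0.0
    for v, p in zip(v1, p1):
        lo = np.searchsorted(v0, v, side="left")
        hi = np.searchsorted(v0, v, side="right")
        p_less = cum[lo - 1] if lo > 0 else 0.0
        p_eq = (cum[hi - 1] if hi > 0 else 0.0) - p_less
        auc += p * (p_less + 0.5 * p_eq)
    return float(auc)


def analytic_bayes_auc(spec: SyntheticSpec, n_mc: int = 1_000_000) -> float:
    """AUC of the exact LLR score: exact convolution for n_bits <= 20,
    seeded large-sample Monte Carlo otherwise.  Ties count 1/2."""
    w1, w0 = _llr_weights(spec.p_metab, spec.p_background)
    if spec.n_bits <= 20:
        dists = []
        for pc in (spec.p_background, spec.p_metab):
            dist = {0.0: 1.0}
            for j in range(spec.n_bits):
                new: dict[float, float] = {}
                for v, pr in dist.items():
                    if pc[j] > 0:
                        key = round(v + w1[j], 10)
                        new[key] = new.get(key, 0.0) + pr * pc[j]
                    if pc[j] < 1:
                        key = round(v + w0[j], 10)
                        new[key] = new.get(key, 0.0) + pr * (1 - pc[j])
                dist = new
            dists.append(dist)
        d0, d1 = dists
        return _auc_from_distributions(
            list(d1.keys()), list(d1.values()), list(d0.keys()), list(d0.values())
        )
    rng = np.random.default_rng(spec.seed + 10_007)
    n = n_mc // 2
    S0 = llr_scores((rng.random((n, spec.n_bits)) < spec.p_background).astype(np.uint8), spec)
    S1 = llr_scores((rng.random((n, spec.n_bits)) < spec.p_metab).astype(np.uint8), spec)
    from .evaluation import roc_auc

    return roc_auc(np.r_[np.zeros(n, int), np.ones(n, int)], np.r_[S0, S1])["auc"]


# --- toy molecule fixture --------------------------------------------------

def _metabolite_like_smiles() -> list[str]:
    out: list[str] = []
    # hydroxy fatty acids and diacids (acyclic, hydroxyl + carboxyl rich)
    out += [f"OC(=O){'C' * n}O" for n in range(1, 13)]
    out += [f"OC(=O){'C' * n}C(=O)O" for n in range(0, 10)]
    # alpha-amino acids
    side = ["C", "CC", "CCC", "CO", "CCO", "CC(=O)O", "CCC(=O)O", "C(C)C", "CC(C)C", "CS"]
    out += [f"NC({r})C(=O)O" for r in side]
    # polyols
    out += ["OC" + "C(O)" * n + "CO" for n in range(1, 9)]
    # pyranoses and methyl/acyl variants
    anomeric = ["O", "OC", "OCC", "OC(=O)C"]
    out += [f"OCC1OC({a})C(O)C(O)C1O" for a in anomeric]
    out += [f"CC1OC({a})C(O)C(O)C1O" for a in anomeric]
    out += [f"OCC1OC({a})C(O)C(O)C1OC" for a in anomeric]
    # sugar phosphates (pyranose ring + phosphate)
    out += [
        "OP(=O)(O)OCC1OC(O)C(O)C(O)C1O",
        "OCC1OC(OP(=O)(O)O)C(O)C(O)C1O",
        "OP(=O)(O)OCC1OC(OC)C(O)C(O)C1O",
        "OP(=O)(O)OCC1OC(O)C(O)C(O)C1OC",
    ]
    # furanoses
    out += [f"OCC1OC({a})C(O)C1O" for a in anomeric]
    # nucleosides (furanose + base)
    out += [
        "Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O",
        "OCC1OC(n2ccc(=O)[nH]c2=O)C(O)C1O",
        "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1",
        "OCC1OC(n2cnc3c2nc[nH]c3=O)C(O)C1O",
    ]
    # inositols / hydroxylated carbocycles
    out += ["OC1C(O)C(O)C(O)C(O)C1O", "OC1CCC(O)CC1", "OC1CCCC(O)C1"]
    # keto acids
    out += [f"OC(=O)C(=O){'C' * n}" for n in range(1, 7)]
    # hydroxy branched acids
    out += [f"OC({'C' * n})CC(=O)O" for n in range(2, 9)]
    # glycerol and its esters
    out += ["OCC(O)CO"] + [f"OCC(O)COC(=O){'C' * n}" for n in range(1, 7)]
    # small polyacids
    out += ["OC(=O)CC(O)(CC(=O)O)C(=O)O", "OC(=O)CC(O)C(=O)O", "OC(=O)C(O)C(O)C(=O)O"]
    # sterol-like scaffolds
    out += ["CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", "CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2O"]
    return out


def _synthetic_like_smiles() -> list[str]:
    out: list[str] = []
    # dialkyl secondary amines
    out += [f"{'C' * a}N{'C' * b}" for a in range(1, 6) for b in range(a, 6)]
    # anilines and N-alkyl anilines
    out += [f"{'C' * n}Nc1ccccc1" for n in range(1, 6)]
    out += [f"CN(C{'C' * n})c1ccccc1" for n in range(0, 5)]
    out += [f"{'C' * n}NCc1ccccc1" for n in range(0, 5)]
    # pyridines
    out += [f"{'C' * n}c1ccncc1" for n in range(0, 5)]
    out += [f"{'C' * n}Nc1ccncc1" for n in range(1, 5)]
    # piperidines / piperazines
    out += [f"{'C' * n}N1CCCCC1" for n in range(1, 6)]
    out += [f"{'C' * n}N1CCN(C)CC1" for n in range(1, 6)]
    out += ["c1ccc(cc1)N1CCNCC1", "CN1CCN(CC1)c1ccccc1"]
    # thiophenes and thiazoles
    out += [f"{'C' * n}c1cccs1" for n in range(0, 5)]
    out += ["NCc1cccs1", "CNCc1cccs1", "Cc1nccs1", "CCc1nccs1", "Nc1nccs1", "CNc1nccs1"]
    # thioethers
    out += [f"{'C' * a}S{'C' * b}" for a in range(1, 5) for b in range(a, 5)]
    out += ["CSc1ccccc1", "CCSc1ccccc1"]
    # N-alkyl azoles
    out += [f"{'C' * n}n1ccnc1" for n in range(1, 5)]
    out += [f"{'C' * n}n1cccn1" for n in range(1, 5)]
    # fused N/S heterocycles
    out += [
        "c1ccc2[nH]cnc2c1",
        "Cc1nc2ccccc2[nH]1",
        "c1ccc2[nH]ccc2c1",
        "Cc1cc2ccccc2[nH]1",
        "c1ccc2ncccc2c1",
        "Cc1ccc2ncccc2c1",
        "c1ccc2nccnc2c1",
        "c1ccc2c(c1)ccs2",
    ]
    # halogenated anilines
    out += ["Nc1ccc(Cl)cc1", "CNc1ccc(Cl)cc1", "Nc1cccc(Cl)c1", "CCNc1ccc(F)cc1"]
    # branched amines
    out += ["CC(C)NCC(C)C", "CC(C)CNCC", "CCN(CC)CC", "CCCN(C)CCC"]
    return out


def _build_records(smiles: list[str], prefix: str, label: str, limit: int) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for smi in smiles:
        if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - fixture lists are valid
            continue
        rec = wash(MoleculeRecord(id="tmp", structure=smi, label=label))
        if rec.structure in seen:
            continue
        seen.add(rec.structure)
        rec.id = f"{prefix}{len(records) + 1:03d}"
        records.append(rec)
        if len(records) >= limit:
            break
    return records


def toy_molecule_fixture(limit: int = 100) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Two deterministic labeled collections (~100 molecules each).

    The metabolite-like set is hydroxyl/carboxyl/phosphate/sugar-rich; the
    synthetic-like set is built from nitrogen and sulfur heterocycles,
    amines and thioethers with essentially no oxygen, so oxygen-bearing
    features and fragments dominate the contrast by construction.
    """
    met = _build_records(_metabolite_like_smiles(), "MET", METABOLITE, limit)
    syn = _build_records(_synthetic_like_smiles(), "SYN", NON_METABOLITE, limit)
    return met, syn
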