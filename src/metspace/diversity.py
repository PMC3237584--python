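"""Tanimoto similarity, maximal-dissimilarity partitioning, and balanced
training/test assembly.

Diversity selection counters the over-representation of compound families
(lipids in metabolite collections, combinatorial series in vendor
libraries): the greedy maximal-dissimilarity partition picks cluster
centers that are mutually more dissimilar than a threshold (default 0.6 on
1 - Tanimoto over folded ECFP_4 bits) and the centers become the
class representatives used for model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import BitFingerprint


def tanimoto(a: BitFingerprint | np.ndarray, b: BitFingerprint | np.ndarray) -> float:
    """|a AND b| / |a OR b|; 1.0 when both fingerprints are all-zero."""
    va = a.bits if isinstance(a, BitFingerprint) else np.asarray(a, dtype=np.uint8)
    vb = b.bits if isinstance(b, BitFingerprint) else np.asarray(b, dtype=np.uint8)
    if va.size != vb.size:
        raise ValueError(f"fingerprint length mismatch: {va.size} vs {vb.size}")
    union = int(np.logical_or(va, vb).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(va, vb).sum()) / union


def _bulk_tanimoto(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    inter = (X & v).sum(axis=1)
    union = (X | v).sum(axis=1)
    out = np.ones(len(X), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


@dataclass
class DiversityPartition:
    """Centers (in selection order), member assignment, and the threshold guarantee."""

    centers: list[str]
    assignment: dict[str, str]
    threshold: float = 0.6

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, center: str) -> list[str]:
        return [m for m, c in self.assignment.items() if c == center]


def max_dissimilarity_partition(
    fps: Sequence[BitFingerprint],
    threshold: float = 0.6,
    sort_keys: Sequence[str] | None = None,
) -> DiversityPartition:
    """Greedy maximal-dissimilarity partitioning.

    The first center is the first molecule under ``sort_keys`` order
    (canonical-SMILES sort in the pipeline; input order when keys are
    omitted).  Centers are then added greedily — always the molecule whose
    minimum dissimilarity (1 - Tanimoto) to the current centers is largest —
    until that value drops to <= ``threshold``; finally every molecule is
    assigned to its nearest center, ties going to the earlier-selected
    center.  On output every member lies within ``threshold`` of its center
    and every center pair is more dissimilar than ``threshold``.
    """
    if not fps:
        raise ValueError("empty fingerprint list")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    ids = [fp.mol_id if fp.mol_id is not None else str(i) for i, fp in enumerate(fps)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids")
    order = (
        sorted(range(len(fps)), key=lambda i: (sort_keys[i], i))
        if sort_keys is not None
        else list(range(len(fps)))
    )
    X = np.asarray([fps[i].bits for i in order], dtype=np.uint8)
    n = len(X)

    centers_idx = [0]
    min_dissim = 1.0 - _bulk_tanimoto(X, X[0])
    while True:
        cand = int(np.argmax(min_dissim))  # ties -> earliest in sort order
        if min_dissim[cand] <= threshold:
            break
        centers_idx.append(cand)
        min_dissim = np.minimum(min_dissim, 1.0 - _bulk_tanimoto(X, X[cand]))

    # nearest-center assignment, ties to the earlier-selected center
    dis = np.stack([1.0 - _bulk_tanimoto(X, X[c]) for c in centers_idx])  # centers x n
    nearest = np.argmin(dis, axis=0)  # argmin keeps first (earlier-selected) on ties
    ordered_ids = [ids[order[i]] for i in range(n)]
    center_ids = [ordered_ids[c] for c in centers_idx]
    assignment = {ordered_ids[i]: center_ids[nearest[i]] for i in range(n)}
    return DiversityPartition(centers=center_ids, assignment=assignment, threshold=threshold)


@dataclass
class SplitSpec:
    """Balanced train/test membership by molecule id."""

    n_per_class: int
    seed: int
    train_metab: list[str] = field(default_factory=list)
    train_background: list[str] = field(default_factory=list)
    test_metab: list[str] = field(default_factory=list)
    test_background: list[str] = field(default_factory=list)

    @property
    def train_ids(self) -> list[str]:
        return self.train_metab + self.train_background

    @property
    def test_ids(self) -> list[str]:
        return self.test_metab + self.test_background


def assemble_training_sets(
    metab_reps: Sequence[str],
    background_pool: Sequence[str],
    n_per_class: int,
    seed: int,
    metab_rest: Sequence[str] = (),
) -> SplitSpec:
    """Balanced training set from diversity representatives + random background.

    Training = all metabolite representatives plus ``n_per_class`` seeded
    uniform draws (without replacement) from the background pool.  The test
    set is built from ``metab_rest`` (metabolites not selected as
    representatives) and the unused background molecules, balanced by
    seeded downsampling of the majority class.
    """
    if len(background_pool) < n_per_class:
        raise ValueError(
            f"background pool ({len(background_pool)}) smaller than n_per_class ({n_per_class})"
        )
    rng = np.random.default_rng(seed)
    pool = sorted(background_pool)
    picked = rng.choice(len(pool), size=n_per_class, replace=False)
    train_bg = [pool[i] for i in sorted(picked)]
    rest_bg = [m for m in pool if m not in set(train_bg)]

    test_metab = sorted(metab_rest)
    test_bg = rest_bg
    n_test = min(len(test_metab), len(test_bg))
    if len(test_metab) > n_test:
        keep = sorted(rng.choice(len(test_metab), size=n_test, replace=False))
        test_metab = [test_metab[i] for i in keep]
    if len(test_bg) > n_test:
        keep = sorted(rng.choice(len(test_bg), size=n_test, replace=False))
        test_bg = [test_bg[i] for i in keep]

    return SplitSpec(
        n_per_class=n_per_class,
        seed=seed,
        train_metab=list(metab_reps),
        train_background=train_bg,
        test_metab=test_metab,
        test_background=test_bg,
    )
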