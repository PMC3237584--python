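import numpy as np
import pytest

from metspace.curation import MoleculeRecord, wash


@pytest.fixture
def washed():
    """Wash a SMILES string into a MoleculeRecord."""

    def _make(smiles: str, mol_id: str = "m") -> MoleculeRecord:
        return wash(MoleculeRecord(id=mol_id, structure=smiles))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20111214)


def brute_force_auc(truth, scores) -> float:
    """Exhaustive pair-counting AUC oracle: P(score_pos > score_neg) + ties/2."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
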