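import itertools

import numpy as np
import pytest

from metspace.curation import load_molecules, write_smiles
from metspace.synthetic import (
    SyntheticSpec,
    analytic_bayes_auc,
    default_spec,
    gen_bernoulli_fingerprints,
    llr_scores,
    null_spec,
    toy_molecule_fixture,
)


def bayes_auc_enumeration_oracle(spec):
    """Brute force over all 2^n_bits outcomes per class."""
    outcomes = list(itertools.product((0, 1), repeat=spec.n_bits))

    def prob(x, p):
        pr = 1.0
        for b, pj in zip(x, p):
            pr *= pj if b else (1 - pj)
        return pr

    def score(x):
        s = 0.0
        for b, p1, p0 in zip(x, spec.p_metab, spec.p_background):
            s += np.log(p1 / p0) if b else np.log((1 - p1) / (1 - p0))
        return round(s, 10)

    d1 = [(score(x), prob(x, spec.p_metab)) for x in outcomes]
    d0 = [(score(x), prob(x, spec.p_background)) for x in outcomes]
    auc = 0.0
    for s1, p1 in d1:
        for s0, p0 in d0:
            if s1 > s0:
                auc += p1 * p0
            elif s1 == s0:
                auc += 0.5 * p1 * p0
    return auc


class TestGenerator:
    def test_exact_class_counts(self):
        spec = default_spec(seed=3, n_per_class=100)
        X, y = gen_bernoulli_fingerprints(spec)
        assert X.shape == (200, 64)
        assert (y == 1).sum() == 100 and (y == 0).sum() == 100

    def test_same_seed_byte_identical(self):
        a = gen_bernoulli_fingerprints(default_spec(seed=9))
        b = gen_bernoulli_fingerprints(default_spec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empirical_frequencies_within_binomial_band(self):
        spec = default_spec(seed=4, n_per_class=2000)
        X, y = gen_bernoulli_fingerprints(spec)
        for c, p in ((0, spec.p_background), (1, spec.p_metab)):
            freq = X[y == c].mean(axis=0)
            sigma = np.sqrt(p * (1 - p) / 2000)
            assert (np.abs(freq - p) <= 3.5 * sigma + 1e-12).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(10, 2, [0.5, 1.2], [0.5, 0.5], 0)


class TestAnalyticBayesAuc:
    def test_no_signal_gives_half(self):
        spec = SyntheticSpec(10, 4, [0.3, 0.5, 0.7, 0.2], [0.3, 0.5, 0.7, 0.2], 0)
        assert analytic_bayes_auc(spec) == pytest.approx(0.5)

    def test_deterministic_bit_gives_one(self):
        spec = SyntheticSpec(10, 1, [1.0], [0.0], 0)
        assert analytic_bayes_auc(spec) == pytest.approx(1.0)

    def test_three_bit_matches_exhaustive_enumeration(self):
        spec = SyntheticSpec(10, 3, [0.8, 0.8, 0.5], [0.2, 0.2, 0.5], 0)
        assert analytic_bayes_auc(spec) == pytest.approx(bayes_auc_enumeration_oracle(spec), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_small_specs_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(0.1, 0.9, 5)
        p0 = rng.uniform(0.1, 0.9, 5)
        spec = SyntheticSpec(10, 5, p1, p0, seed)
        assert analytic_bayes_auc(spec) == pytest.approx(bayes_auc_enumeration_oracle(spec), abs=1e-10)

    def test_monte_carlo_close_to_exact_for_20_bits(self):
        p1 = np.full(20, 0.6)
        p0 = np.full(20, 0.4)
        exact = analytic_bayes_auc(SyntheticSpec(10, 20, p1, p0, 0))
        mc_spec = SyntheticSpec(10, 21, np.r_[p1, 0.5], np.r_[p0, 0.5], 0)
        mc = analytic_bayes_auc(mc_spec, n_mc=400_000)  # extra bit uninformative
        assert mc == pytest.approx(exact, abs=0.01)

    def test_llr_scores_monotone_in_informative_bits(self):
        spec = default_spec(0)
        lo = np.zeros((1, 64))
        hi = np.zeros((1, 64))
        hi[0, :24] = 1
        assert llr_scores(hi, spec)[0] > llr_scores(lo, spec)[0]


class TestToyFixture:
    def test_deterministic_and_parseable(self, tmp_path):
        met1, syn1 = toy_molecule_fixture()
        met2, syn2 = toy_molecule_fixture()
        assert [r.structure for r in met1] == [r.structure for r in met2]
        assert [r.structure for r in syn1] == [r.structure for r in syn2]
        assert len(met1) >= 85 and len(syn1) >= 85
        f = tmp_path / "met.smi"
        write_smiles(met1, f)
        assert len(load_molecules(f, "smiles")) == len(met1)

    def test_oxygen_contrast_by_construction(self):
        met, syn = toy_molecule_fixture()
        met_with_o = sum(1 for r in met if "O" in r.structure)
        syn_with_o = sum(1 for r in syn if "O" in r.structure)
        assert met_with_o == len(met)
        assert syn_with_o == 0

    def test_cit_root_splits_on_oxygen_feature(self):
        from metspace import chemspace, descriptors

        met, syn = toy_molecule_fixture()
        records = met + syn
        y = np.r_[np.ones(len(met), int), np.zeros(len(syn), int)]
        feats = {}
        envs = {}
        for i, rec in enumerate(records):
            sp = descriptors.circular_fingerprint(rec, 4)
            envs.update(descriptors.feature_environments(rec, 4))
            for f in sp.feature_ids:
                feats.setdefault(f, set()).add(i)
        common = sorted(f for f, idx in feats.items() if len(idx) >= 5)
        X = np.array([[1 if i in feats[f] else 0 for f in common] for i in range(len(records))])
        tree = chemspace.conditional_inference_tree(X, y, alpha=0.05, min_node=20)
        root_env = envs[common[tree.root.feature]]
        assert "O" in root_env.upper()

    def test_metabolite_fragment_table_ranks_oxygen_fragment_first(self):
        from metspace.fragments import fragment_frequency

        met, syn = toy_molecule_fixture()
        table = fragment_frequency(met, syn, min_heavy=4, top_k=5)
        assert "O" in table[0].structure.upper()


def test_null_spec_trained_auc_near_half():
    from metspace import models as M
    from metspace.evaluation import roc_auc

    spec = null_spec(seed=2, n_per_class=250)
    X, y = gen_bernoulli_fingerprints(spec)
    test = SyntheticSpec(250, spec.n_bits, spec.p_metab, spec.p_background, seed=1002)
    Xte, yte = gen_bernoulli_fingerprints(test)
    model = M.train(X, y, M.ModelSpec("nb", "ecfp4"), seed=0)
    auc = roc_auc(yte, M.metabolite_likeness(model, Xte))["auc"]
    assert auc == pytest.approx(0.5, abs=0.05)
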