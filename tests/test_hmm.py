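"""HMM correctness against exhaustive path enumeration, EM behavior,
and parameter recovery on planted profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from astropair.hmm import (
    GaussianChainHMM,
    decode_labels,
    fit_hmm,
    pair_logratio,
    posterior_decode,
)
from astropair.params import HMMParams
from astropair.synthetic_data import CohortSpec, build_gene_map, simulate_pair_profiles

from conftest import small_spec


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_loglik(x: np.ndarray, p: HMMParams) -> float:
    """Sum over all 3^T hidden paths of the joint density."""
    total = 0.0
    K = p.n_states
    for path in itertools.product(range(K), repeat=len(x)):
        prob = p.startprob[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            prob *= p.transmat[a, b]
        for t, s in enumerate(path):
            prob *= norm.pdf(x[t], p.means[s], np.sqrt(p.variances[s]))
        total += prob
    return float(np.log(total))


def brute_force_posteriors(x: np.ndarray, p: HMMParams) -> np.ndarray:
    """Per-position marginal state posteriors by path enumeration."""
    K, T = p.n_states, len(x)
    marg = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        prob = p.startprob[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            prob *= p.transmat[a, b]
        for t, s in enumerate(path):
            prob *= norm.pdf(x[t], p.means[s], np.sqrt(p.variances[s]))
        for t, s in enumerate(path):
            marg[t, s] += prob
    return marg / marg.sum(axis=1, keepdims=True)


def random_params(rng) -> HMMParams:
    A = rng.uniform(0.2, 1.0, size=(3, 3))
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.2, 1.0, size=3)
    pi /= pi.sum()
    mu = np.sort(rng.normal(0, 2, size=3))
    mu += np.arange(3) * 0.1  # guarantee strict ordering
    return HMMParams(
        startprob=pi, transmat=A, means=mu,
        variances=rng.uniform(0.3, 2.0, size=3),
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestLikelihood:
    def test_length_one_closed_form(self, rng):
        p = random_params(rng)
        x = np.array([0.7])
        expected = np.log(
            np.sum(p.startprob * norm.pdf(x[0], p.means, np.sqrt(p.variances)))
        )
        got = GaussianChainHMM().score([x], params=p)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_forward_matches_path_enumeration(self, rng):
        model = GaussianChainHMM()
        for _ in range(100):
            p = random_params(rng)
            T = int(rng.integers(1, 7))
            x = rng.normal(0, 2, size=T)
            assert model.score([x], params=p) == pytest.approx(
                brute_force_loglik(x, p), abs=1e-8
            )

    def test_posteriors_match_path_enumeration(self, rng):
        model = GaussianChainHMM()
        for _ in range(100):
            p = random_params(rng)
            T = int(rng.integers(1, 7))
            x = rng.normal(0, 2, size=T)
            gamma = model.predict_proba([x], params=p)
            assert np.allclose(gamma, brute_force_posteriors(x, p), atol=1e-8)
            assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_translation_invariance(self, rng):
        p = random_params(rng)
        x = rng.normal(0, 2, size=50)
        model = GaussianChainHMM()
        base = model.score([x], params=p)
        shifted = HMMParams(
            startprob=p.startprob, transmat=p.transmat,
            means=p.means + 5.0, variances=p.variances,
        )
        assert model.score([x + 5.0], params=shifted) == pytest.approx(
            base, abs=1e-8
        )

    def test_cross_check_against_hmmlearn(self, rng):
        from hmmlearn.hmm import GaussianHMM

        p = random_params(rng)
        x = rng.normal(0, 2, size=200)
        ref = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = p.startprob
        ref.transmat_ = p.transmat
        ref.means_ = p.means[:, None]
        ref.covars_ = p.variances[:, None]
        assert GaussianChainHMM().score([x], params=p) == pytest.approx(
            ref.score(x[:, None]), abs=1e-6
        )


class TestDecoding:
    def test_iid_chain_equals_bayes_classifier(self, rng):
        # transition rows equal to pi -> per-gene Bayes rule in closed form
        pi = np.array([0.2, 0.5, 0.3])
        p = HMMParams(
            startprob=pi, transmat=np.tile(pi, (3, 1)),
            means=np.array([-2.0, 0.0, 2.0]), variances=np.array([1.0, 0.5, 2.0]),
        )
        x = rng.normal(0, 2, size=300)
        gamma = GaussianChainHMM().predict_proba([x], params=p)
        dens = pi[None, :] * norm.pdf(
            x[:, None], p.means[None, :], np.sqrt(p.variances)[None, :]
        )
        bayes = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(gamma, bayes, atol=1e-10)

    def test_tie_breaks_toward_unchanged(self):
        gamma = np.array([[0.4, 0.4, 0.2], [0.3, 0.3, 0.4], [0.2, 0.5, 0.3]])
        assert decode_labels(gamma).tolist() == [0, 1, 0]

    def test_decoding_invariant_to_chromosome_order(self, rng):
        # permuting whole chromosome blocks (keeping within-chromosome gene
        # order) must not change any gene's decoded state
        p = random_params(rng)
        profiles = pd.DataFrame(
            {"P": rng.normal(0, 2, size=60)},
            index=[f"g{i}" for i in range(60)],
        )
        chrom = np.repeat(["chr1", "chr2", "chr3"], 20)
        _, fwd = posterior_decode(profiles, chrom, p)
        perm = np.concatenate([np.arange(40, 60), np.arange(0, 20),
                               np.arange(20, 40)])
        _, rev = posterior_decode(profiles.iloc[perm], chrom[perm], p)
        assert fwd["P"].loc[profiles.index].tolist() == \
            rev["P"].loc[profiles.index].tolist()


class TestEM:
    def test_loglik_trace_non_decreasing(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            seqs = [r.normal(0, 3, size=100) for _ in range(5)]
            model = GaussianChainHMM(means_init=(-2, 0, 2), max_iter=50)
            model.fit(seqs)
            assert np.all(np.diff(model.loglik_trace_) >= -1e-8)

    def test_init_at_truth_is_near_fixed_point(self):
        spec = small_spec(seed=3)
        profiles, _ = simulate_pair_profiles(spec)
        gm = build_gene_map(spec)
        truth = spec.hmm_truth
        model = GaussianChainHMM(max_iter=1)
        seqs = [profiles[c].to_numpy() for c in profiles.columns]
        model.fit(seqs, init=truth)
        assert np.allclose(model.params_.means, truth.means, atol=0.1)
        assert np.allclose(
            np.diag(model.params_.transmat), np.diag(truth.transmat), atol=0.05
        )

    def test_variance_floor_clamp_warns(self):
        x = np.concatenate([np.full(30, -3.0), np.full(30, 0.0), np.full(30, 3.0)])
        model = GaussianChainHMM(max_iter=30)
        with pytest.warns(UserWarning, match="variance collapsed"):
            model.fit([x])
        assert np.all(model.params_.variances >= 1e-4)

    def test_parameter_recovery_small(self):
        # scaled-down recovery run; the full-size run lives in the
        # acceptance suite
        spec = small_spec(n_patients=10, n_genes=1500, seed=2,
                          progression_groups={"A2->A3": 4, "A2->G4": 3,
                                              "A3->G4": 3})
        profiles, truth = simulate_pair_profiles(spec)
        gm = build_gene_map(spec)
        chrom = gm["chrom"].to_numpy()
        params, trace = fit_hmm(profiles, chrom)
        assert np.allclose(params.means, [-3, 0, 3], atol=0.15)
        assert np.allclose(np.diag(params.transmat), 0.9, atol=0.03)
        _, labels = posterior_decode(profiles, chrom, params)
        acc = (labels.to_numpy() == truth.hmm_states.to_numpy()).mean()
        assert acc >= 0.95


class TestPairLogratio:
    def test_basic_difference_and_antisymmetry(self):
        logexpr = pd.DataFrame(
            {"t0": [1.0, 2.0, 3.0], "t1": [3.0, 2.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        pairs = pd.DataFrame(
            {"patient": ["P1"], "initial": ["t0"], "recurrent": ["t1"]}
        )
        prof = pair_logratio(logexpr, pairs)
        assert prof["P1"].tolist() == [2.0, 0.0, -2.0]
        swapped = pairs.rename(columns={"initial": "recurrent",
                                        "recurrent": "initial"})
        assert (pair_logratio(logexpr, swapped)["P1"] == -prof["P1"]).all()

    def test_identical_tumors_zero_profile(self):
        logexpr = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        pairs = pd.DataFrame(
            {"patient": ["P"], "initial": ["a"], "recurrent": ["b"]}
        )
        assert (pair_logratio(logexpr, pairs)["P"] == 0).all()

    def test_missing_member_names_patient(self):
        logexpr = pd.DataFrame({"a": [1.0, 2.0]})
        pairs = pd.DataFrame(
            {"patient": ["P9"], "initial": ["a"], "recurrent": ["zz"]}
        )
        with pytest.raises(KeyError, match="P9"):
            pair_logratio(logexpr, pairs)
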