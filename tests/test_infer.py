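"""Per-codon Bayesian model selection: closed forms and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonlens.codes import AA_ALPHABET, standard_code
from codonlens.infer import (
    InferenceConfig,
    codon_log_likelihoods,
    codon_posterior,
    infer_code,
)
from codonlens.observe import CodonObservation, ObservationSet


def _point_mass(aa: str) -> np.ndarray:
    e = np.zeros(20)
    e[AA_ALPHABET.index(aa)] = 1.0
    return e


def _obs(emission, codon_idx=0):
    return CodonObservation(codon_idx=codon_idx, emission=np.asarray(emission))


def _uniform_config(threshold=0.9999):
    return InferenceConfig(threshold=threshold, background=np.full(20, 0.05))


class TestLogLikelihoods:
    def test_point_mass_closed_form(self):
        ll = codon_log_likelihoods([_obs(_point_mass("K"))], np.full(20, 0.05))
        k = AA_ALPHABET.index("K")
        assert ll[k] == pytest.approx(0.0, abs=1e-12)
        assert ll[20] == pytest.approx(np.log(0.05), abs=1e-12)
        # every other amino-acid model is impossible
        others = np.delete(ll[:20], k)
        assert np.all(np.isinf(others)) and np.all(others < 0)

    def test_uniform_observations_symmetric(self):
        obs = [_obs(np.full(20, 1 / 20)) for _ in range(7)]
        ll = codon_log_likelihoods(obs, np.full(20, 0.05))
        assert np.allclose(ll, 7 * np.log(1 / 20), atol=1e-9)

    def test_empty_set_is_empty_product(self):
        ll = codon_log_likelihoods([], np.full(20, 0.05))
        assert np.allclose(ll, 0.0)


class TestPosteriorClosedForms:
    def test_single_point_mass_posterior(self):
        """One point-mass observation on K: posterior(M_K) = 1/(1+f(K))."""
        cfg = _uniform_config()
        ll = codon_log_likelihoods([_obs(_point_mass("K"))], cfg.background)
        cp = codon_posterior(ll, cfg)
        k = AA_ALPHABET.index("K")
        assert cp.posteriors[k] == pytest.approx(1 / 1.05, abs=1e-9)
        assert cp.decision == "?"  # 0.952 < 0.9999

    def test_uniform_observations_give_uniform_posterior(self):
        cfg = _uniform_config()
        ll = codon_log_likelihoods(
            [_obs(np.full(20, 1 / 20)) for _ in range(5)], cfg.background
        )
        cp = codon_posterior(ll, cfg)
        assert np.allclose(cp.posteriors, 1 / 21, atol=1e-9)
        assert cp.decision == "?"

    def test_empty_set_returns_prior(self):
        prior = np.ones(21)
        prior[3] = 5.0
        prior /= prior.sum()
        cfg = InferenceConfig(prior=prior, background=np.full(20, 0.05))
        cp = codon_posterior(codon_log_likelihoods([], cfg.background), cfg)
        assert np.allclose(cp.posteriors, prior, atol=1e-9)
        assert cp.decision == "?"

    def test_n_point_masses_decide_at_four(self):
        """posterior(M_K) = 1/(1 + f^N) with f = 0.05 crosses 0.9999 at
        N = 4, the smallest N with 0.05^N < 1.0001e-4."""
        cfg = _uniform_config()
        for n, expected in [(3, "?"), (4, "K")]:
            ll = codon_log_likelihoods(
                [_obs(_point_mass("K"))] * n, cfg.background
            )
            cp = codon_posterior(ll, cfg)
            k = AA_ALPHABET.index("K")
            assert cp.posteriors[k] == pytest.approx(
                1 / (1 + 0.05 ** n), abs=1e-9
            )
            assert cp.decision == expected


class TestDecisionRules:
    def test_nonspecific_model_never_decided(self):
        """Even when the non-specific model has overwhelming posterior,
        the decision must be '?', not a label."""
        cfg = _uniform_config(threshold=0.6)
        ll = np.zeros(21)
        ll[20] = 50.0
        cp = codon_posterior(ll, cfg)
        assert cp.top_model == "ns"
        assert cp.decision == "?"

    def test_threshold_monotonicity(self):
        """Raising the threshold never converts '?' into a letter."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            ll = np.concatenate([rng.normal(0, 5, 20), [rng.normal(0, 5)]])
            decided_low = codon_posterior(
                ll, _uniform_config(threshold=0.7)
            ).decision
            decided_high = codon_posterior(
                ll, _uniform_config(threshold=0.9999)
            ).decision
            if decided_high != "?":
                assert decided_low == decided_high

    def test_posteriors_normalised(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ll = rng.normal(0, 10, 21)
            cp = codon_posterior(ll, _uniform_config())
            assert abs(float(cp.posteriors.sum()) - 1.0) < 1e-9

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        emissions = rng.dirichlet(np.ones(20), size=6)
        cfg = _uniform_config()
        obs = [_obs(e) for e in emissions]
        perm = [obs[i] for i in rng.permutation(6)]
        a = codon_posterior(
            codon_log_likelihoods(obs, cfg.background), cfg
        ).posteriors
        b = codon_posterior(
            codon_log_likelihoods(perm, cfg.background), cfg
        ).posteriors
        assert np.allclose(a, b, atol=1e-9)

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 8))
    @settings(max_examples=60, deadline=None)
    def test_consistent_evidence_monotonicity(self, seed, n):
        """Appending another observation whose argmax is amino acid a
        never decreases posterior(M_a) when all previous observations
        also have argmax a."""
        rng = np.random.default_rng(seed)
        a = int(rng.integers(0, 20))
        emissions = []
        for _ in range(n + 1):
            e = rng.dirichlet(np.ones(20) * 0.5)
            j = int(np.argmax(e))
            e[a], e[j] = e[j], e[a]
            emissions.append(e)
        cfg = _uniform_config()
        obs = [_obs(e) for e in emissions]
        before = codon_posterior(
            codon_log_likelihoods(obs[:-1], cfg.background), cfg
        ).posteriors[a]
        after = codon_posterior(
            codon_log_likelihoods(obs, cfg.background), cfg
        ).posteriors[a]
        assert after >= before - 1e-12


class TestInferCode:
    def test_all_empty_gives_64_question_marks(self):
        code, posteriors = infer_code(ObservationSet(), _uniform_config())
        assert code.table == "?" * 64
        assert all(cp.decision == "?" for cp in posteriors)

    def test_never_emits_stop(self):
        """No observation set can produce '*': sense-to-stop reassignment
        is undetectable by construction."""
        rng = np.random.default_rng(11)
        obs_set = ObservationSet()
        for idx in range(64):
            for _ in range(rng.integers(0, 12)):
                e = rng.dirichlet(np.ones(20) * 0.3)
                obs_set.add(_obs(e, codon_idx=idx))
        code, _ = infer_code(obs_set, _uniform_config(threshold=0.51))
        assert "*" not in code.table

    def test_strong_evidence_decides_codons(self):
        obs_set = ObservationSet()
        k = AA_ALPHABET.index("K")
        for _ in range(10):
            e = np.full(20, 1e-9)
            e[k] = 1.0
            obs_set.add(_obs(e / e.sum(), codon_idx=0))
        code, posteriors = infer_code(obs_set, _uniform_config())
        assert code.table[0] == "K"
        assert posteriors[0].n_observations == 10
        assert code.table[1:] == "?" * 63


class TestEndToEndRecovery(object):
    def test_small_fixture_recovers_encoded_meanings(self, small_run):
        """Codons with enough aligned-column evidence must recover their
        true meaning; no codon may get a wrong letter."""
        bundle, _, code, posteriors = small_run
        truth = bundle.truth
        truth_counts = bundle.observation_truth_counts()
        for i in range(64):
            if code.table[i] != "?":
                assert code.table[i] == truth.table[i]
            if truth_counts[i] >= 30 and truth.table[i] != "*":
                assert code.table[i] == truth.table[i]

    def test_stop_codons_uninferred(self, small_run):
        _, _, code, _ = small_run
        sc = standard_code()
        for i, m in enumerate(sc.table):
            if m == "*":
                assert code.table[i] == "?"
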