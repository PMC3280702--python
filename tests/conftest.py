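"""Shared fixtures: small models, a naive spectral oracle, the seeded corpus."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seizureqd as sq
from seizureqd.hmm_glm import GlmParams, HmmGlmModel, Quantizer

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def three_symbol_quantizer() -> Quantizer:
    """Identity quantizer over the 3-letter alphabet {0, 1, 2}."""
    return Quantizer(np.array([0.0, 1.0, 2.0, 3.0]))


@pytest.fixture
def simple_model() -> HmmGlmModel:
    """Small L=1 model over a 3-symbol alphabet with a non-degenerate start."""
    return HmmGlmModel(
        rho=0.15, quantizer=three_symbol_quantizer(),
        theta0=GlmParams(alpha=0.0, betas=np.array([0.12])),
        theta1=GlmParams(alpha=math.log(2.2), betas=np.array([-0.05])),
        M=10, p0=0.85)


@pytest.fixture
def history_free_model() -> HmmGlmModel:
    """History-free (L=0) model: nonictal rate 1, ictal rate 2.5."""
    return HmmGlmModel(
        rho=0.1, quantizer=three_symbol_quantizer(),
        theta0=GlmParams(alpha=0.0, betas=np.array([])),
        theta1=GlmParams(alpha=math.log(2.5), betas=np.array([])),
        M=10, p0=0.9)


def poisson_model(lam0: float, lam1: float, rho: float = 0.1,
                  n_codes: int = 11, p0: float = 1.0) -> HmmGlmModel:
    """History-free model with given state rates over codes 0..n_codes-1."""
    edges = np.arange(n_codes + 1, dtype=float)
    return HmmGlmModel(
        rho=rho, quantizer=Quantizer(edges),
        theta0=GlmParams(alpha=math.log(lam0), betas=np.array([])),
        theta1=GlmParams(alpha=math.log(lam1), betas=np.array([])),
        M=10, p0=p0)


# ---------------------------------------------------------------------------
# Independent spectral oracle (hand-rolled Welch cross-spectra)
# ---------------------------------------------------------------------------

def naive_band_crosspower(window: np.ndarray, rate: float,
                          lb: float, ub: float) -> np.ndarray:
    """Brute-force re-implementation of the band-integrated cross-power.

    Manual Hann-windowed 1-s segments with 50% overlap, explicit DFT
    cross-periodograms averaged over segments, one-sided density scaling,
    trapezoidal band integration, magnitude.  Shares no code with the
    package's scipy-based implementation.
    """
    window = np.asarray(window, dtype=float)
    nseg = int(round(rate))
    step = nseg // 2
    taper = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(nseg) / nseg)
    scale = 1.0 / (rate * np.sum(taper**2))
    n_ch, n_samp = window.shape
    starts = range(0, n_samp - nseg + 1, step)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / rate)
    acc = np.zeros((n_ch, n_ch, len(freqs)), dtype=complex)
    for s in starts:
        seg = window[:, s:s + nseg]
        seg = (seg - seg.mean(axis=1, keepdims=True)) * taper
        spec = np.fft.rfft(seg, axis=1)
        acc += spec[:, None, :] * np.conj(spec[None, :, :])
    csd = acc * scale / len(list(starts))
    csd[..., 1:] *= 2.0
    if nseg % 2 == 0:
        csd[..., -1] /= 2.0
    mask = (freqs >= lb) & (freqs <= ub)
    integral = np.trapezoid(csd[..., mask], freqs[mask], axis=-1)
    return np.abs(integral)


# ---------------------------------------------------------------------------
# Independent stopping-problem oracle (extensive-form enumeration)
# ---------------------------------------------------------------------------

class StoppingOracle:
    """Forward enumeration over the observation tree of a finite-horizon
    stopping problem with discrete history-free emissions.

    Computes the optimal expected cost by recursing over observation
    sequences and exact posteriors — no belief-space representation, no
    thresholds — so it is an independent check of the backward-induction
    policy synthesis.
    """

    def __init__(self, q0, q1, rho, cost):
        self.q0, self.q1 = np.asarray(q0, float), np.asarray(q1, float)
        self.rho, self.cost = rho, cost

    def stop_cost(self, pi):
        return (1 - self.cost.gamma) / self.rho * (1 - pi)

    def delay_weight(self, k):
        if k < 1:
            return 0.0
        d = sq.expected_delay_given_past(k, self.rho)
        return d ** self.cost.delay_exponent

    def step(self, pi, symbol):
        reach = self.rho + (1 - self.rho) * pi
        mass = self.q1[symbol] * reach + self.q0[symbol] * (1 - pi) * (1 - self.rho)
        return (self.q1[symbol] * reach / mass if mass > 0 else 0.0), mass

    def continue_cost(self, k, pi):
        out = self.cost.gamma * self.delay_weight(k) * pi
        for n in range(len(self.q0)):
            pi_next, mass = self.step(pi, n)
            if mass > 0:
                out += mass * self.value(k + 1, pi_next)
        return out

    def value(self, k, pi):
        if k == self.cost.horizon_M:
            return self.stop_cost(pi)
        cont = self.continue_cost(k, pi)
        return min(self.stop_cost(pi), cont) if k >= 1 else cont

    def stop_stage(self, pi0, sequence):
        """First stage where stopping is strictly optimal along a sequence
        of observations feeding stages 1, 2, ...; None if never."""
        pi = pi0
        for k, symbol in enumerate(sequence, start=1):
            pi, _ = self.step(pi, symbol)
            if self.stop_cost(pi) < self.continue_cost(k, pi):
                return k
        return None


# ---------------------------------------------------------------------------
# Seeded benchmark corpus (built once per session)
# ---------------------------------------------------------------------------

class CorpusBundle:
    """Corpus plus the model fitted on its training runs."""

    def __init__(self) -> None:
        self.corpus = sq.make_benchmark_corpus(seed=0)
        segments = [(r.counts.astype(float), r.states)
                    for r in self.corpus.train_runs]
        self.model = sq.fit_hmm_glm(segments, n_bins=50,
                                    candidate_Ls=[0, 1, 2, 3, 5, 8, 15],
                                    M=self.corpus.run_length_s)
        self.training_codes = np.concatenate(
            [self.model.quantizer(r.counts.astype(float))
             for r in self.corpus.train_runs])
        self.obs_runs = [r.counts.astype(float) for r in self.corpus.test_runs]
        self.onset_runs = [list(self.corpus.run_onsets(r))
                           for r in self.corpus.test_runs]
        self.training_nonictal = np.concatenate(
            [r.counts[r.states == 0].astype(float)
             for r in self.corpus.train_runs])

    def default_cost(self, gamma: float = 0.3) -> sq.CostSpec:
        return sq.CostSpec(gamma=gamma, horizon_M=self.model.M,
                           rho=self.model.rho)


@pytest.fixture(scope="session")
def corpus_bundle() -> CorpusBundle:
    return CorpusBundle()
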