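"""Two-state HMM with history-dependent Poisson-GLM emissions.

The detection statistic ``z_k = sigma1(k)`` is quantized to integer counts
``n_k`` and modeled, separately in the nonictal (x=0) and ictal (x=1) states,
as Poisson with log-rate

    log lambda_{x,k} = alpha_x + sum_{j=1..L} beta_{x,j} n_{k-j}.

The hidden state follows a Markov chain with transition matrix
``[[1-rho, rho], [0, 1]]`` (ictal absorbing within a run) and initial
distribution ``P = [p0, 1-p0]`` (monitoring starts nonictal, ``p0 = 1``).

Parameter vectors ``Theta_x = (alpha_x, beta_x)`` are maximum-likelihood
estimates (iteratively reweighted least squares via statsmodels) with
covariances for 95% confidence bounds; the lag order ``L`` is selected by
minimizing AIC over candidate models, and ``rho`` has a closed-form MLE from
labeled training sequences.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .connectivity import BandSpec, connectivity_series, svd_statistic
from .errors import DataError, FitError
from .synthetic import MultichannelRecord

DEFAULT_N_BINS = 50
DEFAULT_LAG = 15
GLM_MAX_ITER = 200
RIDGE_FALLBACK = 1e-6


# ---------------------------------------------------------------------------
# Quantizer
# ---------------------------------------------------------------------------

@dataclass
class Quantizer:
    """Monotone uniform-width quantizer mapping reals to codes 0..n_bins-1."""

    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def __call__(self, z) -> np.ndarray | int:
        """Quantize; out-of-range values clip to the end bins."""
        code = np.searchsorted(self.bin_edges, z, side="right") - 1
        code = np.clip(code, 0, self.n_bins - 1)
        return int(code) if np.isscalar(z) else code


def build_quantizer(training_values: Sequence[float],
                    n_bins: int = DEFAULT_N_BINS) -> Quantizer:
    """Uniform-width bins spanning the training range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(training_values, dtype=float)
    if not np.isfinite(values).all():
        raise DataError("training values must be finite")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DataError("degenerate training range: all values identical")
    return Quantizer(np.linspace(lo, hi, n_bins + 1))


# ---------------------------------------------------------------------------
# GLM parameters and model container
# ---------------------------------------------------------------------------

@dataclass
class GlmParams:
    """One state's emission parameters: baseline log-rate and history weights."""

    alpha: float
    betas: np.ndarray
    cov: np.ndarray | None = None   # (L+1) x (L+1), order (alpha, betas)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if not np.isfinite(self.alpha) or not np.isfinite(self.betas).all():
            raise ValueError("GLM parameters must be finite")

    @property
    def L(self) -> int:
        return len(self.betas)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.betas])

    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% confidence bounds on (alpha, betas)."""
        if self.cov is None:
            raise FitError("no covariance available for confidence bounds")
        se = np.sqrt(np.diag(self.cov))
        return self.vector - 1.96 * se, self.vector + 1.96 * se

    def log_rate(self, history: Sequence[int]) -> float:
        """``alpha + sum_j beta_j n_{k-j}``; ``history[-1]`` is ``n_{k-1}``."""
        if len(history) < self.L:
            raise ValueError(f"history of length {len(history)} < L={self.L}")
        out = self.alpha
        for j in range(self.L):
            out += self.betas[j] * history[-1 - j]
        return out


@dataclass
class HmmGlmModel:
    """The full {P, Sigma, q} triple of the two-state detection model."""

    rho: float
    quantizer: Quantizer
    theta0: GlmParams
    theta1: GlmParams
    M: int = 7200
    p0: float = 1.0                     # P = [p0, 1-p0]
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.theta0.L != self.theta1.L:
            raise ValueError("theta0 and theta1 must share the lag order L")
        if self.M < 1:
            raise ValueError("horizon M must be >= 1")

    @property
    def L(self) -> int:
        return self.theta0.L

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array([[1.0 - self.rho, self.rho], [0.0, 1.0]])

    def theta(self, state: int) -> GlmParams:
        return self.theta1 if state else self.theta0

    def history_pad(self) -> int:
        """Initialization code for stages k < L: nearest integer to the
        nonictal stationary mean ``exp(alpha_0)``."""
        return int(round(math.exp(self.theta0.alpha)))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def params(t: GlmParams) -> dict:
            return {"alpha": t.alpha, "betas": t.betas.tolist(),
                    "cov": None if t.cov is None else t.cov.tolist()}
        doc = {
            "rho": self.rho, "P0": [self.p0, 1.0 - self.p0],
            "bin_edges": self.quantizer.bin_edges.tolist(),
            "L": self.L, "theta0": params(self.theta0),
            "theta1": params(self.theta1), "M": self.M,
            "band": (None if self.band is None
                     else {"name": self.band.name, "lb": self.band.lb,
                           "ub": self.band.ub}),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HmmGlmModel":
        doc = json.loads(text)

        def params(d: dict) -> GlmParams:
            cov = None if d["cov"] is None else np.asarray(d["cov"])
            return GlmParams(d["alpha"], np.asarray(d["betas"]), cov)

        band = doc.get("band")
        return cls(
            rho=doc["rho"], quantizer=Quantizer(np.asarray(doc["bin_edges"])),
            theta0=params(doc["theta0"]), theta1=params(doc["theta1"]),
            M=doc["M"], p0=doc["P0"][0],
            band=None if band is None else BandSpec(**band),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _lag_design(counts: np.ndarray, L: int,
                start: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Response y = counts[start:] and design [1, n_{k-1}, ..., n_{k-L}]."""
    counts = np.asarray(counts, dtype=float)
    if start is None:
        start = L
    n = len(counts)
    y = counts[start:]
    x = np.ones((n - start, L + 1))
    for j in range(1, L + 1):
        x[:, j] = counts[start - j:n - j]
    return y, x


def _fit_poisson(y: np.ndarray, x: np.ndarray) -> GlmParams:
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    model = sm.GLM(y, x, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=GLM_MAX_ITER)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular design in Poisson GLM fit: {exc}") from exc
    if not res.converged:
        raise FitError(
            f"Poisson GLM did not converge within {GLM_MAX_ITER} IRLS "
            f"iterations (last deviance {res.deviance:.4g})")
    params = np.asarray(res.params)
    if not np.isfinite(params).all():
        warnings.warn("degenerate ML fit; refitting with a small ridge "
                      f"penalty ({RIDGE_FALLBACK})", stacklevel=2)
        res = model.fit_regularized(alpha=RIDGE_FALLBACK, L1_wt=0.0)
        params = np.asarray(res.params)
        return GlmParams(params[0], params[1:], cov=None)
    return GlmParams(params[0], params[1:],
                     cov=np.asarray(res.cov_params()))


def fit_glm(counts: Sequence[int], L: int) -> GlmParams:
    """ML fit of the Poisson history GLM on one count sequence.

    The first ``L`` counts serve only as history for later stages.
    """
    counts = np.asarray(counts)
    n_params = L + 1
    if len(counts) <= L + n_params:
        raise ValueError(
            f"sequence of length {len(counts)} too short for L={L} "
            f"({n_params} parameters)")
    y, x = _lag_design(counts, L)
    return _fit_poisson(y, x)


def _poisson_loglik(y: np.ndarray, x: np.ndarray, theta: GlmParams) -> float:
    eta = x @ theta.vector
    lam = np.exp(eta)
    from scipy.special import gammaln
    return float(np.sum(y * eta - lam - gammaln(y + 1.0)))


def select_lag_by_aic(counts: Sequence[int],
                      candidate_Ls: Sequence[int]) -> int:
    """Smallest-AIC lag order, fitted on a common effective sample.

    All candidates are fitted to the stages ``k >= max(candidates)`` so their
    log-likelihoods are comparable; ``AIC = 2(L+1) - 2 loglik``.  Ties break
    toward smaller ``L``.
    """
    if len(candidate_Ls) == 0:
        raise ValueError("candidate lag list is empty")
    counts = np.asarray(counts)
    cands = sorted(set(int(c) for c in candidate_Ls))
    if any(c < 0 for c in cands):
        raise ValueError("lags must be nonnegative")
    l_max = max(cands)
    if len(counts) <= l_max + max(cands) + 1:
        raise ValueError("sequence too short for the largest candidate lag")
    best_l, best_aic = None, np.inf
    for L in cands:
        y, x = _lag_design(counts, L, start=l_max)
        theta = _fit_poisson(y, x)
        aic = 2.0 * (L + 1) - 2.0 * _poisson_loglik(y, x, theta)
        if aic < best_aic - 1e-12:
            best_l, best_aic = L, aic
    return best_l


def estimate_rho(state_labels: Sequence[Sequence[int]]) -> float:
    """Closed-form MLE of the 0 -> 1 transition probability.

    ``rho_hat`` = (# observed 0->1 transitions) / (# stages spent in state 0
    that have a successor), pooled over sequences.  Emits a warning when no
    transition was observed.
    """
    transitions = 0
    exposure = 0
    for seq in state_labels:
        seq = np.asarray(seq, dtype=int)
        if len(seq) == 0:
            continue
        if seq[0] != 0:
            raise ValueError("each training sequence must start in state 0")
        at_zero = seq[:-1] == 0
        exposure += int(at_zero.sum())
        transitions += int(np.sum(at_zero & (seq[1:] == 1)))
    if exposure == 0:
        raise FitError("no stages observed in state 0; rho is not estimable")
    if transitions == 0:
        warnings.warn("no 0->1 transition observed; rho estimated as 0",
                      stacklevel=2)
    return transitions / exposure


# ---------------------------------------------------------------------------
# Emission probabilities
# ---------------------------------------------------------------------------

def emission_log_prob(model: HmmGlmModel, state: int, z: float,
                      history: Sequence[int]) -> float:
    """Log of ``q_x(z | H_k)``: Poisson log-pmf at ``Q(z)``."""
    code = model.quantizer(float(z))
    log_lam = model.theta(state).log_rate(history)
    return code * log_lam - math.exp(log_lam) - math.lgamma(code + 1.0)


def emission_probability(model: HmmGlmModel, state: int, z: float,
                         history: Sequence[int]) -> float:
    """``q_x(z | H_k) = Pr(n_k = Q(z) | H_k, x)`` under the fitted GLM."""
    return math.exp(emission_log_prob(model, state, z, history))


# ---------------------------------------------------------------------------
# Training protocol
# ---------------------------------------------------------------------------

def _masked_state_fit(counts: np.ndarray, states: np.ndarray,
                      state: int, L: int) -> GlmParams:
    """Fit Theta_x using lagged history from the *full* series.

    Target stages are those with ``x_k == state`` and ``k >= L``, so ictal
    epochs shorter than ``L`` borrow their history from the preceding
    (continuous) signal rather than being padded.
    """
    y, x = _lag_design(counts, L)
    mask = states[L:] == state
    if mask.sum() <= L + 1:
        raise FitError(
            f"only {int(mask.sum())} stages in state {state}; cannot fit "
            f"{L + 1} parameters")
    return _fit_poisson(y[mask], x[mask])


def fit_hmm_glm(segments: Sequence[tuple[Sequence[float], Sequence[int]]],
                n_bins: int = DEFAULT_N_BINS,
                candidate_Ls: Sequence[int] | None = None,
                L: int = DEFAULT_LAG,
                M: int = 7200,
                band: BandSpec | None = None) -> HmmGlmModel:
    """Fit the full detection model from labeled training segments.

    Parameters
    ----------
    segments
        ``(values, states)`` pairs: the raw statistic (e.g. ``sigma1``) and
        its 0/1 state labels, one pair per continuous training stretch.
    n_bins
        Quantizer resolution (uniform bins on the pooled training range).
    candidate_Ls
        When given, the lag order is selected by AIC on the pooled nonictal
        data; otherwise ``L`` is used as-is.
    M
        Detection horizon in stages (average inter-event interval).
    """
    all_values = np.concatenate([np.asarray(v, float) for v, _ in segments])
    quantizer = build_quantizer(all_values, n_bins=n_bins)

    coded = [(quantizer(np.asarray(v, float)), np.asarray(s, int))
             for v, s in segments]

    if candidate_Ls is not None:
        pooled_nonictal = np.concatenate(
            [c[s == 0] for c, s in coded])
        L = select_lag_by_aic(pooled_nonictal, candidate_Ls)

    def pooled_fit(state: int) -> GlmParams:
        ys, xs = [], []
        for c, s in coded:
            y, x = _lag_design(c, L)
            mask = s[L:] == state
            ys.append(y[mask])
            xs.append(x[mask])
        y = np.concatenate(ys)
        x = np.vstack(xs)
        if len(y) <= L + 1:
            raise FitError(f"insufficient training data in state {state}")
        return _fit_poisson(y, x)

    theta0 = pooled_fit(0)
    theta1 = pooled_fit(1)
    rho = estimate_rho([s for _, s in coded])
    return HmmGlmModel(rho=rho, quantizer=quantizer, theta0=theta0,
                       theta1=theta1, M=M, band=band)


# ---------------------------------------------------------------------------
# Patient-specific band selection
# ---------------------------------------------------------------------------

def glm_parameter_distance(theta0: GlmParams, theta1: GlmParams) -> float:
    """Standardized Euclidean distance between the two states' parameters.

    Each coordinate of ``Theta_0 - Theta_1`` is scaled by the pooled standard
    error ``sqrt(se0^2 + se1^2)`` so that well-resolved differences dominate.
    Falls back to the raw Euclidean distance when covariances are missing.
    """
    diff = theta0.vector - theta1.vector
    if theta0.cov is not None and theta1.cov is not None:
        scale = np.sqrt(np.diag(theta0.cov) + np.diag(theta1.cov))
        scale = np.where(scale > 0, scale, 1.0)
        diff = diff / scale
    return float(np.linalg.norm(diff))


def select_band(training_record: MultichannelRecord,
                bands: Sequence[BandSpec],
                n_bins: int = DEFAULT_N_BINS,
                L: int = 3,
                min_nonictal_s: float = 3 * 3600.0) -> BandSpec:
    """Choose the band maximizing the ictal/nonictal GLM parameter distance.

    For each candidate band the ``sigma1`` series is computed, quantized, and
    ``Theta_0`` / ``Theta_1`` are fitted on the annotated states; the band with
    the largest :func:`glm_parameter_distance` wins.  ``L`` defaults to a
    short lag so the ictal fit stays well-conditioned on few annotated epochs.
    """
    if len(bands) == 0:
        raise ValueError("no candidate bands")
    if not training_record.annotations:
        raise ValueError("band selection requires annotated ictal epochs")
    ictal_total = sum(b - a for a, b in training_record.annotations)
    nonictal_total = training_record.duration_s - ictal_total
    if nonictal_total < min_nonictal_s:
        raise ValueError(
            f"{nonictal_total:.0f} s of nonictal training data is below the "
            f"required minimum ({min_nonictal_s:.0f} s)")
    if len(bands) == 1:
        return bands[0]

    best_band, best_dist = None, -np.inf
    for band in bands:
        stats = svd_statistic(connectivity_series(training_record, band),
                              keep_spectra=False)
        states = np.array([training_record.state_at(t)
                           for t in stats.times_s])
        quantizer = build_quantizer(stats.sigma1, n_bins=n_bins)
        codes = quantizer(stats.sigma1)
        theta0 = _masked_state_fit(codes, states, 0, L)
        theta1 = _masked_state_fit(codes, states, 1, L)
        dist = glm_parameter_distance(theta0, theta1)
        if dist > best_dist:
            best_band, best_dist = band, dist
    return best_band
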