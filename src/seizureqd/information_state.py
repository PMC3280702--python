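"""Recursive Bayesian information-state filter.

``pi_k = Pr(x_k = 1 | z_k, H_k)`` is the posterior probability that the
hidden state is ictal given all observations so far.  It evolves by

    pi' = L (pi + (1-pi) rho) / [ (1-pi)(1-rho) + L (pi + (1-pi) rho) ]

where ``L = q_1(z|H)/q_0(z|H)`` is the emission likelihood ratio and ``rho``
the per-stage transition probability.  All likelihood work happens in the log
domain; the update is evaluated in the rearranged form above, whose
denominator is a sum of nonnegative terms and therefore free of catastrophic
cancellation as ``pi`` approaches 1.

After a detection the filter *terminates and restarts*: ``pi`` re-initializes
via the prior-weighted one-observation posterior while (by default) the
observation history buffer is retained, since the underlying signal is
physically continuous.  Retention is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import DataError
from .hmm_glm import HmmGlmModel

logger = logging.getLogger(__name__)

#: Clip bounds for the likelihood ratio (log scale).
LOG_LR_CLIP = 50.0

#: pi is clipped to [PI_FLOOR, 1 - PI_FLOOR] between updates so the recursion
#: stays responsive after long quiescent periods.
PI_FLOOR = 1e-12


@dataclass
class InformationTrajectory:
    """Filtered posterior trajectory with its likelihood ratios."""

    pi: np.ndarray
    likelihood_ratios: np.ndarray
    restart_indices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def initial_pi(model: HmmGlmModel, z0: float,
               history: Sequence[int] | None = None) -> float:
    """Posterior ``Pr(x_0 = 1 | z_0)`` at (re)initialization.

    With no ``history`` the emission rates are evaluated on the constant-pad
    history (the empty-history convention); a retained history buffer may be
    passed after a restart.
    """
    from .hmm_glm import emission_log_prob

    if history is None:
        history = [model.history_pad()] * model.L
    p0 = model.p0
    if p0 >= 1.0:
        return 0.0
    if p0 <= 0.0:
        return 1.0
    lq0 = emission_log_prob(model, 0, z0, history)
    lq1 = emission_log_prob(model, 1, z0, history)
    if not np.isfinite(lq0) and not np.isfinite(lq1):
        raise DataError("both emission probabilities vanish at z0")
    # pi0 = q1 (1-p0) / (q0 p0 + q1 (1-p0)), computed via the log-odds
    log_odds = (lq0 + math.log(p0)) - (lq1 + math.log(1.0 - p0))
    return 1.0 / (1.0 + math.exp(log_odds))


def likelihood_ratio(model: HmmGlmModel, z: float,
                     history: Sequence[int]) -> float:
    """``L = q_1(z|H)/q_0(z|H)``, clipped to ``exp(+-50)``."""
    from .hmm_glm import emission_log_prob

    log_lr = (emission_log_prob(model, 1, z, history)
              - emission_log_prob(model, 0, z, history))
    if abs(log_lr) > LOG_LR_CLIP:
        logger.warning("likelihood ratio clipped (log LR = %.1f)", log_lr)
        log_lr = max(-LOG_LR_CLIP, min(LOG_LR_CLIP, log_lr))
    return math.exp(log_lr)


def update_pi(pi: float, L: float, rho: float) -> float:
    """One recursive posterior update; strictly increasing in ``L``."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if L < 0.0:
        raise ValueError("likelihood ratio must be nonnegative")
    reach = pi + (1.0 - pi) * rho         # prior prob of being ictal now
    num = L * reach
    den = (1.0 - pi) * (1.0 - rho) + num
    if den == 0.0:
        logger.warning("update_pi denominator underflow; returning %s",
                       1.0 if num > 0 else pi)
        return 1.0 if num > 0 else pi
    return num / den


# ---------------------------------------------------------------------------
# Vectorized per-segment likelihood machinery
# ---------------------------------------------------------------------------

def _segment_log_emissions(model: HmmGlmModel, codes: np.ndarray,
                           pad_history: Sequence[int] | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Log emission probabilities ``(log q_0, log q_1)`` for a code segment.

    The history before index 0 is ``pad_history`` (constant pad by default).
    """
    n = len(codes)
    L = model.L
    if pad_history is None:
        pad_history = [model.history_pad()] * L
    padded = np.concatenate([np.asarray(pad_history[-L:] if L else [],
                                        dtype=float), codes.astype(float)])
    out = []
    for theta in (model.theta0, model.theta1):
        eta = np.full(n, theta.alpha)
        for j in range(1, L + 1):
            eta += theta.betas[j - 1] * padded[L - j:L - j + n]
        out.append(codes * eta - np.exp(eta) - gammaln(codes + 1.0))
    return out[0], out[1]


def _clip_log_lr(log_lr: np.ndarray) -> np.ndarray:
    n_clip = int(np.sum(np.abs(log_lr) > LOG_LR_CLIP))
    if n_clip:
        logger.warning("clipped %d likelihood ratios to exp(+-%g)",
                       n_clip, LOG_LR_CLIP)
    return np.clip(log_lr, -LOG_LR_CLIP, LOG_LR_CLIP)


def _initial_pi_from_logs(model: HmmGlmModel, lq0: float, lq1: float) -> float:
    p0 = model.p0
    if p0 >= 1.0:
        return 0.0
    if p0 <= 0.0:
        return 1.0
    log_odds = (lq0 + math.log(p0)) - (lq1 + math.log(1.0 - p0))
    return 1.0 / (1.0 + math.exp(log_odds))


# ---------------------------------------------------------------------------
# Whole-series filtering
# ---------------------------------------------------------------------------

def filter_series(model: HmmGlmModel, observations: Sequence[float],
                  restarts: Sequence[int] = (),
                  history_carryover: bool = True) -> InformationTrajectory:
    """Filter a whole observation series with given restart stages.

    ``pi`` is initialized by :func:`initial_pi` at stage 0 and at every stage
    in ``restarts``; elsewhere it follows :func:`update_pi`.  With
    ``history_carryover`` (default) the GLM history runs continuously across
    restarts; without it, each restart segment is treated as a fresh series
    with padded history.
    """
    z = np.asarray(observations, dtype=float)
    if len(z) == 0:
        raise ValueError("observations must be nonempty")
    codes = np.asarray(model.quantizer(z))

    restart_set = sorted(set(int(r) for r in restarts))
    if any(r <= 0 or r >= len(z) for r in restart_set):
        raise ValueError("restart stages must lie strictly inside the series")
    bounds = [0] + restart_set + [len(z)]

    if history_carryover:
        lq0, lq1 = _segment_log_emissions(model, codes)
    else:
        lq0 = np.empty(len(z))
        lq1 = np.empty(len(z))
        for a, b in zip(bounds[:-1], bounds[1:]):
            lq0[a:b], lq1[a:b] = _segment_log_emissions(model, codes[a:b])

    log_lr = _clip_log_lr(lq1 - lq0)
    lr = np.exp(log_lr)

    pi = np.empty(len(z))
    for a, b in zip(bounds[:-1], bounds[1:]):
        p = _initial_pi_from_logs(model, lq0[a], lq1[a])
        pi[a] = p
        for k in range(a + 1, b):
            p = min(max(p, PI_FLOOR), 1.0 - PI_FLOOR)
            p = update_pi(p, float(lr[k]), model.rho)
            pi[k] = p
    return InformationTrajectory(pi=pi, likelihood_ratios=lr,
                                 restart_indices=restart_set)
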