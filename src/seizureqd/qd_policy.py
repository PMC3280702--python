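"""Quickest-detection optimal stopping policy.

The detector decides, at each stage ``k`` of a run, whether to declare a
seizure (stop, ``u_k = 1``) or keep monitoring (``u_k = 0``).  The policy
minimizes the expected sum of per-stage costs

    G_k(pi, 0) = gamma   * D(k)   * pi          (delay penalty)
    G_k(pi, 1) = (1-gamma) * (1/rho) * (1 - pi) (false-positive penalty)

over a horizon ``M``, where ``D(k) = E[k - T | T <= k]`` under the geometric
change prior ``P(T = k) = (1-rho)^(k-1) rho`` and ``1/rho`` is the memoryless
expected residual time to the change.  Backward dynamic programming over the
information state yields a stage-dependent threshold ``F_k``; the detector
fires at the first stage with ``pi_k > F_k`` (strict; ties continue).

Two DP backends share the same cost model:

* ``grid`` (default): the value function is tabulated on a uniform pi grid
  with linear interpolation inside the one-step expectation — fast and
  memory-light at production horizons.
* ``exact``: the value function of this two-state problem is piecewise linear
  and concave in pi, so it can be carried exactly as a lower envelope of
  lines; intended for small alphabets and horizons where exactness matters.

Exact DP over history-dependent emissions is exponential in the lag order, so
policy synthesis uses *history-marginalized* per-state emission pmfs (the
average one-step predictive pmf over training histories); the online filter
retains the full history dependence.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .hmm_glm import HmmGlmModel
from .information_state import (InformationTrajectory, PI_FLOOR,
                                _clip_log_lr, _initial_pi_from_logs,
                                _segment_log_emissions, update_pi)

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.3
DEFAULT_REFRACTORY_S = 60.0
EXACT_LINE_CAP = 500_000


# ---------------------------------------------------------------------------
# Cost primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSpec:
    """Trade-off settings of the stopping cost."""

    gamma: float
    horizon_M: int
    rho: float
    delay_exponent: int = 1
    final_stage: Literal["stop", "delay"] = "stop"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.horizon_M < 2:
            raise ValueError("horizon M must be >= 2")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1) for a proper prior")
        if self.delay_exponent not in (1, 2):
            raise ValueError("delay_exponent must be 1 or 2")


def expected_delay_given_past(k: int, rho: float) -> float:
    """``E[k - T | T <= k]`` under the truncated geometric change prior."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1] for a proper prior")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = 1.0 - rho
    qk = q ** k
    # E[T | T <= k] = (1 - (k+1) q^k + k q^(k+1)) / (rho (1 - q^k))
    return k - (1.0 - (k + 1) * qk + k * qk * q) / (rho * (1.0 - qk))


def _delay_vector(m: int, rho: float) -> np.ndarray:
    """``D(k)`` for k = 0..m-1 (``D(0) = 0``: the change cannot have occurred)."""
    k = np.arange(m, dtype=float)
    q = 1.0 - rho
    with np.errstate(divide="ignore", invalid="ignore"):
        qk = q ** k
        d = k - (1.0 - (k + 1) * qk + k * qk * q) / (rho * (1.0 - qk))
    d[0] = 0.0
    return d


def expected_time_to_change(rho: float) -> float:
    """``E[T - k | T > k] = 1/rho`` (memoryless geometric residual)."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1] for a proper prior")
    return 1.0 / rho


def stage_cost(pi: float, u: int, k: int, cost: CostSpec) -> float:
    """Per-stage cost ``G_k(pi, u)``."""
    if u == 0:
        d = expected_delay_given_past(k, cost.rho) if k >= 1 else 0.0
        return cost.gamma * d ** cost.delay_exponent * pi
    if u == 1:
        return (1.0 - cost.gamma) * expected_time_to_change(cost.rho) * (1.0 - pi)
    raise ValueError("u must be 0 or 1")


# ---------------------------------------------------------------------------
# History-marginalized emission pmfs
# ---------------------------------------------------------------------------

def marginal_emission_pmfs(model: HmmGlmModel,
                           training_codes: Sequence[int] | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-state pmfs over the quantized alphabet for policy synthesis.

    For each state the Poisson pmf (truncated to the alphabet, tail mass
    folded into the last bin) is averaged over the one-step predictive rates
    produced by the training histories; with no training codes the constant
    pad history is used, which is exact for history-free models.
    """
    k_support = np.arange(model.quantizer.n_bins)
    log_fact = gammaln(k_support + 1.0)

    def rates(theta) -> np.ndarray:
        if training_codes is None or theta.L == 0:
            return np.array([math.exp(theta.log_rate(
                [model.history_pad()] * theta.L))])
        codes = np.asarray(training_codes, dtype=float)
        if len(codes) <= theta.L:
            raise ValueError("training codes shorter than the lag order")
        eta = np.full(len(codes) - theta.L, theta.alpha)
        for j in range(1, theta.L + 1):
            eta += theta.betas[j - 1] * codes[theta.L - j:len(codes) - j]
        return np.exp(eta)

    out = []
    for theta in (model.theta0, model.theta1):
        lam = rates(theta)
        logpmf = (k_support[None, :] * np.log(lam)[:, None] - lam[:, None]
                  - log_fact[None, :])
        pmf = np.exp(logpmf).mean(axis=0)
        pmf[-1] += max(0.0, 1.0 - pmf.sum())   # fold the truncated tail
        out.append(pmf / pmf.sum())
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Threshold policy container
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPolicy:
    """Stage-indexed detection thresholds from backward induction.

    ``F[k]`` is the smallest information-state value at which stopping is
    optimal at stage ``k`` (the stopping region is the interval ``[F_k, 1]``
    because stop-minus-continue cost is convex in pi); detection requires the
    strict inequality ``pi_k > F_k``.  ``F[0]`` is 1 by construction: the
    detector never fires at stage 0.
    """

    F: np.ndarray                       # (M,) per-stage thresholds
    cost: CostSpec
    pi_grid: np.ndarray | None = None
    value_table: np.ndarray | None = None   # optional (M+1, grid) J_k table
    j0: float | None = None             # DP value at the nonictal start pi
    method: str = "grid"
    policy_id: str = "qd"

    @property
    def M(self) -> int:
        return len(self.F)

    def threshold_at(self, k_in_segment: int) -> float:
        """Threshold applied at segment stage ``k`` (held at F_{M-1} beyond
        the horizon: the geometric prior is memoryless)."""
        return float(self.F[min(k_in_segment, self.M - 1)])

    def to_json(self) -> str:
        return json.dumps({
            "F": self.F.tolist(),
            "cost": {"gamma": self.cost.gamma, "horizon_M": self.cost.horizon_M,
                     "rho": self.cost.rho,
                     "delay_exponent": self.cost.delay_exponent,
                     "final_stage": self.cost.final_stage},
            "method": self.method, "policy_id": self.policy_id,
            "j0": self.j0,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdPolicy":
        doc = json.loads(text)
        return cls(F=np.asarray(doc["F"]), cost=CostSpec(**doc["cost"]),
                   method=doc["method"], policy_id=doc["policy_id"],
                   j0=doc.get("j0"))


@dataclass(frozen=True)
class DetectionEvent:
    """One detection: the stage it fired at and the posterior there."""

    stage: int
    pi_at_detection: float
    policy_id: str = "qd"


# ---------------------------------------------------------------------------
# Grid DP backend
# ---------------------------------------------------------------------------

def _grid_backward_induction(q0: np.ndarray, q1: np.ndarray, cost: CostSpec,
                             grid_size: int, keep_values: bool,
                             ) -> tuple[np.ndarray, np.ndarray,
                                        np.ndarray | None]:
    rho, gamma, m = cost.rho, cost.gamma, cost.horizon_M
    grid = np.linspace(0.0, 1.0, grid_size)
    p_reach = rho + (1.0 - rho) * grid          # P(x'=1 | pi)
    p_stay = (1.0 - grid) * (1.0 - rho)

    # per-symbol mixture mass and posterior update on the grid
    mass = q1[:, None] * p_reach[None, :] + q0[:, None] * p_stay[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_next = np.where(mass > 0.0,
                           q1[:, None] * p_reach[None, :] / mass, 0.0)
    pi_next = np.clip(pi_next, 0.0, 1.0)
    idx = np.clip(np.searchsorted(grid, pi_next) - 1, 0, grid_size - 2)
    w = (pi_next - grid[idx]) / (grid[1] - grid[0])

    d_eff = _delay_vector(m, rho) ** cost.delay_exponent
    stop = (1.0 - gamma) * (1.0 / rho) * (1.0 - grid)

    if cost.final_stage == "stop":
        j = stop.copy()
    else:
        d_m = expected_delay_given_past(m, rho) ** cost.delay_exponent
        j = gamma * d_m * grid

    f = np.ones(m)
    values = np.empty((m + 1, grid_size)) if keep_values else None
    if keep_values:
        values[m] = j
    for k in range(m - 1, -1, -1):
        j_interp = j[idx] * (1.0 - w) + j[idx + 1] * w
        cont = gamma * d_eff[k] * grid + np.sum(mass * j_interp, axis=0)
        stop_opt = stop <= cont
        if k >= 1:
            hits = np.flatnonzero(stop_opt)
            f[k] = grid[hits[0]] if len(hits) else 1.0
            changes = np.flatnonzero(np.diff(stop_opt.astype(int)))
            if len(changes) > 1:
                logger.warning(
                    "stage %d: stop region is not a single interval on the "
                    "grid; consider a finer pi grid", k)
        j = np.where(stop_opt, stop, cont) if k >= 1 else cont
        if keep_values:
            values[k] = j
    return f, grid, values if keep_values else None


# ---------------------------------------------------------------------------
# Exact piecewise-linear DP backend
# ---------------------------------------------------------------------------

def _lower_envelope(slopes: np.ndarray, intercepts: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower envelope of lines ``a x + b`` on [0, 1].

    Returns ``(slopes, intercepts, starts)`` of the active segments ordered
    left to right; ``starts[i]`` is the x where segment ``i`` becomes active.
    """
    order = np.lexsort((intercepts, -slopes))   # slope desc, intercept asc
    a = slopes[order]
    b = intercepts[order]
    keep_a: list[float] = []
    keep_b: list[float] = []
    starts: list[float] = []
    for ai, bi in zip(a, b):
        if keep_a and ai == keep_a[-1]:
            continue                            # parallel, higher intercept
        while keep_a:
            # x where the new line crosses below the current last segment
            x = (bi - keep_b[-1]) / (keep_a[-1] - ai)
            if x <= starts[-1]:
                keep_a.pop(); keep_b.pop(); starts.pop()
            else:
                break
        if not keep_a:
            starts.append(0.0)
        else:
            x = (bi - keep_b[-1]) / (keep_a[-1] - ai)
            if x >= 1.0:
                continue
            starts.append(max(0.0, x))
        keep_a.append(ai)
        keep_b.append(bi)
    return np.array(keep_a), np.array(keep_b), np.array(starts)


def _sum_envelopes(parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sum of concave piecewise-linear functions, as segment lines."""
    cuts = np.unique(np.concatenate([p[2] for p in parts] + [np.array([0.0])]))
    slopes = np.zeros(len(cuts))
    intercepts = np.zeros(len(cuts))
    for a, b, starts in parts:
        pos = np.clip(np.searchsorted(starts, cuts, side="right") - 1,
                      0, len(starts) - 1)
        slopes += a[pos]
        intercepts += b[pos]
    return slopes, intercepts


def _exact_backward_induction(q0: np.ndarray, q1: np.ndarray, cost: CostSpec,
                              ) -> tuple[np.ndarray, "_PwlValue"]:
    rho, gamma, m = cost.rho, cost.gamma, cost.horizon_M
    d_eff = _delay_vector(m, rho) ** cost.delay_exponent
    stop_a, stop_b = -(1.0 - gamma) / rho, (1.0 - gamma) / rho

    if cost.final_stage == "stop":
        env = (np.array([stop_a]), np.array([stop_b]), np.array([0.0]))
    else:
        d_m = expected_delay_given_past(m, rho) ** cost.delay_exponent
        env = (np.array([gamma * d_m]), np.array([0.0]), np.array([0.0]))

    c_n = q1 * rho + q0 * (1.0 - rho)
    d_n = (1.0 - rho) * (q1 - q0)

    f = np.ones(m)
    for k in range(m - 1, -1, -1):
        a_prev, b_prev, _ = env
        parts = []
        for n in range(len(q0)):
            a_new = a_prev * q1[n] * (1.0 - rho) + b_prev * d_n[n]
            b_new = a_prev * q1[n] * rho + b_prev * c_n[n]
            parts.append(_lower_envelope(a_new, b_new))
        cont_a, cont_b = _sum_envelopes(parts)
        cont_a = cont_a + gamma * d_eff[k]
        if len(cont_a) > EXACT_LINE_CAP:
            raise RuntimeError(
                "exact DP value function exceeded the line budget; use the "
                "grid backend for this problem size")
        if k >= 1:
            f[k] = _stop_boundary(stop_a, stop_b,
                                  _lower_envelope(cont_a, cont_b))
            env = _lower_envelope(np.concatenate([cont_a, [stop_a]]),
                                  np.concatenate([cont_b, [stop_b]]))
        else:
            env = _lower_envelope(cont_a, cont_b)
    return f, _PwlValue(*env)


@dataclass
class _PwlValue:
    """Evaluate a piecewise-linear concave function stored as its envelope."""

    slopes: np.ndarray
    intercepts: np.ndarray
    starts: np.ndarray

    def __call__(self, x) -> np.ndarray | float:
        xv = np.asarray(x, dtype=float)
        vals = np.min(self.slopes * xv[..., None] + self.intercepts, axis=-1)
        return float(vals) if np.isscalar(x) else vals


def _stop_boundary(stop_a: float, stop_b: float,
                   cont_env: tuple[np.ndarray, np.ndarray, np.ndarray],
                   ) -> float:
    """Smallest pi in [0, 1] where the stop line is <= the continue envelope.

    stop - continue is convex, so the stopping region is [F, 1]."""
    a, b, starts = cont_env
    xs = np.concatenate([starts, [1.0]])
    cont_fn = _PwlValue(a, b, starts)
    diff = stop_a * xs + stop_b - cont_fn(xs)
    below = diff <= 0.0
    if below[0]:
        return 0.0
    hits = np.flatnonzero(below)
    if len(hits) == 0:
        return 1.0
    i = hits[0]
    mid = 0.5 * (xs[i - 1] + xs[i])   # crossing lies in (xs[i-1], xs[i]]
    seg = min(max(np.searchsorted(starts, mid, side="right") - 1, 0),
              len(a) - 1)
    denom = stop_a - a[seg]
    if denom == 0.0:
        return float(xs[i])
    x_cross = (b[seg] - stop_b) / denom
    return float(min(max(x_cross, xs[i - 1]), xs[i]))


# ---------------------------------------------------------------------------
# Policy synthesis and online detection
# ---------------------------------------------------------------------------

def policy_from_pmfs(q0: np.ndarray, q1: np.ndarray, cost: CostSpec,
                     method: Literal["grid", "exact"] = "exact",
                     pi_grid_size: int = 1001, keep_values: bool = False,
                     pi_start: float = 0.0,
                     policy_id: str = "qd") -> ThresholdPolicy:
    """Synthesize a policy directly from per-state discrete emission pmfs."""
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    if q0.shape != q1.shape:
        raise ValueError("state pmfs must share one alphabet")
    if method == "exact":
        f, value0 = _exact_backward_induction(q0, q1, cost)
        return ThresholdPolicy(F=f, cost=cost, j0=float(value0(pi_start)),
                               method="exact", policy_id=policy_id)
    f, grid, values = _grid_backward_induction(q0, q1, cost, pi_grid_size,
                                               keep_values or True)
    j0 = float(np.interp(pi_start, grid, values[0]))
    return ThresholdPolicy(F=f, cost=cost, pi_grid=grid,
                           value_table=values if keep_values else None,
                           j0=j0, method="grid", policy_id=policy_id)


def synthesize_policy(model: HmmGlmModel, cost: CostSpec,
                      pi_grid_size: int = 1001,
                      method: Literal["grid", "exact"] = "grid",
                      training_codes: Sequence[int] | None = None,
                      keep_values: bool = False,
                      policy_id: str = "qd") -> ThresholdPolicy:
    """Backward-induction synthesis of the adaptive threshold table.

    ``training_codes`` feed the history marginalization of the emission pmfs;
    omit them for history-free models.
    """
    if method == "grid" and pi_grid_size < 101:
        raise ValueError("pi grid must have at least 101 points")
    q0, q1 = marginal_emission_pmfs(model, training_codes)
    pi_start = 1.0 - model.p0
    if method == "grid":
        f, grid, values = _grid_backward_induction(
            q0, q1, cost, pi_grid_size, keep_values)
        j0 = float(np.interp(pi_start, grid, values[0])) if values is not None \
            else None
        return ThresholdPolicy(F=f, cost=cost, pi_grid=grid,
                               value_table=values, j0=j0, method="grid",
                               policy_id=policy_id)
    if method == "exact":
        f, value0 = _exact_backward_induction(q0, q1, cost)
        return ThresholdPolicy(F=f, cost=cost, j0=float(value0(pi_start)),
                               method="exact", policy_id=policy_id)
    raise ValueError(f"unknown DP backend {method!r}")


def run_qd(model: HmmGlmModel, policy: ThresholdPolicy,
           observations: Sequence[float],
           refractory_s: float = DEFAULT_REFRACTORY_S,
           history_carryover: bool = True,
           ) -> tuple[list[DetectionEvent], InformationTrajectory]:
    """Online detection with terminate-and-restart.

    Runs the information-state filter over the observations, fires a
    detection at the first stage of each segment whose posterior strictly
    exceeds the stage threshold, then restarts the filter and the stage
    clock at the next stage and suppresses further detections for the
    refractory period.
    """
    if policy.M < 2:
        raise ValueError("policy horizon must be >= 2")
    z = np.asarray(observations, dtype=float)
    if len(z) == 0:
        raise ValueError("observations must be nonempty")
    codes = np.asarray(model.quantizer(z))

    if history_carryover:
        lq0, lq1 = _segment_log_emissions(model, codes)
        lr = np.exp(_clip_log_lr(lq1 - lq0))

    detections: list[DetectionEvent] = []
    restarts: list[int] = []
    pi = np.empty(len(z))
    seg_start = 0
    refractory_until = -1.0
    t = 0
    while t < len(z):
        if t == seg_start:
            if not history_carryover:
                end = len(z)
                lq0_s, lq1_s = _segment_log_emissions(model,
                                                      codes[seg_start:end])
                lr_seg = np.exp(_clip_log_lr(lq1_s - lq0_s))
            if history_carryover:
                p = _initial_pi_from_logs(model, lq0[t], lq1[t])
            else:
                p = _initial_pi_from_logs(model, lq0_s[0], lq1_s[0])
        else:
            p = min(max(p, PI_FLOOR), 1.0 - PI_FLOOR)
            lr_t = lr[t] if history_carryover else lr_seg[t - seg_start]
            p = update_pi(p, float(lr_t), model.rho)
        pi[t] = p
        k_seg = t - seg_start
        if (k_seg >= 1 and t > refractory_until
                and p > policy.threshold_at(k_seg)):
            detections.append(DetectionEvent(stage=t, pi_at_detection=p,
                                             policy_id=policy.policy_id))
            refractory_until = t + refractory_s
            seg_start = t + 1
            if seg_start < len(z):
                restarts.append(seg_start)
        t += 1

    if history_carryover:
        lr_full = lr
    else:
        # reporting only: ratios recomputed per final segmentation
        lr_full = np.empty(len(z))
        bounds = [0] + restarts + [len(z)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            l0, l1 = _segment_log_emissions(model, codes[a:b])
            lr_full[a:b] = np.exp(_clip_log_lr(l1 - l0))
    traj = InformationTrajectory(pi=pi, likelihood_ratios=lr_full,
                                 restart_indices=restarts)
    return detections, traj
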