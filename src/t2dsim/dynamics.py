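"""Risk-factor dynamics: net annual transition calibration and application.

Transition probabilities between the ordered states of each modifiable
risk factor are calibrated so that one annual application maps the
age-a prevalence vector onto the age-(a+1) vector.  "Net" means one
directional flow per adjacent state pair: full bidirectional matrices
are unidentifiable from two prevalence cross-sections, so the flow
direction is fixed by the sign of the cumulative prevalence change and
only its magnitude is estimated, by Nelder-Mead simplex search on
logit-transformed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

_EXACT_TOL = 1e-10


@dataclass
class PrevalenceCurve:
    """Age grid of state-probability vectors for one risk factor and stratum."""

    factor: str
    stratum: dict
    ages: np.ndarray
    probs: np.ndarray  # (n_ages, K)
    states: list

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.all(np.diff(self.ages) == 1):
            raise ValueError("age grid must be contiguous")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("state probability vectors must sum to 1")


@dataclass
class TransitionTable:
    """Per-age one-year transition matrices for one factor and stratum.

    ``matrices[i]`` moves an individual of age ``ages[i]`` to age
    ``ages[i] + 1``; ages beyond the grid reuse the last matrix.
    """

    factor: str
    stratum: dict
    ages: np.ndarray
    matrices: np.ndarray  # (n_ages, K, K)
    warnings: list = field(default_factory=list)

    def matrix_for_age(self, age: int) -> np.ndarray:
        i = int(np.clip(age - self.ages[0], 0, len(self.ages) - 1))
        return self.matrices[i]


def smooth_prevalence(raw: PrevalenceCurve, window: int) -> PrevalenceCurve:
    """Centered moving average of each state series, then joint renormalisation.

    The window is truncated symmetrically at the boundaries.  ``window``
    must be odd; 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(raw.ages)
    if window > n:
        raise ValueError(f"window {window} exceeds age range {n}")
    half = window // 2
    sm = np.empty_like(raw.probs)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm[i] = raw.probs[lo:hi].mean(axis=0)
    sm = sm / sm.sum(axis=1, keepdims=True)
    return PrevalenceCurve(raw.factor, dict(raw.stratum), raw.ages.copy(), sm, list(raw.states))


def _build_matrix(flows: np.ndarray, directions: np.ndarray, k: int) -> np.ndarray:
    """Assemble a K x K matrix from per-boundary conditional net flows.

    ``directions[i] = +1`` sends flow up across boundary i (state i -> i+1),
    ``-1`` sends it down (state i+1 -> i), 0 means no flow.
    """
    q = np.eye(k)
    for i, (f, d) in enumerate(zip(flows, directions)):
        if d > 0:
            q[i, i + 1] += f
            q[i, i] -= f
        elif d < 0:
            q[i + 1, i] += f
            q[i + 1, i + 1] -= f
    return q


def _closed_form_flows(p_from: np.ndarray, p_to: np.ndarray):
    """Exact net flows when feasible: the flow across boundary i must equal
    the change in cumulative mass above it."""
    k = len(p_from)
    cum_from = np.cumsum(p_from)
    cum_to = np.cumsum(p_to)
    boundary_flow = cum_from[:-1] - cum_to[:-1]  # >0: mass moves up
    directions = np.sign(boundary_flow)
    directions[np.abs(boundary_flow) < 1e-12] = 0
    flows = np.zeros(k - 1)
    for i, (bf, d) in enumerate(zip(boundary_flow, directions)):
        source = p_from[i] if d > 0 else p_from[i + 1]
        if d != 0:
            flows[i] = abs(bf) / source if source > 0 else 1.0
    return flows, directions.astype(int)


def calibrate_net_transitions(p_from, p_to, bounds=(0.0, 1.0)):
    """Net annual transition matrix mapping prevalence ``p_from`` to ``p_to``.

    Minimises ``||p_to - p_from @ Q||^2`` over the per-boundary flow
    magnitudes using Nelder-Mead on logit-transformed parameters
    (directions fixed from the sign of the cumulative prevalence change;
    a boundary with zero prevalence change carries zero flow).  Returns
    ``(Q, objective, warning)`` where ``warning`` is True when no exact
    solution was attainable (objective > 1e-10).

    Only adjacent-state moves are allowed and, per adjacent pair, flow in
    a single direction — the structural definition of a *net* transition.
    """
    p_from = np.asarray(p_from, dtype=float)
    p_to = np.asarray(p_to, dtype=float)
    k = len(p_from)
    if k not in (2, 3):
        raise ValueError("state count must be 2 or 3")
    for name, p in [("p_from", p_from), ("p_to", p_to)]:
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must sum to 1")

    flows0, directions = _closed_form_flows(p_from, p_to)
    free = np.flatnonzero(directions != 0)
    if free.size == 0:
        return np.eye(k), 0.0, False

    lo, hi = bounds

    def objective(theta):
        flows = np.zeros(k - 1)
        flows[free] = lo + (hi - lo) / (1.0 + np.exp(-theta))
        q = _build_matrix(flows, directions, k)
        penalty = 0.0
        diag = np.diag(q)
        if (diag < 0).any():  # middle state over-committed
            penalty = 1e3 * float((np.minimum(diag, 0) ** 2).sum())
            q = np.clip(q, 0, None)
            q = q / q.sum(axis=1, keepdims=True)
        resid = p_to - p_from @ q
        return float(resid @ resid) + penalty

    x0 = np.clip(flows0[free], 1e-9, 1 - 1e-9)
    theta0 = np.log((x0 - lo) / (hi - x0)) if hi > lo else np.zeros_like(x0)
    res = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
    )
    flows = np.zeros(k - 1)
    flows[free] = lo + (hi - lo) / (1.0 + np.exp(-res.x))
    q = _build_matrix(flows, directions, k)
    q = np.clip(q, 0.0, 1.0)
    q = q / q.sum(axis=1, keepdims=True)
    obj = float(np.sum((p_to - p_from @ q) ** 2))
    return q, obj, obj > _EXACT_TOL


def build_transition_table(curve: PrevalenceCurve, smooth_window: int = 5) -> TransitionTable:
    """Calibrate one-year matrices along an age-smoothed prevalence curve.

    Age-a smoothed prevalence mapped to age-(a+1) prevalence proxies one
    year of follow-up of the same cohort (period-for-cohort approximation).
    """
    sm = smooth_prevalence(curve, smooth_window) if smooth_window > 1 else curve
    n, k = sm.probs.shape
    mats = np.empty((n - 1, k, k))
    warnings = []
    for i in range(n - 1):
        q, obj, warn = calibrate_net_transitions(sm.probs[i], sm.probs[i + 1])
        mats[i] = q
        if warn:
            warnings.append((int(sm.ages[i]), obj))
    return TransitionTable(
        factor=curve.factor,
        stratum=dict(curve.stratum),
        ages=sm.ages[:-1].copy(),
        matrices=mats,
        warnings=warnings,
    )


def apply_transition(state, q_row, rng):
    """Sample the next state from a transition-matrix row."""
    q_row = np.asarray(q_row, dtype=float)
    if q_row.min() < -1e-12 or abs(q_row.sum() - 1) > 1e-9:
        raise ValueError("q_row must be a probability vector")
    return int(rng.choice(len(q_row), p=q_row / q_row.sum()))


def sample_categorical_rows(prob_rows: np.ndarray, rng) -> np.ndarray:
    """Vectorised draw: one category per row of a matrix of probability rows."""
    u = rng.random(prob_rows.shape[0])
    return (prob_rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, prob_rows.shape[1] - 1)


# -- long-format CSV I/O ----------------------------------------------------

def transition_tables_to_frame(tables) -> pd.DataFrame:
    rows = []
    for t in tables:
        states = list(range(t.matrices.shape[1]))
        for age, mat in zip(t.ages, t.matrices):
            for i in states:
                for j in states:
                    rows.append(
                        {
                            "risk_factor": t.factor,
                            **t.stratum,
                            "age": int(age),
                            "from_state": i,
                            "to_state": j,
                            "value": mat[i, j],
                        }
                    )
    return pd.DataFrame(rows)


def curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        for age, vec in zip(c.ages, c.probs):
            for j, p in enumerate(vec):
                rows.append(
                    {"risk_factor": c.factor, **c.stratum, "age": int(age), "state": j, "value": p}
                )
    return pd.DataFrame(rows)
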