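"""Nonparametric and semiparametric estimators for stacked multi-state data.

All estimators consume the stacked long-format transition table produced by
:func:`msmtrial.state_space.stack_transitions`: per patient and occupied
state, one row per competing transition on the shared study-time interval
``(t_start, t_stop]`` with a 0/1 status.  Delayed entry is honored
throughout: a row is at risk at time ``u`` iff ``t_start < u <= t_stop``.

Provided estimators:

* :func:`nelson_aalen` — per-transition cumulative hazard, increments d/n;
* :func:`aalen_johansen` — transition-probability matrix P(s, t) as the
  product integral of I + dA(u) over event times;
* :func:`km_survival` / :func:`inverse_km_followup` — Kaplan-Meier and the
  reverse-KM median follow-up;
* :func:`cuminc_competing` — competing-risks cumulative incidence;
* :func:`cox_transition` / :func:`cox_origin_effect` — transition-specific
  Cox proportional-hazards fits (Breslow or Efron ties, Newton-Raphson);
* :func:`chisq_2x2_yates` — continuity-corrected chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .state_space import StateSpace

__all__ = [
    "CumulativeHazard",
    "ProbabilityPath",
    "CoxTransitionFit",
    "StepCurve",
    "nelson_aalen",
    "aalen_johansen",
    "km_survival",
    "inverse_km_followup",
    "cuminc_competing",
    "cox_transition",
    "cox_origin_effect",
    "chisq_2x2_yates",
    "ConvergenceError",
    "NumericalValidityError",
]


class ConvergenceError(RuntimeError):
    """The Cox partial likelihood did not converge (e.g. monotone likelihood)."""


class NumericalValidityError(RuntimeError):
    """A product-integral factor left the valid stochastic-matrix range."""


# ---------------------------------------------------------------------------
# step functions


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function given by jump times and post-jump values."""

    times: np.ndarray
    values: np.ndarray
    baseline: float = 1.0

    def at(self, t) -> np.ndarray | float:
        """Value at time(s) t (``baseline`` before the first jump)."""
        idx = np.searchsorted(self.times, np.asarray(t), side="right") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], self.baseline)
        return float(vals) if np.isscalar(t) else vals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


@dataclass(frozen=True)
class CumulativeHazard:
    """Nelson-Aalen estimate for one transition: jumps of size events/at-risk."""

    transition_id: int
    jump_times: np.ndarray
    increments: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def cumulative(self) -> StepCurve:
        return StepCurve(self.jump_times, np.cumsum(self.increments), baseline=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transition_id": self.transition_id,
                "time": self.jump_times,
                "increment": self.increments,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "cumulative_hazard": np.cumsum(self.increments),
            }
        )


@dataclass(frozen=True)
class ProbabilityPath:
    """Aalen-Johansen transition-probability matrices P(s, t) on a time grid.

    ``matrices[i]`` is the row-stochastic matrix of probabilities of being in
    each state (columns) at ``eval_times[i]``, given the state occupied
    (rows) at origin time ``s``.
    """

    s: float
    eval_times: np.ndarray
    matrices: np.ndarray  # (n_times, k, k)
    states: tuple[str, ...]

    def at(self, t: float) -> np.ndarray:
        """P(s, t); the identity matrix for t <= s or before the first jump."""
        idx = int(np.searchsorted(self.eval_times, t, side="right")) - 1
        if idx < 0:
            return np.eye(len(self.states))
        return self.matrices[idx]

    def occupation(self, origin_state: Optional[str] = None) -> pd.DataFrame:
        """State-occupation probabilities over time from ``origin_state``.

        Defaults to the model's start state (first state).
        """
        origin_state = origin_state or self.states[0]
        row = self.states.index(origin_state)
        return pd.DataFrame(
            self.matrices[:, row, :], index=self.eval_times, columns=list(self.states)
        ).rename_axis("time")

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialization: one row per (time, from_state, to_state)."""
        k = len(self.states)
        times = np.repeat(self.eval_times, k * k)
        frm = np.tile(np.repeat(np.array(self.states), k), len(self.eval_times))
        to = np.tile(np.array(self.states), k * len(self.eval_times))
        return pd.DataFrame(
            {
                "s": self.s,
                "time": times,
                "from_state": frm,
                "to_state": to,
                "probability": self.matrices.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# nonparametric estimators


def nelson_aalen(table: pd.DataFrame, transition_id: int) -> CumulativeHazard:
    """Nelson-Aalen cumulative-hazard increments for one transition.

    One jump per distinct event time ``u`` of the transition, of size d/n
    where d is the number of status-1 rows stopping at ``u`` and n the number
    of rows with ``t_start < u <= t_stop`` (the at-risk set with delayed
    entry).  A transition with no rows yields an empty (zero) step function.
    """
    sub = table[table["transition_id"] == transition_id]
    start = sub["t_start"].to_numpy(dtype=float)
    stop = sub["t_stop"].to_numpy(dtype=float)
    status = sub["status"].to_numpy()
    times = np.unique(stop[status == 1])
    at_risk = np.empty(times.size, dtype=np.int64)
    d = np.empty(times.size, dtype=np.int64)
    for i, u in enumerate(times):
        at_risk[i] = int(np.sum((start < u) & (u <= stop)))
        d[i] = int(np.sum((stop == u) & (status == 1)))
    increments = d / at_risk if times.size else np.array([])
    return CumulativeHazard(
        transition_id=transition_id,
        jump_times=times,
        increments=np.asarray(increments, dtype=float),
        at_risk=at_risk,
        n_events=d,
    )


def aalen_johansen(
    hazards: Sequence[CumulativeHazard],
    space: StateSpace,
    s: float = 0.0,
    eval_times: Optional[Sequence[float]] = None,
) -> ProbabilityPath:
    """Aalen-Johansen transition probabilities P(s, t) for all t.

    P(s, t) is the product integral of ``I + dA(u)`` over event times
    ``u in (s, t]``.  At each event time, every transition's hazard increment
    enters the same factor (ties across transitions are handled jointly) as
    the off-diagonal entry (from, to); diagonals make rows sum to zero.

    Raises :class:`NumericalValidityError` if the total increment out of a
    state exceeds 1 at some tied time, which would make a diagonal negative.
    """
    k = len(space.states)
    index = {st: i for i, st in enumerate(space.states)}
    by_tid = {h.transition_id: h for h in hazards}
    missing = [tid for tid in space.transition_ids.values() if tid not in by_tid]
    if missing:
        raise ValueError(f"hazards missing for transition id(s) {missing}")

    jumps: dict[float, list[tuple[int, int, float]]] = {}
    for (frm, to), tid in space.transition_ids.items():
        h = by_tid[tid]
        for u, inc in zip(h.jump_times, h.increments):
            if u > s:
                jumps.setdefault(float(u), []).append((index[frm], index[to], float(inc)))
    times = sorted(jumps)
    grid = sorted(set(times) | {float(t) for t in (eval_times or []) if t >= s})

    matrices = np.empty((len(grid), k, k))
    P = np.eye(k)
    for i, u in enumerate(grid):
        if u in jumps:
            dA = np.zeros((k, k))
            for r, c, inc in jumps[u]:
                dA[r, c] += inc
            diag = -dA.sum(axis=1)
            if np.any(1.0 + diag < 0):
                bad = [space.states[j] for j in np.where(1.0 + diag < 0)[0]]
                raise NumericalValidityError(
                    f"total hazard increment exceeds 1 at t={u} for state(s) "
                    f"{bad}; audit tied event times"
                )
            dA[np.diag_indices(k)] = diag
            P = P @ (np.eye(k) + dA)
        matrices[i] = P
    return ProbabilityPath(
        s=float(s),
        eval_times=np.asarray(grid, dtype=float),
        matrices=matrices,
        states=tuple(space.states),
    )


def km_survival(times, events) -> StepCurve:
    """Kaplan-Meier survival curve from right-censored data (no delayed entry)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    uniq = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for u in uniq:
        n = int(np.sum(times >= u))
        d = int(np.sum((times == u) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
    return StepCurve(uniq, np.asarray(surv), baseline=1.0)


def inverse_km_followup(times, events) -> Optional[float]:
    """Median follow-up by reverse Kaplan-Meier (censoring treated as event).

    Returns the smallest time at which the follow-up "survival" curve drops
    to 0.5 or below, or ``None`` when no observation is censored (the
    follow-up distribution is then unidentified).
    """
    events = np.asarray(events, dtype=int)
    if not np.any(events == 0):
        return None
    curve = km_survival(times, 1 - events)
    below = curve.values <= 0.5
    if not np.any(below):
        return None
    return float(curve.times[np.argmax(below)])


def cuminc_competing(times, causes) -> dict[str, StepCurve]:
    """Competing-risks cumulative incidence per cause.

    ``causes`` labels each subject's first event ("censored" for none).  The
    estimator is the classic Aalen-Johansen special case
    ``CIF_k(t) = sum_{u<=t} S(u-) d_k(u) / n(u)`` with S the all-cause
    Kaplan-Meier.  Returns one curve per cause plus the all-cause event-free
    curve under key ``"event_free"``; at any time the cause curves and the
    event-free curve sum to 1.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    labels = sorted(set(causes) - {"censored"})
    if "event_free" in labels:
        raise ValueError('"event_free" is a reserved label')
    any_event = (causes != "censored").astype(int)
    uniq = np.unique(times[any_event == 1])
    s_minus = 1.0
    surv = []
    cif = {lab: [] for lab in labels}
    totals = {lab: 0.0 for lab in labels}
    for u in uniq:
        n = int(np.sum(times >= u))
        d_all = int(np.sum((times == u) & (any_event == 1)))
        for lab in labels:
            d_k = int(np.sum((times == u) & (causes == lab)))
            totals[lab] += s_minus * d_k / n
            cif[lab].append(totals[lab])
        s_minus *= 1.0 - d_all / n
        surv.append(s_minus)
    out = {lab: StepCurve(uniq, np.asarray(cif[lab]), baseline=0.0) for lab in labels}
    out["event_free"] = StepCurve(uniq, np.asarray(surv), baseline=1.0)
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood (delayed entry, Breslow/Efron ties)


@dataclass(frozen=True)
class CoxTransitionFit:
    """A fitted transition-specific Cox model (Wald inference)."""

    transition_ids: tuple[int, ...]
    covariates: tuple[str, ...]
    log_hr: np.ndarray
    se: np.ndarray
    n_events: int
    n_rows: int
    ties: str = "breslow"

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def hr_ci95(self) -> np.ndarray:
        lo = np.exp(self.log_hr - 1.959963984540054 * self.se)
        hi = np.exp(self.log_hr + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_wald(self) -> np.ndarray:
        z = self.log_hr / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        ci = self.hr_ci95
        return pd.DataFrame(
            {
                "covariate": list(self.covariates),
                "log_hr": self.log_hr,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": ci[:, 0],
                "hr_ci_high": ci[:, 1],
                "p_wald": self.p_wald,
                "n_events": self.n_events,
            }
        )


def _partial_loglik(beta, start, stop, status, X, strata, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for st in np.unique(strata):
        m = strata == st
        st_start, st_stop, st_status = start[m], stop[m], status[m]
        st_X, st_w = X[m], w[m]
        for u in np.unique(st_stop[st_status == 1]):
            dead = (st_stop == u) & (st_status == 1)
            risk = (st_start < u) & (u <= st_stop)
            d = int(dead.sum())
            s0 = st_w[risk].sum()
            s1 = st_w[risk] @ st_X[risk]
            s2 = (st_w[risk, None] * st_X[risk]).T @ st_X[risk]
            xsum = st_X[dead].sum(axis=0)
            loglik += float(np.log(st_w[dead]).sum())
            grad += xsum
            if ties == "breslow" or d == 1:
                loglik -= d * np.log(s0)
                grad -= d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            elif ties == "efron":
                s0d = st_w[dead].sum()
                s1d = st_w[dead] @ st_X[dead]
                s2d = (st_w[dead, None] * st_X[dead]).T @ st_X[dead]
                for j in range(d):
                    f = j / d
                    a0 = s0 - f * s0d
                    a1 = s1 - f * s1d
                    a2 = s2 - f * s2d
                    loglik -= np.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1 / a0, a1 / a0)
            else:
                raise ValueError(f"unknown tie method {ties!r}")
    return loglik, grad, hess


def _cox_newton(
    start, stop, status, X, strata, ties="breslow", tol=1e-8, max_iter=50
):
    """Newton-Raphson maximization with step halving; returns (beta, se)."""
    n, p = X.shape
    if status.sum() < 1:
        raise ConvergenceError("no events among the selected rows")
    for j in range(p):
        col = X[:, j]
        ev = col[status == 1]
        if np.all(col == col[0]):
            raise ConvergenceError(f"covariate column {j} is constant")
        uniq = np.unique(col)
        if uniq.size == 2 and (np.all(ev == uniq[0]) or np.all(ev == uniq[1])):
            # every event in one level of a binary covariate -> monotone likelihood
            raise ConvergenceError(
                f"monotone likelihood: all events share one level of covariate column {j}"
            )
    beta = np.zeros(p)
    ll, grad, hess = _partial_loglik(beta, start, stop, status, X, strata, ties)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new = _partial_loglik(new_beta, start, stop, status, X, strata, ties)
        halvings = 0
        # halve only on decreases beyond float noise in the summed likelihood
        decrease_tol = 1e-9 * (abs(ll) + 1.0)
        while new[0] < ll - decrease_tol and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _partial_loglik(new_beta, start, stop, status, X, strata, ties)
            halvings += 1
        beta = new_beta
        ll, grad, hess = new
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError(
                "monotone likelihood suspected: |log HR| exceeded 50"
            )
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError(
                f"Newton-Raphson did not reach gradient norm < {tol} in {max_iter} iterations"
            )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return beta, se


def _design_from_table(table: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for name in covariates:
        if name == "arm":
            cols.append((table["arm"] == "CLO").to_numpy(dtype=float))
        else:
            cols.append(table[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def cox_transition(
    table: pd.DataFrame,
    transition_ids: int | Sequence[int],
    covariates: Sequence[str] = ("arm",),
    ties: str = "breslow",
) -> CoxTransitionFit:
    """Transition-specific Cox model on the stacked table.

    Fits the partial likelihood on the rows of the selected transition(s)
    with delayed entry (risk set ``t_start < u <= t_stop``).  When several
    transition ids are passed, baseline hazards are stratified by transition
    and the covariate effects are shared across strata.  The ``arm``
    covariate is coded 1 for the CLO arm with control as reference.
    """
    if isinstance(transition_ids, (int, np.integer)):
        transition_ids = (int(transition_ids),)
    transition_ids = tuple(int(t) for t in transition_ids)
    sub = table[table["transition_id"].isin(transition_ids)]
    if sub.empty:
        raise ValueError(f"no rows for transition id(s) {transition_ids}")
    X = _design_from_table(sub, covariates)
    beta, se = _cox_newton(
        sub["t_start"].to_numpy(dtype=float),
        sub["t_stop"].to_numpy(dtype=float),
        sub["status"].to_numpy(dtype=int),
        X,
        sub["transition_id"].to_numpy(),
        ties=ties,
    )
    return CoxTransitionFit(
        transition_ids=transition_ids,
        covariates=tuple(covariates),
        log_hr=beta,
        se=se,
        n_events=int(sub["status"].sum()),
        n_rows=len(sub),
        ties=ties,
    )


def cox_origin_effect(
    table: pd.DataFrame,
    target_state: str,
    origin: str,
    adjust: Sequence[str] = ("arm",),
    ties: str = "breslow",
) -> CoxTransitionFit:
    """Effect of the origin state on the hazard of entering ``target_state``.

    Pools all rows whose ``to_state`` equals ``target_state`` into a single
    Cox fit with a 0/1 indicator for rows originating from ``origin`` plus
    the adjustment covariates, sharing one baseline hazard across origins.
    The indicator's hazard ratio compares patients currently in ``origin``
    with patients in any other inbound state.
    """
    sub = table[table["to_state"] == target_state]
    origins = set(sub["from_state"])
    if len(origins) < 2:
        raise ValueError(
            f"target state {target_state!r} needs >=2 inbound origins, found {origins}"
        )
    if origin not in origins:
        raise ValueError(f"origin {origin!r} not among inbound origins {origins}")
    ind = (sub["from_state"] == origin).to_numpy(dtype=float)
    X = np.column_stack([ind, _design_from_table(sub, adjust)]) if adjust else ind[:, None]
    beta, se = _cox_newton(
        sub["t_start"].to_numpy(dtype=float),
        sub["t_stop"].to_numpy(dtype=float),
        sub["status"].to_numpy(dtype=int),
        X,
        np.zeros(len(sub)),
        ties=ties,
    )
    return CoxTransitionFit(
        transition_ids=tuple(sorted(set(int(t) for t in sub["transition_id"]))),
        covariates=(f"origin:{origin}",) + tuple(adjust),
        log_hr=beta,
        se=se,
        n_events=int(sub["status"].sum()),
        n_rows=len(sub),
        ties=ties,
    )


# ---------------------------------------------------------------------------
# 2x2 test


def chisq_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared test on a 2x2 table.

    Cells are ``[[a, b], [c, d]]``.  The statistic is
    ``N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2)`` with the correction clamped at
    zero, referred to a chi-squared distribution with 1 df.  Returns
    ``(nan, nan)`` with a warning when any margin is zero.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        warnings.warn("chi-squared undefined: a table margin is zero", stacklevel=2)
        return float("nan"), float("nan")
    diff = abs(a * d - b * c) - n / 2.0
    if diff < 0:
        diff = 0.0
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p
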