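"""Transition-specific hazard estimation.

Two estimators operate on counting-process transition tables:

* :func:`nelson_aalen` — the (optionally weighted) Nelson-Aalen estimator of
  the cause-specific cumulative transition intensity, with increments
  ``dA(u) = (sum of event weights at u) / (weight at risk at u)`` and left
  truncation respected through entry times;
* :class:`TransitionCoxModel` — a Cox proportional-hazards model for one
  transition, maximising the weighted partial likelihood with Breslow
  handling of ties by Newton-Raphson with step-halving, supporting left
  truncation, case weights (e.g. inverse-probability-of-treatment weights),
  a Breslow baseline cumulative hazard and a person-clustered sandwich
  (robust) covariance.

Both share the same risk-set arithmetic, so a Cox fit with all coefficients
zero reproduces the Nelson-Aalen estimate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import CONTINUOUS_COVARIATES, DESIGN_COLUMNS, encode_pattern
from .states import transition_label

Transition = tuple[str, str]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the last iterate."""

    def __init__(self, message: str, params: np.ndarray | None = None):
        super().__init__(message)
        self.params = params


# ---------------------------------------------------------------------------
# Step functions
# ---------------------------------------------------------------------------


@dataclass
class CumulativeHazard:
    """Right-continuous cumulative-hazard step function for one transition."""

    transition: Transition
    times: np.ndarray
    increments: np.ndarray
    variance_increments: np.ndarray | None = None
    weighted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.increments = np.asarray(self.increments, float)
        if self.variance_increments is not None:
            self.variance_increments = np.asarray(self.variance_increments, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(self.increments < 0):
            raise ValueError("hazard increments must be non-negative")

    @property
    def oversized_steps(self) -> np.ndarray:
        """Jump times where dA(u) > 1 (invalid as a probability step)."""
        return self.times[self.increments > 1.0]

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def evaluate(self, t) -> np.ndarray:
        """A(t): cumulative hazard at the last jump <= t."""
        cum = np.concatenate([[0.0], self.cumulative()])
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        return cum[idx]

    def scaled(self, factor: float) -> "CumulativeHazard":
        return CumulativeHazard(
            transition=self.transition,
            times=self.times.copy(),
            increments=self.increments * factor,
            variance_increments=(
                None
                if self.variance_increments is None
                else self.variance_increments * factor**2
            ),
            weighted=self.weighted,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "time": self.times,
                "increment": self.increments,
                "cumulative": self.cumulative(),
            }
        )
        if self.variance_increments is not None:
            frame["variance"] = np.cumsum(self.variance_increments)
        frame.insert(0, "transition", transition_label(self.transition))
        return frame


# ---------------------------------------------------------------------------
# Risk-set arithmetic (shared by Nelson-Aalen and Cox/Breslow)
# ---------------------------------------------------------------------------


class _RiskSums:
    """Sums of row values over risk sets {i: entry_i < u <= exit_i}.

    Implemented as suffix sums over entry- and exit-sorted orders, evaluated
    at arbitrary query times by binary search.
    """

    def __init__(self, entry: np.ndarray, exit_: np.ndarray):
        self.entry_order = np.argsort(entry, kind="stable")
        self.exit_order = np.argsort(exit_, kind="stable")
        self.entry_sorted = entry[self.entry_order]
        self.exit_sorted = exit_[self.exit_order]

    def __call__(self, values: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Risk-set sums of ``values`` (shape (n,) or (n, ...)) at ``times``."""
        vx = values[self.exit_order]
        ve = values[self.entry_order]
        suffix_exit = np.concatenate(
            [np.cumsum(vx[::-1], axis=0)[::-1], np.zeros((1,) + values.shape[1:])]
        )
        suffix_entry = np.concatenate(
            [np.cumsum(ve[::-1], axis=0)[::-1], np.zeros((1,) + values.shape[1:])]
        )
        ix = np.searchsorted(self.exit_sorted, times, side="left")
        ie = np.searchsorted(self.entry_sorted, times, side="left")
        return suffix_exit[ix] - suffix_entry[ie]


def _extract_transition(
    table: pd.DataFrame, transition: Transition
) -> pd.DataFrame:
    h, j = transition
    sub = table[(table["from_state"] == h) & (table["to_state"] == j)]
    if len(sub) == 0:
        return sub
    return sub


def _resolve_weights(sub: pd.DataFrame, weights) -> np.ndarray:
    if weights is None:
        return (
            sub["weight"].to_numpy(float)
            if "weight" in sub.columns
            else np.ones(len(sub))
        )
    if isinstance(weights, str):
        return sub[weights].to_numpy(float)
    if isinstance(weights, pd.Series):
        w = sub["person_id"].map(weights).to_numpy(float)
        if np.any(~np.isfinite(w)):
            raise ValueError("weights missing for some persons in the table")
        return w
    w = np.asarray(weights, float)
    if w.shape != (len(sub),):
        raise ValueError("weight array must align with the filtered rows")
    return w


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------


def nelson_aalen(
    table: pd.DataFrame, transition: Transition, weights=None
) -> CumulativeHazard:
    """(Weighted) Nelson-Aalen cumulative hazard of one transition.

    ``weights`` may be None (use the table's ``weight`` column), a column
    name, a Series indexed by ``person_id``, or an array aligned with the
    filtered rows.  Variance increments are ``sum(w^2 events) / (risk
    weight)^2``, reducing to the standard ``d/n^2`` for unit weights.
    """
    sub = _extract_transition(table, transition)
    if len(sub) == 0:
        return CumulativeHazard(transition, np.array([]), np.array([]), np.array([]))
    w = _resolve_weights(sub, weights)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    entry = sub["entry"].to_numpy(float)
    exit_ = sub["exit"].to_numpy(float)
    status = sub["status"].to_numpy(int)

    is_event = status == 1
    if not is_event.any():
        return CumulativeHazard(transition, np.array([]), np.array([]), np.array([]))
    times, inverse = np.unique(exit_[is_event], return_inverse=True)
    d_w = np.bincount(inverse, weights=w[is_event], minlength=len(times))
    d_w2 = np.bincount(inverse, weights=w[is_event] ** 2, minlength=len(times))

    risk = _RiskSums(entry, exit_)(w, times)
    if np.any(risk <= 0):
        bad = times[risk <= 0]
        raise ValueError(f"zero at-risk weight at event time(s) {bad[:5]}")
    return CumulativeHazard(
        transition=transition,
        times=times,
        increments=d_w / risk,
        variance_increments=d_w2 / risk**2,
        weighted=weights is not None or not np.allclose(w, 1.0),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards for one transition
# ---------------------------------------------------------------------------


class TransitionCoxModel:
    """Cox model for the cause-specific hazard of a single transition.

    Parameters
    ----------
    table
        Counting-process table with columns ``person_id``, ``from_state``,
        ``to_state``, ``entry``, ``exit``, ``status``, a ``weight`` column
        and the covariate columns.
    transition
        ``(from_state, to_state)`` pair selecting the rows.
    covariates
        Covariate column names entering the linear predictor (default: the
        full 24-column design).
    weights
        As in :func:`nelson_aalen`.
    center
        Continuous columns centered at their estimation-sample mean so the
        Breslow baseline refers to an interpretable covariate pattern;
        predictions undo the centering.  Defaults to the continuous design
        columns present among ``covariates``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        transition: Transition,
        covariates: Sequence[str] | None = None,
        weights=None,
        center: Sequence[str] | None = None,
    ):
        self.transition = transition
        self.covariates = list(covariates) if covariates is not None else list(DESIGN_COLUMNS)
        sub = _extract_transition(table, transition)
        if len(sub) == 0:
            raise ValueError(f"no rows for transition {transition}")
        self._sub = sub.reset_index(drop=True)
        self.weights = _resolve_weights(self._sub, weights)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if center is None:
            center = [c for c in CONTINUOUS_COVARIATES if c in self.covariates]
        self.center_cols = list(center)
        x = self._sub[self.covariates].to_numpy(float)
        self.centers = np.zeros(x.shape[1])
        for col in self.center_cols:
            k = self.covariates.index(col)
            self.centers[k] = np.average(x[:, k], weights=self.weights)
        self._x = x - self.centers
        self._entry = self._sub["entry"].to_numpy(float)
        self._exit = self._sub["exit"].to_numpy(float)
        self._status = self._sub["status"].to_numpy(int)
        self._person = self._sub["person_id"].to_numpy()
        if self._status.sum() == 0:
            raise ValueError(f"no events for transition {transition}")
        self._risk = _RiskSums(self._entry, self._exit)
        ev = self._status == 1
        self._event_times, inv = np.unique(self._exit[ev], return_inverse=True)
        self._d_w = np.bincount(inv, weights=self.weights[ev])
        p = self._x.shape[1]
        self._event_z = np.zeros((len(self._event_times), p))
        np.add.at(self._event_z, inv, self.weights[ev, None] * self._x[ev])

    # -- partial likelihood machinery ---------------------------------------

    def _moments(self, beta: np.ndarray):
        """S0, S1, S2 risk-set moments at the unique event times."""
        eta = self._x @ beta
        r = self.weights * np.exp(eta)
        t = self._event_times
        s0 = self._risk(r, t)
        s1 = self._risk(r[:, None] * self._x, t)
        s2 = self._risk(
            r[:, None, None] * np.einsum("ni,nj->nij", self._x, self._x), t
        )
        return r, s0, s1, s2

    def _loglik_score_info(self, beta: np.ndarray):
        r, s0, s1, s2 = self._moments(beta)
        if np.any(s0 <= 0):
            raise ValueError("zero at-risk weight at an event time")
        m = s1 / s0[:, None]
        loglik = float(
            np.sum(self.weights[self._status == 1] * (self._x[self._status == 1] @ beta))
            - np.sum(self._d_w * np.log(s0))
        )
        score = self._event_z.sum(axis=0) - (self._d_w[:, None] * m).sum(axis=0)
        info = np.einsum(
            "k,kij->ij", self._d_w, s2 / s0[:, None, None]
        ) - np.einsum("k,ki,kj->ij", self._d_w, m, m)
        return loglik, score, info, s0, m, r

    def fit(
        self,
        robust: bool = False,
        max_iter: int = 50,
        tol_loglik: float = 1e-9,
        tol_score: float = 1e-6,
    ) -> "TransitionCoxResults":
        """Maximise the weighted Breslow partial likelihood by Newton-Raphson.

        Raises :class:`ConvergenceError` (carrying the last iterate) on
        non-convergence; flags monotone likelihood / separation when the
        coefficients diverge.
        """
        p = self._x.shape[1]
        beta = np.zeros(p)
        loglik, score, info, *_ = self._loglik_score_info(beta)
        converged = False
        flags: list[str] = []
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(
                    f"singular information matrix for {self.transition}: "
                    "design may be rank-deficient on the event set",
                    beta,
                ) from err
            new_beta = beta + step
            new = self._loglik_score_info(new_beta)
            halvings = 0
            while new[0] < loglik and halvings < 20:
                step /= 2.0
                new_beta = beta + step
                new = self._loglik_score_info(new_beta)
                halvings += 1
            rel_change = abs(new[0] - loglik) / max(abs(loglik), 1.0)
            beta, (loglik, score, info, s0, m, r) = new_beta, new
            if np.max(np.abs(beta)) > 20:
                flags.append("monotone likelihood (possible separation)")
                break
            if rel_change < tol_loglik and np.max(np.abs(score)) < tol_score:
                converged = True
                break
        if not converged and "monotone likelihood (possible separation)" not in flags:
            raise ConvergenceError(
                f"Cox fit for {self.transition} did not converge in {max_iter} "
                f"iterations (last max|score| = {np.max(np.abs(score)):.3g})",
                beta,
            )

        cov = np.linalg.inv(info)
        robust_cov = self._sandwich(beta, cov) if robust else None
        baseline = CumulativeHazard(
            transition=self.transition,
            times=self._event_times.copy(),
            increments=self._d_w / s0,
            variance_increments=self._d_w / s0**2,
            weighted=not np.allclose(self.weights, 1.0),
        )
        return TransitionCoxResults(
            model=self,
            params=pd.Series(beta, index=self.covariates),
            cov_params=pd.DataFrame(cov, index=self.covariates, columns=self.covariates),
            robust_cov_params=(
                None
                if robust_cov is None
                else pd.DataFrame(robust_cov, index=self.covariates, columns=self.covariates)
            ),
            baseline_hazard=baseline,
            loglik=loglik,
            n_iter=n_iter,
            converged=converged,
            flags=flags,
            n_events=int(self._status.sum()),
            n_rows=len(self._x),
        )

    def _sandwich(self, beta: np.ndarray, cov: np.ndarray) -> np.ndarray:
        """Person-clustered sandwich covariance from score residuals.

        One person contributes several at-risk rows, so score residuals are
        aggregated per person before forming the meat.
        """
        _, s0, s1, _ = self._moments(beta)
        m = s1 / s0[:, None]
        dh = self._d_w / s0  # Breslow baseline increments
        c0 = np.concatenate([[0.0], np.cumsum(dh)])
        c1 = np.concatenate([np.zeros((1, m.shape[1])), np.cumsum(dh[:, None] * m, axis=0)])
        hi = np.searchsorted(self._event_times, self._exit, side="right")
        lo = np.searchsorted(self._event_times, self._entry, side="right")
        r = self.weights * np.exp(self._x @ beta)
        expected = r[:, None] * (
            self._x * (c0[hi] - c0[lo])[:, None] - (c1[hi] - c1[lo])
        )
        observed = np.zeros_like(self._x)
        ev = self._status == 1
        k_event = np.searchsorted(self._event_times, self._exit[ev])
        observed[ev] = self.weights[ev, None] * (self._x[ev] - m[k_event])
        resid = observed - expected
        groups = pd.DataFrame(resid).groupby(self._person).sum().to_numpy()
        meat = groups.T @ groups
        return cov @ meat @ cov


@dataclass
class TransitionCoxResults:
    """Fitted Cox model for one transition."""

    model: TransitionCoxModel
    params: pd.Series
    cov_params: pd.DataFrame
    robust_cov_params: pd.DataFrame | None
    baseline_hazard: CumulativeHazard
    loglik: float
    n_iter: int
    converged: bool
    flags: list[str]
    n_events: int
    n_rows: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def robust_bse(self) -> pd.Series | None:
        if self.robust_cov_params is None:
            return None
        return pd.Series(
            np.sqrt(np.diag(self.robust_cov_params)), index=self.params.index
        )

    def hazard_ratios(self, alpha: float = 0.05, robust: bool = False) -> pd.DataFrame:
        """exp(beta) with Wald confidence limits."""
        se = self.robust_bse if robust else self.bse
        if se is None:
            raise ValueError("fit was run without robust=True")
        zq = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "hr": np.exp(self.params),
                "lower": np.exp(self.params - zq * se),
                "upper": np.exp(self.params + zq * se),
            }
        )

    def predict_cumulative_hazard(self, pattern) -> CumulativeHazard:
        """Cumulative hazard for a covariate pattern: exp(beta'z) x baseline.

        ``pattern`` is a mapping of covariate levels / design-column values;
        unspecified fields default to the reference pattern.  Centering of
        continuous covariates is undone here.
        """
        z = _pattern_to_design(pattern, self.params.index)
        if isinstance(pattern, Mapping):
            # unspecified centered covariates sit at their centering value
            for col in self.model.center_cols:
                if col not in pattern:
                    k = self.params.index.get_loc(col)
                    z[k] = self.model.centers[k]
        eta = float(np.dot(self.params.to_numpy(), z - self.model.centers))
        out = self.baseline_hazard.scaled(np.exp(eta))
        return out

    def summary(self) -> pd.DataFrame:
        se = self.bse
        table = pd.DataFrame(
            {
                "coef": self.params,
                "hr": np.exp(self.params),
                "se": se,
                "z": self.params / se,
                "p": 2 * stats.norm.sf(np.abs(self.params / se)),
            }
        )
        if self.robust_bse is not None:
            table["robust_se"] = self.robust_bse
        table.attrs["transition"] = transition_label(self.model.transition)
        table.attrs["loglik"] = self.loglik
        table.attrs["n_events"] = self.n_events
        return table


def _pattern_to_design(pattern, columns: pd.Index) -> np.ndarray:
    """Encode a pattern dict / Series onto the given design columns."""
    if isinstance(pattern, pd.Series):
        return pattern.reindex(columns).fillna(0.0).to_numpy(float)
    if isinstance(pattern, Mapping):
        if set(pattern) <= set(columns):
            return pd.Series(pattern, dtype=float).reindex(columns).fillna(0.0).to_numpy()
        encoded = encode_pattern(dict(pattern))
        return encoded.reindex(columns).fillna(0.0).to_numpy(float)
    z = np.asarray(pattern, float)
    if z.shape != (len(columns),):
        raise ValueError("pattern length does not match design columns")
    return z


# ---------------------------------------------------------------------------
# Module-level convenience functions
# ---------------------------------------------------------------------------


def cox_fit(
    table: pd.DataFrame,
    transition: Transition,
    covariates: Sequence[str] | None = None,
    weights=None,
    robust: bool = False,
    **fit_kwargs,
) -> TransitionCoxResults:
    """Fit a transition-specific Cox model (see :class:`TransitionCoxModel`)."""
    return TransitionCoxModel(table, transition, covariates, weights).fit(
        robust=robust, **fit_kwargs
    )


def breslow_baseline(fit: TransitionCoxResults) -> CumulativeHazard:
    """Breslow baseline cumulative hazard of a fitted Cox model.

    With all coefficients zero this equals :func:`nelson_aalen` exactly.
    """
    return fit.baseline_hazard


def predict_cumulative_hazard(fit: TransitionCoxResults, pattern) -> CumulativeHazard:
    """Covariate-specific cumulative hazard ``exp(beta'z) dA0(u)``."""
    return fit.predict_cumulative_hazard(pattern)
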