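"""Aalen-Johansen product-integral estimation of state probabilities.

Transition-specific cumulative hazards are assembled into a matrix-valued
intensity path: at every jump time ``u`` a 5x5 increment matrix ``dA(u)``
holds the transition-specific hazard increments off the diagonal and minus
the row sums on the diagonal.  The transition probability matrix over
``(s, t]`` is the finite matrix product

    P(s, t) = prod_{u in (s, t]} (I + dA(u)),

the Aalen-Johansen estimator.  State occupation probabilities follow by
mixing over the initial distribution,

    P(X(t) = j) = sum_k P_kj(0, t) P(X(0) = k),

with the initial distribution taken either as the (weighted) empirical
proportions of starting states or from a multinomial logistic model on
baseline covariates.  The same machinery consumes Nelson-Aalen increments
(marginal curves), Cox/Breslow predicted increments (covariate-conditional
curves) and inverse-probability-weighted increments (marginal causal
curves); contrast curves (differences, ratios, and ratios of difference
curves) compare completion with non-completion.

The estimator of state occupation probabilities is consistent even when the
process is not Markov, a property exercised directly in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hazards import CumulativeHazard
from .states import DISABILITY, N_STATES, STATE_INDEX, STATES

#: Canonical rounding (years) applied to jump times before merging grids.
TIME_RESOLUTION_DECIMALS = 9


class EmptyGroupError(ValueError):
    """A (re)sample contains no persons in a required group."""


# ---------------------------------------------------------------------------
# Intensity paths and the product integral
# ---------------------------------------------------------------------------


@dataclass
class IntensityPath:
    """Jump times and 5x5 increment matrices of the cumulative intensity."""

    times: np.ndarray  # (K,)
    increments: np.ndarray  # (K, 5, 5)
    truncated_at: float | None = None  # first invalid jump, if truncation chosen

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.increments = np.asarray(self.increments, float)
        if self.increments.shape != (len(self.times), N_STATES, N_STATES):
            raise ValueError("increments must have shape (K, 5, 5)")


def build_intensity_path(
    hazards: Mapping[tuple[str, str], CumulativeHazard],
    on_invalid: str = "raise",
) -> IntensityPath:
    """Merge transition-specific hazards into one matrix-valued path.

    Jump times are rounded to ``1e-9`` years before taking their union, so
    identical event times coming from different hazards land on the same
    jump.  Missing transitions are treated as identically zero.  Every
    ``I + dA(u)`` must be a valid stochastic matrix; an origin state whose
    total increment at some jump exceeds 1 raises an error naming the state
    and time (``on_invalid='raise'``, the default), or — for conditional
    curves on sparse late risk sets — the path is cut just before the first
    invalid jump and the cut time recorded (``on_invalid='truncate'``).
    """
    if on_invalid not in ("raise", "truncate"):
        raise ValueError("on_invalid must be 'raise' or 'truncate'")
    rounded: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    all_times: list[np.ndarray] = []
    for tr, hz in hazards.items():
        if tr[0] == DISABILITY:
            raise ValueError("hazard out of the absorbing disability state")
        t = np.round(hz.times, TIME_RESOLUTION_DECIMALS)
        rounded[tr] = (t, hz.increments)
        all_times.append(t)
    times = (
        np.unique(np.concatenate(all_times)) if all_times else np.array([], float)
    )
    inc = np.zeros((len(times), N_STATES, N_STATES))
    for (h, j), (t, da) in rounded.items():
        idx = np.searchsorted(times, t)
        np.add.at(inc, (idx, STATE_INDEX[h], STATE_INDEX[j]), da)
    row_sums = inc.sum(axis=2)
    bad = np.argwhere(row_sums > 1.0 + 1e-12)
    truncated_at = None
    if len(bad):
        k, h = bad[np.argmin(bad[:, 0])]
        if on_invalid == "raise":
            raise ValueError(
                f"invalid increment at t={times[k]:.9g}: total hazard step "
                f"{row_sums[k, h]:.6g} > 1 out of state '{STATES[h]}'"
            )
        truncated_at = float(times[k])
        times, inc, row_sums = times[:k], inc[:k], row_sums[:k]
    for h in range(N_STATES):
        inc[:, h, h] = -row_sums[:, h]
    return IntensityPath(times=times, increments=inc, truncated_at=truncated_at)


def product_integral(path: IntensityPath, s: float, t: float) -> np.ndarray:
    """Transition probability matrix P(s, t) as an ordered matrix product.

    Returns the identity when no jumps fall in ``(s, t]``.  Endpoints are
    rounded to the canonical time resolution so queries at (unrounded) event
    times land on the matching jumps.
    """
    if s > t:
        raise ValueError("need s <= t")
    s = round(float(s), TIME_RESOLUTION_DECIMALS)
    t = round(float(t), TIME_RESOLUTION_DECIMALS)
    lo = np.searchsorted(path.times, s, side="right")
    hi = np.searchsorted(path.times, t, side="right")
    p = np.eye(N_STATES)
    eye = np.eye(N_STATES)
    for k in range(lo, hi):
        p = p @ (eye + path.increments[k])
    return p


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


@dataclass
class StateProbabilityCurve:
    """State occupation probabilities over a time grid (step-constant)."""

    times: np.ndarray  # (T,)
    probabilities: np.ndarray  # (T, 5)
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.probabilities = np.asarray(self.probabilities, float)
        if self.probabilities.shape != (len(self.times), N_STATES):
            raise ValueError("probabilities must have shape (T, 5)")

    def at(self, t) -> np.ndarray:
        """Value at the last grid time <= t (step-constant interpolation)."""
        t = np.round(np.asarray(t, float), TIME_RESOLUTION_DECIMALS)
        idx = np.searchsorted(self.times, t, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("requested time precedes the curve's origin")
        return self.probabilities[idx]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.probabilities, columns=list(STATES))
        frame.insert(0, "time", self.times)
        tidy = frame.melt(id_vars="time", var_name="state", value_name="probability")
        tidy["group"] = self.label
        return tidy


@dataclass
class ContrastCurve:
    """Per-state contrast (difference or ratio) between two curves."""

    times: np.ndarray
    values: np.ndarray  # (T, 5); NaN where undefined
    kind: str  # 'difference' | 'ratio' | 'ratio_of_differences'
    label: str = ""
    undefined: np.ndarray = field(default=None)  # bool mask (T, 5)

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)

    def at(self, t) -> np.ndarray:
        t = np.round(np.asarray(t, float), TIME_RESOLUTION_DECIMALS)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(STATES))
        frame.insert(0, "time", self.times)
        tidy = frame.melt(id_vars="time", var_name="state", value_name="value")
        tidy["curve_type"] = self.kind
        tidy["group"] = self.label
        return tidy


def state_probabilities(
    path: IntensityPath,
    init: np.ndarray,
    times: Sequence[float] | None = None,
    label: str = "",
) -> StateProbabilityCurve:
    """Occupation probability curve from an intensity path and P(X(0)=k).

    The curve is evaluated at time 0 and every jump time (plus any requested
    ``times``, using the value at the last jump before each).
    """
    init = np.asarray(init, float)
    if abs(init.sum() - 1.0) > 1e-8:
        raise ValueError("initial distribution must sum to 1")
    jump_probs = np.empty((len(path.times) + 1, N_STATES))
    v = init.copy()
    jump_probs[0] = v
    eye = np.eye(N_STATES)
    for k in range(len(path.times)):
        v = v @ (eye + path.increments[k])
        jump_probs[k + 1] = v
    jump_grid = np.concatenate([[0.0], path.times])

    if times is None:
        grid = jump_grid
        probs = jump_probs
    else:
        extra = np.round(np.asarray(times, float), TIME_RESOLUTION_DECIMALS)
        grid = np.unique(np.concatenate([jump_grid, extra]))
        idx = np.searchsorted(jump_grid, grid, side="right") - 1
        probs = jump_probs[idx]
    return StateProbabilityCurve(times=grid, probabilities=probs, label=label)


# ---------------------------------------------------------------------------
# Initial distributions
# ---------------------------------------------------------------------------


def empirical_initial_distribution(
    trajectories: Mapping[int, object],
    person_ids: Sequence[int] | None = None,
    weights: pd.Series | None = None,
) -> np.ndarray:
    """(Weighted) proportions of starting states; disability excluded.

    ``trajectories`` maps person id to a resolved trajectory (entries that
    are ``None`` are ignored); ``weights`` is an optional Series indexed by
    person id.
    """
    ids = list(person_ids) if person_ids is not None else list(trajectories)
    counts = np.zeros(N_STATES)
    for pid in ids:
        traj = trajectories.get(int(pid))
        if traj is None:
            continue
        state = traj.intervals[0][2]
        if state == DISABILITY:
            raise ValueError(f"person {pid} starts in the absorbing state")
        w = 1.0 if weights is None else float(weights.loc[pid])
        counts[STATE_INDEX[state]] += w
    if counts.sum() == 0:
        raise EmptyGroupError("no observed starting states in the group")
    return counts / counts.sum()


@dataclass
class InitialStateModel:
    """Multinomial logistic model of the starting state.

    ``params`` has one column per non-reference state (states[1:]) and one
    row per design column (intercept first); the reference state is the
    first element of ``states``.
    """

    states: list[str]
    columns: list[str]  # design columns, 'const' first
    params: np.ndarray  # (p, k-1)

    def predict(self, pattern) -> np.ndarray:
        """5-vector of initial-state probabilities at a covariate pattern."""
        if isinstance(pattern, Mapping):
            x = np.array([1.0 if c == "const" else float(pattern.get(c, 0.0)) for c in self.columns])
        else:
            x = np.asarray(pattern, float)
        logits = np.concatenate([[0.0], x @ self.params])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        out = np.zeros(N_STATES)
        for state, prob in zip(self.states, p):
            out[STATE_INDEX[state]] = prob
        return out


def fit_initial_state_model(
    starting_states: pd.Series, design: pd.DataFrame
) -> InitialStateModel:
    """Fit the multinomial logistic starting-state model (Newton/statsmodels)."""
    import warnings

    import statsmodels.api as sm

    observed = [s for s in STATES if s in set(starting_states) and s != DISABILITY]
    if DISABILITY in set(starting_states):
        raise ValueError("disability is not a valid starting state")
    if len(observed) < 2:
        raise ValueError("need at least two observed starting states")
    y = starting_states.map({s: k for k, s in enumerate(observed)}).to_numpy()
    x = sm.add_constant(design.to_numpy(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.MNLogit(y, x).fit(method="newton", disp=False, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("multinomial starting-state model did not converge")
    params = np.asarray(res.params)
    if np.max(np.abs(params)) > 25:
        raise RuntimeError("separation in the multinomial starting-state model")
    return InitialStateModel(
        states=observed,
        columns=["const"] + list(design.columns),
        params=params,
    )


def initial_distribution(
    trajectories: Mapping[int, object],
    person_ids: Sequence[int] | None = None,
    mode: str = "empirical",
    weights: pd.Series | None = None,
    design: pd.DataFrame | None = None,
    pattern=None,
) -> np.ndarray:
    """Initial-state distribution, empirical or model-based.

    ``mode='empirical'`` returns (weighted) starting-state proportions;
    ``mode='model_based'`` fits a multinomial logistic regression of the
    starting state on ``design`` (rows indexed by person id) and evaluates it
    at ``pattern``.
    """
    if mode == "empirical":
        return empirical_initial_distribution(trajectories, person_ids, weights)
    if mode != "model_based":
        raise ValueError(f"unknown mode '{mode}'")
    if design is None or pattern is None:
        raise ValueError("model_based mode needs design and pattern")
    ids = [
        int(pid)
        for pid in (person_ids if person_ids is not None else list(trajectories))
        if trajectories.get(int(pid)) is not None
    ]
    if not ids:
        raise EmptyGroupError("no persons with observed starting states")
    states = pd.Series(
        [trajectories[pid].intervals[0][2] for pid in ids], index=ids
    )
    model = fit_initial_state_model(states, design.loc[ids])
    return model.predict(pattern)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


def _common_grid(a: StateProbabilityCurve, b: StateProbabilityCurve) -> np.ndarray:
    return np.unique(
        np.round(np.concatenate([a.times, b.times]), TIME_RESOLUTION_DECIMALS)
    )


def contrast_curves(
    curve_a: StateProbabilityCurve,
    curve_b: StateProbabilityCurve,
    kind: str = "difference",
    label: str = "",
) -> ContrastCurve:
    """Per-state difference (a - b) or ratio (a / b) on the union grid.

    Ratios with zero denominator are flagged undefined (NaN), never
    fabricated.
    """
    grid = _common_grid(curve_a, curve_b)
    pa, pb = curve_a.at(grid), curve_b.at(grid)
    if kind == "difference":
        values = pa - pb
    elif kind == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(pb > 0, pa / pb, np.nan)
    else:
        raise ValueError(f"unknown contrast kind '{kind}'")
    return ContrastCurve(times=grid, values=values, kind=kind, label=label)


def ratio_of_differences(
    diff_num: ContrastCurve, diff_den: ContrastCurve, label: str = ""
) -> ContrastCurve:
    """Ratio of two difference curves (e.g. weighted / unadjusted effect).

    Undefined (NaN) wherever the denominator difference is zero.
    """
    grid = np.unique(
        np.round(np.concatenate([diff_num.times, diff_den.times]), TIME_RESOLUTION_DECIMALS)
    )
    num, den = diff_num.at(grid), diff_den.at(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den != 0, num / den, np.nan)
    return ContrastCurve(
        times=grid, values=values, kind="ratio_of_differences", label=label
    )


# ---------------------------------------------------------------------------
# Bootstrap bands
# ---------------------------------------------------------------------------


def bootstrap_bands(
    estimate: Callable[[np.ndarray], np.ndarray],
    person_ids: Sequence[int],
    B: int,
    seed: int,
    alpha: float = 0.05,
) -> dict:
    """Pointwise percentile bands from person-level bootstrap resamples.

    ``estimate`` maps an array of (resampled, possibly repeated) person ids
    to a fixed-shape array of curve values.  Replicates raising
    :class:`EmptyGroupError` are skipped and counted.  Deterministic given
    ``seed``.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    ids = np.asarray(person_ids)
    rng = np.random.default_rng(seed)
    reps: list[np.ndarray] = []
    skipped = 0
    for _ in range(B):
        resample = rng.choice(ids, size=len(ids), replace=True)
        try:
            reps.append(np.asarray(estimate(resample), float))
        except EmptyGroupError:
            skipped += 1
    if not reps:
        raise EmptyGroupError("every bootstrap replicate had an empty group")
    stacked = np.stack(reps)
    return {
        "lower": np.nanpercentile(stacked, 100 * alpha / 2, axis=0),
        "upper": np.nanpercentile(stacked, 100 * (1 - alpha / 2), axis=0),
        "n_replicates": len(reps),
        "n_skipped": skipped,
    }
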