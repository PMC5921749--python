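"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own algorithms: precedence
resolution by pointwise evaluation on a fine grid, Cox estimation by direct
grid maximisation of the written-out partial likelihood, and random spell-set
generation for property tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODEL_STATES = ("work", "unemployment", "education", "sick_leave", "disability")
GAP_TYPES = ("emigration_gap", "paternal_leave")
PRECEDENCE = ("disability", "sick_leave", "unemployment", "work", "education")


def brute_force_state(spells: pd.DataFrame, t: np.ndarray, threshold: float = 2.0):
    """State at each time in ``t`` by direct pointwise precedence evaluation.

    Returns an object array with state labels, None where unobserved (gap
    active, or no spell covers t).  Gap-type spells dominate everything; a
    work spell with income below ``threshold`` ranks just below education.
    """
    t = np.asarray(t, float)
    active = (spells["start"].to_numpy()[:, None] <= t[None, :]) & (
        t[None, :] < spells["stop"].to_numpy()[:, None]
    )
    types = spells["spell_type"].to_numpy(object)
    income = (
        spells["annual_income_G"].to_numpy(float)
        if "annual_income_G" in spells
        else np.full(len(spells), np.nan)
    )
    rank = {s: i for i, s in enumerate(PRECEDENCE)}
    out = np.full(len(t), None, dtype=object)
    for k in range(len(t)):
        act = np.flatnonzero(active[:, k])
        if len(act) == 0:
            continue
        if any(types[i] in GAP_TYPES for i in act):
            continue
        best, best_rank = None, np.inf
        for i in act:
            s = types[i]
            if s not in MODEL_STATES:
                continue
            r = rank[s]
            if s == "work" and np.isfinite(income[i]) and income[i] < threshold:
                r = rank["education"] + 0.5
            if r < best_rank:
                best, best_rank = s, r
        out[k] = best
    return out


def random_spell_set(rng: np.random.Generator, horizon: float = 12.5) -> pd.DataFrame:
    """A random overlapping spell set respecting same-type non-overlap."""
    n_types = rng.integers(1, 5)
    chosen = rng.choice(len(MODEL_STATES) + len(GAP_TYPES), size=n_types, replace=False)
    all_types = MODEL_STATES + GAP_TYPES
    rows = []
    has_model = False
    for ti in chosen:
        stype = all_types[ti]
        k = int(rng.integers(1, 4))
        points = np.sort(rng.uniform(0, horizon, 2 * k))
        for j in range(k):
            start, stop = points[2 * j], points[2 * j + 1]
            if stop - start < 1e-3:
                continue
            inc = float(rng.uniform(0.3, 5.0)) if stype == "work" else np.nan
            rows.append((0, stype, start, stop, inc))
            if stype in MODEL_STATES:
                has_model = True
    if not has_model:  # guarantee resolvability
        rows.append((0, "work", 0.0, horizon, float(rng.uniform(0.3, 5.0))))
    return pd.DataFrame(
        rows, columns=["person_id", "spell_type", "start", "stop", "annual_income_G"]
    )


def grid_cox_loglik(
    entry: np.ndarray,
    exit_: np.ndarray,
    status: np.ndarray,
    x: np.ndarray,
    betas: np.ndarray,
) -> np.ndarray:
    """Breslow log partial likelihood on a grid of scalar coefficients.

    Written out directly from its definition: for each event time u,
    contribute x_i * beta - d_u * log(sum_{at risk} exp(x_j * beta)),
    pooling tied events (Breslow).
    """
    lls = np.zeros(len(betas))
    event_times = np.unique(exit_[status == 1])
    for b_idx, beta in enumerate(betas):
        r = np.exp(x * beta)
        ll = 0.0
        for u in event_times:
            events = (status == 1) & (exit_ == u)
            at_risk = (entry < u) & (u <= exit_)
            ll += np.sum(x[events]) * beta - events.sum() * np.log(r[at_risk].sum())
        lls[b_idx] = ll
    return lls
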