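"""From overlapping registry spells to resolved state trajectories and
counting-process transition data.

Registry episodes overlap freely (a person can hold a part-time job while
enrolled, or receive sick-leave benefits during an employment spell).  The
model requires exactly one state at every time point, so concurrent spells
are resolved by precedence — disability > sick leave > unemployment > work >
education — with the 2G income exception: a work spell paying under 2G per
year loses to concurrent education.  Emigration and paternal-leave spells
temporarily remove the person from observation and become recorded gaps with
left-truncated re-entry.

The module also applies the cohort exclusion pipeline (pre-start emigrants,
non-starters of upper secondary education, missing conscript or parental
socioeconomic data, invalid follow-up), enforces the structural transition
rules (absorbing disability; no direct work/education -> disability jumps),
and emits the long-format counting-process table feeding the hazard
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import DESIGN_COLUMNS, encode_covariates
from .states import (
    ALLOWED_TRANSITIONS,
    DEFAULT_INCOME_THRESHOLD_G,
    DISABILITY,
    EDUCATION,
    GAP_TYPES,
    PRECEDENCE_RANK,
    STATES,
    WORK,
)

_TIME_EPS = 1e-12


class NeverObservedError(ValueError):
    """Raised when a person has no model-state spell at all."""


@dataclass
class StateTrajectory:
    """Resolved, non-overlapping state history of one person.

    ``intervals`` are half-open ``[start, stop)`` tuples ``(start, stop,
    state)``, contiguous except across recorded observation ``gaps``.  A
    transition happens at the stop of the origin interval.
    """

    person_id: int
    intervals: list[tuple[float, float, str]]
    gaps: list[tuple[float, float]] = field(default_factory=list)
    edits: list[str] = field(default_factory=list)

    @property
    def entry_time(self) -> float:
        return self.intervals[0][0]

    @property
    def censor_time(self) -> float:
        return self.intervals[-1][1]

    def state_at(self, t: float) -> str | None:
        """State occupied at time t, or None if not under observation."""
        for start, stop, state in self.intervals:
            if start <= t < stop:
                return state
        return None

    def observed_time(self) -> float:
        return sum(stop - start for start, stop, _ in self.intervals)


@dataclass
class FlowReport:
    """Step-by-step record of the exclusion pipeline."""

    n_initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # label, removed, left

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_initial

    def add(self, label: str, n_removed: int) -> None:
        remaining = (self.steps[-1][2] if self.steps else self.n_initial) - n_removed
        self.steps.append((label, n_removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed", "n_remaining"])

    def __str__(self) -> str:
        lines = [f"initial cohort: {self.n_initial}"]
        for label, removed, remaining in self.steps:
            lines.append(f"  - {label}: removed {removed}, remaining {remaining}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Precedence resolution
# ---------------------------------------------------------------------------


def resolve_states(
    spells: pd.DataFrame,
    income_threshold_G: float = DEFAULT_INCOME_THRESHOLD_G,
) -> StateTrajectory:
    """Resolve one person's overlapping spells into a single state path.

    At every instant the resolved state is the active spell type of highest
    precedence, except that an education spell outranks a concurrent work
    spell whose ``annual_income_G`` is below ``income_threshold_G``.
    Gap-type spells (emigration, paternal leave) outrank everything and
    produce recorded gaps; so do stretches covered by no spell between the
    first and last observation.  Adjacent same-state intervals are merged and
    zero-length fragments dropped.

    Raises
    ------
    NeverObservedError
        If no model-state spell exists for the person.
    ValueError
        If any spell has ``stop <= start``.
    """
    pid = int(spells["person_id"].iloc[0]) if "person_id" in spells and len(spells) else -1
    starts = spells["start"].to_numpy(float)
    stops = spells["stop"].to_numpy(float)
    types = spells["spell_type"].to_numpy(object)
    income = (
        spells["annual_income_G"].to_numpy(float)
        if "annual_income_G" in spells
        else np.full(len(spells), np.nan)
    )
    if np.any(stops <= starts) or not (
        np.all(np.isfinite(starts)) and np.all(np.isfinite(stops))
    ):
        raise ValueError(f"person {pid}: spell with stop <= start or non-finite times")
    if not any(t in STATES for t in types):
        raise NeverObservedError(f"person {pid}: no model-state spell observed")

    bounds = np.unique(np.concatenate([starts, stops]))
    segments: list[tuple[float, float, str | None]] = []  # state or None = gap
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi - lo <= _TIME_EPS:
            continue
        active = (starts <= lo + _TIME_EPS) & (stops >= hi - _TIME_EPS)
        act_types = types[active]
        if any(t in GAP_TYPES for t in act_types):
            segments.append((lo, hi, None))
            continue
        best: str | None = None
        best_rank = len(PRECEDENCE_RANK) + 1
        for t, inc in zip(act_types, income[active]):
            if t not in STATES:
                continue
            rank = PRECEDENCE_RANK[t]
            if t == WORK and not np.isnan(inc) and inc < income_threshold_G:
                # sub-2G work ranks just below education
                rank = PRECEDENCE_RANK[EDUCATION] + 0.5
            if rank < best_rank:
                best, best_rank = t, rank
        segments.append((lo, hi, best))

    # trim leading/trailing unobserved stretches
    while segments and segments[0][2] is None:
        segments.pop(0)
    while segments and segments[-1][2] is None:
        segments.pop()
    if not segments:
        raise NeverObservedError(f"person {pid}: observed only in gap spells")

    intervals: list[tuple[float, float, str]] = []
    gaps: list[tuple[float, float]] = []
    for lo, hi, state in segments:
        if state is None:
            if gaps and abs(gaps[-1][1] - lo) <= _TIME_EPS:
                gaps[-1] = (gaps[-1][0], hi)
            else:
                gaps.append((lo, hi))
        elif (
            intervals
            and intervals[-1][2] == state
            and abs(intervals[-1][1] - lo) <= _TIME_EPS
        ):
            intervals[-1] = (intervals[-1][0], hi, state)
        else:
            intervals.append((lo, hi, state))
    return StateTrajectory(person_id=pid, intervals=intervals, gaps=gaps)


def resolve_all(
    spell_table: pd.DataFrame,
    income_threshold_G: float = DEFAULT_INCOME_THRESHOLD_G,
) -> dict[int, StateTrajectory | None]:
    """Resolve every person in a spell table.

    Persons never observed in a model state map to ``None`` (they are
    removed later by :func:`apply_exclusions` as invalid follow-up).
    """
    out: dict[int, StateTrajectory | None] = {}
    for pid, group in spell_table.groupby("person_id", sort=True):
        try:
            out[int(pid)] = resolve_states(group, income_threshold_G)
        except NeverObservedError:
            out[int(pid)] = None
    return out


# ---------------------------------------------------------------------------
# Structural transition rules
# ---------------------------------------------------------------------------


def enforce_transition_rules(trajectory: StateTrajectory) -> StateTrajectory:
    """Make disability absorbing and censor artefactual direct entries.

    Any interval after the first disability entry is absorbed into
    disability (extended to the censor time).  A direct work->disability or
    education->disability jump is treated as an administrative artefact: the
    trajectory is censored at the jump time.  Re-entry into disability after
    an observation gap is accepted (the origin state is unknown).  All edits
    are logged on the returned trajectory.
    """
    iv = trajectory.intervals
    edits = list(trajectory.edits)
    dis_idx = next((k for k, (_, _, s) in enumerate(iv) if s == DISABILITY), None)
    if dis_idx is None:
        return trajectory

    if dis_idx > 0:
        prev = iv[dis_idx - 1]
        contiguous = abs(prev[1] - iv[dis_idx][0]) <= _TIME_EPS
        if contiguous and prev[2] in (WORK, EDUCATION):
            t_jump = iv[dis_idx][0]
            edits.append(
                f"censored at t={t_jump:.6g}: direct {prev[2]}->disability jump"
            )
            return StateTrajectory(
                person_id=trajectory.person_id,
                intervals=iv[:dis_idx],
                gaps=[g for g in trajectory.gaps if g[0] < t_jump],
                edits=edits,
            )

    censor = trajectory.censor_time
    new_iv = iv[: dis_idx + 1]
    if dis_idx < len(iv) - 1 or new_iv[-1][1] < censor:
        edits.append(
            f"disability made absorbing from t={new_iv[-1][0]:.6g} to censor time"
        )
    new_iv[-1] = (new_iv[-1][0], censor, DISABILITY)
    gaps = [g for g in trajectory.gaps if g[1] <= new_iv[-1][0] + _TIME_EPS]
    return StateTrajectory(
        person_id=trajectory.person_id, intervals=new_iv, gaps=gaps, edits=edits
    )


# ---------------------------------------------------------------------------
# Exclusion pipeline
# ---------------------------------------------------------------------------

EXCLUSION_STEPS: tuple[tuple[str, str], ...] = (
    ("emigrated before study start", "pre_start_emigration"),
    ("did not start upper secondary education before age 21", "no_upper_secondary_start"),
    ("missing conscript data", "missing_conscript_data"),
    ("missing parental education or income", "missing_parental_sep"),
)


def apply_exclusions(
    cohort: pd.DataFrame,
    trajectories: dict[int, StateTrajectory | None],
) -> tuple[pd.DataFrame, FlowReport]:
    """Apply the cohort exclusion pipeline in its fixed order.

    Flag-based steps (pre-start emigration, not starting upper secondary,
    missing conscript data, missing parental SEP) are followed by the
    invalid-follow-up step, which removes persons never observed in a model
    state (e.g. only on paternal leave) or whose first resolved state is
    disability.  Counts are order-dependent.
    """
    report = FlowReport(n_initial=len(cohort))
    kept = cohort
    for label, flag in EXCLUSION_STEPS:
        if flag in kept.columns:
            removed = kept[flag].astype(bool)
            report.add(label, int(removed.sum()))
            kept = kept[~removed]
        else:
            report.add(label, 0)

    def invalid(pid: int) -> bool:
        traj = trajectories.get(int(pid))
        return traj is None or traj.intervals[0][2] == DISABILITY

    bad = kept["person_id"].map(invalid).astype(bool)
    report.add("invalid follow-up (starts in disability or never observed)", int(bad.sum()))
    kept = kept[~bad].reset_index(drop=True)
    return kept, report


# ---------------------------------------------------------------------------
# Counting-process export and design matrix
# ---------------------------------------------------------------------------


def build_design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Reference-cell encoded covariate matrix, indexed by person id.

    Columns are the fixed 24-column design: the 0/1 exposure indicator
    followed by the 23 dummy/continuous baseline covariate columns.
    """
    design = encode_covariates(cohort, include_exposure=True)
    design.index = pd.Index(cohort["person_id"].to_numpy(), name="person_id")
    return design[list(DESIGN_COLUMNS)]


def to_counting_process(
    trajectories: dict[int, StateTrajectory | None],
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format counting-process rows for all persons in ``cohort``.

    For every trajectory interval in transient state ``h`` there is one row
    per allowed transition ``h -> j`` with ``entry``/``exit`` equal to the
    interval bounds and ``status`` 1 only on the realised transition (a
    transition is realised when the next interval starts exactly where this
    one stops; gaps and censoring yield all-zero rows, and re-entry after a
    gap opens a new left-truncated at-risk period).  Covariate columns from
    the cohort design matrix and a unit ``weight`` column are attached.
    """
    design = build_design_matrix(cohort)
    records: list[tuple[int, str, float, float, object]] = []
    for pid in cohort["person_id"]:
        traj = trajectories.get(int(pid))
        if traj is None:
            continue
        iv = traj.intervals
        for k, (start, stop, state) in enumerate(iv):
            if state == DISABILITY:
                continue  # absorbing: no at-risk rows
            if state not in STATES:
                raise ValueError(f"person {pid}: unknown state '{state}'")
            event_to = None
            if k + 1 < len(iv) and abs(iv[k + 1][0] - stop) <= _TIME_EPS:
                event_to = iv[k + 1][2]
            records.append((int(pid), state, float(start), float(stop), event_to))

    intervals = pd.DataFrame(
        records, columns=["person_id", "from_state", "entry", "exit", "event_to"]
    )
    trans = pd.DataFrame(ALLOWED_TRANSITIONS, columns=["from_state", "to_state"])
    table = intervals.merge(trans, on="from_state", how="inner")
    table["status"] = (table["event_to"] == table["to_state"]).astype(int)
    table = table.drop(columns="event_to")
    table = table.merge(design, left_on="person_id", right_index=True, how="left")
    table["weight"] = 1.0
    return table.sort_values(["person_id", "entry", "from_state", "to_state"]).reset_index(
        drop=True
    )


def trajectories_from_counting_process(
    table: pd.DataFrame,
) -> dict[int, list[tuple[float, float | None, str]]]:
    """Reconstruct interval sequences from status-1 rows plus censoring.

    Inverse of :func:`to_counting_process`, used for round-trip validation:
    returns ``{person_id: [(start, stop, state), ...]}``.  A terminal jump
    into absorbing disability is reconstructed as a final interval with
    ``stop = None``, since absorbed time generates no at-risk rows.
    """
    out: dict[int, list[tuple[float, float | None, str]]] = {}
    for pid, group in table.groupby("person_id", sort=True):
        ivs: list[tuple[float, float | None, str]] = []
        final_dest: str | None = None
        for (entry, exit_, from_state), period in group.groupby(
            ["entry", "exit", "from_state"], sort=True
        ):
            n_events = int(period["status"].sum())
            if n_events > 1:
                raise ValueError(f"person {pid}: multiple events in one at-risk period")
            ivs.append((float(entry), float(exit_), str(from_state)))
            if n_events == 1:
                final_dest = str(period.loc[period["status"] == 1, "to_state"].iloc[0])
            else:
                final_dest = None
        if final_dest == DISABILITY:
            ivs.append((ivs[-1][1], None, DISABILITY))
        out[int(pid)] = ivs
    return out
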