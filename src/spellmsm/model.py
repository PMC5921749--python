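"""High-level Model/Results interface to the multi-state machinery.

:class:`MultiStateModel` is built from data (a counting-process transition
table, or raw spells plus a cohort via :meth:`MultiStateModel.from_spells`);
``fit()`` estimates all transition-specific cumulative hazards and returns a
:class:`MultiStateResults` carrying the fitted intensity path, from which
state occupation probability curves, transition probability matrices and
summary tables are derived.  Weighted (IPTW) fits take a per-person weight
Series; covariate-conditional fits go through
:class:`spellmsm.hazards.TransitionCoxModel` and feed their predicted
hazards back into the same product-integral machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import trajectories as tb
from .hazards import CumulativeHazard, nelson_aalen
from .probabilities import (
    IntensityPath,
    StateProbabilityCurve,
    build_intensity_path,
    empirical_initial_distribution,
    product_integral,
    state_probabilities,
)
from .states import ALLOWED_TRANSITIONS, transition_label


class MultiStateModel:
    """Nonparametric multi-state model on a counting-process table.

    Parameters
    ----------
    transitions
        Long-format table with one row per person x at-risk period x allowed
        transition (see :func:`spellmsm.trajectories.to_counting_process`).
    trajectories
        Optional mapping person id -> resolved trajectory; needed for
        empirical initial distributions.
    weights
        Optional per-person weight Series (e.g. IPT weights).
    """

    def __init__(
        self,
        transitions: pd.DataFrame,
        trajectories: Mapping[int, object] | None = None,
        weights: pd.Series | None = None,
    ):
        self.transitions = transitions
        self.trajectories = trajectories
        self.weights = weights
        self.flow_report: tb.FlowReport | None = None
        self.cohort: pd.DataFrame | None = None

    @classmethod
    def from_spells(
        cls,
        spells: pd.DataFrame,
        cohort: pd.DataFrame,
        income_threshold_G: float = 2.0,
        weights: pd.Series | None = None,
    ) -> "MultiStateModel":
        """Run the full trajectory builder: precedence resolution, structural
        transition rules, the exclusion pipeline, and counting-process export.
        """
        resolved = tb.resolve_all(spells, income_threshold_G)
        enforced = {
            pid: (tb.enforce_transition_rules(traj) if traj is not None else None)
            for pid, traj in resolved.items()
        }
        kept, report = tb.apply_exclusions(cohort, enforced)
        table = tb.to_counting_process(enforced, kept)
        model = cls(
            table,
            trajectories={int(p): enforced[int(p)] for p in kept["person_id"]},
            weights=weights,
        )
        model.flow_report = report
        model.cohort = kept
        return model

    def fit(self) -> "MultiStateResults":
        """Estimate all transition hazards by (weighted) Nelson-Aalen."""
        hazards: dict[tuple[str, str], CumulativeHazard] = {}
        present = set(
            map(tuple, self.transitions[["from_state", "to_state"]].drop_duplicates().to_numpy())
        )
        for tr in ALLOWED_TRANSITIONS:
            if tr not in present:
                continue
            hz = nelson_aalen(self.transitions, tr, weights=self.weights)
            if len(hz.times):
                hazards[tr] = hz
        return MultiStateResults(model=self, hazards=hazards)


@dataclass
class MultiStateResults:
    """Fitted transition hazards and derived probability estimates."""

    model: MultiStateModel
    hazards: dict[tuple[str, str], CumulativeHazard]
    _path: IntensityPath | None = field(default=None, repr=False)

    @property
    def intensity_path(self) -> IntensityPath:
        if self._path is None:
            self._path = build_intensity_path(self.hazards)
        return self._path

    def transition_matrix(self, s: float, t: float) -> np.ndarray:
        """Aalen-Johansen estimate of P(s, t)."""
        return product_integral(self.intensity_path, s, t)

    def initial_distribution(self, person_ids: Sequence[int] | None = None) -> np.ndarray:
        if self.model.trajectories is None:
            raise ValueError("model was built without trajectories")
        return empirical_initial_distribution(
            self.model.trajectories, person_ids, self.model.weights
        )

    def state_probability_curve(
        self,
        init: np.ndarray | None = None,
        times: Sequence[float] | None = None,
        label: str = "",
    ) -> StateProbabilityCurve:
        """Occupation probability curve P(X(t) = j) from time 0."""
        if init is None:
            init = self.initial_distribution()
        return state_probabilities(self.intensity_path, init, times, label=label)

    def summary(self) -> pd.DataFrame:
        """Per-transition event counts and cumulative hazards at end of
        follow-up."""
        rows = []
        for tr, hz in sorted(self.hazards.items()):
            rows.append(
                {
                    "transition": transition_label(tr),
                    "n_jumps": len(hz.times),
                    "last_event_time": hz.times[-1],
                    "cumulative_hazard": hz.cumulative()[-1],
                    "weighted": hz.weighted,
                }
            )
        return pd.DataFrame(rows).set_index("transition")
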