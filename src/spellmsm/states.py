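"""State space, allowed transitions and precedence rules of the five-state
work/health/education process.

The model follows individuals through five labour-market and health states:
``work``, ``unemployment``, ``education`` (tertiary), ``sick_leave`` and
``disability`` (disability pension).  Disability is absorbing, and direct
entries into disability are only possible from unemployment and sick leave;
direct jumps from work or education are treated as administrative artefacts
and are not modelled.  This yields 14 allowed transitions.

When a person holds several spells simultaneously, a single state is chosen
by precedence: disability > sick leave > unemployment > work > education,
with one exception — a work spell paying less than 2G per year (G being the
Norwegian social-insurance base amount) loses to a concurrent education
spell, so part-time-working students count as students.
"""

from __future__ import annotations

WORK = "work"
UNEMPLOYMENT = "unemployment"
EDUCATION = "education"
SICK_LEAVE = "sick_leave"
DISABILITY = "disability"

#: Canonical state order used for every vector/matrix in the package.
STATES: tuple[str, ...] = (WORK, UNEMPLOYMENT, EDUCATION, SICK_LEAVE, DISABILITY)
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: Spell types that remove a person from observation while active.
GAP_TYPES: tuple[str, ...] = ("emigration_gap", "paternal_leave")
SPELL_TYPES: tuple[str, ...] = STATES + GAP_TYPES

#: Precedence when concurrent spells compete, highest first.
PRECEDENCE: tuple[str, ...] = (DISABILITY, SICK_LEAVE, UNEMPLOYMENT, WORK, EDUCATION)
PRECEDENCE_RANK: dict[str, int] = {s: i for i, s in enumerate(PRECEDENCE)}

#: Work income below this many G makes education outrank work.
DEFAULT_INCOME_THRESHOLD_G = 2.0

# The four transient states communicate freely; disability is entered only
# from unemployment and sick leave and never left.
_TRANSIENT = (WORK, UNEMPLOYMENT, EDUCATION, SICK_LEAVE)
ALLOWED_TRANSITIONS: tuple[tuple[str, str], ...] = tuple(
    (h, j) for h in _TRANSIENT for j in _TRANSIENT if h != j
) + ((UNEMPLOYMENT, DISABILITY), (SICK_LEAVE, DISABILITY))

assert len(ALLOWED_TRANSITIONS) == 14

#: Allowed destinations per origin state, in canonical order.
TRANSITIONS_FROM: dict[str, tuple[str, ...]] = {
    h: tuple(j for (h2, j) in ALLOWED_TRANSITIONS if h2 == h) for h in STATES
}


def transition_label(transition: tuple[str, str]) -> str:
    """Human-readable label, e.g. ``'work->unemployment'``."""
    return f"{transition[0]}->{transition[1]}"


def validate_transitions(transitions) -> None:
    """Raise ``ValueError`` if any pair violates the model structure."""
    for h, j in transitions:
        if h == DISABILITY:
            raise ValueError(
                f"transition out of the absorbing disability state: {(h, j)}"
            )
        if (h, j) in ((WORK, DISABILITY), (EDUCATION, DISABILITY)):
            raise ValueError(
                f"direct transition into disability from {h} is not allowed"
            )
        if (h, j) not in ALLOWED_TRANSITIONS:
            raise ValueError(f"unknown transition {(h, j)}")
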