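"""Declarative multi-state spaces and stacked long-format transition data.

A :class:`StateSpace` is a directed acyclic graph of clinical states.  The
three builders encode the trial models used throughout the package:

* :func:`model1_offprotocol` — off-protocol treatment as a proxy of severe
  treatment-related toxicity;
* :func:`model1_extended` — the same with on-protocol alloSCT and maintenance
  treatment as additional intermediate states;
* :func:`model2_mrd` — MRD-negativity at consolidation as the intermediate
  event of interest (off-protocol is deliberately not a state here).

:func:`stack_transitions` converts patient records into the standard stacked
("long") format for multi-state analysis: per patient and per occupied state,
one row for every transition the patient is at risk of, all sharing the same
half-open study-time interval ``(t_start, t_stop]``, with exactly one row of
``status=1`` if the state was left by an observed transition.  The time scale
is clock-forward (days since the start of induction & consolidation), never
reset at a state entry, matching a time-inhomogeneous Markov model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .event_history import PatientRecord

logger = logging.getLogger(__name__)

#: canonical state names
IND_CONS = "Ind&Cons"
OFF_PROTOCOL = "OffProtocol"
MRD_NEG = "MRDneg"
ALLO_SCT = "alloSCT"
MAINTENANCE = "Maintenance"
REL_REFRACTORY = "R/R"
RELAPSE_MORTALITY = "RM"
NONRELAPSE_MORTALITY = "NRM"

#: minimal sojourn (days) granted when a state is entered and left the same day
HALF_DAY = 0.5

#: columns of the stacked transition table
TABLE_COLUMNS = (
    "patient_id",
    "transition_id",
    "from_state",
    "to_state",
    "t_start",
    "t_stop",
    "status",
    "arm",
)


class StateSpaceError(ValueError):
    """The state-space definition violates an invariant."""


class PathError(ValueError):
    """A patient's event sequence is incompatible with the state space."""


@dataclass(frozen=True)
class StateSpace:
    """Named states and allowed numbered transitions of a multi-state model.

    The first state is the start state.  Transition ids are 1-based in the
    listed order.  Absorbing states are those with no outgoing transitions.
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(
            self, "transitions", tuple((a, b) for a, b in self.transitions)
        )
        self._validate()

    def _validate(self) -> None:
        if not self.states:
            raise StateSpaceError("no states")
        if len(set(self.states)) != len(self.states):
            raise StateSpaceError("duplicate state names")
        known = set(self.states)
        for frm, to in self.transitions:
            if frm not in known or to not in known:
                raise StateSpaceError(f"transition ({frm!r}, {to!r}) uses unknown state")
            if frm == to:
                raise StateSpaceError(f"self-loop on {frm!r}")
        if len(set(self.transitions)) != len(self.transitions):
            raise StateSpaceError("duplicate transitions")
        # acyclicity by DFS from every node
        out = self.outgoing
        color: dict[str, int] = {}

        def dfs(node: str, stack: set[str]) -> None:
            if node in stack:
                raise StateSpaceError(f"cycle through {node!r}")
            if color.get(node):
                return
            stack.add(node)
            for nxt in out.get(node, ()):
                dfs(nxt, stack)
            stack.discard(node)
            color[node] = 1

        for s in self.states:
            dfs(s, set())
        # reachability of every non-start state
        reach = {self.start}
        frontier = [self.start]
        while frontier:
            node = frontier.pop()
            for nxt in out.get(node, ()):
                if nxt not in reach:
                    reach.add(nxt)
                    frontier.append(nxt)
        unreachable = [s for s in self.states if s not in reach]
        if unreachable:
            raise StateSpaceError(f"unreachable state(s): {unreachable}")

    @property
    def start(self) -> str:
        return self.states[0]

    @property
    def outgoing(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {s: [] for s in self.states}
        for frm, to in self.transitions:
            out[frm].append(to)
        return {s: tuple(v) for s, v in out.items()}

    @property
    def absorbing(self) -> frozenset[str]:
        out = self.outgoing
        return frozenset(s for s in self.states if not out[s])

    @property
    def transition_ids(self) -> dict[tuple[str, str], int]:
        """Map (from_state, to_state) -> 1-based transition id."""
        return {pair: i + 1 for i, pair in enumerate(self.transitions)}

    def transition_label(self, transition_id: int) -> tuple[str, str]:
        return self.transitions[transition_id - 1]

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "transitions": [list(pair) for pair in self.transitions],
        }

    @classmethod
    def from_config(cls, config: dict) -> "StateSpace":
        return cls(
            states=tuple(config["states"]),
            transitions=tuple((a, b) for a, b in config["transitions"]),
            name=config.get("name", "custom"),
        )


def model1_offprotocol() -> StateSpace:
    """Off-protocol model: toxicity proxied by leaving protocol treatment.

    Off-protocol and relapsed/refractory disease are intermediate states;
    relapse mortality and non-relapse mortality are absorbing end states.
    """
    return StateSpace(
        states=(IND_CONS, OFF_PROTOCOL, REL_REFRACTORY, RELAPSE_MORTALITY, NONRELAPSE_MORTALITY),
        transitions=(
            (IND_CONS, OFF_PROTOCOL),
            (IND_CONS, REL_REFRACTORY),
            (IND_CONS, NONRELAPSE_MORTALITY),
            (OFF_PROTOCOL, REL_REFRACTORY),
            (OFF_PROTOCOL, NONRELAPSE_MORTALITY),
            (REL_REFRACTORY, RELAPSE_MORTALITY),
        ),
        name="offprotocol",
    )


def model1_extended(
    extra_transitions: Optional[Sequence[tuple[str, str]]] = None,
) -> StateSpace:
    """Extended off-protocol model with alloSCT and maintenance as states.

    Splits the off-protocol risk by treatment phase (induction/consolidation
    versus maintenance).  The default edge set routes patients from the start
    state into on-protocol alloSCT or maintenance, and allows going
    off-protocol from both the start state and maintenance; it can be
    overridden by passing the full transition list.
    """
    transitions = (
        (IND_CONS, OFF_PROTOCOL),
        (IND_CONS, ALLO_SCT),
        (IND_CONS, MAINTENANCE),
        (IND_CONS, REL_REFRACTORY),
        (IND_CONS, NONRELAPSE_MORTALITY),
        (ALLO_SCT, REL_REFRACTORY),
        (ALLO_SCT, NONRELAPSE_MORTALITY),
        (MAINTENANCE, OFF_PROTOCOL),
        (MAINTENANCE, REL_REFRACTORY),
        (MAINTENANCE, NONRELAPSE_MORTALITY),
        (OFF_PROTOCOL, REL_REFRACTORY),
        (OFF_PROTOCOL, NONRELAPSE_MORTALITY),
        (REL_REFRACTORY, RELAPSE_MORTALITY),
    )
    if extra_transitions is not None:
        transitions = tuple((a, b) for a, b in extra_transitions)
    return StateSpace(
        states=(
            IND_CONS,
            ALLO_SCT,
            MAINTENANCE,
            OFF_PROTOCOL,
            REL_REFRACTORY,
            RELAPSE_MORTALITY,
            NONRELAPSE_MORTALITY,
        ),
        transitions=transitions,
        name="offprotocol-extended",
    )


def model2_mrd() -> StateSpace:
    """MRD model: MRD-negativity at consolidation as the intermediate event.

    Patients without an MRD-negativity time (missing or positive MRD) never
    enter the MRD-negativity state.  Off-protocol is not a state here.
    """
    return StateSpace(
        states=(IND_CONS, MRD_NEG, REL_REFRACTORY, RELAPSE_MORTALITY, NONRELAPSE_MORTALITY),
        transitions=(
            (IND_CONS, MRD_NEG),
            (IND_CONS, REL_REFRACTORY),
            (IND_CONS, NONRELAPSE_MORTALITY),
            (MRD_NEG, REL_REFRACTORY),
            (MRD_NEG, NONRELAPSE_MORTALITY),
            (REL_REFRACTORY, RELAPSE_MORTALITY),
        ),
        name="mrd",
    )


# record field -> state it enters; order breaks same-day ties among state
# entries (death is always ordered last, after any state entry that day)
_ENTRY_FIELDS = (
    ("t_mrdneg", MRD_NEG),
    ("t_allosct_onprotocol", ALLO_SCT),
    ("t_maintenance", MAINTENANCE),
    ("t_offprotocol", OFF_PROTOCOL),
    ("t_relrefractory", REL_REFRACTORY),
)


def state_path(record: PatientRecord, space: StateSpace) -> list[tuple[str, float]]:
    """The sequence of (state, entry_time) a record traces through ``space``.

    Event times mapping to states absent from ``space`` are skipped (e.g.
    off-protocol under the MRD model).  Same-day entry and exit of a state is
    resolved by granting a minimal half-day sojourn, so entry times along the
    path are strictly increasing.  Raises :class:`PathError` when the record
    implies a move along a missing edge.
    """
    events: list[tuple[float, int, str]] = []
    for priority, (fld, state) in enumerate(_ENTRY_FIELDS):
        t = getattr(record, fld)
        if t is not None and state in space.states:
            events.append((t, priority, state))
    if record.t_death is not None:
        dead_state = (
            RELAPSE_MORTALITY
            if record.death_is_relapse_mortality
            else NONRELAPSE_MORTALITY
        )
        events.append((record.t_death, len(_ENTRY_FIELDS), dead_state))
    events.sort()

    edges = set(space.transitions)
    path: list[tuple[str, float]] = [(space.start, 0.0)]
    for t, _, state in events:
        cur, cur_t = path[-1]
        if (cur, state) not in edges:
            raise PathError(
                f"patient {record.patient_id!r}: no transition "
                f"{cur!r} -> {state!r} in state space {space.name!r}"
            )
        entry = t if t > cur_t else cur_t + HALF_DAY
        if entry > t:
            logger.debug(
                "patient %r: same-day move %s->%s at day %g given a half-day sojourn",
                record.patient_id, cur, state, t,
            )
        path.append((state, entry))
    return path


def stack_transitions(
    records: Sequence[PatientRecord], space: StateSpace
) -> pd.DataFrame:
    """Build the stacked long-format transition table for ``records``.

    Returns a DataFrame with columns ``patient_id, transition_id, from_state,
    to_state, t_start, t_stop, status, arm``.  For each patient and each
    non-absorbing state they occupy, one row per outgoing transition is
    emitted on the shared half-open interval ``(t_start, t_stop]``; the row of
    the realized transition (if any) has ``status=1``, all competing rows 0.
    Censoring at last contact yields all-zero statuses for the final state.
    """
    out = space.outgoing
    tids = space.transition_ids
    rows: list[tuple] = []
    for rec in records:
        path = state_path(rec, space)
        for i, (state, entry) in enumerate(path):
            if state in space.absorbing:
                continue
            if i + 1 < len(path):
                nxt_state, nxt_t = path[i + 1]
            else:
                nxt_state = None
                nxt_t = rec.t_lastcontact
                if nxt_t <= entry:  # death/censoring on the entry day
                    nxt_t = entry + HALF_DAY
            for to in out[state]:
                rows.append(
                    (
                        rec.patient_id,
                        tids[(state, to)],
                        state,
                        to,
                        entry,
                        nxt_t,
                        1 if to == nxt_state else 0,
                        rec.arm,
                    )
                )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return table


def collapse_paths(table: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    """Reconstruct each patient's state path from a stacked table.

    Inverse of the stacking step (up to the final censoring time): returns,
    per patient, the sequence of (state, entry_time) implied by the status-1
    rows.  Used for consistency checking.
    """
    paths: dict[str, list[tuple[str, float]]] = {}
    for pid, sub in table.groupby("patient_id", sort=False):
        sub = sub.sort_values(["t_start", "t_stop"], kind="stable")
        first = sub.iloc[0]
        path = [(first["from_state"], float(first["t_start"]))]
        for _, row in sub[sub["status"] == 1].sort_values("t_stop").iterrows():
            path.append((row["to_state"], float(row["t_stop"])))
        paths[pid] = path
    return paths
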