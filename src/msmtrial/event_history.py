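"""Patient-level event-history records: data model, delimited-text I/O, validation.

One record per randomized patient. All event times are measured in days from
the start of induction & consolidation chemotherapy (study time, "clock
forward"); there is no calendar-date handling. An empty cell in the delimited
file means the event never occurred (or, for MRD, was never observed).

Column schema (comma-separated by default, header required)::

    patient_id            opaque string, unique within a file
    arm                   "control" or "CLO"
    t_offprotocol         day of going off-protocol (empty = never)
    offprotocol_reason    one of {toxicity, delay, diagnosis_revision,
                          response_revision}; only if t_offprotocol present
    t_mrdneg              day of reaching MRD-negativity (<1e-4 by flow/PCR)
    mrd_assessed          0/1; whether an MRD result exists.  Empty defaults
                          to 1 when t_mrdneg is present, else 0.  Patients
                          with mrd_assessed=1 and empty t_mrdneg are known
                          MRD-positive.
    t_allosct_onprotocol  day of on-protocol allogeneic SCT (empty = none)
    t_maintenance         day of starting maintenance treatment
    t_relrefractory       day of relapse or refractory disease
    t_death               day of death; must equal t_lastcontact
    t_lastcontact         required; last day the patient was known alive,
                          or day of death

Unknown columns are ignored with a logged warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("control", "CLO")
OFFPROTOCOL_REASONS = ("toxicity", "delay", "diagnosis_revision", "response_revision")

#: canonical column order of the delimited-text schema
COLUMNS = (
    "patient_id",
    "arm",
    "t_offprotocol",
    "offprotocol_reason",
    "t_mrdneg",
    "mrd_assessed",
    "t_allosct_onprotocol",
    "t_maintenance",
    "t_relrefractory",
    "t_death",
    "t_lastcontact",
)

_TIME_FIELDS = (
    "t_offprotocol",
    "t_mrdneg",
    "t_allosct_onprotocol",
    "t_maintenance",
    "t_relrefractory",
    "t_death",
)


class SchemaError(ValueError):
    """The input file does not match the documented column schema."""


class ValidationError(ValueError):
    """One or more rows violate the record invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """A single patient's randomization arm and dated event history.

    Times are days from the start of induction & consolidation; ``None``
    means the event did not occur (or was not observed) before last contact.
    """

    patient_id: str
    arm: str
    t_lastcontact: float
    t_offprotocol: Optional[float] = None
    offprotocol_reason: Optional[str] = None
    t_mrdneg: Optional[float] = None
    mrd_assessed: Optional[bool] = None
    t_allosct_onprotocol: Optional[float] = None
    t_maintenance: Optional[float] = None
    t_relrefractory: Optional[float] = None
    t_death: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mrd_assessed is None:
            object.__setattr__(self, "mrd_assessed", self.t_mrdneg is not None)
        problems = self.problems()
        if problems:
            raise ValidationError(
                f"patient {self.patient_id!r}: " + "; ".join(problems)
            )

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty list if valid)."""
        out: list[str] = []
        if not self.patient_id:
            out.append("patient_id is empty")
        if self.arm not in ARMS:
            out.append(f"arm {self.arm!r} not in {ARMS}")
        if self.t_lastcontact is None or self.t_lastcontact < 0:
            out.append("t_lastcontact missing or negative")
            return out
        for field in _TIME_FIELDS:
            t = getattr(self, field)
            if t is None:
                continue
            if t < 0:
                out.append(f"{field}={t} is negative")
            elif t > self.t_lastcontact:
                out.append(f"{field}={t} exceeds t_lastcontact={self.t_lastcontact}")
        if self.t_death is not None and self.t_death != self.t_lastcontact:
            out.append(
                f"t_death={self.t_death} differs from t_lastcontact={self.t_lastcontact}"
            )
        if (
            self.t_mrdneg is not None
            and self.t_relrefractory is not None
            and self.t_mrdneg > self.t_relrefractory
        ):
            out.append("t_mrdneg must precede t_relrefractory")
        if self.offprotocol_reason is not None:
            if self.t_offprotocol is None:
                out.append("offprotocol_reason given without t_offprotocol")
            elif self.offprotocol_reason not in OFFPROTOCOL_REASONS:
                out.append(f"unknown offprotocol_reason {self.offprotocol_reason!r}")
        if self.mrd_assessed is False and self.t_mrdneg is not None:
            out.append("mrd_assessed=0 contradicts a present t_mrdneg")
        return out

    @property
    def died(self) -> bool:
        return self.t_death is not None

    @property
    def death_is_relapse_mortality(self) -> Optional[bool]:
        """True if death followed (or coincided with) relapse/refractory disease.

        Same-day relapse and death counts as relapse mortality: relapse is
        ordered before death when the two share a date.
        """
        if self.t_death is None:
            return None
        return (
            self.t_relrefractory is not None
            and self.t_relrefractory <= self.t_death
        )


@dataclass(frozen=True)
class CohortSummary:
    """Per-arm cohort sizes, realized transition counts and off-protocol reasons."""

    n_per_arm: dict[str, int]
    n_events_per_transition_per_arm: dict[tuple[int, str], int]
    reasons_offprotocol: dict[str, int]
    transition_labels: dict[int, tuple[str, str]]

    def count(self, transition_id: int, arm: Optional[str] = None) -> int:
        if arm is not None:
            return self.n_events_per_transition_per_arm.get((transition_id, arm), 0)
        return sum(
            self.n_events_per_transition_per_arm.get((transition_id, a), 0)
            for a in ARMS
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, (frm, to) in sorted(self.transition_labels.items()):
            rows.append(
                {
                    "transition_id": tid,
                    "from_state": frm,
                    "to_state": to,
                    "events_control": self.count(tid, "control"),
                    "events_CLO": self.count(tid, "CLO"),
                    "events_total": self.count(tid),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "n_per_arm": self.n_per_arm,
            "transitions": [
                {
                    "transition_id": tid,
                    "from_state": frm,
                    "to_state": to,
                    "events": {arm: self.count(tid, arm) for arm in ARMS},
                }
                for tid, (frm, to) in sorted(self.transition_labels.items())
            ],
            "reasons_offprotocol": self.reasons_offprotocol,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _parse_time(value, field: str, patient_id: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"patient {patient_id!r}: column {field!r} has non-numeric value {value!r}"
        ) from None


def read_records(path, sep: str = ",") -> list[PatientRecord]:
    """Read patient records from a delimited-text file.

    Every row is parsed and validated; all row-level problems are collected
    and raised together so a malformed file produces one diagnostic listing
    each offending patient_id.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("patient_id", "arm", "t_lastcontact") if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", ", ".join(unknown))

    records: list[PatientRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        pid = row["patient_id"]
        try:
            if pid in seen:
                raise ValidationError(f"duplicate patient_id {pid!r}")
            seen.add(pid)
            t_last = _parse_time(row.get("t_lastcontact"), "t_lastcontact", pid)
            if t_last is None:
                raise ValidationError(f"patient {pid!r}: t_lastcontact is required")
            kwargs = {
                field: _parse_time(row.get(field), field, pid)
                for field in _TIME_FIELDS
                if field in frame.columns
            }
            reason = row.get("offprotocol_reason", "") or None
            assessed_raw = row.get("mrd_assessed", "")
            assessed = None if assessed_raw in ("", None) else bool(int(assessed_raw))
            records.append(
                PatientRecord(
                    patient_id=pid,
                    arm=row["arm"],
                    t_lastcontact=t_last,
                    offprotocol_reason=reason,
                    mrd_assessed=assessed,
                    **kwargs,
                )
            )
        except ValidationError as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError("invalid rows:\n" + "\n".join(errors))
    return records


def write_records(records: Iterable[PatientRecord], path, sep: str = ",") -> None:
    """Write records in the documented schema; read_records round-trips losslessly."""

    def cell(value):
        if value is None:
            return ""
        if isinstance(value, bool):
            return int(value)
        return value

    rows = [
        {col: cell(getattr(rec, col)) for col in COLUMNS} for rec in records
    ]
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, sep=sep, index=False)


def reconcile_offprotocol(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], int]:
    """Drop the off-protocol label from patients transplanted on-protocol first.

    A patient whose on-protocol alloSCT precedes (or coincides with) the
    recorded off-protocol date is not regarded as off-protocol: the label and
    its reason are cleared, everything else is untouched.  Returns the
    reconciled records and the number of labels cleared.  Idempotent.
    """
    out: list[PatientRecord] = []
    n_cleared = 0
    for rec in records:
        if (
            rec.t_offprotocol is not None
            and rec.t_allosct_onprotocol is not None
            and rec.t_allosct_onprotocol <= rec.t_offprotocol
        ):
            out.append(
                dataclasses.replace(rec, t_offprotocol=None, offprotocol_reason=None)
            )
            n_cleared += 1
        else:
            out.append(rec)
    if n_cleared:
        logger.info("reconcile_offprotocol: cleared %d off-protocol label(s)", n_cleared)
    return out, n_cleared


def summarize_cohort(records: Sequence[PatientRecord], state_space) -> CohortSummary:
    """Count realized transitions per arm under a given state space."""
    from .state_space import stack_transitions  # local import avoids a cycle

    table = stack_transitions(records, state_space)
    n_per_arm = Counter(rec.arm for rec in records)
    events = table[table["status"] == 1]
    counts = Counter(zip(events["transition_id"], events["arm"]))
    reasons = Counter(
        rec.offprotocol_reason for rec in records if rec.offprotocol_reason is not None
    )
    labels = {
        tid: pair for pair, tid in state_space.transition_ids.items()
    }
    return CohortSummary(
        n_per_arm={arm: n_per_arm.get(arm, 0) for arm in ARMS},
        n_events_per_transition_per_arm=dict(counts),
        reasons_offprotocol=dict(reasons),
        transition_labels=labels,
    )
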