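"""End-to-end trial analyses: model runs, forest tables, stacked probability plots.

A :class:`ModelRun` bundles everything one multi-state analysis produces:
the state space, per-arm Aalen-Johansen probability paths from time 0,
per-transition Cox fits of the treatment-arm effect, the origin-state effect
on relapse/refractory disease, cohort transition counts, and provenance.

Per-arm probability paths are nonparametric: the cohort is split by arm and
Nelson-Aalen / Aalen-Johansen estimates are computed within each arm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .estimators import (
    ConvergenceError,
    CoxTransitionFit,
    ProbabilityPath,
    aalen_johansen,
    cox_origin_effect,
    cox_transition,
    nelson_aalen,
)
from .event_history import ARMS, CohortSummary, PatientRecord, summarize_cohort
from .state_space import (
    IND_CONS,
    OFF_PROTOCOL,
    REL_REFRACTORY,
    StateSpace,
    model1_extended,
    model1_offprotocol,
    model2_mrd,
    stack_transitions,
)

TOO_FEW_EVENTS = "too few events"


@dataclass
class ModelRun:
    """Results of one multi-state analysis of a two-arm cohort."""

    state_space: StateSpace
    table: pd.DataFrame
    summary: CohortSummary
    paths: dict[str, ProbabilityPath]
    arm_fits: dict[int, Union[CoxTransitionFit, str]]
    origin_fits: dict[str, Union[CoxTransitionFit, str]]
    provenance: dict

    def arm_fit(self, from_state: str, to_state: str) -> Union[CoxTransitionFit, str]:
        tid = self.state_space.transition_ids[(from_state, to_state)]
        return self.arm_fits[tid]


def _provenance(records: Sequence[PatientRecord], space: StateSpace, **extra) -> dict:
    digest = hashlib.sha256(
        json.dumps(
            [dataclasses.astuple(r) for r in records], sort_keys=True, default=str
        ).encode()
    ).hexdigest()
    prov = {
        "package_version": __version__,
        "state_space": space.name,
        "n_records": len(records),
        "records_sha256": digest,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov.update(extra)
    return prov


def _fit_all_transitions(
    table: pd.DataFrame, space: StateSpace
) -> dict[int, Union[CoxTransitionFit, str]]:
    fits: dict[int, Union[CoxTransitionFit, str]] = {}
    for tid in space.transition_ids.values():
        try:
            fits[tid] = cox_transition(table, tid, covariates=("arm",))
        except (ConvergenceError, ValueError):
            fits[tid] = TOO_FEW_EVENTS
    return fits


def _per_arm_paths(
    records: Sequence[PatientRecord], space: StateSpace
) -> dict[str, ProbabilityPath]:
    paths = {}
    for arm in ARMS:
        sub = [r for r in records if r.arm == arm]
        table = stack_transitions(sub, space)
        hazards = [nelson_aalen(table, tid) for tid in space.transition_ids.values()]
        paths[arm] = aalen_johansen(hazards, space, s=0.0)
    return paths


def run_model1(records: Sequence[PatientRecord], extended: bool = False) -> ModelRun:
    """Run the off-protocol analysis (or its extended sensitivity variant).

    Expects validated, reconciled records.  Fits the treatment-arm effect on
    every transition, the arm-adjusted effect of being off-protocol on the
    hazard of relapse/refractory disease, and per-arm Aalen-Johansen
    probability paths from time 0.
    """
    space = model1_extended() if extended else model1_offprotocol()
    table = stack_transitions(records, space)
    arm_fits = _fit_all_transitions(table, space)
    origin_fits: dict[str, Union[CoxTransitionFit, str]] = {}
    try:
        origin_fits["offprotocol_on_rr"] = cox_origin_effect(
            table, REL_REFRACTORY, OFF_PROTOCOL, adjust=("arm",)
        )
    except (ConvergenceError, ValueError):
        origin_fits["offprotocol_on_rr"] = TOO_FEW_EVENTS
    return ModelRun(
        state_space=space,
        table=table,
        summary=summarize_cohort(records, space),
        paths=_per_arm_paths(records, space),
        arm_fits=arm_fits,
        origin_fits=origin_fits,
        provenance=_provenance(records, space, extended=extended),
    )


def run_model2(
    records: Sequence[PatientRecord], known_mrd_only: bool = False
) -> ModelRun:
    """Run the MRD analysis.

    Records without an MRD-negativity time never enter the MRD-negativity
    state (missing MRD is treated as MRD-positive, no imputation).  With
    ``known_mrd_only`` the cohort is restricted to patients with an MRD
    assessment on record (the known-MRD sensitivity analysis).
    """
    if known_mrd_only:
        records = [r for r in records if r.mrd_assessed]
    space = model2_mrd()
    table = stack_transitions(records, space)
    arm_fits = _fit_all_transitions(table, space)
    origin_fits: dict[str, Union[CoxTransitionFit, str]] = {}
    try:
        # risk of R/R for patients not (yet) MRD-negative, relative to
        # MRD-negative patients, adjusted for treatment arm
        origin_fits["mrd_not_negative_on_rr"] = cox_origin_effect(
            table, REL_REFRACTORY, IND_CONS, adjust=("arm",)
        )
    except (ConvergenceError, ValueError):
        origin_fits["mrd_not_negative_on_rr"] = TOO_FEW_EVENTS
    return ModelRun(
        state_space=space,
        table=table,
        summary=summarize_cohort(records, space),
        paths=_per_arm_paths(records, space),
        arm_fits=arm_fits,
        origin_fits=origin_fits,
        provenance=_provenance(records, space, known_mrd_only=known_mrd_only),
    )


def forest_table(run: ModelRun) -> pd.DataFrame:
    """Per-transition treatment-effect table (events by arm, HR, CI, p).

    One row per modeled transition; transitions whose Cox fit failed (no or
    one-sided events) carry the marker string instead of numbers.
    """
    rows = []
    for (frm, to), tid in run.state_space.transition_ids.items():
        fit = run.arm_fits[tid]
        row = {
            "transition_id": tid,
            "from_state": frm,
            "to_state": to,
            "events_control": run.summary.count(tid, "control"),
            "events_CLO": run.summary.count(tid, "CLO"),
        }
        if isinstance(fit, CoxTransitionFit):
            ci = fit.hr_ci95[0]
            row.update(
                hr=float(fit.hr[0]),
                hr_ci_low=float(ci[0]),
                hr_ci_high=float(ci[1]),
                p_wald=float(fit.p_wald[0]),
                note="",
            )
        else:
            row.update(
                hr=np.nan, hr_ci_low=np.nan, hr_ci_high=np.nan, p_wald=np.nan, note=fit
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stacked_probability_plot(
    path: ProbabilityPath,
    state_order: Sequence[str],
    outfile=None,
    origin_state: Optional[str] = None,
    colors: Optional[Sequence[str]] = None,
    title: Optional[str] = None,
):
    """Stacked state-occupation plot: band heights are occupation probabilities.

    ``state_order`` fixes the stacking (bottom to top) and must be a
    permutation of the path's states; the bands sum to 1 at every time.
    Saves to ``outfile`` when given (format by extension) and returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if sorted(state_order) != sorted(path.states):
        raise ValueError(
            f"state_order {list(state_order)} is not a permutation of {list(path.states)}"
        )
    occ = path.occupation(origin_state)[list(state_order)]
    times = np.concatenate([[path.s], occ.index.to_numpy()])
    first_row = np.array([1.0 if s == (origin_state or path.states[0]) else 0.0
                          for s in state_order])
    data = np.vstack([first_row, occ.to_numpy()])
    cum = np.cumsum(data, axis=1)

    with plt.rc_context({"svg.hashsalt": "msmtrial"}):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        lower = np.zeros_like(times)
        palette = colors or plt.rcParams["axes.prop_cycle"].by_key()["color"]
        for j, state in enumerate(state_order):
            upper = cum[:, j]
            ax.fill_between(
                times / 365.25, lower, upper, step="post",
                color=palette[j % len(palette)], label=state,
            )
            lower = upper
        ax.set_xlabel("years since start of induction & consolidation")
        ax.set_ylabel("probability")
        ax.set_ylim(0, 1)
        ax.set_xlim(left=0)
        if title:
            ax.set_title(title)
        ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), frameon=False)
        fig.tight_layout()
        if outfile is not None:
            fig.savefig(outfile, metadata=_figure_metadata(str(outfile)))
    return fig


def _figure_metadata(filename: str):
    if filename.endswith(".svg"):
        return {"Date": None}
    if filename.endswith(".png"):
        return {"Software": None}
    return None


def serialize_run(run: ModelRun, outdir) -> dict[str, str]:
    """Write a run's tables, paths and manifest under ``outdir``.

    Returns a mapping of artifact name to file path.  Tables and serialized
    probability paths are deterministic given identical input and seed; the
    manifest additionally carries a timestamp.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    written = {}

    def save(name, frame):
        p = os.path.join(outdir, name)
        frame.to_csv(p, index=False)
        written[name] = p

    save("forest.csv", forest_table(run))
    save("cohort_summary.csv", run.summary.to_frame())
    save("transition_table.csv", run.table)
    for arm, path in run.paths.items():
        save(f"probability_path_{arm}.csv", path.to_frame())
    origin_rows = []
    for name, fit in run.origin_fits.items():
        if isinstance(fit, CoxTransitionFit):
            frame = fit.to_frame()
            frame.insert(0, "analysis", name)
            origin_rows.append(frame)
    if origin_rows:
        save("origin_effects.csv", pd.concat(origin_rows, ignore_index=True))
    manifest = os.path.join(outdir, "manifest.json")
    with open(manifest, "w") as fh:
        json.dump(run.provenance, fh, indent=2, sort_keys=True)
    written["manifest.json"] = manifest
    return written
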