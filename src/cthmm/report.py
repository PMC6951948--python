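"""Machine-readable per-state summaries of a fitted progression model.

These tables are the standard readouts of a staging model: per-state
feature profiles (with an x-axis spacing proportional to expected state
durations, so profile plots reflect dwell time), per-state distributions of
auxiliary clinical covariates, the expected-duration table, the transition
probability matrix over a chosen horizon, and the decoded per-patient
sequences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ctmc import expected_durations, transition_matrix
from .model import Cohort, CTHMMParams, StateSequence

__all__ = [
    "state_feature_profiles",
    "covariate_summaries",
    "duration_table",
    "transition_probability_table",
    "sequence_table",
    "report_state_profiles",
]


def _decoded_states_per_visit(cohort: Cohort, decoded: list[StateSequence]) -> np.ndarray:
    by_id = {s.patient_id: s for s in decoded}
    states = []
    for p in cohort:
        seq = by_id.get(p.patient_id)
        if seq is None or seq.times.size != p.num_visits:
            raise ValueError(
                f"decoded sequence missing or misaligned for patient {p.patient_id!r}"
            )
        states.append(seq.states)
    return np.concatenate(states)


def duration_table(params: CTHMMParams) -> pd.DataFrame:
    """Expected sojourn time per state; absorbing states are NaN."""
    dur = expected_durations(params.Q, params.mask.absorbing)
    return pd.DataFrame(
        {
            "state": np.arange(1, params.num_states + 1),
            "expected_duration_years": dur,
            "absorbing": params.mask.absorbing | (np.diag(params.Q) == 0),
        }
    )


def state_feature_profiles(
    params: CTHMMParams, cohort: Cohort, decoded: list[StateSequence]
) -> pd.DataFrame:
    """Per-state empirical mean/SD of every feature among decoded visits.

    ``x_position`` spaces states proportionally to expected durations
    (cumulative midpoints), so a profile plot's x-axis reflects how long
    patients dwell in each state; absorbing states get a unit slot.
    """
    states = _decoded_states_per_visit(cohort, decoded)
    X = np.vstack([p.observations for p in cohort])
    dur = expected_durations(params.Q, params.mask.absorbing)
    widths = np.where(np.isnan(dur), 1.0, dur)
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    midpoints = 0.5 * (edges[:-1] + edges[1:])

    rows = []
    for m in range(1, params.num_states + 1):
        sel = states == m
        for j, name in enumerate(cohort.feature_names):
            vals = X[sel, j]
            rows.append(
                {
                    "state": m,
                    "feature": name,
                    "n_visits": int(sel.sum()),
                    "mean": float(vals.mean()) if sel.any() else np.nan,
                    "sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
                    "model_mean": float(params.emissions.means[m - 1, j]),
                    "x_position": float(midpoints[m - 1]),
                }
            )
    return pd.DataFrame(rows)


def covariate_summaries(
    cohort: Cohort, decoded: list[StateSequence], covariate_columns: list[str]
) -> dict[str, pd.DataFrame]:
    """Per-state distribution summary of each auxiliary covariate column.

    A column absent from the cohort is skipped with a warning rather than
    failing — covariates are optional reporting context, never model input.
    """
    states = _decoded_states_per_visit(cohort, decoded)
    out: dict[str, pd.DataFrame] = {}
    for col in covariate_columns:
        values = []
        for p in cohort:
            if p.covariates is None or col not in p.covariates.columns:
                values = None
                break
            values.append(p.covariates[col].to_numpy())
        if values is None:
            warnings.warn(
                f"covariate column {col!r} absent; summary skipped", stacklevel=2
            )
            continue
        v = pd.to_numeric(pd.Series(np.concatenate(values)), errors="coerce")
        frame = pd.DataFrame({"state": states, "value": v})
        out[col] = (
            frame.groupby("state")["value"]
            .describe()
            .reset_index()
        )
    return out


def transition_probability_table(params: CTHMMParams, delta: float = 1.0) -> pd.DataFrame:
    """``A(delta)`` as a labelled table (default horizon one year).

    Under a forward-type mask the lower triangle is exactly zero.
    """
    A = transition_matrix(params.Q, delta)
    labels = [f"state_{i}" for i in range(1, params.num_states + 1)]
    out = pd.DataFrame(A, columns=labels)
    out.insert(0, "from_state", np.arange(1, params.num_states + 1))
    return out


def sequence_table(decoded: list[StateSequence]) -> pd.DataFrame:
    """All decoded trajectories as (patient_id, visit_time, state) rows."""
    return pd.concat([s.to_frame() for s in decoded], ignore_index=True)


def report_state_profiles(
    params: CTHMMParams,
    cohort: Cohort,
    decoded: list[StateSequence],
    covariate_columns: list[str] | None = None,
    delta: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Bundle every per-state report table into one dictionary.

    Keys: ``feature_profiles``, ``durations``, ``transition_probabilities``,
    ``sequences``, plus ``covariate:<name>`` per summarizable covariate.
    """
    tables = {
        "feature_profiles": state_feature_profiles(params, cohort, decoded),
        "durations": duration_table(params),
        "transition_probabilities": transition_probability_table(params, delta),
        "sequences": sequence_table(decoded),
    }
    for name, frame in covariate_summaries(
        cohort, decoded, covariate_columns or []
    ).items():
        tables[f"covariate:{name}"] = frame
    return tables
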