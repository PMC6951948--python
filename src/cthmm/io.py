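"""Readers, writers and model serialization.

Cohorts travel as long-format delimited text — one row per patient-visit
with a patient identifier, a visit time in years, the feature columns and
any auxiliary covariate columns — the natural shape of registry exports.
Models, fits and selection results serialize to versioned JSON.  All
numeric text output uses 17 significant digits so round-trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmc import StructureMask
from .em import FitConfig, FitResult
from .model import Cohort, CTHMMParams, EmissionParams, PatientSeries, StateSequence
from .selection import SelectionResult

__all__ = [
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "save_fit_result",
    "load_fit_result",
    "save_selection_result",
    "write_state_sequences",
]

FLOAT_FMT = "%.17g"

PARAMS_SCHEMA = "cthmm-params/1"
FIT_SCHEMA = "cthmm-fit/1"
SELECTION_SCHEMA = "cthmm-selection/1"

ID_COL = "patient_id"
TIME_COL = "visit_time"


@dataclass
class ExclusionReport:
    """Counts of rows and patients removed while loading a cohort."""

    visits_read: int = 0
    visits_dropped_missing: int = 0
    patients_read: int = 0
    patients_dropped_min_visits: int = 0
    patients_kept: int = 0
    visits_kept: int = 0

    def summary(self) -> str:
        return (
            f"read {self.visits_read} visits / {self.patients_read} patients; "
            f"dropped {self.visits_dropped_missing} visits with missing features "
            f"and {self.patients_dropped_min_visits} patients below the visit "
            f"minimum; kept {self.visits_kept} visits / {self.patients_kept} patients"
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file or missing header row")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_cohort(
    path: str | Path,
    feature_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
    id_column: str = ID_COL,
    time_column: str = TIME_COL,
    min_visits: int = 2,
    rebase_times: bool = False,
) -> tuple[Cohort, ExclusionReport]:
    """Load a long-format visit table into a :class:`Cohort`.

    Visits with any missing feature value are dropped (and counted), then
    patients with fewer than ``min_visits`` remaining visits are dropped
    (and counted).  Visits are sorted by time within patient; duplicate
    (patient, time) rows and unparseable numerics are rejected with row
    context.  ``feature_columns=None`` takes every column other than the
    identifier, the time and the declared covariates.  ``rebase_times``
    re-expresses each patient's visit times relative to their first kept
    visit.
    """
    df = _read_table(path)
    covariate_columns = list(covariate_columns or [])
    for col in [id_column, time_column] + covariate_columns:
        if col not in df.columns:
            raise ValueError(f"{path}: declared column {col!r} not found")
    if feature_columns is None:
        feature_columns = [
            c
            for c in df.columns
            if c not in {id_column, time_column} and c not in covariate_columns
        ]
    else:
        for col in feature_columns:
            if col not in df.columns:
                raise ValueError(f"{path}: declared feature column {col!r} not found")
    if not feature_columns:
        raise ValueError(f"{path}: no feature columns")

    for col in [time_column] + feature_columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna() & (series.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: unparseable numeric value {series[row]!r} in column "
                f"{col!r} at row {row + 2}"  # +2: header + 1-based
            )
        df[col] = numeric

    dup = df.duplicated(subset=[id_column, time_column], keep=False)
    if dup.any():
        pid = df.loc[dup.idxmax(), id_column]
        t = df.loc[dup.idxmax(), time_column]
        raise ValueError(
            f"{path}: duplicate (patient, time) rows, e.g. patient {pid!r} "
            f"at time {t}"
        )

    report = ExclusionReport(
        visits_read=len(df), patients_read=df[id_column].nunique()
    )
    complete = df[feature_columns].notna().all(axis=1) & df[time_column].notna()
    report.visits_dropped_missing = int((~complete).sum())
    df = df[complete]

    patients = []
    for pid, group in df.groupby(id_column, sort=True):
        if len(group) < min_visits:
            report.patients_dropped_min_visits += 1
            continue
        group = group.sort_values(time_column)
        times = group[time_column].to_numpy(dtype=float)
        if rebase_times:
            times = times - times[0]
        covs = (
            group[covariate_columns].reset_index(drop=True)
            if covariate_columns
            else None
        )
        patients.append(
            PatientSeries(
                patient_id=str(pid),
                times=times,
                observations=group[feature_columns].to_numpy(dtype=float),
                covariates=covs,
            )
        )
    cohort = Cohort(patients=tuple(patients), feature_names=tuple(feature_columns))
    report.patients_kept = len(cohort)
    report.visits_kept = cohort.num_visits
    return cohort, report


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to long-format CSV (exact numeric round-trip)."""
    frames = []
    for p in cohort:
        frame = pd.DataFrame(
            p.observations, columns=list(cohort.feature_names)
        )
        frame.insert(0, TIME_COL, p.times)
        frame.insert(0, ID_COL, p.patient_id)
        if p.covariates is not None:
            frame = pd.concat([frame, p.covariates.reset_index(drop=True)], axis=1)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_state_sequences(sequences: list[StateSequence], path: str | Path) -> None:
    """Write decoded trajectories as (patient_id, visit_time, state) rows."""
    pd.concat([s.to_frame() for s in sequences], ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def params_to_dict(params: CTHMMParams, feature_names=None) -> dict:
    payload = {
        "schema": PARAMS_SCHEMA,
        "mask": params.mask.to_dict(),
        "Q": params.Q.ravel().tolist(),
        "pi": params.pi.tolist(),
        "emission_means": params.emissions.means.ravel().tolist(),
        "emission_variances": params.emissions.variances.ravel().tolist(),
        "num_features": params.num_features,
    }
    if feature_names is not None:
        payload["feature_names"] = list(feature_names)
    return payload


def params_from_dict(payload: dict) -> CTHMMParams:
    if payload.get("schema") != PARAMS_SCHEMA:
        raise ValueError(
            f"unsupported model schema {payload.get('schema')!r}; "
            f"expected {PARAMS_SCHEMA!r}"
        )
    mask = StructureMask.from_dict(payload["mask"])
    m = mask.num_states
    k = int(payload["num_features"])
    return CTHMMParams(
        Q=np.asarray(payload["Q"], dtype=float).reshape(m, m),
        pi=np.asarray(payload["pi"], dtype=float),
        emissions=EmissionParams(
            means=np.asarray(payload["emission_means"], dtype=float).reshape(m, k),
            variances=np.asarray(
                payload["emission_variances"], dtype=float
            ).reshape(m, k),
        ),
        mask=mask,
    )


def save_params(params: CTHMMParams, path: str | Path, feature_names=None) -> None:
    Path(path).write_text(
        json.dumps(params_to_dict(params, feature_names), indent=2)
    )


def load_params(path: str | Path) -> CTHMMParams:
    return params_from_dict(json.loads(Path(path).read_text()))


def save_fit_result(
    result: FitResult, path: str | Path, feature_names=None
) -> None:
    payload = {
        "schema": FIT_SCHEMA,
        "params": params_to_dict(result.params, feature_names),
        "loglik_trace": result.loglik_trace,
        "converged": result.converged,
        "iterations": result.iterations,
        "seed_used": result.seed_used,
        "config": result.config.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_fit_result(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != FIT_SCHEMA:
        raise ValueError(f"unsupported fit schema {payload.get('schema')!r}")
    return FitResult(
        params=params_from_dict(payload["params"]),
        loglik_trace=list(payload["loglik_trace"]),
        converged=bool(payload["converged"]),
        iterations=int(payload["iterations"]),
        seed_used=int(payload["seed_used"]),
        config=FitConfig(**payload["config"]),
    )


def save_selection_result(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "schema": SELECTION_SCHEMA,
        "grid": result.grid,
        "test_loglik": result.test_loglik,
        "chosen_m": result.chosen_m,
        "errors": {str(m): msg for m, msg in result.errors.items()},
        "split_seed": result.split_seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_selection_curve(result: SelectionResult, path: str | Path) -> None:
    """Two-column table (M, held-out log-likelihood) behind the selection curve."""
    pd.DataFrame(
        {"num_states": result.grid, "test_loglik": result.test_loglik}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)
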