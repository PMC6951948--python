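"""CTHMM observation model and exact inference for one patient series.

The hidden state follows a continuous-time Markov chain with generator
``Q``; at each visit the ``K`` observed features are conditionally
independent Gaussians whose mean and variance depend on the current state.
Because visits are irregular, the forward–backward and Viterbi recursions
use an interval-specific transition matrix ``A(tau_t - tau_{t-1})`` for each
consecutive visit pair.

The initial distribution ``pi`` refers to the state at each patient's first
*observed* visit, not at biological disease onset: observational cohorts are
left-truncated, so patients enter the data partway through the disease
course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import StructureMask, TransitionCache, require_valid_generator

__all__ = [
    "EmissionParams",
    "CTHMMParams",
    "PatientSeries",
    "Cohort",
    "PosteriorSummary",
    "StateSequence",
    "emission_loglik",
    "forward_backward",
    "cohort_loglik",
    "viterbi",
    "predict_future",
]

VARIANCE_FLOOR = 1e-6

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EmissionParams:
    """State-wise independent-Gaussian emission parameters.

    ``means[m, k]`` and ``variances[m, k]`` give the Gaussian for feature
    ``k`` under state ``m``; variances are floored at ``VARIANCE_FLOOR``.
    """

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if means.shape != variances.shape:
            raise ValueError("means and variances must have identical shape")
        if not (np.isfinite(means).all() and np.isfinite(variances).all()):
            raise ValueError("emission parameters must be finite")
        if (variances < VARIANCE_FLOOR).any():
            variances = np.maximum(variances, VARIANCE_FLOOR)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "variances", variances)

    @property
    def num_states(self) -> int:
        return self.means.shape[0]

    @property
    def num_features(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class CTHMMParams:
    """Full parameter set Θ = {Q, π, μ, σ²} plus the structural mask."""

    Q: np.ndarray
    pi: np.ndarray
    emissions: EmissionParams
    mask: StructureMask

    def __post_init__(self) -> None:
        Q = require_valid_generator(self.Q, self.mask)
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.mask.num_states,):
            raise ValueError(
                f"pi must have length {self.mask.num_states}, got shape {pi.shape}"
            )
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be a probability vector (sum 1, entries >= 0)")
        if self.emissions.num_states != self.mask.num_states:
            raise ValueError("emission table and mask disagree on the number of states")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "pi", pi)

    @property
    def num_states(self) -> int:
        return self.mask.num_states

    @property
    def num_features(self) -> int:
        return self.emissions.num_features


@dataclass(frozen=True)
class PatientSeries:
    """One patient's time-stamped feature vectors.

    ``times`` are visit times in years, strictly increasing; ``observations``
    is the ``(T, K)`` feature table.  ``covariates`` carries optional
    auxiliary columns (e.g. a diagnostic-confidence level or a clinical
    stage) used only for reporting, never in the likelihood.
    """

    patient_id: str
    times: np.ndarray
    observations: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        obs = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if times.ndim != 1 or times.size == 0:
            raise ValueError(f"patient {self.patient_id}: needs at least one visit")
        if obs.shape[0] != times.size:
            raise ValueError(
                f"patient {self.patient_id}: {times.size} times but "
                f"{obs.shape[0]} observation rows"
            )
        if times.size > 1 and not (np.diff(times) > 0).all():
            raise ValueError(
                f"patient {self.patient_id}: visit times must be strictly increasing"
            )
        if not np.isfinite(obs).all():
            t_bad = int(np.argwhere(~np.isfinite(obs))[0, 0])
            raise ValueError(
                f"patient {self.patient_id}: non-finite feature value at visit "
                f"index {t_bad} (time {times[t_bad]})"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observations", obs)

    @property
    def num_visits(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Cohort:
    """A collection of patient series sharing one feature panel."""

    patients: tuple[PatientSeries, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        patients = tuple(self.patients)
        names = tuple(self.feature_names)
        k = len(names)
        ids = [p.patient_id for p in patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique within a cohort")
        for p in patients:
            if p.observations.shape[1] != k:
                raise ValueError(
                    f"patient {p.patient_id} has {p.observations.shape[1]} features, "
                    f"cohort declares {k}"
                )
        object.__setattr__(self, "patients", patients)
        object.__setattr__(self, "feature_names", names)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def num_features(self) -> int:
        return len(self.feature_names)

    @property
    def num_visits(self) -> int:
        return sum(p.num_visits for p in self.patients)

    @property
    def total_followup(self) -> float:
        """Total observed follow-up time, sum of (last - first visit) per patient."""
        return float(sum(p.times[-1] - p.times[0] for p in self.patients))

    def filter_min_visits(self, min_visits: int) -> "Cohort":
        kept = tuple(p for p in self.patients if p.num_visits >= min_visits)
        return Cohort(patients=kept, feature_names=self.feature_names)

    def subset(self, patient_ids) -> "Cohort":
        wanted = set(patient_ids)
        kept = tuple(p for p in self.patients if p.patient_id in wanted)
        return Cohort(patients=kept, feature_names=self.feature_names)


@dataclass(frozen=True)
class PosteriorSummary:
    """Forward–backward output for one series.

    ``gamma[t, m]`` is the per-visit posterior ``P(S_t = m | Z)``;
    ``xi[t, i, j]`` the pairwise posterior for the interval between visits
    ``t`` and ``t+1``; ``loglik`` the observed-data log-likelihood.
    """

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float


@dataclass(frozen=True)
class StateSequence:
    """A decoded staging trajectory; states are 1-based labels."""

    patient_id: str
    times: np.ndarray
    states: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "visit_time": self.times,
                "state": self.states,
            }
        )


def emission_loglik(observation: np.ndarray, emissions: EmissionParams) -> np.ndarray:
    """Log-density of one visit's feature vector under each state.

    Entry ``m`` is ``sum_k log N(z_k; mu[m,k], sigma2[m,k])``.
    """
    z = np.asarray(observation, dtype=float)
    if z.shape != (emissions.num_features,):
        raise ValueError(
            f"observation has shape {z.shape}, expected ({emissions.num_features},)"
        )
    if not np.isfinite(z).all():
        raise ValueError("observation contains non-finite values")
    return _emission_loglik_matrix(z[None, :], emissions)[0]


def _emission_loglik_matrix(obs: np.ndarray, emissions: EmissionParams) -> np.ndarray:
    """(T, M) log emission densities for a whole series at once."""
    mu = emissions.means  # (M, K)
    var = emissions.variances
    # (T, 1, K) - (M, K) broadcasts to (T, M, K)
    sq = (obs[:, None, :] - mu[None, :, :]) ** 2
    ll = -0.5 * (sq / var[None, :, :] + np.log(var)[None, :, :] + _LOG_2PI)
    return ll.sum(axis=2)


def _interval_matrices(
    params: CTHMMParams, patient: PatientSeries, cache: TransitionCache | None
) -> list[np.ndarray]:
    if cache is None:
        cache = TransitionCache(params.Q)
    gaps = np.diff(patient.times)
    return [cache.transition(d) for d in gaps]


def forward_backward(
    params: CTHMMParams,
    patient: PatientSeries,
    cache: TransitionCache | None = None,
) -> PosteriorSummary:
    """Exact state posteriors and observed-data log-likelihood for one series.

    Uses the scaled forward–backward recursion with per-visit normalization
    constants (log-accumulated), so series of 25 visits and a dozen states
    stay far from underflow.  ``cache`` shares transition matrices across
    patients with repeated inter-visit gaps.
    """
    m = params.num_states
    obs = patient.observations
    T = patient.num_visits
    logb = _emission_loglik_matrix(obs, params.emissions)  # (T, M)
    b_shift = logb.max(axis=1)
    b = np.exp(logb - b_shift[:, None])  # scaled densities, max 1 per visit

    A_list = _interval_matrices(params, patient, cache)

    alpha = np.zeros((T, m))
    c = np.zeros(T)  # per-step normalizers on the scaled densities
    a0 = params.pi * b[0]
    c[0] = a0.sum()
    if c[0] == 0:
        raise FloatingPointError(
            f"patient {patient.patient_id}: zero likelihood at first visit"
        )
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        at = (alpha[t - 1] @ A_list[t - 1]) * b[t]
        c[t] = at.sum()
        if c[t] == 0:
            raise FloatingPointError(
                f"patient {patient.patient_id}: zero likelihood at visit index {t}"
            )
        alpha[t] = at / c[t]

    beta = np.zeros((T, m))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A_list[t] * b[t + 1][None, :]) @ beta[t + 1] / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.zeros((max(T - 1, 0), m, m))
    for t in range(T - 1):
        s = alpha[t][:, None] * A_list[t] * (b[t + 1] * beta[t + 1])[None, :]
        xi[t] = s / s.sum()

    loglik = float(np.log(c).sum() + b_shift.sum())
    return PosteriorSummary(gamma=gamma, xi=xi, loglik=loglik)


def cohort_loglik(
    params: CTHMMParams, cohort: Cohort, cache: TransitionCache | None = None
) -> float:
    """Total observed-data log-likelihood, summed over independent patients."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if cohort.num_features != params.num_features:
        raise ValueError(
            f"cohort has {cohort.num_features} features, model expects "
            f"{params.num_features}"
        )
    if cache is None:
        cache = TransitionCache(params.Q)
    return float(
        sum(forward_backward(params, p, cache).loglik for p in cohort)
    )


def viterbi(
    params: CTHMMParams,
    patient: PatientSeries,
    cache: TransitionCache | None = None,
) -> StateSequence:
    """Most probable state sequence (1-based labels) for one series.

    Log-space dynamic programming; ties break toward the lower state index
    for determinism.  Under a forward-type mask the decoded sequence is
    non-decreasing because backward transitions have probability zero.
    """
    m = params.num_states
    T = patient.num_visits
    logb = _emission_loglik_matrix(patient.observations, params.emissions)
    A_list = _interval_matrices(params, patient, cache)

    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = [np.log(A) for A in A_list]

    delta = np.zeros((T, m))
    psi = np.zeros((T, m), dtype=int)
    delta[0] = logpi + logb[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA[t - 1]  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta[t] = cand[psi[t], np.arange(m)] + logb[t]

    states = np.zeros(T, dtype=int)
    states[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]

    return StateSequence(
        patient_id=patient.patient_id,
        times=patient.times.copy(),
        states=states + 1,
    )


def predict_future(
    params: CTHMMParams,
    patient: PatientSeries,
    horizon: float,
    cache: TransitionCache | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """State distribution and expected features ``horizon`` years past the
    last visit.

    The last-visit posterior is propagated through ``A(horizon)`` and the
    expected feature vector is the posterior mixture of state means.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    post = forward_backward(params, patient, cache)
    gamma_last = post.gamma[-1]
    if cache is None:
        cache = TransitionCache(params.Q)
    dist = gamma_last @ cache.transition(horizon)
    expected = dist @ params.emissions.means
    return dist, expected
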