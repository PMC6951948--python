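"""Synthetic CTHMM cohorts with the structure of pooled observational
registry data.

The simulator mirrors how chronic-disease registries actually observe
patients: each patient's hidden disease course starts in the first state
and evolves as a continuous-time Markov chain, but observation begins at a
random *entry time* into that course (left truncation), visits are roughly
annual with jitter, and the number of visits per patient is small and
skewed.  Ground-truth state sequences are returned alongside the cohort so
estimation and selection can be scored against truth.

``hd_preset`` builds a nine-state, second-order forward-chain scenario with
an absorbing terminal state whose sojourn times match the durations of a
published Huntington's-disease staging model; its feature means are
illustrative (three monotone trends across motor, functional and cognitive
factor triplets), chosen for roughly two-sigma separation between adjacent
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctmc import StructureMask, build_structure_mask, require_valid_generator
from .model import Cohort, CTHMMParams, EmissionParams, PatientSeries, StateSequence

__all__ = [
    "VisitModel",
    "ScenarioConfig",
    "sample_ctmc_path",
    "simulate_cohort",
    "hd_preset",
    "hd_preset_durations",
]

#: published expected sojourn times (years) for the nine-state HD model;
#: the ninth (terminal) state is absorbing and has no finite duration
HD_STATE_DURATIONS = (9.7, 9.2, 3.8, 2.9, 5.8, 3.5, 3.0, 3.2)


@dataclass
class VisitModel:
    """Per-patient visit schedule: count and spacing distributions.

    Visit counts are 1 + Poisson(``mean_visits`` - 1), truncated at
    ``max_visits`` — a skewed distribution matching registry cohorts where
    the average participant contributes about three visits.  Set
    ``fixed_visits`` for a balanced panel (every patient contributes exactly
    that many visits, as in a designed study).  Gaps are Gamma-distributed
    around ``mean_gap`` years and rounded to a 0.1-year grid, emulating
    scheduled ~annual visits with month-scale jitter.
    """

    mean_visits: float = 2.9
    max_visits: int = 25
    mean_gap: float = 1.0
    gap_shape: float = 25.0
    gap_grid: float = 0.1
    fixed_visits: int | None = None

    def sample_times(self, rng: np.random.Generator) -> np.ndarray:
        if self.fixed_visits is not None:
            n = int(self.fixed_visits)
        else:
            n = 1 + rng.poisson(max(self.mean_visits - 1.0, 0.0))
        n = int(min(n, self.max_visits))
        if n == 1:
            return np.zeros(1)
        gaps = rng.gamma(self.gap_shape, self.mean_gap / self.gap_shape, size=n - 1)
        if self.gap_grid > 0:
            gaps = np.maximum(np.round(gaps / self.gap_grid), 1.0) * self.gap_grid
        return np.concatenate([[0.0], np.cumsum(gaps)])


@dataclass
class ScenarioConfig:
    """Ground truth plus observation model for one simulated cohort.

    ``params.pi`` is the state distribution at disease onset (the start of
    each hidden course); the distribution over states at the first
    *observed* visit additionally reflects ``entry_window``: patients enter
    observation uniformly within the first ``entry_window`` years of their
    course, mixing early and late presentations as pooled registries do.
    """

    params: CTHMMParams
    num_patients: int = 1000
    visit_model: VisitModel = field(default_factory=VisitModel)
    entry_window: float = 30.0
    seed: int = 0
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.feature_names is not None and len(self.feature_names) != (
            self.params.num_features
        ):
            raise ValueError("feature_names length must match the emission table")
        if self.num_patients < 1:
            raise ValueError("num_patients must be >= 1")
        if self.entry_window < 0:
            raise ValueError("entry_window must be >= 0")


def sample_ctmc_path(
    Q: np.ndarray,
    start_state: int,
    t_max: float,
    rng: np.random.Generator,
    mask: StructureMask | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie simulation of one hidden course (states are 1-based).

    Returns ``(jump_times, states)`` where ``states[k]`` is occupied from
    ``jump_times[k]`` until ``jump_times[k+1]`` (or ``t_max``).  The path
    starts at time 0 in ``start_state`` and ends at ``t_max`` or upon
    entering an absorbing state, whichever comes first.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    if not 1 <= start_state <= m:
        raise ValueError(f"start_state must be in 1..{m}, got {start_state}")
    times = [0.0]
    states = [int(start_state)]
    t = 0.0
    s = start_state - 1
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            break  # absorbing
        t += rng.exponential(1.0 / rate)
        if t >= t_max:
            break
        probs = Q[s].clip(min=0.0)
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(m, p=probs))
        times.append(t)
        states.append(s + 1)
    return np.asarray(times), np.asarray(states, dtype=int)


def _state_at(times: np.ndarray, states: np.ndarray, query: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, query, side="right") - 1
    return states[idx]


def simulate_cohort(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[Cohort, list[StateSequence]]:
    """Simulate a cohort and its aligned ground-truth state sequences.

    Per patient: draw an entry time into the hidden course, a visit
    schedule, the hidden path, and Gaussian observations around the state
    means at each visit.  Visit times in the returned cohort are relative
    to each patient's first visit.  Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.params
    m = params.num_states
    k = params.num_features
    sd = np.sqrt(params.emissions.variances)

    patients = []
    truths = []
    for n in range(config.num_patients):
        entry = rng.uniform(0.0, config.entry_window) if config.entry_window > 0 else 0.0
        offsets = config.visit_model.sample_times(rng)
        start = 1 + rng.choice(m, p=params.pi)
        path_t, path_s = sample_ctmc_path(
            params.Q, start, entry + offsets[-1] + 1e-9, rng
        )
        visit_states = _state_at(path_t, path_s, entry + offsets)
        obs = params.emissions.means[visit_states - 1] + rng.standard_normal(
            (offsets.size, k)
        ) * sd[visit_states - 1]
        pid = f"P{n + 1:05d}"
        patients.append(
            PatientSeries(patient_id=pid, times=offsets, observations=obs)
        )
        truths.append(
            StateSequence(patient_id=pid, times=offsets, states=visit_states)
        )
    feature_names = config.feature_names or tuple(f"f{j + 1}" for j in range(k))
    return Cohort(patients=tuple(patients), feature_names=feature_names), truths


def _hd_rate(duration: float) -> float:
    """Total exit rate whose reciprocal reproduces the printed duration as
    closely as float64 allows (exactly for 7 of the 8 states)."""
    r = 1.0 / duration
    for cand in (r, np.nextafter(r, 0.0), np.nextafter(r, np.inf)):
        if 1.0 / cand == duration:
            return float(cand)
    return r


def hd_preset(num_patients: int = 1000, seed: int = 0) -> ScenarioConfig:
    """Nine-state Huntington's-disease-like scenario.

    Second-order forward chain with absorbing state 9; exit rates set so the
    expected state durations match the published values
    ``HD_STATE_DURATIONS``.  The exit mass splits 80/20 between the +1 and
    +2 jumps, except out of states 3 and 4 where the +2 ("skipping") share
    is enlarged to 40% — the transition period where parallel progression
    pathways make state-skipping non-negligible.  Nine features in three
    domains: motor factors trend upward (worse), functional and cognitive
    factors trend downward, all with unit variance and roughly two-sigma
    adjacent-state separation.
    """
    m = 9
    mask = build_structure_mask(m, "forward_chain", order=2, absorbing_last=True)
    Q = np.zeros((m, m))
    for i, dur in enumerate(HD_STATE_DURATIONS):
        rate = _hd_rate(dur)
        plus2_share = 0.4 if (i + 1) in (3, 4) else 0.2
        if i + 2 < m:
            q2 = plus2_share * rate
            q1 = rate - q2  # exact complement so the row sums to -rate
        else:
            q1, q2 = rate, 0.0
        Q[i, i + 1] = q1
        if i + 2 < m:
            Q[i, i + 2] = q2
        # diagonal pinned to -rate so -1/Q[i,i] reproduces the printed
        # duration; the row-sum residual is at most one ulp
        Q[i, i] = -rate
    require_valid_generator(Q, mask)

    severity = np.arange(m, dtype=float) * 2.0  # 2-sigma spacing, unit variance
    means = np.zeros((m, 9))
    means[:, 0:3] = severity[:, None]  # motor: worse = higher
    means[:, 3:6] = -severity[:, None]  # functional: worse = lower
    means[:, 6:9] = -severity[:, None]  # cognitive: worse = lower
    emissions = EmissionParams(means=means, variances=np.ones((m, 9)))

    pi = np.zeros(m)
    pi[0] = 1.0  # every hidden course starts prodromal; entry time truncates
    params = CTHMMParams(Q=Q, pi=pi, emissions=emissions, mask=mask)
    return ScenarioConfig(
        params=params,
        num_patients=num_patients,
        visit_model=VisitModel(),
        entry_window=30.0,
        seed=seed,
        feature_names=tuple(
            f"{dom}_{j}" for dom in ("motor", "func", "cog") for j in (1, 2, 3)
        ),
    )


def hd_preset_durations() -> np.ndarray:
    """Expected durations of the preset's states (years; terminal state NaN)."""
    return np.asarray(list(HD_STATE_DURATIONS) + [np.nan])
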