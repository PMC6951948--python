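"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own computational paths:
likelihoods are enumerated over all state sequences with scipy.stats
densities and direct matrix exponentials, and endpoint-conditioned
expectations are estimated by a vectorized Gillespie sampler written from
the generator definition alone.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
import scipy.linalg
import scipy.stats
from hypothesis import settings
from scipy.special import logsumexp

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from cthmm import (
    Cohort,
    CTHMMParams,
    EmissionParams,
    PatientSeries,
    build_structure_mask,
)


def make_random_params(
    num_states: int,
    num_features: int,
    seed: int,
    kind: str = "full",
    order: int = 1,
    absorbing_last: bool = False,
    rate_scale: float = 1.0,
    mean_spread: float = 3.0,
) -> CTHMMParams:
    """A random valid parameter set for property tests."""
    rng = np.random.default_rng(seed)
    mask = build_structure_mask(
        num_states, kind=kind, order=order, absorbing_last=absorbing_last
    )
    Q = np.zeros((num_states, num_states))
    for i in range(num_states):
        js = np.flatnonzero(mask.allowed[i])
        if js.size:
            Q[i, js] = rng.uniform(0.1, 1.0, size=js.size) * rate_scale
            Q[i, i] = -Q[i, js].sum()
    pi = rng.dirichlet(np.ones(num_states))
    means = rng.normal(0.0, mean_spread, size=(num_states, num_features))
    variances = rng.uniform(0.5, 2.0, size=(num_states, num_features))
    return CTHMMParams(
        Q=Q,
        pi=pi,
        emissions=EmissionParams(means=means, variances=variances),
        mask=mask,
    )


def make_random_series(
    params: CTHMMParams, num_visits: int, seed: int, patient_id: str = "P1"
) -> PatientSeries:
    """Random (not model-generated) visit times and observations."""
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(0.3, 2.0, size=num_visits - 1) if num_visits > 1 else []
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    obs = rng.normal(0.0, 2.0, size=(num_visits, params.num_features))
    return PatientSeries(patient_id=patient_id, times=times, observations=obs)


def enum_loglik(params: CTHMMParams, patient: PatientSeries) -> float:
    """Brute-force observed-data log-likelihood: logsumexp over every one of
    the M^T hidden state sequences, with densities and transition matrices
    computed from first principles."""
    m = params.num_states
    T = patient.num_visits
    A_list = [
        scipy.linalg.expm(d * params.Q) for d in np.diff(patient.times)
    ]
    logb = np.array(
        [
            [
                scipy.stats.norm.logpdf(
                    patient.observations[t],
                    params.emissions.means[s],
                    np.sqrt(params.emissions.variances[s]),
                ).sum()
                for s in range(m)
            ]
            for t in range(T)
        ]
    )
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = [np.log(np.clip(A, 1e-300, None)) for A in A_list]
        # restore true -inf for exact zeros
        for A, lA in zip(A_list, logA):
            lA[A == 0] = -np.inf
    terms = []
    for seq in product(range(m), repeat=T):
        lp = logpi[seq[0]] + logb[0, seq[0]]
        for t in range(1, T):
            lp += logA[t - 1][seq[t - 1], seq[t]] + logb[t, seq[t]]
        terms.append(lp)
    return float(logsumexp(terms))


def batch_path_stats(
    Q: np.ndarray,
    delta: float,
    start: int,
    n_paths: int,
    rng: np.random.Generator,
):
    """Vectorized Gillespie simulation of ``n_paths`` trajectories over
    ``[0, delta]`` from 0-based ``start``.

    Returns ``(end_state, N, R)``: the 0-based end states, per-path jump
    count matrices ``(n, M, M)`` and per-path occupancy times ``(n, M)``.
    """
    m = Q.shape[0]
    rates = -np.diag(Q)
    P = np.zeros((m, m))
    for i in range(m):
        if rates[i] > 0:
            P[i] = np.clip(Q[i], 0.0, None)
            P[i, i] = 0.0
            P[i] /= P[i].sum()
    cumP = P.cumsum(axis=1)

    state = np.full(n_paths, start, dtype=int)
    t = np.zeros(n_paths)
    N = np.zeros((n_paths, m, m))
    R = np.zeros((n_paths, m))
    active = np.ones(n_paths, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        s = state[idx]
        r = rates[s]
        absorbed = r <= 0
        ia = idx[absorbed]
        R[ia, s[absorbed]] += delta - t[ia]
        active[ia] = False
        idx, s = idx[~absorbed], s[~absorbed]
        if idx.size == 0:
            break
        hold = rng.exponential(1.0 / rates[s])
        t_new = t[idx] + hold
        over = t_new >= delta
        io = idx[over]
        R[io, s[over]] += delta - t[io]
        active[io] = False
        idx2, s2, h2 = idx[~over], s[~over], hold[~over]
        if idx2.size:
            R[idx2, s2] += h2
            u = rng.random(idx2.size)
            nxt = (u[:, None] > cumP[s2]).sum(axis=1)
            N[idx2, s2, nxt] += 1
            state[idx2] = nxt
            t[idx2] = t_new[~over]
    return state, N, R


@pytest.fixture
def small_cohort():
    """A 20-patient cohort simulated from a known 3-state forward chain."""
    from cthmm import ScenarioConfig, VisitModel, simulate_cohort

    params = make_random_params(
        3, 2, seed=7, kind="forward_chain", order=2, rate_scale=0.5,
        mean_spread=4.0,
    )
    config = ScenarioConfig(
        params=params,
        num_patients=20,
        visit_model=VisitModel(mean_visits=4.0),
        entry_window=3.0,
        seed=11,
    )
    cohort, truth = simulate_cohort(config)
    return cohort.filter_min_visits(2), params


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """A small hand-written long-format visit file with quirks to exercise
    the reader: one single-visit patient and one visit missing a feature."""
    text = (
        "patient_id,visit_time,f1,f2,dcl\n"
        "A,0.0,1.0,2.0,0\n"
        "A,1.1,1.5,2.5,1\n"
        "A,2.0,1.8,,2\n"
        "B,0.0,0.5,1.0,0\n"
        "B,0.9,0.7,1.2,1\n"
        "C,0.0,3.0,4.0,4\n"
    )
    path = tmp_path / "toy.csv"
    path.write_text(text)
    return path
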