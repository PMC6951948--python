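"""EM estimation of CTHMM parameters from a longitudinal cohort.

Soft (posterior-weighted) EM throughout: the E-step combines the pairwise
visit posteriors ``xi`` from forward–backward with the endpoint-conditioned
jump-count and sojourn-time expectations from the CTMC core, and the M-step
updates

* ``Q[i, j] = E[N_ij] / E[R_i]`` on mask-allowed entries (rates clipped to
  keep matrix exponentials well-conditioned),
* ``pi`` as the average first-visit posterior,
* ``mu`` and ``sigma2`` as posterior-weighted feature moments.

Viterbi decoding is an output-side operation only; using posteriors rather
than a single decoded sequence inside EM gives the monotone-likelihood
guarantee the tests rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ctmc import StructureMask, TransitionCache
from .model import (
    Cohort,
    CTHMMParams,
    EmissionParams,
    forward_backward,
)

__all__ = [
    "ESuffStats",
    "FitConfig",
    "FitResult",
    "DegenerateStateError",
    "initialize",
    "e_step",
    "m_step",
    "fit",
]

logger = logging.getLogger(__name__)


class DegenerateStateError(RuntimeError):
    """A state accumulated transitions but no occupancy time."""


@dataclass
class FitConfig:
    """Knobs of the EM fit.

    ``rel_tol`` is the relative change in observed-data log-likelihood below
    which EM stops; ``rate_min``/``rate_max`` clip the off-diagonal rates
    (per year) so intermediate generators keep their exponentials
    well-conditioned — disease sojourns of interest span days to decades.
    """

    max_iters: int = 500
    rel_tol: float = 1e-6
    num_restarts: int = 3
    seed: int = 0
    variance_floor: float = 1e-6
    rate_min: float = 1e-6
    rate_max: float = 1e3

    def __post_init__(self) -> None:
        for name in ("max_iters", "rel_tol", "num_restarts", "variance_floor",
                     "rate_min", "rate_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FitConfig.{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "max_iters": self.max_iters,
            "rel_tol": self.rel_tol,
            "num_restarts": self.num_restarts,
            "seed": self.seed,
            "variance_floor": self.variance_floor,
            "rate_min": self.rate_min,
            "rate_max": self.rate_max,
        }


@dataclass
class ESuffStats:
    """Posterior-weighted expected sufficient statistics over a cohort.

    ``exp_N[k, l]`` accumulates expected ``k -> l`` jump counts over all
    patient intervals, ``exp_R[k]`` expected sojourn times (their total
    equals the cohort's observed follow-up time), ``first_visit_gamma`` the
    per-patient first-visit posteriors, and ``moment0/1/2`` the
    gamma-weighted emission count/sum/sum-of-squares tables.
    """

    exp_N: np.ndarray
    exp_R: np.ndarray
    first_visit_gamma: np.ndarray
    moment0: np.ndarray
    moment1: np.ndarray
    moment2: np.ndarray
    loglik: float


def e_step(
    params: CTHMMParams, cohort: Cohort, cache: TransitionCache | None = None
) -> ESuffStats:
    """Accumulate expected sufficient statistics over the cohort.

    For each interval with gap ``delta``, the pairwise posterior
    ``xi[i, j]`` weights the endpoint-conditioned expectations
    ``EN(i,j,·,·)`` and ``ER(i,j,·)`` fetched from a per-``delta`` cache.
    """
    m = params.num_states
    k = params.num_features
    if cache is None:
        cache = TransitionCache(params.Q)

    exp_N = np.zeros((m, m))
    exp_R = np.zeros(m)
    first = np.zeros((len(cohort), m))
    m0 = np.zeros(m)
    m1 = np.zeros((m, k))
    m2 = np.zeros((m, k))
    total_ll = 0.0

    for n, patient in enumerate(cohort):
        post = forward_backward(params, patient, cache)
        total_ll += post.loglik
        first[n] = post.gamma[0]
        m0 += post.gamma.sum(axis=0)
        m1 += post.gamma.T @ patient.observations
        m2 += post.gamma.T @ patient.observations**2
        gaps = np.diff(patient.times)
        for t, delta in enumerate(gaps):
            cond = cache.expectations(delta)
            xi = post.xi[t]
            exp_N += np.tensordot(xi, cond.EN, axes=([0, 1], [0, 1]))
            exp_R += np.tensordot(xi, cond.ER, axes=([0, 1], [0, 1]))

    return ESuffStats(
        exp_N=exp_N,
        exp_R=exp_R,
        first_visit_gamma=first,
        moment0=m0,
        moment1=m1,
        moment2=m2,
        loglik=float(total_ll),
    )


def m_step(stats: ESuffStats, mask: StructureMask, config: FitConfig) -> CTHMMParams:
    """Closed-form parameter updates from expected sufficient statistics."""
    m = mask.num_states
    Q = np.zeros((m, m))
    has_exit = mask.allowed.any(axis=1)
    for i in range(m):
        if not has_exit[i]:
            continue
        js = np.flatnonzero(mask.allowed[i])
        if stats.exp_R[i] <= 0:
            if stats.exp_N[i, js].sum() > 0:
                raise DegenerateStateError(
                    f"state {i + 1} has expected transitions but zero expected "
                    "occupancy time"
                )
            # state never visited: keep a minimal exit rate so A stays supported
            Q[i, js] = config.rate_min
        else:
            Q[i, js] = np.clip(
                stats.exp_N[i, js] / stats.exp_R[i], config.rate_min, config.rate_max
            )
        Q[i, i] = -Q[i, js].sum()

    pi = stats.first_visit_gamma.mean(axis=0)
    pi = pi / pi.sum()

    denom = np.maximum(stats.moment0, 1e-300)[:, None]
    mu = stats.moment1 / denom
    sigma2 = stats.moment2 / denom - mu**2
    sigma2 = np.maximum(sigma2, config.variance_floor)

    return CTHMMParams(
        Q=Q,
        pi=pi,
        emissions=EmissionParams(means=mu, variances=sigma2),
        mask=mask,
    )


def _severity_scores(cohort: Cohort) -> np.ndarray:
    """Project pooled features onto their first principal direction, signed
    so the score increases over within-patient time."""
    X = np.vstack([p.observations for p in cohort])
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    direction = vt[0]
    scores = Xc @ direction
    # average within-patient slope of score against visit time
    slopes = []
    offset = 0
    for p in cohort:
        s = scores[offset : offset + p.num_visits]
        offset += p.num_visits
        if p.num_visits >= 2:
            t = p.times - p.times.mean()
            denom = (t**2).sum()
            if denom > 0:
                slopes.append((t * (s - s.mean())).sum() / denom)
    if slopes and np.mean(slopes) < 0:
        scores = -scores
    return scores


def initialize(cohort: Cohort, mask: StructureMask, seed: int) -> CTHMMParams:
    """K-means initialization with severity-ordered states.

    Clusters the pooled visit features into ``M`` groups, relabels them in
    ascending order of a severity score (first principal direction, oriented
    to increase over within-patient time), and seeds the generator with
    0.3/year on the first allowed transition per row and 0.05/year on the
    second.  Deterministic given ``seed``.
    """
    m = mask.num_states
    X = np.vstack([p.observations for p in cohort])
    if np.unique(X, axis=0).shape[0] < m:
        raise ValueError(
            f"cohort has fewer than {m} distinct observation vectors; "
            "cannot initialize that many states"
        )
    km = KMeans(n_clusters=m, n_init=10, random_state=int(seed) % (2**32))
    # cluster on a canonically sorted copy so the result is invariant to
    # patient order, then label the original rows
    canonical = X[np.lexsort(X.T[::-1])]
    km.fit(canonical)
    labels = km.predict(X)

    scores = _severity_scores(cohort)
    cluster_severity = np.array(
        [scores[labels == c].mean() for c in range(m)]
    )
    order = np.argsort(cluster_severity, kind="stable")
    relabel = np.empty(m, dtype=int)
    relabel[order] = np.arange(m)
    labels = relabel[labels]

    k = cohort.num_features
    mu = np.zeros((m, k))
    sigma2 = np.ones((m, k))
    for s in range(m):
        pts = X[labels == s]
        mu[s] = pts.mean(axis=0)
        sigma2[s] = np.maximum(pts.var(axis=0), VARIANCE_FLOOR_INIT)

    first_idx = np.cumsum([0] + [p.num_visits for p in cohort])[:-1]
    first_labels = labels[first_idx]
    pi = np.bincount(first_labels, minlength=m).astype(float) + 1.0 / m
    pi /= pi.sum()

    Q = np.zeros((m, m))
    for i in range(m):
        js = np.flatnonzero(mask.allowed[i])
        for rank, j in enumerate(js):
            Q[i, j] = 0.3 if rank == 0 else 0.05
        Q[i, i] = -Q[i].sum()

    return CTHMMParams(
        Q=Q,
        pi=pi,
        emissions=EmissionParams(means=mu, variances=sigma2),
        mask=mask,
    )


VARIANCE_FLOOR_INIT = 1e-4


@dataclass
class FitResult:
    """A fitted model with its likelihood trace and provenance."""

    params: CTHMMParams
    loglik_trace: list[float]
    converged: bool
    iterations: int
    seed_used: int
    config: FitConfig = field(repr=False, default_factory=FitConfig)

    @property
    def final_loglik(self) -> float:
        return self.loglik_trace[-1]


def _run_em(
    cohort: Cohort, mask: StructureMask, config: FitConfig, seed: int
) -> FitResult:
    params = initialize(cohort, mask, seed)
    trace: list[float] = []
    converged = False
    for it in range(config.max_iters):
        cache = TransitionCache(params.Q)
        stats = e_step(params, cohort, cache)
        trace.append(stats.loglik)
        logger.debug("restart seed %d iter %d loglik %.6f", seed, it, stats.loglik)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) < config.rel_tol * abs(prev):
                converged = True
                break
        params = m_step(stats, mask, config)
    return FitResult(
        params=params,
        loglik_trace=trace,
        converged=converged,
        iterations=len(trace),
        seed_used=seed,
        config=config,
    )


def fit(cohort: Cohort, mask: StructureMask, config: FitConfig | None = None) -> FitResult:
    """Fit Θ by EM with multiple k-means restarts; returns the best restart.

    Every patient must have at least two visits (single-visit series carry
    no transition information; the reader excludes and counts them).
    """
    if config is None:
        config = FitConfig()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    short = [p.patient_id for p in cohort if p.num_visits < 2]
    if short:
        raise ValueError(
            f"{len(short)} patient(s) have fewer than 2 visits "
            f"(e.g. {short[0]!r}); filter the cohort before fitting"
        )

    best: FitResult | None = None
    errors: list[str] = []
    for r in range(config.num_restarts):
        seed = config.seed + r
        try:
            result = _run_em(cohort, mask, config, seed)
        except DegenerateStateError as exc:
            logger.warning("restart seed %d degenerate: %s", seed, exc)
            errors.append(str(exc))
            continue
        logger.info(
            "restart seed %d: loglik %.4f after %d iters (converged=%s)",
            seed,
            result.final_loglik,
            result.iterations,
            result.converged,
        )
        if best is None or result.final_loglik > best.final_loglik:
            best = result
    if best is None:
        raise DegenerateStateError(
            "all restarts degenerate: " + "; ".join(errors)
        )
    return best
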