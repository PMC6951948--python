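"""Data-driven choice of the number of disease states.

The number of states ``M`` is rarely known for under-studied diseases, so
it is chosen by held-out fit: split the cohort by patient into a training
and a testing side, fit one model per candidate ``M`` on the training side,
and score each on the testing side by total log-likelihood.  The candidate
with the highest held-out log-likelihood wins; ties break toward the
smaller (more parsimonious) ``M``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ctmc import build_structure_mask
from .em import FitConfig, FitResult, fit
from .model import Cohort, cohort_loglik

__all__ = ["SelectionResult", "split_cohort", "select_num_states"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Held-out log-likelihood curve over candidate state counts.

    ``test_loglik`` is NaN for candidates whose fit failed; the failure
    message is kept in ``errors`` under the candidate's ``M``.
    """

    grid: list[int]
    test_loglik: list[float]
    chosen_m: int
    fits: dict[int, FitResult] = field(repr=False, default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)
    split_seed: int = 0

    def curve(self) -> "np.ndarray":
        """(len(grid), 2) array of (M, held-out log-likelihood)."""
        return np.column_stack([self.grid, self.test_loglik])


def split_cohort(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Random patient-level train/test split, deterministic given ``seed``.

    Splitting is always by patient — a patient's visits never straddle the
    two sides — so the held-out score measures generalization to new
    patients, not interpolation within known trajectories.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty side for {n} patients"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = {cohort.patients[i].patient_id for i in perm[:n_train]}
    train = cohort.subset(train_ids)
    test = cohort.subset(
        p.patient_id for p in cohort if p.patient_id not in train_ids
    )
    return train, test


def select_num_states(
    cohort: Cohort,
    grid: list[int],
    mask_kind: str = "forward_chain",
    order: int = 2,
    absorbing_last: bool = True,
    config: FitConfig | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    per_visit: bool = False,
) -> SelectionResult:
    """Fit each candidate ``M`` on the training side and score it held-out.

    ``per_visit=True`` normalizes the held-out log-likelihood by the number
    of test visits, an option for strongly unbalanced cohorts; the default
    is the plain total.  For ``forward_chain`` masks the order is capped at
    ``M - 1`` so small candidates remain well-defined.  A failed candidate
    is recorded (NaN score) rather than aborting the grid.
    """
    grid = [int(m) for m in grid]
    if not grid:
        raise ValueError("grid is empty")
    if any(m < 2 for m in grid):
        raise ValueError("every candidate M must be >= 2")
    if sorted(set(grid)) != grid:
        raise ValueError("grid must be strictly increasing")
    if config is None:
        config = FitConfig()

    train, test = split_cohort(cohort, train_fraction, seed)
    n_test_visits = test.num_visits

    scores: list[float] = []
    fits: dict[int, FitResult] = {}
    errors: dict[int, str] = {}
    for m in grid:
        kwargs = {"kind": mask_kind, "absorbing_last": absorbing_last}
        if mask_kind == "forward_chain":
            kwargs["order"] = min(order, m - 1)
        mask = build_structure_mask(m, **kwargs)
        try:
            result = fit(train, mask, config)
            score = cohort_loglik(result.params, test)
            if per_visit:
                score /= n_test_visits
            fits[m] = result
            scores.append(float(score))
            logger.info("M=%d held-out loglik %.4f", m, score)
        except Exception as exc:  # noqa: BLE001 - record and continue the grid
            errors[m] = str(exc)
            scores.append(float("nan"))
            logger.warning("M=%d failed: %s", m, exc)

    if np.all(np.isnan(scores)):
        raise RuntimeError(
            "every candidate failed: "
            + "; ".join(f"M={m}: {msg}" for m, msg in errors.items())
        )
    # first occurrence of the max = smallest M on ties (grid is increasing)
    chosen = grid[int(np.nanargmax(scores))]
    return SelectionResult(
        grid=grid,
        test_loglik=scores,
        chosen_m=chosen,
        fits=fits,
        errors=errors,
        split_seed=seed,
    )
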