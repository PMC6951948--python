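"""Continuous-time Markov chain core.

A progression process over ``M`` disease states is parameterized by an
``M x M`` generator matrix ``Q`` whose off-diagonal entry ``Q[i, j]`` is the
instantaneous rate (per year) of jumping from state ``i`` to state ``j``.
Rows sum to zero, so the diagonal is determined by the off-diagonal rates and
``-1/Q[i, i]`` is the expected sojourn time in state ``i``.  Structural
assumptions about the disease (irreversibility, limited jump range, terminal
absorbing states) are expressed as a boolean mask over the off-diagonal
entries of ``Q``.

Transition probabilities over an elapsed time ``delta`` are
``A(delta) = expm(delta * Q)``, and the endpoint-conditioned expectations
needed by the EM algorithm — the expected number of ``k -> l`` jumps and the
expected time spent in ``k`` during an interval, given the states at both
ends — are obtained from matrix exponentials of an auxiliary ``2M x 2M``
block matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "StructureMask",
    "ConditionedExpectations",
    "GeneratorViolation",
    "TransitionCache",
    "build_structure_mask",
    "validate_generator",
    "transition_matrix",
    "conditioned_expectations",
    "expected_durations",
    "reachability_pattern",
]

#: generator row sums must vanish to this absolute tolerance
ROW_SUM_TOL = 1e-10

#: elapsed times are canonicalized to this grid (years) before caching, so
#: repeated intervals (e.g. exact annual visits) share one matrix exponential
DELTA_DECIMALS = 6

#: transition probabilities smaller than this are treated as structurally
#: unreachable when normalizing endpoint-conditioned expectations
_REACH_EPS = 1e-300


@dataclass(frozen=True)
class StructureMask:
    """Which instantaneous transitions a generator may use.

    Parameters
    ----------
    num_states
        Number of disease states ``M >= 2``.
    allowed
        Boolean ``(M, M)`` array; ``allowed[i, j]`` permits an instantaneous
        ``i -> j`` jump.  The diagonal is always ``False`` (it is determined
        by the row-sum constraint, not a free transition).
    absorbing
        Boolean ``(M,)`` flags; an absorbing state has no allowed exits.
    kind
        ``"full"``, ``"forward"`` or ``"forward_chain"``.
    order
        Chain order ``L`` for ``forward_chain`` masks, else ``None``.
    """

    num_states: int
    allowed: np.ndarray
    absorbing: np.ndarray
    kind: str = "custom"
    order: int | None = None

    def __post_init__(self) -> None:
        allowed = np.asarray(self.allowed, dtype=bool).copy()
        np.fill_diagonal(allowed, False)
        allowed[np.asarray(self.absorbing, dtype=bool), :] = False
        object.__setattr__(self, "allowed", allowed)
        object.__setattr__(
            self, "absorbing", np.asarray(self.absorbing, dtype=bool).copy()
        )

    def to_dict(self) -> dict:
        return {
            "num_states": int(self.num_states),
            "mask_kind": self.kind,
            "order": None if self.order is None else int(self.order),
            "allowed": self.allowed.astype(int).ravel().tolist(),
            "absorbing": [int(i) + 1 for i in np.flatnonzero(self.absorbing)],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "StructureMask":
        m = int(payload["num_states"])
        allowed = np.asarray(payload["allowed"], dtype=bool).reshape(m, m)
        absorbing = np.zeros(m, dtype=bool)
        for label in payload.get("absorbing", []):
            absorbing[int(label) - 1] = True
        return cls(
            num_states=m,
            allowed=allowed,
            absorbing=absorbing,
            kind=payload.get("mask_kind", "custom"),
            order=payload.get("order"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_structure_mask(
    num_states: int,
    kind: str = "forward_chain",
    order: int = 2,
    absorbing_last: bool = True,
) -> StructureMask:
    """Build the transition mask for a named progression-model family.

    ``full`` permits every off-diagonal jump (progression and recovery);
    ``forward`` permits only jumps to strictly later states; and
    ``forward_chain`` of order ``L`` permits jumps only to the next ``L``
    states.  With ``absorbing_last`` the final state has no exits, modelling
    a terminal stage.
    """
    m = int(num_states)
    if m < 2:
        raise ValueError(f"num_states must be >= 2, got num_states={m}")
    i, j = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    if kind == "full":
        allowed = i != j
        order_out = None
    elif kind == "forward":
        allowed = j > i
        order_out = None
    elif kind == "forward_chain":
        ell = int(order)
        if not 1 <= ell <= m - 1:
            raise ValueError(
                f"order must satisfy 1 <= order <= num_states - 1, got order={ell}"
            )
        allowed = (j > i) & (j <= i + ell)
        order_out = ell
    else:
        raise ValueError(f"unknown mask kind={kind!r}")
    absorbing = np.zeros(m, dtype=bool)
    if absorbing_last:
        absorbing[m - 1] = True
        allowed = allowed.copy()
        allowed[m - 1, :] = False
    return StructureMask(
        num_states=m, allowed=allowed, absorbing=absorbing, kind=kind, order=order_out
    )


@dataclass(frozen=True)
class GeneratorViolation:
    """One violated generator invariant, with the offending indices (0-based)."""

    code: str
    indices: tuple
    message: str


def validate_generator(Q: np.ndarray, mask: StructureMask) -> list[GeneratorViolation]:
    """Report every invariant of ``Q`` violated under ``mask``.

    Never raises; an empty report means the generator is valid.
    """
    Q = np.asarray(Q, dtype=float)
    report: list[GeneratorViolation] = []
    m = mask.num_states
    if Q.shape != (m, m):
        report.append(
            GeneratorViolation(
                "shape", Q.shape, f"expected shape {(m, m)}, got {Q.shape}"
            )
        )
        return report
    off = ~np.eye(m, dtype=bool)
    for i, j in zip(*np.nonzero(off & (Q < 0))):
        report.append(
            GeneratorViolation(
                "negative_rate",
                (int(i), int(j)),
                f"off-diagonal rate Q[{i},{j}]={Q[i, j]} is negative",
            )
        )
    for i, j in zip(*np.nonzero(off & ~mask.allowed & (Q != 0))):
        report.append(
            GeneratorViolation(
                "masked_entry",
                (int(i), int(j)),
                f"Q[{i},{j}]={Q[i, j]} must be 0 (transition not allowed by mask)",
            )
        )
    row_sums = Q.sum(axis=1)
    for i in np.flatnonzero(np.abs(row_sums) > ROW_SUM_TOL):
        report.append(
            GeneratorViolation(
                "row_sum",
                (int(i),),
                f"row {i} sums to {row_sums[i]}, expected 0",
            )
        )
    return report


def require_valid_generator(Q: np.ndarray, mask: StructureMask) -> np.ndarray:
    """Return ``Q`` as a float array, raising on the first invariant violation."""
    Q = np.asarray(Q, dtype=float)
    report = validate_generator(Q, mask)
    if report:
        details = "; ".join(v.message for v in report[:5])
        raise ValueError(f"invalid generator matrix: {details}")
    return Q


def reachability_pattern(Q: np.ndarray) -> np.ndarray:
    """Boolean matrix of state pairs connected by some admissible path.

    ``A(delta)[i, j]`` can be nonzero only where this pattern is ``True``;
    the pattern is used to pin structural zeros of the matrix exponential
    (e.g. the lower triangle under a forward mask) to exact zeros.
    """
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    step = (Q != 0) | np.eye(m, dtype=bool)
    reach = np.eye(m, dtype=bool)
    for _ in range(m):
        new = reach @ step
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def _canonical_delta(delta: float) -> float:
    return round(float(delta), DELTA_DECIMALS)


def transition_matrix(Q: np.ndarray, delta: float) -> np.ndarray:
    """Transition probabilities ``A(delta) = expm(delta * Q)``.

    Entries outside the reachability pattern of ``Q`` are pinned to exact
    zero and tiny negative round-off is clipped, so the result is
    row-stochastic and structurally faithful to the mask.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got delta={delta}")
    Q = np.asarray(Q, dtype=float)
    if delta == 0:
        return np.eye(Q.shape[0])
    A = expm(delta * Q)
    A[~reachability_pattern(Q)] = 0.0
    np.clip(A, 0.0, 1.0, out=A)
    return A


@dataclass(frozen=True)
class ConditionedExpectations:
    """Endpoint-conditioned jump counts and sojourn times over one interval.

    ``EN[i, j, k, l]`` is the expected number of ``k -> l`` jumps during
    ``(0, delta)`` given the chain starts in ``i`` and ends in ``j``;
    ``ER[i, j, k]`` is the expected time spent in ``k`` under the same
    conditioning.  Entries for endpoint pairs with ``A(delta)[i, j] = 0``
    are zero.  For every reachable pair, ``ER[i, j, :].sum() == delta``.
    """

    EN: np.ndarray
    ER: np.ndarray
    delta: float
    A: np.ndarray = field(repr=False)


def _interval_integral(Q: np.ndarray, delta: float, k: int, l: int) -> np.ndarray:
    """``D[i, j] = int_0^delta A(s)[i, k] * A(delta - s)[l, j] ds``.

    Computed as the top-right block of ``expm(delta * [[Q, B], [0, Q]])``
    with ``B`` the unit matrix at ``(k, l)`` — robust for defective ``Q``
    (tied rates in forward chains make eigendecompositions unreliable).
    """
    m = Q.shape[0]
    C = np.zeros((2 * m, 2 * m))
    C[:m, :m] = Q
    C[m:, m:] = Q
    C[k, m + l] = 1.0
    D = expm(delta * C)[:m, m:]
    np.clip(D, 0.0, None, out=D)
    return D


def conditioned_expectations(Q: np.ndarray, delta: float) -> ConditionedExpectations:
    """Expected jump counts ``EN`` and sojourn times ``ER`` for one interval,
    conditioned on the states at both endpoints.

    These are the E-step building blocks: for an interval of length ``delta``
    between visits with posterior endpoint weights ``xi[i, j]``, the expected
    sufficient statistics are ``sum_ij xi[i, j] * EN[i, j]`` and
    ``sum_ij xi[i, j] * ER[i, j]``.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got delta={delta}")
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    A = transition_matrix(Q, delta)
    reachable = A > _REACH_EPS
    inv_A = np.zeros_like(A)
    inv_A[reachable] = 1.0 / A[reachable]

    ER = np.zeros((m, m, m))
    for k in range(m):
        ER[:, :, k] = _interval_integral(Q, delta, k, k) * inv_A

    EN = np.zeros((m, m, m, m))
    off = ~np.eye(m, dtype=bool)
    for k, l in zip(*np.nonzero(off & (Q != 0))):
        EN[:, :, k, l] = Q[k, l] * _interval_integral(Q, delta, k, l) * inv_A

    return ConditionedExpectations(EN=EN, ER=ER, delta=float(delta), A=A)


def expected_durations(Q: np.ndarray, absorbing: np.ndarray | None = None) -> np.ndarray:
    """Expected sojourn time per state, ``-1 / Q[i, i]`` years.

    Absorbing states (zero exit rate, or flagged explicitly) have no defined
    duration and are reported as ``nan``.
    """
    Q = np.asarray(Q, dtype=float)
    diag = np.diag(Q)
    if absorbing is None:
        absorbing = diag == 0
    else:
        absorbing = np.asarray(absorbing, dtype=bool) | (diag == 0)
    out = np.full(Q.shape[0], np.nan)
    active = ~absorbing
    out[active] = -1.0 / diag[active]
    return out


class TransitionCache:
    """Per-generator cache of ``A(delta)`` and conditioned expectations.

    Elapsed times are canonicalized by rounding to ``10**-DELTA_DECIMALS``
    years before lookup, so repeated gaps (annual visits, date-grid data)
    share one matrix exponential.  The cache is tied to one ``Q`` and must
    be discarded when the generator changes (each EM iteration).
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self._A: dict[float, np.ndarray] = {}
        self._cond: dict[float, ConditionedExpectations] = {}

    def transition(self, delta: float) -> np.ndarray:
        # key on the canonical delta, compute at the exact one: equal gaps
        # share work, and sub-microyear collisions are below data precision
        key = _canonical_delta(delta)
        if key not in self._A:
            self._A[key] = transition_matrix(self.Q, float(delta))
        return self._A[key]

    def expectations(self, delta: float) -> ConditionedExpectations:
        key = _canonical_delta(delta)
        if key not in self._cond:
            self._cond[key] = conditioned_expectations(self.Q, float(delta))
        return self._cond[key]
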