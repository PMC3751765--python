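"""Priority derivation by the principal right eigenvector, and consistency.

For a positive reciprocal matrix ``A`` the priority vector ``w`` solves
``A w = lambda_max w`` with ``w > 0`` summing to one (Perron-Frobenius
guarantees existence and uniqueness). ``lambda_max >= n`` always, with
equality iff the matrix is consistent (``a_ij a_jk = a_ik``); the excess
drives the consistency index CI = (lambda_max - n)/(n - 1) and the
consistency ratio CR = CI/RI, where RI is the mean CI of random reciprocal
matrices of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, DesignError
from .judgments import PairwiseMatrix

#: Classical random-index table (mean CI of random reciprocal matrices drawn
#: from the 1-9 scale), indexed by matrix size; sizes 1-2 admit no
#: inconsistency. Extended to n=10 to cover the 9-innovations-plus-baseline
#: block.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Conventional CR acceptability threshold; reports warn rather than fail
#: above it (moderately inconsistent panels are still interpretable).
DEFAULT_CR_THRESHOLD = 0.10


@dataclass(frozen=True)
class PriorityVector:
    """Normalized priorities plus the principal eigenvalue they came from."""

    items: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.items) != self.weights.shape[0]:
            raise DesignError("items and weights length mismatch")

    @property
    def n(self) -> int:
        return len(self.items)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights.tolist()))

    def __getitem__(self, item: str) -> float:
        return float(self.weights[self.items.index(item)])


@dataclass(frozen=True)
class ConsistencyReport:
    """CI/CR diagnostics for one judgment matrix."""

    n: int
    ci: float
    ri: float
    cr: float
    threshold: float
    acceptable: bool


def principal_eigenvector(
    m: PairwiseMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> PriorityVector:
    """Power iteration for the principal right eigenvector of ``m``.

    Starts from the uniform vector, renormalizes to unit sum each step, and
    stops when successive vectors differ by less than ``tol`` in max norm.
    ``lambda_max`` is the mean of the component-wise Rayleigh ratios
    ``(A w)_i / w_i`` at convergence — exact for consistent matrices and
    stable near consistency.

    Non-convergence raises :class:`ComputationError`; this is defensive only,
    as the iteration converges for every positive matrix.
    """
    a = m.values
    w = np.full(m.n, 1.0 / m.n)
    for _ in range(max_iter):
        aw = a @ w
        w_next = aw / aw.sum()
        if np.max(np.abs(w_next - w)) < tol:
            lam = float(np.mean((a @ w_next) / w_next))
            return PriorityVector(items=m.items, weights=w_next, lambda_max=lam)
        w = w_next
    raise ComputationError(f"power iteration did not converge in {max_iter} steps")


def consistency(
    pv: PriorityVector, threshold: float = DEFAULT_CR_THRESHOLD
) -> ConsistencyReport:
    """Consistency diagnostics from a matrix's priority vector.

    CI = (lambda_max - n)/(n - 1); CR = CI/RI with the random index from
    :data:`RANDOM_INDEX` (CR = 0 by convention when RI = 0, i.e. n <= 2).
    Matrices larger than the embedded table (n > 10) are an error.
    """
    n = pv.n
    if n not in RANDOM_INDEX:
        raise DesignError(f"no random index for matrix size {n} (table covers 1-10)")
    # clip tiny negative CI from floating-point lambda_max on consistent input
    ci = max(0.0, (pv.lambda_max - n) / (n - 1)) if n > 1 else 0.0
    ri = RANDOM_INDEX[n]
    cr = ci / ri if ri > 0 else 0.0
    return ConsistencyReport(
        n=n, ci=ci, ri=ri, cr=cr, threshold=threshold, acceptable=cr <= threshold
    )


def cr_acceptable(cr: float, threshold: float = DEFAULT_CR_THRESHOLD) -> bool:
    """Acceptability screen applied to an already-computed consistency ratio."""
    if cr < 0:
        raise DesignError(f"consistency ratio cannot be negative, got {cr}")
    return cr <= threshold


def star_priorities(
    ratios, items: tuple[str, ...] | None = None, baseline: str = "current_care"
) -> PriorityVector:
    """Closed-form priorities for a star (hub) design.

    Given ratios ``a_i0`` of m alternatives against the hub, the completed
    matrix is consistent and its eigenvector is proportional to
    ``(1, a_10, ..., am0)``: hub weight ``1/(1 + sum a_i0)``, alternative i
    ``a_i0/(1 + sum a_i0)``. ``lambda_max`` is exactly m+1. Item order is
    ``(baseline, *alternatives)``, matching :func:`ahpgroup.judgments.star_matrix`.
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise DesignError("ratios must be a non-empty 1-d vector")
    if np.any(r <= 0):
        raise DesignError("star ratios must be positive")
    if items is None:
        items = (baseline, *(f"alt_{i+1}" for i in range(r.size)))
    if len(items) != r.size + 1:
        raise DesignError("items must have length m+1 (hub first)")
    col = np.concatenate(([1.0], r))
    return PriorityVector(items=tuple(items), weights=col / col.sum(),
                          lambda_max=float(r.size + 1))


def geometric_mean_weights(m: PairwiseMatrix) -> np.ndarray:
    """Row geometric-mean weights (logarithmic least squares).

    Coincides with the eigenvector for consistent matrices; kept as a
    secondary derivation for cross-checks, not as the primary method.
    """
    g = np.exp(np.mean(np.log(m.values), axis=1))
    return g / g.sum()
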