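"""Gaussian-approximation transfer entropy and mutual information.

Under a multivariate-normal approximation of the joint response
distribution, the transfer entropy from a cause channel Y to a result
channel X at target time t, with reference time Tr and causal time Tc,
reduces to a ratio of conditional variances

    TE = 1/2 * ln[ Var(X_t | X_Tr) / Var(X_t | X_Tr, Y_Tc) ]   (nats),

where each conditional variance is the Schur complement of the
corresponding block of the sample covariance matrix.  This equals the
mutual-information difference I(X_t; X_Tr, Y_Tc) - I(X_t; X_Tr), which
serves as an independent oracle in the test suite.

All quantities are in nats (natural log); :func:`nats_to_bits` converts.
The covariance variable order used throughout is
``(result_t, result_tr, cause_tc)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import PairedDataset

__all__ = [
    "TEQuery",
    "CovTriplet",
    "TEEstimate",
    "sample_covariance",
    "cov_triplet",
    "conditional_variance",
    "gaussian_te",
    "gaussian_mi",
    "te_estimate",
    "nats_to_bits",
    "DegenerateDataError",
]

#: negative TE values above this magnitude are treated as numerical
#: round-off and clipped to zero; larger negatives indicate invalid input
NEG_TOL = 1e-12

DIRECTIONS = ("fw", "bw")


class DegenerateDataError(ValueError):
    """Raised when a covariance block is singular and no ridge is enabled."""


@dataclass(frozen=True)
class TEQuery:
    """One TE evaluation point.

    ``direction``: ``"fw"`` (cause channel -> result channel) or ``"bw"``
    (roles swapped).  ``tc`` is the causal time, ``tr`` the reference
    time (defaults to ``tc``, the standard setting), ``t`` the target
    time; all in minutes with ``tc < t`` and ``tr < t``.
    """

    direction: str
    tc: float
    t: float
    tr: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        tr = self.tc if self.tr is None else self.tr
        object.__setattr__(self, "tr", float(tr))
        if not (self.tr < self.t and self.tc < self.t):
            raise ValueError("TE query requires tr < t and tc < t")


@dataclass(frozen=True)
class CovTriplet:
    """3x3 covariance over (result_t, result_tr, cause_tc) with sample size n."""

    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("CovTriplet needs a 3x3 matrix")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.n < 3:
            raise ValueError("need n >= 3 samples")
        ev = np.linalg.eigvalsh(s)
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("covariance is not positive semidefinite")
        s.setflags(write=False)
        object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class TEEstimate:
    """A TE value (nats) with optional significance annotation."""

    value: float
    query: TEQuery
    n: int
    threshold: float | None = None
    significant: bool = False


def sample_covariance(columns, ddof: int = 1) -> np.ndarray:
    """Unbiased (n-1 denominator) sample covariance of per-cell columns.

    Zero-variance columns are flagged with a warning, not an error:
    downstream Schur complements decide whether they are fatal.
    """
    cols = [np.asarray(c, dtype=float) for c in columns]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("columns must have equal length")
    if n < 3:
        raise ValueError("need at least 3 samples for a covariance estimate")
    mat = np.vstack(cols)
    sigma = np.cov(mat, ddof=ddof)
    sigma = np.atleast_2d(sigma)
    if np.any(np.diag(sigma) == 0):
        warnings.warn("zero-variance column in covariance estimate", stacklevel=2)
    return sigma


def cov_triplet(result_t, result_tr, cause_tc) -> CovTriplet:
    """Covariance of the ordered triplet used by :func:`gaussian_te`."""
    sigma = sample_covariance([result_t, result_tr, cause_tc])
    return CovTriplet(sigma, len(np.asarray(result_t)))


def conditional_variance(sigma: np.ndarray | CovTriplet, target: int, given, ridge: float = 0.0) -> float:
    """Schur-complement conditional variance Var(target | given).

    ``ridge`` adds epsilon*I to the given-block before inversion; by
    default a singular given-block is fatal (silent regularization would
    bias TE).
    """
    s = sigma.sigma if isinstance(sigma, CovTriplet) else np.asarray(sigma, dtype=float)
    given = list(given)
    if not given:
        return float(s[target, target])
    block = s[np.ix_(given, given)] + ridge * np.eye(len(given))
    cross = s[target, given]
    try:
        sol = np.linalg.solve(block, cross)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "singular conditioning block; enable ridge regularization to proceed"
        ) from exc
    if np.linalg.cond(block) > 1e12:
        raise DegenerateDataError(
            "near-singular conditioning block; enable ridge regularization to proceed"
        )
    return float(s[target, target] - cross @ sol)


def gaussian_te(sigma: np.ndarray | CovTriplet, ridge: float = 0.0) -> float:
    """TE in nats from a (result_t, result_tr, cause_tc) covariance."""
    v_ref = conditional_variance(sigma, 0, [1], ridge=ridge)
    v_full = conditional_variance(sigma, 0, [1, 2], ridge=ridge)
    if v_full <= 0:
        raise DegenerateDataError("zero conditional variance; TE undefined")
    te = 0.5 * np.log(v_ref / v_full)
    if te < 0:
        if te < -NEG_TOL:
            raise ValueError(f"negative TE beyond round-off ({te:g}); invalid covariance")
        te = 0.0
    return float(te)


def gaussian_mi(sigma: np.ndarray | float) -> float:
    """Gaussian mutual information in nats: -1/2 ln(1 - rho^2).

    Accepts a 2x2 covariance matrix or a correlation coefficient.
    """
    if np.isscalar(sigma):
        rho = float(sigma)
    else:
        s = np.asarray(sigma, dtype=float)
        if s.shape != (2, 2):
            raise ValueError("expected a 2x2 covariance matrix or a correlation")
        if s[0, 0] <= 0 or s[1, 1] <= 0:
            raise ValueError("variances must be positive")
        rho = s[0, 1] / np.sqrt(s[0, 0] * s[1, 1])
    if abs(rho) >= 1:
        raise ValueError("|rho| = 1 implies infinite mutual information")
    return float(-0.5 * np.log1p(-rho * rho))


def nats_to_bits(x: float) -> float:
    return float(x) / float(np.log(2.0))


def query_columns(dataset: PairedDataset, query: TEQuery):
    """Extract the (result_t, result_tr, cause_tc) per-cell columns.

    ``fw`` uses the dataset's cause channel as cause; ``bw`` swaps the
    channel roles.
    """
    cause_m = dataset.cause if query.direction == "fw" else dataset.result
    result_m = dataset.result if query.direction == "fw" else dataset.cause
    return (
        result_m.column(query.t),
        result_m.column(query.tr),
        cause_m.column(query.tc),
    )


def te_estimate(dataset: PairedDataset, query: TEQuery, min_cells: int = 50, ridge: float = 0.0) -> TEEstimate:
    """Point estimate of TE for one query (no significance threshold)."""
    n = dataset.n_cells
    if n < min_cells:
        raise ValueError(f"only {n} cells; need at least {min_cells}")
    a, b, c = query_columns(dataset, query)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        triplet = cov_triplet(a, b, c)
    return TEEstimate(gaussian_te(triplet, ridge=ridge), query, n)


# ---------------------------------------------------------------------------
# vectorized moment path (used by the resampling machinery)


def te_from_moments(saa, sbb, scc, sab, sac, sbc):
    """Vectorized TE from second moments of (a=result_t, b=result_tr, c=cause_tc).

    Closed form of the scalar Schur complements; broadcasts over arrays
    of moments (one entry per permutation/bootstrap replicate).
    """
    saa, sbb, scc, sab, sac, sbc = np.broadcast_arrays(saa, sbb, scc, sab, sac, sbc)
    v_ref = saa - sab * sab / sbb
    det = sbb * scc - sbc * sbc
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (sab * sab * scc - 2.0 * sab * sac * sbc + sac * sac * sbb) / det
        v_full = saa - quad
        te = 0.5 * np.log(v_ref / v_full)
    if np.any(~np.isfinite(te)):
        raise DegenerateDataError("degenerate moments in TE evaluation")
    te = np.where((te < 0) & (te > -NEG_TOL), 0.0, te)
    if np.any(te < 0):
        raise ValueError("negative TE beyond round-off in moment path")
    return te
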