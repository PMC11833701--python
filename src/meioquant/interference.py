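"""Crossover-interference estimation via the gamma shape factor.

Crossover (CO) interference makes neighbouring COs on the same chromosome
more evenly spaced than expected under random placement.  A standard way of
quantifying its strength is to fit a gamma distribution to the distances
between consecutive COs (genetic data) or between consecutive cytological CO
markers such as COSA-1 foci, each distance normalized by the length of its
chromosome.  The fitted shape factor ``gamma`` reads directly as an
interference strength: shape 1 corresponds to the memoryless (exponential)
gap distribution of a Poisson process, i.e. no interference; larger shapes
correspond to increasingly regular spacing (positive interference) and
shapes below 1 to clustering (negative interference).

The fit is a full two-parameter maximum-likelihood fit.  The scale is
profiled out analytically (``scale = mean / shape``), leaving a concave
one-dimensional profile log-likelihood in the shape whose root is found by
bracketed root finding on its derivative.  The standard error of the shape
is the inverse square root of the observed profile information, which
equals the shape entry of the inverse observed Fisher information of the
two-parameter fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "FocusSet",
    "InterferenceFit",
    "interfocus_distances",
    "fit_gamma_interference",
    "gamma_fit_curve",
]

DEFAULT_SHAPE_CAP = 1000.0


@dataclass(frozen=True)
class FocusSet:
    """Ordered focus (or CO) positions on one chromosome.

    Parameters
    ----------
    chromosome_id:
        Identifier of the chromosome or synaptonemal-complex trace.
    length:
        Physical length of the chromosome: micrometres for cytological
        traces, base pairs for genomic chromosomes.  Must be positive.
    positions:
        Focus/CO coordinates in ``[0, length]``, sorted ascending.
    """

    chromosome_id: str
    length: float
    positions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.length) or self.length <= 0:
            raise InvalidInputError(
                f"chromosome {self.chromosome_id!r}: length must be positive, "
                f"got {self.length}"
            )
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", tuple(pos.tolist()))
        if pos.size:
            if np.any(np.diff(pos) < 0):
                raise InvalidInputError(
                    f"chromosome {self.chromosome_id!r}: positions must be sorted"
                )
            if pos[0] < 0 or pos[-1] > self.length:
                raise InvalidInputError(
                    f"chromosome {self.chromosome_id!r}: positions must lie in "
                    f"[0, {self.length}]"
                )

    @property
    def n_foci(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class InterferenceFit:
    """Result of a maximum-likelihood gamma fit to normalized distances."""

    shape: float
    scale: float
    loglik: float
    shape_se: float | None
    n: int
    capped: bool = False


def interfocus_distances(foci: Iterable[FocusSet]) -> np.ndarray:
    """Consecutive inter-focus distances, normalized per chromosome.

    Each chromosome with ``k >= 2`` foci contributes its ``k - 1``
    consecutive gaps divided by that chromosome's length; chromosomes with
    fewer than two foci contribute nothing.  Distances from all chromosomes
    are pooled.  Zero-width gaps (coincident foci) are dropped so that every
    returned value lies in ``(0, 1]``.
    """
    out: list[np.ndarray] = []
    for fs in foci:
        if not isinstance(fs, FocusSet):
            fs = FocusSet(*fs)
        if fs.n_foci < 2:
            continue
        gaps = np.diff(np.asarray(fs.positions, dtype=float)) / fs.length
        out.append(gaps[gaps > 0])
    if not out:
        return np.empty(0, dtype=float)
    return np.concatenate(out)


def _profile_score(shape: float, n: int, mean_log: float, log_mean: float) -> float:
    # d/dk of the profile log-likelihood, up to the positive factor n
    return mean_log - log_mean + np.log(shape) - special.digamma(shape)


def _profile_loglik(shape: float, n: int, mean_log: float, mean: float) -> float:
    scale = mean / shape
    return n * (
        (shape - 1.0) * mean_log
        - shape
        - shape * np.log(scale)
        - special.gammaln(shape)
    )


def fit_gamma_interference(
    distances: Sequence[float] | np.ndarray,
    shape_cap: float = DEFAULT_SHAPE_CAP,
) -> InterferenceFit:
    """Maximum-likelihood gamma fit to normalized inter-focus distances.

    Both shape and scale are free.  If the shape estimate reaches
    ``shape_cap`` (which happens e.g. in the zero-variance limit, where the
    MLE diverges), the fit is reported with ``capped=True`` and an undefined
    standard error.

    Raises
    ------
    InsufficientDataError
        If fewer than two distances are supplied.
    InvalidInputError
        If any distance is non-positive or non-finite.
    """
    if shape_cap <= 0:
        raise InvalidInputError(f"shape_cap must be positive, got {shape_cap}")
    x = np.asarray(distances, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise InsufficientDataError(
            f"gamma fit requires at least 2 distances, got {x.size}"
        )
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise InvalidInputError("all distances must be finite and > 0")

    n = int(x.size)
    mean = float(np.mean(x))
    mean_log = float(np.mean(np.log(x)))
    log_mean = float(np.log(mean))

    lo = 1e-8
    score_hi = _profile_score(shape_cap, n, mean_log, log_mean)
    if score_hi >= 0:
        # likelihood still increasing at the cap (includes zero-variance data)
        shape = float(shape_cap)
        scale = mean / shape
        return InterferenceFit(
            shape=shape,
            scale=scale,
            loglik=_profile_loglik(shape, n, mean_log, mean),
            shape_se=None,
            n=n,
            capped=True,
        )
    shape = float(
        optimize.brentq(
            _profile_score, lo, shape_cap, args=(n, mean_log, log_mean), xtol=1e-12
        )
    )
    scale = mean / shape
    # observed profile information: -d2l/dk2 = n * (psi'(k) - 1/k)
    info = n * (special.polygamma(1, shape) - 1.0 / shape)
    shape_se = float(1.0 / np.sqrt(info)) if info > 0 else None
    return InterferenceFit(
        shape=shape,
        scale=float(scale),
        loglik=float(_profile_loglik(shape, n, mean_log, mean)),
        shape_se=shape_se,
        n=n,
        capped=False,
    )


def gamma_fit_curve(
    fit: InterferenceFit, grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Gamma CDF of a fit evaluated on a grid, for ECDF overlays."""
    g = np.asarray(grid, dtype=float)
    if np.any(g < 0):
        raise InvalidInputError("grid values must be non-negative")
    return stats.gamma.cdf(g, a=fit.shape, scale=fit.scale)
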