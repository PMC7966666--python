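"""Uniform cubic B-spline bases with difference penalties (P-splines).

The latent log-mortality trend in the main model is a penalised B-spline:
coefficients sit on equally spaced knots and a second-order difference
penalty shrinks the fitted curve toward a straight line in log space.  The
basis extends past the last observation year so that short-term projection
years are inside the span; beyond the data, only the penalty informs the
coefficients, which is what produces widening projection uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_basis", "difference_matrix"]


def difference_matrix(n: int, order: int = 2) -> np.ndarray:
    """Dense d-th order difference operator of shape (n - order, n)."""
    if order >= n:
        raise ValueError("difference order must be smaller than the dimension")
    return np.diff(np.eye(n), n=order, axis=0)


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis on equally spaced knots over a closed year domain.

    Attributes
    ----------
    domain : tuple of float
        (year_min, year_max); evaluation outside raises.
    knot_spacing : float
        Distance between adjacent knots, in years.
    degree : int
        Polynomial degree of the basis (3 = cubic).
    knots : ndarray
        Full knot vector, extended ``degree`` knots past each end of the
        domain so the basis is a partition of unity on the whole domain.
    """

    domain: tuple[float, float]
    knot_spacing: float
    degree: int
    knots: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate the basis at times ``t`` -> matrix (len(t), n_basis)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(
                f"evaluation time outside basis domain [{lo}, {hi}]"
            )
        t = np.clip(t, lo, hi - 1e-9 * self.knot_spacing)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        """Difference penalty matrix D such that D @ alpha are the
        order-th differences of the coefficient vector."""
        return difference_matrix(self.n_basis, order)


def build_basis(
    year_min: float,
    year_max: float,
    knot_spacing: float = 2.5,
    degree: int = 3,
) -> SplineBasis:
    """Construct a uniform B-spline basis spanning [year_min, year_max].

    The number of basis functions is (number of knot intervals covering the
    domain) + degree.  The domain must span at least three knot intervals for
    the penalty to be defined.
    """
    if year_max <= year_min:
        raise ValueError("year_max must exceed year_min")
    span = year_max - year_min
    n_intervals = int(np.ceil(span / knot_spacing - 1e-9))
    if n_intervals < 3:
        raise ValueError(
            "domain must span at least 3 knot intervals; widen the domain "
            "or reduce knot_spacing"
        )
    # interior knots from year_min, extended `degree` uniform knots past each
    # end so every basis function has full support information
    idx = np.arange(-degree, n_intervals + degree + 1)
    knots = year_min + idx * knot_spacing
    return SplineBasis(
        domain=(year_min, year_min + n_intervals * knot_spacing),
        knot_spacing=knot_spacing,
        degree=degree,
        knots=knots,
    )
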