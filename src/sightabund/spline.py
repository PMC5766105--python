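"""Natural cubic spline basis over survey years.

The temporally-smoothed abundance model places a natural cubic spline on
the logit of the mean presence probability across years.  The basis here
is the truncated-power construction: for knots xi_1 < ... < xi_K (the two
boundary knots plus K-2 interior knots),

    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)

and the basis columns are x, and d_k(x) - d_{K-1}(x) for k = 1..K-2.
This spans exactly the space of cubic splines that are linear beyond the
boundary knots (second and third derivatives vanish there).  R's ns()
uses a B-spline representation of the same space; the two differ by an
invertible linear map, so fits are identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "natural_cubic_basis"]


@dataclass
class SplineBasis:
    """A natural cubic spline basis evaluated at a set of points."""

    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    basis_matrix: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def evaluate(self, new_values) -> np.ndarray:
        """Evaluate the same basis (same knots) at new points."""
        return _tp_basis(
            np.asarray(new_values, dtype=float),
            self.interior_knots,
            self.boundary_knots,
        )


def _tp_basis(x: np.ndarray, interior: np.ndarray, boundary) -> np.ndarray:
    knots = np.concatenate(([boundary[0]], interior, [boundary[1]]))
    K = len(knots)

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def natural_cubic_basis(values, df: int = 3, knots=None, boundary_knots=None) -> SplineBasis:
    """Build a natural cubic spline basis evaluated at `values`.

    Parameters
    ----------
    values
        Points (e.g. survey years) at which to evaluate the basis.
    df
        Number of basis columns (default 3, as used for the yearly
        presence-probability trend).  Interior knot count is df - 1.
    knots
        Optional explicit interior knots.  When omitted they are placed
        at the k/(K+1) quantiles of `values` (K = df - 1), mirroring the
        default of R's ns().
    boundary_knots
        Optional (low, high); defaults to the range of `values`.

    Raises
    ------
    ValueError
        If df < 1, there are fewer than df + 1 distinct values, or the
        knots are duplicated / outside the boundary.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise ValueError(
            f"need at least df + 1 = {df + 1} distinct values, got {distinct.size}"
        )
    if boundary_knots is None:
        boundary_knots = (float(distinct[0]), float(distinct[-1]))
    lo, hi = map(float, boundary_knots)
    if not lo < hi:
        raise ValueError("boundary knots must be increasing")
    K = df - 1
    if knots is None:
        if K > 0:
            probs = np.arange(1, K + 1) / (K + 1)
            interior = np.quantile(x, probs)
        else:
            interior = np.array([])
    else:
        interior = np.sort(np.asarray(knots, dtype=float))
        if interior.size != K:
            raise ValueError(f"df={df} requires exactly {K} interior knots")
    allk = np.concatenate(([lo], interior, [hi]))
    if np.any(np.diff(allk) <= 0):
        raise ValueError("duplicate or out-of-order knots")
    basis = _tp_basis(x, interior, (lo, hi))
    return SplineBasis(
        df=df,
        interior_knots=interior,
        boundary_knots=(lo, hi),
        basis_matrix=basis,
        values=x,
    )
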