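"""Projection median via Monte Carlo integration or trapezoidal quadrature.

The projection median of a finite set X in R^n integrates the vector-valued
median of the one-dimensional projections of X over all directions on the
unit sphere:

    M_P(X) = n * integral med(X_a) df(a)

with f the normalised uniform measure on the sphere and
``med(X_a) = a * median_i <x_i, a>``.  In 2-D this specialises to
``(1/pi) * int_0^{2pi} med(X_theta) dtheta``.

Two interchangeable computations are provided: Monte Carlo averaging over
random directions (any n >= 2) and the composite trapezoidal rule over
spherical coordinates (2-D and 3-D).
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import as_point_cloud, sample_uniform_directions
from .medians import MedianEstimate

__all__ = ["projection_median_mc", "projection_median_trapz", "projected_median_scalars"]

#: below this many subintervals the trapezoidal rule loses accuracy
MIN_RECOMMENDED_SUBINTERVALS = 15


def projected_median_scalars(X, directions, mu=None) -> np.ndarray:
    """Scalar projected medians ``m_j = median_i <x_i - mu, a_j>``.

    ``directions`` is a ``(J, n)`` array of unit vectors; returns a length-J
    vector.  The vector-valued projected median of the definition is
    ``m_j * a_j``; storing the scalar and rescaling is equivalent.
    """
    X = as_point_cloud(X)
    A = np.asarray(directions, dtype=float)
    P = X @ A.T  # (k, J)
    if mu is not None:
        P = P - np.asarray(mu, dtype=float) @ A.T
    return np.median(P, axis=0)


def projection_median_mc(X, nprojs: int = 20000, seed=None) -> MedianEstimate:
    """Monte Carlo projection median: ``(n/J) * sum_j m_j a_j`` over ``J``
    uniform random directions.

    A large ``nprojs`` is needed for a stable answer; the default 20000
    matches common practice.  The same seed reproduces the estimate exactly.
    """
    X = as_point_cloud(X, min_dim=2)
    n = X.shape[1]
    A = sample_uniform_directions(n, nprojs, seed)
    # centring at the (translation-equivariant) marginal median before
    # projecting makes the estimate exactly translation-equivariant for a
    # fixed seed and removes the bulk-location part of the MC error
    c0 = np.median(X, axis=0)
    m = projected_median_scalars(X - c0, A)
    est = c0 + n * (m[:, None] * A).mean(axis=0)
    return MedianEstimate(est, "pmed_mc", {"nprojs": int(nprojs), "seed": seed})


def _check_subintervals(s: int) -> int:
    s = int(s)
    if s < 2:
        raise ValueError(f"need at least 2 subintervals; got {s}")
    if s < MIN_RECOMMENDED_SUBINTERVALS:
        warnings.warn(
            f"{s} subintervals is below the recommended minimum of "
            f"{MIN_RECOMMENDED_SUBINTERVALS}; results may be inaccurate",
            stacklevel=3,
        )
    return s


def projection_median_trapz(X, subintervals=36) -> MedianEstimate:
    """Projection median by the trapezoidal rule in spherical coordinates.

    Parameters
    ----------
    X : array-like, shape (k, n) with n in {2, 3}
    subintervals : int or (int, int)
        Number of equal subintervals for the angular grid(s): a single count
        for the 2-D circle integral, a pair ``(s1, s2)`` for the nested 3-D
        integral over ``(theta_1, theta_2) in [0, pi] x [0, 2pi]``.  At
        least 36 per integral is recommended.

    Notes
    -----
    Both endpoint nodes are included; the duplicated node of the periodic
    coordinate receives the standard trapezoidal half-weight.  The 3-D
    integrand is weighted by the sphere volume element ``sin(theta_1)`` and
    normalised by the same quadrature of the bare weight, so the two
    specialisations agree with the single normalised definition.
    """
    X = as_point_cloud(X, min_dim=2)
    n = X.shape[1]
    c0 = np.median(X, axis=0)  # centring: exact translation equivariance
    Xc = X - c0
    if n == 2:
        if np.ndim(subintervals) != 0:
            (subintervals,) = np.ravel(subintervals)
        s = _check_subintervals(subintervals)
        theta = np.linspace(0.0, 2.0 * np.pi, s + 1)
        A = np.column_stack([np.cos(theta), np.sin(theta)])
        m = projected_median_scalars(Xc, A)
        integrand = m[:, None] * A  # med(X_theta) as a vector, per node
        est = c0 + np.trapezoid(integrand, theta, axis=0) / np.pi
        return MedianEstimate(est, "pmed_trapz", {"subintervals": s})
    if n == 3:
        if np.ndim(subintervals) == 0:
            s1 = s2 = _check_subintervals(subintervals)
        else:
            s1, s2 = (int(v) for v in np.ravel(subintervals))
            s1 = _check_subintervals(s1)
            s2 = _check_subintervals(s2)
        t1 = np.linspace(0.0, np.pi, s1 + 1)
        t2 = np.linspace(0.0, 2.0 * np.pi, s2 + 1)
        T1, T2 = np.meshgrid(t1, t2, indexing="ij")
        A = np.column_stack(
            [
                (np.cos(T1)).ravel(),
                (np.sin(T1) * np.cos(T2)).ravel(),
                (np.sin(T1) * np.sin(T2)).ravel(),
            ]
        )
        m = projected_median_scalars(Xc, A)
        w = np.sin(T1)  # sphere volume element for n = 3
        num = np.empty(3)
        integrand = (m[:, None] * A).reshape(s1 + 1, s2 + 1, 3)
        for c in range(3):
            inner = np.trapezoid(integrand[:, :, c] * w, t2, axis=1)
            num[c] = np.trapezoid(inner, t1)
        den = np.trapezoid(np.trapezoid(w, t2, axis=1), t1)  # -> 4*pi
        est = c0 + 3.0 * num / den
        return MedianEstimate(est, "pmed_trapz", {"subintervals": (s1, s2)})
    raise ValueError(
        f"trapezoidal projection median supports n in {{2, 3}}; got n={n} "
        "(use projection_median_mc or yamm for higher dimensions)"
    )
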