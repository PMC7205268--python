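"""Directions on the unit sphere and projections of point clouds.

A point cloud is a plain ``(k, n)`` numpy array: rows are observations,
columns are coordinates.  Directions are unit vectors in R^n, either drawn
uniformly from the sphere or built from spherical coordinates
``(theta_1, ..., theta_{n-1})`` with ``theta_1..theta_{n-2}`` ranging over
``[0, pi]`` and ``theta_{n-1}`` over ``[0, 2*pi)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_point_cloud",
    "as_unit_direction",
    "project_points",
    "sample_uniform_directions",
    "direction_from_angles",
    "sphere_weight",
]

_UNIT_TOL = 1e-12


def as_point_cloud(points, min_dim: int = 1) -> np.ndarray:
    """Validate and coerce input into a ``(k, n)`` float array.

    Parameters
    ----------
    points : array-like
        ``k`` observations of dimension ``n``; a single 1-D vector is
        treated as one observation.
    min_dim : int
        Minimum admissible dimension ``n`` (projection-median operations
        require ``n >= 2``).

    Returns
    -------
    numpy.ndarray
        A float array of shape ``(k, n)`` with all entries finite.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.ndim != 2:
        raise ValueError(f"point cloud must be 2-D (k, n); got ndim={X.ndim}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"point cloud must be non-empty; got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("point cloud contains non-finite entries")
    if X.shape[1] < min_dim:
        raise ValueError(
            f"operation requires dimension >= {min_dim}; got n={X.shape[1]}"
        )
    return X


def as_unit_direction(vector) -> np.ndarray:
    """Validate a unit direction (Euclidean norm 1 within 1e-12)."""
    a = np.asarray(vector, dtype=float)
    if a.ndim != 1:
        raise ValueError("direction must be a 1-D vector")
    nrm = np.linalg.norm(a)
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"direction is not unit length (norm={nrm!r})")
    if abs(nrm - 1.0) > _UNIT_TOL:
        a = a / nrm
    return a


def project_points(X, a, mu=None) -> np.ndarray:
    """Project a (shifted) point cloud onto a direction.

    Returns the length-``k`` vector ``y = (X - 1_k mu^T) a``; element ``i``
    equals ``<x_i - mu, a>``.  With ``mu`` omitted the cloud is projected
    as-is.
    """
    X = as_point_cloud(X)
    a = np.asarray(a, dtype=float)
    if a.shape != (X.shape[1],):
        raise ValueError(
            f"direction shape {a.shape} does not match cloud dimension {X.shape[1]}"
        )
    if mu is None:
        return X @ a
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (X.shape[1],):
        raise ValueError(
            f"shift shape {mu.shape} does not match cloud dimension {X.shape[1]}"
        )
    # (X - mu) @ a == X @ a - mu @ a : avoid materialising the shifted cloud
    return X @ a - float(mu @ a)


def sample_uniform_directions(n: int, J: int, seed=None) -> np.ndarray:
    """Draw ``J`` independent directions uniformly from the unit (n-1)-sphere.

    Uniformity comes from normalising i.i.d. standard-Gaussian coordinates.
    ``seed`` may be an int or a :class:`numpy.random.Generator`; the same
    seed reproduces the same set bit-for-bit.

    Returns a ``(J, n)`` array whose rows have unit norm.
    """
    if n < 2:
        raise ValueError(f"directions require dimension n >= 2; got {n}")
    if J < 1:
        raise ValueError(f"number of directions must be >= 1; got {J}")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((J, n))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    # a resampled row for the (measure-zero) zero draw keeps the output shape
    bad = norms[:, 0] == 0.0
    while np.any(bad):
        g[bad] = rng.standard_normal((int(bad.sum()), n))
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        bad = norms[:, 0] == 0.0
    return g / norms


def direction_from_angles(angles) -> np.ndarray:
    """Unit vector from spherical coordinates.

    For angles ``(theta_1, ..., theta_{n-1})`` returns::

        (cos t1, sin t1 cos t2, ..., sin t1 ... sin t_{n-2} cos t_{n-1},
         sin t1 ... sin t_{n-2} sin t_{n-1})

    which has unit norm by construction.
    """
    t = np.atleast_1d(np.asarray(angles, dtype=float))
    if t.ndim != 1 or t.size < 1:
        raise ValueError("angles must be a non-empty 1-D vector")
    m = t.size  # n - 1
    x = np.empty(m + 1)
    sin_prod = 1.0
    for j in range(m):
        x[j] = sin_prod * np.cos(t[j])
        sin_prod *= np.sin(t[j])
    x[m] = sin_prod
    return x


def sphere_weight(angles, n: int) -> float:
    """Surface (volume-element) weight of the (n-1)-sphere at given angles.

    Returns ``sin^{n-2}(t1) * sin^{n-3}(t2) * ... * sin(t_{n-2})``; the empty
    product for ``n = 2`` is 1.  Used to weight the nested trapezoidal rule.
    """
    if n < 2:
        raise ValueError(f"sphere weight requires n >= 2; got {n}")
    t = np.atleast_1d(np.asarray(angles, dtype=float))
    if t.size != n - 1:
        raise ValueError(f"expected {n - 1} angles for dimension {n}; got {t.size}")
    w = 1.0
    for j in range(n - 2):
        w *= np.sin(t[j]) ** (n - 2 - j)
    return abs(w)
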