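"""Muqie (MUltivariate QuantIlE) contours: projected pseudo-quantile plots.

A muqie point Q(alpha, u) rescales the unit direction u by the empirical
alpha-quantile of the data's projections onto u after centring at a robust
location (yamm by default).  Collecting Q(alpha, u) over a grid of
directions gives a contour that conveys the spread and configuration of the
data; sweeping alpha upward makes the contour grow outward, which is the
basis of the animated plots.  These are not true multivariate quantiles —
the quantile can be negative, in which case the point sits opposite u,
which is exactly what reveals cluster structure at sub-median levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import YammConfig, yamm
from .geometry import as_point_cloud, as_unit_direction
from .medians import componentwise_median, sample_mean, spatial_median

__all__ = ["MuqieContour", "muqie_point", "muqie_contour", "muqie_frames"]

_CENTER_METHODS = ("yamm", "spatial", "componentwise", "mean")


def _quantile_scalar(X: np.ndarray, center: np.ndarray, u: np.ndarray, alpha: float) -> float:
    # type-7 (linear interpolation) empirical quantile of the centred projections
    proj = (X - center) @ u
    return float(np.quantile(proj, alpha))


def muqie_point(X, center, u, alpha: float) -> np.ndarray:
    """The muqie point Q(alpha, u): u rescaled by the empirical
    alpha-quantile of ``<x_i - center, u>``.  The scalar keeps its sign."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    X = as_point_cloud(X)
    center = np.asarray(center, dtype=float)
    u = as_unit_direction(u)
    return _quantile_scalar(X, center, u, alpha) * u


@dataclass
class MuqieContour:
    """One muqie contour: per-direction quantile points around a centre."""

    alpha: float
    center: np.ndarray
    directions: np.ndarray  # (J, n)
    points: np.ndarray  # (J, n), points[j] = q_j * directions[j]
    center_method: str

    def to_frame(self) -> pd.DataFrame:
        n = self.points.shape[1]
        cols = {f"q{i+1}": self.points[:, i] for i in range(n)}
        cols.update({f"u{i+1}": self.directions[:, i] for i in range(n)})
        return pd.DataFrame(cols)


def _direction_grid(n: int, n_directions) -> np.ndarray:
    if n == 2:
        J = int(n_directions) if np.ndim(n_directions) == 0 else int(np.ravel(n_directions)[0])
        if J < 3:
            raise ValueError("need at least 3 directions")
        theta = 2.0 * np.pi * np.arange(J) / J
        return np.column_stack([np.cos(theta), np.sin(theta)])
    if n == 3:
        if np.ndim(n_directions) == 0:
            n_lat, n_lon = 24, 48
        else:
            n_lat, n_lon = (int(v) for v in np.ravel(n_directions))
        if n_lat < 2 or n_lon < 3:
            raise ValueError("3-D grid needs at least 2 latitudes and 3 longitudes")
        lat = np.linspace(0.0, np.pi, n_lat)
        lon = 2.0 * np.pi * np.arange(n_lon) / n_lon
        T1, T2 = np.meshgrid(lat, lon, indexing="ij")
        return np.column_stack(
            [
                (np.cos(T1)).ravel(),
                (np.sin(T1) * np.cos(T2)).ravel(),
                (np.sin(T1) * np.sin(T2)).ravel(),
            ]
        )
    raise ValueError(f"muqie contours support n in {{2, 3}}; got n={n}")


def _compute_center(X, center_method, config: YammConfig | None):
    if not isinstance(center_method, str):
        return np.asarray(center_method, dtype=float), "explicit"
    if center_method not in _CENTER_METHODS:
        raise ValueError(
            f"unknown center method {center_method!r}; choose from {_CENTER_METHODS}"
        )
    if center_method == "yamm":
        return yamm(X, config or YammConfig()).location, "yamm"
    fn = {
        "spatial": spatial_median,
        "componentwise": componentwise_median,
        "mean": sample_mean,
    }[center_method]
    return fn(X).location, center_method


def muqie_contour(
    X,
    alpha: float,
    n_directions=360,
    center_method="yamm",
    config: YammConfig | None = None,
) -> MuqieContour:
    """Muqie contour at level alpha.

    Directions form a regular angular grid in 2-D (``n_directions`` angles)
    or a latitude-longitude grid in 3-D (``n_directions`` as
    ``(n_lat, n_lon)``, default 24 x 48).  ``center_method`` may also be an
    explicit centre vector.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    X = as_point_cloud(X, min_dim=2)
    n = X.shape[1]
    A = _direction_grid(n, n_directions)
    center, method = _compute_center(X, center_method, config)
    proj = (X - center) @ A.T
    scal = np.quantile(proj, alpha, axis=0)
    return MuqieContour(
        alpha=float(alpha),
        center=center,
        directions=A,
        points=scal[:, None] * A,
        center_method=method,
    )


def muqie_frames(
    X,
    alphas,
    n_directions=360,
    center_method="yamm",
    config: YammConfig | None = None,
) -> list[MuqieContour]:
    """One contour per alpha, all sharing the same centre and direction
    grid; alphas must be strictly increasing within (0, 1)."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size < 1 or np.any(alphas <= 0.0) or np.any(alphas >= 1.0):
        raise ValueError("alphas must lie strictly in (0, 1)")
    if np.any(np.diff(alphas) <= 0.0):
        raise ValueError("alphas must be strictly increasing")
    X = as_point_cloud(X, min_dim=2)
    A = _direction_grid(X.shape[1], n_directions)
    center, method = _compute_center(X, center_method, config)
    proj = (X - center) @ A.T
    frames = []
    for a in alphas:
        scal = np.quantile(proj, a, axis=0)
        frames.append(
            MuqieContour(
                alpha=float(a),
                center=center,
                directions=A,
                points=scal[:, None] * A,
                center_method=method,
            )
        )
    return frames
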