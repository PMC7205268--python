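"""The yamm estimator: projection median by objective minimisation.

yamm ("yet another multivariate median") locates the shift vector mu that
minimises the integrated squared projected univariate median

    M_{X,m}(mu) = integral_{||a||=1} m_X(mu, a)^2 da,
    m_X(mu, a)  = median_i <x_i - mu, a>,

which is equivalent to the projection median.  The integral is approximated
by Monte Carlo over a direction set drawn once per call and held fixed
across all objective evaluations (common random numbers), so the objective
seen by the optimiser is a deterministic function of mu and quasi-Newton
line searches behave.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .geometry import as_point_cloud, sample_uniform_directions
from .medians import MedianEstimate, componentwise_median, sample_mean, spatial_median
from .projection import projected_median_scalars

__all__ = ["YammConfig", "yamm_objective", "yamm"]

_OPTIMIZERS = {"bfgs", "nelder-mead", "cg", "l-bfgs-b", "sann"}
_STARTS = {"spatial", "componentwise", "mean"}


@dataclass
class YammConfig:
    """Settings for :func:`yamm`.

    Parameters
    ----------
    nprojs : int
        Number of Monte Carlo projection directions (default 2000).
    reltol : float
        Relative function tolerance forwarded to the optimiser.
    start : str or array-like
        Starting shift: a named rule in {"spatial", "componentwise",
        "mean"} or an explicit length-n vector.  A good start (the spatial
        median, the default) shortens the optimisation markedly.
    optimizer : str
        One of {"bfgs", "nelder-mead", "cg", "l-bfgs-b", "sann"}.
    doabs : int
        0 integrates the squared projected median, 1 the absolute value;
        the two give similar results on well-conditioned clouds.
    seed : int or numpy.random.Generator, optional
        Seed for the direction set; fixing it makes the call deterministic.
    """

    nprojs: int = 2000
    reltol: float = 1e-6
    start: object = "spatial"
    optimizer: str = "bfgs"
    doabs: int = 0
    seed: object = None

    def __post_init__(self):
        if self.nprojs < 1:
            raise ValueError("nprojs must be >= 1")
        if self.reltol <= 0:
            raise ValueError("reltol must be positive")
        if isinstance(self.optimizer, str):
            self.optimizer = self.optimizer.lower()
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(_OPTIMIZERS)}"
            )
        if self.doabs not in (0, 1):
            raise ValueError("doabs must be 0 (squared) or 1 (absolute)")
        if isinstance(self.start, str) and self.start not in _STARTS:
            raise ValueError(
                f"unknown start rule {self.start!r}; choose from {sorted(_STARTS)} "
                "or pass an explicit vector"
            )


def yamm_objective(X, mu, directions, doabs: int = 0) -> float:
    """Monte Carlo yamm objective ``J^{-1} sum_j m_X(mu, a_j)^2``
    (or ``|m_X|`` with ``doabs=1``)."""
    A = np.asarray(directions, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1:
        raise ValueError("directions must be a non-empty (J, n) array")
    m = projected_median_scalars(X, A, mu=mu)
    if doabs:
        return float(np.mean(np.abs(m)))
    return float(np.mean(m * m))


def _start_vector(X: np.ndarray, start) -> np.ndarray:
    if isinstance(start, str):
        fn = {
            "spatial": spatial_median,
            "componentwise": componentwise_median,
            "mean": sample_mean,
        }[start]
        return fn(X).location
    mu0 = np.asarray(start, dtype=float)
    if mu0.shape != (X.shape[1],):
        raise ValueError("explicit start must be a length-n vector")
    return mu0


def yamm(X, config: YammConfig | None = None, **overrides) -> MedianEstimate:
    """Compute the yamm estimate of location.

    Keyword overrides (``nprojs=…``, ``seed=…`` …) are applied on top of
    ``config``.  Diagnostics carry the final objective value, function/
    gradient call counts and the optimiser's convergence flag; optimiser
    non-convergence is flagged, not raised.
    """
    if config is None:
        config = YammConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    X = as_point_cloud(X, min_dim=2)
    k, n = X.shape

    A = sample_uniform_directions(n, config.nprojs, config.seed)
    P = X @ A.T  # (k, J), fixed across objective evaluations

    doabs = config.doabs

    def fun(mu):
        m = np.median(P - A @ mu, axis=0)
        if doabs:
            return float(np.mean(np.abs(m)))
        return float(np.mean(m * m))

    mu0 = _start_vector(X, config.start)

    if config.optimizer == "sann":
        # simulated-annealing analogue; bounds span the data with margin
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.maximum(hi - lo, 1.0)
        seed_int = np.random.default_rng(config.seed).integers(2**31 - 1)
        res = optimize.dual_annealing(
            fun,
            bounds=list(zip(lo - 0.5 * span, hi + 0.5 * span)),
            x0=mu0,
            seed=int(seed_int),
            maxiter=200,
        )
    else:
        method = {
            "bfgs": "BFGS",
            "nelder-mead": "Nelder-Mead",
            "cg": "CG",
            "l-bfgs-b": "L-BFGS-B",
        }[config.optimizer]
        options = {}
        if method in ("BFGS", "CG"):
            options["gtol"] = config.reltol
        elif method == "L-BFGS-B":
            options["ftol"] = config.reltol
        else:  # Nelder-Mead
            options["fatol"] = config.reltol * max(1.0, abs(fun(mu0)))
            options["xatol"] = config.reltol
        res = optimize.minimize(fun, mu0, method=method, options=options)

    diagnostics = {
        "objective": float(res.fun),
        "nfev": int(res.nfev),
        "njev": int(getattr(res, "njev", 0)),
        "nit": int(getattr(res, "nit", 0)),
        "converged": bool(res.success),
        "message": str(res.message),
        "nprojs": int(config.nprojs),
        "optimizer": config.optimizer,
        "doabs": doabs,
        "seed": config.seed,
        "start": config.start if isinstance(config.start, str) else "explicit",
    }
    return MedianEstimate(res.x, "yamm", diagnostics)
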