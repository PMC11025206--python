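"""Univariate Gaussian mixture fitting by EM and MAP-EM.

The segmentation pipeline clusters voxel intensities twice: a 2-component
fit separating CSF from the brighter wall/choroid-plexus class, then a
3-component fit on smoothed intensities whose highest-mean component is the
choroid plexus. Both fits use this module.

Two modes are available:

``ml``
    Plain maximum-likelihood EM.
``map`` (default)
    MAP-EM with weak conjugate priors — Dirichlet(alpha) on the weights and
    a Normal-Inverse-Gamma prior on each (mean, variance) pair centred on
    the sample moments — so estimates approach maximum likelihood while all
    M-steps stay closed-form and variances cannot collapse to zero.

The M-step in ``map`` mode maximises the expected complete-data log
posterior exactly (joint mode of the conjugate Normal-Inverse-Gamma
posterior), so the per-iteration objective (log-likelihood, plus log prior
in ``map`` mode) is non-decreasing — asserted by the property tests.

Initialisation is deterministic by default: component means are placed at
the (2i-1)/(2k) sample quantiles, variances at the sample variance, and
weights uniform. Random initialisation with an explicit seed is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import FitError, ParameterError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMConfig:
    """Fit configuration.

    mode : "map" or "ml".
    tol : relative objective-change convergence threshold.
    max_iter : EM iteration cap.
    init : "quantile" (deterministic) or "random".
    seed : RNG seed for random init (ignored for quantile init).
    var_floor_frac : variance floor as a fraction of the sample variance;
        a component falling below it raises :class:`FitError`.
    dirichlet_alpha : Dirichlet concentration on weights (map mode).
    kappa0 : pseudo-count of the Normal prior on means (map mode).
    a0 : Inverse-Gamma shape; scale is ``a0 * sample variance`` (map mode).
    """

    mode: str = "map"
    tol: float = 1e-6
    max_iter: int = 500
    init: str = "quantile"
    seed: int | None = None
    var_floor_frac: float = 1e-6
    dirichlet_alpha: float = 1.0 + 1e-3
    kappa0: float = 1e-3
    a0: float = 1e-3

    def __post_init__(self):
        if self.mode not in ("ml", "map"):
            raise ParameterError(f"mode must be 'ml' or 'map', got {self.mode!r}")
        if self.init not in ("quantile", "random"):
            raise ParameterError(
                f"init must be 'quantile' or 'random', got {self.init!r}"
            )
        if self.tol <= 0 or self.max_iter < 1:
            raise ParameterError("tol must be > 0 and max_iter >= 1")
        if self.dirichlet_alpha < 1.0:
            raise ParameterError("dirichlet_alpha must be >= 1 for a closed-form "
                                 "weight M-step")


@dataclass
class GMMFit:
    """Fitted univariate mixture and its EM trace."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    log_objective_trace: np.ndarray
    converged: bool
    n_iter: int
    mode: str
    seed: int | None = None
    config: GMMConfig = field(default_factory=GMMConfig)

    def hard_assignment(self) -> np.ndarray:
        """Component index of maximum responsibility per observation.

        Ties are broken toward the higher-mean component, then toward the
        lower component index.
        """
        return _hard_assign(self.responsibilities, self.means)


def _hard_assign(resp: np.ndarray, means: np.ndarray) -> np.ndarray:
    # Stable tie-break: among argmax-tied components prefer larger mean,
    # then lower index. Implemented by lexicographic ordering of component
    # priority, scanning components from least to most preferred.
    order = sorted(range(len(means)), key=lambda j: (means[j], -j))
    assign = np.full(resp.shape[0], order[0], dtype=np.intp)
    best = resp[:, order[0]].copy()
    for j in order[1:]:
        take = resp[:, j] >= best  # >= lets later (preferred) components win ties
        assign[take] = j
        best = np.maximum(best, resp[:, j])
    return assign


def _log_gauss(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    # (n, k) log N(x | mu_j, var_j)
    d = x[:, None] - means[None, :]
    return -0.5 * (_LOG_2PI + np.log(variances)[None, :] + d * d / variances[None, :])


def _initial_params(x, k, config, rng):
    n = x.size
    svar = float(np.var(x))
    if config.init == "quantile":
        q = (2.0 * np.arange(1, k + 1) - 1.0) / (2.0 * k)
        means = np.quantile(x, q)
    else:
        means = rng.choice(x, size=k, replace=False).astype(float)
        means.sort()
    # Nudge exactly-coincident initial means apart so components can separate.
    for j in range(1, k):
        if means[j] <= means[j - 1]:
            means[j] = means[j - 1] + 1e-8 * max(1.0, abs(means[j - 1]))
    variances = np.full(k, svar)
    weights = np.full(k, 1.0 / k)
    return weights, means, variances


def _log_prior(weights, means, variances, m0, kappa0, alpha, a0, b0):
    # Non-normalised conjugate log prior; constants cancel in the trace but
    # the variance-dependent Normal normaliser must be kept for monotonicity.
    dir_term = (alpha - 1.0) * np.sum(np.log(weights))
    norm_term = np.sum(
        -0.5 * (_LOG_2PI + np.log(variances / kappa0))
        - kappa0 * (means - m0) ** 2 / (2.0 * variances)
    )
    ig_term = np.sum(-(a0 + 1.0) * np.log(variances) - b0 / variances)
    return dir_term + norm_term + ig_term


def fit_gmm(values: np.ndarray, k: int, config: GMMConfig | None = None) -> GMMFit:
    """Fit a k-component univariate Gaussian mixture to ``values``.

    Parameters
    ----------
    values : 1-D array of finite intensities, at least ``10 * k`` of them.
    k : number of components (the pipeline uses 2 and 3).
    config : :class:`GMMConfig`; defaults to deterministic MAP-EM.

    Returns
    -------
    GMMFit with weights on the simplex, per-component means/variances,
    responsibilities row-normalised to 1, and the per-iteration objective
    trace (non-decreasing).

    Raises
    ------
    FitError
        For samples smaller than ``10 * k``, non-finite values, zero sample
        variance, or variance collapse below the floor during EM.
    """
    config = config or GMMConfig()
    x = np.asarray(values, dtype=np.float64).ravel()
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if x.size < 10 * k:
        raise FitError(f"need at least {10 * k} observations for k={k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise FitError("non-finite values in sample")
    svar = float(np.var(x))
    if svar <= 1e-14 * max(1.0, float(np.mean(x)) ** 2):
        raise FitError("variance collapse: all sample values are identical")

    rng = np.random.default_rng(config.seed)
    weights, means, variances = _initial_params(x, k, config, rng)
    var_floor = config.var_floor_frac * svar
    m0 = float(np.mean(x))
    b0 = config.a0 * svar
    n = x.size

    is_map = config.mode == "map"
    trace: list[float] = []
    converged = False
    resp = np.full((n, k), 1.0 / k)
    prev_obj = -np.inf

    for it in range(config.max_iter):
        # E-step
        log_comp = np.log(weights)[None, :] + _log_gauss(x, means, variances)
        log_norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - log_norm[:, None])

        obj = float(np.sum(log_norm))
        if is_map:
            obj += _log_prior(weights, means, variances, m0, config.kappa0,
                              config.dirichlet_alpha, config.a0, b0)
        trace.append(obj)
        if it > 0:
            rel_change = abs(obj - prev_obj) / max(1.0, abs(prev_obj))
            if rel_change < config.tol:
                converged = True
                break
        prev_obj = obj

        # M-step
        nk = resp.sum(axis=0)
        if is_map:
            weights = nk + (config.dirichlet_alpha - 1.0)
            weights /= weights.sum()
            sx = resp.T @ x
            means = (config.kappa0 * m0 + sx) / (config.kappa0 + nk)
            sq = resp.T @ (x * x) - 2.0 * means * sx + nk * means**2
            variances = (2.0 * b0 + config.kappa0 * (means - m0) ** 2 + sq) / (
                nk + 2.0 * config.a0 + 3.0
            )
        else:
            if np.any(nk <= 1e-12):
                raise FitError("a component lost all responsibility mass")
            weights = nk / n
            means = (resp.T @ x) / nk
            sq = resp.T @ (x * x) - nk * means**2
            variances = sq / nk
        # numerical guard: weighted sum-of-squares can round slightly negative
        variances = np.maximum(variances, 0.0)
        if np.any(variances < var_floor):
            raise FitError(
                f"variance collapse below floor {var_floor:.3e} "
                f"(variances={variances})"
            )

    return GMMFit(
        k=k,
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=resp,
        log_objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
        mode=config.mode,
        seed=config.seed,
        config=config,
    )


def select_component(means: np.ndarray, variances: np.ndarray,
                     which: str = "highest") -> int:
    """Index of the highest- (or lowest-) mean component.

    Ties on the mean are broken toward the larger variance, then the lower
    component index — the documented deterministic tie rule.
    """
    sign = 1.0 if which == "highest" else -1.0
    return int(
        max(range(len(means)), key=lambda j: (sign * means[j], variances[j], -j))
    )
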