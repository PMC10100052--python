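"""Loglinear Poisson point-process models of settlement density.

A site-year's settled-male locations are modelled as an inhomogeneous
Poisson process with intensity

    lambda(u) = exp(beta0 + sum_k beta_k * S_k(u)),

where the S_k are gridded covariates (habitat attractiveness, playback
proximity).  The likelihood is approximated by the Berman–Turner
device: the window is tiled by a regular dummy grid, every data and
dummy point j gets a counting weight w_j = (tile area) / (points in
tile), and

    logLik ~= sum_j w_j (y_j log lambda_j - lambda_j),   y_j = z_j / w_j,

which is a weighted Poisson regression solved here by IRLS from first
principles.  Several site-year patterns are fitted jointly with fully
shared coefficients (one common intercept), mirroring a common model
across replicate point patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_selection import aicc
from .raster import GridRaster, Window, sample_raster

DEFAULT_DUMMY_SPACING = 10.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PointPattern:
    """Settled-male locations for one site-year inside its window."""

    site: str
    year: int
    window: Window
    x: np.ndarray
    y: np.ndarray
    male_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        inside = self.window.contains(self.x, self.y)
        if not np.all(inside):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class QuadScheme:
    """Data + dummy quadrature points with Berman–Turner counting weights."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray  # 1 for data points, 0 for dummies
    w: np.ndarray  # positive weights, m^2; sums to the window area
    covariates: np.ndarray  # (n_points, n_covariates)

    @property
    def n_data(self) -> int:
        return int(self.z.sum())


@dataclass
class PPMFit:
    coefficients: np.ndarray  # (intercept, beta_1, ..., beta_K)
    covariance: np.ndarray
    log_likelihood: float
    n_points: int
    k: int
    aicc: float
    names: list[str] = field(default_factory=list)
    n_iter: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        zq = norm.ppf(0.5 + level / 2)
        se = self.se()
        return np.column_stack([self.coefficients - zq * se, self.coefficients + zq * se])


def _tile_edges(origin: float, length: float, spacing: float) -> np.ndarray:
    """Tile edges covering [origin, origin+length]; last tile may be short."""
    n = int(np.ceil(length / spacing - 1e-9))
    edges = origin + spacing * np.arange(n + 1)
    edges[-1] = origin + length
    return edges


def make_quadrature(
    pattern: PointPattern,
    covariates: list[GridRaster],
    dummy_spacing: float = DEFAULT_DUMMY_SPACING,
) -> QuadScheme:
    """Berman–Turner quadrature for one pattern.

    Dummy points sit at the centres of a regular `dummy_spacing` tiling
    of the window (edge tiles clipped so the tile areas sum exactly to
    the window area); each point's weight is its tile's area divided by
    the number of quadrature points (data + dummy) in that tile.
    Covariate values are attached by nearest-cell sampling; a covariate
    undefined at any quadrature point is an error.
    """
    if dummy_spacing <= 0:
        raise ValueError("dummy_spacing must be positive")
    win = pattern.window
    xe = _tile_edges(win.x0, win.width, dummy_spacing)
    ye = _tile_edges(win.y0, win.height, dummy_spacing)
    xc = (xe[:-1] + xe[1:]) / 2
    yc = (ye[:-1] + ye[1:]) / 2
    xg, yg = np.meshgrid(xc, yc)
    dx = np.diff(xe)
    dy = np.diff(ye)
    tile_area = np.outer(dy, dx)  # (nrow, ncol)

    qx = np.concatenate([pattern.x, xg.ravel()])
    qy = np.concatenate([pattern.y, yg.ravel()])
    z = np.concatenate([np.ones(pattern.n), np.zeros(xg.size)])

    # half-open tile membership [edge_i, edge_{i+1})
    col = np.minimum(np.searchsorted(xe, qx, side="right") - 1, len(dx) - 1)
    row = np.minimum(np.searchsorted(ye, qy, side="right") - 1, len(dy) - 1)
    flat = row * len(dx) + col
    counts = np.bincount(flat, minlength=tile_area.size)
    w = tile_area.ravel()[flat] / counts[flat]

    cov = (
        np.column_stack([sample_raster(r, qx, qy) for r in covariates])
        if covariates
        else np.empty((qx.size, 0))
    )
    return QuadScheme(qx, qy, z, w, cov)


def _pooled_design(schemes: list[QuadScheme]):
    w = np.concatenate([s.w for s in schemes])
    z = np.concatenate([s.z for s in schemes])
    cov = np.vstack([s.covariates for s in schemes])
    X = np.column_stack([np.ones(len(w)), cov])
    y = z / w
    return X, y, w


def fit_ppm(
    patterns: list[PointPattern] | PointPattern,
    covariate_sets: list[list[GridRaster]] | list[GridRaster] | None = None,
    names: list[str] | None = None,
    dummy_spacing: float = DEFAULT_DUMMY_SPACING,
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> PPMFit:
    """Fit a common loglinear PPM across one or more point patterns.

    `covariate_sets[i]` is the list of covariate rasters aligned with
    pattern i; all patterns must supply the same covariates in the same
    order (the coefficients, including the intercept, are shared).  The
    pooled Berman–Turner likelihood is maximised by IRLS starting from
    the homogeneous fit, declaring convergence when the score norm
    drops below `gtol`; the coefficient covariance is the inverse
    Fisher information.  AICc uses n = total data points.
    """
    if isinstance(patterns, PointPattern):
        patterns = [patterns]
        if covariate_sets and isinstance(covariate_sets[0], GridRaster):
            covariate_sets = [covariate_sets]
    if covariate_sets is None:
        covariate_sets = [[] for _ in patterns]
    if len(covariate_sets) != len(patterns):
        raise ValueError("one covariate set per pattern required")
    ncov = {len(c) for c in covariate_sets}
    if len(ncov) != 1:
        raise ValueError("all patterns must share the same covariates")

    schemes = [
        make_quadrature(p, c, dummy_spacing) for p, c in zip(patterns, covariate_sets)
    ]
    X, y, w = _pooled_design(schemes)
    n_data = int(sum(s.n_data for s in schemes))
    p = X.shape[1]

    beta = np.zeros(p)
    beta[0] = np.log(max(n_data, 1) / w.sum())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(eta)
        score = X.T @ (w * (y - mu))
        if np.linalg.norm(score) < gtol:
            break
        WX = X * (w * mu)[:, None]
        info = X.T @ WX
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving keeps full Newton steps from overshooting when a
        # covariate has a wide range
        ll_old = np.sum(w * (y * eta - mu))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            mu_c = np.exp(eta_c)
            if np.all(np.isfinite(mu_c)) and np.sum(w * (y * eta_c - mu_c)) >= ll_old - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        # realistic settlement densities keep every coefficient well
        # inside +-30 log-intensity units; beyond that the likelihood is
        # drifting to an infinite ridge
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30.0:
            raise ConvergenceError(
                "coefficients diverged (separation: a covariate perfectly "
                "separates data from dummy points)"
            )
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    if np.max(np.abs(beta)) > 20.0:
        # densities observable at site scale keep log-intensities within
        # roughly +-14; a converged coefficient beyond +-20 means the
        # score only vanished by underflow on an infinite ridge
        raise ConvergenceError(
            "separation: likelihood maximised on an unbounded coefficient ridge"
        )

    mu = np.exp(X @ beta)
    info = X.T @ (X * (w * mu)[:, None])
    cov = np.linalg.inv(info)
    ll = quad_log_likelihood(schemes, beta)
    names = names or [f"cov{k}" for k in range(p - 1)]
    return PPMFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        n_points=n_data,
        k=p,
        aicc=aicc(ll, p, n_data),
        names=["(intercept)", *names],
        n_iter=n_iter,
    )


def quad_log_likelihood(schemes: list[QuadScheme] | QuadScheme, beta: np.ndarray) -> float:
    """Berman–Turner approximate log-likelihood sum_data log lambda - sum w*lambda."""
    if isinstance(schemes, QuadScheme):
        schemes = [schemes]
    X, y, w = _pooled_design(schemes)
    eta = X @ np.asarray(beta, dtype=float)
    return float(np.sum(eta[y > 0]) - np.sum(w * np.exp(eta)))


def relative_importance(beta: float, value_range: tuple[float, float]) -> float:
    """Range-standardised effect size exp(beta * (max - min)).

    The multiplicative change in predicted settlement density across the
    observed span of the covariate; lets coefficients on different
    scales be compared.
    """
    lo, hi = value_range
    if not np.isfinite(beta) or not np.isfinite(hi - lo):
        raise ValueError("inputs must be finite")
    return float(np.exp(beta * (hi - lo)))
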