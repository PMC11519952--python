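"""Bayesian optimization of probe orientation with image entropy objective.

After the search phase the probe position is held fixed and only the tilt
angles are tuned: a Gaussian-process surrogate is fitted to the entropy of
the frames observed so far, and expected improvement selects each next
tilt, within a strict budget of N = 5 evaluations (2 quasi-random initial
points + 3 acquisition steps by default).  Acquisition is maximized on a
dense angle grid (0.5 deg), which is exact and deterministic at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel


@dataclass
class BOConfig:
    budget: int = 5
    n_init: int = 2
    lengthscale_deg: float = 2.0
    signal_std: float = 1.0
    noise_jitter: float = 1e-8
    fit_lengthscale: bool = False   # marginal-likelihood fit of the kernel
    grid_resolution_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not 1 <= self.n_init <= self.budget:
            raise ValueError("n_init must lie in [1, budget]")


@dataclass
class BOTrace:
    """Evaluated orientations, objective values and the incumbent path."""

    x: np.ndarray               # (n, d) orientations, degrees
    y: np.ndarray               # (n,) objective values (entropy, bits)
    incumbent: np.ndarray       # (n,) best objective after each evaluation
    config: BOConfig
    best_x: np.ndarray = field(default_factory=lambda: np.zeros(1))
    best_y: float = -np.inf

    def as_dict(self) -> dict:
        return {
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "incumbent": self.incumbent.tolist(),
            "best_x": np.atleast_1d(self.best_x).tolist(),
            "best_y": float(self.best_y),
            "budget": self.config.budget,
            "n_init": self.config.n_init,
            "lengthscale_deg": self.config.lengthscale_deg,
            "seed": self.config.seed,
        }


class GPPosterior:
    """Thin wrapper over a fitted GP exposing mean/variance callables."""

    def __init__(self, gp: GaussianProcessRegressor, prior_var: float):
        self._gp = gp
        self.prior_variance = prior_var

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(x)
        mean, std = self._gp.predict(x, return_std=True)
        return mean, std**2


def fit_surrogate(x: np.ndarray, y: np.ndarray, config: BOConfig | None = None) -> GPPosterior:
    """Fit a squared-exponential GP posterior to (orientation, entropy) data.

    A small noise jitter keeps the system well conditioned even with
    duplicate inputs.  By default the lengthscale is fixed (2 deg); set
    ``fit_lengthscale`` to optimize it by marginal likelihood.
    """
    config = config or BOConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 1:
        raise ValueError("need at least one observation")
    y = np.asarray(y, dtype=float)
    kernel = ConstantKernel(config.signal_std**2, constant_value_bounds=(1e-6, 1e3)) * RBF(
        config.lengthscale_deg, length_scale_bounds=(1e-2, 1e3)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=config.noise_jitter,
        optimizer="fmin_l_bfgs_b" if config.fit_lengthscale else None,
        normalize_y=True,
    )
    gp.fit(x, y)
    return GPPosterior(gp, prior_var=config.signal_std**2)


def expected_improvement(
    mean: np.ndarray, variance: np.ndarray, incumbent: float
) -> np.ndarray:
    """Closed-form EI for maximization; >= 0 everywhere.

    With zero variance it degenerates to ``max(mean - incumbent, 0)``.
    """
    mean = np.asarray(mean, dtype=float)
    std = np.sqrt(np.maximum(np.asarray(variance, dtype=float), 0.0))
    imp = mean - incumbent
    ei = np.where(std > 1e-12, 0.0, np.maximum(imp, 0.0))
    ok = std > 1e-12
    if np.any(ok):
        z = imp[ok] / std[ok]
        ei_ok = imp[ok] * norm.cdf(z) + std[ok] * norm.pdf(z)
        ei = ei.copy()
        ei[ok] = np.maximum(ei_ok, 0.0)
    return ei


def acquisition(posterior: GPPosterior, incumbent: float):
    """EI utility function over orientations, for a fitted posterior."""

    def utility(x: np.ndarray) -> np.ndarray:
        mean, var = posterior(x)
        return expected_improvement(mean, var, incumbent)

    return utility


def _grid(bounds: list[tuple[float, float]], resolution: float) -> np.ndarray:
    axes = [
        np.arange(lo, hi + resolution / 2, resolution) for lo, hi in bounds
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def optimize_orientation(
    objective,
    bounds: list[tuple[float, float]] | None = None,
    config: BOConfig | None = None,
    candidates: np.ndarray | None = None,
) -> BOTrace:
    """Run budgeted BO of ``objective`` over tilt angles.

    ``bounds`` is a list of (lo, hi) per tilt axis (default one axis,
    +-10 deg); alternatively ``candidates`` restricts the search to a
    discrete set, all of which are evaluated when the budget allows.
    Evaluations never leave the bounds, the trace length equals the budget
    exactly (or the candidate count if smaller), and the incumbent sequence
    is non-decreasing by construction.
    """
    config = config or BOConfig()
    if candidates is not None:
        cand = np.atleast_2d(np.asarray(candidates, dtype=float))
        if cand.ndim == 2 and cand.shape[0] == 1 and cand.shape[1] > 1:
            cand = cand.T
    else:
        if not bounds:
            bounds = [(-10.0, 10.0)]
        if any(hi <= lo for lo, hi in bounds):
            raise ValueError("empty bounds")
        cand = _grid(bounds, config.grid_resolution_deg)

    n_evals = min(config.budget, cand.shape[0])
    rng = np.random.default_rng(config.seed)

    xs: list[np.ndarray] = []
    ys: list[float] = []

    # seeded quasi-random initial design
    n_init = min(config.n_init, n_evals)
    sob = qmc.Sobol(d=cand.shape[1], scramble=True, seed=int(rng.integers(2**31)))
    u = sob.random(n_init)
    lo = cand.min(axis=0)
    hi = cand.max(axis=0)
    init_pts = lo + u * (hi - lo)
    for p in init_pts:
        # snap to the candidate set so discrete domains stay discrete
        d = np.linalg.norm(cand - p, axis=1)
        for x in xs:
            d[_index_of(cand, x)] = np.inf  # no duplicate evaluations
        j = int(np.argmin(d))
        xs.append(cand[j])
        ys.append(float(objective(cand[j] if cand.shape[1] > 1 else float(cand[j, 0]))))

    while len(xs) < n_evals:
        post = fit_surrogate(np.array(xs), np.array(ys), config)
        util = acquisition(post, max(ys))
        ei = util(cand)
        for x in xs:
            ei[_index_of(cand, x)] = -np.inf  # never re-evaluate a point
        j = int(np.argmax(ei))
        xs.append(cand[j])
        ys.append(float(objective(cand[j] if cand.shape[1] > 1 else float(cand[j, 0]))))

    y_arr = np.array(ys)
    inc = np.maximum.accumulate(y_arr)
    best = int(np.argmax(y_arr))
    return BOTrace(
        x=np.array(xs),
        y=y_arr,
        incumbent=inc,
        config=config,
        best_x=np.array(xs[best]),
        best_y=float(y_arr[best]),
    )


def _index_of(cand: np.ndarray, x: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(cand - x, axis=1)))
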