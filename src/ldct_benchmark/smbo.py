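"""Sequential model-based hyperparameter optimization (SMBO).

A Gaussian-process surrogate (Matern 5/2 kernel with automatic relevance
determination, small observation-noise jitter) models the validation
objective over the search space mapped to the unit cube (log-space for
log-uniform priors). The next configuration maximizes the expected
improvement

    EI(lambda) = E[max(z - Psi*, 0)],  z ~ N(mu(lambda), sigma(lambda)^2)
               = (mu - Psi*) Phi(u) + sigma phi(u),   u = (mu - Psi*)/sigma,

where Psi* is the best objective observed so far. Integer parameters are
optimized in a continuous relaxation and rounded at evaluation time. The
``rel_dev`` diagnostic reports the relative deviation of the running best
objective from the final best, used to judge convergence of a run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from ldct_benchmark._seeding import rng_from

__all__ = [
    "ParamSpec",
    "SearchSpace",
    "Trial",
    "HPOHistory",
    "sample_prior",
    "fit_surrogate",
    "expected_improvement",
    "propose_next",
    "run_smbo",
    "rel_dev",
    "retrain_with_seeds",
]

DEFAULT_N_ITER = 50  # SMBO iterations per method
DEFAULT_N_INIT = 5   # prior draws before the surrogate takes over
DEFAULT_RETRAIN_SEEDS = 10


@dataclass(frozen=True)
class ParamSpec:
    """One hyperparameter: a uniform or log-uniform prior over [low, high]."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log-uniform prior requires low > 0")

    def to_unit(self, value: float) -> float:
        if self.log:
            return (math.log(value) - math.log(self.low)) / (math.log(self.high) - math.log(self.low))
        return (value - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.log:
            value = math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low)))
        else:
            value = self.low + u * (self.high - self.low)
        if self.integer:
            value = int(min(max(round(value), math.ceil(self.low)), math.floor(self.high)))
        return value


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of hyperparameter priors."""

    params: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        if not self.params:
            raise ValueError("search space needs at least one parameter")
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def dim(self) -> int:
        return len(self.params)

    def to_unit(self, lam: dict[str, float]) -> np.ndarray:
        return np.array([p.to_unit(lam[p.name]) for p in self.params])

    def from_unit(self, u: np.ndarray) -> dict[str, float]:
        return {p.name: p.from_unit(float(v)) for p, v in zip(self.params, u)}

    @classmethod
    def from_dicts(cls, specs: list[dict]) -> "SearchSpace":
        return cls(tuple(
            ParamSpec(
                name=s["name"], low=float(s["low"]), high=float(s["high"]),
                log=s.get("prior", "uniform") == "log-uniform" or s.get("log", False),
                integer=bool(s.get("integer", False)),
            )
            for s in specs
        ))


@dataclass
class Trial:
    lam: dict[str, float]
    objective: float  # NaN for failed evaluations
    iteration: int
    seed: int

    @property
    def failed(self) -> bool:
        return not np.isfinite(self.objective)


@dataclass
class HPOHistory:
    trials: list[Trial] = field(default_factory=list)
    metric_name: str = "SSIM"

    @property
    def objectives(self) -> np.ndarray:
        return np.array([t.objective for t in self.trials])

    @property
    def best_trial(self) -> Trial:
        finite = [t for t in self.trials if not t.failed]
        if not finite:
            raise ValueError("no successful trial in history")
        return max(finite, key=lambda t: t.objective)

    @property
    def best_lambda(self) -> dict[str, float]:
        return self.best_trial.lam

    @property
    def best_objective(self) -> float:
        return self.best_trial.objective

    def to_dicts(self) -> list[dict]:
        return [{"lambda": t.lam, "objective": t.objective, "iteration": t.iteration, "seed": t.seed}
                for t in self.trials]

    @classmethod
    def from_dicts(cls, rows: list[dict], metric_name: str = "SSIM") -> "HPOHistory":
        return cls(
            trials=[Trial(lam=r["lambda"], objective=r["objective"], iteration=r["iteration"], seed=r["seed"])
                    for r in rows],
            metric_name=metric_name,
        )


def sample_prior(space: SearchSpace, seed: int, n: int) -> list[dict[str, float]]:
    """``n`` independent draws from the prior; log-uniform via exp(uniform(ln a, ln b))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed, 11)
    u = rng.uniform(size=(n, space.dim))
    return [space.from_unit(row) for row in u]


def fit_surrogate(trials: list[Trial], space: SearchSpace) -> GaussianProcessRegressor:
    """Fit the GP surrogate on successful trials, inputs mapped to the unit cube."""
    ok = [t for t in trials if not t.failed]
    if len(ok) < 2:
        raise ValueError("surrogate requires at least 2 successful trials")
    x = np.array([space.to_unit(t.lam) for t in ok])
    y = np.array([t.objective for t in ok])
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(space.dim, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, n_restarts_optimizer=1, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x, y)
    return gp


def expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    """Closed-form EI for a Gaussian posterior; the sigma = 0 branch is max(mu - best, 0)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    improvement = mu - best
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sigma > 0, improvement / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(
            sigma > 0,
            improvement * norm.cdf(u) + sigma * norm.pdf(u),
            np.maximum(improvement, 0.0),
        )
    return np.maximum(ei, 0.0)


def propose_next(
    history: HPOHistory,
    space: SearchSpace,
    seed: int,
    candidate_count: int = 512,
    refine_count: int = 64,
) -> dict[str, float]:
    """EI-maximizing candidate over a seeded random set plus local refinement."""
    gp = fit_surrogate(history.trials, space)
    best = history.best_objective
    rng = rng_from(seed, 13)
    cand = rng.uniform(size=(candidate_count, space.dim))
    mu, sd = gp.predict(cand, return_std=True)
    ei = expected_improvement(mu, sd, best)
    top = cand[int(np.argmax(ei))]
    # local refinement: shrinking Gaussian perturbations around the incumbent candidate
    width = 0.1
    for _ in range(3):
        local = np.clip(top + rng.normal(scale=width, size=(refine_count, space.dim)), 0.0, 1.0)
        local = np.vstack([top, local])
        mu, sd = gp.predict(local, return_std=True)
        ei = expected_improvement(mu, sd, best)
        top = local[int(np.argmax(ei))]
        width /= 3.0
    return space.from_unit(top)


def run_smbo(
    objective,
    space: SearchSpace,
    n_iter: int = DEFAULT_N_ITER,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
    metric_name: str = "SSIM",
) -> HPOHistory:
    """Run SMBO: ``n_init`` prior draws, then EI-driven proposals up to ``n_iter`` trials.

    ``objective`` maps a hyperparameter dict to a scalar to maximize; an
    exception during evaluation records a failed trial (NaN) that is
    excluded from the surrogate while the loop continues.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    if n_iter < n_init:
        raise ValueError("n_iter must be >= n_init")
    history = HPOHistory(metric_name=metric_name)
    initial = sample_prior(space, seed, n_init)
    for i in range(n_iter):
        if i < n_init:
            lam = initial[i]
        else:
            n_ok = sum(not t.failed for t in history.trials)
            if n_ok >= 2:
                lam = propose_next(history, space, seed * 1_000_003 + i)
            else:  # surrogate not yet fittable (failures during init)
                lam = sample_prior(space, seed * 7 + i, 1)[0]
        try:
            value = float(objective(lam))
        except Exception:
            value = float("nan")
        history.trials.append(Trial(lam=lam, objective=value, iteration=i, seed=seed))
    return history


def rel_dev(history: HPOHistory | np.ndarray) -> np.ndarray:
    """Relative deviation of the running best objective from the overall best.

    ``RelDev_i = 1 - max_{j<=i} M_j / max_j M_j``; non-increasing, final
    element 0.
    """
    values = history.objectives if isinstance(history, HPOHistory) else np.asarray(history, dtype=float)
    if values.size == 0:
        raise ValueError("empty history")
    finite = np.where(np.isfinite(values), values, -np.inf)
    running = np.maximum.accumulate(finite)
    overall = running[-1]
    if not np.isfinite(overall) or overall <= 0:
        raise ValueError("rel_dev requires a positive best objective")
    return 1.0 - running / overall


def retrain_with_seeds(train_fn, best_lambda: dict[str, float], n_seeds: int = DEFAULT_RETRAIN_SEEDS) -> list:
    """Retrain at the tuned configuration with seeds 0..n_seeds-1.

    Per-seed outputs are returned in seed order; a failure is recorded as a
    ``{"seed": s, "error": message}`` dict rather than swallowed.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    out = []
    for s in range(n_seeds):
        try:
            out.append(train_fn(best_lambda, s))
        except Exception as exc:  # noqa: BLE001 - reported to the caller
            out.append({"seed": s, "error": f"{type(exc).__name__}: {exc}"})
    return out


def table1_search_space(method: str = "all") -> SearchSpace:
    """The published hyperparameter priors shared by all benchmarked methods.

    Learning rate logU(1e-5, 0.01), maximum iterations U(1e3, 1e5),
    mini-batch size U(2, 128); patch-based methods add patch size U(32, 128).
    """
    common = [
        ParamSpec("learning_rate", 1e-5, 0.01, log=True),
        ParamSpec("max_iterations", 1e3, 1e5, integer=True),
        ParamSpec("batch_size", 2, 128, integer=True),
    ]
    patch = [ParamSpec("patch_size", 32, 128, integer=True)]
    if method in ("all", "cnn", "patch"):
        return SearchSpace(tuple(common + patch))
    return SearchSpace(tuple(common))
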