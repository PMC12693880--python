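"""Firefly metaheuristic with stochastic perturbation, best-crossover and
Mantegna Levy flight, used to search DNN hyperparameters.

Each firefly is a bounded real vector; its brightness is ``1 / (1 + loss)``
so brighter means fitter.  One iteration applies, in order:

1. pairwise moves toward every brighter firefly with distance-decaying
   attractiveness ``beta0 * exp(-gamma r^2)`` plus a uniform random step;
2. a differential perturbation ``delta * (x_p - x_q)`` from two other
   population members;
3. fitness-proportional crossover with the global best, followed by an
   alpha-scaled Levy-flight kick, accepted only if the objective improves
   (greedy selection).

Disabling stages 2-3 (``use_perturbation/use_crossover/use_levy``) recovers
the plain firefly algorithm.  All positions stay clipped to the search box
and the best-ever loss is non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IFAConfig",
    "HyperparamEncoding",
    "OptimizeResult",
    "brightness",
    "attractiveness",
    "firefly_distance",
    "move",
    "perturb",
    "crossover_prob",
    "crossover",
    "levy_sigma",
    "levy_step",
    "optimize",
]


@dataclass(frozen=True)
class IFAConfig:
    """Search-box and operator settings of the (improved) firefly algorithm."""

    bounds: tuple[tuple[float, float], ...]
    n_fireflies: int = 15
    max_iter: int = 100
    beta0: float = 1.0
    gamma: float = 1.0
    alpha: float = 0.2
    levy_lambda: float = 1.5
    seed: int = 0
    plateau_patience: int | None = None
    plateau_tol: float = 1e-10
    use_perturbation: bool = True
    use_crossover: bool = True
    use_levy: bool = True

    def __post_init__(self) -> None:
        if self.n_fireflies < 2:
            raise ValueError("n_fireflies must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.levy_lambda < 2:
            raise ValueError("levy_lambda must be in (0, 2)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


def brightness(loss: float) -> float:
    """Brightness I = 1 / (1 + loss) of a firefly with the given loss."""
    if loss < 0:
        raise ValueError("loss must be nonnegative")
    return 1.0 / (1.0 + loss)


def attractiveness(r: float, beta0: float, gamma: float) -> float:
    """Distance-decaying attractiveness beta0 * exp(-gamma * r**2)."""
    return beta0 * math.exp(-gamma * r * r)


def firefly_distance(xi: np.ndarray, xj: np.ndarray) -> float:
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("firefly vectors have different dimensions")
    return float(np.sqrt(((xi - xj) ** 2).sum()))


def _clip(x: np.ndarray, cfg: IFAConfig) -> np.ndarray:
    return np.clip(x, cfg.lower, cfg.upper)


def move(xi: np.ndarray, xj: np.ndarray, cfg: IFAConfig,
         rng: np.random.Generator) -> np.ndarray:
    """Move firefly i toward brighter firefly j (caller checks brightness)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    beta = attractiveness(firefly_distance(xi, xj), cfg.beta0, cfg.gamma)
    eps = rng.uniform(0.0, 1.0, size=xi.shape)
    return _clip(xi + beta * (xj - xi) + cfg.alpha * eps, cfg)


def perturb(xi_new: np.ndarray, population: np.ndarray, i: int,
            cfg: IFAConfig, rng: np.random.Generator) -> np.ndarray:
    """Differential perturbation x + delta * (x_p - x_q), p != q != i."""
    population = np.asarray(population, dtype=float)
    n = population.shape[0]
    if n < 3:
        raise ValueError("perturbation needs a population of at least 3")
    others = [k for k in range(n) if k != i]
    p, q = rng.choice(others, size=2, replace=False)
    delta = rng.uniform(0.0, 1.0)
    return _clip(np.asarray(xi_new, dtype=float)
                 + delta * (population[p] - population[q]), cfg)


def crossover_prob(brightnesses: np.ndarray) -> np.ndarray:
    """Fitness-proportional crossover probabilities P_i = I_i / sum I_k."""
    b = np.asarray(brightnesses, dtype=float)
    if b.size == 0:
        raise ValueError("empty population")
    if np.any(b <= 0):
        raise ValueError("brightnesses must be positive")
    return b / b.sum()


def crossover(xi_pert: np.ndarray, x_best: np.ndarray, Pi: float,
              rng: np.random.Generator) -> np.ndarray:
    """Per-dimension: take the global-best component with probability Pi."""
    if not 0 <= Pi <= 1:
        raise ValueError("Pi must lie in [0, 1]")
    xi_pert = np.asarray(xi_pert, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    mask = rng.uniform(0.0, 1.0, size=xi_pert.shape) < Pi
    return np.where(mask, x_best, xi_pert)


def levy_sigma(lam: float) -> float:
    """Mantegna scale sigma_u for the numerator Gaussian of a Levy draw."""
    num = math.gamma(1 + lam) * math.sin(math.pi * lam / 2)
    den = math.gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2)
    return (num / den) ** (1.0 / lam)


def levy_step(cfg: IFAConfig, rng: np.random.Generator,
              size: int | None = None) -> float | np.ndarray:
    """Heavy-tailed step s = u / |v|^(1/lambda) via the Mantegna algorithm."""
    lam = cfg.levy_lambda
    if not 0 < lam < 2:
        raise ValueError("levy_lambda must be in (0, 2)")
    sigma = levy_sigma(lam)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    s = u / np.abs(v) ** (1.0 / lam)
    return s if size is not None else float(s)


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_loss: float
    history: list[float] = field(default_factory=list)
    n_iter: int = 0
    n_evals: int = 0


def optimize(objective, cfg: IFAConfig) -> OptimizeResult:
    """Run the (improved) firefly search and return the best-ever solution.

    ``objective`` maps a position vector to a nonnegative, finite loss.
    The returned ``history`` holds the best-ever loss after each iteration
    and is non-increasing; the whole run is reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF]))
    dim = len(cfg.bounds)
    n = cfg.n_fireflies
    evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(
                f"objective returned a non-finite value at position {x}")
        return v

    pop = rng.uniform(cfg.lower, cfg.upper, size=(n, dim))
    loss = np.array([evaluate(x) for x in pop])
    best_idx = int(np.argmin(loss))
    best_x = pop[best_idx].copy()
    best_loss = float(loss[best_idx])

    history: list[float] = []
    stall = 0
    t = 0
    for t in range(1, cfg.max_iter + 1):
        # stage 1: attraction moves toward every brighter neighbour
        for i in range(n):
            moved = False
            xi = pop[i]
            for j in range(n):
                if loss[j] < loss[i]:  # brighter
                    xi = move(xi, pop[j], cfg, rng)
                    moved = True
            if cfg.use_perturbation:
                xi = perturb(xi, pop, i, cfg, rng)
                moved = True
            if moved:
                pop[i] = xi
                loss[i] = evaluate(xi)
                if loss[i] < best_loss:
                    best_loss = float(loss[i])
                    best_x = pop[i].copy()

        # stage 2: crossover with the global best + Levy kick, greedy accept
        if cfg.use_crossover or cfg.use_levy:
            P = crossover_prob(np.array([brightness(v) for v in loss]))
            for i in range(n):
                z = pop[i]
                if cfg.use_crossover:
                    z = crossover(z, best_x, float(P[i]), rng)
                if cfg.use_levy:
                    s = levy_step(cfg, rng, size=dim)
                    sign = np.sign(rng.uniform(0.0, 1.0, size=dim) - 0.5)
                    z = z + cfg.alpha * s * sign
                z = _clip(z, cfg)
                fz = evaluate(z)
                if fz < loss[i]:  # greedy selection
                    pop[i] = z
                    loss[i] = fz
                    if fz < best_loss:
                        best_loss = fz
                        best_x = z.copy()

        improved = history and history[-1] - best_loss > cfg.plateau_tol
        history.append(best_loss)
        if cfg.plateau_patience is not None and len(history) > 1:
            stall = 0 if improved else stall + 1
            if stall >= cfg.plateau_patience:
                break

    return OptimizeResult(best_position=best_x, best_loss=best_loss,
                          history=history, n_iter=t, n_evals=evals)


@dataclass(frozen=True)
class HyperparamEncoding:
    """Ordered map between firefly coordinates and DNN hyperparameters.

    Each dimension is ``(name, lower, upper, kind)`` with kind one of
    ``"linear"``, ``"log10"`` (coordinate is the base-10 exponent) or
    ``"int"`` (rounded on decode).
    """

    dims: tuple[tuple[str, float, float, str], ...]

    def __post_init__(self) -> None:
        for name, lo, hi, kind in self.dims:
            if not lo < hi:
                raise ValueError(f"dimension {name}: lower must be < upper")
            if kind not in ("linear", "log10", "int"):
                raise ValueError(f"dimension {name}: unknown kind {kind!r}")

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple((lo, hi) for _, lo, hi, _ in self.dims)

    def decode(self, position: np.ndarray) -> dict:
        out = {}
        for x, (name, lo, hi, kind) in zip(position, self.dims):
            x = float(np.clip(x, lo, hi))
            if kind == "log10":
                out[name] = 10.0 ** x
            elif kind == "int":
                out[name] = int(round(x))
            else:
                out[name] = x
        return out

    def encode(self, values: dict) -> np.ndarray:
        pos = []
        for name, lo, hi, kind in self.dims:
            v = values[name]
            x = math.log10(v) if kind == "log10" else float(v)
            pos.append(np.clip(x, lo, hi))
        return np.array(pos)

    def center(self) -> dict:
        """Hyperparameters at the midpoint of the search box."""
        return self.decode((np.array([lo for _, lo, _, _ in self.dims])
                            + np.array([hi for _, _, hi, _ in self.dims])) / 2)


def default_dnn_encoding(width_range: tuple[int, int] = (6, 16),
                         epochs_range: tuple[int, int] = (200, 1000)
                         ) -> HyperparamEncoding:
    """Search space for the sub-model search: learning rate (log scale),
    hidden width, weight-init range and training epochs."""
    return HyperparamEncoding(dims=(
        ("lr", -4.0, -0.5, "log10"),
        ("width", float(width_range[0]), float(width_range[1]), "int"),
        ("init_range", 0.1, 2.0, "linear"),
        ("epochs", float(epochs_range[0]), float(epochs_range[1]), "int"),
    ))
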