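"""Gravitational search algorithm (classical and refined variants).

Candidate solutions are point masses in the unit hypercube. Each iteration,
fitness-derived masses attract one another with forces proportional to
G(t) · M_i · M_j / (R_ij + ξ); only the current k best agents exert force, and
G(t) = G0·exp(−α t/T) decays so the swarm moves from exploration to
exploitation. The refined variant replaces the uniform force weights with
Bernoulli(p) draws (a force either exists or does not) and the uniform
velocity-memory coefficient with a logarithmic/Gaussian mixture.

All randomness flows through one seeded generator; the low-level update
functions take their random draws as explicit arguments so each equation can
be checked in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GSAConfig:
    """Optimizer settings.

    Defaults follow the published tumour-classification configuration
    (100 agents, 500 iterations, G0 = 100); α = 20 is the standard decay
    setting, p the Bernoulli force-existence probability of the refined
    variant, ξ a small softening constant preventing division blow-up for
    coincident agents.
    """

    n_agents: int = 100
    n_iters: int = 500
    g0: float = 100.0
    alpha: float = 20.0
    xi: float = 1e-9
    p: float = 0.8
    variant: str = "refined"
    vmax: float = 0.1  # per-dimension velocity limit, as a fraction of the unit domain

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.variant not in ("classical", "refined"):
            raise ValueError(f"unknown variant {self.variant!r}")


def gravitational_constant(t: int, config: GSAConfig) -> float:
    """G(t) = G0 · exp(−α t / T)."""
    return config.g0 * float(np.exp(-config.alpha * t / config.n_iters))


def update_masses(fitnesses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw masses m_i = (fit_i − worst)/(best − worst) and normalized M_i = m_i/Σm.

    Minimization sense: best = min, worst = max. When every fitness is equal
    the masses are uniform 1/N.
    """
    fit = np.asarray(fitnesses, dtype=float)
    n = fit.size
    best, worst = fit.min(), fit.max()
    if worst == best:
        m = np.full(n, 1.0 / n)
    else:
        m = (fit - worst) / (best - worst)
    tot = m.sum()
    M = m / tot if tot > 0 else np.full(n, 1.0 / n)
    return m, M


def kbest_count(t: int, config: GSAConfig) -> int:
    """Linear schedule: all agents attract at t=0, only the best at t=T."""
    T = max(config.n_iters, 1)
    return max(1, int(round(config.n_agents - (config.n_agents - 1) * t / T)))


def compute_forces(
    positions: np.ndarray,
    M: np.ndarray,
    G: float,
    kbest_idx: np.ndarray,
    r: np.ndarray,
    xi: float,
) -> np.ndarray:
    """Total force on each agent from the k best attractors.

    F_i^d = Σ_{j ∈ kbest, j≠i} r[i,j] · G · M_i·M_j / (R_ij + ξ) · (x_j^d − x_i^d)
    with R_ij the Euclidean distance. ``r`` holds the per-pair random force
    weights (uniform for the classical variant, Bernoulli(p) for the refined).
    """
    X = np.asarray(positions, dtype=float)
    n = X.shape[0]
    F = np.zeros_like(X)
    for j in kbest_idx:
        diff = X[j] - X  # (n, d)
        R = np.linalg.norm(diff, axis=1)
        coeff = G * M * M[j] / (R + xi) * r[:, j]
        coeff[j] = 0.0
        F += coeff[:, None] * diff
    return F


def rand_refined_value(rand_u: float, rand_d: float, rand_g: float) -> float:
    """Refined velocity-memory coefficient from its three source randoms.

    rand_i = ln(1/rand_d)/4 when rand_u > 0.4, else 0.4 + 0.1·rand_g; the
    result is clamped to [0, 1] (the logarithmic branch is unbounded, and the
    coefficient scales retained velocity).
    """
    if rand_u > 0.4:
        v = np.log(1.0 / rand_d) / 4.0
    else:
        v = 0.4 + 0.1 * rand_g
    return float(np.clip(v, 0.0, 1.0))


def rand_refined(rng: np.random.Generator, size: int) -> np.ndarray:
    """Vector of refined velocity-memory coefficients."""
    u = rng.uniform(size=size)
    d = rng.uniform(size=size)
    g = rng.standard_normal(size)
    v = np.where(u > 0.4, np.log(1.0 / d) / 4.0, 0.4 + 0.1 * g)
    return np.clip(v, 0.0, 1.0)


def update_motion(
    positions: np.ndarray,
    velocities: np.ndarray,
    forces: np.ndarray,
    M: np.ndarray,
    rand_v: np.ndarray,
    vmax: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Accelerations a_i = F_i / M_i (zero-mass agents get zero acceleration),
    velocity v ← rand_i·v + a, position x ← clip(x + v, 0, 1).

    ``rand_v`` is the per-agent velocity-memory coefficient, broadcast over
    dimensions. ``vmax`` limits each velocity component: with the gravitational
    constant fixed at G0 = 100 the early-phase accelerations far exceed the
    unit domain, and an unchecked swarm pins at the walls; a velocity limit of
    a fraction of the domain width is the standard swarm-search remedy.
    """
    M = np.asarray(M, dtype=float)
    a = np.zeros_like(forces)
    nzm = M > 0
    a[nzm] = forces[nzm] / M[nzm, None]
    rv = np.asarray(rand_v, dtype=float)
    if rv.ndim == 1:
        rv = rv[:, None]
    v_new = np.clip(rv * velocities + a, -vmax, vmax)
    x_new = np.clip(positions + v_new, 0.0, 1.0)
    return v_new, x_new


@dataclass
class OptimizeResult:
    """Best-so-far solution of a GSA run with its per-iteration history."""

    position: np.ndarray
    fitness: float
    history: np.ndarray  # best-so-far fitness after each iteration
    n_evaluations: int = 0
    extras: dict = field(default_factory=dict)


def optimize(
    fitness_fn,
    n_dims: int,
    config: GSAConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    callback=None,
) -> OptimizeResult:
    """Minimize ``fitness_fn`` over [0,1]^n_dims with GSA or refined GSA.

    Elitist bookkeeping: the returned solution is the best position ever
    evaluated, and ``history`` is monotone non-increasing. ``fitness_fn``
    receives a single position vector and returns a scalar.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N, T = config.n_agents, config.n_iters
    X = rng.uniform(size=(N, n_dims))
    V = rng.uniform(size=(N, n_dims))

    best_pos = None
    best_fit = np.inf
    history = np.empty(T)
    n_eval = 0

    for t in range(T):
        try:
            fit = np.array([float(fitness_fn(x)) for x in X])
        except Exception as exc:  # noqa: BLE001 - re-raise with optimizer context
            raise RuntimeError(
                f"fitness evaluation failed at iteration {t}: {exc}"
            ) from exc
        n_eval += N
        i_best = int(np.argmin(fit))
        if fit[i_best] < best_fit:
            best_fit = float(fit[i_best])
            best_pos = X[i_best].copy()
        history[t] = best_fit

        _, M = update_masses(fit)
        G = gravitational_constant(t, config)
        K = kbest_count(t, config)
        kbest_idx = np.argsort(fit)[:K]

        if config.variant == "classical":
            r = rng.uniform(size=(N, N))
            rand_v = rng.uniform(size=N)
        else:
            r = (rng.uniform(size=(N, N)) < config.p).astype(float)
            rand_v = rand_refined(rng, N)

        F = compute_forces(X, M, G, kbest_idx, r, config.xi)
        V, X = update_motion(X, V, F, M, rand_v, vmax=config.vmax)
        if callback is not None:
            callback(t, best_fit, X)

    return OptimizeResult(
        position=best_pos, fitness=best_fit, history=history, n_evaluations=n_eval
    )


def make_geometric_fitness(voi):
    """Sum-of-squared-distances objective over a VOI (a localisation benchmark).

    The agent's 3 coordinates in [0,1] decode linearly to a point inside the
    VOI bounding box; the objective is Σ_v ‖v − P‖² over all in-mask voxels.
    Its unconstrained minimiser is the centroid. Points whose nearest voxel is
    outside the mask incur an additive penalty proportional to that miss
    distance, keeping the search feasible.
    """
    coords = voi.coords.astype(float)
    (x0, x1), (y0, y1), (z0, z1) = voi.bounding_box
    lo = np.array([x0, y0, z0], dtype=float)
    hi = np.array([x1, y1, z1], dtype=float)
    n = coords.shape[0]
    scale = float(np.square(hi - lo + 1).sum())

    def fitness(position: np.ndarray) -> float:
        P = lo + np.asarray(position[:3]) * (hi - lo)
        val = float(np.square(coords - P).sum())
        nearest = np.round(P).astype(int)
        inside = (
            voi.mask[tuple(np.clip(nearest, lo.astype(int), hi.astype(int)))]
            if np.all(nearest >= lo) and np.all(nearest <= hi)
            else False
        )
        if not inside:
            d2 = np.square(coords - P).sum(axis=1).min()
            val += n * scale * (1.0 + d2)
        return val

    return fitness
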