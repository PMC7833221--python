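"""Reynolds flocking model with a centre-of-mass emergence feature.

Each boid is three numbers — a 2-D position and a heading angle — and
steers by three weighted rules: aggregation (``a1``, toward the centre of
the other boids), avoidance (``a2``, away from its nearest neighbour) and
alignment (``a3``, toward the mean heading of neighbours within a fixed
radius).  The candidate emergent feature is the flock's centre of mass,
analysed with the Gaussian mutual-information estimator over lagged,
strided trajectory samples.

The arena is toroidal by default: interactions use minimal-image relative
displacements and the centre of mass is the circular mean of the wrapped
coordinates, which keeps the position process stationary — on an unbounded
plane the flock performs an integrated random walk and mutual information
between raw coordinates diverges with the observation window.  A ``plane``
boundary mode (no wrapping) is available; there the dynamics depend on
relative positions only and are exactly translation-equivariant.

Increasing ``a2`` drives the flock through the regimes the emergence sweep
probes: tight orbiting around a slowly-drifting centre of mass at zero
avoidance, smooth collective wandering at intermediate values, and
dispersal into mutually avoiding singletons when repulsion dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .prob import ArgumentError, SampleMatrix

__all__ = [
    "FlockParams",
    "FlockState",
    "boids_step",
    "center_of_mass",
    "initial_state",
    "simulate",
    "flock_sample_matrices",
    "sweep_avoidance",
    "nearest_neighbour_distance",
]


@dataclass(frozen=True)
class FlockParams:
    """Flocking parameters.

    ``a1``/``a2``/``a3`` weight aggregation, avoidance and alignment.
    Defaults: 10 boids, unit speed and timestep, toroidal arena of side 60
    with neighbourhood radius arena/5, heading noise sd 0.05 rad, and
    aggregation-dominant fixed weights (a1=0.5, a3=0.05) so that the
    zero-avoidance flock orbits a slowly-moving centre of mass instead of
    flying ballistically.
    """

    a1: float = 0.5
    a2: float = 0.0
    a3: float = 0.05
    n_boids: int = 10
    speed: float = 1.0
    timestep: float = 1.0
    arena: float = 60.0
    radius: float | None = None
    heading_noise: float = 0.05
    boundary: str = "torus"

    def __post_init__(self) -> None:
        if self.n_boids < 2:
            raise ArgumentError("need at least two boids")
        if min(self.a1, self.a2, self.a3) < 0:
            raise ArgumentError("rule weights must be non-negative")
        if min(self.speed, self.timestep, self.arena) <= 0:
            raise ArgumentError("speed, timestep and arena must be positive")
        if self.radius is not None and self.radius <= 0:
            raise ArgumentError("neighbourhood radius must be positive")
        if self.boundary not in ("torus", "plane"):
            raise ArgumentError("boundary must be 'torus' or 'plane'")

    @property
    def neighbourhood(self) -> float:
        return self.arena / 5 if self.radius is None else self.radius


@dataclass
class FlockState:
    """Positions (N x 2) and heading angles (N,), wrapped to [0, 2pi)."""

    positions: np.ndarray
    headings: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.mod(np.asarray(self.headings, dtype=float), 2 * np.pi)
        if self.positions.shape != (len(self.headings), 2):
            raise ArgumentError("positions must be N x 2 matching headings")


def _min_image(diff: np.ndarray, arena: float) -> np.ndarray:
    return (diff + arena / 2) % arena - arena / 2


def center_of_mass(state: FlockState, params: FlockParams | None = None) -> np.ndarray:
    """Centre of mass of the flock.

    Arithmetic mean of the positions; on a toroidal arena the per-coordinate
    circular mean mapped back to [0, arena), which is the standard
    centre-of-mass definition for periodic domains and agrees with the
    arithmetic mean whenever the flock does not straddle the seam.
    """
    p = state.positions
    if params is None or params.boundary == "plane":
        return p.mean(axis=0)
    theta = 2 * np.pi * p / params.arena
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return (mean_angle / (2 * np.pi) * params.arena) % params.arena


def nearest_neighbour_distance(
    state: FlockState, params: FlockParams | None = None
) -> np.ndarray:
    """Distance from each boid to its closest flockmate (minimal image on a
    torus)."""
    diff = state.positions[:, None, :] - state.positions[None, :, :]
    if params is not None and params.boundary == "torus":
        diff = _min_image(diff, params.arena)
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.divide(v, norm, out=np.zeros_like(v), where=norm > 1e-12)


def boids_step(
    state: FlockState,
    params: FlockParams,
    rng: np.random.Generator | None = None,
) -> FlockState:
    """Advance the flock one timestep.

    The steering update per boid is
    ``a1 * u_centre + a2 * u_away + a3 * (u_align - u_heading)`` added to the
    current heading unit vector and renormalised; the position advances by
    ``speed * timestep`` along the new heading.
    """
    p = state.positions
    n = len(p)
    torus = params.boundary == "torus"
    v = np.stack([np.cos(state.headings), np.sin(state.headings)], axis=1)

    # displacement from boid i to boid j (minimal image on a torus)
    diff = p[None, :, :] - p[:, None, :]
    if torus:
        diff = _min_image(diff, params.arena)

    # all three rules are local, as in the classic flocking formulation:
    # boids perceive flockmates within the neighbourhood radius only, which
    # is what lets sub-flocks form, wander and disintegrate
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)

    # aggregation: toward the centre of perceived flockmates
    mask_n = dist <= params.neighbourhood
    counts_n = mask_n.sum(axis=1)
    centre_disp = np.einsum("ij,ijk->ik", mask_n, diff) / np.maximum(
        counts_n, 1
    )[:, None]
    u_centre = np.where(counts_n[:, None] > 0, _unit(centre_disp), 0.0)

    # avoidance: away from the nearest neighbour, active within the
    # neighbourhood radius (an ungated unit-vector repulsion would disperse
    # the flock without bound whenever a2 > a1)
    nn = dist.argmin(axis=1)
    close = dist[np.arange(n), nn] <= params.neighbourhood
    u_away = np.where(close[:, None], _unit(-diff[np.arange(n), nn]), 0.0)

    # alignment: toward the mean heading of neighbours within the radius
    mask = dist <= params.neighbourhood
    counts = mask.sum(axis=1)
    mean_head = mask @ v
    u_align = _unit(mean_head)
    align_corr = np.where(counts[:, None] > 0, u_align - v, 0.0)

    steer = params.a1 * u_centre + params.a2 * u_away + params.a3 * align_corr
    new_v = _unit(v + steer)
    headings = np.arctan2(new_v[:, 1], new_v[:, 0])
    if rng is not None and params.heading_noise > 0:
        headings = headings + rng.normal(0.0, params.heading_noise, size=n)
        new_v = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    positions = p + params.speed * params.timestep * new_v
    if torus:
        positions = positions % params.arena
    return FlockState(positions=positions, headings=headings)


def initial_state(params: FlockParams, rng: np.random.Generator) -> FlockState:
    """Uniform positions over the arena scale, uniform headings."""
    pos = rng.uniform(0.0, params.arena, size=(params.n_boids, 2))
    head = rng.uniform(0.0, 2 * np.pi, size=params.n_boids)
    return FlockState(positions=pos, headings=head)


def simulate(
    params: FlockParams, n_steps: int, seed: int, initial: FlockState | None = None
) -> np.ndarray:
    """Simulate the flock; returns a (n_steps + 1, N, 3) trajectory array of
    per-boid (x, y, heading) triples, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    state = initial_state(params, rng) if initial is None else initial
    out = np.empty((n_steps + 1, params.n_boids, 3))
    for t in range(n_steps + 1):
        out[t, :, :2] = state.positions
        out[t, :, 2] = state.headings
        if t < n_steps:
            state = boids_step(state, params, rng)
    return out


def flock_sample_matrices(
    trajectory: np.ndarray,
    params: FlockParams | None = None,
    burn_in: int = 200,
    stride: int = 5,
) -> tuple[SampleMatrix, SampleMatrix]:
    """(system, feature) SampleMatrix pair from a trajectory.

    The system groups each boid's three columns as one part; the feature is
    the 2-D centre of mass (circular mean on a toroidal arena).  Samples are
    strided to reduce autocorrelation between lag pairs.
    """
    if trajectory.ndim != 3 or trajectory.shape[2] != 3:
        raise ArgumentError("trajectory must be (time, boids, 3)")
    traj = trajectory[burn_in::stride]
    t_len, n, _ = traj.shape
    if t_len < 3:
        raise ArgumentError("trajectory too short after burn-in and striding")
    system_vals = traj.reshape(t_len, n * 3)[None, :, :]
    parts = tuple(tuple(range(3 * i, 3 * i + 3)) for i in range(n))
    system = SampleMatrix(system_vals, kind="continuous", parts=parts)
    pos = traj[:, :, :2]
    if params is not None and params.boundary == "torus":
        theta = 2 * np.pi * pos / params.arena
        ang = np.arctan2(np.sin(theta).mean(axis=1), np.cos(theta).mean(axis=1))
        com = (ang / (2 * np.pi) * params.arena) % params.arena
    else:
        com = pos.mean(axis=1)
    feature = SampleMatrix(com[None, :, :], kind="continuous")
    return system, feature


DEFAULT_SWEEP = (0.0, 0.3, 1.0, 3.0, 8.0)


def sweep_avoidance(
    a2_values=DEFAULT_SWEEP,
    params: FlockParams | None = None,
    n_steps: int = 6000,
    seed: int = 0,
    n_surrogates: int = 100,
    burn_in: int = 200,
    stride: int = 5,
) -> list[dict]:
    """Emergence sweep over the avoidance weight ``a2``.

    For each value the flock is simulated afresh (same seed, so sweeps are
    comparable), and Psi of the centre of mass is computed with the Gaussian
    estimator plus surrogate statistics.  The two components of Psi —
    the feature self-information I(V_t;V_t') and the subtracted sum
    ``sum_i I(X_t^i;V_t')`` — are reported separately, since low- and
    high-avoidance regimes suppress Psi for opposite reasons (redundancy
    with individual boids vs. loss of self-predictability).
    """
    from .criteria import evaluate
    from .info import gaussian_mi_samples

    if params is None:
        params = FlockParams()
    a2_values = list(a2_values)
    if len(a2_values) < 2:
        raise ArgumentError("sweep needs at least two avoidance values")
    results = []
    for a2 in a2_values:
        p = replace(params, a2=float(a2))
        traj = simulate(p, n_steps, seed)
        system, feature = flock_sample_matrices(traj, p, burn_in, stride)
        report = evaluate(
            system,
            feature,
            k=1,
            tau=1,
            estimator="gaussian",
            n_surrogates=n_surrogates,
            seed=seed,
        )
        v_past, v_future = feature.lagged(1)
        self_mi = gaussian_mi_samples(v_past, v_future)
        results.append(
            {
                "a2": float(a2),
                "a1": p.a1,
                "a3": p.a3,
                "seed": seed,
                "psi": report.psi,
                "feature_self_mi": self_mi,
                "sum_part_mi": self_mi - report.psi,
                "report": report,
            }
        )
    return results
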