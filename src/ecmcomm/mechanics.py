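"""Quasi-static mechanics of contractile cells in nonlinear fiber networks.

Fibers are one-dimensional truss elements joined at freely rotating hinges.
The material law captures the two hallmarks of biopolymer networks: buckling
(the tangent modulus drops tenfold at compressive strains beyond 2%) and
strain stiffening (exponential modulus growth at tensile strains beyond 2%).
Cell contraction is imposed as stepwise radial displacement of the nodes on a
void's perimeter; after each step the positions of all free nodes are found by
minimizing the total elastic energy with an analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .network import NetworkGeometry

__all__ = [
    "ConstitutiveParams",
    "ContractionSchedule",
    "SimulationTrajectory",
    "SolverError",
    "element_modulus",
    "fiber_stress",
    "fiber_energy_density",
    "solve_equilibrium",
    "run_contraction_simulation",
    "follower_contraction",
    "follower_contraction_beta",
]

# exponential stiffening rate 1/strain: characteristic strain ~3.3%, the
# scale measured for collagen/fibrin gels in fibrous-network models
_DEFAULT_STIFFENING_RATE = 30.0


@dataclass
class ConstitutiveParams:
    """Piecewise fiber material law.

    ``variant="stiffening"`` stiffens exponentially beyond the 2% tension
    threshold; ``variant="linear_to_15pct"`` stays linear until 15% strain
    (fibrin-like) and stiffens beyond that.  The buckling branch is shared:
    tangent modulus ``buckling_factor * E0`` below the compression threshold.
    """

    base_modulus: float = 1.0  # E0, force per unit strain (unit cross-section)
    compression_threshold: float = -0.02
    tension_threshold: float = 0.02
    buckling_factor: float = 0.1
    stiffening_rate: float = _DEFAULT_STIFFENING_RATE
    variant: str = "stiffening"

    def __post_init__(self) -> None:
        if not (0.0 < self.buckling_factor < 1.0):
            raise ValueError("buckling_factor must be in (0, 1)")
        if not (self.compression_threshold < 0.0 < self.tension_threshold):
            raise ValueError("strain thresholds must bracket 0")
        if self.variant not in ("stiffening", "linear_to_15pct"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def stiffening_onset(self) -> float:
        return self.tension_threshold if self.variant == "stiffening" else 0.15


def element_modulus(strain, params: ConstitutiveParams):
    """Tangent modulus at the given strain (vectorized, total function)."""
    eps = np.asarray(strain, dtype=float)
    E0 = params.base_modulus
    ec = params.compression_threshold
    onset = params.stiffening_onset
    k = params.stiffening_rate
    out = np.full_like(eps, E0)
    out = np.where(eps < ec, params.buckling_factor * E0, out)
    out = np.where(eps > onset, E0 * np.exp(k * np.minimum(eps - onset, 50.0 / k)), out)
    return out if out.ndim else float(out)


def fiber_stress(strain, params: ConstitutiveParams):
    """Engineering stress (force at unit cross-section): integral of the modulus."""
    eps = np.asarray(strain, dtype=float)
    E0 = params.base_modulus
    ec = params.compression_threshold
    onset = params.stiffening_onset
    b = params.buckling_factor
    k = params.stiffening_rate
    lin = E0 * eps
    comp = E0 * ec + b * E0 * (eps - ec)
    de = np.minimum(np.maximum(eps - onset, 0.0), 50.0 / k)
    tens = E0 * onset + (E0 / k) * (np.exp(k * de) - 1.0)
    out = np.where(eps < ec, comp, np.where(eps > onset, tens, lin))
    return out if out.ndim else float(out)


def fiber_energy_density(strain, params: ConstitutiveParams):
    """Elastic energy per unit rest length; C1-continuous across thresholds."""
    eps = np.asarray(strain, dtype=float)
    E0 = params.base_modulus
    ec = params.compression_threshold
    onset = params.stiffening_onset
    b = params.buckling_factor
    k = params.stiffening_rate
    lin = 0.5 * E0 * eps**2
    dc = eps - ec
    comp = 0.5 * E0 * ec**2 + E0 * ec * dc + 0.5 * b * E0 * dc**2
    dt = np.minimum(np.maximum(eps - onset, 0.0), 50.0 / k)
    tens = (
        0.5 * E0 * onset**2
        + E0 * onset * dt
        + (E0 / k) * ((np.exp(k * dt) - 1.0) / k - dt)
    )
    out = np.where(eps < ec, comp, np.where(eps > onset, tens, lin))
    return out if out.ndim else float(out)


class SolverError(RuntimeError):
    def __init__(self, residual: float, tol: float, step: int | None = None):
        self.residual = residual
        self.step = step
        at = f" at step {step}" if step is not None else ""
        super().__init__(
            f"equilibrium solve did not converge{at}: "
            f"max residual force {residual:.3e} > tol {tol:.1e}"
        )


def _energy_and_grad(x_free, free_idx, fixed_pos, fibers, rest, params):
    pos = fixed_pos.copy()
    pos[free_idx] = x_free.reshape(-1, 2)
    d = pos[fibers[:, 1]] - pos[fibers[:, 0]]
    length = np.sqrt(np.einsum("ij,ij->i", d, d))
    length = np.maximum(length, 1e-300)
    eps = length / rest - 1.0
    energy = float(np.sum(rest * fiber_energy_density(eps, params)))
    sigma = fiber_stress(eps, params)
    f = (sigma / length)[:, None] * d  # force contribution along the fiber
    n = pos.shape[0]
    gx = np.bincount(fibers[:, 1], weights=f[:, 0], minlength=n) - np.bincount(
        fibers[:, 0], weights=f[:, 0], minlength=n
    )
    gy = np.bincount(fibers[:, 1], weights=f[:, 1], minlength=n) - np.bincount(
        fibers[:, 0], weights=f[:, 1], minlength=n
    )
    grad = np.stack([gx, gy], axis=1)
    return energy, grad[free_idx].ravel()


def _tangent_stiffness(pos, free_idx, fibers, rest, params):
    """Sparse tangent stiffness restricted to the free degrees of freedom."""
    from scipy import sparse

    n = pos.shape[0]
    dofmap = np.full(n, -1, dtype=int)
    dofmap[free_idx] = np.arange(free_idx.size)
    i, j = fibers[:, 0], fibers[:, 1]
    d = pos[j] - pos[i]
    length = np.maximum(np.sqrt(np.einsum("ij,ij->i", d, d)), 1e-300)
    u = d / length[:, None]
    eps = length / rest - 1.0
    k_ax = element_modulus(eps, params) / rest
    k_geo = fiber_stress(eps, params) / length
    # per-fiber 2x2 block: k_ax * u u^T + k_geo * (I - u u^T)
    bxx = k_ax * u[:, 0] ** 2 + k_geo * (1.0 - u[:, 0] ** 2)
    byy = k_ax * u[:, 1] ** 2 + k_geo * (1.0 - u[:, 1] ** 2)
    bxy = (k_ax - k_geo) * u[:, 0] * u[:, 1]

    rows, cols, vals = [], [], []
    di, dj = dofmap[i], dofmap[j]
    for (a, b, sign) in ((di, di, 1.0), (dj, dj, 1.0), (di, dj, -1.0), (dj, di, -1.0)):
        ok = (a >= 0) & (b >= 0)
        for (ra, ca, block) in ((0, 0, bxx), (0, 1, bxy), (1, 0, bxy), (1, 1, byy)):
            rows.append(2 * a[ok] + ra)
            cols.append(2 * b[ok] + ca)
            vals.append(sign * block[ok])
    m = 2 * free_idx.size
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )


def _factorize(x, free_idx, pos, fibers, rest, params):
    from scipy.sparse import identity
    from scipy.sparse.linalg import splu

    full = pos.copy()
    full[free_idx] = x.reshape(-1, 2)
    H = _tangent_stiffness(full, free_idx, fibers, rest, params)
    reg = 1e-10 * max(H.diagonal().max(), 1.0)
    return splu((H + reg * identity(H.shape[0])).tocsc())


def _newton_polish(
    x, free_idx, pos, fibers, rest, params, tol, max_newton=120, lu_cache=None
):
    """Drive the free-node force residual below tol with damped Newton steps.

    The sparse LU factorization of the tangent stiffness is reused across
    iterations (and, via ``lu_cache``, across contraction steps) and only
    recomputed when the cached factor stops making progress -- a modified
    Newton scheme that exploits how little the stiffness changes per step.
    """
    energy, grad = _energy_and_grad(x, free_idx, pos, fibers, rest, params)
    residual = float(np.max(np.abs(grad))) if grad.size else 0.0
    lu = lu_cache[0] if lu_cache else None
    fresh = False
    it = 0
    stale_iters = 0
    while residual > tol and it < max_newton:
        it += 1
        if lu is None or stale_iters > 15:
            lu = _factorize(x, free_idx, pos, fibers, rest, params)
            fresh = True
            stale_iters = 0
        try:
            step = lu.solve(-grad)
        except RuntimeError:
            step = -grad
        if float(step @ grad) >= 0.0:  # not a descent direction (stale/indefinite)
            if not fresh:
                lu = None
                continue
            step = -grad
        alpha = 1.0
        slope = float(step @ grad)
        for _ in range(30):
            e_new, g_new = _energy_and_grad(
                x + alpha * step, free_idx, pos, fibers, rest, params
            )
            if e_new <= energy + 1e-4 * alpha * slope or np.max(np.abs(g_new)) < residual:
                break
            alpha *= 0.5
        new_residual = float(np.max(np.abs(g_new)))
        # a stale factorization is kept while it still contracts the residual;
        # triangular solves are ~30x cheaper than a refactorization
        if new_residual > 0.7 * residual and not fresh:
            lu = None  # stalled: refactor and retry this iterate
            continue
        x = x + alpha * step
        energy, grad = e_new, g_new
        residual = new_residual
        fresh = False
        stale_iters += 1
    if lu_cache is not None:
        lu_cache[0] = lu
    return x, residual


def solve_equilibrium(
    geom: NetworkGeometry,
    imposed: dict[int, np.ndarray] | None = None,
    params: ConstitutiveParams | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 4000,
    fixed_ids: np.ndarray | None = None,
    fixed_positions: np.ndarray | None = None,
    lu_cache: list | None = None,
) -> np.ndarray:
    """Positions minimizing elastic energy with imposed node displacements.

    ``imposed`` maps node index -> displacement offset (added to the reference
    position); the outer rim is always held fixed.  Alternatively
    ``fixed_ids``/``fixed_positions`` pin nodes at absolute positions.
    Returns the full (N, 2) equilibrium position array.
    """
    if params is None:
        params = ConstitutiveParams()
    pos = geom.node_positions.copy()
    pinned = np.zeros(geom.n_nodes, dtype=bool)
    pinned[geom.rim_node_ids] = True
    pinned[geom.degrees() == 0] = True  # orphaned nodes (e.g. interior to a void)
    if imposed:
        for nid, off in imposed.items():
            pos[nid] = geom.node_positions[nid] + np.asarray(off, float)
            pinned[nid] = True
    if fixed_ids is not None:
        pos[fixed_ids] = fixed_positions
        pinned[fixed_ids] = True

    free_idx = np.flatnonzero(~pinned)
    if free_idx.size == 0:
        return pos
    start = pos[free_idx] if x0 is None else x0[free_idx]
    args = (free_idx, pos, geom.fibers, geom.rest_lengths, params)
    x = start.ravel()
    if x0 is None:
        # cold start: L-BFGS with analytic gradient takes large cheap steps
        res = minimize(
            _energy_and_grad,
            x,
            args=args,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 4 * max_iter, "gtol": 1e-5, "ftol": 1e-16},
        )
        x = res.x
    # damped semismooth Newton on the assembled tangent stiffness; the
    # piecewise law is C1 but not C2, which stalls quasi-Newton methods well
    # above tight residuals while Newton steps remain effective
    x, residual = _newton_polish(x, *args, tol=tol, lu_cache=lu_cache)
    pos[free_idx] = x.reshape(-1, 2)
    return pos


@dataclass
class ContractionSchedule:
    """Per-cell, per-step contraction fractions in percent of initial radius."""

    fractions: np.ndarray  # (n_steps, n_cells) percent
    mode: str = "constant"
    rng_seed: int | None = None

    @property
    def n_steps(self) -> int:
        return int(self.fractions.shape[0])

    @property
    def n_cells(self) -> int:
        return int(self.fractions.shape[1])

    def cumulative(self) -> np.ndarray:
        """Cumulative contraction percent after each step, shape (n_steps, n_cells)."""
        return np.cumsum(self.fractions, axis=0)

    @classmethod
    def constant(cls, n_cells: int, n_steps: int = 50, percent: float = 1.0):
        return cls(np.full((n_steps, n_cells), percent), mode="constant")

    @classmethod
    def heterogeneous(
        cls,
        n_cells: int,
        mu: float = 1.0,
        sigma: float = 0.5,
        n_steps: int = 50,
        rng_seed: int = 0,
    ):
        """I.i.d. normal N(mu, sigma) percent contraction per cell per step.

        Negative draws (possible at large sigma) are applied as drawn, i.e. as
        small expansions, preserving the stated distribution.
        """
        rng = np.random.default_rng(rng_seed)
        frac = rng.normal(mu, sigma, size=(n_steps, n_cells))
        return cls(frac, mode="heterogeneous", rng_seed=rng_seed)

    @classmethod
    def leader_follower(
        cls,
        alpha: float,
        mu: float = 1.0,
        sigma: float = 0.5,
        n_steps: int = 50,
        rng_seed: int = 0,
    ):
        """Leader cell (column 0) drives a follower (column 1) with one-step lag."""
        rng = np.random.default_rng(rng_seed)
        leader = rng.normal(mu, sigma, size=n_steps)
        follower = follower_contraction(leader, alpha, mu, sigma, rng)
        return cls(
            np.stack([leader, follower], axis=1), mode=f"follower_alpha({alpha})",
            rng_seed=rng_seed,
        )

    def with_passive(self, cell_index: int) -> "ContractionSchedule":
        frac = self.fractions.copy()
        frac[:, cell_index] = 0.0
        return ContractionSchedule(frac, mode=self.mode + "+passive", rng_seed=self.rng_seed)


def follower_contraction(
    leader_series: np.ndarray,
    alpha: float,
    mu: float = 1.0,
    sigma: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Follower contraction: (1 - alpha) * N(mu, sigma) + alpha * leader(t-1).

    The first step is drawn independently from N(mu, sigma).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if not hasattr(rng, "normal"):
        rng = np.random.default_rng(rng)
    leader = np.asarray(leader_series, dtype=float)
    draws = rng.normal(mu, sigma, size=leader.shape[0])
    out = np.empty_like(leader)
    out[0] = draws[0]
    out[1:] = (1.0 - alpha) * draws[1:] + alpha * leader[:-1]
    return out


def follower_contraction_beta(
    leader_series: np.ndarray,
    beta: float,
    mu: float = 1.0,
    sigma: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Follower as an amplified one-step-lagged copy: beta * leader(t-1), beta >= 1."""
    if beta < 1.0:
        raise ValueError("beta must be >= 1")
    if not hasattr(rng, "normal"):
        rng = np.random.default_rng(rng)
    leader = np.asarray(leader_series, dtype=float)
    out = np.empty_like(leader)
    out[0] = rng.normal(mu, sigma)
    out[1:] = beta * leader[:-1]
    return out


@dataclass
class SimulationTrajectory:
    """Node positions and applied contraction per step of a simulation."""

    geometry: NetworkGeometry
    positions: np.ndarray  # (n_steps + 1, N, 2); step 0 == input geometry
    applied: np.ndarray  # (n_steps, n_cells) percent of initial radius
    params: ConstitutiveParams = field(default_factory=ConstitutiveParams)

    @property
    def n_steps(self) -> int:
        return int(self.applied.shape[0])

    def cumulative_contraction(self, step: int) -> np.ndarray:
        """Cumulative contraction percent per cell after `step` steps."""
        if step == 0:
            return np.zeros(self.applied.shape[1])
        return self.applied[:step].sum(axis=0)

    def cell_radius(self, step: int, cell: int) -> float:
        r0 = self.geometry.cell_voids[cell].radius
        return float(r0 * (1.0 - self.cumulative_contraction(step)[cell] / 100.0))

    def cell_radius_trend(self, step: int, cell: int) -> float:
        """Cell radius along the linearized contraction trend.

        Interpolates the cell's total applied contraction uniformly over the
        steps, i.e. the boundary position stripped of step-to-step contraction
        noise.  Identical to :meth:`cell_radius` for noise-free schedules.
        """
        r0 = self.geometry.cell_voids[cell].radius
        if self.n_steps == 0:
            return float(r0)
        cum_t = self.cumulative_contraction(self.n_steps)[cell] * step / self.n_steps
        return float(r0 * (1.0 - cum_t / 100.0))

    def strains(self, step: int) -> np.ndarray:
        pos = self.positions[step]
        fib = self.geometry.fibers
        length = np.linalg.norm(pos[fib[:, 1]] - pos[fib[:, 0]], axis=1)
        return length / self.geometry.rest_lengths - 1.0


def run_contraction_simulation(
    geom: NetworkGeometry,
    schedule: ContractionSchedule,
    params: ConstitutiveParams | None = None,
    tol: float = 1e-8,
    passive_cells: tuple[int, ...] = (),
) -> SimulationTrajectory:
    """Run a stepwise contraction simulation.

    At every step each void's boundary nodes are displaced radially toward the
    void center by that step's fraction of the *initial* cell radius (along the
    node's original radial direction), the outer rim stays fixed, and the free
    nodes are re-equilibrated starting from the previous step's solution.
    Passive cells receive no imposed displacement; their boundary nodes move
    only under network forces.
    """
    if params is None:
        params = ConstitutiveParams()
    n_cells = len(geom.cell_voids)
    if schedule.n_cells != n_cells:
        raise ValueError(
            f"schedule covers {schedule.n_cells} cells but geometry has {n_cells} voids"
        )
    applied = schedule.fractions.copy()
    for c in passive_cells:
        applied[:, c] = 0.0

    # original radial geometry of each void's boundary nodes
    units, r0s, bsets = [], [], []
    for v, bset in zip(geom.cell_voids, geom.void_boundary_nodes):
        vec = geom.node_positions[bset] - v.center
        units.append(vec / np.linalg.norm(vec, axis=1, keepdims=True))
        r0s.append(v.radius)
        bsets.append(bset)

    positions = np.empty((schedule.n_steps + 1,) + geom.node_positions.shape)
    positions[0] = geom.node_positions
    cum = np.zeros(n_cells)
    prev = geom.node_positions
    lu_cache: list = [None]  # factorization reused across steps
    for t in range(schedule.n_steps):
        cum = cum + applied[t] / 100.0
        fixed_ids = [geom.rim_node_ids]
        fixed_pos = [geom.node_positions[geom.rim_node_ids]]
        for c in range(n_cells):
            if c in passive_cells:
                continue
            fixed_ids.append(bsets[c])
            fixed_pos.append(
                geom.node_positions[bsets[c]] - cum[c] * r0s[c] * units[c]
            )
        try:
            new = solve_equilibrium(
                geom,
                params=params,
                x0=prev,
                tol=tol,
                fixed_ids=np.concatenate(fixed_ids),
                fixed_positions=np.concatenate(fixed_pos, axis=0),
                lu_cache=lu_cache,
            )
        except SolverError as err:
            raise SolverError(err.residual, tol, step=t + 1) from err
        positions[t + 1] = new
        prev = new
    return SimulationTrajectory(
        geometry=geom, positions=positions, applied=applied, params=params
    )
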