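"""3D lattice infotaxis in a laminar-plume wind tunnel.

The agent moves on a rectangular lattice spanning the flyable volume,
maintaining a discrete belief over candidate source locations.  Its
internal plume model is turbulent (hit-rate likelihood with effective
diffusivity D), while the "true" plume generating observations is the
laminar Gaussian plume: a hit occurs deterministically whenever the
agent's cell concentration is at or above the detection threshold.
Moves greedily maximize the expected decrease in belief Shannon
entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plumetrack.geometry import GaussianPlume, Trajectory, WindTunnelGeometry

# fixed tie-breaking preference for moves
MOVE_ORDER = ("stay", "-x", "+x", "-y", "+y", "-z", "+z")
_MOVE_DELTAS = {
    "stay": (0, 0, 0),
    "-x": (-1, 0, 0),
    "+x": (1, 0, 0),
    "-y": (0, -1, 0),
    "+y": (0, 1, 0),
    "-z": (0, 0, -1),
    "+z": (0, 0, 1),
}


@dataclass(frozen=True)
class InfotaxisPlumeModel:
    """Turbulent-plume internal model of the infotaxis agent."""

    D: float = 0.09  # turbulent diffusivity, m^2/s
    R_emit: float = 1000.0  # source emission rate, Hz
    V: float = 0.4  # wind speed, m/s (+x downwind)
    tau_p: float = np.inf  # odor particle lifetime, s
    a_det: float = 0.01  # detector size, m

    def __post_init__(self) -> None:
        if self.D <= 0 or self.R_emit <= 0 or self.a_det <= 0:
            raise ValueError("D, R_emit, a_det must be > 0")
        if self.V < 0:
            raise ValueError("V must be >= 0")

    @property
    def lam(self) -> float:
        """Plume length scale lambda; tends to 2D/V as tau_p -> inf."""
        if np.isinf(self.tau_p):
            if self.V == 0:
                raise ValueError("lambda undefined for V = 0 with infinite tau_p")
            return 2.0 * self.D / self.V
        return float(
            np.sqrt(self.D * self.tau_p / (1.0 + self.V**2 * self.tau_p / (4 * self.D)))
        )


def hit_rate(agent_position, source_position, model: InfotaxisPlumeModel):
    """Time-averaged hit rate (Hz) at the agent for a candidate source.

    ``rate = (R a / |dr|) * exp(V dx / (2D) - |dr| / lambda)`` with
    ``dr = agent - source`` and ``dx`` its downwind (+x) component.
    Vectorized over either argument.
    """
    a = np.asarray(agent_position, dtype=float)
    s = np.asarray(source_position, dtype=float)
    dr = a - s
    dist = np.linalg.norm(dr, axis=-1)
    dx = dr[..., 0]
    with np.errstate(divide="ignore", over="ignore"):
        rate = (model.R_emit * model.a_det / dist) * np.exp(
            model.V * dx / (2 * model.D) - dist / model.lam
        )
    return rate


@dataclass(frozen=True)
class Lattice:
    """Regular lattice of points spanning the flyable volume."""

    shape: tuple[int, int, int]
    spacing: float
    origin: np.ndarray  # position of point (0, 0, 0)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def flat_index(self, ijk) -> int:
        i, j, k = ijk
        nx, ny, nz = self.shape
        return (i * ny + j) * nz + k

    def unflatten(self, flat: int) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        i, rem = divmod(flat, ny * nz)
        j, k = divmod(rem, nz)
        return i, j, k

    def position(self, flat: int) -> np.ndarray:
        return self.origin + np.array(self.unflatten(flat)) * self.spacing

    def nearest(self, position) -> int:
        ijk = np.round((np.asarray(position) - self.origin) / self.spacing).astype(int)
        ijk = np.clip(ijk, 0, np.array(self.shape) - 1)
        return self.flat_index(ijk)


def build_lattice(env: WindTunnelGeometry, spacing: float = 0.02) -> Lattice:
    """Lattice points at ``spacing``, centred within the flyable volume."""
    lo, hi = env.lower, env.upper
    ext = hi - lo
    shape = tuple(int(np.floor(e / spacing + 1e-9)) + 1 for e in ext)
    span = (np.array(shape) - 1) * spacing
    origin = lo + (ext - span) / 2
    return Lattice(shape=shape, spacing=spacing, origin=origin)


@dataclass
class InfotaxisBelief:
    """Normalized probability field over lattice source locations."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("probabilities must be >= 0")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"belief mass {total} != 1")

    @property
    def entropy(self) -> float:
        """Shannon entropy in nats; 0 iff a point mass."""
        p = self.p[self.p > 0]
        return float(-(p * np.log(p)).sum())


def uniform_belief(lattice: Lattice) -> InfotaxisBelief:
    n = lattice.n_cells
    return InfotaxisBelief(p=np.full(n, 1.0 / n))


class DegenerateBeliefError(RuntimeError):
    """Posterior mass vanished (observation impossible under the belief)."""


def hit_probability_row(
    lattice: Lattice,
    agent_cell: int,
    model: InfotaxisPlumeModel,
    dt_step: float,
    _centers: np.ndarray | None = None,
) -> np.ndarray:
    """Per-step hit probability at ``agent_cell`` for every candidate
    source cell: ``p = 1 - exp(-rate * dt)``; the agent's own cell is
    set to 0 (handled by the "found" branch)."""
    centers = lattice.centers() if _centers is None else _centers
    rate = hit_rate(centers[agent_cell], centers, model)
    rate[agent_cell] = 0.0
    rate = np.minimum(rate, 1e12)
    return -np.expm1(-rate * dt_step)


def belief_update(
    belief: InfotaxisBelief,
    agent_cell: int,
    observation: str,
    p_hit_row: np.ndarray,
) -> InfotaxisBelief:
    """Bayes update for one observation at the agent's cell.

    "hit" multiplies each cell's mass by its per-step hit probability,
    "miss" by the complement; in both cases the agent's own cell is
    zeroed (were the source there, it would have been found).  "found"
    collapses the belief onto the agent's cell.
    """
    p = belief.p.copy()
    if observation == "found":
        p[:] = 0.0
        p[agent_cell] = 1.0
        return InfotaxisBelief(p=p)
    if p[agent_cell] >= 1.0 - 1e-12:
        return InfotaxisBelief(p=p)  # degenerate point mass: unchanged
    if observation == "hit":
        p *= p_hit_row
    elif observation == "miss":
        p *= 1.0 - p_hit_row
    else:
        raise ValueError(f"unknown observation {observation!r}")
    p[agent_cell] = 0.0
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateBeliefError("all-zero posterior after observation")
    return InfotaxisBelief(p=p / total)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def choose_move(
    belief: InfotaxisBelief,
    agent_cell: int,
    model: InfotaxisPlumeModel,
    lattice: Lattice,
    dt_step: float,
    row_cache: dict | None = None,
    _centers: np.ndarray | None = None,
) -> tuple[str, float]:
    """Greedy move minimizing expected posterior entropy.

    For candidate cell j:
    ``E[S'] = (1 - p_found) * (p_hit * S_hit + (1 - p_hit) * S_miss)``
    with ``p_found = belief.p[j]`` and ``p_hit`` marginalized over the
    belief conditioned on not-found.  Exact ties in expected entropy
    prefer the higher ``p_found`` (so a point mass at a neighbour is
    walked into rather than orbited), then the fixed order
    stay, -x, +x, -y, +y, -z, +z.  Returns (move, expected entropy).
    """
    centers = lattice.centers() if _centers is None else _centers
    ijk = np.array(lattice.unflatten(agent_cell))
    best_move, best_val, best_pf = None, np.inf, -1.0
    for move in MOVE_ORDER:
        nijk = ijk + _MOVE_DELTAS[move]
        if np.any(nijk < 0) or np.any(nijk >= lattice.shape):
            continue
        j = lattice.flat_index(nijk)
        p_found = belief.p[j]
        if p_found >= 1.0 - 1e-12:
            val = 0.0
        else:
            if row_cache is not None and j in row_cache:
                row = row_cache[j]
            else:
                row = hit_probability_row(lattice, j, model, dt_step, _centers=centers)
                if row_cache is not None:
                    row_cache[j] = row
            bc = belief.p.copy()
            bc[j] = 0.0
            bc /= bc.sum()
            p_hit = float(bc @ row)
            post_hit = bc * row
            post_miss = bc * (1.0 - row)
            s_hit = _entropy(post_hit / p_hit) if p_hit > 0 else 0.0
            pm = post_miss.sum()
            s_miss = _entropy(post_miss / pm) if pm > 0 else 0.0
            val = (1.0 - p_found) * (p_hit * s_hit + (1.0 - p_hit) * s_miss)
        if val < best_val - 1e-15 or (
            abs(val - best_val) <= 1e-15 and p_found > best_pf + 1e-15
        ):
            best_move, best_val, best_pf = move, val, p_found
    return best_move, float(best_val)


@dataclass
class InfotaxisRunInfo:
    hits: np.ndarray  # bool per step
    entropy_trace: np.ndarray  # belief entropy after each update
    found: bool
    n_steps_run: int


def run_infotaxis(
    start_cell: int,
    n_steps: int,
    model: InfotaxisPlumeModel,
    plume: GaussianPlume,
    env: WindTunnelGeometry,
    rng: np.random.Generator | None = None,
    lattice: Lattice | None = None,
    lattice_spacing: float = 0.02,
    dt_step: float | None = None,
    found_threshold: float = 0.95,
    row_cache: dict | None = None,
    traj_id: str = "infotaxis_0",
    prior: InfotaxisBelief | None = None,
) -> tuple[Trajectory, InfotaxisRunInfo]:
    """One infotaxis run emitting a standard trajectory.

    Each step: observe (deterministic hit iff the agent's cell is
    inside the discretized laminar plume), Bayes-update the belief,
    then move greedily.  Terminates early when the posterior mass at
    the agent's cell exceeds ``found_threshold``.  The emitted
    trajectory holds lattice positions at ``dt_step`` spacing,
    finite-difference velocities (zero-displacement steps carry the
    previous velocity so heading is preserved), and true-plume
    concentrations, so crossing extraction applies unchanged.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    lattice = lattice or build_lattice(env, lattice_spacing)
    if dt_step is None:
        dt_step = lattice.spacing / 0.4  # one cell per step at 0.4 m/s
    centers = lattice.centers()
    yc, zc = plume.centerline
    sig = plume.sigma(centers[:, 0])
    conc_cells = plume.c_max * np.exp(
        -((centers[:, 1] - yc) ** 2 + (centers[:, 2] - zc) ** 2) / (2 * sig**2)
    )
    in_plume = conc_cells >= plume.detection_threshold

    belief = prior or uniform_belief(lattice)
    if row_cache is None:
        row_cache = {}
    cell = int(start_cell)
    cells = [cell]
    hits = []
    entropy_trace = []
    found = False
    for step in range(n_steps):
        hit = bool(in_plume[cell])
        if belief.p[cell] > found_threshold:
            found = True
            entropy_trace.append(belief.entropy)
            hits.append(hit)
            break
        if cell in row_cache:
            row = row_cache[cell]
        else:
            row = hit_probability_row(lattice, cell, model, dt_step, _centers=centers)
            row_cache[cell] = row
        belief = belief_update(belief, cell, "hit" if hit else "miss", row)
        hits.append(hit)
        entropy_trace.append(belief.entropy)
        move, _ = choose_move(
            belief, cell, model, lattice, dt_step, row_cache, _centers=centers
        )
        ijk = np.array(lattice.unflatten(cell)) + _MOVE_DELTAS[move]
        cell = lattice.flat_index(ijk)
        cells.append(cell)

    pos = centers[np.array(cells)]
    n = len(pos)
    if n < 2:  # found immediately; pad one stay step for a valid trajectory
        pos = np.vstack([pos, pos])
        n = 2
    vel = np.zeros_like(pos)
    vel[1:] = np.diff(pos, axis=0) / dt_step
    # carry heading over zero-displacement (stay) steps
    for i in range(1, n):
        if np.allclose(vel[i], 0):
            vel[i] = vel[i - 1]
    vel[0] = vel[1]
    conc = plume.c_max * np.exp(
        -((pos[:, 1] - yc) ** 2 + (pos[:, 2] - zc) ** 2)
        / (2 * plume.sigma(pos[:, 0]) ** 2)
    )
    traj = Trajectory(
        id=traj_id, dt=dt_step, positions=pos, velocities=vel, concentrations=conc
    )
    info = InfotaxisRunInfo(
        hits=np.array(hits, bool),
        entropy_trace=np.array(entropy_trace),
        found=found,
        n_steps_run=len(hits),
    )
    return traj, info


def run_infotaxis_batch(
    n_runs: int,
    model: InfotaxisPlumeModel,
    plume: GaussianPlume,
    env: WindTunnelGeometry,
    seed: int = 0,
    lattice_spacing: float = 0.02,
    steps_range: tuple[int, int] = (100, 400),
    dt_step: float | None = None,
    found_threshold: float = 0.95,
) -> tuple[list[Trajectory], list[InfotaxisRunInfo]]:
    """Batch of runs with random start cells (downwind half) and
    log-uniform run lengths; the hit-probability row cache is shared."""
    rng = np.random.default_rng(seed)
    lattice = build_lattice(env, lattice_spacing)
    nx, ny, nz = lattice.shape
    row_cache: dict = {}
    trajs, infos = [], []
    for r in range(n_runs):
        ijk = (
            rng.integers(nx // 2, nx),
            rng.integers(0, ny),
            rng.integers(0, nz),
        )
        n_steps = int(
            np.exp(rng.uniform(np.log(steps_range[0]), np.log(steps_range[1])))
        )
        traj, info = run_infotaxis(
            lattice.flat_index(ijk),
            n_steps,
            model,
            plume,
            env,
            lattice=lattice,
            dt_step=dt_step,
            found_threshold=found_threshold,
            row_cache=row_cache,
            traj_id=f"infotaxis_{r:05d}",
        )
        trajs.append(traj)
        infos.append(info)
    return trajs, infos
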