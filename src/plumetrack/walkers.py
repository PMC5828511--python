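"""Correlated-random-walk flight simulators.

The base walker integrates ``tau * dv/dt = -v + eta*xi + b*w_c`` with
Euler steps, where ``xi`` is a standard-normal 3-vector drawn fresh at
each timestep and ``w_c`` is a unit vector in the crosswind (y, z)
plane pointing toward the tunnel centerline.  Two augmentations add an
upwind drive term:

- surge-cast: a transient alpha-function force triggered at each plume
  crossing's concentration peak;
- centerline-inferring: a continuous drive ``k = kstar / |K|`` that
  grows as the determinant of a Gaussian centerline belief shrinks,
  with ``w_c`` redirected toward the belief's MAP estimate.

All simulators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from plumetrack.geometry import GaussianPlume, Trajectory, WindTunnelGeometry

_N_RING = 12  # surge triggers remembered per walker; 12*tau_s >> kernel support


@dataclass(frozen=True)
class WalkerParams:
    """Base correlated-random-walk parameters."""

    tau: float = 0.42  # turning timescale, s
    eta: float = 1.9  # noise scale, m/s
    bias: float = 0.25  # crosswind centerline bias, m/s
    dt: float = 0.01  # integration step, s

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.eta < 0 or self.bias < 0:
            raise ValueError("require tau > 0, eta >= 0, bias >= 0")
        if not 0 < self.dt < self.tau:
            raise ValueError("require 0 < dt < tau")


@dataclass(frozen=True)
class SurgeParams:
    """Alpha-function upwind surge: peak ``amplitude`` at lag ``timescale``."""

    amplitude: float = 0.8  # m/s
    timescale: float = 0.07  # s

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.timescale <= 0:
            raise ValueError("require amplitude >= 0, timescale > 0")


def alpha_kernel(s: np.ndarray) -> np.ndarray:
    """Unit-peak alpha function ``u(s) = s * exp(1 - s)`` for s >= 0."""
    s = np.asarray(s, dtype=float)
    ok = (s > 0) & (s < 60.0)
    return np.where(ok, np.where(ok, s, 1.0) * np.exp(1.0 - np.where(ok, s, 1.0)), 0.0)


def surge_force(t: float, trigger_times: np.ndarray, trigger_amps: np.ndarray,
                timescale: float) -> np.ndarray:
    """Superposed alpha-function force at time ``t``.

    ``trigger_times`` and ``trigger_amps`` have shape (..., K); entries
    with time > t (or far in the past) contribute zero.
    """
    s = (t - trigger_times) / timescale
    return np.sum(trigger_amps * alpha_kernel(s), axis=-1)


@dataclass
class CenterlineBelief:
    """Diagonal 2D Gaussian belief over the plume centerline (y*, z*).

    The MAP estimate of a Gaussian is its mean.  With no updates the
    belief relaxes back to (mean 0, prior covariance) with timescale
    ``tau_m``.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    var: np.ndarray = field(default_factory=lambda: np.full(2, 25.0))  # (5 m)^2
    prior_var: np.ndarray = field(default_factory=lambda: np.full(2, 25.0))
    obs_var: np.ndarray = field(default_factory=lambda: np.full(2, 4.0))  # (2 m)^2
    tau_m: float = 10.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).copy()
        self.var = np.asarray(self.var, dtype=float).copy()
        self.prior_var = np.asarray(self.prior_var, dtype=float)
        self.obs_var = np.asarray(self.obs_var, dtype=float)
        if np.any(self.var <= 0) or np.any(self.prior_var <= 0) or np.any(
            self.obs_var <= 0
        ):
            raise ValueError("covariances must be positive definite")

    @property
    def det(self) -> float:
        """Determinant |K| of the belief covariance, m^4."""
        return float(self.var[0] * self.var[1])


def update_centerline_belief(
    belief: CenterlineBelief, observation, elapsed: float
) -> CenterlineBelief:
    """Memory decay over ``elapsed`` seconds, then conjugate Gaussian update.

    Decay relaxes the mean exponentially toward (0, 0) and the
    covariance toward the prior with timescale ``tau_m``; the update is
    the standard product of Gaussians:
    ``K_post = (K^-1 + K_s^-1)^-1``,
    ``mean_post = K_post (K^-1 mean + K_s^-1 obs)``.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    obs = np.asarray(observation, dtype=float)
    decay = np.exp(-elapsed / belief.tau_m)
    mean = belief.mean * decay
    var = belief.prior_var + (belief.var - belief.prior_var) * decay
    post_var = 1.0 / (1.0 / var + 1.0 / belief.obs_var)
    post_mean = post_var * (mean / var + obs / belief.obs_var)
    if np.any(post_var <= 0) or not np.all(np.isfinite(post_var)):
        raise FloatingPointError("belief covariance became non-positive-definite")
    return CenterlineBelief(
        mean=post_mean,
        var=post_var,
        prior_var=belief.prior_var,
        obs_var=belief.obs_var,
        tau_m=belief.tau_m,
    )


def decay_centerline_belief(belief: CenterlineBelief, elapsed: float) -> CenterlineBelief:
    """Memory decay only (no observation)."""
    decay = np.exp(-elapsed / belief.tau_m)
    return CenterlineBelief(
        mean=belief.mean * decay,
        var=belief.prior_var + (belief.var - belief.prior_var) * decay,
        prior_var=belief.prior_var,
        obs_var=belief.obs_var,
        tau_m=belief.tau_m,
    )


@dataclass
class WalkerState:
    """Instantaneous state of a single walker."""

    position: np.ndarray
    velocity: np.ndarray


def step_base_walker(
    state: WalkerState,
    params: WalkerParams,
    rng: np.random.Generator,
    env: WindTunnelGeometry | None = None,
    upwind_force: float = 0.0,
    centerline_target: np.ndarray | None = None,
) -> WalkerState:
    """One Euler step of the base walker (single agent).

    ``upwind_force`` adds ``a * w_u`` inside the drift; a non-None
    ``centerline_target`` (y, z) redirects the crosswind bias there.
    """
    pos = np.asarray(state.position, dtype=float)
    vel = np.asarray(state.velocity, dtype=float)
    target = np.zeros(2) if centerline_target is None else np.asarray(centerline_target)
    wc = np.zeros(3)
    d = target - pos[1:]
    norm = np.linalg.norm(d)
    if norm > 0:
        wc[1:] = d / norm
    xi = rng.standard_normal(3)
    drift = -vel + params.eta * xi + params.bias * wc
    drift[0] -= upwind_force  # upwind = -x
    vel = vel + (params.dt / params.tau) * drift
    pos = pos + params.dt * vel
    if env is not None:
        pos, vel = _reflect_single(pos, vel, env)
    return WalkerState(position=pos, velocity=vel)


def _reflect_single(pos, vel, env):
    lo, hi = env.lower, env.upper
    pos = pos.copy()
    vel = vel.copy()
    for _ in range(4):
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            break
        pos = np.where(below, 2 * lo - pos, pos)
        pos = np.where(above, 2 * hi - pos, pos)
        vel = np.where(below | above, -vel, vel)
    return np.clip(pos, lo, hi), vel


def _reflect_batch(pos, vel, lo, hi):
    for _ in range(4):
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            break
        np.copyto(pos, np.where(below, 2 * lo - pos, pos))
        np.copyto(pos, np.where(above, 2 * hi - pos, pos))
        np.copyto(vel, np.where(below | above, -vel, vel))
    np.copyto(pos, np.clip(pos, lo, hi))


def simulate_batch(
    params: WalkerParams,
    env: WindTunnelGeometry,
    plume: GaussianPlume | None,
    n_steps: np.ndarray,
    start_positions: np.ndarray,
    rng: np.random.Generator,
    mode: str = "base",
    surge: SurgeParams | None = None,
    amp_fn=None,
    belief_template: CenterlineBelief | None = None,
    kstar: float = 0.0,
    k_max: float = 3.0,
    crossing_threshold: float | None = None,
    id_prefix: str = "sim",
) -> list[Trajectory]:
    """Simulate a batch of walkers in lockstep (vectorized over agents).

    Parameters
    ----------
    mode
        "base", "surge" (alpha-function upwind surges at online-detected
        crossing peaks) or "centerline" (belief-scaled upwind drive).
    amp_fn
        Optional vectorized callable ``(c_peak, crossing_number) ->
        amplitude`` overriding the constant surge amplitude; used by the
        synthetic-data generator to inject known effects.
    crossing_threshold
        Concentration threshold for online peak detection; defaults to
        the plume's detection threshold.

    Crossing peaks are detected online: within an above-threshold
    excursion, the first sample at which concentration starts to fall
    is taken as the peak and triggers the model's odor response.
    """
    if mode not in {"base", "surge", "centerline"}:
        raise ValueError(f"unknown mode {mode!r}")
    n_steps = np.asarray(n_steps, dtype=int)
    n = len(n_steps)
    if np.any(n_steps < 1):
        raise ValueError("each trajectory needs >= 1 step")
    start = np.array(start_positions, dtype=float).reshape(n, 3)
    dt = params.dt
    max_steps = int(n_steps.max())
    lo, hi = env.lower, env.upper

    pos = start.copy()
    # start from (approximately) the stationary velocity distribution of
    # the discretized walker so early samples are not atypical
    v_std = params.eta * np.sqrt(dt / (2 * params.tau - dt))
    vel = v_std * rng.standard_normal((n, 3))
    vel[np.linalg.norm(vel, axis=1) < 1e-9] += 1e-6  # avoid zero-speed start

    pos_out = np.empty((max_steps + 1, n, 3))
    vel_out = np.empty((max_steps + 1, n, 3))
    pos_out[0] = pos
    vel_out[0] = vel

    th = None
    if plume is not None:
        th = crossing_threshold if crossing_threshold is not None else plume.detection_threshold
        yc, zc = plume.centerline
    conc_prev = _conc(pos, plume) if plume is not None else np.zeros(n)
    conc_out = np.empty((max_steps + 1, n))
    conc_out[0] = conc_prev

    in_exc = (conc_prev >= th) if th is not None else np.zeros(n, bool)
    triggered = np.zeros(n, bool)
    n_cross = np.zeros(n, int)

    trig_t = np.full((n, _N_RING), -1e12)
    trig_a = np.zeros((n, _N_RING))
    trig_ptr = np.zeros(n, int)

    if mode == "centerline":
        tmpl = belief_template or CenterlineBelief()
        bel_mean = np.tile(tmpl.mean, (n, 1))
        bel_var = np.tile(tmpl.var, (n, 1))
        prior_var = np.asarray(tmpl.prior_var, float)
        obs_var = np.asarray(tmpl.obs_var, float)
        decay = np.exp(-dt / tmpl.tau_m)

    surge_p = surge or SurgeParams()
    wu_sign = -1.0  # upwind = -x

    for step in range(max_steps):
        active = step < n_steps
        t_now = step * dt

        # crosswind bias target: tunnel centerline or belief MAP
        if mode == "centerline":
            target = bel_mean
        else:
            target = np.zeros((n, 2))
        d = target - pos[:, 1:]
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        wc = np.zeros((n, 3))
        nz = norm[:, 0] > 0
        wc[nz, 1:] = d[nz] / norm[nz]

        a_up = np.zeros(n)
        if mode == "surge":
            a_up = surge_force(t_now, trig_t, trig_a, surge_p.timescale)
        elif mode == "centerline":
            k = kstar / (bel_var[:, 0] * bel_var[:, 1])
            a_up = np.minimum(k, k_max)

        xi = rng.standard_normal((n, 3))
        drift = -vel + params.eta * xi + params.bias * wc
        drift[:, 0] += wu_sign * a_up
        vel = np.where(active[:, None], vel + (dt / params.tau) * drift, vel)
        pos = np.where(active[:, None], pos + dt * vel, pos)
        _reflect_batch(pos, vel, lo, hi)

        if mode == "centerline":
            bel_mean *= decay
            bel_var = prior_var + (bel_var - prior_var) * decay

        if plume is not None:
            conc = _conc(pos, plume)
            above = conc >= th
            entering = above & ~in_exc
            in_exc |= entering
            triggered &= ~entering  # new excursion resets the trigger latch
            falling = in_exc & ~triggered & (conc < conc_prev) & active
            if falling.any():
                idx = np.nonzero(falling)[0]
                c_peak = conc_prev[idx]
                n_cross[idx] += 1
                triggered[idx] = True
                if mode == "surge":
                    if amp_fn is None:
                        amps = np.full(len(idx), surge_p.amplitude)
                    else:
                        amps = np.asarray(amp_fn(c_peak, n_cross[idx]), float)
                    trig_t[idx, trig_ptr[idx]] = t_now  # peak was one step ago; force onset now
                    trig_a[idx, trig_ptr[idx]] = amps
                    trig_ptr[idx] = (trig_ptr[idx] + 1) % _N_RING
                elif mode == "centerline":
                    obs = pos[idx, 1:]
                    post_var = 1.0 / (1.0 / bel_var[idx] + 1.0 / obs_var)
                    bel_mean[idx] = post_var * (
                        bel_mean[idx] / bel_var[idx] + obs / obs_var
                    )
                    bel_var[idx] = post_var
            in_exc &= above
            triggered &= above
            conc_prev = conc
        else:
            conc = np.zeros(n)

        pos_out[step + 1] = pos
        vel_out[step + 1] = vel
        conc_out[step + 1] = conc

    trajs = []
    for i in range(n):
        m = n_steps[i] + 1
        trajs.append(
            Trajectory(
                id=f"{id_prefix}_{i:05d}",
                dt=dt,
                positions=pos_out[:m, i],
                velocities=vel_out[:m, i],
                concentrations=conc_out[:m, i],
            )
        )
    return trajs


def _conc(pos, plume):
    yc, zc = plume.centerline
    sig = plume.sigma(pos[:, 0])
    r2 = (pos[:, 1] - yc) ** 2 + (pos[:, 2] - zc) ** 2
    return plume.c_max * np.exp(-r2 / (2.0 * sig**2))


def simulate_base(
    params: WalkerParams,
    env: WindTunnelGeometry,
    duration: float,
    rng: np.random.Generator,
    start_position=None,
) -> Trajectory:
    """Single base-walker trajectory (no plume interaction)."""
    start = _default_start(env, rng) if start_position is None else start_position
    return simulate_batch(
        params, env, None, [int(round(duration / params.dt))], [start], rng,
        mode="base", id_prefix="base",
    )[0]


def simulate_surge_cast(
    params: WalkerParams,
    surge: SurgeParams,
    plume: GaussianPlume,
    env: WindTunnelGeometry,
    duration: float,
    rng: np.random.Generator,
    start_position=None,
) -> Trajectory:
    """Single surge-cast trajectory."""
    start = _default_start(env, rng) if start_position is None else start_position
    return simulate_batch(
        params, env, plume, [int(round(duration / params.dt))], [start], rng,
        mode="surge", surge=surge, id_prefix="surgecast",
    )[0]


def simulate_centerline_inferring(
    params: WalkerParams,
    belief: CenterlineBelief,
    kstar: float,
    plume: GaussianPlume,
    env: WindTunnelGeometry,
    duration: float,
    rng: np.random.Generator,
    start_position=None,
    k_max: float = 3.0,
) -> Trajectory:
    """Single centerline-inferring trajectory."""
    if kstar <= 0:
        raise ValueError("kstar must be > 0")
    start = _default_start(env, rng) if start_position is None else start_position
    return simulate_batch(
        params, env, plume, [int(round(duration / params.dt))], [start], rng,
        mode="centerline", belief_template=belief, kstar=kstar, k_max=k_max,
        id_prefix="centerline",
    )[0]


def _default_start(env: WindTunnelGeometry, rng: np.random.Generator) -> np.ndarray:
    """Uniform start in the downwind half of the tunnel."""
    lo, hi = env.lower, env.upper
    x = rng.uniform((lo[0] + hi[0]) / 2, hi[0])
    y = rng.uniform(lo[1] * 0.8, hi[1] * 0.8)
    z = rng.uniform(lo[2] * 0.8, hi[2] * 0.8)
    return np.array([x, y, z])


def draw_batch_geometry(
    n_traj: int,
    env: WindTunnelGeometry,
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (2.0, 20.0),
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-uniform durations (as step counts) and downwind-half starts."""
    lo_d, hi_d = duration_range
    durations = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), n_traj))
    n_steps = np.maximum(1, np.round(durations / dt).astype(int))
    starts = np.stack([_default_start(env, rng) for _ in range(n_traj)])
    return n_steps, starts


# ---------------------------------------------------------------------------
# distribution-matching fit of the base walker
# ---------------------------------------------------------------------------

def _kinematic_histograms(trajs, edges=None):
    """Normalized histograms of speed, angular speed, and crosswind position."""
    speeds, angs, ys = [], [], []
    for tr in trajs:
        v = tr.velocities
        sp = np.linalg.norm(v, axis=1)
        speeds.append(sp)
        v0, v1 = v[:-1], v[1:]
        s0, s1 = sp[:-1], sp[1:]
        ok = (s0 > 0) & (s1 > 0)
        cosang = np.clip(np.sum(v0 * v1, axis=1)[ok] / (s0[ok] * s1[ok]), -1, 1)
        angs.append(np.arccos(cosang) / tr.dt)  # rad/s
        ys.append(tr.positions[:, 1])
    speeds = np.concatenate(speeds)
    angs = np.concatenate(angs)
    ys = np.concatenate(ys)
    if edges is None:
        edges = (
            np.linspace(0, np.percentile(speeds, 99.5), 31),
            np.linspace(0, np.percentile(angs, 99.5), 31),
            np.linspace(ys.min() - 1e-6, ys.max() + 1e-6, 31),
        )
    hists = []
    for data, e in zip((speeds, angs, ys), edges):
        h, _ = np.histogram(data, bins=e)
        hists.append(h / max(h.sum(), 1))
    return hists, edges


class FitConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message: str, best_params: "WalkerParams"):
        super().__init__(message)
        self.best_params = best_params


def fit_base_walker(
    reference_trajs,
    env: WindTunnelGeometry,
    dt: float = 0.01,
    n_sim: int = 60,
    sim_duration: float = 6.0,
    seed: int = 0,
    bounds=((0.05, 2.0), (0.0, 8.0), (0.0, 2.0)),
    maxiter: int = 120,
) -> WalkerParams:
    """Fit (tau, eta, b) by matching kinematic distributions.

    Minimizes the summed L2 distance between normalized histograms of
    speed, angular speed and crosswind position of simulated vs.
    reference trajectories (common reference-derived bin edges), using
    Nelder-Mead from the best point of a coarse grid.  Simulation noise
    is held fixed across evaluations (common random numbers).
    """
    if len(reference_trajs) < 10:
        raise ValueError("need >= 10 reference trajectories")
    ref_hists, edges = _kinematic_histograms(reference_trajs)
    n_steps = np.full(n_sim, int(round(sim_duration / dt)))
    rng0 = np.random.default_rng(seed)
    starts = np.stack([_default_start(env, rng0) for _ in range(n_sim)])

    def objective(theta):
        tau, eta, b = theta
        for val, (lo, hi) in zip(theta, bounds):
            if not lo <= val <= hi:
                return 1e6 + abs(val)
        if tau <= dt:
            return 1e6
        params = WalkerParams(tau=tau, eta=eta, bias=b, dt=dt)
        sim = simulate_batch(
            params, env, None, n_steps, starts,
            np.random.default_rng(seed + 1), mode="base",
        )
        sim_hists, _ = _kinematic_histograms(sim, edges)
        return sum(
            float(np.linalg.norm(a - b_)) for a, b_ in zip(sim_hists, ref_hists)
        )

    # coarse grid start
    grid = [
        (tau, eta, b)
        for tau in (0.2, 0.42, 0.8)
        for eta in (0.5, 1.9, 4.0)
        for b in (0.05, 0.25, 0.8)
    ]
    best = min(grid, key=objective)
    res = minimize(
        objective, best, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4},
    )
    tau, eta, b = res.x
    eta = max(eta, bounds[1][0])
    b = max(b, bounds[2][0])
    fitted = WalkerParams(tau=float(tau), eta=float(eta), bias=float(b), dt=dt)
    if not res.success and res.status not in (1, 2):  # 1/2 = iter limits
        raise FitConvergenceError(f"Nelder-Mead did not converge: {res.message}", fitted)
    return fitted


def calibrate_upwind_gain(
    params: WalkerParams,
    surge: SurgeParams,
    plume: GaussianPlume,
    env: WindTunnelGeometry,
    candidates=(0.3, 1.0, 3.0, 10.0, 30.0),
    n_traj: int = 40,
    seed: int = 0,
    belief: CenterlineBelief | None = None,
) -> float:
    """Choose kstar so the centerline model's mean crossing-triggered
    upwind turn roughly matches the surge-cast model's.

    Runs small batches of both models, measures the mean drop in
    heading over 0-0.5 s after each crossing peak, and returns the
    candidate kstar minimizing the mismatch.
    """
    from plumetrack.crossings import extract_crossings

    def mean_dip(trajs):
        dips = []
        for tr in trajs:
            for seg in extract_crossings(tr, plume.detection_threshold):
                h = seg.heading_series
                m = seg.valid_mask
                upto = m & (seg.time_grid <= 0.5)
                if upto.sum() > 2 and np.isfinite(seg.h0):
                    dips.append(np.nanmean(h[upto]) - seg.h0)
        return np.nan if not dips else float(np.mean(dips))

    rng = np.random.default_rng(seed)
    n_steps, starts = draw_batch_geometry(n_traj, env, rng, dt=params.dt)
    sc = simulate_batch(
        params, env, plume, n_steps, starts, np.random.default_rng(seed + 1),
        mode="surge", surge=surge,
    )
    target = mean_dip(sc)
    best_k, best_err = candidates[0], np.inf
    for k in candidates:
        cl = simulate_batch(
            params, env, plume, n_steps, starts, np.random.default_rng(seed + 2),
            mode="centerline", belief_template=belief, kstar=k,
        )
        d = mean_dip(cl)
        err = abs(d - target) if np.isfinite(d) else np.inf
        if err < best_err:
            best_k, best_err = k, err
    return float(best_k)
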