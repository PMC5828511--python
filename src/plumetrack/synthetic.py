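"""Synthetic trajectory datasets with injectable, known effects.

Trajectories follow the base correlated random walk plus an upwind
surge at each online-detected crossing peak whose amplitude is

    A = (A0 + conc_gain * c_peak) * (history_factor if n >= 3 else 1)

(step variant), or ``A = (A0 + conc_gain * c_peak) * history_factor**(n-1)``
(smooth variant), so downstream analyses can be validated by
parameter/sign recovery against the injected truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from plumetrack.geometry import GaussianPlume, Trajectory, WindTunnelGeometry
from plumetrack.walkers import (
    SurgeParams,
    WalkerParams,
    draw_batch_geometry,
    simulate_batch,
)


@dataclass(frozen=True)
class SyntheticEffects:
    """Injected effect sizes and dataset shape for the generator."""

    base_surge_amp: float = 0.8  # A0, m/s
    conc_gain: float = 0.0  # g_c, (m/s) per concentration unit
    history_factor: float = 1.0  # rho in [0, 1]; < 1 attenuates crossings 3+
    history_mode: str = "step"  # "step" (attenuate n>=3) or "smooth" (rho**(n-1))
    heading_noise: float = 0.0  # degrees; random rotation of stored velocities
    n_traj: int = 100
    duration_range: tuple[float, float] = (2.0, 20.0)  # log-uniform, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_surge_amp < 0:
            raise ValueError("base_surge_amp must be >= 0")
        if not 0 <= self.history_factor <= 1:
            raise ValueError("history_factor must lie in [0, 1]")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.history_mode not in {"step", "smooth"}:
            raise ValueError("history_mode must be 'step' or 'smooth'")
        for v in (self.base_surge_amp, self.conc_gain, self.heading_noise):
            if not np.isfinite(v):
                raise ValueError("effect parameters must be finite")


def surge_amplitude(effects: SyntheticEffects, c_peak, crossing_number):
    """Vectorized injected surge amplitude for given crossing covariates."""
    c_peak = np.asarray(c_peak, dtype=float)
    n = np.asarray(crossing_number, dtype=int)
    base = effects.base_surge_amp + effects.conc_gain * c_peak
    if effects.history_mode == "step":
        factor = np.where(n >= 3, effects.history_factor, 1.0)
    else:
        factor = effects.history_factor ** (n - 1)
    return np.maximum(base, 0.0) * factor


def generate_dataset(
    effects: SyntheticEffects,
    env: WindTunnelGeometry,
    plume: GaussianPlume,
    walker_params: WalkerParams | None = None,
    surge_timescale: float = 0.07,
) -> list[Trajectory]:
    """Generate a reproducible synthetic trajectory dataset.

    Pure function of (parameters, seed): the same inputs give
    bit-identical output.
    """
    params = walker_params or WalkerParams()
    rng = np.random.default_rng(effects.seed)
    n_steps, starts = draw_batch_geometry(
        effects.n_traj, env, rng, effects.duration_range, params.dt
    )
    trajs = simulate_batch(
        params,
        env,
        plume,
        n_steps,
        starts,
        rng,
        mode="surge",
        surge=SurgeParams(amplitude=effects.base_surge_amp, timescale=surge_timescale),
        amp_fn=lambda c, n: surge_amplitude(effects, c, n),
        id_prefix="synth",
    )
    if effects.heading_noise > 0:
        for tr in trajs:
            tr.velocities = _rotate_velocities(
                tr.velocities, effects.heading_noise, rng
            )
    return trajs


def _rotate_velocities(v: np.ndarray, noise_deg: float, rng: np.random.Generator):
    """Rotate each velocity by a small random angle about a random axis
    perpendicular to it (observation noise on stored headings)."""
    n = len(v)
    angles = np.radians(rng.normal(0.0, noise_deg, n))
    # random unit axis perpendicular to each v
    raw = rng.standard_normal((n, 3))
    speed = np.linalg.norm(v, axis=1, keepdims=True)
    vhat = np.where(speed > 0, v / np.maximum(speed, 1e-300), 0.0)
    perp = raw - np.sum(raw * vhat, axis=1, keepdims=True) * vhat
    pn = np.linalg.norm(perp, axis=1, keepdims=True)
    axis = np.where(pn > 0, perp / np.maximum(pn, 1e-300), 0.0)
    # Rodrigues rotation of v about axis
    cosa = np.cos(angles)[:, None]
    sina = np.sin(angles)[:, None]
    cross = np.cross(axis, v)
    dot = np.sum(axis * v, axis=1, keepdims=True)
    return v * cosa + cross * sina + axis * dot * (1 - cosa)


def write_ground_truth(effects: SyntheticEffects, path) -> None:
    """YAML sidecar recording the injected effect sizes of a dataset."""
    with open(Path(path), "w") as f:
        yaml.safe_dump({"synthetic_effects": asdict(effects)}, f)


# ---------------------------------------------------------------------------
# toy concentration series (fixtures for crossing extraction)
# ---------------------------------------------------------------------------

def make_toy_concentration_series(
    n_samples: int,
    pulses,
    baseline: float = 0.0,
) -> np.ndarray:
    """Deterministic 1D series with known above-baseline excursions.

    ``pulses`` is a list of ``(center_index, half_width, amplitude)``;
    each pulse is triangular with its maximum ``baseline + amplitude``
    at the center index.  Overlapping pulses are rejected so peak
    indices stay unambiguous.
    """
    c = np.full(n_samples, float(baseline))
    spans = []
    for center, half_width, amp in pulses:
        lo, hi = center - half_width, center + half_width
        if lo < 0 or hi >= n_samples:
            raise ValueError("pulse extends beyond the series")
        for plo, phi in spans:
            if lo <= phi and plo <= hi:
                raise ValueError("overlapping pulses")
        spans.append((lo, hi))
        idx = np.arange(lo, hi + 1)
        c[idx] = np.maximum(
            c[idx], baseline + amp * (1 - np.abs(idx - center) / (half_width + 1))
        )
    return c
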