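"""Wind-tunnel geometry, plume model, trajectory data model, heading.

Coordinate convention: +x points downwind, x = 0 at the upwind wall of
the flyable section; y and z are centred on the tunnel midline, so the
flyable volume is ``[0, Lx] x [-Ly/2, Ly/2] x [-Lz/2, Lz/2]``.  The
upwind unit vector is ``(-1, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UPWIND = np.array([-1.0, 0.0, 0.0])

_POS_TOL = 1e-9


class OutOfDomainError(ValueError):
    """Raised when a position lies outside the flyable volume."""


class UndefinedHeadingError(ValueError):
    """Raised when heading is requested for a zero-length velocity."""


@dataclass(frozen=True)
class WindTunnelGeometry:
    """Flyable volume of the wind tunnel plus wind speed and margins.

    Parameters
    ----------
    flyable_extent
        Lengths (Lx, Ly, Lz) of the flyable section in meters.
    wind_speed
        Mean wind speed V in m/s (blowing toward +x).
    end_margin
        Width in meters of the upwind/downwind end zones used by the
        crossing exclusion rules.
    """

    flyable_extent: tuple[float, float, float] = (1.3, 0.3, 0.3)
    wind_speed: float = 0.4
    end_margin: float = 0.30

    def __post_init__(self) -> None:
        ext = np.asarray(self.flyable_extent, dtype=float)
        if ext.shape != (3,) or not np.all(ext > 0):
            raise ValueError("flyable_extent must be 3 positive lengths")
        if not 0 < self.end_margin < ext[0] / 2:
            raise ValueError("end_margin must lie in (0, Lx/2)")
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")
        object.__setattr__(self, "flyable_extent", tuple(float(v) for v in ext))

    @property
    def lower(self) -> np.ndarray:
        lx, ly, lz = self.flyable_extent
        return np.array([0.0, -ly / 2, -lz / 2])

    @property
    def upper(self) -> np.ndarray:
        lx, ly, lz = self.flyable_extent
        return np.array([lx, ly / 2, lz / 2])

    def contains(self, position: np.ndarray, tol: float = _POS_TOL) -> bool:
        p = np.asarray(position, dtype=float)
        return bool(np.all(p >= self.lower - tol) and np.all(p <= self.upper + tol))


@dataclass(frozen=True)
class GaussianPlume:
    """Stationary axial plume with Gaussian cross-section.

    Concentration at (x, y, z) is
    ``c_max * exp(-((y - y_c)^2 + (z - z_c)^2) / (2 sigma(x)^2))``
    with ``sigma(x) = sigma0 + widen_rate * x``.  ``widen_rate = 0``
    models the non-widening laminar ethanol plume; a positive rate
    models slight downwind widening (the CO2 case).
    """

    centerline: tuple[float, float] = (0.0, 0.0)
    sigma0: float = 0.01
    widen_rate: float = 0.0
    c_max: float = 1.0
    detection_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.widen_rate < 0:
            raise ValueError("widen_rate must be >= 0")
        if self.c_max <= 0:
            raise ValueError("c_max must be > 0")
        if not 0 < self.detection_threshold < self.c_max:
            raise ValueError("detection_threshold must lie in (0, c_max)")

    def sigma(self, x):
        return self.sigma0 + self.widen_rate * np.asarray(x, dtype=float)


def concentration_at(
    position: np.ndarray,
    plume: GaussianPlume,
    env: WindTunnelGeometry | None = None,
) -> np.ndarray:
    """Plume concentration at one position or an (n, 3) array of positions.

    Raises
    ------
    OutOfDomainError
        If ``env`` is given and any position lies outside the flyable
        volume.
    """
    p = np.asarray(position, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[-1] != 3:
        raise ValueError("position must have 3 components")
    if env is not None:
        lo, hi = env.lower, env.upper
        ok = np.all(p >= lo - _POS_TOL, axis=-1) & np.all(p <= hi + _POS_TOL, axis=-1)
        if not np.all(ok):
            raise OutOfDomainError(
                f"{int((~ok).sum())} position(s) outside the flyable volume"
            )
    yc, zc = plume.centerline
    sig = plume.sigma(p[:, 0])
    r2 = (p[:, 1] - yc) ** 2 + (p[:, 2] - zc) ** 2
    c = plume.c_max * np.exp(-r2 / (2.0 * sig**2))
    return float(c[0]) if single else c


def heading_of(velocity: np.ndarray) -> np.ndarray:
    """Angle in degrees, in [0, 180], between velocity and upwind (-x).

    0 deg = flying directly upwind, 180 deg = directly downwind.
    Accepts a single 3-vector or an (n, 3) array.

    Raises
    ------
    UndefinedHeadingError
        For any zero-length velocity; callers must mask such samples.
    """
    v = np.asarray(velocity, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    speed = np.linalg.norm(v, axis=-1)
    if np.any(speed == 0):
        raise UndefinedHeadingError("heading undefined for zero-speed sample")
    cosang = np.clip(v @ UPWIND / speed, -1.0, 1.0)
    h = np.degrees(np.arccos(cosang))
    return float(h[0]) if single else h


def heading_of_masked(velocity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized heading with a validity mask instead of an error.

    Returns ``(headings, valid)`` where headings are NaN at zero-speed
    samples and ``valid`` flags the well-defined ones.
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    speed = np.linalg.norm(v, axis=-1)
    valid = speed > 0
    h = np.full(v.shape[0], np.nan)
    if valid.any():
        cosang = np.clip(v[valid] @ UPWIND / speed[valid], -1.0, 1.0)
        h[valid] = np.degrees(np.arccos(cosang))
    return h, valid


@dataclass
class Trajectory:
    """Time series of one flight: 3D kinematics + experienced odor.

    All arrays share the same length (>= 2); samples are evenly spaced
    at ``dt`` seconds starting at ``takeoff_time``.
    """

    id: str
    dt: float
    positions: np.ndarray
    velocities: np.ndarray
    concentrations: np.ndarray
    takeoff_time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        n = len(self.positions)
        if n < 2:
            raise ValueError(f"trajectory {self.id!r}: need >= 2 samples")
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError(f"trajectory {self.id!r}: bad array shapes")
        if self.concentrations.shape != (n,):
            raise ValueError(f"trajectory {self.id!r}: bad concentration shape")
        if not self.dt > 0:
            raise ValueError(f"trajectory {self.id!r}: dt must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return self.takeoff_time + self.dt * np.arange(len(self))

    @property
    def duration(self) -> float:
        return self.dt * (len(self) - 1)

    def headings(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample heading (degrees) and validity mask."""
        return heading_of_masked(self.velocities)

    def validate_in(self, env: WindTunnelGeometry, tol: float = _POS_TOL) -> None:
        lo, hi = env.lower, env.upper
        ok = np.all(self.positions >= lo - tol, axis=1) & np.all(
            self.positions <= hi + tol, axis=1
        )
        if not np.all(ok):
            raise OutOfDomainError(
                f"trajectory {self.id!r}: {int((~ok).sum())} sample(s) outside tunnel"
            )
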