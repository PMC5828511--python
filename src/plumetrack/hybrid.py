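"""Hybrid surge-cast / infotaxis crossing mixtures.

A hybrid crossing pairs each infotaxis crossing with a random
surge-cast crossing of the same crossing number and mixes their
heading-change series:
``dh_hybrid(t) = P/100 * dh_surge_cast(t) + (1 - P/100) * dh_infotaxis(t)``.
The mixing percentage best matching a target late-minus-early
difference is solved in closed form (the difference is linear in P for
any fixed pairing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class HybridConfig:
    mixing_percentage: float = 70.0  # P in [0, 100]
    pairing_seed: int = 0
    window: tuple[float, float] = (0.3, 0.8)  # s post-crossing
    n_pairings: int = 100
    early_numbers: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if not 0 <= self.mixing_percentage <= 100:
            raise ValueError("mixing percentage must lie in [0, 100]")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be increasing")


@dataclass
class HybridCrossing:
    crossing_number: int
    delta_h: np.ndarray
    valid_mask: np.ndarray
    time_grid: np.ndarray
    surge_cast_id: str
    infotaxis_id: str


class PairingError(ValueError):
    """A crossing number in the infotaxis pool has no surge-cast match."""


def _pair_indices(surge_cast, infotaxis, rng) -> list[int]:
    by_number: dict[int, list[int]] = {}
    for i, s in enumerate(surge_cast):
        by_number.setdefault(s.crossing_number, []).append(i)
    missing = sorted(
        {s.crossing_number for s in infotaxis} - set(by_number)
    )
    if missing:
        raise PairingError(f"no surge-cast crossings with number(s) {missing}")
    return [
        by_number[s.crossing_number][rng.integers(len(by_number[s.crossing_number]))]
        for s in infotaxis
    ]


def _resample_delta_h(seg, target_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delta-h of a segment linearly interpolated onto ``target_grid``."""
    dh = seg.delta_h()
    ok = seg.valid_mask & np.isfinite(dh)
    if ok.sum() < 2:
        return np.full(len(target_grid), np.nan), np.zeros(len(target_grid), bool)
    tg, vg = seg.time_grid[ok], dh[ok]
    out = np.interp(target_grid, tg, vg, left=np.nan, right=np.nan)
    mask = (target_grid >= tg[0]) & (target_grid <= tg[-1])
    out[~mask] = np.nan
    return out, mask


def make_hybrid_crossings(
    surge_cast, infotaxis, P: float, rng: np.random.Generator
) -> list[HybridCrossing]:
    """Pair pools by crossing number and mix their Delta-h series.

    Grids may differ (simulators run at different dt); both series are
    linearly interpolated onto the infotaxis grid before mixing.
    """
    if not 0 <= P <= 100:
        raise ValueError("P must lie in [0, 100]")
    pick = _pair_indices(surge_cast, infotaxis, rng)
    out = []
    for it_seg, sc_idx in zip(infotaxis, pick):
        sc_seg = surge_cast[sc_idx]
        grid = it_seg.time_grid
        dh_it, m_it = _resample_delta_h(it_seg, grid)
        dh_sc, m_sc = _resample_delta_h(sc_seg, grid)
        w = P / 100.0
        out.append(
            HybridCrossing(
                crossing_number=it_seg.crossing_number,
                delta_h=w * dh_sc + (1 - w) * dh_it,
                valid_mask=m_it & m_sc,
                time_grid=grid,
                surge_cast_id=sc_seg.traj_id,
                infotaxis_id=it_seg.traj_id,
            )
        )
    return out


def _late_minus_early(crossings, window, early_numbers) -> float:
    """Late-minus-early difference of window-averaged mean Delta-h."""
    lo, hi = window
    early, late = [], []
    for c in crossings:
        sel = c.valid_mask & (c.time_grid >= lo) & (c.time_grid <= hi)
        sel &= np.isfinite(c.delta_h)
        if not sel.any():
            continue
        val = float(np.mean(c.delta_h[sel]))
        (early if c.crossing_number in early_numbers else late).append(val)
    if len(early) < 1 or len(late) < 1:
        return np.nan
    return float(np.mean(late) - np.mean(early))


@dataclass
class MixingFractionResult:
    p_star: np.ndarray  # per-pairing optimum, clipped to [0, 100]
    mean: float
    sd: float
    endpoint_diffs: np.ndarray  # (n_pairings, 2): diff at P=0 and P=100


class NoIdentifiabilityError(ValueError):
    """The hybrid difference does not depend on P (identical pools)."""


def match_mixing_fraction(
    surge_cast, infotaxis, target_difference: float, config: HybridConfig
) -> MixingFractionResult:
    """Distribution over pairings of the P best matching the target.

    For each random pairing, the late-minus-early difference of the
    window-averaged hybrid Delta-h is exactly linear in P, so the
    minimizer of ``|difference(P) - target|`` is the linear solve
    clipped to [0, 100].
    """
    if not np.isfinite(target_difference):
        raise ValueError("target difference must be finite")
    rng = np.random.default_rng(config.pairing_seed)
    p_stars, ends = [], []
    for _ in range(config.n_pairings):
        pairing_rng = np.random.default_rng(rng.integers(2**63))
        hyb0 = make_hybrid_crossings(surge_cast, infotaxis, 0.0, pairing_rng)
        # same pairing for P=100: reuse the pairing by re-seeding
        d0 = _late_minus_early(hyb0, config.window, config.early_numbers)
        # linearity: d(P) = d0 + (d100 - d0) * P/100, with d100 from the
        # surge-cast series on the identical pairing
        d100 = _late_minus_early(
            [
                HybridCrossing(
                    crossing_number=h.crossing_number,
                    delta_h=h_sc,
                    valid_mask=h.valid_mask,
                    time_grid=h.time_grid,
                    surge_cast_id=h.surge_cast_id,
                    infotaxis_id=h.infotaxis_id,
                )
                for h, h_sc in zip(
                    hyb0,
                    _paired_sc_series(surge_cast, infotaxis, pairing_rng, hyb0),
                )
            ],
            config.window,
            config.early_numbers,
        )
        if not (np.isfinite(d0) and np.isfinite(d100)):
            continue
        slope = d100 - d0
        if abs(slope) < 1e-12:
            raise NoIdentifiabilityError("hybrid difference constant in P")
        p = 100.0 * (target_difference - d0) / slope
        p_stars.append(float(np.clip(p, 0.0, 100.0)))
        ends.append((d0, d100))
    if not p_stars:
        raise ValueError("no pairing produced a defined difference")
    p_stars = np.array(p_stars)
    return MixingFractionResult(
        p_star=p_stars,
        mean=float(p_stars.mean()),
        sd=float(p_stars.std(ddof=1)) if len(p_stars) > 1 else 0.0,
        endpoint_diffs=np.array(ends),
    )


def _paired_sc_series(surge_cast, infotaxis, used_rng, hyb0):
    """Pure surge-cast Delta-h series for the pairing behind ``hyb0``.

    Each hybrid records its partner's (traj_id, crossing_number), which
    identifies the surge-cast crossing uniquely (numbers are unique
    within a trajectory), so the P=100 endpoint can be rebuilt on the
    identical pairing without replaying the RNG.
    """
    by_key: dict[tuple[str, int], object] = {}
    for s in surge_cast:
        by_key.setdefault((s.traj_id, s.crossing_number), s)
    out = []
    for h in hyb0:
        sc = by_key[(h.surge_cast_id, h.crossing_number)]
        dh_sc, _ = _resample_delta_h(sc, h.time_grid)
        out.append(dh_sc)
    return out
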