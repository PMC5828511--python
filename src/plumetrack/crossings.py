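"""Plume-crossing extraction, exclusion rules, and threshold scanning.

A crossing is a maximal interval during which experienced odor
concentration stays at or above a detection threshold.  Each crossing
is indexed by the time of its concentration peak (t = 0) and its
analysis window runs until the next excursion begins or the trajectory
ends (the agent "reenters the plume or lands").  Post-peak headings are
resampled onto a fixed grid (default 0-1 s at the trajectory dt) with a
validity mask where the window ends early or heading is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plumetrack.geometry import Trajectory, WindTunnelGeometry, heading_of_masked

DEFAULT_GRID_DURATION = 1.0  # seconds of post-peak heading retained


@dataclass
class CrossingSegment:
    """One plume crossing, aligned to its concentration peak."""

    traj_id: str
    crossing_number: int  # 1-based order within the trajectory (pre-exclusion)
    peak_index: int  # sample index of the concentration maximum
    c_peak: float
    x0: float  # x-position at the peak, m
    h0: float  # heading at the peak, degrees (NaN if speed was 0)
    T: float  # flight time since takeoff at the peak, s
    heading_series: np.ndarray  # degrees on the post-peak grid, NaN where invalid
    valid_mask: np.ndarray  # True where the window covers the grid point
    time_grid: np.ndarray  # seconds post-peak
    end_time: float  # seconds post-peak at which the window closed

    def delta_h(self) -> np.ndarray:
        """Heading change Delta-h(t) = h(t) - h(0)."""
        return self.heading_series - self.h0


@dataclass(frozen=True)
class ExclusionPolicy:
    """Geometric and initial-heading exclusion rules.

    Keeps crossings with ``end_margin <= x0 <= Lx - end_margin`` and
    ``h0`` inside ``heading_window`` (default 60-120 degrees, i.e.
    roughly crosswind at the peak).
    """

    end_margin: float = 0.30
    heading_window: tuple[float, float] = (60.0, 120.0)
    apply_margin: bool = True
    apply_heading: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.heading_window
        if not 0 <= lo < hi <= 180:
            raise ValueError("heading_window must satisfy 0 <= low < high <= 180")


def extract_crossings(
    traj: Trajectory,
    threshold: float,
    grid_duration: float = DEFAULT_GRID_DURATION,
) -> list[CrossingSegment]:
    """Segment one trajectory into peak-aligned plume crossings.

    Returns one segment per maximal above-threshold excursion, in
    temporal order with crossing numbers starting at 1.  A trajectory
    with no excursion yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    c = traj.concentrations
    above = c >= threshold
    if not above.any():
        return []
    # excursion start/end indices (end = first index after the excursion)
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]

    headings, _ = heading_of_masked(traj.velocities)
    n_grid = int(round(grid_duration / traj.dt)) + 1
    grid = traj.dt * np.arange(n_grid)
    n_samples = len(traj)

    segments: list[CrossingSegment] = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        peak = s + int(np.argmax(c[s:e]))
        window_end = starts[k + 1] if k + 1 < len(starts) else n_samples
        avail = window_end - peak  # grid points covered by the window
        mask = np.zeros(n_grid, bool)
        mask[: min(avail, n_grid)] = True
        series = np.full(n_grid, np.nan)
        take = min(avail, n_grid)
        series[:take] = headings[peak : peak + take]
        mask &= np.isfinite(series)
        segments.append(
            CrossingSegment(
                traj_id=traj.id,
                crossing_number=k + 1,
                peak_index=peak,
                c_peak=float(c[peak]),
                x0=float(traj.positions[peak, 0]),
                h0=float(headings[peak]),
                T=float(peak * traj.dt),
                heading_series=series,
                valid_mask=mask,
                time_grid=grid,
                end_time=float((window_end - peak) * traj.dt),
            )
        )
    return segments


def extract_all_crossings(
    trajs, threshold: float, grid_duration: float = DEFAULT_GRID_DURATION
) -> list[CrossingSegment]:
    """Concatenated crossings of a trajectory collection."""
    out: list[CrossingSegment] = []
    for tr in trajs:
        out.extend(extract_crossings(tr, threshold, grid_duration))
    return out


def apply_exclusions(
    crossings, policy: ExclusionPolicy, env: WindTunnelGeometry
) -> list[CrossingSegment]:
    """Filter crossings by the end-margin and initial-heading rules.

    Crossing numbers are preserved (numbering was assigned before
    exclusion, so the early/late variable reflects the full crossing
    history of the trajectory).
    """
    lx = env.flyable_extent[0]
    kept = []
    for seg in crossings:
        if policy.apply_margin and not (
            policy.end_margin <= seg.x0 <= lx - policy.end_margin
        ):
            continue
        if policy.apply_heading:
            lo, hi = policy.heading_window
            if not (np.isfinite(seg.h0) and lo <= seg.h0 <= hi):
                continue
        kept.append(seg)
    return kept


@dataclass
class ThresholdScanResult:
    """Separation scores of candidate crossing thresholds."""

    candidates: np.ndarray
    scores: np.ndarray  # below-group minus above-group mean heading
    ses: np.ndarray  # propagated standard error of each score
    n_below: np.ndarray
    n_above: np.ndarray
    defined: np.ndarray  # False where a group was empty
    elbow_index: int
    elbow_threshold: float


def threshold_scan(
    trajs,
    candidates,
    capture_threshold: float,
    grid_duration: float = DEFAULT_GRID_DURATION,
    average_window: float = 1.0,
) -> ThresholdScanResult:
    """Scan candidate crossing thresholds for group separation.

    The pool of potential crossings is extracted at ``capture_threshold``
    (low).  For each candidate the pool splits by ``c_peak`` into
    below/above groups; the score is the difference of the groups' mean
    headings, time-averaged over the first ``average_window`` seconds
    post-peak (above-threshold crossings surge upwind, so a real
    detection threshold yields below-minus-above > 0).  Uncertainty is
    the two group standard errors propagated through the difference.
    The "elbow" is the candidate of maximum discrete curvature of the
    score curve (single candidate: selected trivially).
    """
    candidates = np.asarray(candidates, dtype=float)
    if np.any(np.diff(candidates) <= 0):
        raise ValueError("candidates must be sorted ascending")
    pool = extract_all_crossings(trajs, capture_threshold, grid_duration)
    c_peaks = np.array([s.c_peak for s in pool])
    means = np.array(
        [
            np.nanmean(np.where(s.valid_mask & (s.time_grid <= average_window),
                                s.heading_series, np.nan))
            if (s.valid_mask & (s.time_grid <= average_window)).any()
            else np.nan
            for s in pool
        ]
    )
    ok = np.isfinite(means)
    c_peaks, means = c_peaks[ok], means[ok]

    n_c = len(candidates)
    scores = np.full(n_c, np.nan)
    ses = np.full(n_c, np.nan)
    n_below = np.zeros(n_c, int)
    n_above = np.zeros(n_c, int)
    defined = np.zeros(n_c, bool)
    for i, cand in enumerate(candidates):
        below = means[c_peaks < cand]
        abv = means[c_peaks >= cand]
        n_below[i], n_above[i] = len(below), len(abv)
        if len(below) >= 2 and len(abv) >= 2:
            scores[i] = below.mean() - abv.mean()
            ses[i] = float(
                np.sqrt(below.var(ddof=1) / len(below) + abv.var(ddof=1) / len(abv))
            )
            defined[i] = True

    elbow = _elbow_index(candidates, scores, defined)
    return ThresholdScanResult(
        candidates=candidates,
        scores=scores,
        ses=ses,
        n_below=n_below,
        n_above=n_above,
        defined=defined,
        elbow_index=elbow,
        elbow_threshold=float(candidates[elbow]),
    )


def _elbow_index(candidates, scores, defined) -> int:
    """Index of the separation elbow.

    A true detection threshold shows up as the score rising and then
    flattening or falling.  If the score has an interior maximum we take
    it (rise-then-fall case); for a monotone curve we fall back to the
    point of strongest concave bend (most negative second difference).
    """
    idx = np.nonzero(defined)[0]
    if len(idx) == 0:
        return 0
    if len(idx) < 3:
        return int(idx[np.nanargmax(scores[idx])])
    s = scores[idx]
    imax = int(np.nanargmax(s))
    if 0 < imax < len(s) - 1:
        return int(idx[imax])
    d2 = s[:-2] - 2 * s[1:-1] + s[2:]
    return int(idx[1 + np.argmin(d2)])


# ---------------------------------------------------------------------------
# crossing table I/O
# ---------------------------------------------------------------------------

def crossings_to_frame(crossings) -> pd.DataFrame:
    """Wide crossing table: covariates plus ms-labelled heading columns."""
    if not crossings:
        return pd.DataFrame()
    grid = crossings[0].time_grid
    hcols = [f"h_{int(round(t * 1000)):04d}" for t in grid]
    vcols = [f"valid_{int(round(t * 1000)):04d}" for t in grid]
    rows = []
    for s in crossings:
        row = {
            "traj_id": s.traj_id,
            "crossing_number": s.crossing_number,
            "t_peak": s.T,
            "c_peak": s.c_peak,
            "x0": s.x0,
            "h0": s.h0,
            "T": s.T,
            "end_time": s.end_time,
        }
        row.update(dict(zip(hcols, s.heading_series)))
        row.update(dict(zip(vcols, s.valid_mask.astype(int))))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_crossings(df: pd.DataFrame) -> list[CrossingSegment]:
    hcols = sorted(c for c in df.columns if c.startswith("h_") and c[2:].isdigit())
    vcols = sorted(c for c in df.columns if c.startswith("valid_"))
    grid = np.array([int(c[2:]) / 1000.0 for c in hcols])
    out = []
    for _, row in df.iterrows():
        out.append(
            CrossingSegment(
                traj_id=str(row["traj_id"]),
                crossing_number=int(row["crossing_number"]),
                peak_index=-1,
                c_peak=float(row["c_peak"]),
                x0=float(row["x0"]),
                h0=float(row["h0"]),
                T=float(row["T"]),
                heading_series=row[hcols].to_numpy(float),
                valid_mask=row[vcols].to_numpy(float).astype(bool),
                time_grid=grid,
                end_time=float(row["end_time"]),
            )
        )
    return out
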