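"""Occupancy heatmaps: normalized histograms of all trajectory timepoints."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plumetrack.geometry import WindTunnelGeometry


@dataclass
class OccupancyHeatmap:
    hist: np.ndarray  # (nx, ny), normalized to sum 1
    x_edges: np.ndarray
    y_edges: np.ndarray

    def x_marginal(self) -> np.ndarray:
        return self.hist.sum(axis=1)


def occupancy_heatmap(
    trajs, env: WindTunnelGeometry, bin_size: float = 0.02
) -> OccupancyHeatmap:
    """Bin all timepoints of all trajectories into an x-y histogram.

    No crossing exclusions are applied; z is marginalized.  The
    histogram is normalized to total mass 1.
    """
    lo, hi = env.lower, env.upper
    x_edges = np.arange(lo[0], hi[0] + bin_size / 2, bin_size)
    y_edges = np.arange(lo[1], hi[1] + bin_size / 2, bin_size)
    xs = np.concatenate([tr.positions[:, 0] for tr in trajs])
    ys = np.concatenate([tr.positions[:, 1] for tr in trajs])
    h, _, _ = np.histogram2d(xs, ys, bins=(x_edges, y_edges))
    total = h.sum()
    if total > 0:
        h = h / total
    return OccupancyHeatmap(hist=h, x_edges=x_edges, y_edges=y_edges)


def downwind_margin_mass(hm: OccupancyHeatmap, margin: float = 0.15) -> float:
    """Occupancy mass in the downwind-most ``margin`` meters."""
    centers = (hm.x_edges[:-1] + hm.x_edges[1:]) / 2
    return float(hm.x_marginal()[centers >= hm.x_edges[-1] - margin].sum())


def upwind_half_mass(hm: OccupancyHeatmap) -> float:
    centers = (hm.x_edges[:-1] + hm.x_edges[1:]) / 2
    mid = (hm.x_edges[0] + hm.x_edges[-1]) / 2
    return float(hm.x_marginal()[centers < mid].sum())
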