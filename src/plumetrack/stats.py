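"""Crossing-triggered inferential statistics.

Implements the analysis layer applied to extracted plume crossings:

- residualized partial correlations (target regressed on conditioners,
  residual correlated with the predictor) with trajectory-level
  bootstrap confidence intervals;
- nested comparison of a binary vs. a threshold-linear model of the
  post-crossing heading response, with an F-test whose sample size is
  the number of unique trajectories (conservative: crossings from one
  trajectory are not independent);
- the early/late history-dependence analysis on confound-corrected
  heading changes h*(t), and the crossing-number partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class UndefinedCorrelationError(ValueError):
    """Residual (or predictor) is constant; correlation undefined."""


def _ols_residual(y: np.ndarray, conditioners: np.ndarray | None) -> np.ndarray:
    """Residual of y on [1, conditioners] by least squares."""
    n = len(y)
    if conditioners is None or conditioners.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(n), conditioners])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class PartialCorrResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int  # crossings used
    n_groups: int  # unique trajectories
    p_value: float  # computed with trajectory-level degrees of freedom
    n_conditioners: int


def partial_correlation(
    target,
    predictor,
    conditioners=None,
    groups=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PartialCorrResult:
    """Correlation of ``predictor`` with the residual of ``target``.

    ``target`` is regressed (OLS with intercept) on the conditioners;
    the Pearson correlation between that residual and ``predictor`` is
    returned.  The 2.5-97.5% CI is a bootstrap over whole groups
    (trajectories) when ``groups`` is given, else over samples.  The
    p-value uses the number of unique groups as the sample size.
    """
    y = np.asarray(target, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cond = None
    k = 0
    if conditioners is not None:
        cond = np.column_stack([np.asarray(c, dtype=float) for c in conditioners]) \
            if isinstance(conditioners, (list, tuple)) else np.atleast_2d(
                np.asarray(conditioners, dtype=float)
            ).reshape(len(y), -1)
        k = cond.shape[1]
    if len(y) != len(x) or (cond is not None and len(cond) != len(y)):
        raise ValueError("target, predictor, conditioners must have equal length")
    if len(y) < 3 + k:
        raise ValueError("need at least 3 + #conditioners samples")
    if groups is None:
        groups = np.arange(len(y))
    groups = np.asarray(groups)

    r = _partial_r(y, x, cond)

    uniq = np.unique(groups)
    n_groups = len(uniq)
    df = n_groups - 2 - k
    if df > 0 and abs(r) < 1:
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
    else:
        p = np.nan

    rng = np.random.default_rng(seed)
    by_group = {g: np.nonzero(groups == g)[0] for g in uniq}
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=n_groups, replace=True)
        idx = np.concatenate([by_group[g] for g in pick])
        try:
            boots.append(_partial_r(y[idx], x[idx], None if cond is None else cond[idx]))
        except UndefinedCorrelationError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return PartialCorrResult(
        estimate=float(r),
        ci_low=float(lo),
        ci_high=float(hi),
        n=len(y),
        n_groups=n_groups,
        p_value=float(p),
        n_conditioners=k,
    )


def _partial_r(y, x, cond) -> float:
    resid = _ols_residual(y, cond)
    sy = resid.std()
    sx = x.std()
    if sy < 1e-12 * max(1.0, np.abs(y).max()) or sx == 0:
        raise UndefinedCorrelationError("constant residual or predictor")
    return float(np.corrcoef(resid, x)[0, 1])


# ---------------------------------------------------------------------------
# concentration dependence of post-crossing heading
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationCurve:
    timepoints: np.ndarray
    estimates: np.ndarray  # NaN where undefined
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_crossings: np.ndarray
    defined: np.ndarray


def heading_concentration_curve(
    crossings, timepoints, n_boot: int = 500, seed: int = 0
) -> ConcentrationCurve:
    """Partial correlation of c_peak vs. h(t), conditioned on (x0, h0),
    at each requested post-peak time."""
    timepoints = np.asarray(timepoints, dtype=float)
    grid = crossings[0].time_grid
    est = np.full(len(timepoints), np.nan)
    lo = np.full(len(timepoints), np.nan)
    hi = np.full(len(timepoints), np.nan)
    ncr = np.zeros(len(timepoints), int)
    defined = np.zeros(len(timepoints), bool)
    for i, tp in enumerate(timepoints):
        j = _grid_index(grid, tp)
        h = np.array([s.heading_series[j] for s in crossings])
        ok = np.array([s.valid_mask[j] for s in crossings]) & np.isfinite(h)
        ok &= np.array([np.isfinite(s.h0) for s in crossings])
        if ok.sum() < 5:
            continue
        sub = [s for s, o in zip(crossings, ok) if o]
        try:
            res = partial_correlation(
                h[ok],
                np.array([s.c_peak for s in sub]),
                conditioners=[
                    np.array([s.x0 for s in sub]),
                    np.array([s.h0 for s in sub]),
                ],
                groups=np.array([s.traj_id for s in sub]),
                n_boot=n_boot,
                seed=seed + i,
            )
        except UndefinedCorrelationError:
            continue
        est[i], lo[i], hi[i] = res.estimate, res.ci_low, res.ci_high
        ncr[i] = res.n
        defined[i] = True
    return ConcentrationCurve(timepoints, est, lo, hi, ncr, defined)


def _grid_index(grid: np.ndarray, timepoint: float) -> int:
    j = int(round(timepoint / (grid[1] - grid[0])))
    if not 0 <= j < len(grid):
        raise ValueError(f"timepoint {timepoint} beyond the heading grid")
    return j


# ---------------------------------------------------------------------------
# binary vs. threshold-linear model comparison
# ---------------------------------------------------------------------------

@dataclass
class ThresholdModelFit:
    """Least-squares fit of one crossing-response model.

    Binary model: ``h(t) = a_h h0 + a_x x0 + h_lt + h_gt * Theta(c_peak - c_th)``.
    Threshold-linear adds ``a_c * c_peak * Theta(c_peak - c_th)``.
    """

    a_h: float
    a_x: float
    h_lt: float
    h_gt: float
    c_th: float
    sse: float
    n_crossings: int
    n_trajectories: int
    a_c: float | None = None  # absent in the binary model

    def predict(self, h0, x0, c_peak):
        theta = (np.asarray(c_peak) >= self.c_th).astype(float)
        out = self.a_h * np.asarray(h0) + self.a_x * np.asarray(x0) + self.h_lt \
            + self.h_gt * theta
        if self.a_c is not None:
            out = out + self.a_c * np.asarray(c_peak) * theta
        return out


class InsufficientDataError(ValueError):
    pass


def fit_threshold_models(
    crossings,
    timepoint: float = 0.3,
    n_grid: int = 100,
    count_mode: str = "trajectories",
):
    """Fit the nested binary / threshold-linear models and F-test them.

    The threshold ``c_th`` is profiled by grid search over the 1st-99th
    percentiles of observed ``c_peak`` (``n_grid`` steps); the remaining
    coefficients are exact least squares at each grid value.  The F-test
    of the nested pair uses the number of unique trajectories as the
    sample size unless ``count_mode="crossings"``.

    Returns ``(binary_fit, threshold_linear_fit, F, p)``.
    """
    grid = crossings[0].time_grid
    j = _grid_index(grid, timepoint)
    rows = [
        s for s in crossings
        if s.valid_mask[j] and np.isfinite(s.heading_series[j]) and np.isfinite(s.h0)
    ]
    y = np.array([s.heading_series[j] for s in rows])
    h0 = np.array([s.h0 for s in rows])
    x0 = np.array([s.x0 for s in rows])
    cpk = np.array([s.c_peak for s in rows])
    tids = np.array([s.traj_id for s in rows])
    n_traj = len(np.unique(tids))
    n_eff = len(rows) if count_mode == "crossings" else n_traj
    if n_traj < 2:
        raise InsufficientDataError("need >= 2 unique trajectories")
    if n_eff - 6 < 1:
        raise InsufficientDataError(
            f"insufficient degrees of freedom: {n_eff} effective samples"
        )

    c_grid = np.quantile(cpk, np.linspace(0.01, 0.99, n_grid))
    c_grid = np.unique(c_grid)

    best = {"binary": (np.inf, None, None), "tl": (np.inf, None, None)}
    base = np.column_stack([h0, x0, np.ones(len(y))])
    for c_th in c_grid:
        theta = (cpk >= c_th).astype(float)
        Xb = np.column_stack([base, theta])
        bb, res_b, *_ = np.linalg.lstsq(Xb, y, rcond=None)
        sse_b = float(np.sum((y - Xb @ bb) ** 2))
        if sse_b < best["binary"][0]:
            best["binary"] = (sse_b, bb, c_th)
        Xt = np.column_stack([base, theta, cpk * theta])
        bt, *_ = np.linalg.lstsq(Xt, y, rcond=None)
        sse_t = float(np.sum((y - Xt @ bt) ** 2))
        if sse_t < best["tl"][0]:
            best["tl"] = (sse_t, bt, c_th)

    sse_b, bb, cth_b = best["binary"]
    sse_t, bt, cth_t = best["tl"]
    fit_b = ThresholdModelFit(
        a_h=float(bb[0]), a_x=float(bb[1]), h_lt=float(bb[2]), h_gt=float(bb[3]),
        c_th=float(cth_b), sse=sse_b, n_crossings=len(rows), n_trajectories=n_traj,
    )
    fit_t = ThresholdModelFit(
        a_h=float(bt[0]), a_x=float(bt[1]), h_lt=float(bt[2]), h_gt=float(bt[3]),
        c_th=float(cth_t), sse=sse_t, n_crossings=len(rows), n_trajectories=n_traj,
        a_c=float(bt[4]),
    )
    df2 = n_eff - 6
    if sse_t <= 0:
        F = np.inf
        p = 0.0
    else:
        F = max(sse_b - sse_t, 0.0) / (sse_t / df2)
        p = float(sps.f.sf(F, 1, df2))
    return fit_b, fit_t, float(F), p


# ---------------------------------------------------------------------------
# early vs. late history dependence
# ---------------------------------------------------------------------------

@dataclass
class HistoryAnalysisResult:
    """Per-timepoint early/late comparison of confound-corrected h*(t)."""

    time_grid: np.ndarray
    early_mean: np.ndarray
    early_se: np.ndarray
    late_mean: np.ndarray
    late_se: np.ndarray
    p_values: np.ndarray
    n_early: np.ndarray  # crossings per timepoint
    n_late: np.ndarray
    n_traj_early: int
    n_traj_late: int
    confound_coefs: np.ndarray  # (n_time, 3): intercept, x0, T
    pooled_mean: np.ndarray  # ~0 by construction

    def late_minus_early(self) -> np.ndarray:
        return self.late_mean - self.early_mean


def history_dependence(
    crossings,
    early_numbers=(1, 2),
    count_mode: str = "trajectories",
    baseline: str = "h0",
) -> HistoryAnalysisResult:
    """Early vs. late comparison of h*(t).

    For each crossing, ``Delta-h(t) = h(t) - h(0)`` (or minus a
    pre-window mean when ``baseline="prewindow"`` is unavailable here;
    only "h0" is supported for extracted segments).  At each timepoint
    the best linear prediction of Delta-h from (x0, T) — fit over all
    crossings pooled, with intercept — is subtracted, yielding h*(t)
    with pooled mean 0 by construction.  Early and late groups are then
    compared with a Welch t-test whose sample sizes are the unique
    trajectory counts (``count_mode="crossings"`` uses crossing counts).
    """
    if baseline != "h0":
        raise NotImplementedError("only the h0 baseline is available for segments")
    early_numbers = set(early_numbers)
    grid = crossings[0].time_grid
    n_time = len(grid)
    dh = np.stack([s.delta_h() for s in crossings])  # (n_cross, n_time)
    valid = np.stack([s.valid_mask for s in crossings]) & np.isfinite(dh)
    x0 = np.array([s.x0 for s in crossings])
    T = np.array([s.T for s in crossings])
    is_early = np.array([s.crossing_number in early_numbers for s in crossings])
    tids = np.array([s.traj_id for s in crossings])

    tr_early = np.unique(tids[is_early])
    tr_late = np.unique(tids[~is_early])
    if len(tr_early) < 2 or len(tr_late) < 2:
        raise InsufficientDataError(
            "each group needs >= 2 unique trajectories "
            f"(early {len(tr_early)}, late {len(tr_late)})"
        )

    e_mean = np.full(n_time, np.nan)
    e_se = np.full(n_time, np.nan)
    l_mean = np.full(n_time, np.nan)
    l_se = np.full(n_time, np.nan)
    pvals = np.full(n_time, np.nan)
    n_e = np.zeros(n_time, int)
    n_l = np.zeros(n_time, int)
    coefs = np.full((n_time, 3), np.nan)
    pooled = np.full(n_time, np.nan)

    for j in range(n_time):
        ok = valid[:, j]
        if ok.sum() < 6:
            continue
        yj = dh[ok, j]
        X = np.column_stack([np.ones(ok.sum()), x0[ok], T[ok]])
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        hstar = yj - X @ beta
        coefs[j] = beta
        pooled[j] = hstar.mean()

        ej = is_early[ok]
        he, hl = hstar[ej], hstar[~ej]
        if len(he) < 2 or len(hl) < 2:
            continue
        ne_t = len(np.unique(tids[ok][ej])) if count_mode == "trajectories" else len(he)
        nl_t = len(np.unique(tids[ok][~ej])) if count_mode == "trajectories" else len(hl)
        n_e[j], n_l[j] = len(he), len(hl)
        ve, vl = he.var(ddof=1), hl.var(ddof=1)
        e_mean[j], l_mean[j] = he.mean(), hl.mean()
        e_se[j] = np.sqrt(ve / ne_t)
        l_se[j] = np.sqrt(vl / nl_t)
        se2 = ve / ne_t + vl / nl_t
        if se2 > 0 and ne_t > 1 and nl_t > 1:
            tstat = (hl.mean() - he.mean()) / np.sqrt(se2)
            dof = se2**2 / (
                (ve / ne_t) ** 2 / (ne_t - 1) + (vl / nl_t) ** 2 / (nl_t - 1)
            )
            pvals[j] = 2 * sps.t.sf(abs(tstat), dof)

    return HistoryAnalysisResult(
        time_grid=grid,
        early_mean=e_mean,
        early_se=e_se,
        late_mean=l_mean,
        late_se=l_se,
        p_values=pvals,
        n_early=n_e,
        n_late=n_l,
        n_traj_early=len(tr_early),
        n_traj_late=len(tr_late),
        confound_coefs=coefs,
        pooled_mean=pooled,
    )


def crossing_number_partial_corr(
    crossings,
    window: tuple[float, float] = (0.35, 0.45),
    max_number: int = 5,
    n_boot: int = 500,
    seed: int = 0,
) -> PartialCorrResult:
    """Partial correlation of crossing number vs. window-averaged Delta-h,
    conditioned on (x0, T); crossings with number > ``max_number`` are
    dropped (they are rare and unbalanced)."""
    lo, hi = window
    rows, dhm = [], []
    for s in crossings:
        if s.crossing_number > max_number or not np.isfinite(s.h0):
            continue
        sel = s.valid_mask & (s.time_grid >= lo) & (s.time_grid <= hi)
        if not sel.any():
            continue
        v = s.delta_h()[sel]
        if not np.all(np.isfinite(v)):
            continue
        rows.append(s)
        dhm.append(v.mean())
    if len(rows) < 6:
        raise InsufficientDataError("too few crossings in the averaging window")
    return partial_correlation(
        np.array(dhm),
        np.array([s.crossing_number for s in rows], dtype=float),
        conditioners=[
            np.array([s.x0 for s in rows]),
            np.array([s.T for s in rows]),
        ],
        groups=np.array([s.traj_id for s in rows]),
        n_boot=n_boot,
        seed=seed,
    )
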