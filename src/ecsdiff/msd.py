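"""Ensemble mean-squared-displacement analysis and diffusivity estimation.

The effective diffusion coefficient is read off the linear ("stage II")
regime of the ensemble MSD: per-axis, D_x = slope(<R_x^2> vs t) / 2, and
the x/y estimates are averaged for the in-plane (perpendicular) D.  A run
shows three stages: an interaction-dominated transient just after release
(stage I), the statistically stable linear regime (stage II), and a
depleted fluctuating tail once particles start exiting the domain
(stage III).  Stage II is found by a sliding-window rule: the longest
window that is linear (high R^2), has a stable local slope, and retains
most of the ensemble.

MSD at each time averages over the particles still alive at that time
(matching the removal boundary condition); this is a known mild downward
bias source near stage III.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import TrajectoryRecord

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "StageWindowError",
    "msd_curve",
    "detect_stage2",
    "estimate_D",
    "analyze_trajectory",
]


class StageWindowError(RuntimeError):
    """No window satisfying the stage-II criteria exists."""


@dataclass
class MSDCurve:
    """Ensemble MSD time series (SI units).

    msd_total = msd_x + msd_y at every time; all averages are over the
    particles alive at that time.
    """

    times: np.ndarray       # (m,) s
    msd_x: np.ndarray       # (m,) m^2
    msd_y: np.ndarray       # (m,) m^2
    msd_total: np.ndarray   # (m,) m^2
    n_alive: np.ndarray     # (m,) int

    def alive_fraction(self) -> np.ndarray:
        n0 = max(int(self.n_alive[0]), 1)
        return self.n_alive / n0


@dataclass
class DiffusionEstimate:
    """Fitted diffusion coefficient with per-axis values and fit SE."""

    D: float                # m^2/s, (D_x + D_y)/2
    D_x: float
    D_y: float
    window: tuple[float, float]      # s
    stderr: float           # m^2/s, propagated slope SE
    stderr_x: float = 0.0
    stderr_y: float = 0.0
    n_points: int = 0
    stage_labels: np.ndarray | None = field(default=None, repr=False)


def msd_curve(record: TrajectoryRecord) -> MSDCurve:
    """Per-time ensemble MSD, per axis and total, from a trajectory record.

    Displacements are measured from each particle's release position and
    averaged over the particles alive at each recorded time.
    """
    if record.times.shape[0] < 2:
        raise ValueError("need at least 2 recorded times")
    disp = record.positions - record.release_positions[None, :, :]
    sq = disp**2
    alive = record.alive
    n_alive = alive.sum(axis=1)
    if n_alive[1] == 0:
        raise StageWindowError("all particles exited before the second record")
    with np.errstate(invalid="ignore"):
        mx = np.where(alive, sq[..., 0], 0.0).sum(axis=1) / np.maximum(n_alive, 1)
        my = np.where(alive, sq[..., 1], 0.0).sum(axis=1) / np.maximum(n_alive, 1)
    mx[n_alive == 0] = np.nan
    my[n_alive == 0] = np.nan
    return MSDCurve(
        times=record.times.copy(),
        msd_x=mx,
        msd_y=my,
        msd_total=mx + my,
        n_alive=n_alive.astype(int),
    )


def _window_fit(t: np.ndarray, y: np.ndarray):
    """Least-squares line with free intercept: slope, R^2 (via prefix-free
    direct computation; small windows, so plain numpy is fine)."""
    tm = t.mean()
    ym = y.mean()
    dt = t - tm
    dy = y - ym
    stt = float(dt @ dt)
    if stt == 0:
        return np.nan, -np.inf
    slope = float(dt @ dy) / stt
    ss_res = float(dy @ dy) - slope**2 * stt
    ss_tot = float(dy @ dy)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def detect_stage2(
    curve: MSDCurve,
    min_window: float = 0.20,
    r2_threshold: float = 0.995,
    slope_tolerance: float = 0.10,
    min_alive_fraction: float = 0.80,
    n_scan: int = 40,
) -> tuple[float, float]:
    """Locate the statistically stable linear regime of the MSD curve.

    Scans candidate windows (coarse grid of start/end indices) and returns
    the longest one in which (a) the linear fit of msd_total reaches
    ``r2_threshold``, (b) the slopes of the two window halves agree with
    the full-window slope within ``slope_tolerance`` (excludes the steep
    stage-I transient and curvature), and (c) the alive fraction stays at
    or above ``min_alive_fraction`` (excludes stage-III depletion).
    Returns the window as a (t_start, t_end) time interval.

    Raises
    ------
    StageWindowError
        If no window satisfies all criteria.
    """
    t = curve.times
    y = curve.msd_total
    m = len(t)
    if m < 5:
        raise StageWindowError("curve too short for stage detection")
    frac = curve.alive_fraction()
    valid = np.isfinite(y) & (frac >= min_alive_fraction)
    # restrict to the leading contiguous valid block
    if not valid[0] and not valid[1]:
        raise StageWindowError("ensemble depleted from the start")
    last = int(np.argmin(valid)) if not valid.all() else m
    if last < 5:
        raise StageWindowError(
            f"only {last} records before depletion below "
            f"{min_alive_fraction:.0%} alive"
        )
    t = t[:last]
    y = y[:last]
    m = last
    span = t[-1] - t[0]
    min_len = min_window * span
    step = max(1, m // n_scan)
    starts = list(range(0, m - 4, step))
    ends = list(range(4, m, step)) + [m - 1]
    best: tuple[float, int, int] | None = None
    for i in starts:
        for j in ends:
            if j - i < 4 or t[j] - t[i] < min_len:
                continue
            if best is not None and t[j] - t[i] <= best[0]:
                continue
            slope, r2 = _window_fit(t[i:j + 1], y[i:j + 1])
            if not np.isfinite(slope) or slope == 0 or r2 < r2_threshold:
                continue
            mid = (i + j) // 2
            s1, _ = _window_fit(t[i:mid + 1], y[i:mid + 1])
            s2, _ = _window_fit(t[mid:j + 1], y[mid:j + 1])
            if abs(s1 - slope) > slope_tolerance * abs(slope):
                continue
            if abs(s2 - slope) > slope_tolerance * abs(slope):
                continue
            best = (t[j] - t[i], i, j)
    if best is None:
        raise StageWindowError(
            "no window met the stage-II criteria "
            f"(R^2>={r2_threshold}, slope tol {slope_tolerance:.0%}, "
            f"alive>={min_alive_fraction:.0%}, min length {min_len:.3g} s); "
            "consider extending the run"
        )
    _, i, j = best
    return float(t[i]), float(t[j])


def estimate_D(curve: MSDCurve, window: tuple[float, float]) -> DiffusionEstimate:
    """Diffusion coefficient from per-axis MSD slopes over the window.

    D_axis = slope/2 from an ordinary least-squares line with free
    intercept (the stage-I transient offsets the line; the slope alone
    carries D).  D is the x/y average; the SE combines the two fit SEs.
    """
    t0, t1 = window
    mask = (curve.times >= t0 - 1e-300) & (curve.times <= t1 + 1e-300)
    mask &= np.isfinite(curve.msd_total)
    if mask.sum() < 5:
        raise ValueError("need at least 5 points inside the fit window")
    t = curve.times[mask]
    if np.ptp(t) == 0:
        raise ValueError("singular fit: constant time in window")
    fx = stats.linregress(t, curve.msd_x[mask])
    fy = stats.linregress(t, curve.msd_y[mask])
    D_x = fx.slope / 2.0
    D_y = fy.slope / 2.0
    se_x = fx.stderr / 2.0
    se_y = fy.stderr / 2.0
    labels = np.empty(len(curve.times), dtype="<U3")
    labels[:] = "I"
    labels[mask] = "II"
    labels[curve.times > t1] = "III"
    return DiffusionEstimate(
        D=0.5 * (D_x + D_y),
        D_x=float(D_x),
        D_y=float(D_y),
        window=(float(t0), float(t1)),
        stderr=float(0.5 * np.hypot(se_x, se_y)),
        stderr_x=float(se_x),
        stderr_y=float(se_y),
        n_points=int(mask.sum()),
        stage_labels=labels,
    )


def analyze_trajectory(
    record: TrajectoryRecord, **stage_kwargs
) -> tuple[MSDCurve, DiffusionEstimate]:
    """Full pipeline: MSD curve, stage-II window, D estimate."""
    curve = msd_curve(record)
    window = detect_stage2(curve, **stage_kwargs)
    return curve, estimate_D(curve, window)
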