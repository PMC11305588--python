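"""Phase-plane demographic diagnostics for binned density series.

A density series (simulated trajectory binned per generation, or an
empirical mean-KDE curve in 30-year bins) is turned into a *phase path*:
ordered pairs of density against per-capita growth ln(v_{t+1}/v_t).  On
that path the macro-demographic signatures of interest are

* **demographic transition** — an inverse-V (or U) excursion: growth rises
  to a local peak and falls back while density gains ground;
* **cycle** — the path winds a full turn around a central density value;
* **overshoot / recession** — density exceeding the terminal equilibrium
  followed by an interval of negative growth (the "hook").

Detection thresholds are heuristic and configurable; defaults are chosen
so the simulator presets reproduce the expected qualitative counts.  All
detectors are invariant to uniform rescaling of density, since empirical
mean-KDE curves are in arbitrary units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import NoPositiveEquilibriumError, Trajectory, equilibrium_density

__all__ = [
    "DensitySeries",
    "PhasePath",
    "TransitionEvent",
    "CycleEvent",
    "RecessionSummary",
    "LogisticTrendFit",
    "per_capita_growth",
    "phase_path",
    "detect_transitions",
    "detect_cycles",
    "recession_summary",
    "fit_logistic_trend",
    "bin_trajectory",
]


@dataclass(frozen=True)
class DensitySeries:
    """Non-negative density estimates on a uniformly spaced axis."""

    bin_centers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bc = np.asarray(self.bin_centers, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "bin_centers", bc)
        object.__setattr__(self, "values", v)
        if bc.shape != v.shape or bc.ndim != 1:
            raise ValueError("bin_centers and values must be 1-D and equal length")
        if len(bc) < 3:
            raise ValueError("density series needs at least 3 bins")
        steps = np.diff(bc)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("bin centers must be uniformly spaced")
        if np.any(v < 0):
            raise ValueError("density values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class PhasePath:
    """Ordered (density, growth) pairs, oldest to youngest.

    ``indices`` maps each pair back to its bin in the source series;
    growth element t is attached to density element t, and the trailing
    bin (with no forward ratio) is dropped.  Pairs whose growth is
    undefined (zero density at either bin) are excluded.
    """

    density: np.ndarray
    growth: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.density) == len(self.growth) == len(self.indices)):
            raise ValueError("phase path arrays must share one length")
        if not (np.all(np.isfinite(self.density)) and np.all(np.isfinite(self.growth))):
            raise ValueError("phase path must contain finite values only")

    def __len__(self) -> int:
        return len(self.density)


@dataclass(frozen=True)
class TransitionEvent:
    """One inverse-V/U demographic-transition excursion on a phase path."""

    start: int
    peak: int
    end: int
    growth_at_peak: float
    density_start: float
    density_end: float


@dataclass(frozen=True)
class CycleEvent:
    """One full winding of the phase path around its (rolling) centroid."""

    start: int
    end: int
    center_density: float
    loop_count: int = 1


@dataclass(frozen=True)
class RecessionSummary:
    """Overshoot above the terminal equilibrium and time spent with f < 0."""

    overshoot: float
    negative_fitness_duration: float
    equilibrium: float


@dataclass(frozen=True)
class LogisticTrendFit:
    """Least-squares logistic trend v(t) = K / (1 + exp(-rho (t - t0)))."""

    capacity: float
    rate: float
    midpoint: float
    residual_variance: float
    converged: bool
    message: str = ""


def per_capita_growth(series: DensitySeries) -> np.ndarray:
    """Per-bin growth ln(v_{t+1} / v_t); one element fewer than the input.

    Elements needing a zero (or negative) density are NaN, with a warning —
    missingness is flagged, never fabricated.
    """
    v = series.values
    out = np.full(len(v) - 1, np.nan)
    valid = (v[:-1] > 0) & (v[1:] > 0)
    out[valid] = np.log(v[1:][valid] / v[:-1][valid])
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} growth element(s) undefined "
            "(zero density); flagged as NaN",
            stacklevel=2,
        )
    return out


def phase_path(series: DensitySeries) -> PhasePath:
    """Density-against-growth path in time order (oldest bin first)."""
    if len(series) < 3:
        raise ValueError("phase path needs at least 3 bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = per_capita_growth(series)
    keep = np.isfinite(g)
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} zero-density bin(s) from phase path",
            stacklevel=2,
        )
    idx = np.nonzero(keep)[0]
    return PhasePath(density=series.values[idx], growth=g[idx], indices=idx)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_transitions(
    path: PhasePath,
    smooth_window: int = 3,
    rise_threshold: float = 0.005,
    min_density_gain: float = 0.10,
) -> list[TransitionEvent]:
    """Find inverse-V/U growth excursions accompanying a density gain.

    After centered moving-average smoothing, a transition is a maximal
    interval on which smoothed growth rises by at least ``rise_threshold``
    to a local maximum and falls back by at least as much, while density
    gains at least ``min_density_gain`` (fractional) from start to end.
    Events are disjoint and returned oldest first; an empty list means
    nothing qualified.
    """
    if len(path) < 3:
        return []
    g = _smooth(path.growth, smooth_window)
    peaks, _ = find_peaks(g, prominence=rise_threshold)
    if len(peaks) == 0:
        return []
    # event bounds: the growth minima between consecutive peaks (and the
    # series ends), so events partition the axis and never overlap
    bounds = [int(np.argmin(g[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(g[a : b + 1])))
    bounds.append(int(peaks[-1] + np.argmin(g[peaks[-1] :])))
    events: list[TransitionEvent] = []
    prev_end = -1
    for k, peak in enumerate(peaks):
        start = max(bounds[k], prev_end)
        end = bounds[k + 1]
        if not (start < peak < end):
            continue
        rise = g[peak] - g[start]
        fall = g[peak] - g[end]
        if rise < rise_threshold or fall < rise_threshold:
            continue
        d0, d1 = path.density[start], path.density[end]
        if d0 <= 0 or (d1 - d0) / d0 < min_density_gain:
            continue
        events.append(
            TransitionEvent(
                start=start, peak=int(peak), end=end,
                growth_at_peak=float(g[peak]),
                density_start=float(d0), density_end=float(d1),
            )
        )
        prev_end = end
    return events


def detect_cycles(path: PhasePath, window: int | None = None) -> list[CycleEvent]:
    """Count full windings of the phase path around a rolling centroid.

    The signed rotation angle about the centroid (window-local mean of
    density and growth; global mean when ``window`` is None or exceeds the
    path length) is accumulated along the path; every accumulated 2π emits
    one :class:`CycleEvent` whose center is the mean density over the loop
    span.  Axes are rescaled to unit range first, so the winding count is
    invariant to the (arbitrary) density units.
    """
    n = len(path)
    if n < 4:
        return []
    # unit-range rescale for angle conditioning; winding count is unaffected
    d = path.density.astype(float)
    g = path.growth.astype(float)
    d_span = np.ptp(d) or 1.0
    g_span = np.ptp(g) or 1.0
    dn, gn = d / d_span, g / g_span
    if window is None or window >= n:
        cd = np.full(n, dn.mean())
        cg = np.full(n, gn.mean())
    else:
        kernel = np.ones(window)
        den = np.convolve(np.ones(n), kernel, mode="same")
        cd = np.convolve(dn, kernel, mode="same") / den
        cg = np.convolve(gn, kernel, mode="same") / den
    theta = np.arctan2(gn - cg, dn - cd)
    dtheta = np.diff(theta)
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    cum = np.concatenate([[0.0], np.cumsum(dtheta)])
    events: list[CycleEvent] = []
    loop_start = 0
    k = 0  # full turns emitted so far
    eps = 1e-9  # tolerate float round-off on exactly closed curves
    for i in range(1, n):
        while abs(cum[i]) >= (k + 1) * 2 * np.pi - eps:
            span = slice(loop_start, i + 1)
            events.append(
                CycleEvent(
                    start=loop_start,
                    end=i,
                    center_density=float(d[span].mean()),
                    loop_count=1,
                )
            )
            k += 1
            loop_start = i
    return events


def bin_trajectory(traj: Trajectory, bin_width: float = 1.0) -> DensitySeries:
    """Downsample a simulated trajectory to per-bin mean density.

    One bin per ``bin_width`` generations (default one generation, i.e.
    30 calendar years), producing the series on which the phase-plane
    diagnostics operate.
    """
    per = max(int(round(bin_width / traj.params.dt)), 1)
    n_bins = len(traj.p) // per
    vals = traj.p[: n_bins * per].reshape(n_bins, per).mean(axis=1)
    centers = traj.times[: n_bins * per].reshape(n_bins, per).mean(axis=1)
    return DensitySeries(bin_centers=centers, values=vals)


def recession_summary(traj: Trajectory) -> RecessionSummary:
    """Overshoot above the terminal regime's equilibrium, and time with f < 0.

    The reference equilibrium is the closed-form fixed point of the
    terminal regime at the long-run mean climate (Delta = 0).
    """
    params = traj.params
    C_end = params.climate.mean_at(float(traj.times[-1]))
    eq = equilibrium_density(params.r, params.S, traj.terminal_regime, C_end)
    overshoot = max(float(traj.p.max() - eq), 0.0)
    duration = float(np.count_nonzero(traj.f < 0) * params.dt)
    return RecessionSummary(
        overshoot=overshoot, negative_fitness_duration=duration, equilibrium=eq
    )


def _logistic(t: np.ndarray, K: float, rho: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-rho * (t - t0)))


def fit_logistic_trend(series: DensitySeries) -> LogisticTrendFit:
    """Least-squares logistic trend fit to a density series.

    Returns parameter estimates with the residual variance and a
    convergence flag; constant (or near-constant) input is reported as a
    degenerate, non-converged fit rather than a spurious optimum.
    """
    from scipy.optimize import curve_fit

    v = series.values.astype(float)
    if len(v) < 6:
        raise ValueError("logistic trend fit needs at least 6 bins")
    t = series.bin_centers - series.bin_centers[0]
    vmax = v.max()
    if vmax <= 0 or np.ptp(v) < 1e-12 * max(vmax, 1.0):
        return LogisticTrendFit(
            capacity=float(v.mean()), rate=0.0, midpoint=float(t.mean()),
            residual_variance=float(np.var(v)), converged=False,
            message="degenerate: series has no trend",
        )
    # initial guesses from a logit-linear regression
    K0 = 1.05 * vmax
    y = np.clip(v / K0, 1e-6, 1 - 1e-6)
    logit = np.log(y / (1 - y))
    slope, intercept = np.polyfit(t, logit, 1)
    rho0 = slope if abs(slope) > 1e-12 else 1e-3
    t00 = -intercept / rho0
    try:
        popt, _ = curve_fit(
            _logistic, t, v, p0=[K0, rho0, t00], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        return LogisticTrendFit(
            capacity=np.nan, rate=np.nan, midpoint=np.nan,
            residual_variance=np.nan, converged=False, message=str(exc),
        )
    resid = v - _logistic(t, *popt)
    return LogisticTrendFit(
        capacity=float(popt[0]),
        rate=float(popt[1]),
        midpoint=float(popt[2] + series.bin_centers[0]),
        residual_variance=float(np.var(resid)),
        converged=True,
    )
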