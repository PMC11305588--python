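"""Mean kernel-density demography on calendar-age samples.

Estimates a relative population-density curve from a set of dated samples
(site label, calendar age in cal BP, 1-sigma age uncertainty) the way
radiocarbon-based paleodemography builds "mean KDEs": dates are clustered
within site to control for oversampled sites, one date per cluster is
drawn per iteration with its age perturbed by its Gaussian uncertainty, a
fixed-bandwidth Gaussian KDE is evaluated on an annual grid, the
iteration KDEs are averaged and summed into 30-year bins, and the ends of
the window are trimmed against edge effects.

Calendar ages with Gaussian uncertainty stand in for calibrated
radiocarbon determinations: calibration itself (curve, reservoir effects)
is out of scope, so a "calibrated sample" is modeled as Normal(age,
sigma).  ``mean_kde`` accepts an ``age_sampler`` hook for arbitrary
per-sample age distributions should calibrated densities become
available.

Axis convention: cal BP, larger = older; bins run old to young
(descending cal BP).  Use :meth:`MeanKDE.to_forward_series` before
feeding the curve to the phase-plane diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .diagnostics import DensitySeries

__all__ = [
    "DatedSample",
    "MeanKDE",
    "cluster_dates",
    "mean_kde",
    "synthetic_dates",
    "DEFAULT_WINDOW",
    "DEFAULT_TRIM",
]

#: construction window (old, young) in cal BP, and the trimmed analysis window
DEFAULT_WINDOW = (4000.0, 200.0)
DEFAULT_TRIM = (3700.0, 300.0)


@dataclass(frozen=True)
class DatedSample:
    """One dated sample: site label, calendar age (cal BP), 1-sigma error."""

    site: str
    age: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("age uncertainty sigma must be >= 0")


@dataclass(frozen=True)
class MeanKDE:
    """Binned mean density curve with its iteration envelope.

    ``bin_calBP`` descends (older to younger).  ``lo``/``hi`` are the
    2.5th/97.5th percentiles of the per-iteration binned KDEs.
    """

    bin_calBP: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_iterations: int
    bandwidth: float
    cluster_h: float

    def __post_init__(self) -> None:
        n = len(self.bin_calBP)
        if not (len(self.mean) == len(self.lo) == len(self.hi) == n):
            raise ValueError("mean KDE arrays must share one length")
        if np.any(self.mean < 0):
            raise ValueError("densities must be non-negative")
        if np.any(self.lo > self.hi + 1e-12):
            raise ValueError("envelope lower bound exceeds upper bound")

    def to_forward_series(self) -> DensitySeries:
        """Re-index to forward time (oldest bin first) for diagnostics."""
        order = np.argsort(-self.bin_calBP)
        # forward-time axis: generations before the youngest bin, ascending
        centers = self.bin_calBP[order]
        return DensitySeries(bin_centers=-centers, values=self.mean[order])


def cluster_dates(samples: Sequence[DatedSample], h: float = 100.0) -> list[list[int]]:
    """Group sample indices by site, then single-linkage on age cut at height h.

    Samples from different sites never share a cluster.  Empty input gives
    an empty clustering.
    """
    if h <= 0:
        raise ValueError("cluster cut height h must be > 0")
    by_site: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_site.setdefault(s.site, []).append(i)
    clusters: list[list[int]] = []
    for site in sorted(by_site):
        idx = by_site[site]
        site_clusters: list[list[int]]
        if len(idx) == 1:
            site_clusters = [idx]
        else:
            ages = np.array([[samples[i].age] for i in idx])
            labels = fcluster(
                linkage(ages, method="single"), t=h, criterion="distance"
            )
            site_clusters = [
                [idx[j] for j in np.nonzero(labels == lab)[0]]
                for lab in np.unique(labels)
            ]
        # canonical order (by age within and across clusters) so downstream
        # bootstrap draws do not depend on input sample order
        for c in site_clusters:
            c.sort(key=lambda i: (samples[i].age, samples[i].sigma))
        site_clusters.sort(key=lambda c: samples[c[0]].age)
        clusters.extend(site_clusters)
    return clusters


def mean_kde(
    samples: Sequence[DatedSample],
    n_iter: int = 200,
    bandwidth: float = 50.0,
    bin_width: float = 30.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
    trim: tuple[float, float] | None = DEFAULT_TRIM,
    h: float = 100.0,
    seed: int | None = None,
    age_sampler: Callable[[DatedSample, np.random.Generator], float] | None = None,
) -> MeanKDE:
    """Clustered-bootstrap mean KDE of a set of dated samples.

    Per iteration: one sample is drawn uniformly from each site/age
    cluster, its age perturbed by Normal(0, sigma) (or by ``age_sampler``),
    and a Gaussian KDE with the stated bandwidth (years) is evaluated on a
    1-year grid spanning ``window``, normalized to integrate to 1 over
    that (untrimmed) grid.  Iterations are averaged, grid density is
    summed into ``bin_width``-year bins, and the bins are trimmed to
    ``trim``.  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    old, young = window
    if old <= young:
        raise ValueError("window must be (older, younger) in cal BP")
    clusters = cluster_dates(samples, h=h)
    if not clusters:
        raise ValueError("no samples to estimate from")
    rng = np.random.default_rng(seed)
    grid = np.arange(young, old + 1.0)  # 1-year resolution, ascending cal BP

    n_bins = int((old - young) // bin_width)
    # bins laid old -> young: [old, old-30), [old-30, old-60), ...
    edges_old = old - bin_width * np.arange(n_bins + 1)
    centers = (edges_old[:-1] + edges_old[1:]) / 2.0

    binned = np.empty((n_iter, n_bins))
    mean_grid = np.zeros_like(grid)
    for it in range(n_iter):
        ages = np.empty(len(clusters))
        for c, members in enumerate(clusters):
            s = samples[members[rng.integers(len(members))]]
            if age_sampler is not None:
                ages[c] = age_sampler(s, rng)
            else:
                ages[c] = s.age + (rng.normal(0.0, s.sigma) if s.sigma > 0 else 0.0)
        dens = np.exp(
            -0.5 * ((grid[:, None] - ages[None, :]) / bandwidth) ** 2
        ).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi) * len(ages))
        total = np.trapezoid(dens, grid)
        if total > 0:
            dens = dens / total
        mean_grid += dens
        # sum grid density within each 30-year bin (old -> young)
        which = np.clip(((old - grid) // bin_width).astype(int), 0, n_bins - 1)
        binned[it] = np.bincount(which, weights=dens, minlength=n_bins)
    mean_grid /= n_iter

    mean_b = binned.mean(axis=0)
    lo = np.percentile(binned, 2.5, axis=0)
    hi = np.percentile(binned, 97.5, axis=0)

    if trim is not None:
        t_old, t_young = trim
        keep = (centers <= t_old) & (centers >= t_young)
        centers, mean_b, lo, hi = centers[keep], mean_b[keep], lo[keep], hi[keep]

    return MeanKDE(
        bin_calBP=centers, mean=mean_b, lo=lo, hi=hi,
        n_iterations=n_iter, bandwidth=bandwidth, cluster_h=h,
    )


def synthetic_dates(
    curve: DensitySeries,
    n: int,
    n_sites: int = 50,
    sigma_range: tuple[float, float] = (20.0, 60.0),
    seed: int | None = None,
) -> list[DatedSample]:
    """Draw dated samples from an occupation curve, with site oversampling.

    Ages come from inverse-CDF sampling of the normalized curve
    (``curve.bin_centers`` interpreted as cal BP).  Sites are assigned by
    preferential attachment — each new sample joins a site with
    probability proportional to one plus the site's current sample count —
    so some sites end up heavily oversampled, stress-testing the
    within-site clustering.  Age uncertainties are uniform in
    ``sigma_range``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = curve.values.astype(float)
    if w.sum() <= 0:
        raise ValueError("occupation curve is identically zero")
    rng = np.random.default_rng(seed)
    # piecewise-linear inverse CDF on bin centers
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    u = rng.random(n)
    pos = np.searchsorted(cdf, u)
    ages = curve.bin_centers[pos] + (rng.random(n) - 0.5) * curve.bin_width

    site_counts = np.ones(n_sites)
    sigmas = rng.uniform(*sigma_range, size=n)
    out = []
    for i in range(n):
        j = rng.choice(n_sites, p=site_counts / site_counts.sum())
        site_counts[j] += 1.0
        out.append(DatedSample(site=f"site{j:03d}", age=float(ages[i]), sigma=float(sigmas[i])))
    return out
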