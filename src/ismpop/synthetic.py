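"""Synthetic scenario factory with machine-readable ground truth.

Every detector and estimator in the package can be scored against one of
these scenarios without hand-derived expectations: each generator returns
its data together with a ground-truth record (true change points, true
equilibria, true cycle count, true injected lift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .diagnostics import DensitySeries

__all__ = [
    "ScenarioSpec",
    "DensityScenario",
    "InterventionScenario",
    "make_density_scenario",
    "make_intervention_scenario",
    "DENSITY_SCENARIOS",
]

DENSITY_SCENARIOS = (
    "logistic",
    "two_epoch_jump",
    "damped_oscillation",
    "bimodal_occupation",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario with its effect parameters; the seed is mandatory."""

    scenario: str
    n: int = 120
    seed: int = 0
    noise_sd: float = 0.0  # additive Gaussian, as a fraction of signal range
    jump_ratio: float = 2.0  # capacity ratio of epoch 2 to epoch 1
    jump_bin: int | None = None  # default: n // 2
    lift: float = 0.5  # multiplicative post-intervention lift (0.5 = +50%)
    ar_coef: float = 0.8
    beta: float = 1.0
    # damped_oscillation: oscillation periods in the window; intended < 1
    # (a partial-loop "hook"); decaying spirals with more periods wind fewer
    # full turns about a fixed centroid than their period count
    n_cycles: float = 0.8
    split_bin: int | None = None  # intervention: default n * 3 // 5


@dataclass(frozen=True)
class DensityScenario:
    series: DensitySeries
    truth: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class InterventionScenario:
    response: np.ndarray
    covariate: np.ndarray
    pre_window: tuple[int, int]
    post_window: tuple[int, int]
    truth: dict[str, Any] = field(default_factory=dict)


def _logistic_curve(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def make_density_scenario(spec: ScenarioSpec) -> DensityScenario:
    """Build a density series with known structure plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    t = np.arange(n, dtype=float)
    truth: dict[str, Any] = {"scenario": spec.scenario}

    if spec.scenario == "logistic":
        K, r, t0 = 1.0, 0.15, n / 3.0
        v = _logistic_curve(t, K, r, t0)
        truth.update(capacity=K, rate=r, midpoint=t0, n_transitions=0, n_cycles=0)
    elif spec.scenario == "two_epoch_jump":
        jump = spec.jump_bin if spec.jump_bin is not None else n // 2
        K1 = 1.0
        K2 = K1 * spec.jump_ratio
        r = 0.25
        v = np.empty(n)
        v[:jump] = _logistic_curve(t[:jump], K1, r, jump / 3.0)
        # second logistic epoch continues from the epoch-1 endpoint
        p = v[jump - 1]
        for i in range(jump, n):
            p = p + r * p * (1 - p / K2)
            v[i] = p
        truth.update(
            capacity_1=K1, capacity_2=K2, jump_bin=jump, n_transitions=1, n_cycles=0
        )
    elif spec.scenario == "damped_oscillation":
        eq, amp, decay = 1.0, 0.6, 3.0 / n
        omega = 2 * np.pi * spec.n_cycles / n
        v = eq + amp * np.exp(-decay * t) * np.cos(omega * t + np.pi)
        v = np.clip(v, 1e-6, None)
        truth.update(equilibrium=eq, n_full_cycles=int(spec.n_cycles), hook=True)
    elif spec.scenario == "bimodal_occupation":
        # occupation curve over cal BP: two Gaussian pulses inside 4000-200
        axis = np.arange(3985.0, 200.0, -30.0)
        v = np.exp(-0.5 * ((axis - 3000.0) / 300.0) ** 2) + 1.4 * np.exp(
            -0.5 * ((axis - 1200.0) / 250.0) ** 2
        )
        t = axis
        truth.update(modes_calBP=(3000.0, 1200.0), n_modes=2)
    else:
        raise ValueError(f"unknown density scenario {spec.scenario!r}")

    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd * np.ptp(v), size=len(v))
        v = np.clip(v, 0.0, None)
    return DensityScenario(series=DensitySeries(bin_centers=t, values=v), truth=truth)


def make_intervention_scenario(spec: ScenarioSpec) -> InterventionScenario:
    """Covariate-driven response with a multiplicative post-split lift.

    Covariate: smooth AR(1) (coefficient ``spec.ar_coef``).  Response:
    constant level + beta * covariate + Gaussian noise, multiplied by
    (1 + lift) from the split bin onward.  The truth record echoes the
    lift in percent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    split = spec.split_bin if spec.split_bin is not None else n * 3 // 5
    if not (10 <= split < n):
        raise ValueError("split bin leaves too short a pre window")
    x = np.empty(n)
    innov = rng.normal(0.0, 1.0, size=n)
    x[0] = innov[0]
    for i in range(1, n):
        x[i] = spec.ar_coef * x[i - 1] + np.sqrt(1 - spec.ar_coef**2) * innov[i]
    level = 10.0
    signal = level + spec.beta * x
    noise = rng.normal(0.0, spec.noise_sd * np.ptp(signal) if spec.noise_sd > 0 else 0.0, n)
    y = signal + noise
    y[split:] *= 1.0 + spec.lift
    return InterventionScenario(
        response=y,
        covariate=x,
        pre_window=(0, split),
        post_window=(split, n),
        truth={"lift_percent": 100.0 * spec.lift, "split_bin": split, "beta": spec.beta},
    )
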