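"""Forward integration of the ISM and the canonical experiment presets.

The integrator is fixed-step explicit Euler with a delay buffer read by
linear interpolation (history before t = 0 is the constant p0).  Climate
noise Delta(t) is redrawn once per whole generation and held constant
within it, so a run is bit-reproducible from (parameters, seed).

Three preset families mirror the standard numerical experiments on this
model:

* ``set1_climate_ladder`` — no innovations, pressure undetectable
  (f_min = 0), mean climate suitability doubling every ~33.3 generations
  (1000 years at 30 yr/generation): expansion driven by climate alone.
* ``set1_innovation_ladder`` — constant climate, a four-rung ladder of
  successively more productive infrastructure (ratchet mode, f_min = 0.1):
  expansion driven by repeated innovation, three demographic transitions.
* ``set2_A_sweep`` / ``set2_C_sweep`` — a two-rung ladder with delayed
  density feedback (d = 25) and an innovation ceiling: overshoot and
  recession growing with the productivity jump A and with mean climate C.
* ``set3_stochastic`` — pressure undetectable (f_min = 0) plus short-term
  climate noise: variability, not detection, triggers the innovation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import (
    ClimateModel,
    InfrastructureRegime,
    ISMParameters,
    Trajectory,
    carrying_capacity,
    dpdt,
    fitness,
    select_regime,
)

__all__ = ["simulate", "run_preset", "preset_parameters", "PRESET_NAMES"]

#: calendar years per model generation, used to map climate schedules
YEARS_PER_GENERATION = 30.0


def _draw_deltas(climate: ClimateModel, n_generations: int, rng: np.random.Generator) -> np.ndarray:
    if climate.delta_amplitude == 0.0:
        return np.zeros(n_generations)
    if climate.noise == "gaussian":
        return rng.normal(0.0, climate.delta_amplitude, size=n_generations)
    # uniform with matching standard deviation
    half = climate.delta_amplitude * math.sqrt(3.0)
    return rng.uniform(-half, half, size=n_generations)


def simulate(params: ISMParameters, seed: int | None = None) -> Trajectory:
    """Integrate the ISM forward and return the full gridded trajectory.

    Each step: read the delayed density from the history buffer, evaluate
    the active regime's carrying capacity and the instantaneous fitness,
    apply the threshold rule (possibly switching rungs, in which case K
    and f are re-evaluated under the adopted rung), then take one Euler
    step of dp/dt = r p − S p²/K.

    Raises
    ------
    DegenerateCapacityError
        If capacity falls to <= 0 and ``params.capacity_floor`` is None.
    FloatingPointError
        If the state becomes non-finite (message carries the step index).
    """
    dt = params.dt
    n = int(round(params.horizon / dt)) + 1
    times = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    n_gen = int(math.floor(times[-1])) + 1
    deltas = _draw_deltas(params.climate, n_gen, rng)

    p = np.empty(n)
    K = np.empty(n)
    f = np.empty(n)
    regime_idx = np.empty(n, dtype=np.int64)
    delta_out = np.empty(n)

    p[0] = params.p0
    current = 1
    max_reached = 1
    regimes = params.regimes
    r, S, d = params.r, params.S, params.d
    floor = params.capacity_floor

    for i in range(n):
        t = times[i]
        # delayed density: history before t=0 is p0
        s = t - d
        if s <= 0.0:
            p_del = params.p0
        else:
            j = s / dt
            j0 = int(j)
            frac = j - j0
            p_del = p[j0] if frac == 0.0 or j0 + 1 >= i + 1 else (
                (1.0 - frac) * p[j0] + frac * p[j0 + 1]
            )
        C_t = params.climate.mean_at(t)
        dlt = deltas[min(int(t), n_gen - 1)]
        K_i = carrying_capacity(regimes[current - 1], p_del, C_t, dlt, floor=floor)
        f_i = fitness(p[i], K_i, r, S)
        chosen = select_regime(
            f_i, params.f_min, current, regimes,
            mode=params.switching_mode, max_reached=max_reached,
        )
        if chosen != current:
            current = chosen
            max_reached = max(max_reached, current)
            K_i = carrying_capacity(regimes[current - 1], p_del, C_t, dlt, floor=floor)
            f_i = fitness(p[i], K_i, r, S)
        K[i] = K_i
        f[i] = f_i
        regime_idx[i] = current
        delta_out[i] = dlt
        if i + 1 < n:
            p_next = p[i] + dt * dpdt(p[i], K_i, r, S)
            if not math.isfinite(p_next):
                raise FloatingPointError(
                    f"non-finite density at step {i + 1} (t = {times[i + 1]:.3f})"
                )
            p[i + 1] = max(p_next, 0.0)

    return Trajectory(
        times=times, p=p, K=K, f=f,
        regime_index=regime_idx, delta=delta_out,
        params=params, seed=seed,
    )


# ---------------------------------------------------------------------------
# presets


def _doubling_schedule(base: float, every_generations: float, n_doublings: int):
    """Stepwise C(t): doubles every `every_generations`, capped after n_doublings."""

    def trend(t: float) -> float:
        k = min(int(t // every_generations), n_doublings)
        return base * (2.0 ** k)

    return trend


def _set1_climate_ladder() -> list[ISMParameters]:
    # pressure undetectable, no innovations; suitability doubles every
    # 1000 calendar years = 1000/30 generations, over three millennia
    trend = _doubling_schedule(1.0, 1000.0 / YEARS_PER_GENERATION, 2)
    return [
        ISMParameters(
            r=0.25, S=1.0, d=0.0, f_min=0.0,
            regimes=(InfrastructureRegime(1, 0.0, 0.0),),
            climate=ClimateModel(C=1.0, trend=trend),
            p0=0.01, dt=0.01, horizon=100.0,
        )
    ]


def _set1_innovation_ladder() -> list[ISMParameters]:
    # each rung doubles total capacity A + C: K = 1, 2, 4, 8
    ladder = tuple(
        InfrastructureRegime(i + 1, float(a), 0.0) for i, a in enumerate((0, 1, 3, 7))
    )
    return [
        ISMParameters(
            r=0.25, S=1.0, d=0.0, f_min=0.1,
            regimes=ladder,
            climate=ClimateModel(C=1.0),
            p0=0.01, dt=0.01, horizon=150.0,
            switching_mode="ratchet",
        )
    ]


def _two_rung(A: float, B2: float = 0.3) -> tuple[InfrastructureRegime, ...]:
    # B2 enters the capacity as -B2*p(t-d): positive B2 degrades K with density
    return (InfrastructureRegime(1, 0.0, 0.0), InfrastructureRegime(2, A, B2))


def _set2_A_sweep() -> list[ISMParameters]:
    return [
        ISMParameters(
            r=0.25, S=0.5, d=25.0, f_min=0.1,
            regimes=_two_rung(A),
            climate=ClimateModel(C=1.0),
            p0=0.01, dt=0.01, horizon=400.0,
            switching_mode="ratchet",
        )
        for A in (0.5, 1.0, 2.0, 3.0)
    ]


def _set2_C_sweep() -> list[ISMParameters]:
    return [
        ISMParameters(
            r=0.25, S=0.5, d=25.0, f_min=0.1,
            regimes=_two_rung(0.5),
            climate=ClimateModel(C=C),
            p0=0.01, dt=0.01, horizon=400.0,
            switching_mode="ratchet",
        )
        for C in (1.0, 2.0, 3.0)
    ]


def _set3_stochastic(delta_amplitude: float = 0.01) -> list[ISMParameters]:
    return [
        ISMParameters(
            r=0.25, S=0.5, d=25.0, f_min=0.0,
            regimes=_two_rung(0.5),
            climate=ClimateModel(C=C, delta_amplitude=delta_amplitude),
            p0=0.01, dt=0.01, horizon=400.0,
            switching_mode="literal",
        )
        for C in (1.0, 3.0)
    ]


_PRESETS = {
    "set1_climate_ladder": _set1_climate_ladder,
    "set1_innovation_ladder": _set1_innovation_ladder,
    "set2_A_sweep": _set2_A_sweep,
    "set2_C_sweep": _set2_C_sweep,
    "set3_stochastic": _set3_stochastic,
}

PRESET_NAMES = tuple(_PRESETS)


def preset_parameters(name: str) -> list[ISMParameters]:
    """The parameter grid of a named preset (one ISMParameters per run)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}"
        ) from None


def run_preset(name: str, seed: int = 0) -> list[Trajectory]:
    """Run every grid point of a named preset; one trajectory per point.

    Stochastic presets derive one child seed per grid point from ``seed``
    so runs are independent but jointly reproducible.
    """
    grid = preset_parameters(name)
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    return [
        simulate(params, seed=int(ss.generate_state(1)[0] % (2**31)))
        for params, ss in zip(grid, seeds)
    ]
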