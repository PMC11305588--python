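"""State equations of the ideal specialization model (ISM).

The ISM couples a delayed logistic population equation to a ladder of
"infrastructure regimes" — latent innovations that raise the carrying
capacity of a region — and to a stochastic climate term.  Density obeys

    dp/dt = r p - S p^2 / K,

so per-capita fitness f = dp/dt / p = r - S p / K falls linearly with
density.  The capacity constraint for the active regime i is

    K_i(t) = A_i - B_i p(t - d) + C + Delta(t),

where A_i is the productivity augmentation of the regime's infrastructure,
B_i its delayed density feedback, C the long-run mean climate suitability
and Delta(t) stochastic climate variability.  When fitness falls to the
population-pressure threshold f_min, the next rung of the ladder (the next
latent innovation) is adopted; absence of a further rung is the innovation
ceiling.

Everything here is a pure function of its arguments; the time-stepping
loop lives in :mod:`ismpop.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "InfrastructureRegime",
    "ClimateModel",
    "ISMParameters",
    "Trajectory",
    "DegenerateCapacityError",
    "NoPositiveEquilibriumError",
    "carrying_capacity",
    "fitness",
    "dpdt",
    "select_regime",
    "equilibrium_density",
]


class DegenerateCapacityError(ValueError):
    """Carrying capacity fell to zero or below; fitness is undefined."""


class NoPositiveEquilibriumError(ValueError):
    """No stable positive equilibrium exists for the given parameters."""


@dataclass(frozen=True)
class InfrastructureRegime:
    """One rung of the latent-innovation ladder.

    Parameters
    ----------
    index
        1-based ordinal position in the ladder.
    A
        Productivity augmentation of the infrastructure system
        (dimensionless, same scale as K).
    B
        Density-feedback coefficient, entering the capacity as
        ``-B * p(t - d)``.  May be negative, in which case density
        *raises* capacity under the literal sign convention.
    """

    index: int
    A: float
    B: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"regime index must be >= 1, got {self.index}")
        if not (math.isfinite(self.A) and math.isfinite(self.B)):
            raise ValueError("regime A and B must be finite")


@dataclass(frozen=True)
class ClimateModel:
    """Climate suitability: long-run mean C plus stochastic variability Delta(t).

    ``trend``, when given, maps time (generations) to a deterministic C(t)
    schedule (e.g. a stepwise doubling); otherwise C is constant.  Delta(t)
    is drawn i.i.d. once per whole generation with scale ``delta_amplitude``
    (Gaussian by default, uniform on ±amplitude*sqrt(3) as an option).
    """

    C: float = 1.0
    delta_amplitude: float = 0.0
    trend: Callable[[float], float] | None = None
    noise: Literal["gaussian", "uniform"] = "gaussian"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"mean suitability C must be > 0, got {self.C}")
        if self.delta_amplitude < 0:
            raise ValueError("delta_amplitude must be >= 0")

    def mean_at(self, t: float) -> float:
        """C(t): the trend schedule if present, otherwise the constant C."""
        if self.trend is None:
            return self.C
        c = float(self.trend(t))
        if c <= 0:
            raise ValueError(f"climate trend returned non-positive C({t}) = {c}")
        return c


@dataclass(frozen=True)
class ISMParameters:
    """Full configuration of one ISM run.

    Time is measured in generations (one generation maps to 30 calendar
    years when aligning with empirical 30-year bins).
    """

    r: float = 0.25
    S: float = 0.5
    d: float = 0.0
    f_min: float = 0.0
    regimes: Sequence[InfrastructureRegime] = field(
        default_factory=lambda: (InfrastructureRegime(1, 0.0, 0.0),)
    )
    climate: ClimateModel = field(default_factory=ClimateModel)
    p0: float = 0.01
    dt: float = 0.01
    horizon: float = 200.0
    switching_mode: Literal["literal", "ratchet"] = "literal"
    capacity_floor: float | None = None  # None: abort on K <= 0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if not (0 < self.S <= 1):
            raise ValueError(f"S must satisfy 0 < S <= 1, got {self.S}")
        if self.d < 0:
            raise ValueError("delay d must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.d > 0 and self.dt > self.d:
            raise ValueError("dt must not exceed the delay d (delay unresolvable)")
        if self.p0 <= 0:
            raise ValueError("p0 must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if len(self.regimes) < 1:
            raise ValueError("at least one infrastructure regime is required")
        if self.switching_mode not in ("literal", "ratchet"):
            raise ValueError(f"unknown switching_mode {self.switching_mode!r}")


@dataclass
class Trajectory:
    """Time-indexed record of a simulated run.

    All arrays share one uniform grid.  ``regime_index`` is the 1-based
    active rung; ``delta`` the realized climate noise.
    """

    times: np.ndarray
    p: np.ndarray
    K: np.ndarray
    f: np.ndarray
    regime_index: np.ndarray
    delta: np.ndarray
    params: ISMParameters
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("p", "K", "f", "regime_index", "delta"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trajectory series {name!r} length mismatch")

    @property
    def terminal_regime(self) -> InfrastructureRegime:
        return self.params.regimes[int(self.regime_index[-1]) - 1]

    @property
    def n_switches(self) -> int:
        """Number of regime changes along the run."""
        return int(np.count_nonzero(np.diff(self.regime_index)))


def carrying_capacity(
    regime: InfrastructureRegime,
    p_delayed: float,
    C_t: float,
    delta_t: float = 0.0,
    floor: float | None = None,
) -> float:
    """K_i(t) = A_i - B_i p(t-d) + (C + Delta(t)), with the literal sign convention.

    Parameters
    ----------
    floor
        If None (default), a result <= 0 raises
        :class:`DegenerateCapacityError`; otherwise the result is clamped
        at ``floor`` (which must be positive).
    """
    if C_t <= 0:
        raise ValueError(f"climate suitability must be > 0, got {C_t}")
    K = regime.A - regime.B * p_delayed + C_t + delta_t
    if K <= 0:
        if floor is None:
            raise DegenerateCapacityError(
                f"carrying capacity {K:.4g} <= 0 for regime {regime.index} "
                f"(A={regime.A}, B={regime.B}, p_delayed={p_delayed:.4g}, "
                f"C={C_t}, delta={delta_t:.4g})"
            )
        if floor <= 0:
            raise ValueError("capacity floor must be positive")
        return floor
    return K


def fitness(p: float, K: float, r: float, S: float) -> float:
    """Per-capita growth rate f = r - S p / K (1/generation)."""
    if K <= 0:
        raise DegenerateCapacityError(f"fitness undefined for K = {K} <= 0")
    if p < 0:
        raise ValueError(f"density must be >= 0, got {p}")
    return r - S * p / K

def dpdt(p: float, K: float, r: float, S: float) -> float:
    """Rate of density change r p - S p^2 / K; identically p * fitness(p, ...)."""
    if K <= 0:
        raise DegenerateCapacityError(f"dpdt undefined for K = {K} <= 0")
    if p < 0:
        raise ValueError(f"density must be >= 0, got {p}")
    return r * p - S * p * p / K


def select_regime(
    f: float,
    f_min: float,
    current: int,
    regimes: Sequence[InfrastructureRegime],
    mode: Literal["literal", "ratchet"] = "literal",
    max_reached: int | None = None,
) -> int:
    """Threshold rule for innovation adoption.

    Literal mode re-evaluates the threshold rule every step: while
    ``f_min < f`` (strict) the ladder steps down one rung (bounded at the
    first); once fitness reaches the pressure threshold (``f <= f_min``)
    the next rung is adopted, bounded by the ladder length — exhaustion is
    the innovation ceiling, never an error.  With a two-rung ladder this is
    exactly "if f_min < f then K1 else K2".

    Ratchet mode applies the same rule but never returns a rung below the
    highest reached so far (innovations, once adopted, persist).
    """
    n = len(regimes)
    if not (1 <= current <= n):
        raise ValueError(f"current rung {current} outside ladder of length {n}")
    if f_min < f:
        nxt = max(current - 1, 1)
    else:
        nxt = min(current + 1, n)
    if mode == "ratchet":
        hi = current if max_reached is None else max(max_reached, current)
        nxt = max(nxt, hi)
    return nxt


def equilibrium_density(
    r: float, S: float, regime: InfrastructureRegime, C: float
) -> float:
    """Stable positive equilibrium p* = r (A + C) / (S + r B).

    Solves f = 0 simultaneously with the capacity equation at Delta = 0 and
    p(t - d) = p*.  With B = 0 this is the familiar logistic equilibrium
    r K / S with K = A + C.
    """
    denom = S + r * regime.B
    num = regime.A + C
    if denom <= 0 or num <= 0:
        raise NoPositiveEquilibriumError(
            f"no positive equilibrium: S + r*B = {denom:.4g}, A + C = {num:.4g}"
        )
    return r * num / denom
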