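"""CSV/JSON/YAML serialization for every artifact the package produces.

All CSVs are UTF-8 with a header row and dot decimals.  Schema problems
raise :class:`SchemaError` so callers (and the CLI) can distinguish
malformed input from unreadable files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ClimateModel, InfrastructureRegime, ISMParameters, Trajectory
from .diagnostics import CycleEvent, DensitySeries, TransitionEvent
from .paleodemo import DatedSample, MeanKDE

__all__ = [
    "SchemaError",
    "write_trajectory",
    "read_density_series",
    "write_density_series",
    "read_dated_samples",
    "write_dated_samples",
    "write_mean_kde",
    "read_intervention_table",
    "write_intervention_table",
    "events_to_json",
    "params_from_config",
    "params_to_config",
    "write_sidecar",
]


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for c in required:
        if c != "site" and not pd.api.types.is_numeric_dtype(df[c]):
            raise SchemaError(f"{path}: column {c!r} is not numeric")
    return df


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time": traj.times,
            "p": traj.p,
            "K": traj.K,
            "f": traj.f,
            "regime": traj.regime_index,
            "delta": traj.delta,
        }
    ).to_csv(path, index=False)


def read_density_series(path: str | Path) -> DensitySeries:
    df = _read_csv(path, ["bin_center", "density"])
    return DensitySeries(
        bin_centers=df["bin_center"].to_numpy(float),
        values=df["density"].to_numpy(float),
    )


def write_density_series(series: DensitySeries, path: str | Path) -> None:
    pd.DataFrame(
        {"bin_center": series.bin_centers, "density": series.values}
    ).to_csv(path, index=False)


def read_dated_samples(path: str | Path) -> list[DatedSample]:
    df = _read_csv(path, ["site", "age_calBP", "sigma"])
    return [
        DatedSample(site=str(r.site), age=float(r.age_calBP), sigma=float(r.sigma))
        for r in df.itertuples()
    ]


def write_dated_samples(samples: Sequence[DatedSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site": [s.site for s in samples],
            "age_calBP": [s.age for s in samples],
            "sigma": [s.sigma for s in samples],
        }
    ).to_csv(path, index=False)


def write_mean_kde(kde: MeanKDE, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_calBP": kde.bin_calBP,
            "mean_density": kde.mean,
            "lo95": kde.lo,
            "hi95": kde.hi,
        }
    ).to_csv(path, index=False)


def read_intervention_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(bin, response, covariate) arrays from an aligned 3-column CSV."""
    df = _read_csv(path, ["bin", "response", "covariate"])
    return (
        df["bin"].to_numpy(float),
        df["response"].to_numpy(float),
        df["covariate"].to_numpy(float),
    )


def write_intervention_table(
    bins: np.ndarray, response: np.ndarray, covariate: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"bin": bins, "response": response, "covariate": covariate}).to_csv(
        path, index=False
    )


def events_to_json(
    transitions: Sequence[TransitionEvent],
    cycles: Sequence[CycleEvent],
    series: DensitySeries | None = None,
    metadata: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Detected events as JSON-serializable records with bin centers attached."""

    def center(i: int) -> float | None:
        return float(series.bin_centers[i]) if series is not None else None

    return {
        "metadata": metadata or {},
        "transitions": [
            {**dataclasses.asdict(e), "start_center": center(e.start),
             "peak_center": center(e.peak), "end_center": center(e.end)}
            for e in transitions
        ],
        "cycles": [
            {**dataclasses.asdict(e), "start_center": center(e.start),
             "end_center": center(e.end)}
            for e in cycles
        ],
    }


def params_from_config(cfg: dict[str, Any] | str | Path) -> ISMParameters:
    """Build ISMParameters from a YAML file or an equivalent mapping."""
    if not isinstance(cfg, dict):
        with open(cfg, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise SchemaError("config must be a YAML mapping")
    cfg = dict(cfg)
    regimes = tuple(
        InfrastructureRegime(
            index=int(r.get("index", i + 1)), A=float(r["A"]), B=float(r["B"])
        )
        for i, r in enumerate(cfg.pop("regimes", [{"A": 0.0, "B": 0.0}]))
    )
    clim = dict(cfg.pop("climate", {}))
    climate = ClimateModel(
        C=float(clim.get("C", 1.0)),
        delta_amplitude=float(clim.get("delta_amplitude", 0.0)),
        noise=clim.get("noise", "gaussian"),
    )
    known = {f.name for f in dataclasses.fields(ISMParameters)}
    unknown = set(cfg) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return ISMParameters(regimes=regimes, climate=climate, **cfg)


def params_to_config(params: ISMParameters) -> dict[str, Any]:
    """ISMParameters as a plain mapping (YAML/JSON-ready)."""
    return {
        "r": params.r,
        "S": params.S,
        "d": params.d,
        "f_min": params.f_min,
        "p0": params.p0,
        "dt": params.dt,
        "horizon": params.horizon,
        "switching_mode": params.switching_mode,
        "regimes": [
            {"index": rg.index, "A": rg.A, "B": rg.B} for rg in params.regimes
        ],
        "climate": {
            "C": params.climate.C,
            "delta_amplitude": params.climate.delta_amplitude,
            "noise": params.climate.noise,
        },
    }


def write_sidecar(path: str | Path, **metadata: Any) -> None:
    """JSON metadata sidecar next to a data artifact (adds '.meta.json')."""
    from . import __version__

    out = Path(str(path) + ".meta.json")
    payload = {"software_version": __version__, **metadata}
    out.write_text(json.dumps(payload, indent=2, default=_jsonable), encoding="utf-8")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
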