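"""Aggregate repair realizations into survival curves and dose-response.

One realization = one cell.  The survival function S(t) is averaged
pointwise across repeats on the shared logarithmic grid; "dicentrics per
cell" counts dicentric-forming join events (not reconstructed karyotypes)
up to the scoring time, averaged across realizations.  Power-law exponents
are read off log-log least-squares fits over a late-time window, default
1-10 h, after the fast initial partner-rejoining transient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fgn import derive_seed, fit_powerlaw
from .repair import SimulationConfig, SimulationResult, run_repair_simulation

__all__ = [
    "SurvivalCurve",
    "DoseResponse",
    "survival_curve",
    "dicentrics_per_cell",
    "dose_response",
    "fit_survival_exponent",
    "run_repeats",
]

DEFAULT_FIT_WINDOW = (3600.0, 36000.0)  # 1-10 h


@dataclass
class SurvivalCurve:
    """Mean survival of unrepaired DSBs across repeats."""

    times: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_repeats: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.times.shape == self.mean.shape == self.se.shape):
            raise ValueError("times, mean, se must share shape")
        if np.any(self.mean < -1e-12) or np.any(self.mean > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "survival": self.mean, "se": self.se}
        )


@dataclass
class DoseResponse:
    """Mean dicentrics per cell at the scoring time, per dose."""

    doses: np.ndarray  # Gy
    mean: np.ndarray
    se: np.ndarray
    n_repeats: int
    at_time: float  # s

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.mean < 0):
            raise ValueError("means must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.doses, "dicentrics_per_cell": self.mean, "se": self.se}
        )


def survival_curve(results: Sequence[SimulationResult]) -> SurvivalCurve:
    """Pointwise mean and standard error of S(t) across realizations."""
    if not results:
        raise ValueError("need at least one realization")
    t0 = results[0].times
    for res in results:
        if res.times.shape != t0.shape or not np.allclose(res.times, t0):
            raise ValueError("all realizations must share the survival time grid")
    mat = np.stack([res.survival for res in results])
    mean = mat.mean(axis=0)
    if len(results) > 1:
        se = mat.std(axis=0, ddof=1) / math.sqrt(len(results))
    else:
        se = np.zeros_like(mean)  # single realization: SE 0 by convention
    return SurvivalCurve(t0, mean, se, len(results))


def dicentrics_per_cell(
    results: Sequence[SimulationResult], at_time: float
) -> tuple[float, float]:
    """Mean and SE of dicentric-forming events per realization up to at_time."""
    counts = np.array([res.dicentrics(at_time) for res in results], dtype=float)
    mean = float(counts.mean()) if counts.size else 0.0
    se = (
        float(counts.std(ddof=1) / math.sqrt(counts.size)) if counts.size > 1 else 0.0
    )
    return mean, se


def run_repeats(
    config: SimulationConfig, n_repeats: int, seed: int, dose_index: int = 0
) -> list[SimulationResult]:
    """Run independent realizations with deterministically derived sub-seeds."""
    return [
        run_repair_simulation(config, derive_seed(seed, dose_index, rep))
        for rep in range(n_repeats)
    ]


def dose_response(
    config: SimulationConfig,
    doses: Sequence[float],
    n_repeats: int,
    seed: int,
    at_time: float | None = None,
) -> DoseResponse:
    """Dicentric dose-response: repeats per dose, scored at 24 h by default."""
    from dataclasses import replace

    doses = list(doses)
    if not doses:
        raise ValueError("doses must be non-empty")
    at_time = config.t_max_s if at_time is None else at_time
    if at_time > config.t_max_s:
        raise ValueError("at_time must not exceed t_max_s")
    means, ses = [], []
    for di, dose in enumerate(doses):
        cfg = replace(config, dose_gy=float(dose))
        results = run_repeats(cfg, n_repeats, seed, dose_index=di)
        mean, se = dicentrics_per_cell(results, at_time)
        means.append(mean)
        ses.append(se)
    return DoseResponse(np.array(doses), np.array(means), np.array(ses), n_repeats, at_time)


def fit_survival_exponent(
    curve: SurvivalCurve, window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> float:
    """Log-log slope of mean S(t) over the window (negative for decay).

    Grid points where the mean survival has reached 0 are excluded (a power
    law cannot pass through zero); at least 3 positive points must remain.
    """
    mask = curve.mean > 0
    return fit_powerlaw(curve.times[mask], curve.mean[mask], window).exponent


def table_header(config: SimulationConfig, seed, extra: dict | None = None) -> str:
    """JSON-style run-metadata block for embedding as table header comments."""
    from . import __version__

    meta = {"config": config.to_dict(), "seed": seed, "version": __version__}
    meta.update(extra or {})
    return json.dumps(meta, default=str)
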