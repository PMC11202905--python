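"""Heterogeneous Langevin motion of DSB ends inside a reflecting nucleus.

The discrete update for one end is

    r(t + dt) = reflect( r(t) + xi_fGn(t) + I(t) * v * d(t) * dt )

where ``xi_fGn`` are exact fGn increments (module :mod:`dsbdyn.fgn`), ``I``
is the two-state indicator and ``d`` the per-active-phase unit direction
(module :mod:`dsbdyn.switching`), and ``reflect`` mirrors radially at a
spherical nuclear envelope.  Reflection acts on the position only — the
stored noise stream is never redrawn, so the long-range correlation
structure of the noise is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _engine
from .fgn import (
    STREAM_SWITCH,
    MotionParams,
    Trajectory3D,
    fgn_increments_3d,
    substream,
)
from .switching import simulate_two_state

__all__ = ["Nucleus", "apply_boundary", "simulate_end_trajectory", "end_displacements"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Nucleus:
    """Spherical nuclear envelope with a reflecting boundary.

    Default radius 4600 nm — a typical mammalian fibroblast nucleus scale.
    """

    radius: float = 4600.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.boundary != "reflecting":
            raise ValueError("only a reflecting boundary is supported")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def contains(self, position) -> bool | np.ndarray:
        pos = np.asarray(position, dtype=float)
        d = np.linalg.norm(pos - np.asarray(self.center), axis=-1)
        # tiny tolerance: reflected points may sit on the surface
        return d <= self.radius * (1.0 + 1e-12)


def apply_boundary(position, nucleus: Nucleus):
    """Map positions outside the sphere back inside by radial reflection.

    A point at radial distance R + delta (delta < R) maps to R - delta on
    the same ray; interior points are untouched.  A pathological point more
    than one radius outside the surface is clamped to the surface and a
    warning is logged.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float)).copy()
    center = np.asarray(nucleus.center)
    rel = pos - center
    d = np.linalg.norm(rel, axis=-1)
    outside = d > nucleus.radius
    if np.any(outside):
        far = d >= 2.0 * nucleus.radius
        if np.any(far):
            log.warning(
                "%d position(s) more than one radius outside the nucleus; "
                "clamped to the surface", int(np.sum(far)),
            )
        scale = np.ones_like(d)
        mirror = outside & ~far
        scale[mirror] = (2.0 * nucleus.radius - d[mirror]) / d[mirror]
        scale[far] = nucleus.radius / d[far]
        pos = center + rel * scale[:, None]
    return pos[0] if np.asarray(position).ndim == 1 else pos


def end_displacements(
    params: MotionParams,
    n_steps: int,
    seed: int | None,
    end_id: int,
    direction_mode: str = "isotropic3d",
) -> np.ndarray:
    """Per-step displacement increments (n_steps, 3) for one end.

    fGn noise increments plus, when the switching process is enabled
    (mu0 > 0 and v > 0), the folded-in active contribution I * v * d * dt.
    Substreams are keyed on (seed, end_id), so ends are independent and the
    result does not depend on simulation order.
    """
    disp = fgn_increments_3d(params, n_steps, seed, end_id)
    if params.mu0 > 0 and params.v > 0:
        trace = simulate_two_state(
            params.mu0,
            params.mu1,
            n_steps * params.dt,
            seed=substream(seed, end_id, STREAM_SWITCH),
            direction_mode=direction_mode,
        )
        disp += trace.step_velocities(params.v, n_steps, params.dt)
    return disp


def simulate_end_trajectory(
    params: MotionParams,
    origin: Sequence[float],
    nucleus: Nucleus,
    t_max: float,
    seed: int | None = None,
    end_id: int = 0,
    direction_mode: str = "isotropic3d",
) -> Trajectory3D:
    """Integrate one DSB end over [0, t_max] inside the nucleus.

    With ``mu0 = 0`` and an unbounded nucleus this reproduces
    :func:`dsbdyn.fgn.generate_fbm_3d` bit for bit (same substreams, same
    accumulation order).
    """
    origin = np.asarray(origin, dtype=float)
    if math.isfinite(nucleus.radius) and not nucleus.contains(origin):
        raise ValueError("origin must lie inside the nucleus")
    n_steps = int(round(t_max / params.dt))
    if n_steps < 1:
        raise ValueError("t_max must cover at least one time step")
    disp = end_displacements(params, n_steps, seed, end_id, direction_mode)
    cx, cy, cz = nucleus.center
    positions, n_clamped = _engine.walk_reflect(
        origin, disp, float(nucleus.radius), cx, cy, cz
    )
    if n_clamped:
        log.warning("%d pathological steps clamped to the nuclear surface", n_clamped)
    times = np.arange(n_steps + 1) * params.dt
    return Trajectory3D(times, positions)
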