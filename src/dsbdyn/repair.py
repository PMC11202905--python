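"""NHEJ repair as diffusion-annihilation of DSB ends.

Each end carries a kinetic state reflecting the sequential recruitment of
repair machinery: naked -> Ku70/80-bound -> DNA-PKcs-bound (long-range
synapsis-competent) -> ligated.  Transitions are memoryless with
configurable rates; ligation is irreversible and happens when two
synapsis-competent ends come within the capture radius (the synaptic
length scale, default 25 nm).  Repair of the whole end population is then a
pairwise annihilation reaction A + A -> 0 driven by the heterogeneous
motion of the ends, and the survival function

    S(t) = (unligated end count / 2) / initial DSB count

is the primary observable.  A join between non-partner ends is a misrepair;
if both joined fragments carry a centromere, the product is a dicentric
chromosome.

The NHEJ rate constants are calibration parameters (the recruitment
kinetics are not uniquely pinned by the motion model); the defaults here
are naked->ku 0.02 /s and ku->pkcs 0.005 /s, giving a mean lag of about
250 s before an end becomes joinable.  A ``minimal`` kinetics mode makes
every end immediately joinable — the configuration used for the pure
annihilation-kinetics oracles.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Sequence

import numpy as np
import yaml

from . import _engine
from .damage import BreakEnd, generate_genome, induce_damage
from .fgn import (
    STREAM_DAMAGE,
    STREAM_KINETICS,
    MotionParams,
    _as_generator,
    substream,
)
from .motion import Nucleus, end_displacements

__all__ = [
    "RepairState",
    "RepairKinetics",
    "JoinEvent",
    "DamageConfig",
    "SimulationConfig",
    "SimulationResult",
    "step_repair_states",
    "attempt_joins",
    "classify_join",
    "run_repair_simulation",
    "survival_time_grid",
    "save_event_log",
]

log = logging.getLogger(__name__)


class RepairState(IntEnum):
    NAKED = 0
    KU_BOUND = 1
    PKCS_BOUND = 2  # long-range synapsis-competent
    LIGATED = 3


CORRECT = "correct"
INTRA_MISREPAIR = "intra_misrepair"
INTER_MISREPAIR = "inter_misrepair"


@dataclass(frozen=True)
class RepairKinetics:
    """Recruitment rates and contact criterion for end joining.

    ``mode='full'`` runs the naked -> ku -> pkcs ladder; ``mode='minimal'``
    makes all ends immediately joinable.  ``dissociation_rate`` is a hook
    for synapse dissociation and defaults to 0 (joining irreversible).
    """

    rate_ku: float = 0.02  # naked -> ku_bound, 1/s
    rate_pkcs: float = 0.005  # ku_bound -> pkcs_bound, 1/s
    capture_radius: float = 25.0  # nm
    mode: str = "full"
    dissociation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be > 0")
        if self.rate_ku < 0 or self.rate_pkcs < 0:
            raise ValueError("rates must be >= 0")
        if self.mode not in ("full", "minimal"):
            raise ValueError("mode must be 'full' or 'minimal'")
        if self.dissociation_rate != 0.0:
            raise NotImplementedError("synapse dissociation is a hook; must be 0")


@dataclass(frozen=True)
class JoinEvent:
    """Irreversible ligation of two ends."""

    time: float
    end_a: int
    end_b: int
    category: str  # correct | intra_misrepair | inter_misrepair
    forms_dicentric: bool


def step_repair_states(
    ends: Sequence[BreakEnd], dt: float, kinetics: RepairKinetics, seed=None
) -> None:
    """Advance each non-ligated end's state by one step of length dt.

    Each transition fires independently with probability 1 - exp(-rate*dt)
    (the exact discretization of an exponential clock).  Ligated ends are
    absorbing.  Modifies ends in place.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = _as_generator(seed)
    if kinetics.mode == "minimal":
        for end in ends:
            if end.repair_state < RepairState.PKCS_BOUND:
                end.repair_state = int(RepairState.PKCS_BOUND)
        return
    p_ku = 1.0 - math.exp(-kinetics.rate_ku * dt)
    p_pkcs = 1.0 - math.exp(-kinetics.rate_pkcs * dt)
    u = rng.random(len(ends))
    for end, ui in zip(ends, u):
        if end.repair_state == RepairState.NAKED:
            if ui < p_ku:
                end.repair_state = int(RepairState.KU_BOUND)
        elif end.repair_state == RepairState.KU_BOUND:
            if ui < p_pkcs:
                end.repair_state = int(RepairState.PKCS_BOUND)


def classify_join(end_a: BreakEnd, end_b: BreakEnd) -> tuple[str, bool]:
    """Category of a ligation and whether it forms a dicentric.

    Correct = original partners; intra-chromosomal misrepair = same
    chromosome, not partners; inter-chromosomal misrepair otherwise.  A
    misjoin of two centromere-carrying fragments forms a dicentric.
    """
    if end_b.end_id == end_a.partner_end_id:
        return CORRECT, False
    category = (
        INTRA_MISREPAIR if end_a.chrom_id == end_b.chrom_id else INTER_MISREPAIR
    )
    return category, bool(end_a.has_centromere and end_b.has_centromere)


def attempt_joins(
    ends: Sequence[BreakEnd], capture_radius: float, time: float
) -> list[JoinEvent]:
    """Join synapsis-competent end pairs within the capture radius.

    Pairs are formed greedily in ascending distance order with a
    deterministic (end_id, end_id) tie-break; each join ligates both ends
    and emits one event.  Modifies ends in place.
    """
    from scipy.spatial import cKDTree

    eligible = [
        e for e in ends if e.repair_state == RepairState.PKCS_BOUND and e.joined_to is None
    ]
    if len(eligible) < 2:
        return []
    pos = np.array([e.position for e in eligible])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(capture_radius, output_type="ndarray")
    if pairs.size == 0:
        return []
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    ids = np.array([[eligible[i].end_id, eligible[j].end_id] for i, j in pairs])
    ids.sort(axis=1)
    order = np.lexsort((ids[:, 1], ids[:, 0], d))
    events: list[JoinEvent] = []
    for k in order:
        a, b = eligible[pairs[k, 0]], eligible[pairs[k, 1]]
        if a.joined_to is not None or b.joined_to is not None:
            continue
        if a.end_id > b.end_id:
            a, b = b, a
        category, dicentric = classify_join(a, b)
        a.joined_to, b.joined_to = b.end_id, a.end_id
        a.repair_state = int(RepairState.LIGATED)
        b.repair_state = int(RepairState.LIGATED)
        events.append(JoinEvent(time, a.end_id, b.end_id, category, dicentric))
    return events


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DamageConfig:
    yield_per_gy: float = 35.0  # DSB per Gy per cell
    n_chromosomes: int = 46
    placement: str = "uniform"
    end_offset_nm: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one repair simulation.

    Defaults correspond to the heterogeneous-FBM (HFBM) model: subdiffusion
    with alpha = 0.5 (H = 0.25) and K_alpha = 20 nm^2/s^0.5, interrupted by
    directed runs at v = 16 nm/s switched at mu0 = 0.001 /s / mu1 = 0.016 /s,
    for 24 h of repair.  Set ``motion.mu0 = 0`` for the FBM-only variant.
    """

    dose_gy: float = 1.0
    t_max_s: float = 86400.0
    dt_s: float = 1.0
    motion: MotionParams = field(
        default_factory=lambda: MotionParams(
            alpha=0.5, k_alpha=20.0, v=16.0, mu0=0.001, mu1=0.016
        )
    )
    direction_mode: str = "isotropic3d"
    nucleus: Nucleus = field(default_factory=Nucleus)
    kinetics: RepairKinetics = field(default_factory=RepairKinetics)
    damage: DamageConfig = field(default_factory=DamageConfig)
    n_repeats: int = 200
    survival_points_per_decade: int = 32

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError("dose_gy must be >= 0")
        if self.t_max_s <= 0:
            raise ValueError("t_max_s must be > 0")
        if self.motion.dt != self.dt_s:
            object.__setattr__(self, "motion", self.motion.replace(dt=self.dt_s))

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max_s / self.dt_s))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nucleus"]["center"] = list(self.nucleus.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "motion" in d and isinstance(d["motion"], dict):
            m = {k: v for k, v in d["motion"].items() if k != "n_steps"}
            d["motion"] = MotionParams(n_steps=1, **m)
        if "nucleus" in d and isinstance(d["nucleus"], dict):
            d["nucleus"] = Nucleus(**d["nucleus"])
        if "kinetics" in d and isinstance(d["kinetics"], dict):
            d["kinetics"] = RepairKinetics(**d["kinetics"])
        if "damage" in d and isinstance(d["damage"], dict):
            d["damage"] = DamageConfig(**d["damage"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimulationResult:
    """One realization: survival samples, join events, final end states."""

    times: np.ndarray  # survival sample times (log grid, 0 prepended), s
    survival: np.ndarray  # S(t) at those times
    events: list[JoinEvent]
    n_dsb: int
    final_states: np.ndarray  # RepairState codes per end
    seed: int | None = None

    def dicentrics(self, at_time: float | None = None) -> int:
        return sum(
            1
            for ev in self.events
            if ev.forms_dicentric and (at_time is None or ev.time <= at_time)
        )


def survival_time_grid(
    dt: float, t_max: float, points_per_decade: int = 32
) -> np.ndarray:
    """Logarithmic sample grid for S(t), with t = 0 prepended."""
    n_decades = math.log10(t_max / dt)
    n_pts = max(2, int(round(points_per_decade * n_decades)) + 1)
    grid = np.logspace(math.log10(dt), math.log10(t_max), n_pts)
    return np.concatenate([[0.0], grid])


def _eligibility_steps(
    n_ends: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pre-sampled step index at which each end becomes synapsis-competent.

    Equivalent in distribution to iterating ``step_repair_states``: with a
    per-step success probability p = 1 - exp(-rate*dt) the waiting time in
    steps is geometric, and the ladder naked -> ku -> pkcs is the sum of two
    independent geometric variates.
    """
    if config.kinetics.mode == "minimal":
        return np.zeros(n_ends, dtype=np.int64)
    dt = config.dt_s
    out = np.zeros(n_ends, dtype=np.int64)
    for rate in (config.kinetics.rate_ku, config.kinetics.rate_pkcs):
        if rate <= 0:
            return np.full(n_ends, np.iinfo(np.int64).max // 2, dtype=np.int64)
        p = 1.0 - math.exp(-rate * dt)
        out += rng.geometric(p, n_ends)
    return out


def run_repair_simulation(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run one cell realization of damage induction, motion and repair.

    The loop over t = 0 .. t_max advances every unligated end by its
    precomputed displacement increment (fGn + active runs), reflects at the
    nuclear envelope, and joins synapsis-competent pairs on contact.  All
    randomness derives from ``seed`` through per-end substreams, so the
    result is reproducible and independent of iteration order.
    """
    grid = survival_time_grid(
        config.dt_s, config.t_max_s, config.survival_points_per_decade
    )
    genome = generate_genome(config.damage.n_chromosomes)
    ends = induce_damage(
        genome,
        config.dose_gy,
        config.nucleus,
        yield_per_gy=config.damage.yield_per_gy,
        seed=substream(seed, 0, STREAM_DAMAGE),
        end_offset_nm=config.damage.end_offset_nm,
        placement=config.damage.placement,
    )
    n_dsb = len(ends) // 2
    if n_dsb == 0:
        warnings.warn("no DSBs induced; survival reported as 1 by convention")
        return SimulationResult(
            grid, np.ones_like(grid), [], 0, np.empty(0, dtype=int), seed
        )

    m = len(ends)
    n_steps = config.n_steps
    params = config.motion.replace(n_steps=n_steps)
    disp = np.empty((m, n_steps, 3))
    for i, end in enumerate(ends):
        disp[i] = end_displacements(
            params, n_steps, seed, end.end_id, config.direction_mode
        )
    eligible = _eligibility_steps(m, config, substream(seed, 0, STREAM_KINETICS))

    pos0 = np.array([e.position for e in ends])
    ncell = _engine.choose_ncell(m, config.nucleus.radius, config.kinetics.capture_radius)
    cx, cy, cz = config.nucleus.center
    join_step, partner, n_clamped = _engine.simulate_annihilation(
        pos0,
        disp,
        eligible,
        float(config.nucleus.radius),
        cx,
        cy,
        cz,
        config.kinetics.capture_radius,
        ncell,
    )
    if n_clamped:
        log.warning("%d pathological steps clamped to the nuclear surface", n_clamped)

    events: list[JoinEvent] = []
    for i in range(m):
        j = int(partner[i])
        if j < 0 or j < i:
            continue
        a, b = ends[i], ends[j]
        t_join = (int(join_step[i]) + 1) * config.dt_s
        category, dicentric = classify_join(a, b)
        a.joined_to, b.joined_to = b.end_id, a.end_id
        a.repair_state = int(RepairState.LIGATED)
        b.repair_state = int(RepairState.LIGATED)
        events.append(JoinEvent(t_join, a.end_id, b.end_id, category, dicentric))
    events.sort(key=lambda ev: (ev.time, ev.end_a))

    join_times = np.array([ev.time for ev in events])
    survival = 1.0 - np.searchsorted(join_times, grid, side="right") / n_dsb
    final_states = np.array([e.repair_state for e in ends])
    # ends never ligated: report their kinetic ladder position at t_max
    for i, end in enumerate(ends):
        if end.joined_to is None and config.kinetics.mode == "full":
            if eligible[i] <= n_steps:
                final_states[i] = int(RepairState.PKCS_BOUND)
    return SimulationResult(grid, survival, events, n_dsb, final_states, seed)


def run_annihilation_oracle(
    n_ends: int = 2000,
    radius: float = 1000.0,
    d_coeff: float = 2000.0,
    dt: float = 1.0,
    n_steps: int = 2000,
    capture_radius: float = 25.0,
    seed: int | None = None,
    points_per_decade: int = 32,
) -> SimulationResult:
    """Brownian diffusion-annihilation reference: A + A -> 0 in a sphere.

    ``n_ends`` independent Brownian walkers (diffusion coefficient
    ``d_coeff`` in the MSD = 6 D t convention) start uniformly in a
    reflecting sphere and annihilate pairwise on contact within the capture
    radius, with no kinetic lag.  In 3D the long-time survival of this
    reaction decays as S(t) ~ 1/t — the classical benchmark against which
    the subdiffusive repair survival is compared.

    Ends here are unpaired walkers, so the survival is the surviving *end*
    fraction: S(t) = alive ends / initial ends.
    """
    rng = _as_generator(seed)
    sigma = math.sqrt(2.0 * d_coeff * dt)  # per-dimension step std
    vec = rng.standard_normal((n_ends, 3))
    vec /= np.maximum(np.linalg.norm(vec, axis=1, keepdims=True), 1e-300)
    pos0 = vec * (radius * rng.random(n_ends)[:, None] ** (1.0 / 3.0))
    disp = rng.standard_normal((n_ends, n_steps, 3)) * sigma
    eligible = np.zeros(n_ends, dtype=np.int64)
    ncell = _engine.choose_ncell(n_ends, radius, capture_radius)
    join_step, partner, _ = _engine.simulate_annihilation(
        pos0, disp, eligible, float(radius), 0.0, 0.0, 0.0, capture_radius, ncell
    )
    grid = survival_time_grid(dt, n_steps * dt, points_per_decade)
    joined = np.sort(join_step[join_step >= 0] + 1) * dt
    survival = 1.0 - np.searchsorted(joined, grid, side="right") / n_ends
    events = [
        JoinEvent((int(join_step[i]) + 1) * dt, i, int(partner[i]), INTER_MISREPAIR, False)
        for i in range(n_ends)
        if partner[i] >= 0 and partner[i] > i
    ]
    states = np.where(
        join_step >= 0, int(RepairState.LIGATED), int(RepairState.PKCS_BOUND)
    )
    return SimulationResult(grid, survival, events, n_ends // 2, states, seed)


def save_event_log(path, events: Sequence[JoinEvent], header: str | None = None) -> None:
    """Delimited export: time_s, end_a, end_b, category, forms_dicentric."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("time_s\tend_a\tend_b\tcategory\tforms_dicentric\n")
        for ev in events:
            fh.write(
                f"{ev.time:.6g}\t{ev.end_a}\t{ev.end_b}\t{ev.category}\t"
                f"{int(ev.forms_dicentric)}\n"
            )
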