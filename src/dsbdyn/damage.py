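"""Synthetic radiation damage: DSB induction, fragments, centromeres, SDD I/O.

Initial damage for a simulated cell is drawn here rather than taken from a
track-structure code: the DSB count is Poisson with mean ``dose *
yield_per_gy`` and positions are uniform in the nuclear sphere (a track-like
placer clustering DSBs along random chords is available as a plug-in for
sensitivity studies).  Genomic bookkeeping uses a normalized karyotype —
each chromosome has unit genomic length and one centromere — because the
dicentric logic only needs to know which fragment of a broken chromosome
carries the centromere.

A minimal dialect of the Standard DNA Damage (SDD) interchange format is
supported for reading/writing initial damage: a ``key=value`` header block
terminated by ``***EndOfHeader***`` followed by one comma-separated record
per damage site (``type,chrom_id,locus,x_nm,y_nm,z_nm``).  Records whose
type is not ``DSB`` (e.g. SSB, BD) are skipped with a logged count.  Full
SDD compliance is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fgn import _as_generator
from .motion import Nucleus

__all__ = [
    "ChromosomeModel",
    "BreakEnd",
    "REPAIR_STATE_NAKED",
    "generate_genome",
    "sample_dsb_count",
    "induce_damage",
    "read_sdd",
    "write_sdd",
    "save_damage_table",
    "SddParseError",
]

log = logging.getLogger(__name__)

# Repair-state codes; the enum view lives in dsbdyn.repair.RepairState.
REPAIR_STATE_NAKED = 0

LEFT, RIGHT = "left", "right"


@dataclass(frozen=True)
class ChromosomeModel:
    """One chromosome: normalized genomic length and a single centromere."""

    chrom_id: int
    genomic_length: float = 1.0
    centromere_locus: float = 0.5

    def __post_init__(self) -> None:
        if self.genomic_length <= 0:
            raise ValueError("genomic_length must be > 0")
        if not 0.0 < self.centromere_locus < self.genomic_length:
            raise ValueError(
                "centromere_locus must lie strictly inside (0, genomic_length)"
            )


@dataclass
class BreakEnd:
    """One free end of a double-strand break.

    ``fragment_interval`` is the genomic interval of the chromosome fragment
    this end belongs to, given *all* breaks on its chromosome, and
    ``has_centromere`` flags whether that fragment contains the centromere —
    the ingredient of the dicentric criterion (a misjoin of two
    centromere-carrying ends forms a dicentric chromosome).
    """

    end_id: int
    dsb_id: int
    partner_end_id: int
    chrom_id: int
    break_locus: float
    side: str  # LEFT or RIGHT of the break point
    fragment_interval: tuple[float, float]
    has_centromere: bool
    position: np.ndarray
    repair_state: int = REPAIR_STATE_NAKED
    joined_to: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.side not in (LEFT, RIGHT):
            raise ValueError("side must be 'left' or 'right'")


def generate_genome(
    n_chromosomes: int = 46,
    centromere_loci: Sequence[float] | None = None,
    genomic_length: float = 1.0,
) -> list[ChromosomeModel]:
    """Normalized karyotype: ``n_chromosomes`` chromosomes of unit length.

    Default 46 chromosomes with the centromere at locus 0.5; per-chromosome
    centromere loci may be overridden with a list of matching length.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if centromere_loci is None:
        centromere_loci = [0.5 * genomic_length] * n_chromosomes
    if len(centromere_loci) != n_chromosomes:
        raise ValueError(
            f"centromere_loci has length {len(centromere_loci)}, "
            f"expected {n_chromosomes}"
        )
    return [
        ChromosomeModel(cid, genomic_length, float(locus))
        for cid, locus in enumerate(centromere_loci)
    ]


def sample_dsb_count(dose: float, yield_per_gy: float, seed=None) -> int:
    """Poisson DSB count with mean ``dose * yield_per_gy`` (per cell)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if yield_per_gy < 0:
        raise ValueError("yield_per_gy must be >= 0")
    rng = _as_generator(seed)
    return int(rng.poisson(dose * yield_per_gy))


def _uniform_in_sphere(rng: np.random.Generator, n: int, nucleus: Nucleus) -> np.ndarray:
    vec = rng.standard_normal((n, 3))
    vec /= np.maximum(np.linalg.norm(vec, axis=1, keepdims=True), 1e-300)
    r = nucleus.radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(nucleus.center) + vec * r[:, None]


def _track_placer(rng: np.random.Generator, n: int, nucleus: Nucleus) -> np.ndarray:
    """Plug-in placer clustering DSBs along random chords (track-like)."""
    center = np.asarray(nucleus.center)
    out = np.empty((n, 3))
    placed = 0
    while placed < n:
        a = _uniform_in_sphere(rng, 1, nucleus)[0]
        b = _uniform_in_sphere(rng, 1, nucleus)[0]
        k = min(n - placed, int(rng.poisson(5)) + 1)
        frac = rng.random(k)[:, None]
        pts = a + frac * (b - a)
        out[placed : placed + k] = pts
        placed += k
    return out


_PLACERS: dict[str, Callable] = {"uniform": _uniform_in_sphere, "track": _track_placer}


def _assign_fragments(
    ends: list[BreakEnd], genome: Sequence[ChromosomeModel]
) -> None:
    """Recompute fragment intervals and centromere flags from all breaks.

    Breaks on a chromosome of length L at sorted loci b_1 < ... < b_k
    partition (0, L) into fragments (0, b_1), (b_1, b_2), ..., (b_k, L); the
    left end of break b_i belongs to the fragment ending at b_i and the
    right end to the fragment starting at b_i.  Exactly one fragment per
    broken chromosome contains the centromere.
    """
    chrom_map = {c.chrom_id: c for c in genome}
    by_chrom: dict[int, list[BreakEnd]] = {}
    for end in ends:
        by_chrom.setdefault(end.chrom_id, []).append(end)
    for cid, chrom_ends in by_chrom.items():
        chrom = chrom_map[cid]
        loci = sorted({e.break_locus for e in chrom_ends})
        bounds = [0.0] + loci + [chrom.genomic_length]
        for end in chrom_ends:
            i = loci.index(end.break_locus)
            if end.side == LEFT:
                interval = (bounds[i], bounds[i + 1])
            else:
                interval = (bounds[i + 1], bounds[i + 2])
            end.fragment_interval = interval
            end.has_centromere = bool(
                interval[0] < chrom.centromere_locus < interval[1]
            )


def induce_damage(
    genome: Sequence[ChromosomeModel],
    dose: float,
    nucleus: Nucleus,
    yield_per_gy: float = 35.0,
    seed=None,
    end_offset_nm: float = 10.0,
    placement: str | Callable = "uniform",
) -> list[BreakEnd]:
    """Draw the initial DSB set for one cell at the given dose.

    Each DSB gets a uniformly random chromosome, a uniformly random break
    locus, and a spatial position from the chosen placer; its two ends are
    co-located up to ``end_offset_nm`` (a small symmetric separation that
    avoids zero-distance immediate-rejoin artifacts; 0 is allowed).
    Fragment intervals and centromere flags are computed from the complete
    break set per chromosome.
    """
    rng = _as_generator(seed)
    n_dsb = sample_dsb_count(dose, yield_per_gy, rng)
    if n_dsb == 0:
        return []
    placer = _PLACERS[placement] if isinstance(placement, str) else placement
    centers = placer(rng, n_dsb, nucleus)
    chrom_ids = rng.integers(0, len(genome), n_dsb)
    loci = rng.random(n_dsb)
    offsets = rng.standard_normal((n_dsb, 3))
    offsets /= np.maximum(np.linalg.norm(offsets, axis=1, keepdims=True), 1e-300)
    offsets *= end_offset_nm / 2.0

    from .motion import apply_boundary

    ends: list[BreakEnd] = []
    for d in range(n_dsb):
        chrom = genome[int(chrom_ids[d])]
        locus = float(loci[d]) * chrom.genomic_length
        for side, sign in ((LEFT, -1.0), (RIGHT, +1.0)):
            eid = 2 * d + (0 if side == LEFT else 1)
            # the end offset can nudge a surface-adjacent end outside; reflect
            pos = apply_boundary(centers[d] + sign * offsets[d], nucleus)
            ends.append(
                BreakEnd(
                    end_id=eid,
                    dsb_id=d,
                    partner_end_id=2 * d + (1 if side == LEFT else 0),
                    chrom_id=chrom.chrom_id,
                    break_locus=locus,
                    side=side,
                    fragment_interval=(0.0, chrom.genomic_length),
                    has_centromere=False,
                    position=pos,
                )
            )
    _assign_fragments(ends, genome)
    return ends


# ---------------------------------------------------------------------------
# Minimal SDD dialect
# ---------------------------------------------------------------------------

_SDD_HEADER_END = "***EndOfHeader***"


class SddParseError(ValueError):
    pass


def write_sdd(path, ends: Sequence[BreakEnd], header: dict | None = None) -> None:
    """Write one record per DSB (position = midpoint of its two ends)."""
    by_dsb: dict[int, list[BreakEnd]] = {}
    for end in ends:
        by_dsb.setdefault(end.dsb_id, []).append(end)
    with open(path, "w") as fh:
        fh.write("format=dsbdyn-sdd-minimal-1\n")
        for key, val in (header or {}).items():
            fh.write(f"{key}={val}\n")
        fh.write(_SDD_HEADER_END + "\n")
        for dsb_id in sorted(by_dsb):
            pair = by_dsb[dsb_id]
            pos = np.mean([e.position for e in pair], axis=0)
            e0 = pair[0]
            fh.write(
                f"DSB,{e0.chrom_id},{e0.break_locus:.12g},"
                f"{pos[0]:.6g},{pos[1]:.6g},{pos[2]:.6g}\n"
            )


def read_sdd(
    path,
    genome: Sequence[ChromosomeModel] | None = None,
    end_offset_nm: float = 0.0,
) -> list[BreakEnd]:
    """Read a minimal-dialect SDD file into BreakEnd pairs.

    Non-DSB records are skipped (count logged).  Fragment intervals and
    centromere flags are recomputed against ``genome`` (default: the
    standard 46-chromosome normalized genome).
    """
    if genome is None:
        genome = generate_genome()
    chrom_map = {c.chrom_id: c for c in genome}
    records: list[tuple[int, float, np.ndarray]] = []
    n_skipped = 0
    with open(path) as fh:
        in_header = True
        saw_header_end = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if in_header:
                if line == _SDD_HEADER_END:
                    in_header = False
                    saw_header_end = True
                    continue
                if "=" not in line:
                    raise SddParseError(
                        f"{path}: line {lineno}: malformed header line {line!r}"
                    )
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 6:
                raise SddParseError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(parts)}"
                )
            rtype = parts[0].upper()
            if rtype != "DSB":
                n_skipped += 1
                continue
            try:
                cid = int(parts[1])
                locus = float(parts[2])
                pos = np.array([float(parts[3]), float(parts[4]), float(parts[5])])
            except ValueError as exc:
                raise SddParseError(f"{path}: line {lineno}: {exc}") from exc
            if cid not in chrom_map:
                raise SddParseError(
                    f"{path}: line {lineno}: unknown chromosome id {cid}"
                )
            records.append((cid, locus, pos))
    if not saw_header_end:
        raise SddParseError(f"{path}: missing {_SDD_HEADER_END} line")
    if n_skipped:
        log.info("read_sdd: skipped %d non-DSB damage record(s)", n_skipped)

    rng = np.random.default_rng(0)  # offset directions only; 0 offset by default
    ends: list[BreakEnd] = []
    for d, (cid, locus, pos) in enumerate(records):
        if end_offset_nm > 0:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
        else:
            direction = np.zeros(3)
        for side, sign in ((LEFT, -1.0), (RIGHT, +1.0)):
            ends.append(
                BreakEnd(
                    end_id=2 * d + (0 if side == LEFT else 1),
                    dsb_id=d,
                    partner_end_id=2 * d + (1 if side == LEFT else 0),
                    chrom_id=cid,
                    break_locus=locus,
                    side=side,
                    fragment_interval=(0.0, chrom_map[cid].genomic_length),
                    has_centromere=False,
                    position=pos + sign * direction * end_offset_nm / 2.0,
                )
            )
    _assign_fragments(ends, genome)
    return ends


def save_damage_table(path, ends: Sequence[BreakEnd]) -> None:
    """Delimited export: dsb_id, chrom_id, locus, x_nm, y_nm, z_nm (per DSB)."""
    by_dsb: dict[int, list[BreakEnd]] = {}
    for end in ends:
        by_dsb.setdefault(end.dsb_id, []).append(end)
    with open(path, "w") as fh:
        fh.write("dsb_id\tchrom_id\tlocus\tx_nm\ty_nm\tz_nm\n")
        for dsb_id in sorted(by_dsb):
            pair = by_dsb[dsb_id]
            pos = np.mean([e.position for e in pair], axis=0)
            e0 = pair[0]
            fh.write(
                f"{dsb_id}\t{e0.chrom_id}\t{e0.break_locus:.12g}\t"
                f"{pos[0]:.6g}\t{pos[1]:.6g}\t{pos[2]:.6g}\n"
            )
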