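"""Numba kernels: sequential reflected walks and pairwise annihilation.

These are internal work-horses behind :mod:`dsbdyn.motion` and
:mod:`dsbdyn.repair`.  Positions advance by precomputed per-step
displacement increments (fGn plus any active-run contribution, folded
together beforehand), are reflected radially at the spherical boundary, and
eligible end pairs within the capture radius are joined greedily in
ascending-distance order with an end-index tie-break.  Neighbour search uses
a per-step cell list sized so that binning and pair checking balance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["walk_reflect", "simulate_annihilation", "choose_ncell"]


@njit(cache=True, inline="always")
def _reflect(x, y, z, cx, cy, cz, radius):
    """Radial mirror reflection at a sphere; clamps pathological overshoots.

    Returns (x, y, z, clamped) with clamped = 1 when the point lay more than
    one radius outside the surface and was clamped onto it.
    """
    dx = x - cx
    dy = y - cy
    dz = z - cz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d <= radius:
        return x, y, z, 0
    if d >= 2.0 * radius:
        s = radius / d
        return cx + dx * s, cy + dy * s, cz + dz * s, 1
    s = (2.0 * radius - d) / d
    return cx + dx * s, cy + dy * s, cz + dz * s, 0


@njit(cache=True)
def walk_reflect(origin, disp, radius, cx, cy, cz):
    """Sequential walk from origin through per-step displacements.

    disp has shape (n_steps, 3).  A non-finite radius disables the boundary.
    Returns (positions (n_steps+1, 3), n_clamped).
    """
    n = disp.shape[0]
    pos = np.empty((n + 1, 3))
    x, y, z = origin[0], origin[1], origin[2]
    pos[0, 0], pos[0, 1], pos[0, 2] = x, y, z
    bounded = np.isfinite(radius)
    nclamp = 0
    for s in range(n):
        x += disp[s, 0]
        y += disp[s, 1]
        z += disp[s, 2]
        if bounded:
            x, y, z, cl = _reflect(x, y, z, cx, cy, cz, radius)
            nclamp += cl
        pos[s + 1, 0], pos[s + 1, 1], pos[s + 1, 2] = x, y, z
    return pos, nclamp


def choose_ncell(n_ends: int, radius: float, capture_radius: float) -> int:
    """Cells per axis: ~cbrt(5*m) total cells, but cells never narrower than
    the capture radius (so one neighbour shell suffices)."""
    if not np.isfinite(radius):
        return 1
    target = max(1, int(round((5.0 * max(n_ends, 1)) ** (1.0 / 3.0))))
    return int(max(1, min(target, int(2.0 * radius / capture_radius))))


@njit(cache=True)
def simulate_annihilation(
    pos0, disp, eligible_step, radius, cx, cy, cz, capture_radius, ncell
):
    """Advance all ends and join eligible pairs on contact, irreversibly.

    Parameters
    ----------
    pos0 : (m, 3) initial positions.
    disp : (m, n_steps, 3) per-step displacement increments per end.
    eligible_step : (m,) step index from which an end may join (1-based step
        count; 0 = immediately eligible).
    radius, cx, cy, cz : reflecting sphere (radius may be inf).
    capture_radius : contact distance for joining, nm.
    ncell : cells per axis for the neighbour grid (>= 1).

    Returns
    -------
    join_step : (m,) 0-based step index at which each end joined, -1 if never.
    partner : (m,) index of the end it joined, -1 if never.
    n_clamped : number of pathological boundary clamps.
    """
    m = pos0.shape[0]
    n = disp.shape[1]
    pos = pos0.copy()
    alive = np.ones(m, np.bool_)
    join_step = -np.ones(m, np.int64)
    partner = -np.ones(m, np.int64)
    bounded = np.isfinite(radius)
    capsq = capture_radius * capture_radius
    nclamp = 0

    ncell3 = ncell * ncell * ncell
    cell = (2.0 * radius / ncell) if bounded else 0.0
    counts = np.zeros(ncell3 + 1, np.int64)
    sorted_ids = np.empty(m, np.int64)
    cand = np.empty(m, np.int64)
    cand_cell = np.empty(m, np.int64)
    maxpairs = 8 * m + 16
    pair_i = np.empty(maxpairs, np.int64)
    pair_j = np.empty(maxpairs, np.int64)
    pair_d = np.empty(maxpairs, np.float64)

    for s in range(n):
        for i in range(m):
            if alive[i]:
                x = pos[i, 0] + disp[i, s, 0]
                y = pos[i, 1] + disp[i, s, 1]
                z = pos[i, 2] + disp[i, s, 2]
                if bounded:
                    x, y, z, cl = _reflect(x, y, z, cx, cy, cz, radius)
                    nclamp += cl
                pos[i, 0], pos[i, 1], pos[i, 2] = x, y, z

        # candidates: alive and repair-state eligible after this step
        ne = 0
        for i in range(m):
            if alive[i] and eligible_step[i] <= s + 1:
                cand[ne] = i
                ne += 1
        if ne < 2:
            continue

        npairs = 0
        if ncell3 <= 1 or not bounded:
            # brute force over candidates
            for a in range(ne):
                i = cand[a]
                for b in range(a + 1, ne):
                    j = cand[b]
                    ddx = pos[i, 0] - pos[j, 0]
                    ddy = pos[i, 1] - pos[j, 1]
                    ddz = pos[i, 2] - pos[j, 2]
                    dsq = ddx * ddx + ddy * ddy + ddz * ddz
                    if dsq <= capsq and npairs < maxpairs:
                        pair_i[npairs] = i
                        pair_j[npairs] = j
                        pair_d[npairs] = dsq
                        npairs += 1
        else:
            for k in range(ncell3 + 1):
                counts[k] = 0
            for a in range(ne):
                i = cand[a]
                ix = int((pos[i, 0] - cx + radius) / cell)
                iy = int((pos[i, 1] - cy + radius) / cell)
                iz = int((pos[i, 2] - cz + radius) / cell)
                if ix < 0:
                    ix = 0
                elif ix >= ncell:
                    ix = ncell - 1
                if iy < 0:
                    iy = 0
                elif iy >= ncell:
                    iy = ncell - 1
                if iz < 0:
                    iz = 0
                elif iz >= ncell:
                    iz = ncell - 1
                cid = (ix * ncell + iy) * ncell + iz
                cand_cell[a] = cid
                counts[cid + 1] += 1
            for k in range(ncell3):
                counts[k + 1] += counts[k]
            # counting sort candidate ids by cell
            for a in range(ne):
                cid = cand_cell[a]
                sorted_ids[counts[cid]] = cand[a]
                counts[cid] += 1
            # counts[cid] now holds end offset; start offset = counts[cid-1]
            for a in range(ne):
                i = cand[a]
                cid = cand_cell[a]
                iz = cid % ncell
                iy = (cid // ncell) % ncell
                ix = cid // (ncell * ncell)
                for ddx_c in range(-1, 2):
                    jx = ix + ddx_c
                    if jx < 0 or jx >= ncell:
                        continue
                    for ddy_c in range(-1, 2):
                        jy = iy + ddy_c
                        if jy < 0 or jy >= ncell:
                            continue
                        for ddz_c in range(-1, 2):
                            jz = iz + ddz_c
                            if jz < 0 or jz >= ncell:
                                continue
                            cjd = (jx * ncell + jy) * ncell + jz
                            lo = counts[cjd - 1] if cjd > 0 else 0
                            hi = counts[cjd]
                            for b in range(lo, hi):
                                j = sorted_ids[b]
                                if j <= i:
                                    continue
                                ddx = pos[i, 0] - pos[j, 0]
                                ddy = pos[i, 1] - pos[j, 1]
                                ddz = pos[i, 2] - pos[j, 2]
                                dsq = ddx * ddx + ddy * ddy + ddz * ddz
                                if dsq <= capsq and npairs < maxpairs:
                                    pair_i[npairs] = i
                                    pair_j[npairs] = j
                                    pair_d[npairs] = dsq
                                    npairs += 1

        if npairs == 0:
            continue
        # insertion sort by (distance, i, j): npairs is small
        for a in range(1, npairs):
            di, ii, jj = pair_d[a], pair_i[a], pair_j[a]
            b = a - 1
            while b >= 0 and (
                pair_d[b] > di
                or (pair_d[b] == di and (pair_i[b] > ii or (pair_i[b] == ii and pair_j[b] > jj)))
            ):
                pair_d[b + 1] = pair_d[b]
                pair_i[b + 1] = pair_i[b]
                pair_j[b + 1] = pair_j[b]
                b -= 1
            pair_d[b + 1] = di
            pair_i[b + 1] = ii
            pair_j[b + 1] = jj
        for a in range(npairs):
            i = pair_i[a]
            j = pair_j[a]
            if alive[i] and alive[j]:
                alive[i] = False
                alive[j] = False
                join_step[i] = s
                join_step[j] = s
                partner[i] = j
                partner[j] = i

    return join_step, partner, nclamp
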