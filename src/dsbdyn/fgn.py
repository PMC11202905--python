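"""Fractional Gaussian noise and 3D fractional Brownian motion.

The passive mobility of a double-strand-break (DSB) end is modelled as an
overdamped Langevin particle driven by fractional Gaussian noise (fGn): the
position increments over a uniform time grid form a stationary Gaussian
process with power-law correlated increments.  The normalization convention
used throughout the package is

    3D ensemble MSD  <r^2(t)> = 6 * K_alpha * t**alpha,

so each Cartesian component contributes ``2 * K_alpha * t**alpha`` and the
one-step increment variance per dimension is ``2 * K_alpha * dt**alpha``.
``alpha = 2 * H`` where ``H`` is the Hurst exponent; ``alpha < 1`` gives
anti-persistent, subdiffusive motion; ``alpha = 1`` is ordinary Brownian
motion with independent increments.

Generation uses exact circulant embedding (Davies-Harte) with a single FFT
per series: the full-length covariance structure is sampled in one pass,
which is essential because chunked generation destroys the long-range
anticorrelation of the noise.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MotionParams",
    "Trajectory3D",
    "FgnEmbeddingError",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_fbm_3d",
    "ensemble_msd",
    "time_averaged_msd",
    "fit_powerlaw",
    "PowerLawFit",
    "MSDCurve",
    "substream",
    "derive_seed",
    "save_trajectories_text",
    "save_trajectories_npz",
]

# ---------------------------------------------------------------------------
# Seeding: one master seed per simulation; every stochastic stream is derived
# from (master, end_id, stream_tag, ...) so results do not depend on the
# order in which ends are simulated.
# ---------------------------------------------------------------------------

STREAM_FGN = 0
STREAM_SWITCH = 1
STREAM_DAMAGE = 2
STREAM_KINETICS = 3


def substream(seed: int | None, *key: int) -> np.random.Generator:
    """Deterministic, order-independent sub-generator for a master seed.

    ``seed=None`` yields a fresh OS-entropy generator (non-reproducible).
    """
    if seed is None:
        return np.random.default_rng()
    entropy = [int(seed)] + [int(k) for k in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *key: int) -> int:
    """Derive an integer sub-seed (< 2**31) from a master seed and a key."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Parameters and trajectory containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionParams:
    """Mobility parameters of one DSB end.

    Parameters
    ----------
    alpha
        Anomalous MSD exponent in (0, 2); ``alpha = 2 * hurst``.  Either
        ``alpha`` or ``hurst`` may be given; if both, they must agree exactly.
    k_alpha
        Generalized diffusion coefficient, nm^2 / s^alpha, in the
        ``MSD = 6 K_alpha t^alpha`` convention.
    dt
        Integration time step, s.
    n_steps
        Number of increments per generated trajectory.
    v
        Speed of the active (directed) state, nm/s.
    mu0
        Passive -> active switching rate, 1/s.
    mu1
        Active -> passive switching rate, 1/s.
    """

    alpha: float | None = None
    k_alpha: float = 20.0
    dt: float = 1.0
    n_steps: int = 1024
    v: float = 0.0
    mu0: float = 0.0
    mu1: float = 0.016
    hurst: float | None = None

    def __post_init__(self) -> None:
        alpha, hurst = self.alpha, self.hurst
        if alpha is None and hurst is None:
            alpha = 0.5
        if alpha is None:
            alpha = 2.0 * hurst
        if hurst is None:
            hurst = alpha / 2.0
        if alpha != 2.0 * hurst:
            raise ValueError(
                f"alpha ({alpha}) must equal 2*hurst ({2.0 * hurst}) exactly"
            )
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "hurst", float(hurst))
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha must lie in (0, 2), got {self.alpha}")
        if self.k_alpha < 0:
            raise ValueError("k_alpha must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.mu0 < 0:
            raise ValueError("mu0 must be >= 0")
        if self.mu0 > 0 and self.mu1 <= 0:
            raise ValueError("mu1 must be > 0 when mu0 > 0")

    def replace(self, **kwargs) -> "MotionParams":
        from dataclasses import replace as _replace

        if "alpha" in kwargs and "hurst" not in kwargs:
            kwargs["hurst"] = None
        if "hurst" in kwargs and "alpha" not in kwargs:
            kwargs["alpha"] = None
        return _replace(self, **kwargs)


@dataclass
class Trajectory3D:
    """Uniformly sampled 3D trajectory: ``positions[0]`` is the start point."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.times.size, 3):
            raise ValueError("positions must have shape (len(times), 3)")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def __len__(self) -> int:
        return int(self.times.size)


class MSDCurve(NamedTuple):
    lags: np.ndarray  # s
    msd: np.ndarray  # nm^2


class PowerLawFit(NamedTuple):
    exponent: float
    prefactor: float


class FgnEmbeddingError(RuntimeError):
    """Circulant embedding of the fGn covariance is not non-negative definite."""


# ---------------------------------------------------------------------------
# Autocovariance and the Davies-Harte sampler
# ---------------------------------------------------------------------------


def fgn_autocovariance(params: MotionParams, lag):
    """Per-dimension autocovariance of one-step FBM increments, nm^2.

    gamma(k) = K_alpha * dt**alpha * (|k+1|**alpha - 2|k|**alpha + |k-1|**alpha)

    so that gamma(0) = 2 K_alpha dt**alpha and the summed 3-component
    variance after one step equals 6 K_alpha dt**alpha.
    """
    k = np.asarray(lag, dtype=float)
    if np.any(k < 0):
        raise ValueError("lag must be non-negative")
    a = params.alpha
    g = (
        params.k_alpha
        * params.dt**a
        * (np.abs(k + 1) ** a - 2.0 * np.abs(k) ** a + np.abs(k - 1) ** a)
    )
    return float(g) if np.isscalar(lag) or g.ndim == 0 else g


def _next_pow2(n: int) -> int:
    return 1 << max(0, int(n - 1).bit_length())


def _fgn_eigenvalues(params: MotionParams, n_pad: int) -> np.ndarray:
    """Cached eigenvalues of the circulant embedding for these parameters."""
    return _cached_eigenvalues(params.alpha, params.k_alpha, params.dt, n_pad)


@functools.lru_cache(maxsize=16)
def _cached_eigenvalues(
    alpha: float, k_alpha: float, dt: float, n_pad: int
) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns the first ``n_pad + 1`` (distinct) eigenvalues of the length
    ``2 * n_pad`` symmetric circulant.  Raises :class:`FgnEmbeddingError` if
    the embedding is not non-negative definite (it is, for fGn with H < 1).
    """
    params = MotionParams(alpha=alpha, k_alpha=k_alpha, dt=dt, n_steps=1)
    gamma = fgn_autocovariance(params, np.arange(n_pad + 1))
    circ = np.concatenate([gamma, gamma[n_pad - 1:0:-1]])  # length 2*n_pad
    lam = np.fft.rfft(circ).real
    lmax = float(lam.max(initial=0.0))
    if lam.min() < -1e-10 * max(lmax, 1.0):
        raise FgnEmbeddingError(
            "circulant embedding has negative eigenvalues "
            f"(min {lam.min():.3e}, alpha={params.alpha}, n={n_pad}); "
            "the fGn covariance cannot be embedded at this length"
        )
    return np.maximum(lam, 0.0)


def generate_fgn(params: MotionParams, n: int, seed=None) -> np.ndarray:
    """Sample one fGn series of ``n`` one-step increments (one dimension), nm.

    Exact stationary sample via Davies-Harte circulant embedding: the series
    is generated in a single FFT pass at the full padded length (next power
    of two), and the padding is discarded, so the long-range correlation
    structure is exact at every lag.  ``seed`` may be an int, a
    ``numpy.random.Generator`` or None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_generator(seed)
    if params.k_alpha == 0.0:
        return np.zeros(n)
    n_pad = _next_pow2(n)
    lam = _fgn_eigenvalues(params, n_pad)
    m = 2 * n_pad
    u = rng.standard_normal(n_pad + 1)
    w = rng.standard_normal(n_pad + 1)
    spec = np.empty(n_pad + 1, dtype=complex)
    spec[0] = math.sqrt(lam[0]) * u[0]
    spec[n_pad] = math.sqrt(lam[n_pad]) * u[n_pad]
    spec[1:n_pad] = np.sqrt(lam[1:n_pad] / 2.0) * (u[1:n_pad] + 1j * w[1:n_pad])
    series = np.fft.irfft(spec, m) * math.sqrt(m)
    return series[:n]


def generate_fbm_3d(
    params: MotionParams,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int | None = None,
    end_id: int = 0,
) -> Trajectory3D:
    """3D FBM trajectory: cumulative sum of three independent fGn series.

    Each Cartesian component draws from its own deterministic substream
    ``(seed, end_id, STREAM_FGN, dim)``, so ensembles are reproducible and
    independent of generation order.
    """
    n = params.n_steps
    origin = np.asarray(origin, dtype=float)
    positions = np.empty((n + 1, 3))
    positions[0] = origin
    for dim in range(3):
        inc = generate_fgn(params, n, substream(seed, end_id, STREAM_FGN, dim))
        positions[1:, dim] = origin[dim] + np.cumsum(inc)
    times = np.arange(n + 1) * params.dt
    return Trajectory3D(times, positions)


def fgn_increments_3d(
    params: MotionParams, n: int, seed: int | None, end_id: int
) -> np.ndarray:
    """Raw (n, 3) fGn increments for one end, same substreams as FBM above."""
    inc = np.empty((n, 3))
    for dim in range(3):
        inc[:, dim] = generate_fgn(params, n, substream(seed, end_id, STREAM_FGN, dim))
    return inc


# ---------------------------------------------------------------------------
# MSD estimators and power-law fitting
# ---------------------------------------------------------------------------


def ensemble_msd(trajectories: Iterable[Trajectory3D]) -> MSDCurve:
    """Ensemble-averaged MSD relative to each trajectory's own start point."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t0 = trajectories[0].times
    total = np.zeros(t0.size)
    for traj in trajectories:
        if traj.times.size != t0.size or not np.allclose(traj.times, t0):
            raise ValueError("all trajectories must share the same time grid")
        disp = traj.positions - traj.positions[0]
        total += np.einsum("ij,ij->i", disp, disp)
    lags = t0 - t0[0]
    return MSDCurve(lags, total / len(trajectories))


def time_averaged_msd(traj: Trajectory3D, max_lag: int) -> MSDCurve:
    """Time-averaged MSD of one trajectory over a sliding window.

    tamsd(k) = mean_j |r(t_{j+k}) - r(t_j)|^2 for k = 0 .. max_lag.
    For an ergodic process (FBM, unlike CTRW) this converges to the
    ensemble MSD at lags much shorter than the trajectory.
    """
    n = len(traj)
    if max_lag >= n:
        raise ValueError(f"max_lag ({max_lag}) must be < trajectory length ({n})")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    pos = traj.positions
    # FFT autocorrelation form: sum_j |r_{j+k}-r_j|^2 =
    #   sum_j (|r_j|^2 + |r_{j+k}|^2) - 2 sum_j r_j . r_{j+k}
    sq = np.einsum("ij,ij->i", pos, pos)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    total = csum[-1]
    k = np.arange(max_lag + 1)
    sq_terms = (total - csum[k]) + (csum[n - k] - 0.0)
    nfft = 1 << int(2 * n - 1).bit_length()
    corr = np.zeros(max_lag + 1)
    for dim in range(3):
        f = np.fft.rfft(pos[:, dim], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
        corr += ac
    out = (sq_terms - 2.0 * corr) / (n - k)
    out[0] = 0.0
    return MSDCurve(k * traj.dt, np.maximum(out, 0.0))


def fit_powerlaw(x, y, window: tuple[float, float] | None = None) -> PowerLawFit:
    """Least-squares power law ``y = prefactor * x**exponent`` on log-log axes.

    Only points with ``window[0] <= x <= window[1]`` are used; all used
    values must be strictly positive and at least 3 points are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    mask = np.isfinite(x) & np.isfinite(y)
    if window is not None:
        lo, hi = window
        mask &= (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")
    xs, ys = x[mask], y[mask]
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    slope, intercept = np.polyfit(np.log(xs), np.log(ys), 1)
    return PowerLawFit(float(slope), float(np.exp(intercept)))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def save_trajectories_text(path, trajectories: Sequence[Trajectory3D], end_ids=None,
                           thin: int = 1) -> None:
    """Write trajectories as delimited text: end_id, t_s, x_nm, y_nm, z_nm."""
    if end_ids is None:
        end_ids = range(len(trajectories))
    with open(path, "w") as fh:
        fh.write("end_id\tt_s\tx_nm\ty_nm\tz_nm\n")
        for eid, traj in zip(end_ids, trajectories):
            for i in range(0, len(traj), max(1, int(thin))):
                t = traj.times[i]
                x, y, z = traj.positions[i]
                fh.write(f"{eid}\t{t:.6g}\t{x:.6g}\t{y:.6g}\t{z:.6g}\n")


def save_trajectories_npz(path, trajectories: Sequence[Trajectory3D], end_ids=None) -> None:
    """Binary container for large runs: stacked times/positions per end."""
    if end_ids is None:
        end_ids = list(range(len(trajectories)))
    np.savez_compressed(
        path,
        end_ids=np.asarray(list(end_ids)),
        times=trajectories[0].times if trajectories else np.empty(0),
        positions=np.stack([t.positions for t in trajectories])
        if trajectories
        else np.empty((0, 0, 3)),
    )
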