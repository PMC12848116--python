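"""Single-cell trajectory statistics for anomalous-diffusion classification.

Implements the metrics used to classify migration as sub- or super-diffusive:

* mean squared displacement (MSD) versus lag and the power-law fit
  ``MSD = mu * t**alpha`` (``alpha < 1`` sub-diffusive, trapping-dominated;
  ``alpha > 1`` super-diffusive, persistent; ``alpha = 1`` Brownian);
* normalized velocity autocorrelation (VAC), whose decay rate measures
  directional persistence;
* track straightness, the ratio of net displacement to path length;
* trap/step segmentation: maximal low-speed intervals ("trapping times")
  and the displacements of the intervening mobile segments ("step sizes");
* the Pearson kurtosis number ``K = m4 / m2**2`` (Gaussian reference 3) of
  trap-time and step-size samples, and the ratio ``K_trap / K_step`` that
  summarizes which tail dominates the motion.

All operations accept the :class:`~glassyclutch.engine.Trajectory` container
(or a list of them) and are estimator-only: they never look at simulation
internals, so they apply equally to experimental track tables read through
:mod:`glassyclutch.fixtures_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .engine import Trajectory

__all__ = [
    "MSDResult",
    "TrapSegment",
    "StepEvent",
    "msd_curve",
    "fit_alpha",
    "velocity_autocorrelation",
    "track_straightness",
    "segment_traps_steps",
    "kurtosis",
    "kurtosis_ratio",
]

MIN_FRAMES = 64        # shortest track the MSD exponent fit accepts
MIN_FIT_LAGS = 8


@dataclass(frozen=True)
class MSDResult:
    """MSD curve and (optionally) its fitted power law."""

    lags: np.ndarray            # s
    msd: np.ndarray             # nm^2
    n_cells: int
    alpha: float | None = None
    mu: float | None = None     # nm^2 / s^alpha
    r_squared: float | None = None
    fit_window: tuple[float, float] | None = None  # (lag_lo, lag_hi) seconds


@dataclass(frozen=True)
class TrapSegment:
    """A maximal low-motility interval of a track."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        """Trapping time t_p (s)."""
        return self.t_end - self.t_start


@dataclass(frozen=True)
class StepEvent:
    """An inter-trap mobile segment and its net displacement."""

    displacement: float         # nm, >= 0
    duration: float             # s

    def __post_init__(self):
        if self.displacement < 0 or self.duration <= 0:
            raise ValueError("displacement must be >= 0 and duration > 0")


def _as_list(trajs) -> list[Trajectory]:
    if isinstance(trajs, Trajectory):
        return [trajs]
    out = list(trajs)
    if not out:
        raise ValueError("need at least one trajectory")
    return out


def _uniform_dt(traj: Trajectory) -> float:
    dts = np.diff(traj.times)
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform frame spacing; resample the track first")
    return float(dt)


# ---------------------------------------------------------------------------
# MSD and the anomalous exponent
# ---------------------------------------------------------------------------

def msd_curve(trajs, max_lag_fraction: float = 0.25,
              from_origin: bool = False) -> MSDResult:
    """Time-and-ensemble averaged MSD over lag.

    The default estimator averages ``|r(t + tau) - r(t)|**2`` over all start
    times ``t``, all lags ``tau`` up to ``max_lag_fraction`` of the track
    length, and all cells — the standard estimator in particle tracking and
    the one the exponent fit assumes.  ``from_origin=True`` instead averages
    the squared displacement from each track's initial position,
    ``|r(tau) - r(0)|**2`` over cells (an aging-sensitive alternative).
    """
    trajs = _as_list(trajs)
    n = min(t.n_frames for t in trajs)
    if n < MIN_FRAMES:
        raise ValueError(
            f"trajectories have {n} frames; at least {MIN_FRAMES} are required"
        )
    dt = _uniform_dt(trajs[0])
    for t in trajs[1:]:
        if not math.isclose(_uniform_dt(t), dt, rel_tol=1e-6):
            raise ValueError("all trajectories must share one frame interval")
    max_lag = max(2, int(n * max_lag_fraction))
    lags = np.arange(1, max_lag)
    P = np.stack([t.positions[:n] for t in trajs])      # (cells, frames, 2)
    if from_origin:
        d = P[:, lags, :] - P[:, :1, :]
        msd = np.mean(np.sum(d * d, axis=-1), axis=0)
    else:
        msd = np.empty(lags.shape)
        for i, k in enumerate(lags):
            d = P[:, k:, :] - P[:, :-k, :]
            msd[i] = np.mean(np.sum(d * d, axis=-1))
    return MSDResult(lags=lags * dt, msd=msd, n_cells=len(trajs))


def fit_alpha(msd: MSDResult, window: tuple[float, float] | None = None) -> MSDResult:
    """Fit ``MSD = mu * tau**alpha`` by least squares in log-log coordinates.

    The fit window defaults to one decade of lags starting at the first
    recorded lag — the short-lag regime where displacement pairs are
    plentiful and the estimator variance is lowest.  Returns a copy of the
    input with ``alpha``, ``mu``, ``r_squared`` and ``fit_window`` filled in.
    """
    if window is None:
        lo = float(msd.lags[0])
        window = (lo, 10.0 * lo)
    lo, hi = window
    sel = (msd.lags >= lo * (1 - 1e-9)) & (msd.lags <= hi * (1 + 1e-9))
    if sel.sum() < MIN_FIT_LAGS:
        raise ValueError(
            f"fit window [{lo}, {hi}] s contains {int(sel.sum())} lags; "
            f"at least {MIN_FIT_LAGS} are required"
        )
    y = msd.msd[sel]
    if np.any(y <= 0):
        raise ValueError("MSD is zero or negative inside the fit window")
    res = _sps.linregress(np.log(msd.lags[sel]), np.log(y))
    return replace(msd, alpha=float(res.slope), mu=float(np.exp(res.intercept)),
                   r_squared=float(res.rvalue ** 2), fit_window=(lo, hi))


def ensemble_alpha(trajs, max_lag_fraction: float = 0.25,
                   window: tuple[float, float] | None = None) -> MSDResult:
    """Convenience: pooled-ensemble MSD followed by the power-law fit."""
    return fit_alpha(msd_curve(trajs, max_lag_fraction), window)


# ---------------------------------------------------------------------------
# persistence metrics
# ---------------------------------------------------------------------------

def velocity_autocorrelation(trajs, max_lag_frames: int | None = None) -> np.ndarray:
    """Normalized VAC: ``C(k) = <v_i . v_{i+k}> / <|v_i|^2>``, ``C(0) = 1``.

    Frame velocities are finite differences of recorded positions.  Slower
    decay indicates more persistent, directed migration.
    """
    trajs = _as_list(trajs)
    n = min(t.n_frames for t in trajs)
    if n < 3:
        raise ValueError("need at least 3 frames for a velocity autocorrelation")
    if max_lag_frames is None:
        max_lag_frames = (n - 1) // 2
    dt = _uniform_dt(trajs[0])
    V = np.stack([np.diff(t.positions[:n], axis=0) for t in trajs]) / dt
    norm = np.mean(np.sum(V * V, axis=-1))
    if norm == 0:
        raise ValueError("all-zero velocities: VAC normalization undefined")
    out = np.empty(max_lag_frames + 1)
    out[0] = 1.0
    for k in range(1, max_lag_frames + 1):
        out[k] = np.mean(np.sum(V[:, k:, :] * V[:, :-k, :], axis=-1)) / norm
    return out


def track_straightness(traj: Trajectory) -> float:
    """Net displacement over total path length, in [0, 1]."""
    d = np.diff(traj.positions, axis=0)
    path = float(np.sum(np.linalg.norm(d, axis=1)))
    if path == 0:
        raise ValueError("zero path length: straightness undefined")
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return net / path


# ---------------------------------------------------------------------------
# trap / step segmentation
# ---------------------------------------------------------------------------

def segment_traps_steps(traj: Trajectory, v_eps: float | None = None,
                        t_min: float | None = None,
                        ) -> tuple[list[TrapSegment], list[StepEvent]]:
    """Partition a track into traps (slow intervals) and steps (mobile ones).

    A trap is a maximal run of frames whose frame speed stays below
    ``v_eps`` for at least ``t_min``; every other stretch is a step whose
    size is its net displacement.  Thresholds are explicit: ``v_eps``
    defaults to 5% of the unloaded flow speed recorded in the trajectory
    metadata (and must be given when no metadata is present); ``t_min``
    defaults to three frame intervals.
    """
    dt = _uniform_dt(traj)
    if v_eps is None:
        try:
            v_eps = 0.05 * float(traj.meta["params"]["V_u"])
        except (KeyError, TypeError):
            raise ValueError(
                "v_eps not given and trajectory metadata carries no V_u"
            ) from None
    if t_min is None:
        t_min = 3.0 * dt
    speeds = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) / dt
    slow = speeds < v_eps
    k_min = max(1, int(round(t_min / dt)))

    traps: list[TrapSegment] = []
    boundaries: list[tuple[int, int, bool]] = []   # (i0, i1, is_trap) over intervals
    i = 0
    n = len(slow)
    while i < n:
        j = i
        while j < n and slow[j] == slow[i]:
            j += 1
        boundaries.append((i, j, bool(slow[i]) and (j - i) >= k_min))
        i = j
    # merge adjacent non-trap stretches (short slow runs are part of steps)
    merged: list[list] = []
    for i0, i1, is_trap in boundaries:
        if not is_trap and merged and not merged[-1][2]:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1, is_trap])

    steps: list[StepEvent] = []
    t = traj.times
    p = traj.positions
    for i0, i1, is_trap in merged:
        if is_trap:
            traps.append(TrapSegment(t_start=float(t[i0]), t_end=float(t[i1])))
        else:
            disp = float(np.linalg.norm(p[i1] - p[i0]))
            steps.append(StepEvent(displacement=disp, duration=float(t[i1] - t[i0])))
    return traps, steps


# ---------------------------------------------------------------------------
# kurtosis numbers
# ---------------------------------------------------------------------------

def kurtosis(samples) -> float:
    """Pearson kurtosis m4/m2^2 (Gaussian = 3, heavier tails larger).

    The Pearson (non-excess) convention is used so that ratios of kurtosis
    numbers are positive and well defined.
    """
    a = np.asarray(samples, dtype=float)
    if a.size < 4:
        raise ValueError(f"need at least 4 samples, got {a.size}")
    if np.var(a) == 0:
        raise ValueError("zero variance: kurtosis undefined")
    return float(_sps.kurtosis(a, fisher=False, bias=True))


@dataclass(frozen=True)
class KurtosisRatio:
    """K_trap / K_step with the underlying numbers and a small-sample flag."""

    ratio: float
    k_trap: float
    k_step: float
    n_traps: int
    n_steps: int
    low_sample_warning: bool = field(default=False)


def kurtosis_ratio(traps: Sequence[TrapSegment] | Sequence[float],
                   steps: Sequence[StepEvent] | Sequence[float]) -> KurtosisRatio:
    """Tail-dominance summary ``K_trap / K_step``.

    Large values mean trap times are the heavy-tailed quantity (trapping
    dominates, sub-diffusive signature); small values mean step sizes carry
    the tail (super-diffusive signature).  Flags results based on fewer than
    10 traps or steps.
    """
    t = [s.duration if isinstance(s, TrapSegment) else float(s) for s in traps]
    d = [s.displacement if isinstance(s, StepEvent) else float(s) for s in steps]
    kt, ks = kurtosis(t), kurtosis(d)
    return KurtosisRatio(ratio=kt / ks, k_trap=kt, k_step=ks,
                         n_traps=len(t), n_steps=len(d),
                         low_sample_warning=(len(t) < 10 or len(d) < 10))
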