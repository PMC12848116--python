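"""Config parsing, trajectory I/O, logging, and reference random walks.

The reference walks are synthetic tracks with known anomalous-diffusion
exponents, used to validate the statistics layer independently of the
motor-clutch simulator:

* ``ballistic`` — straight-line motion, alpha = 2;
* ``brownian`` — i.i.d. Gaussian steps, alpha = 1;
* ``ctrw`` — a continuous-time random walk: Gaussian jumps separated by
  power-law waiting times with tail exponent ``gamma`` in (0, 1), giving
  sub-diffusion with alpha = gamma;
* ``levy`` — a Levy walk: constant-speed flights with power-law durations,
  tail exponent ``gamma`` in (1, 2), giving super-diffusion with
  alpha = 3 - gamma.

Trajectories are exchanged as plain CSV with columns
``cell_id, t_s, x_nm, y_nm`` (gzip transparently supported via the file
extension), diff-able and readable by any tracking tool.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .engine import CellParams, Trajectory

__all__ = [
    "ReferenceWalkSpec",
    "make_reference_walks",
    "read_trajectories",
    "write_trajectories",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("glassyclutch")


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# reference walks
# ---------------------------------------------------------------------------

_KINDS = ("ballistic", "brownian", "ctrw", "levy")


@dataclass(frozen=True)
class ReferenceWalkSpec:
    """Specification of a synthetic reference-walk ensemble."""

    kind: str
    n_walkers: int = 200
    n_frames: int = 500
    frame_interval: float = 10.0    # s
    speed: float = 10.0             # nm/s (ballistic, levy)
    step_sigma: float = 50.0        # nm per frame (brownian, ctrw jumps)
    gamma: float | None = None      # tail exponent (ctrw, levy)
    target_alpha: float | None = None  # alternative to gamma
    wait_min: float | None = None   # s, minimum CTRW wait / Levy flight time;
                                    # defaults: 0.01 (ctrw, so the observed
                                    # lags are deep in the asymptotic regime)
                                    # and 1.0 (levy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_walkers < 1 or self.n_frames < 2:
            raise ValueError("need n_walkers >= 1 and n_frames >= 2")
        if self.wait_min is None:
            object.__setattr__(self, "wait_min", 0.01 if self.kind == "ctrw" else 1.0)
        g = self._gamma()
        if self.kind == "ctrw" and not (0.0 < g < 1.0):
            raise ValueError(
                f"ctrw waiting-time exponent gamma must lie in (0, 1), got {g}"
            )
        if self.kind == "levy" and not (1.0 < g < 2.0):
            raise ValueError(
                f"levy flight exponent gamma must lie in (1, 2), got {g}"
            )

    def _gamma(self) -> float:
        if self.kind in ("ballistic", "brownian"):
            return math.nan
        if self.gamma is not None:
            return self.gamma
        if self.target_alpha is None:
            raise ValueError(f"{self.kind} walks need gamma or target_alpha")
        # ctrw: alpha = gamma; levy: alpha = 3 - gamma
        return self.target_alpha if self.kind == "ctrw" else 3.0 - self.target_alpha

    @property
    def theoretical_alpha(self) -> float:
        """Asymptotic MSD exponent implied by the walk law."""
        if self.kind == "ballistic":
            return 2.0
        if self.kind == "brownian":
            return 1.0
        g = self._gamma()
        return g if self.kind == "ctrw" else 3.0 - g


def _pareto_waits(rng: np.random.Generator, gamma: float, t_min: float, size) :
    # survival P(T > t) = (t / t_min)^(-gamma)
    return t_min * rng.random(size) ** (-1.0 / gamma)


def _one_walk(spec: ReferenceWalkSpec, rng: np.random.Generator) -> np.ndarray:
    n, dt = spec.n_frames, spec.frame_interval
    T = n * dt
    t_grid = np.arange(n + 1) * dt
    if spec.kind == "ballistic":
        phi = rng.uniform(0, 2 * np.pi)
        v = spec.speed * np.array([np.cos(phi), np.sin(phi)])
        return t_grid[:, None] * v[None, :]
    if spec.kind == "brownian":
        steps = rng.normal(0.0, spec.step_sigma, size=(n, 2))
        return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    g = spec._gamma()
    if spec.kind == "ctrw":
        # renewal process: wait, then instantaneous Gaussian jump
        times, pos = [0.0], [np.zeros(2)]
        t = 0.0
        while t <= T:
            t += float(_pareto_waits(rng, g, spec.wait_min, None))
            times.append(t)
            pos.append(pos[-1] + rng.normal(0.0, spec.step_sigma, 2))
        times = np.asarray(times)
        pos = np.vstack(pos)
        idx = np.searchsorted(times, t_grid, side="right") - 1
        return pos[idx]
    # levy: constant-speed flights of power-law duration, fresh direction each
    times, pos = [0.0], [np.zeros(2)]
    t = 0.0
    while t <= T:
        dur = float(_pareto_waits(rng, g, spec.wait_min, None))
        phi = rng.uniform(0, 2 * np.pi)
        v = spec.speed * np.array([np.cos(phi), np.sin(phi)])
        t += dur
        times.append(t)
        pos.append(pos[-1] + v * dur)
    times = np.asarray(times)
    pos = np.vstack(pos)
    # linear interpolation within flights (motion is continuous)
    x = np.interp(t_grid, times, pos[:, 0])
    y = np.interp(t_grid, times, pos[:, 1])
    return np.column_stack([x, y])


def make_reference_walks(spec: ReferenceWalkSpec) -> list[Trajectory]:
    """Generate the seeded reference-walk ensemble described by ``spec``."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_walkers)
    t_grid = np.arange(spec.n_frames + 1) * spec.frame_interval
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p = _one_walk(spec, rng)
        out.append(Trajectory(
            times=t_grid, positions=p,
            meta={"kind": spec.kind, "cell_id": i,
                  "theoretical_alpha": spec.theoretical_alpha,
                  "seed": spec.seed},
        ))
    return out


# ---------------------------------------------------------------------------
# trajectory tables
# ---------------------------------------------------------------------------

_COLUMNS = ["cell_id", "t_s", "x_nm", "y_nm"]


def write_trajectories(trajs, path) -> None:
    """Write tracks as CSV (``cell_id, t_s, x_nm, y_nm``); .gz compresses."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    frames = []
    for i, tr in enumerate(trajs):
        cid = tr.meta.get("cell_id", i)
        frames.append(pd.DataFrame({
            "cell_id": cid, "t_s": tr.times,
            "x_nm": tr.positions[:, 0], "y_nm": tr.positions[:, 1],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV back into :class:`Trajectory` objects.

    Validates the header, numeric fields (reporting the first offending line
    number) and strictly increasing times within each cell.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns {missing}")
    for c in ("t_s", "x_nm", "y_nm"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[c].notna().to_numpy())[0]
        if df[c].isna().any() or bad.size:
            row = int((bad[0] if bad.size else df[c].isna().idxmax())) + 2
            raise ValueError(f"malformed value in column {c!r} at line {row}")
        df[c] = vals
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        t = grp["t_s"].to_numpy(float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"times for cell {cid!r} are not strictly increasing"
            )
        out.append(Trajectory(
            times=t,
            positions=grp[["x_nm", "y_nm"]].to_numpy(float),
            meta={"cell_id": cid, "source": str(path)},
        ))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# config section -> {config key: CellParams field}
_SECTION_KEYS = {
    "clutches": {"n_clutches": "n_clutches", "k_c": "k_c", "r_on": "r_on",
                 "F_bond": "F_bond"},
    "motors": {"N_m": "N_m", "F_motor": "F_motor", "V_u": "V_u"},
    "substrate": {"k_a": "k_a", "k_l": "k_l", "tau_s": "tau_s"},
    "glassy": {"off_time_mode": "off_time_mode", "beta": "beta",
               "tau_min": "tau_min", "tau_max": "tau_max",
               "resample_per_step": "resample_per_step"},
    "cell": {"dimensionality": "dimensionality", "half_velocity": "half_velocity"},
    "run": {"duration": "duration", "dt": "dt",
            "record_interval": "record_interval", "burn_in": "burn_in",
            "init_stationary": "init_stationary"},
}
_RUN_EXTRA = {"seed", "n_cells"}
_EXTRA_SECTIONS = {"scenario", "sweep"}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved configuration: cell parameters plus run/driver extras."""

    params: CellParams
    seed: int = 0
    n_cells: int = 1
    scenario: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load a YAML config (flat key-value sections) onto shipped defaults.

    Unknown sections or keys and out-of-range values are rejected with
    descriptive errors; the derived timescales (tau_l, tau_s, F_stall) are
    logged so runs can be sanity-checked against the regime they target.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    kwargs: dict = {}
    extras: dict = {"seed": 0, "n_cells": 1, "scenario": {}, "sweep": {}}
    for section, content in raw.items():
        if section in _EXTRA_SECTIONS:
            if not isinstance(content, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            extras[section] = content
            continue
        if section not in _SECTION_KEYS:
            raise ValueError(f"unknown config section {section!r}")
        content = content or {}
        for key, value in content.items():
            if section == "run" and key in _RUN_EXTRA:
                extras[key] = value
                continue
            try:
                field_name = _SECTION_KEYS[section][key]
            except KeyError:
                raise ValueError(
                    f"unknown key {key!r} in section {section!r}"
                ) from None
            kwargs[field_name] = value
    params = CellParams(**kwargs)   # range validation happens here
    log.info(
        "config %s resolved: tau_l=%.3g s, tau_s=%.3g s, tau_min=%.3g s, "
        "F_stall=%.3g pN, dt=%.3g s",
        path, params.tau_l, params.tau_s, params.tau_min, params.F_stall,
        params.timestep,
    )
    return RunConfig(params=params, seed=int(extras["seed"]),
                     n_cells=int(extras["n_cells"]),
                     scenario=extras["scenario"], sweep=extras["sweep"])


def write_run_metadata(path, params: CellParams, seed, extra: dict | None = None) -> None:
    """JSON sidecar with the fully resolved parameter set for reproducibility."""
    meta = {"params": params.resolved(), "seed": seed,
            "timescales": params.timescales()}
    if extra:
        meta.update(extra)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_default)
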