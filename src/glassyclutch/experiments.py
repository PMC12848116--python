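"""Scripted in-silico experiments.

Drivers that reproduce the model's headline computational experiments:

* :func:`phase_diagram` — the (glass coefficient beta) x (substrate
  relaxation timescale tau_s) sweep, mapping the fitted MSD exponent alpha
  and the kurtosis ratio K_trap/K_step over the grid;
* :func:`relaxation_contrast` — the fast- (tau_s = 10 s) versus
  slow-relaxing (tau_s = 1000 s) substrate comparison with the full metric
  panel (alpha, straightness, VAC, trap/step samples and kurtosis numbers);
* :func:`inhibition_study` — actomyosin-inhibition scenarios on the
  fast-relaxing substrate (motor count and polymerization-speed scaling).

Sweeps are expressed in tau_s rather than raw viscosity, matching the
timescale framing of the analysis; eta = tau_s * k_a is derived per grid
cell.  All drivers are deterministic under a seed and return plain,
JSON-serializable dictionaries (plus the :class:`PhaseMap` container for
sweeps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .engine import CellParams, apply_scenario, simulate_ensemble
from .trajstats import (
    ensemble_alpha,
    kurtosis_ratio,
    segment_traps_steps,
    track_straightness,
    velocity_autocorrelation,
)

__all__ = ["PhaseMap", "phase_diagram", "relaxation_contrast", "inhibition_study"]

log = logging.getLogger("glassyclutch.experiments")

FAST_TAU_S = 10.0       # s, fast-relaxing substrate condition
SLOW_TAU_S = 1000.0     # s, slow-relaxing substrate condition


@dataclass(frozen=True)
class PhaseMap:
    """Gridded sweep results over (beta, tau_s)."""

    betas: np.ndarray
    tau_s_values: np.ndarray
    alpha: np.ndarray           # (n_beta, n_tau)
    kurtosis_ratio: np.ndarray  # (n_beta, n_tau); NaN where undefined
    alpha_se: np.ndarray        # Monte-Carlo standard error of per-cell alphas
    n_reps: int
    failed: np.ndarray          # bool mask of grid cells that errored

    def to_dict(self) -> dict:
        return {
            "betas": self.betas.tolist(),
            "tau_s_values": self.tau_s_values.tolist(),
            "alpha": self.alpha.tolist(),
            "kurtosis_ratio": self.kurtosis_ratio.tolist(),
            "alpha_se": self.alpha_se.tolist(),
            "n_reps": self.n_reps,
            "failed": self.failed.tolist(),
        }


def _condition_stats(params: CellParams, reps: int, seed,
                     vac_lags: int = 20) -> dict:
    """Simulate one condition and compute the full metric panel."""
    trajs = simulate_ensemble(params, reps, seed)
    fit = ensemble_alpha(trajs)
    traps, steps = [], []
    for tr in trajs:
        t, s = segment_traps_steps(tr)
        traps.extend(seg.duration for seg in t)
        steps.extend(ev.displacement for ev in s)
    straight = [track_straightness(tr) for tr in trajs
                if np.any(np.diff(tr.positions, axis=0))]
    vac = velocity_autocorrelation(trajs, vac_lags)
    out = {
        "alpha": fit.alpha, "mu": fit.mu, "r_squared": fit.r_squared,
        "straightness_mean": float(np.mean(straight)) if straight else float("nan"),
        "straightness": [float(s) for s in straight],
        "vac": vac.tolist(),
        "trap_times_s": [float(x) for x in traps],
        "step_sizes_nm": [float(x) for x in steps],
        "mean_trap_time_s": float(np.mean(traps)) if traps else float("nan"),
        "mean_step_size_nm": float(np.mean(steps)) if steps else float("nan"),
        "n_cells": reps,
    }
    try:
        kr = kurtosis_ratio(traps, steps)
        out.update(k_trap=kr.k_trap, k_step=kr.k_step,
                   kurtosis_ratio=kr.ratio,
                   kurtosis_low_sample=kr.low_sample_warning)
    except ValueError:
        out.update(k_trap=float("nan"), k_step=float("nan"),
                   kurtosis_ratio=float("nan"), kurtosis_low_sample=True)
    return out


def phase_diagram(beta_grid, tau_s_grid, reps: int, base_params: CellParams,
                  seed, resume_from: PhaseMap | None = None) -> PhaseMap:
    """Sweep the glassy model over a (beta, tau_s) grid.

    Each grid cell simulates ``reps`` cells from its own deterministic child
    seed (so the sweep can be re-run cell-by-cell and partial results reused
    via ``resume_from``), fits the ensemble MSD exponent, and computes the
    trap/step kurtosis ratio.  Failures in individual cells are flagged, not
    fatal to the sweep.
    """
    betas = np.asarray(list(beta_grid), dtype=float)
    taus = np.asarray(list(tau_s_grid), dtype=float)
    if betas.size == 0 or taus.size == 0:
        raise ValueError("beta and tau_s grids must be nonempty")
    if reps < 3:
        raise ValueError(f"need at least 3 replicates per grid cell, got {reps}")
    shape = (betas.size, taus.size)
    alpha = np.full(shape, np.nan)
    kr = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    children = root.spawn(betas.size * taus.size)
    for i, beta in enumerate(betas):
        for j, tau_s in enumerate(taus):
            if (resume_from is not None
                    and np.any(np.isclose(resume_from.betas, beta))
                    and np.any(np.isclose(resume_from.tau_s_values, tau_s))):
                i0 = int(np.argmin(np.abs(resume_from.betas - beta)))
                j0 = int(np.argmin(np.abs(resume_from.tau_s_values - tau_s)))
                if not resume_from.failed[i0, j0]:
                    alpha[i, j] = resume_from.alpha[i0, j0]
                    kr[i, j] = resume_from.kurtosis_ratio[i0, j0]
                    se[i, j] = resume_from.alpha_se[i0, j0]
                    continue
            child = children[i * taus.size + j]
            try:
                params = replace(base_params, beta=beta, tau_s=tau_s)
                trajs = simulate_ensemble(params, reps, child)
                fit = ensemble_alpha(trajs)
                alpha[i, j] = fit.alpha
                # per-cell alpha spread for a Monte-Carlo error bar
                cell_alphas = []
                for tr in trajs:
                    try:
                        cell_alphas.append(ensemble_alpha([tr]).alpha)
                    except ValueError:
                        pass
                if len(cell_alphas) > 1:
                    se[i, j] = float(np.std(cell_alphas, ddof=1)
                                     / np.sqrt(len(cell_alphas)))
                traps, steps = [], []
                for tr in trajs:
                    t, s = segment_traps_steps(tr)
                    traps.extend(seg.duration for seg in t)
                    steps.extend(ev.displacement for ev in s)
                try:
                    kr[i, j] = kurtosis_ratio(traps, steps).ratio
                except ValueError:
                    pass
            except Exception as exc:  # flagged, sweep continues
                log.warning("grid cell beta=%g tau_s=%g failed: %s",
                            beta, tau_s, exc)
                failed[i, j] = True
            log.info("phase cell beta=%g tau_s=%g: alpha=%s", beta, tau_s,
                     alpha[i, j])
    return PhaseMap(betas=betas, tau_s_values=taus, alpha=alpha,
                    kurtosis_ratio=kr, alpha_se=se, n_reps=reps, failed=failed)


def relaxation_contrast(base_params: CellParams, reps: int, seed) -> dict:
    """Fast- versus slow-relaxing substrate comparison (full metric panel).

    Returns per-condition metrics and the observed effect directions
    (fast-vs-slow differences of alpha, straightness, short-lag VAC, trap
    time and step size).
    """
    if reps < 10:
        raise ValueError(f"need at least 10 replicates, got {reps}")
    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    s_fast, s_slow = root.spawn(2)
    fast = _condition_stats(replace(base_params, tau_s=FAST_TAU_S), reps, s_fast)
    slow = _condition_stats(replace(base_params, tau_s=SLOW_TAU_S), reps, s_slow)
    k = min(5, len(fast["vac"]) - 1)
    directions = {
        "alpha_fast_minus_slow": fast["alpha"] - slow["alpha"],
        "straightness_fast_minus_slow":
            fast["straightness_mean"] - slow["straightness_mean"],
        "vac_shortlag_fast_minus_slow":
            float(np.mean(fast["vac"][1:k + 1]) - np.mean(slow["vac"][1:k + 1])),
        "trap_time_slow_minus_fast":
            slow["mean_trap_time_s"] - fast["mean_trap_time_s"],
        "step_size_fast_minus_slow":
            fast["mean_step_size_nm"] - slow["mean_step_size_nm"],
    }
    return {"fast": fast, "slow": slow, "directions": directions,
            "tau_s": {"fast": FAST_TAU_S, "slow": SLOW_TAU_S}}


def inhibition_study(base_params: CellParams, scenarios, reps: int, seed,
                     factors: dict | None = None) -> dict:
    """Actomyosin-inhibition scenarios on the fast-relaxing substrate.

    ``scenarios`` is a subset of {control, myosin_inhibited, actin_inhibited};
    each is simulated at tau_s = 10 s and summarized by alpha, straightness
    and VAC.  Returns per-scenario panels plus alpha differences from control.
    """
    scenarios = list(scenarios)
    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    children = root.spawn(len(scenarios))
    fast = replace(base_params, tau_s=FAST_TAU_S)
    out: dict = {"scenarios": {}}
    for name, child in zip(scenarios, children):
        params = apply_scenario(fast, name, factors)
        out["scenarios"][name] = _condition_stats(params, reps, child)
    if "control" in out["scenarios"]:
        a0 = out["scenarios"]["control"]["alpha"]
        out["alpha_vs_control"] = {
            name: stats["alpha"] - a0
            for name, stats in out["scenarios"].items() if name != "control"
        }
    return out
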