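"""Whole-cell migration simulation.

A cell is represented by two opposing protruding ends per axis, with fully
independent X and Y axes (2D runs are two 1D runs with different random
streams).  Each end is a motor-clutch module on its own standard-linear-solid
substrate element.  The migration velocity along an axis follows from the
retrograde-flow imbalance of its two ends,

    V_m = (V_r_left - V_r_right) / 2,

with +x toward the right end: the cell drifts toward the end with stronger
adhesion, i.e. slower retrograde flow.  The factor 1/2 reflects the cell
center being the mean of two edges whose equal protrusion terms cancel; it
rescales the diffusion constant only, never the MSD exponent, and can be
disabled (``half_velocity=False``) for the bare difference.

The per-step physics matches :mod:`glassyclutch.mechanics` exactly; the inner
loop here is compiled with numba for throughput (a 2000 s trajectory at the
default timestep is ~200k coupled steps over 4 x 75 clutches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .mechanics import IntegrationError

__all__ = [
    "CellParams",
    "Trajectory",
    "simulate_cell",
    "simulate_ensemble",
    "apply_scenario",
    "nondimensionalize",
]

#: default long-term stiffness: calibrated so the motor-stall timescale
#: tau_l = F_motor N_m / (V_u k_l) is 10 s at the default motor parameters
_DEFAULT_K_L = 50 * 2.0 / (120.0 * 10.0)  # pN/nm


@dataclass(frozen=True)
class CellParams:
    """Full parameter set of one simulated cell.

    Units: seconds, nanometers, piconewtons.  The substrate is specified by
    its relaxation timescale ``tau_s`` (the experimental knob); the viscosity
    follows as ``eta = tau_s * k_a``.
    """

    # clutch ensemble (per end)
    n_clutches: int = 75
    k_c: float = 0.8            # pN/nm clutch spring stiffness
    r_on: float = 1.0           # 1/s association rate
    F_bond: float = 2.0         # pN Bell characteristic rupture force
    # motors (per end)
    N_m: int = 50
    F_motor: float = 2.0        # pN single-motor stall force
    V_u: float = 120.0          # nm/s unloaded retrograde flow / polymerization scale
    # substrate (per end)
    k_a: float = _DEFAULT_K_L   # pN/nm additional-branch stiffness
    k_l: float = _DEFAULT_K_L   # pN/nm long-term stiffness
    tau_s: float = 10.0         # s substrate stress-relaxation timescale
    # glassy off-time law
    off_time_mode: str = "glassy"   # {"glassy", "constant"}
    beta: float = 1.5
    tau_min: float = 1.0        # s
    tau_max: float = 100.0      # s, upper end of the dissociation-time spectrum
    resample_per_step: bool = False
    # run control
    duration: float = 2000.0    # s
    dt: float | None = None     # s; None -> min(tau_min, tau_s, 1/r_on)/100
    record_interval: float = 10.0  # s between recorded frames
    burn_in: float = 200.0      # s discarded before recording (stationarity)
    init_stationary: bool = True  # start with the dashpot pre-extended
    dimensionality: int = 2
    half_velocity: bool = True

    def __post_init__(self) -> None:
        if self.off_time_mode not in ("glassy", "constant"):
            raise ValueError(f"off_time_mode must be glassy|constant, got {self.off_time_mode!r}")
        if self.off_time_mode == "glassy" and not self.beta > 1.0:
            raise ValueError(f"beta must be > 1, got {self.beta}")
        for name in ("k_c", "F_bond", "F_motor", "k_a", "k_l", "tau_s", "tau_min",
                     "duration", "record_interval"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.r_on < 0 or self.V_u < 0 or self.N_m < 0 or self.n_clutches < 1:
            raise ValueError("r_on, V_u, N_m must be >= 0 and n_clutches >= 1")
        if self.dimensionality not in (1, 2):
            raise ValueError(f"dimensionality must be 1 or 2, got {self.dimensionality}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        dt = self.timestep
        if dt <= 0 or self.record_interval < dt - 1e-12:
            raise ValueError("need 0 < dt <= record_interval")
        if self.n_frames < 64:
            raise ValueError(
                f"duration/record_interval = {self.n_frames} recorded frames; "
                "at least 64 are required for downstream MSD exponent fitting"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def eta(self) -> float:
        """Substrate viscosity eta = tau_s * k_a (pN*s/nm)."""
        return self.tau_s * self.k_a

    @property
    def F_stall(self) -> float:
        """Motor-ensemble stall force per end, N_m * F_motor (pN)."""
        return self.N_m * self.F_motor

    @property
    def tau_l(self) -> float:
        """Motor-stall timescale F_motor N_m / (V_u k_l) (s)."""
        if self.V_u == 0 or self.N_m == 0:
            return math.inf
        return self.F_motor * self.N_m / (self.V_u * self.k_l)

    @property
    def timestep(self) -> float:
        """Actual integration step: explicit ``dt`` or the default heuristic.

        The default resolves the fastest of the minimum dissociation time,
        the substrate relaxation time and the association time by a factor
        100, and always respects the ``tau_s / 10`` substrate accuracy bound.
        """
        if self.dt is not None:
            return float(self.dt)
        scales = [self.tau_min, self.tau_s]
        if self.r_on > 0:
            scales.append(1.0 / self.r_on)
        return min(scales) / 100.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.record_interval))

    def timescales(self) -> dict[str, float]:
        """The three diagnostic timescales the dynamics are framed in."""
        return {"tau_min": self.tau_min, "tau_l": self.tau_l, "tau_s": self.tau_s}

    def resolved(self) -> dict:
        """Fully resolved parameter dictionary for run metadata."""
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["dt"] = self.timestep
        out.update(eta=self.eta, F_stall=self.F_stall, tau_l=self.tau_l)
        return out


@dataclass(frozen=True)
class Trajectory:
    """Recorded cell-center track: times (s) and (x, y) positions (nm)."""

    times: np.ndarray           # (n_frames,)
    positions: np.ndarray       # (n_frames, 2); y identically 0 for 1D runs
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] != t.shape[0]:
            raise ValueError("positions must be (n_frames, 2) matching times")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("non-finite times or positions")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])


# ---------------------------------------------------------------------------
# compiled axis kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_axis(seed, n_frames, record_every, burn_steps, dt, n_c, k_c, r_on,
              F_bond, N_m, F_motor, V_u, k_a, k_l, eta, glassy, beta, tau_min,
              tau_max, resample_per_step, half_velocity,
              x_s0):  # pragma: no cover - compiled
    np.random.seed(seed)
    F_stall = N_m * F_motor
    p_on = -math.expm1(-r_on * dt)
    a_coef = (k_a + k_l) * eta / dt

    bound = np.zeros((2, n_c), dtype=np.bool_)
    x_c = np.full((2, n_c), x_s0)
    tau_off = np.zeros((2, n_c))
    x_s = np.full(2, x_s0)
    F_s = np.zeros(2)

    out = np.zeros(n_frames + 1)
    pos = 0.0
    vfac = 0.5 if half_velocity else 1.0
    step = 0
    for frame in range(n_frames + 1):
        n_sub = burn_steps if frame == 0 else record_every
        for _ in range(n_sub):
            step += 1
            v_r0 = 0.0
            v_r1 = 0.0
            for e in range(2):
                # 1. motor load and Hill retrograde flow
                F_load = F_s[e] if F_s[e] > 0.0 else 0.0
                if F_stall > 0.0:
                    v_r = V_u * (1.0 - F_load / F_stall)
                    if v_r < 0.0:
                        v_r = 0.0
                    elif v_r > V_u:
                        v_r = V_u
                else:
                    v_r = 0.0
                if e == 0:
                    v_r0 = v_r
                else:
                    v_r1 = v_r

                # 2. advect bound clutches; accumulate coupling terms
                adv = v_r * dt
                S = 0.0
                n_b = 0
                for i in range(n_c):
                    if bound[e, i]:
                        x_c[e, i] += adv
                        S += x_c[e, i]
                        n_b += 1

                # 3. semi-implicit substrate solve with F_s(x_s) coupling
                A = k_c * S
                B = k_c * n_b
                x_new = (a_coef * x_s[e] + k_a * A + eta * (A - F_s[e]) / dt) / (
                    a_coef + k_a * k_l + k_a * B + eta * B / dt
                )
                x_s[e] = x_new

                # 4. Monte Carlo clutch kinetics at the new displacement
                F_tot = 0.0
                for i in range(n_c):
                    if bound[e, i]:
                        if resample_per_step and glassy:
                            u = 1.0 - np.random.random()
                            t_new = tau_min * u ** (-1.0 / (beta - 1.0))
                            if t_new > tau_max:
                                t_new = tau_max
                            tau_off[e, i] = t_new
                        F_c = k_c * (x_c[e, i] - x_new)
                        r_off = math.exp(abs(F_c) / F_bond) / tau_off[e, i]
                        if np.random.random() < -math.expm1(-r_off * dt):
                            bound[e, i] = False
                            x_c[e, i] = x_new
                        else:
                            F_tot += F_c
                    else:
                        x_c[e, i] = x_new
                        if np.random.random() < p_on:
                            bound[e, i] = True
                            if glassy:
                                u = 1.0 - np.random.random()
                                t_new = tau_min * u ** (-1.0 / (beta - 1.0))
                                if t_new > tau_max:
                                    t_new = tau_max
                                tau_off[e, i] = t_new
                            else:
                                tau_off[e, i] = tau_min
                # 5. force bookkeeping (newly bound clutches carry zero force)
                F_s[e] = F_tot

            pos += vfac * (v_r0 - v_r1) * dt
        if frame == 0:
            pos = 0.0  # burn-in displacement is discarded
        out[frame] = pos
        if not math.isfinite(pos):
            return out, step
    return out, -1


def _axis_positions(params: CellParams, seed: int) -> np.ndarray:
    dt = params.timestep
    record_every = int(round(params.record_interval / dt))
    burn_steps = int(round(params.burn_in / dt))
    x_s0 = 0.0
    if params.init_stationary:
        # stationary dashpot pre-extension under repeated loading to stall
        x_s0 = params.F_stall * (1.0 / params.k_l - 1.0 / (params.k_a + params.k_l))
    out, bad_step = _run_axis(
        np.uint32(seed), params.n_frames, record_every, burn_steps, dt,
        params.n_clutches, params.k_c, params.r_on, params.F_bond,
        params.N_m, params.F_motor, params.V_u,
        params.k_a, params.k_l, params.eta,
        params.off_time_mode == "glassy", params.beta, params.tau_min,
        params.tau_max, params.resample_per_step, params.half_velocity,
        x_s0,
    )
    if bad_step >= 0:
        raise IntegrationError(f"non-finite cell position at step {bad_step}")
    return out


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_cell(params: CellParams, seed) -> Trajectory:
    """Simulate one cell; identical ``(params, seed)`` gives an identical track.

    ``seed`` is an integer or a :class:`numpy.random.SeedSequence`; each axis
    receives its own deterministic substream.
    """
    ss = _as_seedseq(seed)
    axis_seeds = ss.generate_state(2)
    x = _axis_positions(params, axis_seeds[0])
    if params.dimensionality == 2:
        y = _axis_positions(params, axis_seeds[1])
    else:
        y = np.zeros_like(x)
    times = np.arange(params.n_frames + 1) * params.record_interval
    meta = {"seed": ss.entropy, "params": params.resolved(),
            "timescales": params.timescales()}
    return Trajectory(times=times, positions=np.column_stack([x, y]), meta=meta)


def simulate_ensemble(params: CellParams, n_cells: int, seed) -> list[Trajectory]:
    """Simulate ``n_cells`` independent cells from deterministic child streams.

    Child RNG streams are spawned from ``seed`` so the result is independent
    of evaluation order, and ``n_cells = 1`` coincides with
    :func:`simulate_cell` on the first child stream.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    children = _as_seedseq(seed).spawn(n_cells)
    out = []
    for i, child in enumerate(children):
        traj = simulate_cell(params, child)
        traj.meta["cell_id"] = i
        out.append(traj)
    return out


_SCENARIOS = ("control", "myosin_inhibited", "actin_inhibited")


def apply_scenario(params: CellParams, scenario: str,
                   factors: dict | None = None) -> CellParams:
    """Parameter modifiers for the actomyosin-inhibition in-silico experiments.

    ``myosin_inhibited`` scales the motor count ``N_m`` (default factor 0.5),
    emulating reduced myosin II activity.  ``actin_inhibited`` scales both the
    unloaded flow / polymerization speed ``V_u`` and ``N_m`` (default factors
    0.5 each), since depolymerizing actin both slows protrusion and removes
    the scaffold myosin contracts against.  ``control`` is the identity.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
    factors = dict(factors or {})
    for name, f in factors.items():
        if not (0.0 < f <= 1.0):
            raise ValueError(f"scenario factor {name}={f} must be in (0, 1]")
    if scenario == "control":
        return params
    if scenario == "myosin_inhibited":
        f = factors.get("N_m", 0.5)
        return replace(params, N_m=max(1, int(round(params.N_m * f))))
    f_v = factors.get("V_u", 0.5)
    f_m = factors.get("N_m", 0.5)
    return replace(params, V_u=params.V_u * f_v,
                   N_m=max(1, int(round(params.N_m * f_m))))


def nondimensionalize(traj: Trajectory, params: CellParams) -> Trajectory:
    """Rescale a track to clutch units: time by ``1/r_on``, length by ``v_p/r_on``.

    The polymerization speed ``v_p`` is identified with the unloaded flow
    scale ``V_u`` (both measure the free actin speed at a protruding end).
    """
    if params.r_on <= 0 or params.V_u <= 0:
        raise ValueError("nondimensional units require r_on > 0 and V_u > 0")
    scale_t = params.r_on
    scale_x = params.r_on / params.V_u
    return Trajectory(times=traj.times * scale_t,
                      positions=traj.positions * scale_x,
                      meta={**traj.meta, "nondimensional": True})
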