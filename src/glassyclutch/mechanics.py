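"""Single protruding-end physics of the motor-clutch module.

One cell end couples three elements:

* a set of molecular clutches — Hookean springs of stiffness ``k_c`` that
  stochastically engage (constant rate ``r_on``) and disengage (Bell slip-bond
  rate ``r_off = exp(|F_c|/F_bond) / tau_off``), with the dissociation time
  constant ``tau_off`` drawn from the glassy power law at each binding event;
* a standard-linear-solid (SLS) substrate element — spring ``k_l`` in parallel
  with (spring ``k_a`` in series with dashpot ``eta``) — carrying the summed
  clutch force ``F_s = sum k_c (x_c,i - x_s)`` and relaxing stress on the
  timescale ``tau_s = eta / k_a``;
* a myosin motor ensemble driving retrograde actin flow by the linear Hill
  relation ``V_r = V_u (1 - F_load / F_stall)``, where the motor load is the
  total clutch force on this end (quasi-static force balance across
  motors, clutches and substrate).

Engaged clutches ride the actin flow (``x_c`` advected at ``V_r``);
disengaged clutches track the substrate so that re-binding occurs at zero
extension.  The SLS ordinary differential equation is discretized with a
semi-implicit (backward-Euler in ``x_s``) scheme, with the clutch-force
dependence on ``x_s`` folded into the linear solve, so the update is stable
for any timestep that resolves the kinetics.

Units throughout: seconds, nanometers, piconewtons (stiffness pN/nm,
viscosity pN*s/nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .heavytail import ConstantOffTime, OffTimeDistribution

__all__ = [
    "Clutch",
    "SubstrateSLS",
    "MotorEnsemble",
    "EndModule",
    "bell_off_rate",
    "hill_retrograde",
    "clutch_kinetics_step",
    "substrate_step",
    "end_step",
    "relax_at_fixed_displacement",
    "force_relaxation_efolding",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered during time stepping."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Clutch:
    """One adhesion clutch: binding state, spring top end, drawn tau_off."""

    bound: bool = False
    x_c: float = 0.0        # nm, position of the actin-side end of the spring
    tau_off: float = math.inf  # s, current dissociation time constant

    def force(self, x_s: float, k_c: float) -> float:
        """Spring force k_c (x_c - x_s); zero when unbound."""
        return k_c * (self.x_c - x_s) if self.bound else 0.0


@dataclass
class SubstrateSLS:
    """Standard-linear-solid substrate element and its displacement state."""

    k_a: float              # pN/nm, additional-branch stiffness
    k_l: float              # pN/nm, long-term stiffness
    eta: float              # pN*s/nm, dashpot viscosity
    x_s: float = 0.0        # nm, substrate displacement
    F_s: float = 0.0        # pN, force currently transmitted

    def __post_init__(self) -> None:
        for name in ("k_a", "k_l", "eta"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def tau_s(self) -> float:
        """Stress-relaxation timescale eta / k_a (s)."""
        return self.eta / self.k_a


@dataclass
class MotorEnsemble:
    """Myosin motors of one end: count, single-motor stall force, free speed."""

    N_m: int                # number of motors (>= 0)
    F_motor: float          # pN, single-motor stall force
    V_u: float              # nm/s, unloaded retrograde flow speed

    def __post_init__(self) -> None:
        if self.N_m < 0:
            raise ValueError(f"N_m must be >= 0, got {self.N_m}")
        if self.F_motor <= 0 or self.V_u < 0:
            raise ValueError("F_motor must be > 0 and V_u >= 0")

    @property
    def F_stall(self) -> float:
        """Ensemble stall force N_m * F_motor (pN)."""
        return self.N_m * self.F_motor


@dataclass
class EndModule:
    """One protruding end: clutch ensemble + SLS substrate + motors."""

    clutches: list[Clutch]
    substrate: SubstrateSLS
    motors: MotorEnsemble
    k_c: float              # pN/nm clutch spring stiffness
    r_on: float             # 1/s association rate
    F_bond: float           # pN Bell characteristic rupture force
    off_dist: OffTimeDistribution | ConstantOffTime
    V_r: float = field(default=0.0)  # nm/s, current retrograde flow
    resample_per_step: bool = False  # redraw tau_off of bound clutches each step

    @classmethod
    def fresh(cls, n_clutches: int, substrate: SubstrateSLS, motors: MotorEnsemble,
              k_c: float, r_on: float, F_bond: float, off_dist,
              resample_per_step: bool = False) -> "EndModule":
        return cls(
            clutches=[Clutch() for _ in range(n_clutches)],
            substrate=substrate, motors=motors, k_c=k_c, r_on=r_on,
            F_bond=F_bond, off_dist=off_dist,
            resample_per_step=resample_per_step,
        )

    def total_clutch_force(self) -> float:
        """F_s = sum over bound clutches of k_c (x_c,i - x_s)."""
        x_s = self.substrate.x_s
        return sum(c.force(x_s, self.k_c) for c in self.clutches)

    @property
    def n_bound(self) -> int:
        return sum(c.bound for c in self.clutches)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def bell_off_rate(F_c: float, tau_off: float, F_bond: float) -> float:
    """Slip-bond dissociation rate (1/s): exp(|F_c| / F_bond) / tau_off.

    The magnitude of the clutch force is used — tension amplifies rupture,
    compression does not (slip bond, no catch behavior).
    """
    if tau_off <= 0.0:
        raise ValueError(f"tau_off must be positive, got {tau_off}")
    if F_bond <= 0.0:
        raise ValueError(f"F_bond must be positive, got {F_bond}")
    return math.exp(abs(F_c) / F_bond) / tau_off


def hill_retrograde(F_load: float, motors: MotorEnsemble) -> float:
    """Linear Hill force-velocity relation, clamped to [0, V_u].

    ``V_r = V_u (1 - F_load / F_stall)``; at stall the flow stops rather than
    reversing.  With no motors there is no flow.
    """
    if F_load < 0.0:
        raise ValueError(
            f"F_load must be >= 0 (sign convention: load opposes motors), got {F_load}"
        )
    if motors.N_m == 0:
        return 0.0
    v = motors.V_u * (1.0 - F_load / motors.F_stall)
    return min(max(v, 0.0), motors.V_u)


def clutch_kinetics_step(clutch: Clutch, r_on: float, r_off: float, dt: float,
                         x_s: float, off_dist, rng: np.random.Generator) -> Clutch:
    """One Monte Carlo kinetics step for a single clutch (in place).

    Transition probabilities use the exact exponential survival form
    ``1 - exp(-r dt)`` so that arbitrarily large Bell-amplified rates map to
    probabilities in [0, 1).  At most one transition occurs per step.  A
    binding event places the clutch at zero extension (``x_c = x_s``) and
    draws a fresh ``tau_off`` from the glassy law.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    u = rng.random()
    if clutch.bound:
        if u < -math.expm1(-r_off * dt):
            clutch.bound = False
            clutch.x_c = x_s
            clutch.tau_off = math.inf
    else:
        if u < -math.expm1(-r_on * dt):
            clutch.bound = True
            clutch.x_c = x_s
            clutch.tau_off = float(off_dist.sample(rng))
    return clutch


def substrate_step(sub: SubstrateSLS, F_s_new: float, dt: float) -> float:
    """Advance the SLS displacement one step under a prescribed force.

    Discretizes ``(k_a + k_l) eta dx_s/dt + k_a k_l x_s = k_a F_s + eta dF_s/dt``
    with backward Euler in ``x_s`` and a finite-difference force derivative
    ``(F_s_new - F_s_old)/dt``.  The scheme is unconditionally stable for this
    linear ODE; a ``dt <= tau_s / 10`` accuracy bound is enforced regardless.
    Returns and stores the new displacement, and stores ``F_s_new``.
    """
    tau_s = sub.tau_s
    if dt > tau_s / 10.0 + 1e-15:
        raise ValueError(
            f"dt = {dt} violates the accuracy bound dt <= tau_s/10 = {tau_s / 10.0}"
        )
    ka, kl, eta = sub.k_a, sub.k_l, sub.eta
    a = (ka + kl) * eta / dt
    x_new = (a * sub.x_s + ka * F_s_new + eta * (F_s_new - sub.F_s) / dt) / (
        a + ka * kl
    )
    sub.x_s = x_new
    sub.F_s = F_s_new
    return x_new


def end_step(end: EndModule, dt: float, rng: np.random.Generator,
             step_index: int | None = None) -> EndModule:
    """Advance one protruding end by one timestep ``dt`` (in place).

    Order of sub-steps:

    1. motor load = current total clutch force (clamped at 0 from below);
       retrograde flow from the Hill relation;
    2. bound clutches advected with the actin flow, ``x_c += V_r dt``;
    3. substrate displacement advanced semi-implicitly with the clutch-force
       coupling ``F_s(x_s) = k_c sum_bound x_c,i - n_b k_c x_s`` folded into
       the linear solve; unbound clutches then track the substrate;
    4. per-clutch Bell rates evaluated at the new displacement and Monte
       Carlo binding/unbinding applied;
    5. the stored total force re-established from the post-kinetics state.
    """
    sub = end.substrate
    motors = end.motors

    # 1. motor load and retrograde flow
    F_load = max(sub.F_s, 0.0)
    end.V_r = hill_retrograde(F_load, motors)

    # 2. advect bound clutches with the actin flow
    for c in end.clutches:
        if c.bound:
            c.x_c += end.V_r * dt

    # 3. coupled semi-implicit substrate solve:
    #    F_s_new = A - B x_s_new with A = k_c sum_bound x_c, B = n_b k_c
    bound = [c for c in end.clutches if c.bound]
    A = end.k_c * sum(c.x_c for c in bound)
    B = end.k_c * len(bound)
    ka, kl, eta = sub.k_a, sub.k_l, sub.eta
    tau_s = sub.tau_s
    if dt > tau_s / 10.0 + 1e-15:
        raise ValueError(
            f"dt = {dt} violates the accuracy bound dt <= tau_s/10 = {tau_s / 10.0}"
        )
    a = (ka + kl) * eta / dt
    x_new = (a * sub.x_s + ka * A + eta * (A - sub.F_s) / dt) / (
        a + ka * kl + ka * B + eta * B / dt
    )
    sub.x_s = x_new
    sub.F_s = A - B * x_new
    for c in end.clutches:
        if not c.bound:
            c.x_c = x_new

    # 4. Monte Carlo kinetics at the new substrate displacement
    if end.resample_per_step:
        for c in end.clutches:
            if c.bound:
                c.tau_off = float(end.off_dist.sample(rng))
    for c in end.clutches:
        if c.bound:
            r_off = bell_off_rate(end.k_c * (c.x_c - x_new), c.tau_off, end.F_bond)
            clutch_kinetics_step(c, end.r_on, r_off, dt, x_new, end.off_dist, rng)
        else:
            clutch_kinetics_step(c, end.r_on, 0.0, dt, x_new, end.off_dist, rng)

    # 5. re-establish the force bookkeeping invariant
    sub.F_s = end.total_clutch_force()

    if not (math.isfinite(sub.F_s) and math.isfinite(sub.x_s)):
        where = "" if step_index is None else f" at step {step_index}"
        raise IntegrationError(f"non-finite end state{where}: F_s={sub.F_s}, x_s={sub.x_s}")
    return end


# ---------------------------------------------------------------------------
# substrate diagnostics
# ---------------------------------------------------------------------------

def relax_at_fixed_displacement(sub: SubstrateSLS, x_hold: float, t_end: float,
                                dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Force history of the SLS element held at a fixed displacement.

    With ``dx_s/dt = 0`` the SLS equation reduces to
    ``dF_s/dt = (k_a / eta) (k_l x_hold - F_s)``: the force decays toward the
    long-term spring value ``k_l x_hold`` with e-folding time
    ``tau_s = eta / k_a``.  Integrated with the same backward-Euler scheme as
    the coupled solver.  Returns ``(times, forces)`` including t = 0.
    """
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    F = np.empty(n + 1)
    F[0] = sub.F_s
    r = dt * sub.k_a / sub.eta
    target = sub.k_l * x_hold
    f = sub.F_s
    for i in range(1, n + 1):
        f = (f + r * target) / (1.0 + r)
        F[i] = f
    sub.F_s = f
    sub.x_s = x_hold
    return t, F


def force_relaxation_efolding(sub: SubstrateSLS, x_hold: float, dt: float) -> float:
    """Measured e-folding time of the force excess under fixed displacement.

    Runs :func:`relax_at_fixed_displacement` for ``5 tau_s`` and returns the
    (log-linearly interpolated) time at which the excess of the force over
    its long-term value ``k_l x_hold`` has fallen by a factor e.
    """
    target = sub.k_l * x_hold
    e0 = sub.F_s - target
    if e0 == 0.0:
        raise ValueError("initial force offset is zero; relaxation unobservable")
    t, F = relax_at_fixed_displacement(sub, x_hold, 5.0 * sub.tau_s, dt)
    excess = (F - target) / e0
    below = np.nonzero(excess <= math.exp(-1.0))[0]
    i = below[0]
    # log-linear interpolation between the straddling samples
    l0, l1 = math.log(excess[i - 1]), math.log(excess[i])
    frac = (-1.0 - l0) / (l1 - l0)
    return float(t[i - 1] + frac * dt)
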