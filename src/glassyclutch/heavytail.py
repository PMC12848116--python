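"""Power-law distribution of clutch dissociation time constants.

Adhesion clusters are supramolecular assemblies (integrin, talin, vinculin,
zyxin, ...) whose coupled unfolding/unbinding proceeds over a rugged energy
landscape with many metastable states.  The net effect is that the
characteristic dissociation time constant of a clutch is not a single number
but a broad, glass-like spectrum.  We model it as a Pareto-type power law on
``[tau_min, inf)``::

    p(tau) = (beta - 1) / tau_min * (tau / tau_min) ** (-beta)

``beta`` is the glass coefficient: small ``beta`` (<= 3) gives a divergent
variance and heavy tails (the glassy regime); large ``beta`` concentrates all
mass near ``tau_min``, recovering the conventional constant-off-time
motor-clutch model as a limit.  A degenerate constant distribution is also
provided so the conventional model can be selected exactly rather than
through a large-``beta`` approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OffTimeDistribution",
    "ConstantOffTime",
    "make_off_time_distribution",
]


class InvalidDistributionError(ValueError):
    """Raised for non-normalizable parameter choices (beta <= 1, tau_min <= 0)."""


@dataclass(frozen=True)
class OffTimeDistribution:
    """Power-law law for the clutch dissociation time constant tau_off.

    Parameters
    ----------
    beta
        Glass coefficient (dimensionless).  Must be > 1 for the density to be
        normalizable on ``[tau_min, inf)``.
    tau_min
        Characteristic minimum dissociation time in seconds (> 0).
    tau_max
        Optional upper truncation, for numerical hygiene only.  Defaults to
        ``inf`` (untruncated): truncation destroys the heavy tail that drives
        the glassy dynamics, so it is never applied silently.
    """

    beta: float
    tau_min: float
    tau_max: float = field(default=math.inf)

    def __post_init__(self) -> None:
        if not (self.beta > 1.0):
            raise InvalidDistributionError(
                f"glass coefficient beta must be > 1 (got {self.beta}); "
                "the power law is not normalizable otherwise"
            )
        if not (self.tau_min > 0.0):
            raise InvalidDistributionError(
                f"tau_min must be positive seconds (got {self.tau_min})"
            )
        if not (self.tau_max > self.tau_min):
            raise InvalidDistributionError(
                f"tau_max ({self.tau_max}) must exceed tau_min ({self.tau_min})"
            )

    # -- law ---------------------------------------------------------------

    def pdf(self, tau):
        """Probability density at ``tau`` (1/seconds); 0 below ``tau_min``."""
        tau = np.asarray(tau, dtype=float)
        out = np.where(
            (tau >= self.tau_min) & (tau <= self.tau_max),
            (self.beta - 1.0) / self.tau_min
            * (np.maximum(tau, self.tau_min) / self.tau_min) ** (-self.beta)
            / self._trunc_mass,
            0.0,
        )
        return out if out.ndim else float(out)

    def cdf(self, tau):
        """P(tau_off <= tau); 0 below ``tau_min``, monotone to 1."""
        tau = np.asarray(tau, dtype=float)
        t = np.clip(tau, self.tau_min, self.tau_max)
        out = np.where(
            tau < self.tau_min,
            0.0,
            (1.0 - (t / self.tau_min) ** (1.0 - self.beta)) / self._trunc_mass,
        )
        return out if out.ndim else float(out)

    @property
    def _trunc_mass(self) -> float:
        # mass of the untruncated law below tau_max (1 when tau_max = inf)
        if math.isinf(self.tau_max):
            return 1.0
        return 1.0 - (self.tau_max / self.tau_min) ** (1.0 - self.beta)

    def ppf(self, u):
        """Inverse CDF: tau = tau_min * (1 - u)^(-1/(beta-1)) on the open unit interval.

        Written so that ``u -> 1`` maps to the tail and ``u = 0`` to
        ``tau_min`` exactly, matching the analytic CDF above.
        """
        u = np.asarray(u, dtype=float)
        out = self.tau_min * (1.0 - u * self._trunc_mass) ** (-1.0 / (self.beta - 1.0))
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        """Inverse-transform draws: tau = tau_min * u^(-1/(beta-1)), u ~ U(0, 1].

        Output is always >= tau_min; reproducible under a fixed generator
        state.  ``rng.random()`` yields [0, 1), so ``1 - u`` is used to obtain
        the half-open (0, 1] needed for a finite draw.
        """
        u = rng.random(size)
        return self.ppf(u)

    # -- diagnostics --------------------------------------------------------

    def moment(self, k: int) -> tuple[float, bool]:
        """k-th raw moment as ``(value, finite)``.

        The mean (k=1) is ``tau_min * (beta-1)/(beta-2)`` and is finite only
        for beta > 2; the second moment requires beta > 3.  Divergent moments
        are flagged ``(inf, False)`` rather than approximated — the divergence
        is the physics (it breaks the central limit theorem and makes the
        glassy regime non-Gaussian).
        """
        if k not in (1, 2):
            raise ValueError(f"moment order must be 1 or 2, got {k}")
        if math.isinf(self.tau_max) and self.beta <= k + 1:
            return (math.inf, False)
        b, tm, tx = self.beta, self.tau_min, self.tau_max
        if math.isinf(tx):
            val = tm**k * (b - 1.0) / (b - 1.0 - k)
        else:
            c = (b - 1.0) / tm / self._trunc_mass
            p = k - b
            if abs(p + 1.0) < 1e-12:  # logarithmic case
                val = c * tm ** (b) * (math.log(tx) - math.log(tm))
            else:
                val = c * tm**b * (tx ** (p + 1) - tm ** (p + 1)) / (p + 1)
        return (float(val), True)

    @property
    def mean(self) -> tuple[float, bool]:
        return self.moment(1)

    @property
    def variance(self) -> tuple[float, bool]:
        m2, ok2 = self.moment(2)
        if not ok2:
            return (math.inf, False)
        m1, _ = self.moment(1)
        return (m2 - m1 * m1, True)


@dataclass(frozen=True)
class ConstantOffTime:
    """Degenerate law returning ``tau_min`` always (conventional model).

    Selected by the ``off_time_mode = constant`` configuration flag rather
    than by a large glass coefficient, so constancy is exact.
    """

    tau_min: float

    def __post_init__(self) -> None:
        if not (self.tau_min > 0.0):
            raise InvalidDistributionError(
                f"tau_min must be positive seconds (got {self.tau_min})"
            )

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.tau_min
        return np.full(size, self.tau_min)

    def moment(self, k: int) -> tuple[float, bool]:
        if k not in (1, 2):
            raise ValueError(f"moment order must be 1 or 2, got {k}")
        return (self.tau_min**k, True)


def make_off_time_distribution(mode: str, beta: float, tau_min: float,
                               tau_max: float = math.inf):
    """Build the off-time law from config keys (mode in {glassy, constant})."""
    if mode == "glassy":
        return OffTimeDistribution(beta=beta, tau_min=tau_min, tau_max=tau_max)
    if mode == "constant":
        return ConstantOffTime(tau_min=tau_min)
    raise ValueError(f"off_time_mode must be 'glassy' or 'constant', got {mode!r}")
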