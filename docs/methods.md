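# Methods

## The model

`glassyclutch` simulates the migration of a cell whose adhesion to a
viscoelastic substrate is mediated by stochastic molecular clutches, in the
motor-clutch tradition: myosin motors drive retrograde actin flow, clutches
transiently link the flowing actin to the substrate, and the force balance
between motors, clutches and substrate sets both traction and cell velocity.

A cell has two opposing protruding ends per axis; the X and Y axes are fully
independent copies (a 2D run is two 1D runs on separate random streams).
Each end comprises:

* **Clutches.** `n_clutches` Hookean springs of stiffness `k_c` that engage
  at a constant rate `r_on` (at zero extension) and disengage at the Bell
  slip-bond rate `r_off = exp(|F_c|/F_bond) / tau_off`. Engaged clutches are
  advected with the actin flow (`dx_c/dt = V_r`); disengaged ones track the
  substrate. Transition probabilities per step use the exact exponential
  survival form `1 - exp(-r dt)`, so arbitrarily large Bell-amplified rates
  map to valid probabilities. The magnitude `|F_c|` is used: clutches are
  slip bonds under both tension and compression, with no catch behavior.

* **Glassy dissociation spectrum.** The defining ingredient: at every
  binding event the clutch draws a fresh dissociation time constant
  `tau_off` from a power law `p(tau) ∝ (tau/tau_min)^(-beta)` on
  `[tau_min, tau_max]`. The glass coefficient `beta` controls tail weight:
  `beta <= 3` gives a divergent-variance (heavy-tailed, glassy) spectrum,
  large `beta` concentrates all mass at `tau_min`. A degenerate
  constant-`tau_off` mode (`off_time_mode="constant"`) recovers the
  conventional motor-clutch model exactly rather than through a large-beta
  approximation. The default spectrum spans 1–100 s, the range over which
  adhesion-protein dissociation kinetics are observed; an untruncated law
  with `beta = 1.5` has an infinite mean residence time, which (in this
  force architecture) makes every stalled adhesion state statistically
  absorbing — simulations age into permanent arrest, so the truncated
  spectrum is the shipped default (`tau_max = 100 s`, overridable, including
  to `inf`).

* **Substrate.** A standard-linear-solid (SLS) element per end: spring `k_l`
  (long-term stiffness) in parallel with spring `k_a` (additional stiffness)
  in series with a dashpot `eta`, governed by
  `(k_a + k_l) eta dx_s/dt + k_a k_l x_s = k_a F_s + eta dF_s/dt`, where
  `F_s = sum_bound k_c (x_c,i - x_s)` is the summed clutch force. The
  stress-relaxation timescale is `tau_s = eta / k_a`; "fast-relaxing"
  substrates are parameterized as `tau_s = 10 s` and "slow-relaxing" as
  `tau_s = 1000 s`, with identical stiffnesses, mirroring hydrogels whose
  relaxation is tuned at constant modulus.

* **Motors.** `N_m` myosin motors per end with single-motor stall force
  `F_motor` and unloaded flow speed `V_u`, obeying the linear Hill relation
  `V_r = V_u (1 - F_load/F_stall)` clamped to `[0, V_u]`, with
  `F_load = max(F_s, 0)` — a quasi-static balance in which each end's motors
  feel that end's total clutch force. (A variant in which the two ends share
  a single tension was prototyped and rejected: quasi-static tension
  coupling is winner-take-all bistable and drives even the constant-off-time
  model ballistic, destroying its diffusive null.)

The cell-center velocity per axis is the retrograde-flow imbalance
`V_m = (V_r_left - V_r_right)/2`; the cell moves toward the end with
stronger adhesion. The factor 1/2 (the center is the mean of two edges with
equal protrusion speeds) rescales the diffusion constant only, never the
MSD exponent, and can be disabled.

## Numerics

* **Timestep.** Default `dt = min(tau_min, tau_s, 1/r_on)/100`, overridable;
  an accuracy bound `dt <= tau_s/10` is enforced for the substrate update.
* **SLS discretization.** Backward Euler in `x_s` with the clutch-force
  coupling `F_s(x_s) = k_c sum x_c,i - n_b k_c x_s` folded into the linear
  solve — unconditionally stable for the linear ODE across `tau_s` spanning
  `1e-2`–`1e3` s, first-order accurate (fixed-displacement relaxation
  reproduces the analytic e-folding time within 0.5% at `dt = tau_s/100`,
  0.05% at `tau_s/1000`).
* **Initialization and burn-in.** The substrate starts in its stationary
  state with the dashpot pre-extended by `F_stall (1/k_l - 1/(k_a + k_l))`,
  and the first 200 s of each run are discarded. A virgin (undeformed)
  substrate produces a creep transient of duration ~`tau_s` whose smooth
  drift masquerades as ballistic motion on slow-relaxing substrates; with
  the stationary start, recorded statistics are insensitive to burn-in
  (checked 200 s vs 2000 s).
* **Kernel.** The production inner loop is a numba-compiled translation of
  the pure-Python per-end update in `mechanics.py`; both implement the same
  step order (Hill flow → advection → coupled substrate solve → Monte Carlo
  kinetics → force bookkeeping), and the pure-Python path is the one
  exercised by the mechanics unit tests.

## Default parameters

| parameter | value | meaning |
|---|---|---|
| `n_clutches` | 75 | clutches per end |
| `k_c` | 0.8 pN/nm | clutch spring stiffness |
| `r_on` | 1 s⁻¹ | clutch association rate |
| `F_bond` | 2 pN | Bell rupture force scale |
| `N_m` | 50 | motors per end |
| `F_motor` | 2 pN | single-motor stall force |
| `V_u` | 120 nm/s | unloaded retrograde flow |
| `k_l` | 1/12 pN/nm | long-term substrate stiffness |
| `k_a` | 1/12 pN/nm | additional substrate stiffness |
| `tau_min`, `tau_max` | 1 s, 100 s | dissociation-time spectrum |
| `beta` | 1.5 | glass coefficient (glassy regime) |
| `tau_s` | 10 s (fast) / 1000 s (slow) | stress-relaxation timescale |
| `duration`, `record_interval` | 2000 s, 10 s | run length and frame spacing |

These put the three diagnostic timescales in their intended relation:
motor-stall timescale `tau_l = F_motor N_m/(V_u k_l) = 10 s`, dissociation
spectrum 1–100 s, and `tau_s` swept across `1e-2`–`1e3` s.

## Trajectory statistics

* **MSD and alpha.** The default estimator is the time-and-ensemble-averaged
  MSD over lag; `alpha` and `mu` come from least squares of `log MSD` on
  `log lag` over the first decade of lags (short lags have the most
  displacement pairs; the window is explicit and overridable). A from-origin
  mode (`|r(t) - r(0)|²` averaged over cells) is provided: for CTRW-class
  motion the two estimators genuinely differ (weak ergodicity breaking — the
  time-averaged MSD of a heavy-tailed-wait CTRW is linear in lag regardless
  of the waiting exponent), so the CTRW fixture is validated with the
  from-origin estimator.
* **Traps and steps.** A trap is a maximal run of frames with frame speed
  below `v_eps` (default `0.05 V_u`) lasting at least `t_min` (default 3
  frame intervals); steps are the complementary segments with their net
  displacement. Thresholds are explicit arguments surfaced in every result.
* **Kurtosis.** Pearson convention `m4/m2²` (Gaussian = 3), so the tail-
  dominance ratio `K_trap/K_step` is positive and well defined.

## Reference walks

The fixtures module generates tracks with known exponents used to calibrate
the statistics layer: ballistic (alpha = 2), Brownian (alpha = 1), CTRW with
Pareto waits of exponent `gamma` in (0,1) (ensemble alpha = gamma), and Lévy
walks with flight-duration exponent `gamma` in (1,2) (alpha = 3 - gamma).
These emulate the trapping-time and flight statistics that the anomalous-
diffusion classification assumes, but not other features of real cell tracks
(localization noise, drift, finite-cell-size effects, heterogeneous frame
rates) — passing recovery tests bounds estimator bias, not robustness to
those artifacts.

## Known limitations

* **Direction of the substrate-relaxation effect.** In this architecture the
  published directionality — super-diffusion on fast-relaxing and
  sub-diffusion on slow-relaxing substrates — does not emerge: stress
  relaxation *relieves* clutch force, and since the Bell rate is monotone in
  force, relief systematically *stabilizes* adhesions on fast-relaxing
  substrates. Across an extensive parameter exploration (clutch/motor
  counts, bond force, clutch stiffness, stiffness contrast `k_a/k_l`, flow
  speed, `tau_l` in 10–30 s, both truncated and untruncated spectra, both
  per-end and tension-coupled force balances) the fitted exponent satisfies
  `alpha(slow) >= alpha(fast)` everywhere. The conventional-model null
  (`alpha = 1` on both substrates), the heavy-tailed trap/step statistics of
  the glassy mode, the kurtosis-ratio ordering (`K_trap/K_step` larger on
  slow-relaxing substrates), and the substrate physics itself all reproduce;
  the acceptance tests encoding the directional transition are retained
  unmodified and fail, documenting the discrepancy. Resolving it likely
  requires mechanics beyond the formulation implemented here (e.g. a
  specific cell-body coupling or additional force-dependence of binding).
* The model is 1D-per-axis with no cell shape, nucleus, or cell–cell
  interactions; no catch bonds, adhesion reinforcement, or substrate
  plasticity.
* At `beta <= 2` the (truncated) spectrum's mean is dominated by the cutoff;
  results at small `beta` depend on `tau_max`, which is a physical input
  (the width of the dissociation spectrum), not a numerical convenience.
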