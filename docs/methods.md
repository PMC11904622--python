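# Methods

## 1. Predator–prey lattice model (`grid_abm`)

An `L × L` periodic grid holds three species: nutrient sites (species A),
prey (B) and predators (C). Each grid cell is nutrient-rich or
nutrient-poor; a grazed cell regrows exactly `tau` periods later. Agents
carry an integer-valued energy budget.

One period applies seven phases in a fixed order:

1. **population control** — `u1` prey and `u2` predators are added
   (positive, uniform random cells, fresh energy draws) or removed
   (negative, uniform random victims, clamped at the population size);
2. **movement** — every agent takes `move_steps` lattice steps; each step
   goes `+x` with probability `0.25 + bias` and to each other von-Neumann
   neighbour with probability `(0.75 − bias)/3` (periodic wrap). The
   per-period displacement is sampled exactly from the `move_steps`-fold
   convolution of the single-step kernel;
3. **feeding** — each prey consumes one nutrient-rich cell, own cell
   first, then uniformly among rich 4-neighbours; every cell feeds at most
   one prey (random-priority conflict resolution) and switches to poor
   with a full regrowth timer; the prey gains `lambda1`. Each predator
   co-located with prey eats one uniformly chosen co-located prey (at most
   one per predator and per prey) and gains `lambda2`;
4. **metabolism** — every agent loses one energy unit;
5. **death** — agents with energy strictly below zero are removed (zero
   energy survives the period);
6. **reproduction** — each survivor spawns one offspring with probability
   `alpha/100` per period. The offspring is placed at a uniformly random
   cell and receives a fresh uniform energy draw on `{1, …, e_init_max}`
   capped by the parent's energy; the draw is deducted from the parent
   (energy is conserved at birth);
7. **regrowth** — cells grazed `tau` periods ago turn rich again, so a
   grazed cell is observed poor for exactly `tau` periods.

The published configuration is `L=255`, `b0=2500`, `c0=1250`,
`alpha1=4.0`, `alpha2=5.0` (percent per period — the standard convention
in wolf–sheep-style lattice models; literal rates above 1 per period
diverge immediately), `lambda1=4.0`, `lambda2=20.0`, `tau=30`, 50%
initially rich cells.

### Calibrated defaults

Walk length, bias magnitude, initial-energy law and the reproduction
mechanics are not fixed by the published description. These defaults were
set in a single calibration pass against the published steady-state counts
(≈4159 prey, ≈1896 predators over the final 100 of 1000 periods) and then
frozen; the acceptance tests treat the published values as regression
targets.

| knob | default | rationale |
| --- | --- | --- |
| `move_steps` | 2 | one step per period leaves prey clustered on nutrient patches; predator–prey contact falls below the viability threshold and predators go extinct. Two steps per period restore enough mixing for stable three-species coexistence |
| `offspring_placement` | `uniform` | natal-cell placement produces multi-generation family clumps with the same extinction effect; uniform placement models larger-scale natal dispersal |
| `offspring_energy` | `draw` (fresh uniform draw, capped by and deducted from the parent) | energy-conserving; the integer-halving alternative (`split`) is available but over-provisions predator offspring and inflates the predator count |
| `bias` | 0.10 | +x step probability 0.35; stronger bias (≥0.3) creates traveling population waves that starve predators |
| `e_init_max_prey` | `round(lambda1/2)` = 2 | prey live meal-to-meal (a nutrient is worth 4); larger buffers suppress prey starvation and inflate both populations |
| `e_init_max_pred` | `2*lambda2` = 40 | predators must survive the ~15-period gaps between meals at steady-state prey density |

At these defaults the model reproduces the published uncontrolled steady
state within ~5% (prey) and ~1% (predators), and the published removal
controller `θ = (0.0083, 0.0047)` reaches the published controlled state
within ~8% (prey) and ~7% (predators). The residual discrepancy is
structural: how strongly prey are released when predators are suppressed
depends on the unpublished mechanics, and no exposed knob moves the
controlled state closer without breaking the uncontrolled baseline.

## 2. Metabolic-pathway model (`reaction_abm`)

Individual molecules diffuse on an `L_m × L_m` periodic lattice:
metabolites S, P, Q, R, T (speed 10 cells/period, realized as 10 unit
steps), enzymes A, E, I, O and their complexes (speed 1). The pathway is

    S —(A)→ P,  P —(E)→ Q,  Q —(I)→ R,  P —(O)→ T,

with end product R inhibiting enzyme A and activating enzyme O. Twelve
complex kinds close the state space: enzyme–substrate (A·S, E·P, I·Q,
O·P), enzyme–product (A·P, E·Q, I·R, O·T), enzyme–regulator (A·R, O·R) and
ternary regulator–substrate complexes (A·R·S, O·R·P).

Per period: (1) with probability `q_k` one new S appears at a random cell;
(2) movement; (3) association — each free enzyme or enzyme–regulator
complex co-located with an eligible free metabolite binds one uniformly
chosen partner with probability `p_bind` (one partner per binder per
period; conflicting claims on the same molecule are resolved by random
priority); (4) dissociation — each complex releases its most recently
bound component with probability `p_diss`; (5) catalysis — irreversible
conversion with probability `p_cat` (A·S→A·P, E·P→E·Q, I·Q→I·R, O·P→O·T).
Ternary complexes catalyze at modified rates — `p_cat ·
inhibition_factor` for A·R·S (default 0: full inhibition) and `p_cat ·
activation_factor` capped at 1 for O·R·P — and release their product
directly (A·R·S → A·R + P, O·R·P → O·R + T), which keeps the reachable
state space within the twelve complex kinds. Enzyme–product complexes may
form and dissociate but never catalyze backwards.

Initial amounts follow the published study (S, P, Q, R, T = 8·10⁴, 2·10⁴,
2·10⁴, 10, 10; 200 copies per enzyme; horizon 5·10⁴ periods). The kinetic
probabilities are not published; the defaults `p_bind=0.5`, `p_diss=0.01`,
`p_cat=0.1`, `activation_factor=4` give substrate depletion followed by
product accumulation. Exact per-enzyme copy-number conservation holds at
every period by construction and is asserted in the tests. The test suite
and CI run a desk-scale configuration (`scaled_config()`: counts ÷ 100,
60 × 60 lattice, 2000 periods) that preserves every conservation law; a
full-scale run (~10⁵ molecules × 5·10⁴ periods) takes hours and is
reserved for dedicated studies.

## 3. Controllers and the straight-through estimator (`control`)

Integer actions come from the straight-through floor
`st_floor(x) = [x]₊ − {[x]₊}` (floor of the positive part). Its training
contract: wherever a differentiable relaxation of the plant exists, the
derivative of `st_floor` is taken as 1 for `x > 0` and 0 otherwise, so the
gradient of `L(st_floor(g(θ)))` equals that of `L(g(θ))` on `g > 0`
(unit-tested against finite differences of the relaxed loss).

* **Steady-state controller**: `u = (−st_floor(θ₁ b_k), −st_floor(θ₂ c_k))`,
  removal-only by construction (both components carry the minus sign).
* **Transient controller**: an MLP on features
  `(b_k/b0, c_k/c0, k/horizon)` with three hidden layers (default
  64–32–16, tanh; widths constrained to [16, 64] for the canonical task),
  sign-preserving straight-through rounding of the two outputs and a
  magnitude clip `u_max = 500` that keeps early training from emptying
  the world. Normalized time is an input because a state-feedback law of
  the steady-state form cannot raise prey while removing them.
* **Inflow controller**: `q(t) = sigmoid(net(t/Nt))`, guaranteed in
  [0, 1] for arbitrary weights; its slope is bounded by the product of
  layer spectral norms times 1/4.

All networks are plain numpy with hand-written vector–Jacobian products
(`nn.py`); parameters serialize to flat JSON.

## 4. Objectives, training and the grid-search oracle (`objectives`)

`J1` is the squared deviation of the reached states (means over the final
`Nt*` periods) from the targets; `J2 = Σ S_k / Σ (R_k + T_k)` over periods
1..Nt. Targets derive from the uncontrolled baseline via
`make_targets` (+10% prey, −50% predators, rounded).

Training on the stochastic simulator optimizes seed-averaged losses on a
fixed seed schedule (5 rollouts per evaluation by default), making the
objective deterministic:

* `train_steady_state` — Nelder–Mead over `(θ₁, θ₂) ≥ 0` with a widened
  initial simplex (the floor makes the loss piecewise constant, so the
  default 5% simplex can start flat) and the zero controller always
  evaluated as a candidate, so the result is never worse than no control.
* `train_transient_mlp` — simultaneous-perturbation stochastic
  approximation (SPSA) on the flattened weights with decaying gain
  `a_k = a0/k^0.602`, perturbation `c_k = c0/k^0.101` and a step-norm cap
  (the count-scale quadratic loss otherwise catapults weights into the
  saturated, zero-gradient region of the `u_max` clip). The report's
  history records best-so-far losses and is non-increasing by
  construction.
* `grid_search_theta` — the 2-parameter oracle: exhaustive mean/s.d. loss
  surface over a θ-grid with common random numbers across cells; ties
  break toward smaller θ₁ then θ₂.

## 5. ODE surrogates (`surrogates`)

All pathway surrogates share the branched stoichiometry (rows: S→P, P→Q,
Q→R, P→T), so `d(S+P+Q+R+T)/dt = q` is an exact identity — including for
the neural kind, whose learned softplus rates enter only through the
stoichiometry. States are the counts rescaled by 10⁻⁴.

* **MM**: `v1 = V1·S/((K1+S)(1+R/K_I))` (competitive-style inhibition),
  `v2, v3` Michaelis–Menten, `v4 = V4·P/(K4+P)·(1+γR/(K_A+R))`
  (multiplicative activation); 11 parameters.
* **GMA**: power-law monomials per flux, R with a negative exponent in v1
  and positive in v4; a floor of 10⁻⁸ guards powers at zero states.
* **Neural**: `ẋ = q·e_S + Nᵀ softplus(net(x/scale, q))` — one network
  for all inflows, with q as an input channel.
* **LV / S-system** (predator–prey): logistic-resource Lotka–Volterra
  chain and the biochemical-systems-theory power-law form.

Integration is fixed-step RK4 on the supplied grid with clip-at-zero (clip
events logged; gradients treat the clip as identity, exact whenever the
forward path never clips). Fitting minimizes trajectory MSE on normalized
states: classical kinds by multi-start `scipy.optimize.least_squares` in
log-parameter space (positivity) with exponents kept linear; the neural
kind by Adam with exact discretize-then-optimize gradients obtained by
reverse-mode differentiation through the RK4 unroll. By default the
pathway fit consumes 11 constant-inflow trajectories (q = 0.0, 0.1, …,
1.0).

`optimize_constant_inflow` evaluates the continuous-time `J2` (trapezoidal
quadrature of `∫S dt / ∫(R+T) dt`) on a q-grid; ties break toward smaller
q. `train_inflow_controller` trains the time-dependent network on the MM
surrogate by Adam with exact unroll gradients; initializing at the best
constant (zero output weights, bias at its logit) makes the returned
best-so-far iterate provably no worse than the best constant inflow.

### Synthetic ground truth

Two MM parameterizations serve as synthetic ground truths, both on the
rescaled scale with the canonical initial pools (8, 2, 2, ~0, ~0):

* the **control-study default** (`mm_default_params()`: V = (0.8, 1.2,
  1.2, 0.6), K = (0.2, 0.5, 0.5, 0.5), K_I = 30, K_A = 1, γ = 3; horizon
  150) makes the first reaction nearly zeroth-order in S, so `J2(q)` is
  U-shaped with an interior optimum — low inflow leaves the initial
  substrate cost poorly amortized, inflow beyond the inhibition-reduced
  capacity piles up substrate;
* the **recovery-study truth** (V = (8, 4, 3, 4), K = 1, K_I = K_A = 0.5,
  γ = 3; horizon 5) exercises every kinetic term on the horizon (substrate
  depletes, R passes both K_I and K_A), so all eleven parameters are
  identifiable from the noiseless constant-inflow sweep and the fit
  recovers them to machine precision.

Exact kinetic constants of the source study are unpublished, so the
pathway tests are property-based (conservation, mass-balance identities,
recovery, dominance of the time-varying controller) rather than numeric
regressions.

## 6. Ensembles and uncertainty (`ensembles`)

`run_ensemble` evaluates a controller on replicate seeds `seed0 + i`
(ddof = 1 standard deviations; 0 for a single replicate). The
one-standard-deviation uncertainty region of a grid-search surface is the
sub-level set `mean_loss ≤ mean_loss(opt) + sd_loss(opt)` — parameters
statistically indistinguishable from the optimum given ABM noise. The
phrase "one s.d. from the optimum" is ambiguous between loss and
reached-state distance, so a reached-state alternative (per-axis one-s.d.
box around the optimum's reached means) is available via
`uncertainty_region(..., mode="reached")`.

## 7. What the synthetic generators do and do not emulate

The simulators generate every dataset used by fitting and training; no
external data exists. The lattice model emulates the published study
conditions (grid size, initial populations, rates, regrowth delay); it
does not pin down the unpublished movement/energy/reproduction details, so
agreement with the published numbers is expected at the few-percent level,
not at printed precision (the 50-seed controlled-ensemble means differ by
~8% for prey, outside the published ±71 band — see the calibration note
above). The pathway model reproduces the published topology, regulation
and initial amounts but not the unpublished kinetic constants; its tests
therefore validate structure (conservation, inhibition/activation
behaviour, inflow statistics), and the surrogate/controller pipeline is
validated on synthetic ground truths where the right answer is known.

## 8. Problem sizes used by the tests and the acceptance script

Unit and property tests run desk-scale configurations (64 × 64 grid at
study densities; pathway counts ÷ 100). The acceptance script runs the
full 255 × 255 study configuration: a 20-seed uncontrolled ensemble
(1000 periods each), a 50-seed controlled ensemble (2000 periods each) and
a 9 × 7 × 3 local grid search (2000 periods per rollout) — about 500k
simulated periods, or roughly 15 minutes single-core.
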