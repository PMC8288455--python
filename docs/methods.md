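# Methods

`rktumor` models the population ecology of two experimentally evolved tumor
cell phenotypes: **r cells**, selected at low density for a high intrinsic
growth rate, and **K cells**, selected at high density for competitive
ability and crowding tolerance. The package contains three simulators of
increasing structure (deterministic well-mixed, stochastic well-mixed with
serial passaging, spatial on-lattice), an estimator for the strength of the
between-type competition, and a generator of synthetic measurement data.
This note records the models, their assumptions, the defaults and why they
were chosen, and what the desk-scale experiments do and do not show.

## The competition model

The well-mixed core is the classical two-type competitive Lotka–Volterra
system,

```
dn_r/dt = r_r n_r (1 − (n_r + α n_K)/K_r)
dn_K/dt = r_K n_K (1 − (n_K + β n_r)/K_K)
```

with intrinsic per-capita rates `r_i` (per hour), carrying capacities `K_i`
(cells), and dimensionless competition coefficients: `α` converts K-cell
density into crowding felt by r cells, `β` the reverse. The asymmetric
setting `α = 2.2, β = 0` — K cells suppress r cells, r cells do not
measurably affect K cells — is the package-wide default interaction; it is
the configuration the estimator recovers from the shipped synthetic
reference dataset.

Long-run outcomes follow standard invasion analysis (`classify_outcome`):
r invades the K-only equilibrium iff `α < K_r/K_K`, K invades the r-only
equilibrium iff `β < K_K/K_r`; both criteria → coexistence, neither →
founder control, exactly one → exclusion. Knife-edge equalities are lumped
with the non-invading side.

**Integration.** Classic fixed-step 4th-order Runge–Kutta, default step
0.1 h. A fixed step keeps trajectories bit-reproducible across platforms;
the step-halving test bounds the discretization error below 10⁻⁶ relative.
Undershoots below zero (possible at very strong competition) are clamped to
zero with a warning — counts are physical.

**Default phenotypes (well-mixed).** r: `r_r = 0.05/h` (≈14 h doubling,
fast for a HeLa derivative), `K_r = 5×10⁴`; K: `r_K = 0.03/h` (≈23 h
doubling), `K_K = 10⁵`. The 2:1 capacity ratio encodes the r/K trade-off —
speed at the cost of crowding tolerance — and makes the interaction
coefficient identifiable: with `α = 2.2 > K_r/K_K = 0.5` the r population is
deterministically excluded under high-density passaging, while with
`α = β = 0` the two types stably coexist. These are desk-scale calibration
values, not measurements.

## Serial-passage simulator

A passage grows the co-culture stochastically for `passage_duration`
(default 48 h) and then reseeds `seed_size` cells (default 10% of the
capacity scale `capacity_total = 10⁵`) drawn without replacement from the
pooled population, so the reseeded composition is hypergeometric and
unbiased in the fraction. Pre-dilution states at each passage boundary are
the recorded observable, matching how mixed cultures are scored by flow
cytometry before splitting.

Within a passage the discrete-time binomial (τ-leap) scheme draws, per type
and step, `births ~ Binomial(n_i, b_i dt)` and `deaths ~ Binomial(n_i,
d_i dt)` with

```
b_i = r_i + d0_i            (constant per-capita birth)
d_i = d0_i + r_i (n_i + γ_ij n_j)/K_i    (density loaded onto death)
```

where `d0_i` is the baseline turnover and `γ_rK = α`, `γ_Kr = β`. The
expected net change per step reproduces the LV rates exactly; putting the
density dependence entirely on death reflects the biology of the system —
crowding acts on r cells chiefly by increasing their death rate, not by
throttling birth. The scheme costs O(steps) independent of population size.

**Numerical accuracy of the τ-leap.** The binomial update advances the mean
by a factor `(1 + r dt)` per step where the continuous model advances by
`e^{r dt}`; the scheme is therefore first-order accurate in `dt`. At the
protocol default `dt = 1 h` this bias is irrelevant for qualitative runs
but visible wherever stochastic means are compared quantitatively with the
ODE: the per-passage log-growth deficit (≈6% at `dt = 1` for `r = 0.05/h`)
shifts the fraction trajectory and, in estimation, masquerades as a spurious
`β ≈ +0.1`. Convergence checks put the bias safely below Monte-Carlo and
gating noise at `dt = 0.02 h`, which is the step used by the synthetic-data
generator and by the stochastic/mean-field agreement analyses. This is a
solver-step choice, like the RK4 step, not a change of experimental design.

**Deterministic passage map.** The ODE-mode counterpart integrates each
passage with RK4, rescales to `seed_size` preserving the fraction exactly,
and treats real-valued counts below **half a cell** as extinct. Without the
cutoff the ODE fraction decays forever without reaching zero, which is an
artifact of real-valued counts; the half-cell rule makes deterministic and
integer-valued stochastic trajectories comparable through extinction.

**Randomness.** One root seed per run; replicate `i` uses child stream `i`
of `numpy.random.SeedSequence(root).spawn(n)`. Identical configuration and
seed give bit-identical results. The optimized replicate loop consumes draws
in exactly the same order as the step-by-step API; a test asserts equality.

## Extinction analyses

`extinction_passage` reports the first passage (0 = seeding) at which
`n_r = 0` pre-dilution, with an explicit censoring flag at the horizon.
Medians treat censored replicates as +infinity.

Two regimes are exercised:

* **Competition-driven extinction** (defaults, 30 passages): for
  `α > K_r/K_K` exclusion is deterministic and faster for larger `α`
  (median extinction passage is non-increasing in `α` over {0, 1, 2, 3};
  at `α ≤ 1` with these capacities exclusion is too slow to resolve within
  30 passages and the medians are censored).
* **Drift-driven extinction** (`MICRO_CULTURE`: 10 cells reseeded into a
  100-cell capacity every 144 h, 200-passage horizon): with `α = β = 0` the
  LV structure protects each type when rare (mutual invasibility), so
  extinction can only occur by demographic sampling. At flow-cytometry
  scale (10⁴-cell reseeds) this essentially never happens — exploratory
  runs gave 0/100 extinctions in 150 passages — so the founder-number
  ordering of absorption times (fewer founding r cells → earlier
  extinction) is demonstrated in an explicit micro-culture regime where
  drift is visible. This is a demonstration of the absorption mechanism at
  demographic scale, not a claim about realistic culture volumes.

## Estimating α and β

`fit_interactions` does an exhaustive grid search (`α ∈ [0, 4]`,
`β ∈ [0, 2]`, step 0.1 — brackets the default interaction with margin) and
minimizes the mean squared error between observed per-record fractions and
the simulated mean fraction per passage. MSE is the simplest defensible
comparison and is isolated behind `trajectory_loss` so a likelihood under
binomial gating noise could be swapped in. Ties break toward smaller
`α + β`, then smaller `α` (parsimony).

The default ODE mode evaluates the deterministic passage map for all grid
points simultaneously (vectorized RK4), fitting a 41×21 grid in about a
second. The stochastic mode replaces the mean trajectory with the mean of
`M` simulated replicates using **common random numbers** (the same root
seed at every grid point) so loss differences across the grid reflect the
parameters rather than sampling noise; invalid grid points (event
probability outside [0, 1]) are recorded as infinite loss with a warning.

With the default design (3 replicates, 30 passages, 10⁴-cell gate, 9:1
start) the α̂ sampling distribution concentrates within one grid step of
the truth. β is only weakly identified when the true `β = 0`: its imprint
on the trajectory is of the order of the gating noise, and averaging three
stochastic replicates flattens the sharp fraction crash relative to any
single deterministic trajectory (a Jensen effect of the crash-time jitter),
so a neighboring ridge point such as `(α, β) = (2.3, 0.1)` occasionally
fits marginally better than the truth. Across root seeds the joint event
{α̂ within ±0.2 and β̂ = 0} occurs in roughly 75–95% of 20-dataset batches,
while α̂ alone is within ±0.2 essentially always. The parsimony tie-break
and the convergent generator step both matter for recovering `β̂ = 0`
reliably.

## Synthetic measurement data

`gen_flow_fractions` measures each latent (replicate, passage) fraction as
`Binomial(gated_cells, f)/gated_cells` with a 10⁴-cell gate — the counting
noise of scoring a finite number of cells in a cytometer, unbiased with SD
`sqrt(f(1−f)/gate)`. This is the only measurement-noise model; real
instrument effects (gating drift, spectral spillover, debris) are not
emulated, so passing recovery tests bounds estimator behavior under ideal
counting noise only. The shipped fixture
(`data/synthetic_cocult_9to1.csv`, seed 424242) is three replicates of the
30-passage high-density protocol at `α = 2.2, β = 0` from a 9:1 start; it
is synthetic — a stand-in with the statistical shape of such measurements —
and regenerates bit-identically from its documented seed.

## Spatial agent-based model

Cells occupy at most one site each on a 2D lattice (default 200×200,
reflecting walls) and interact through the Moore neighborhood. Per 1 h
sweep, cells act in a fresh uniform random order, attempting mutually
exclusive events death → division → migration:

* `p_death = (d0 + density_death_coef · c) dt`, with local crowding
  `c = (same-type neighbors + γ · other-type neighbors)/8`, `γ = α` for r
  cells and `β` for K cells — the competition coefficients enter the
  spatial model through crowding-weighted death;
* `p_divide = intrinsic_rate · dt` into a uniformly chosen empty neighbor,
  only if one exists;
* `p_migrate = motility · dt` likewise gated by free space.

Daughters first act in the following sweep. `dt = 1 h` matches the interval
at which growth rates are measured; per-cell event exclusivity keeps the
probabilities interpretable at this step.

**Spatial phenotype defaults** (calibration knobs, not measurements): r:
division 0.06/h, density death 0.10/h, motility 0.3/h; K: division
0.025/h, density death 0.01/h, motility 0.05/h; baseline death 0.002/h
both. Deep in a crowded mixed region an r cell with `α = 2.2` dies at
≈0.16/h while a K cell dies at <0.01/h; at the sparse colony edge both
types mostly divide. These choices express the phenotypes' defining
trade-off on the lattice.

Two emergent phenomena are the model's validation targets:

* **Niche separation.** From a well-mixed 1:1 central seeding (~2,800 cells
  in a radius-32 disc — a desk-scale stand-in for ~10⁶ cells in a culture
  well), r cells end up at the expanding periphery and K cells occupy the
  crowded center. Quantified by the segregation index: (mean radial
  distance of r cells − mean radial distance of K cells)/(mean radial
  distance of all cells), positive = r peripheral; significance against a
  label-permutation null that shuffles types among occupied sites.
* **Mixed-culture growth advantage.** Per-capita growth `(N(t+1)−N(t))/N(t)`
  at 1 h intervals, compared between pure r, pure K and 1:1 mixed seedings
  on a reduced 128×128 well run for 16 days (100 replicates). The mix
  outgrows both pure cultures in the near-confluence window (here roughly
  days 11–16): the r front has reached the wall, so pure r stalls in
  high-death churn, pure K is still slowly expanding its dense disc, while
  in the mix the K core keeps converting churned half-empty r territory
  into fully occupied tissue as α-driven death clears r cells. Earlier the
  pure-r culture grows fastest and much later the pure-K culture does —
  the mixed advantage is a property of the crowded transition, which is
  also the regime the phenotypes were selected in. The comparison window
  is fixed at the final 48 h of the 384 h horizon.

## Degenerate inputs and edge rules

Zero counts are absorbing everywhere. Empty lattices and zero-duration
passages/horizons return their inputs. Dilution of a population smaller
than the seed size reseeds everything with a warning. The segregation
index is NaN when a type is absent; growth-rate intervals starting from an
empty lattice are flagged and excluded from averages. Event probabilities
leaving [0, 1] raise configuration errors naming the offending type and
step (except inside the grid search, where the point is recorded as
infinitely bad instead of aborting the scan).

## Known limitations

* The well-mixed model is the textbook two-type LV form; more than two
  phenotypes, evolution (mutation/switching), and explicit resources are
  out of scope.
* At `α = β = 0` the LV structure enforces protected coexistence, so
  drift-driven extinction requires demographically small cultures (see
  above); the package reports this honestly rather than forcing extinction
  at realistic scales.
* The lattice model has no nutrient or oxygen fields, no off-lattice
  mechanics, no 3D growth; its parameters are calibrated to reproduce the
  qualitative phenomena at desk scale, and absolute cell numbers and times
  should not be read as predictions.
* Flow-cytometry noise is idealized as binomial counting error.
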