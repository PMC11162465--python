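# Methods

## The problem

The chemical master equation (CME) governs the probability `p(t, x)` that a
stochastic reaction network occupies copy-number state `x` at time `t`:

    dp(t,x)/dt = sum_j lambda_j(x - zeta_j) p(t, x - zeta_j)
               - sum_j lambda_j(x) p(t, x),

with `zeta_j` the net stoichiometric change and `lambda_j` the propensity of
reaction `j`.  Direct truncation-based solvers (finite state projection,
FSP) scale with the product of per-species state-space sizes; Monte Carlo
(Gillespie / SSA ensembles) has an L1 error whose `1/sqrt(N)` prefactor is
the band `sqrt(2/pi) (sum_x sqrt(p(t,x)) +/- 1)`, which itself grows
exponentially with dimension.  Both collapse for networks beyond a few
species.

## Rao-Blackwellized solver

The package splits the components (species, plus parameter pseudo-species
during identification) into a **leader** set and disjoint **follower
subsystems** such that, given the *entire leader trajectory*, the follower
subsystems are conditionally independent.  Sufficient topological
conditions enforced by `decompose.check_conditions`:

* **C1** — every reaction involves at most one follower subsystem, through
  either its propensity or its stoichiometry;
* **C2** — the set of reactions sharing each distinct non-zero leader net
  change involves at most one follower subsystem;
* **C3** — each observation channel depends on at most one follower
  subsystem (filtering only);
* **C4** — all gridded parameters are follower-side (identification only).

Given a sampled leader path, each subsystem's conditional law evolves by a
*filtered CME*: between leader jumps, the subsystem's internal CME at the
frozen leader state plus an exponential reweighting by
`exp(-int Lambda_i(z) ds)`, where `Lambda_i(z)` sums the propensities of
leader-changing reactions that depend on the subsystem state — Bayesian
conditioning on "no leader jump happened".  At an observed leader jump with
net change `Delta`, the filter receives

    pi'(z)  \propto  sum_{j : zeta_j^lead = Delta}
                     lambda_j(x_lead^-, z - zeta_j^sub) pi(z - zeta_j^sub).

Reactions sharing `Delta` but not touching the subsystem contribute
constant terms, so subsystems untouched by the matching reactions are
unchanged.  Because the detailed forms of the prediction/correction/jump
operators are not uniquely pinned down by their high-level description, the
implementation is validated against two independent oracles (mandatory
tests): conditional distributions rejection-sampled from large SSA
ensembles sharing the leader's no-jump event, and the same filtered
equations run on the *unpartitioned* joint follower space, which must agree
with the per-subsystem factorization to 1e-6.

The RB-CME solver simulates `N` whole-system SSA paths, discards the
follower coordinates, advances the follower filters along each retained
leader path, and estimates

    p_hat(t, x) = (1/N) sum_j 1(x_lead_j(t) = x_lead) prod_i q_j^i(t, z_i).

With every species leader-side this is the plain Monte Carlo estimator;
with every species follower-side it is the FSP (the package's tests pin
both limits).  A conditional-intensity (Ogata thinning) leader-path sampler
is retained purely as a cross-validation oracle; the production sampler is
whole-system SSA with follower discard.

## Decomposition optimizer

The search space is leader subsets only: for a fixed leader set the unique
*finest* valid follower partition (union-find closure of the C1-C3 merge
rules) maximizes the whole-follower size `prod_i SS_i`, so coarser
partitions are never considered.  A decomposition is feasible when every
subsystem's truncated size `SS_i` (product of member truncation/grid sizes)
is at most the user cap; among feasible candidates the optimizer maximizes
`prod_i SS_i`, then prefers fewer leaders, then the lexicographically
*greatest* leader index tuple.  The last tie-break is this package's own
convention: on the linear chain every feasible two-leader split ties in
`prod SS_i`, and preferring later-indexed leaders selects `{S3, S6}` — the
split published for this family — where an ascending tie-break would pick
`{S1, S4}` (equally valid mathematically).  Exhaustive search is used up to
22 components; beyond that a greedy leader-growth fallback runs with a
warning.

## Filtering and identification

Observations are `Y(t_i) = h(X(t_i)) + Sigma W_i` with iid standard normal
`W_i`; channels are identity, thresholded identity (readout zero unless the
count exceeds a threshold — the microscopy platform's behavior), or linear
combinations.  Three filters share the prediction/correction recursion: the
exact FSP filter (reference, tractable to ~1e5 states), a bootstrap
particle filter (SSA proposal, Gaussian weighting, systematic resampling at
ESS < N/2), and the RB particle filter, whose prediction step is the
RB-CME solver.  Between observations an RB-PF particle draws one follower
configuration from its current conditionals, simulates the whole system by
SSA, keeps the leader path (an exact draw from the leader's conditional
marginal by the law of total probability) and rebuilds its follower
filters from the previous conditionals along that path; the sampled
configuration is never conditioned on.  The weight update multiplies, per
channel, the likelihood marginalized over the touched follower filter
(exact under C3), simultaneously Bayes-correcting that filter.  On total
weight collapse the step is retried once with the likelihood tempered to
the power 0.5, with a warning.

Identification recasts each gridded parameter as a static pseudo-species
(zero net change everywhere, state space = grid, initial law = prior).
The RB-PF on the augmented network then yields the parameter posterior as
the final-time marginal over the pseudo-species.  No artificial parameter
jitter is ever injected: C4 keeps parameters inside follower filters, so
their inference runs through the filtered FSP rather than raw particle
diversity.  Because parameters are static, a particle lineage whose leader
path implies an impossible parameter value (e.g. a gene activation under
`k3 = 0`) permanently zeroes that value in its filter; at small particle
counts this makes posterior summaries noticeably seed-noisy, which is why
the shipped tests assert scale-robust properties (e.g. the deviation of an
irrelevant parameter's marginal from its prior is bounded by the committed
particle weight) rather than full-scale posterior numbers.

The joint MAP is the argmax of the exact mixture posterior evaluated on the
product of each block's top-3 marginal candidates plus the per-marginal
argmax vector (the posterior is concentrated, so the argmax lies in this
set); ties break toward the lowest grid indices, and the per-marginal
argmax is reported alongside.

Validation compares the occupation-time distribution of measurements
(rounded to the nearest integer) with the FSP stationary law of the MAP
model, both binned (default width 10), via `KL(data || model)` with model
bins floored at 1e-12; the direction is configurable.

## Noise decomposition

By the law of total variance the population variance of a species'
stationary count splits into intrinsic (`E[Var(X*|theta)]`) and extrinsic
(`Var(E[X*|theta])`) components.  With ergodic dynamics and per-cell
time-course data, the per-cell conditional moments are approximated by time
averages over `[0, T]` — exact event integrals for simulated trajectories,
trapezoidal integration of the (rounded, possibly thresholded) readouts for
measured series; no dual reporter is needed.  The decomposition is computed
on the readout scale; de-censoring thresholded readouts is out of scope.
Cells with fewer than one nonzero reading (configurable) are excluded with
a logged count.  The model route computes the same moments exactly from
per-cell FSP stationary laws, for which total = intrinsic + extrinsic holds
to machine precision; route concordance on synthetic populations (130
cells, 4-hour horizon) is a few percent relative.

## Numerical choices

* **Propensity kinds** — mass-action (falling-factorial convention without
  factorial division; identical for unit stoichiometries), Hill
  activation/repression, and linear combinations of parameter sums times
  state indicators (covering state-dependent transcription such as
  `kp1*G1 + (kp1+kp2)*G2`).  Networks compile to flat numeric arrays so the
  SSA and filter kernels run under numba.
* **FSP integration** — adaptive BDF on the sparse generator (rtol 1e-8,
  atol 1e-12) with a single absorbing sink state; uniformization
  (exact matrix-exponential action by the Poisson-weighted substochastic
  series, tolerance ~1e-12, substepped so the Poisson rate per step stays
  below 50) is available as a cross-checked alternative and is the default
  inside the exact filter's prediction step, where stiff short-horizon
  propagation dominates.
* **Filter propagation** — uniformization throughout: RB runs perform
  millions of short segment propagations and ODE-solver call overhead
  dominates there.  The two routes agree to 1e-8 in tests.  Consecutive
  leader segments that share a subsystem's generator (the generator depends
  on the leader state only through the components its reactions reference)
  are merged into one exponential action.
* **Stationary distributions** — long-horizon integration with doubling
  steps, renormalizing truncation leakage, stopping when the residual
  `||A p||_1` falls below 1e-9 per unit time or reaches the leak floor;
  matching the "large time point" convention rather than an eigensolve.
* **Reproducibility** — one RNG stream per trajectory/particle derived from
  the master seed by `SeedSequence` spawning; ensembles are bit-reproducible
  for a fixed seed under serial execution.
* **Degenerate inputs** — zero total propensity ends an SSA path at the
  horizon; a leader jump with zero filter mass raises a recoverable signal
  and the ensemble drops the particle (erroring if more than half fail);
  zero-noise channels use exact matching.

## Synthetic fixtures and what passing tests show

The linear chain (production 2.4 into S1, internal production 0.9,
conversions at rate 1, degradations 0.6 and 1.6 at the end, independent
Poisson(0.5) initial counts) admits an exact product-Poisson solution whose
means follow the linear rate ODE — the reference for every convergence and
dominance test.  The yeast transcription model (gene states G0/G1/G2
encoded as binary species with switching rates k1..k4, transcription
`kp1*G1 + (kp1+kp2)*G2`, mRNA degradation rate 1) ships with the published
discrete grids and priors for both the in-silico regime (k on {0,0.05,...,1},
kp on {1..10}, mRNA truncated to {0..20}, half of k3's prior at zero) and
the experimental regime (k4 to 2, kp1 on {0,8,...,80}, kp2 on
{20,30,...,120}, mRNA to 150, threshold-7 readout, sigma defaulting to 1).
Repressilator and toggle-switch rate constants are *representative
defaults* chosen once to produce the qualitative regimes (oscillation;
bistable switching with protein levels a few tens) at state-space sizes
where reference filters are computable — they are not published values, and
no quantitative acceptance number depends on them.

The in-silico identification horizon is 240 minutes sampled every minute
(the experimental protocol's four-hour design); the cell-population
generator mirrors the experimental schema (130 cells, readouts every 2
minutes, gene initially inactive, zero initial mRNA) with ground-truth
parameters retained for recovery tests.  Synthetic populations lack cell
cycle, lineage, segmentation noise, and photobleaching; passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to those effects.

Problem sizes in the shipped tests and in `scripts/acceptance.py` are the
package's chosen study scales: the error-ratio benchmark runs both solvers
at N = 10^4 (the RB solver's operating sample size in this model family;
at much smaller N the plain-MC L1 error saturates near its ceiling of 2
and the ratio is not interpretable), the Monte-Carlo error-law checks run
on the 3-species chain where desk-scale N lies inside the asymptotic
regime of the prefactor law, and identification protocols run at a few
hundred to ~1500 particles averaged over seeds (posterior summaries that
hinge on lineage survival, such as the mass on a boundary grid point,
converge from below as the particle count grows; the shipped scripts use
the largest count their runtime target allows).

## Known limitations

* Exhaustive decomposition search is exponential in the component count
  (capped at 22; greedy fallback beyond).
* The RB-PF parameter posterior is a mixture over particle lineages; at
  small N, lineage commitment makes summaries seed-noisy (see above).
* Joint tables are only densified on request; still, `dense_joint` on very
  large truncations (above ~10^7 states) is not supported.
* Time-varying propensities, tau-leaping/hybrid simulation, moment-closure
  follower filters, smoothing, grid refinement, and SBML import are out of
  scope.
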