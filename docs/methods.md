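# Methods

`mutdiv` implements the quantitative chain from the per-generation mutation
rate to the macroevolutionary diversification rate in three layers: (1)
fixation of new mutations in a population whose size changes
deterministically, (2) accumulation of Dobzhansky-Muller incompatibilities
between isolated populations on a holey adaptive landscape, and (3) an
event-driven simulation of lineage splitting, secondary contact and
reproductive isolation (RI) that yields reconstructed phylogenies and
diversification-rate estimates.

## 1. Wright-Fisher fixation under changing population size

**Model.** A diploid population of census size `N(g)` carries `2N(g)` gene
copies. A derived allele at frequency `x` with selection coefficient `s`
(genic selection, `s > -1`) is resampled each generation as
`Binomial(2N(g+1), x(1+s)/(1+xs)) / 2N(g+1)`; 0 and 1 are absorbing. We
chose genic selection as the simplest scheme consistent with a single
scalar `s`; the binomial kernel is exposed in `wf_step` and the exact
absorbing-chain oracle uses the same kernel, so the two routes are
comparable state for state.

**Demography.** `DemographyProfile(n0, ratio, duration, shape, ne_over_n)`
interpolates the census size from `n0` to `round(n0*ratio)` over
`duration` generations (linear by default, exponential optional — the
endpoints and durations are what matter for the scenarios shipped in
`standard_scenarios`: growth to 1.9x or decline to 0.1x over 20 or 200
generations). Sizes are rounded to the nearest integer and the profile is
rejected if any generation would hold fewer than 2 individuals. Effective
size is `ne_over_n * N` throughout (default 1, i.e. Ne = N).

**Fixation probability.** For a mutation arising at frequency
`x0 = 1/(2 n0)` just before a size change of length `T`,

    P_fix = (1 - E[exp(-4 Ne s X(T))]) / (1 - exp(-4 Ne s)),

with `Ne` the *final* (post-change) effective size: after generation `T`
the population is constant, so the formula is the expectation of Kimura's
constant-size fixation probability over the frequency `X(T)` reached by
drift and selection during the change. The estimator averages the Kimura
transform per replicate, which keeps the ratio numerically stable
(`expm1`) and gives a delta-method standard error directly as the standard
error of that mean. The `s = 0` singularity is never evaluated: the
neutral branch returns `E[X(T)]` (analytically `x0` by the martingale
property). Constant-size profiles short-circuit to the closed form.

**Substitution rate.** The long-run rate is (new mutations per generation)
x (fixation probability) = `2 Ne0 u P_fix`, with `Ne0` the effective size
at the mutation's origin. For neutral mutations this is `u Ne/N` under
every demographic scenario, hence exactly `u` when Ne = N — the invariance
the neutral rows of the scenario grid verify. `dN/dS` is computed as
`P_fix(s=-0.001)/P_fix(s=0)` and `Kr/Kc` as
`P_fix(s=-0.01)/P_fix(s=-0.001)`, both at `x0 = 1/(2 n0)`.

**Replicates and streams.** The grid default is 500,000 replicates per
cell; the test suite and acceptance script use 50,000 (with 3-standard-
error tolerances) or fewer, which keeps the full suite under a minute of
simulation while leaving every comparison statistically sharp. Each
(scenario, Ne, s) cell draws from `SeedSequence(seed, spawn_key=(i,j,k))`,
so any cell is reproducible in isolation.

**Oracles.** `exact_matrix_fixation` solves the `2n+1`-state absorbing
chain by dense linear solve (limited to `2n <= 200`) and anchors the Monte
Carlo and the diffusion closed form in tests. Where fixation is
essentially impossible (e.g. Ne = 1000, s = -0.01, expected fixations
~1e-14 in 1e5 replicates) the sample standard error degenerates to zero,
so closed-form comparisons use the binomial SE computed from the analytic
probability (a score-type tolerance).

## 2. Holey landscape / incompatibility accumulation

Each substitution independently has probability `epsilon` of forming a
lethal ("hole") combination with an earlier derived allele. Pairwise
counting gives `epsilon*d` expected incompatibilities at divergence `d`;
all-pairs (snowball) counting gives `epsilon*d(d-1)/2`, quadratic in `d`.
We fixed the snowball constant at `d(d-1)/2` — all unordered pairs of
derived alleles across both populations with `d` the total divergence —
since only the quadratic order is prescribed by the model. A genotype with
`L` mutational targets has `L(1-epsilon)` expected viable one-step paths
(viability requires `> 1`, strict), and quadratic accumulation requires
`epsilon < ln(L)/L`.

With any single incompatible pair causing complete RI (the implemented
default; partial-RI strength models are out of scope), the substitution
index at which RI completes is geometric: `pmf(k) = (1-epsilon)^(k-1)
epsilon`, mean `1/epsilon`, and the probability that populations `d`
substitutions apart can still interbreed is the survival function
`(1-epsilon)^d`. Expected time to RI is `(1/epsilon)/substitution_rate`;
`epsilon` is treated as constant per lineage pair.

**Fitting.** `fit_epsilon_and_exponent` fits `count = a * d^b` by OLS on
log-log scale, dropping zero-count rows (documented; they have no log
image), and reads `epsilon` off `a` under the declared counting model
(`a = epsilon` pairwise, `a = epsilon/2` snowball). Note `d(d-1)/2` is
only asymptotically a power law: on `d = 10..100` the fitted exponent is
~2.03, and recovery to three decimals requires species-scale divergences
(`d ~ 10^3..10^4`), which is where the recovery tests operate. The
synthetic-table generator emulates the observable of a hybrid-
incompatibility survey — exact expected counts, or Poisson counts around
them — and does not emulate divergence-estimation error or ascertainment
bias in which species pairs get surveyed, so passing recovery tests speak
to the estimator, not to those field problems.

## 3. Lineage diversification under T_I / T_S / T_R

**Events.** Starting from one population, each extant lineage waits
`T_I` (mean `t_i`) for an isolating event; a split creates a sister pair
that schedules secondary contact (mean `t_s`) and RI completion (`t_r`,
or a coupled draw `k/u` with `k ~ Geometric(epsilon)` and `u` the neutral
substitution rate — the layer-1 result that the neutral rate equals the
mutation rate). `timing_mode` is `"exponential"` (default; waiting times
are random with the stated mean) or `"fixed"`. Contact after RI has no
consequence. Contact before RI resolves by the `ContactOutcomes`
probabilities: reinforcement (RI completes, defaults 0.5), extinction of
one (0.25) or both (0.05) populations, remainder fusion. On fusion the
pair merges and carries the earlier birth time — implemented by the
branching representation (a split spawns one new record while the parent
line continues; fusion kills the spawned record), so the period of
isolation becomes invisible to reconstruction automatically, and the
merged line's divergence restarts from zero.

**Contact topology.** Contact occurs between the sister populations of a
split; spatial arrangement is not modelled. A pending contact is cancelled
when either member undergoes a population-changing event (its own later
split, a fusion, an extinction) before contact fires — epoch counters gate
validity. RI completion and reinforcement change genetic state only and do
not perturb any clock; this is what makes fixed-timing runs exactly
periodic (every internal edge equals `t_i` in the isolation regime).
Reaching `max_lineages` halts the run with a `truncated` flag rather than
raising.

**Regimes.** `classify_regime` operationalises the four qualitative
patterns; "much less than" is `t_r/t_s >= 10` (`far_factor`,
configurable), ties `t_s = t_r` go to the isolation regime and `t_i = t_s`
to chained isolation.

**Reconstruction.** Tips are the populations alive at the reading time;
splits survive if both sides leave living descendants; single-child nodes
are collapsed. Branch lengths are generations; trees are ultrametric at
the reading time and serialise to Newick via dendropy.

**Estimators.** `internode_summary` reports internal-edge lengths
(including the origin edge). Note a subtlety: under exponential timing the
per-lineage wait between splits is `Exp(t_i)`, but the *grand mean of
internal edges* of a reconstructed tree is ~`t_i/2`, because the total
tree length at the n-th split is `(n-1) t_i` in expectation and pendant
edges absorb the incomplete waits; the distributional test therefore
targets the scaled branching intervals (`k * wait` with `k` concurrent
lineages, exponential with mean `t_i`), not the internal-edge mean.
`diversification_estimate` is the crown estimator `ln(n)/crown_age`,
chosen for robustness at small n and swappable. The mutation-rate sweep
uses the stem form `ln(n)/elapsed_time` instead: fusion prunes the oldest
splits, so the crown age itself shrinks with the fusion rate and would
cancel the tip-count signal the sweep is designed to expose.

**Sweep conditions.** The shipped mutation-rate sweep uses `t_i = 5e4`,
`t_s = 1e4`, `total_time = 1.5e5` generations, cap 100 lineages,
`epsilon = 0.05`, pure-fusion contact outcomes, and `u` spanning
`4e-4..4e-3` — chosen so the mean `T_R = 20/u` sweeps from `5 t_s` to
`0.5 t_s` across the 10x grid, i.e. the runs cross from the
fusion-dominated to the isolation-dominated regime, where diversification
responds most strongly to the mutation rate.

## Known limitations

- Selection parameterisation is genic; dominance, linked selection and
  diffusion solvers are out of scope.
- The geometric RI waiting time counts new mutations only; standing
  variation would shorten real waiting times.
- The adaptive shortening of T_R under positive selection (proportional to
  Ne*s) is noted but not implemented — no formula is available to
  implement faithfully.
- Trees are read from the true history (the reconstruction-is-accurate
  assumption); sequence evolution, inference error and incomplete lineage
  sorting are not modelled.
- Contact is pairwise between sisters; the chained-isolation geometry in
  which a middle population touches both neighbours is simplified away.
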