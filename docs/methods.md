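# Methods

## Model

`micrm` simulates well-mixed microbial communities of `S_tot` potential
species consuming `M` substitutable resources, with cross-feeding: a
fraction `l` of every unit of consumed energy flux is re-secreted into
the environment as metabolic byproducts, redistributed over resource
types by a column-stochastic matrix `D`.  Population densities `N_i`
and resource concentrations `R_a` obey

    dN_i/dt = g_i N_i [ sum_a w_a (1 - l_a) c_ia R_a - (m_i + m_env) ]
    dR_a/dt = kappa_a - R_a/tau_R - sum_i c_ia N_i R_a
              + sum_{i,b} D_ab (w_b/w_a) l_b c_ib N_i R_b

where `c_ia` are uptake rates (volume/time), `m_i` maintenance costs
(energy/time), `kappa_a` external supply (mass/volume/time), `w_a`
energy contents and `tau_R` the dilution timescale.  Defaults are
`g = w = tau_R = 1` and `l = 0.8` everywhere.  `m_env` is a scalar
"harshness" offset applied to all maintenance costs of a sample; it is
a purely energetic abstraction of pH/temperature stress, not a
mechanistic model of either.

## Random ecosystems

A regional pool is defined by twelve global parameters.  Consumer
preferences are binary: `c_ia = c0/M + c1 X_ia` with `X_ia` Bernoulli.
Resources are grouped into `T` equal classes; species belong to one of
`F` specialist families (plus generalists).  A specialist concentrates
a fraction `q` of its consumption capacity on its preferred class: the
high-level probability is `(mu_c/(M c1)) (1 + q (M - M_A)/M_A)` inside
the class and `(mu_c/(M c1)) (1 - q)` outside, so every row sums to
`mu_c` on average regardless of `q`.  Parameter combinations that push
a probability above 1 are rejected rather than clipped (clipping would
silently bias `mu_c`); with the standard `q = 0.9`, `mu_c = 10`, `T = 6`
this imposes `M >= 55`, which sets the floor on how far the structured
scenarios can be shrunk.

The metabolic matrix is sampled column-wise from Dirichlet
distributions with a three-tier concentration structure: on average a
fraction `f_w` of secreted flux goes to a designated waste class (the
last class by convention), `f_s` to the class of the input resource,
and the remainder to everything else; for waste-class inputs the first
two tiers merge.  The sparsity parameter `s` divides all
concentrations, interpolating between dense (`s -> 0`) and
single-output (`s -> 1`) networks.  With a single resource class the
tier structure degenerates: all concentrations are uniform,
`(f_w + f_s)/(s M)`.  For the unstructured global-survey pool we set
`f_w = 1, f_s = 0` so that the total concentration is exactly `1/s` and
`s` retains its sparsity meaning; the unstructured mixture control
keeps the host-associated values `f_s = f_w = 0.45`.

Maintenance costs are `N(1, 0.01)` draws.  All sampling is a pure
function of `(parameters, seed)`: the consumer matrix, metabolic matrix
and maintenance costs use independent streams derived from one master
seed by fixed offsets, so any component can be replayed bit-for-bit.

## Steady states

Communities are colonized with a uniformly random subset of `S` species
(equal initial abundances `1/S`, resources at zero; only the fixed
point matters for the reported patterns) and integrated to an
approximately uninvadable equilibrium with LSODA and an analytic dense
Jacobian, in chunks of increasing length.  After each chunk:

* species below the extinction threshold (default `1e-6 x` mean
  initial abundance) are removed from the active system;
* past a warmup (`t > 100`), species that are still declining faster
  than the residual tolerance and have fallen more than four orders of
  magnitude below the most abundant species are also removed ("doomed"
  pruning) — their effect on the resource environment is negligible and
  waiting for them to decay across the threshold would dominate the
  runtime;
* integration stops when the largest per-capita growth rate
  `|d ln N_i/dt|` among survivors (and the relative resource residual)
  falls below the tolerance (default `1e-6`), or `t_max` is reached.

At the stopping point, pruned colonists whose invasion growth rate at
the candidate fixed point is positive are reintroduced just above the
extinction threshold and integration continues (up to 20 rounds).  This
guards against both premature pruning and genuine alternative states;
without it roughly a fifth of reduced-scale communities ended at
invadable fixed points.  A community whose final residual is `>= 1e-5`
is flagged `converged = False`; analyses discard such samples (they are
never silently dropped from tables).  Two invariants back these
choices: the steady-state energy budget
`sum w kappa = tau^-1 sum w R + sum N (m + m_env)` closes to better
than `1e-4` relative for every converged community, and the surviving
and extinct groups are separated by at least four orders of magnitude
in abundance.

## Scenarios

* Global survey (`run_emp`): unstructured pool, 180 species x 90
  resources, `s = 0.05`, 150 colonists (or `U{1..180}` when dispersal
  varies), single supplied resource `kappa_1 = 200` (or `200/M` on all
  resources in the complex variant), harshness `m_env ~ U(-0.5, 9.5)`
  (or 0 when only dispersal varies).  One pool is shared by all samples
  of a scenario; matched comparisons across variants reuse identical
  per-sample draws.
* Host-associated (`run_hmp`): structured pool, 5000 species (6
  families x 800 + 200 generalists) x 300 resources in 6 classes,
  `q = 0.9`, `s = 0.3`, `f_s = f_w = 0.45`; three "body sites" supplied
  from class pairs (A+B, C+D, E+F) at total flux 1000, either as one
  resource per class with a random split `a ~ U(0,1)` (simple) or all
  resources of both classes with random weights (complex); controls
  remove taxonomy (`q = 0`) or supply random thirds of the resources
  (overlapping).  Which single resource represents a class in the
  simple variant is fixed (the class's first resource) to remove a
  nuisance degree of freedom.  Colonization is 2500 species (strong
  dispersal limitation) or 4900 (weak).
* Mixtures (`run_mixture`): the additivity experiment; every community
  is initialized with the full pool, two resources are supplied at
  fluxes `(1-a) kappa` and `a kappa`, and the mixture community
  (`a = 0.5`) is compared with the flux-weighted average of the two
  endpoint communities.  The unstructured control assigns all resources
  to one class before sampling.

A `scale` factor shrinks `(S_tot, M, S, n_samples)` proportionally
while preserving `T, F, q, s, f_w, f_s, l`.  Test-suite problem sizes
(chosen so the default suite runs in minutes): quarter scale for the
conservation checks, full scale for the richness-harshness comparison
(cheap because single-resource unstructured communities converge
quickly, and at quarter scale richness saturates at a handful of
species, washing out the correlation), half scale for nestedness, and
scale 0.2-0.3 for the structured scenarios (see the probability floor
above).

## Pattern statistics

* Nestedness: rows sorted by prevalence, columns by richness (ties by
  index), scored by standard NODF (mean paired-overlap percentage over
  row and column pairs with strictly decreasing marginals).  The model
  comparison is ordinal — selection-dominated assembly scores above
  dispersal-limited — so any monotone nestedness scalar would do.
* Species-abundance distributions: `n` individuals are sampled
  multinomially per community (default 1000); rarefaction of count data
  uses the multivariate hypergeometric.  The Fisher log series
  `s(n) = (alpha/n) x^n` is fitted from the identities
  `S = -alpha ln(1-x)`, `N = alpha x/(1-x)` via bracketed root-finding
  (`x` to 1e-15 absolute).  The truncated-Gaussian null draws Gaussian
  invasion fitnesses with the mean set so the positive fraction matches
  the observed survival fraction, keeps positive values as relative
  abundances, and multinomially samples `N = 1000` individuals,
  averaged over 10000 iterations by default.
* Dissimilarity-overlap: overlap is the mean shared-species abundance
  fraction of the two samples; dissimilarity is the square root of the
  Jensen-Shannon divergence (natural log, hence bounded by
  `sqrt(ln 2)`) between the profiles renormalized over the shared pool.
  Disjoint pairs are excluded and counted.  The curve is a lowess fit
  (default fraction 0.3; the smoothing parameter is not critical for
  the ordinal conclusions and is exposed).
* Ordination: classical metric scaling (double-centering +
  eigendecomposition) of the Jensen-Shannon distance matrix; negative
  eigenvalues are dropped with a count.  Checked against scikit-bio's
  implementation in the tests.
* Additivity: `R^2 = 1 - SS_res/SS_tot` of the prediction
  `(1-a) N^1 + a N^2` against the observed mixture abundances.  Two
  variants are provided: a linear-scale score over all species
  (`additivity_r2`, `SS_tot` about the mean observed abundance), and a
  log-scale score over the species with positive observed and
  predicted abundance (`additivity_r2_log`).  Steady-state abundances
  span several decades, so the linear score is set almost entirely by
  the two or three most abundant species (it stays around 0.6-0.9 for
  unstructured ecosystems at every size we ran); the log score weights
  every coexisting species' prediction error equally and is the one
  used for quantitative comparisons of mixture experiments.

## Effective Lotka-Volterra reduction

At fixed populations the resource dynamics are linear,
`dR/dt = kappa - A(N) R` with
`A = tau^-1 I + Q diag(phi)`, `phi_b = sum_i N_i c_ib`,
`Q = I - D (w_b l_b/w_a)`, so the fast-equilibration resource state is
`R(N) = A(N)^-1 kappa` and its sensitivities follow by implicit
differentiation: `dR/dN_j = -A^-1 Q diag(R) c_j`.  Writing
`G = c diag(w(1-l)) A^-1 Q diag(R) c^T` over survivors, the effective
parameters are `alpha_ij = G_ij / G_ii` (so `alpha_ii = 1` exactly),
`K_i = sum_j alpha_ij N_bar_j` (equilibrium consistency), and
`r_i = K_i g_i G_ii`.  The overall signs are fixed by requiring that
the LV Jacobian `-(r_i/K_i) N_i alpha_ij` at the fixed point equal the
exact Jacobian of the resource-eliminated dynamics; the test suite
verifies this entry-wise to 1e-4 relative against central finite
differences, which also validates the implicit-differentiation step.
Depleted resources are retained in the linear algebra — the dilution
term keeps `A` well conditioned — and the reduction is evaluated only
at the converged fixed point (no quasi-static reduction along
trajectories).  Between-community variability of carrying capacities is
the RMS difference over shared survivors normalized by the mean shared
carrying capacity.

## What the generator does and does not emulate

The synthetic ecosystems capture niche partitioning, cross-feeding,
energy limitation, taxonomic correlation of diets, and stochastic
colonization.  They do not include demographic noise, spatial
structure, temporal fluctuation of supply, strain-level variation,
plasticity, or any mechanistic chemistry of pH/temperature;
"harshness" is a uniform energetic offset.  Passing pattern tests shows
the model reproduces the qualitative survey patterns, not that real
communities are governed by these mechanisms.

## Numerical choices and limitations

* Integration tolerances: `rtol = 1e-7`, `atol` tied to the extinction
  threshold; residual tolerance `1e-6`; discard flag at `1e-5`.
* `t_max` defaults to 1e4 time units (3e4 for the large mixture runs,
  which relax slowly near threshold); hitting `t_max` with a high
  residual flags the sample, it never raises.
* The additivity `R^2` of the unstructured control is strongly
  size-dependent below full scale and carries substantial
  realization-to-realization spread even at full scale (standard
  deviation roughly 0.15 across replicate pools); the quantitative
  mixture experiment of `scripts/acceptance.py` therefore runs at the
  full 5000-species size and averages up to eight replicate pools
  under an explicit time budget, while the reduced-scale test asserts
  only the ordinal structured-vs-unstructured comparison on matched
  seeds.  Any single replicate (including a single published
  simulation) should be read as one draw from this distribution.
* Large-community integration uses BDF with a sparse Jacobian
  (the Jacobian is bordered-diagonal: a diagonal species block, two
  thin species-resource coupling blocks, and a dense resource block),
  which avoids the dense factorizations that would otherwise dominate
  the runtime; smaller systems use LSODA with the dense Jacobian.
* Ties in presence/absence sorting are broken by original index;
  NODF pairs with equal marginals contribute zero, as in the standard
  definition.
* With very small `M` the preferred-class probability bound rejects the
  standard `mu_c = 10`; tiny examples must lower `mu_c`.
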