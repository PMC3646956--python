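# Methods

`skystruct` is a simulation study in a package: it quantifies how population
structure confounds skyline-plot inference of demographic history. It
simulates genealogies of maternally inherited (mtDNA-like) sequences under
the structured coalescent, infers piecewise-constant effective-size
trajectories with a Bayesian change-point sampler, and scores the results
against the known simulated truth.

## The structured coalescent simulator

A scenario is a set of `d` demes with `N_i` females each, a backward
migration matrix `M` (entry `m_ij` = per-generation probability that a
lineage in deme `i` traces back to deme `j`), and optional demographic
events. Backwards in time, while deme `i` holds `k_i` sampled lineages,
coalescences occur at rate `k_i (k_i - 1) / (2 N_i(t))` (haploid scaling)
and each lineage migrates at its row rate. Event times are drawn by
competing exponentials; the continuous-time approximation of per-generation
probabilities is the standard coalescent limit, with errors of order `1/N`
at the default deme size of 500.

Two canonical topologies are provided. The **island model** splits a
lineage's total migration rate `m = Nm / N` equally over the other `d - 1`
demes, where `Nm` is the number of female migrants per deme per generation.
The **stepping-stone model** is a one-dimensional ring with rate `m/2` to
each neighbour; the ring (rather than a line or a 2-D lattice) keeps every
deme exchangeable, matching the symmetry of the island scenarios. A
**data-informed model** inverts a pairwise FST matrix through the haploid
island-model relation `Nm_ij = (1/F_ij - 1)/2` and uses the resulting
migrant numbers directly as pairwise rates (no per-deme renormalisation);
this is deliberately the simplest reading of an "FST-informed migration
matrix" and is an equilibrium approximation, not an estimate of history.

**Demographic events.** An `exponential_change` event at time `T` with
factor `f` makes every deme size equal `f` times its value at the event's
more recent boundary, interpolated exponentially across the phase. Deme
sizes are anchored at the present, so a 10-fold Holocene decline
(`decline(4200, 10)` with 500 females per deme today) puts 5,000 females
per deme at 4,200 years ago; the boom-bust preset composes that decline
with a 10-fold expansion starting at the Last Glacial Maximum (25,200 years
ago), placing the peak at the mid-Holocene. A `subdivision` event merges
all demes, backwards in time, into one panmictic pool of the summed size —
structure that arose at the event time rather than being permanent. For
simulation, exponential phases are discretised into 32 piecewise-constant
steps per phase evaluated at step midpoints; at a 10-fold change this
biases mean coalescence times by well under 1%, and the discretisation is
the reference behaviour (an exact time rescaling would be an optimisation,
not a correctness change).

Internal time is in generations; all user-facing times are years via a
generation time of 7 years (a large savanna ungulate). Replicate `r` of any
experiment uses seed `base_seed + r` (schemes offset by 100,000), so result
tables are bit-reproducible.

**Analytic validation.** For two lineages on any constant-size scenario the
expected coalescence time solves a first-step linear system over unordered
deme pairs; the test suite checks the simulator against this oracle and
against the island closed forms `E[T_same] = dN` and
`E[T_diff] = dN + (d-1)/(2m)`, plus an independent cross-check against
msprime. The collecting-phase effective size used for expectations is
`census * (1 + 1/(2 Nm))`, equivalently a mean relative departure of
`1/(2 Nm)` — 4.00, 0.40 and 0.04 at `Nm` = 0.125, 1.25 and 12.5. (The
prose form "(1 + 1/Nm) times the census" that sometimes accompanies these
numbers is inconsistent with them by a factor of two in the exponent's
denominator; the implementation follows the numbers.)

## Sequence simulation

Sequences evolve along the genealogy under HKY with continuous gamma rate
heterogeneity: kappa = 50, shape 0.5, 600 bp, substitution rate 32% per
million years per bp — i.e. 0.001344 mutations per sequence per generation
at the 7-year generation time. These defaults emulate a mitochondrial
D-loop fragment. Base frequencies default to equal (they are not part of
any quantitative target and no empirical composition is assumed). Each site
draws a Gamma(0.5, mean 1) rate multiplier (continuous, not discretised
into categories); branch transition matrices come from the symmetrised
eigendecomposition of the unit-mean-rate HKY generator, so multiple hits
are modelled exactly.

## FST estimation

Hudson's estimator `F = 1 - pi_w / pi_b` uses the mean within-deme pairwise
difference per site (unweighted mean of the two demes) and the mean over
all cross-deme pairs. Negative point estimates are returned as computed so
replicate averages stay unbiased; the matrix convenience wrapper floors
them at zero only to satisfy the matrix contract. By default distances are
raw proportions of differing sites; a `k2p_gamma` option applies the
Jin–Nei gamma-corrected Kimura two-parameter distance (exact for the
equal-frequency HKY used in simulation), which removes multiple-hit
saturation at deep divergences. At the default rates both variants close on
the equilibrium expectation `F = 1/(1 + 2 Nm d/(d-1))` within Monte-Carlo
error; the finite-`d` correction `d/(d-1)` is used because it reproduces
the standard printed values (0.80/0.28/0.04 at d = 40), while the
infinite-island variant is exposed alongside it.

## Skyline inference

The Bayesian skyline sampler works on the *true* simulated genealogy
rather than re-inferring genealogies from sequences. This is a deliberate
design decision: the structure effect is a property of structured
genealogies themselves (the scattering/collecting phase transition), so it
survives conditioning on the tree, while full phylogenetic MCMC would add
an orthogonal layer of machinery and noise. The consequence is that
sequence-level credible intervals are narrower here than a
sequence-integrating sampler would give, so coverage-type numbers are not
comparable to tools that integrate over genealogies — only the qualitative
patterns and the analytic expectations are.

The demographic function is piecewise-constant (not piecewise-linear), with
change points restricted to coalescence times of the pooled genealogies
(all but the last). The state is an indicator vector over candidate change
points plus one size per segment. Priors: the change-point count (PSC) is
Poisson(ln 2) — zero change and "some change" a priori equally likely —
spread uniformly over the configurations of a given count; segment sizes
are scale-invariant (1/N) truncated to [1, 1e8] females. Proposals: an
indicator birth/death that draws a new segment's size from its prior (so
the trans-dimensional acceptance ratio needs no Jacobian), a log-scale
random walk on one segment size (prior and Jacobian cancel exactly), and
an adjacent-size swap. The coalescent likelihood reduces to sufficient
statistics — the cumulative coalescence-pressure integral `A(t)` and event
counts per segment — so each MCMC step is O(number of segments).

Chain defaults are 100,000 steps, 10% burn-in, thinning 100; the fixed-tree
state space is tiny, and the sampler's ESS on the log posterior is reported
with a warning flag below 50. Posterior summaries (median and shortest 95%
interval per grid point) are evaluated on 100 equally spaced points from 0
to the 95th percentile of the input root heights; this grid is also the
reference for coverage and MRD, since "all time points" is otherwise
ill-defined for a continuous function. The sampler is validated against
exact prior recovery (PSC ~ Poisson(ln 2), sizes log-uniform) and against
1-D numerical integration of the model-averaged posterior on a three-tip
genealogy.

## Evaluation statistics

* **Coverage** — fraction of grid points where the simulated census size
  lies inside the 95% HPD band.
* **MRD** — signed mean of `(median(t) - truth(t)) / truth(t)` over the
  grid; "relative departure" is ratio minus one, so an expectation of 4.00
  means the inferred size is five times the census. Under-estimation (the
  structure-effect decline) gives negative values.
* **False-positive rate** — fraction of constant-size replicates whose
  posterior mean PSC exceeds 1.
* **PSC vs connectedness** — ordinary least squares of per-deme mean PSC on
  per-deme mean pairwise FST, fitted separately below and above FST 0.2
  (the empirical two-phase split: connectedness raises the risk of a false
  decline up to moderate isolation, beyond which genealogies increasingly
  coalesce entirely within the sampled deme and the signal fades).

## Synthetic data and experiment scale

The buffalo-like preset stands in for an empirical 34-population mtDNA
system: 34 demes of 500 females (census 17,000) whose migration matrix
derives from a synthetic FST matrix. The generator gives each deme an
isolation score on the log-survival scale (`1 - F_ij = exp(-(v_i + v_j))`),
with offset and scale solved numerically so the per-deme mean FST values
span a requested range exactly (default 0.007–0.123, the low-differentiation
regime; a 0.069–0.827 variant covers the wide-isolation sweep). The matrix
is an explicit stand-in: it reproduces heterogeneous, ordered connectedness
but no geography, and a real system's history would add non-equilibrium
structure the generator does not emulate. Passing tests therefore show that
the *pipeline* behaves as the theory predicts under these conditions, not
that any particular empirical dataset does.

Reference experiments default to 20 replicates per scenario with
40 samples (local: 40 from one deme; pooled: 4 from each of 10 demes;
scattered: 1 from each deme); 100-replicate designs are available by
setting `n_replicates=100`. The 10-deme preset omits scattered sampling
(it would yield only 10 sequences). Multi-locus mode (several independent
genealogies sharing one demography) exists, but the reference experiments
analyse replicates separately.

## Numerical notes and limitations

* Degenerate inputs: zero migration with a multi-deme sample and no
  subdivision event is detected up front and raises rather than spinning.
* Hudson FST is undefined when the between-deme diversity is zero; this is
  raised explicitly, not returned as 0.
* The two-lineage oracle requires constant sizes; it rejects models with
  exponential phases.
* Saturated sequence pairs make the corrected K2P distance undefined (NaN);
  at the default rates this does not occur in practice.
* Serially sampled (dated) tips, recombination, diploid scaling,
  two-dimensional lattices and piecewise-linear demographic functions are
  out of scope.
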