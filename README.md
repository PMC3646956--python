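# skystruct

Structured-coalescent simulation and Bayesian skyline inference for studying
the **structure effect**: population structure masquerading as population
size change in panmixia-assuming demographic inference.

Skyline plots infer the female effective population size N(t) from the
coalescence pattern of a genealogy, assuming one panmictic population. In a
structured population (d demes of N females exchanging Nm migrants per
generation) the genealogy of a sample has two phases: a recent *scattering*
phase, during which co-sampled lineages quickly coalesce or migrate apart,
and an older *collecting* phase, in which lineages must first co-locate by
migration. The effective size differs between the phases — roughly the deme
size recently and `census x (1 + 1/(2Nm))` anciently — so a skyline fitted
to samples from one deme shows a population *decline* that never happened.
This package simulates that situation end to end and measures how bad it
gets under three sampling designs: **local** (all samples from one deme),
**pooled** (a few samples from each of several demes) and **scattered**
(one sample per deme).

What it provides:

* a structured-coalescent genealogy simulator (island, stepping-stone and
  FST-informed migration; exponential size changes; subdivision events),
* HKY+Gamma sequence evolution emulating a 600 bp mtDNA D-loop fragment,
* a Bayesian piecewise-constant skyline sampler with a posterior over the
  number of size-change points (Poisson(ln 2) prior),
* Hudson FST estimation and island-model equilibrium theory
  (`F = 1/(1 + 2 Nm d/(d-1))`, inversion `Nm = (1/F - 1)/2`),
* evaluation statistics (coverage, signed mean relative departure, PSC
  false-positive rate, PSC-vs-connectedness regression) and replicated
  experiment drivers with named scenario presets.

See `docs/methods.md` for the model, priors and design decisions.

## Worked example

Simulate a constant-size 40-deme island model (500 females per deme, census
20,000; intermediate gene flow Nm = 1.25), sample all 40 lineages from a
single deme, and run skyline inference on the resulting genealogy:

```python
import numpy as np
import skystruct as ss

model, schemes = ss.scenario("island40", np.random.default_rng(0), Nm=1.25)
rng = np.random.default_rng(1)
g = ss.simulate_genealogy(model, schemes["local"], rng)
post = ss.bayesian_skyline(g, rng)

print("TMRCA (kya):", round(g.root_time * 7 / 1000, 1))
print("posterior mean PSC:", round(ss.psc_mean(post), 2))
print("median N(now):", int(post.median_curve[0]))
print("median N(root):", int(post.median_curve[-1]))
print("MRD:", round(ss.mrd(post, lambda t: ss.census_size(model, t)), 2))
```

Output:

```
TMRCA (kya): 326.8
posterior mean PSC: 1.96
median N(now): 427
median N(root): 24195
MRD: 0.2
```

The population never changed size, yet the posterior strongly supports a
size change (mean PSC 1.96 against a prior mean of ln 2 ≈ 0.69): the
inferred present-day size (~430) tracks the sampled deme, while the ancient
size (~24,000) tracks the whole structured population — a spurious ~50-fold
"decline". Replicated versions of this experiment (`ss.run_experiment`, or
`skystruct experiment --preset island40` from the shell) tabulate coverage,
MRD and PSC across replicates and sampling designs; the boom-bust preset
shows the complementary blind spots of each design (local sampling hides
the ancient expansion, scattered sampling hides the recent decline).

## Command line

```sh
skystruct presets                       # list named scenarios
skystruct simulate --config scenario.yaml --out run/   # Newick + FASTA
skystruct infer --tree run/genealogy.nwk --out skyline.csv
skystruct evaluate --skyline skyline.csv --config scenario.yaml
skystruct experiment --preset boom_bust --out exp/ --replicates 20
skystruct fst --fasta aln.fasta --demes demes.csv --out fst.csv
```

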