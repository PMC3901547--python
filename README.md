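# serialabc

Coalescent-based reconstruction of recent effective-population-size (Ne)
trajectories from **serially sampled microsatellite genotypes**, built
around the question of how indoor residual spraying (IRS) reshapes a
malaria-vector population between spray rounds.

## The problem

A population of *Anopheles gambiae* was sampled six times over thirteen
months spanning two IRS rounds, and genotyped at 13 microsatellite loci.
Allelic diversity barely moves across samples, yet the interesting signal —
how hard each spray round hit the population and how fast it rebounded — is
hiding in the subtle temporal shifts of allele frequencies.  The package
fits this with approximate Bayesian computation (ABC) over six competing
demographic models of the piecewise-constant trajectory N(t):

| scenario | narrative |
|---|---|
| 1 | Ne constant |
| 2 | Ne drops at each spray round, recovers soon after |
| 3 | Ne drops at each round, no recovery |
| 4 | Ne tracks rainfall (rank-concordant) |
| 5 | Ne anti-tracks rainfall (rank-discordant) |
| 6 | like 2, but decline continues 3 months before recovery |

For each scenario, datasets are simulated from the heterochronous
coalescent (lineages enter at their sample's collection date, converted to
fractional generations at 18 generations/year; coalescence rate
k(k−1)/4N(t)) with generalized stepwise microsatellite mutation (median
rate 6.34×10⁻⁴/generation).  Each dataset is reduced to a 44-dimensional
summary vector (per-sample number of alleles, unbiased Hₑ, allele-size
variance, Garza–Williamson M; pooled versions plus Weir–Cockerham F_ST per
adjacent sample pair).  The 1% of simulations nearest the observed vector
is retained; multinomial logistic regression of the scenario label on the
retained statistics, evaluated at the observed point, gives posterior model
probabilities; medians and 95% intervals of the retained parameter draws
give the Ne estimates.

A density-dependent Lefkovitch stage projection (egg/larva/pupa/adult,
48-hour steps, logistic increment `N(t+1) = N(t) + ((K_tot − ΣN)/K_tot)(M − I)N(t)`,
adult carrying capacity = Ne) is included to ask whether a single-day
aquatic-mortality event (a deluge washing out larval habitat) could
plausibly explain an inferred Ne crash.  It cannot: adults bridge the gap.

Because the study's genotypes are not deposited, a first-class synthetic
module generates pseudo-observed studies under the inferred trajectory
(5692 → 428 → 1782 → 12060 → 4204 across the five sampling intervals) with
the observed diversity level, and the whole pipeline is validated by
recovering what it planted.  See `docs/methods.md` for models, defaults,
and limitations.

## Worked example

```python
import numpy as np, serialabc as sa
from serialabc.scenarios import build_scenario, mongola_design, punta_europa_rainfall
from serialabc.sumstats import stat_vector

design = mongola_design()                      # 6 samples, 13 loci, spray dates
clock  = sa.GenerationClock(18.0, design.sample_dates[-1])

# a pseudo-observed study under the canonical spray-response truth
data, truth = sa.generate_study(seed=109)
observed = stat_vector(data)

specs = [build_scenario(s, design, clock, rainfall=punta_europa_rainfall())
         for s in range(1, 7)]
table = sa.simulate_reference_table(specs, 2000, design, clock, seed=42)
fit = sa.fit_scenario(table, observed, fraction=0.01)
print(fit.best_scenario, {k: round(v, 3) for k, v in fit.scenario_probabilities.items()})
for k, v in fit.parameters.items():
    print(f"{k}: median {v['median']:.0f}  95% CrI [{v['ci95_quantile'][0]:.0f}, {v['ci95_quantile'][1]:.0f}]")
```

prints (seed-exact):

```
2 {1: 0.116, 2: 0.709, 4: 0.038, 5: 0.095, 6: 0.042}
N_anc: median 1946  95% CrI [697, 7425]
N1: median 15332  95% CrI [1958, 87157]
N2: median 84  95% CrI [12, 6387]
N3: median 1361  95% CrI [39, 31096]
N4: median 15455  95% CrI [656, 95022]
N5: median 635  95% CrI [17, 24454]
```

— the spray-response scenario ranks first (posterior 0.71), and the
interval bracketing the first spray round (N2, truth 428) comes back two
orders of magnitude below the pre-spray size (N1, truth 5692): the crash is
recovered.  At this deliberately small table size (2 000
simulations/scenario; the original analysis used 10⁶) the intervals are
wide and replicate pseudo-observed studies do not always rank the true
scenario first — the constant-size scenario is a strong mimic; see
`docs/methods.md` for the power analysis.

The projection model, shocked with 99% aquatic mortality for one day:

```python
from serialabc import StageModel, PerturbationEvent, project, summarize_trajectory
traj = project(StageModel(), steps=100,
               perturbations=[PerturbationEvent.aquatic(10, 0.99)])
print(summarize_trajectory(traj))
# {'min_adult': 4285.86..., 'percent_reduction': 24.70..., 'recovery_step': -1}
```

A one-day kill of *all* aquatic stages dents the adult class by only ~25%,
with most of the dip recovered within a handful of 48-hour steps
(`recovery_step` is −1 because the severe shock plateaus at ~0.98 K, just
under the 1%-of-K recovery threshold) — far too small and brief to explain
a 92% decline lasting months.

## Command line

`serialabc synth | stats | simulate | fit | sensitivity | clocks | project`
— thin wrappers over the library, configured by a YAML file (see
`serialabc --help`); every run writes a provenance block (config hash,
seeds, versions) next to its outputs.

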