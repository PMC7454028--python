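# temporal-demes

Temporal genetic structure in biennial plant populations: a forward-time
demographic-genetic simulator of two temporally offset demes linked by
temporal migrants, together with the population-genetic toolkit needed to
analyse both simulated and empirical genotype data.

## The problem

A strictly biennial, semelparous plant splits a site into **two demes that
never interbreed directly**: the cohorts flowering in odd years and those
flowering in even years. Individuals that delay flowering from age 2 to
age 3 — *temporal migrants* — are the only bridge between them. Field
surveys of tagged rosettes measure how often that happens; the question is
what those temporal migration rates do to the genetic structure of the
population over time.

The package is for population geneticists and plant ecologists who want to

* simulate the two-deme system under a grid of temporal migration rates
  *m* ∈ [0, 0.9] and migration-event probabilities *p* ∈ [0, 1],
* estimate temporal migration and mortality from tagged-rosette transition
  counts,
* compute diversity (n_a, H_O, Nei's unbiased H_S), AMOVA F_ST with
  permutation tests, hierarchical F-statistics with bootstrap CIs, and DAPC
  centroid distances on grouped co-dominant genotypes (microsatellite or
  diallelic), read from GenAlEx-like CSV, STRUCTURE text or Arlequin `.arp`
  files.

The core bookkeeping, per deme and reproductive year, is

```
N_T = N_R + N_M − N_E
N_R = round(λ·N_T′),  λ ~ N(1, 0.01)     recruits
N_E = round(m·N_R) on a migration event   emigrants (delay flowering)
N_M = the other deme's emigrants of the preceding year
```

with deme 1 reproducing in years *y* = 2t − 1 and deme 2 in years *z* = 2t.
Individuals carry 100 unlinked diallelic loci; offspring are Binomial(2, p)
draws from the parental allele frequencies. F_ST comes from
Excoffier/Cockerham variance components (raw, summed over loci), tested by
permuting individuals among groups. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
import numpy as np
from temporal_demes import (SimulationConfig, run_simulation, amova_fst,
                            fit_dapc, centroid_distance,
                            load_transition_table, transition_summary)

cfg = SimulationConfig(n_generations=100, n0=1000, n_loci=100,
                       m12=0.3, m21=0.3, p_event=0.5, seed=42)
traj = run_simulation(cfg)
print(traj.series.groupby("deme").tail(1)[["deme", "generation", "year",
                                           "N_T", "H_S"]].to_string(index=False))

gg = traj.to_grouped_genotypes()
res = amova_fst(gg, "deme", n_perm=1000, rng=np.random.default_rng(0))
print(f"F_ST = {res.fst:.4f}  (p = {res.p_fst:.4g})")

model = fit_dapc(gg, "deme", n_pca=50, n_da=2)
print(f"DAPC centroid distance = {centroid_distance(model, 'd1', 'd2'):.3f}")

print(transition_summary(load_transition_table(), "2011-12").to_string(index=False))
```

prints

```
deme  generation  year  N_T      H_S
  d1         100   199 1014 0.489606
  d2         100   200  840 0.489940
F_ST = 0.0007  (p = 0.000999)
DAPC centroid distance = 0.538
transition statistic  n_sites      mean        sd
   2011-12 mortality        3 53.952020 13.199349
   2011-12 migration        3 41.845456 23.314169
```

Read: after 100 generations with 30% of recruits emigrating whenever one of
the (roughly every-other-year) migration events fires, the demes are
demographically intact (≈1014 and 840 plants), retain most of their gene
diversity (H_S ≈ 0.49 of an initial 0.5), and are genetically almost
homogenized (F_ST ≈ 0.001 — compare ≈ 0.049 under complete isolation) yet
still statistically distinguishable (p ≈ 0.001, small DAPC distance). The
field table shows 2011-12 vegetative mortality of 53.95 ± 13.20% across the
three sites with data.

The same analyses are available from the shell:

```sh
temporal-demes field                        # tagged-rosette rate table
temporal-demes simulate --m12 0.3 --m21 0.3 --p-event 0.5 --seed 42 \
    --out traj.csv --arp-out final.arp
temporal-demes grid --m 0.0 --m 0.9 --p-event 0.1 --replicates 20 \
    --permutations 0 --out grid.csv
temporal-demes curve --rates 0,0.2,0.5,0.7,0.9 --replicates 30
temporal-demes stats --input genotypes.csv --what amova
```

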