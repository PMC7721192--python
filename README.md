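# tagmove

Length-based, age-structured Bayesian hierarchical movement models for
tag-recovery data.

## The problem

Fisheries managed in spatial management units (MUs) need movement rates
between units: a stock that leaks fish into a neighbouring unit is more
vulnerable to overharvest than its local assessment suggests. Tag-recovery
studies — fish tagged, released, and later reported when harvested by a
fishery — are the standard data source, but two complications arise in
practice:

* ages of tagged fish are not observed; only lengths are, so age must be
  inferred through an age-length key that itself carries sampling noise;
* movement may vary by year and by age class, and the data are rarely rich
  enough for fully saturated year x age parameterisations.

`tagmove` implements a spatial Brownie-type tag-return model that addresses
both: tagged-cohort fates are propagated through annual movement, survival
and exploitation across regions, age composition per length class is a
multinomial state variable updated jointly with the tagging data, and seven
movement configurations of increasing flexibility are fitted by MCMC and
compared with DIC, WAIC and PSIS-LOO. The motivating dataset — 13,694
PIT-tagged yellow perch released in Lake Erie MUs 1-2 during 2009-2015, 322
of them recovered by the Ontario commercial gillnet fishery — ships with the
package as plain-CSV fixtures, together with the scanned-catch reporting
rates.

## The model

The probability that an age-`a` fish tagged in year `ty`, region `tk` is
harvested and reported in year `fy`, region `fk` is built by vector-matrix
propagation:

```
P(a, ty, tk, fy, ·) =  π(a, ty, tk, ·) ∘ u(a, fy, ·) ∘ λ(fy, ·)            fy = ty
P(a, ty, tk, fy, ·) = [π ∘ S](a, ty) × ... × [π ∘ S](a', fy−1)
                       × π(a'', fy) ∘ u(a'', fy) ∘ λ(fy)                    fy > ty
```

with row-stochastic annual movement matrices `π`, survival
`S = exp(−s_a F − M)`, exploitation `u = s_a F / (s_a F + M) · (1 − S)`,
double-logistic (dome-shaped) gillnet selectivity `s_a`, and fixed reporting
rates `λ`. Ages advance each year boundary into an absorbing plus-group
(6+). Stratum fate probabilities mix `P` over the length class's age
composition `κ_l`, and release strata are multinomial across their recovery
cells plus a right-censored never-recovered cell.

Movement matrices come from normalising strictly positive weights with
Exponential(1) priors (a flat Dirichlet construction). The seven
configurations: `C` constant; `YF`/`AF` fixed effects by year/age;
`YR`/`AR` log-normal random effects by year/age; `AY` nested age-year
random effects; `AYc` adds a release-year partial-dispersal correction
`ratio`.

## Worked example

```python
import numpy as np
import tagmove as tm

# the packaged Lake Erie tables
ds = tm.lake_erie_dataset()
print(ds.total_releases, ds.total_recoveries, ds.total_at_large)
# 13694 322 13372

# simulate a synthetic study with the same design, then refit it
truth = tm.lake_erie_like_truth()            # constant-movement truth
data, age_sample = tm.simulate_study(truth, seed=42)
run = tm.run_mcmc(data, truth.reporting(), age_sample,
                  tm.MovementConfig("C"),
                  n_chains=2, n_iter=3000, thin=5, seed=7)
pi = np.median(run.movement_probability_draws()[:, 0, 0], axis=0)
print(pi.round(2))
# [[0.87 0.12 0.01]
#  [0.05 0.26 0.68]
#  [0.14 0.37 0.46]]
```

The printed matrix is the posterior median annual movement probability
between MU1-MU3 (rows = source): strong MU1 site fidelity (0.87 stay) and
heavy exchange within the central basin, close to the generating truth of
(0.87, 0.10, 0.03) / (0.05, 0.28, 0.67) / (0.05, 0.33, 0.62). The MU3 row
is the least certain — the design releases no fish from MU3, so its row is
informed only by immigrants.

The command line mirrors the library:

```
tagmove simulate --config truth.yaml --seed 5 --out data/
tagmove fit --config run_c.yaml --out runs/C
tagmove fit --config run_ar.yaml --out runs/AR
tagmove compare runs/C runs/AR --out comparison.csv
tagmove summarize runs/AR
```

Every artifact is regenerable from config plus seed alone.

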