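# winterflux

Winter movement, regional fidelity, and energy expenditure of
GPS/accelerometer-tagged geese.

Midcontinent greater white-fronted geese winter across eight ecologically
distinct regions of the south-central USA and Mexico, and have been
shifting their winter distribution eastward toward rice-growing regions
such as the Mississippi Alluvial Valley (MAV). `winterflux` implements the
full analysis chain needed to study that system from hourly GPS fixes and
tri-axial accelerometer bursts:

- **Movement products** — winter delimitation, hourly resampling,
  great-circle step lengths with gap filtering, daily-distance series, and
  a backward-elimination polynomial regression of log daily movement on
  the winter date index.
- **Weekly multistate capture–recapture model** — daily region states
  (point-in-polygon against the eight regions, one state per day nearest
  midnight) collapsed into weekly capture histories and fitted with a
  Bayesian nine-state model (eight regions + absorbing dead state):

  z<sub>i,t+1</sub> | z<sub>i,t</sub> ~ categorical(Ω<sub>z<sub>i,t</sub></sub>), y<sub>i,t</sub> | z<sub>i,t</sub> ~ categorical(Θ<sub>z<sub>i,t</sub></sub>)

  with Ω combining per-region weekly survival φ and the row-stochastic
  transition matrix ψ, and Θ mapping true states to observations through
  per-region detection p. ψ rows use a multinomial-logit parameterisation
  relative to "stay", so off-diagonal probabilities sum to < 1 and weekly
  fidelity is the complement. Sampling is block-wise adaptive random-walk
  Metropolis on the forward-algorithm likelihood; convergence is assessed
  by the Gelman–Rubin statistic (R̂ ≤ 1.10). Derived quantities: weekly
  fidelity (ψ diagonal), cumulative immigration (column off-diagonal sum)
  and emigration (row off-diagonal sum).
- **Energy expenditure** — overall dynamic body acceleration per burst,
  ODBA = |DA<sub>x</sub>| + |DA<sub>y</sub>| + |DA<sub>z</sub>|, with
  static acceleration removed by a centred 1-s moving average; quantile
  mapping harmonises the bounded (±2048 mV) device family onto the
  unbounded family's scale; daily ODBA is modelled with a linear mixed
  model (region fixed effect, MAV reference; individual and winter as
  crossed random intercepts) on a standardised inverse-hyperbolic-sine
  response, with single-step max-|t| pairwise contrasts and
  marginal/conditional R².
- **Behaviour** — a random-forest classifier over burst features assigns
  each burst to foraging, walking, stationary, or flight; daily time
  budgets per region are related to regional ODBA contrasts by beta
  regression with a logit link.
- **Synthetic generator** — every stage runs end-to-end against a
  simulator with known ground truth (latent weekly Markov region
  dynamics with survival and detection, roost–forage commuting fixes,
  behaviour-dependent burst signatures with device clipping), so all
  estimators are testable without any field data.

## Worked example

```python
import winterflux as wf

cfg = wf.SimConfig(n_individuals=100, n_weeks=19, seed=42)
histories, truth = wf.simulate_capture_histories(cfg)

model = wf.MultistateModel(histories)
res = model.fit(chains=3, iterations=20_000, burn_in=5_000, thin=5, seed=42)
print(res.summary())
```

```
Multistate capture-recapture posterior summary
  chains=3, iterations=20000, burn_in=5000, thin=5
  all interpreted transitions converged (R-hat <= 1.1): True (max R-hat = 1.009)
  weekly fidelity (posterior mean [95% CrI]):
      South Texas Brushlands: 0.85 [0.79, 0.90]
                         MAV: 0.70 [0.48, 0.88]
               Chenier Plain: 0.91 [0.87, 0.94]
             Texas Mid-coast: 0.83 [0.75, 0.90]
                       Other: 0.68 [0.56, 0.79]
                      Mexico: 0.98 [0.94, 1.00]
           Lower Texas Coast: 0.63 [0.51, 0.73]
         Rolling/High Plains: 0.94 [0.92, 0.97]
  transitions returning the prior (never observed): 0
  survival/detection estimated as nuisance only (not interpreted)
```

The fidelity column is the posterior mean probability that a goose in a
region one week is in the same region the next week (here recovering the
generator's truth diagonal of 0.89, 0.84, 0.90, 0.82, 0.73, 0.99, 0.70,
0.93, up to the Monte-Carlo noise of a single simulated winter); `MAV` is
wide because no simulated bird is captured there, so its row rests on few
observed transitions. Transitions that never occur in the data return the
vague prior (posterior mean ≤ 0.001) and are flagged, not interpreted.

The same end-to-end chain is available from the shell:

```bash
winterflux all --config run.yaml --seed 42 --out my_run
```

which writes fixes, bursts, capture histories, posterior summaries, daily
ODBA, time budgets, and a run report with a manifest of seeds and digests.

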