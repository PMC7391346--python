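# moveseg

Behavioral segmentation of satellite-tracked marine animal movement.

Satellite relay tags on marine animals — here, juvenile loggerhead
turtles (*Caretta caretta*) in the southern Tyrrhenian Sea — deliver
Argos locations that are temporally irregular and carry large,
anisotropic errors (error ellipses with semi-major axes from hundreds of
metres to tens of km), alongside dive counts, depths and water-temperature
profiles. `moveseg` turns these streams into behavioral inference:

1. **Regularization** — a continuous-time correlated random walk (CTCRW:
   position as the integral of an Ornstein–Uhlenbeck velocity, dv = −βv dt
   + σ dW) is fitted per animal by Kalman-filter maximum likelihood with
   each fix's error ellipse as measurement covariance; smoothed positions
   are predicted on an exact 6-hr grid, and multiple imputations of the
   position process are drawn with a simulation smoother to propagate
   location uncertainty.
2. **Summarization** — per 6-hr interval: step length, turning angle,
   dive count, maximum depth, dive time, haul-out time and a two-stage
   median water temperature; the first 24 h after release are excluded.
3. **Hidden Markov model** — a 3-state chain (transit, low-intensity
   diving, high-intensity diving) with state-dependent Gamma step
   lengths, von Mises turning angles and Poisson dive counts, fitted by
   multi-start direct likelihood maximization; Viterbi decoding,
   forward–backward state probabilities (merged "diving probability"),
   pseudo-residual diagnostics, AIC model comparison, and Rubin's-rules
   pooling across imputations.
4. **Post hoc** — multinomial logistic regression of state on median
   water temperature; activity budgets against distance-to-coast and
   bathymetry; autocorrelation-aware kernel utilization densities with
   75% isopleth home ranges and Bhattacharyya overlap.

A synthetic-data module generates all four input streams (plus an island
bathymetry raster) from known ground truth, so every stage is verified by
parameter recovery and closed-form/exhaustive oracles. See
`docs/methods.md` for the model details and design choices.

## Worked example

Simulate interval observations from the fitted published model (nine
animals, 200 six-hr intervals each) and refit the 3-state HMM:

```python
from moveseg.hmm import HMMSpec, fit_hmm
from moveseg.synthetic_data import SimConfig, simulate_truth_records

records = simulate_truth_records(SimConfig(n_animals=9, n_intervals=200, seed=7))
fit = fit_hmm(HMMSpec(), records, n_starts=10, seed=7)

for i, lab in enumerate(fit.spec.state_labels):
    print(f"{lab:<22} {fit.emissions['step_km']['mean'][i]:>13.2f} "
          f"{fit.emissions['n_dives']['rate'][i]:>16.2f} {fit.tpm[i, i]:>16.2f}")
print(f"log-likelihood = {fit.loglik:.1f}   AIC = {fit.aic:.1f}")
```

```
transit                         7.97             1.68             0.87
low-intensity diving            6.21             6.47             0.82
high-intensity diving           5.29            14.19             0.87
log-likelihood = -11644.3   AIC = 23334.5
```

Columns are the state's mean step length (km), Poisson dive rate per 6 h
and self-transition probability. The generating values were 8.152 / 6.2 /
5.3 km, 1.6 / 6.54 / 14.12 dives, and self-transitions 0.86 / 0.80 /
0.86: at 1,800 intervals the fit recovers them to a few percent, with
states relabeled canonically by ascending dive rate so "transit" is
always state 1.

The full pipeline (CSV streams in, report + decoded states + home ranges
out) runs from the shell:

```
moveseg simulate --seed 42 --out data/
moveseg run --data-dir data/ --nsims 100 --seed 42 --out results/
```

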