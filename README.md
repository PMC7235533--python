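# spikevar

Partitioning retinal-ganglion-cell spike-train variability under
sub-threshold electrical white-noise stimulation, with a nested family of
Poisson generalized linear models.

## The problem

Retinal prostheses that drive the retina with weak (sub-threshold) pulse
trains elicit responses through network integration rather than direct
activation. Those responses are variable: firing rates drift over a
session, only part of the variability is stimulus-locked, and only part of
*that* is captured by a linear filter. For anyone tuning stimulation
parameters, the question is not just "is there an STA?" but **how much of
the response is non-stationary drift, how much is linear stimulus drive,
how much is repeatable but non-linear, and how much is noise?**

`spikevar` answers this with a hierarchy of nested Poisson GLMs fitted to
binned spike counts y_ti ~ Poisson(μ_ti), μ_ti = exp(z_ti):

| level   | activation z_ti          | adds                         |
|---------|--------------------------|------------------------------|
| BS      | b₀                       | mean rate                    |
| NS      | b₀ + φᵢ                  | per-trial drift offsets      |
| NS-LNP  | b₀ + φᵢ + xₜᵀk           | linear stimulus filter       |
| NS-PSTH | b₀ + φᵢ + xₜᵀk + ρₜ      | per-bin rate modulation      |

Each added block is MAP-regularized by a Gaussian-process prior (Matérn
over trials/taps, discretized Ornstein–Uhlenbeck over bins) whose
hyper-parameters are chosen by 10-fold trial-level cross-validation,
sequentially level by level, with a collapse rule that forces the reported
cross-validated log-likelihood (CVLL) to be non-decreasing across the
hierarchy. With the saturated bound L_sat (one free rate per trial and
bin), the explainable gain is partitioned as

    P_nonstat = (L_NS − L_BS) / (L_sat − L_BS)
    P_lin     = (L_LNP − L_NS) / (L_sat − L_BS)
    P_nonlin  = (L_PSTH − L_LNP) / (L_sat − L_BS)
    P_sig     = P_nonstat + P_lin + P_nonlin,   P_noise = 1 − P_sig

on both training data (structure present) and held-out folds (structure
that generalizes). A synthetic-data generator reproduces the assumed
recording conditions — 36 × 100 s trials, 25 Hz pulses (Δt = 40 ms, 2,500
bins/trial), Gaussian amplitudes −800/280 mV, a frozen noise realization
interleaved with unique noise — so the whole pipeline is testable without
any recordings. See `docs/methods.md` for the full model account.

## Worked example

```python
import spikevar as sv

stim = sv.generate_stimulus(n_trials=36, n_pulses=2500, seed=1)
truth = sv.draw_ground_truth(K=36, T=2500, m=25, seed=1)   # drift + filter + per-bin modulation
raster = sv.simulate_raster(truth, stim, delta_t=0.04, seed=1)

model = sv.NestedPoissonGLM(raster, stim, m=25)
result = model.fit(seed=1)
print(result.summary())
```

```
Nested Poisson GLM hierarchy
================================================================
cell: -    type: -
repeating trials: 18   bins/trial: 2500   dt: 40 ms
spikes: 17532   mean rate: 9.74 Hz

Level      CVLL           collapsed  scale   length/corr
----------------------------------------------------------------
BS         -3774.74       False      -       -
NS         -3582.94       False      3.0     10.0
NS-LNP     -3450.03       False      0.1     5.0
NS-PSTH    -3325.75       False      1.0     0.99
----------------------------------------------------------------
Partition of explainable log-likelihood gain (fraction of L_sat - L_BS)
                      cv     train
nonstationary      0.082     0.083
linear             0.057     0.057
nonlinear          0.053     0.074
signal             0.193     0.214
unexplained        0.807     0.786
```

Reading this: of the cell's total explainable log-likelihood gain, about
8% generalizes through the per-trial drift, ~6% through the linear filter,
~5% through the remaining repeatable per-bin structure, and ~81% stays
unexplained on held-out trials — the typical signature of weak
sub-threshold drive. Only the 18 repeating (frozen-noise) trials are
fitted; the CVLL column is non-decreasing by the collapse rule. Fitted
parameters are in `result.params["NS-PSTH"]` (`b0`, `phi`, `k`, `rho`),
per-level hyper-parameters and per-fold CVLLs in `result.selection`, and
`result.partition("cv")` / `result.partition("train")` carry the
fractions. `sv.group_summary` aggregates many cells into a per-type
(ON/OFF/ON-OFF) table of mean ± sd/sem per component.

The same pipeline is scriptable from the shell:

```bash
spikevar simulate --seed 1 --out data/
spikevar preprocess --spikes data/spikes.csv --stimulus data/stimulus.csv --out pre/
spikevar crossval --raster pre/raster.csv --stimulus data/stimulus.csv --out cv.json
spikevar partition --raster pre/raster.csv --stimulus data/stimulus.csv --out parts/
spikevar pipeline --simulate --n-cells 5 --seed 1 --out run/   # end to end
spikevar report --in run/ --format md
```

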