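# Methods

`spikevar` quantifies how much of a retinal ganglion cell's spiking
variability under sub-threshold electrical white-noise stimulation is
attributable to slow non-stationarity, to a linear dependence on the
stimulus, to residual stimulus-locked (non-linear) structure, and to
unexplained noise. This note records the model, the estimation and
selection procedure, the synthetic-data generator, the numerical choices,
and the limitations of what the tests demonstrate.

## The model hierarchy

Spike trains are discretized into bins of width Δt = 40 ms, one bin per
25 Hz stimulus pulse, with the bin onset aligned to the pulse timestamp and
spikes in the first 10 ms after the pulse discarded (they may reflect
direct electrical activation rather than network-mediated drive). The
count y_ti of trial i, bin t is modelled as Poisson with mean μ_ti =
exp(z_ti), where the activation z grows through four nested levels:

| level   | activation                         | captures                      |
|---------|------------------------------------|-------------------------------|
| BS      | z = b₀                             | mean firing rate              |
| NS      | z = b₀ + φᵢ                        | trial-to-trial drift          |
| NS-LNP  | z = b₀ + φᵢ + xₜᵀk                 | linear stimulus filtering     |
| NS-PSTH | z = b₀ + φᵢ + xₜᵀk + ρₜ            | any repeatable per-bin rate   |

xₜ is the m-bin stimulus history ending at bin t (lag 0 = the bin's own
pulse). μ is a **mean count per bin**: the bin width is absorbed into b₀,
and firing rates in Hz are μ/Δt for display only. This makes the baseline
closed form exact — exp(b₀) = n_sp/(TK) — and keeps every likelihood
well-defined without carrying Δt through the algebra.

Each added block is MAP-estimated under a zero-mean Gaussian-process prior
while all earlier blocks stay fixed:

* φ (per-trial drift): Matérn kernel (ν = 3/2 by default, configurable)
  over the session trial index, hyper-parameters (σ_NS, τ_NS). Using the
  session index (not the position within the repeating subset) means that
  in interleaved frozen/unique designs the drift correlation respects real
  elapsed time.
* k (filter taps): Matérn kernel over tap index, (σ_LNP, τ_LNP) — a
  smoothness prior on the filter shape.
* ρ (per-bin modulation): the covariance of a discretized
  Ornstein–Uhlenbeck process, C_ij = σ²_PSTH · a^{|i−j|}. Its precision is
  tridiagonal, so the T-dimensional Newton step is a banded solve
  (verified against a dense solve to 1e−6 in the tests).

A prior scale of exactly 0 pins the block to zero — the collapse point
that recovers the previous level.

## Fitting

The penalized log-likelihood Σ[y·z − exp(z)] − ½θᵀC⁻¹θ is concave in each
block, and is maximized by damped Newton iterations: the full Newton step
is backtracked (halved) until the objective improves, so the objective is
non-decreasing across iterations by construction. Convergence is declared
at relative objective change ≤ 1e−8 (≤ 100 iterations); failure raises an
error carrying the iterate diagnostics. Activations are clipped at ±30
before exponentiation — far outside plausible rates — as an overflow
guard. A raster with zero spikes gets a floored baseline,
exp(b₀) = 1/(10·TK), with a warning.

Because frozen-noise trials share one stimulus realization, the filter
design collapses to a single T×m matrix and the per-trial structure enters
only through φ; all heavy contractions are then O(T·m²) or banded O(T).

The stimulus covariate is z-scored before entering the design (default,
configurable). Raw amplitudes are on the order of −800 ± 280 mV, which
would put filter taps on a 1e−4 scale; standardization puts taps and
their GP prior on an order-one scale so that a single log-spaced
hyper-parameter grid serves all levels. The first m−1 bins of each trial
have incomplete stimulus history; they are zero-padded and flagged by
default, or excluded from all likelihoods via a bin mask
(`history="drop"`).

## Selection: cross-validation, sequential search, collapse rule

Only the repeating (frozen-noise) trials are modelled. They are shuffled
once and dealt round-robin into 10 folds, so 18 repeating trials give 8
folds holding out 2 trials and 2 holding out 1 — a proper partition, each
trial held out exactly once. The same folds are reused for every level and
every grid point.

Levels are optimized in order NS → NS-LNP → NS-PSTH. At each level, every
grid point is scored by the average held-out log-likelihood (CVLL) over
folds, with the earlier blocks frozen per fold at the values they took
under the previous level's winning hyper-parameters on that same fold.
Ties prefer the most regularized point (smallest σ, then smallest τ or a).
Default grids are log-spaced — σ ∈ {0, 0.03, 0.1, 0.3, 1, 3},
τ ∈ {0.5, 1, 2, 5, 10, 20} (trial units for the drift, tap units for the
filter), a ∈ {0, 0.3, 0.6, 0.8, 0.9, 0.95, 0.99} — and always contain the
collapse point σ = 0. If the best new CVLL does not beat the previous
level's, the level collapses: its parameters are set to 0 and its CVLL
copied. Reported CVLL is therefore non-decreasing across the hierarchy for
every cell, as a hard assertion.

Held-out trials need a drift value that was never fitted. The joint MAP
with likelihood terms only on training trials profiles exactly to the GP
conditional mean, so φ on a held-out trial is interpolated from the fitted
trials through the Matérn kernel. This is what gives the NS level genuine
held-out predictive content: nearby trials inform the held-out trial's
rate.

CVLL is summed over held-out bins and averaged over folds (not per-bin
normalized); this is configurable as the convention is not forced by
anything.

## The partition

With L_BS ≤ L_NS ≤ L_LNP ≤ L_PSTH ≤ L_sat on common data, where L_sat is
the saturated bound Σ[y·log y − y − log y!] (each bin's rate set to its own
count), the explainable gain L_sat − L_BS is split into

    P_nonstat = (L_NS − L_BS) / (L_sat − L_BS)
    P_lin     = (L_LNP − L_NS) / (L_sat − L_BS)
    P_nonlin  = (L_PSTH − L_LNP) / (L_sat − L_BS)
    P_sig     = P_nonstat + P_lin + P_nonlin,   P_noise = 1 − P_sig.

Two evaluation modes are emitted for every cell. **train**: each level is
refit on the full repeating-trial raster at its selected hyper-parameters
and scored on that same data (an optimistic bound — how much structure is
present). **cv**: the per-fold held-out log-likelihoods are averaged, and
the saturated bound is likewise computed per fold from the held-out counts
and averaged, keeping numerator and denominator on the same data (a
pessimistic bound — how much generalizes). On training data the MAP
refits make the L's monotone automatically (each block could have stayed
at zero); any negative gain within 1e−9 of zero is clamped with a log
entry, anything larger is an error. The partition closes —
P_nonstat + P_lin + P_nonlin + P_noise = 1 — to 1e−12 on every output.

Group summaries report mean across cells per type (ON / OFF / ON-OFF) with
both standard deviation and standard error of the mean, since either
dispersion convention is found in practice. "Unexplained" in the summary
table is P_noise, the complement of the three components on the same
evaluation data.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
at the design's conditions: 36 trials of 100 s (one hour), 25 Hz pulses
(2,500 bins of 40 ms per trial), Gaussian amplitudes mean −800 mV, sd
280 mV, half the trials carrying one frozen realization interleaved with
unique-noise trials (even-indexed trials frozen, deterministic and
configurable, since any fixed interleaving is consistent with the design).

Ground truth for a cell is b₀ plus a GP draw of φ over trials, a GP draw
of ρ over bins, and a named filter template. Defaults were chosen once for
physiological plausibility: base rate 7.5 Hz (0.3 counts/bin) — a
realistic sub-threshold driven rate; drift sd 0.5 with Matérn length 5
trials (clearly visible non-stationarity over a 36-trial session); per-bin
modulation sd 0.4 with lag-one correlation 0.95 (slow within-trial rate
structure); and a biphasic difference-of-Gaussians filter scaled so the
stimulus drive has sd 0.4 on the log-rate scale. The filter template is
balanced to sum to zero so the −800 mV pulse mean injects no DC into the
rate and b₀ alone fixes the mean rate; together these scales keep peak
per-bin means well inside the simulator's rate cap (50 counts/bin, an
error guard against runaway parameters, far above physiological rates).
Counts are independent Poisson draws given the activation. Spike times
can additionally be placed uniformly inside each bin, with a configurable
fraction forced into the first 10 ms to exercise the dead-time discard;
by default no spikes land in the dead window, so binning round-trips the
counts exactly.

What the generator does **not** emulate: refractoriness and spike-history
dependence (counts are conditionally Poisson), bursting, spike-sorting
contamination, electrode drift in stimulus delivery, and any non-linearity
beyond what a per-bin rate can express. Passing tests therefore show that
the estimator recovers the model's own structure at realistic scales and
is calibrated under its own null — not that real retinal responses satisfy
the model.

## STA and its surrogate test

The classical spike-triggered average is computed over bins with full
m-bin history, tap j being the mean (optionally mean-centered) stimulus j
bins before the spike's own bin. Significance is assessed with a
circular-shift surrogate: each trial's count sequence is rotated by an
independent random offset, destroying spike–stimulus alignment while
preserving counts and autostructure; the per-tap [α/2, 1−α/2] envelope
over ≥100 surrogates is the null band and the STA is flagged significant
if any tap exits it (α = 0.01 default). This is a pragmatic stand-in for a
full cell-inclusion pipeline (spike sorting and validation are out of
scope); note the any-tap rule makes the family-wise rate grow with m.

## Numerical and design choices

* Matérn ν = 3/2 default (ν ∈ {1/2, 3/2, 5/2} supported); filter length
  m = 25 taps (1 s of history) by default — both configurable because no
  single value is canonical.
* A spike exactly on a bin boundary belongs to the later bin (half-open
  bins aligned to pulse timestamps).
* Dead-time and out-of-range spikes are counted and logged, never silently
  dropped; spikes in = spikes binned + dead-dropped + out-of-range holds
  exactly.
* b₀ is fitted once by the baseline and held fixed at all later levels;
  each level fits only its new block (the drift can absorb any mean
  mismatch).
* All randomness flows from one seed through named substreams (stimulus,
  truth, spikes, folds, surrogates), so a run is reproducible end to end
  and streams are independent across purposes.
* Degenerate inputs: zero-spike rasters are floored (see above); a
  saturated bound equal to the baseline likelihood (e.g. an empty raster)
  makes the partition undefined and raises; non-PSD priors raise at the
  Cholesky.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
the design scale where the claim depends on it — 18 repeating trials ×
2,500 bins for parameter recovery, null calibration (50 seeds in the test
suite) and drift-only collapse — and on smaller rasters (4–8 trials,
150–400 bins) where the property checked is exact arithmetic, a
serialization round-trip, or solver equivalence. Reduced hyper-parameter
grids (4 scales × 2 lengths/correlations, collapse point included) are
used for the multi-seed sweeps; grid size trades search resolution against
compute and does not change the data-generating conditions.

## Limitations

* MAP point estimates only — no posterior uncertainty on φ, k, ρ, and no
  marginal-likelihood hyper-parameter choice; selection is by CVLL grid
  search exactly because that is the procedure being characterized.
* No spike-history terms and no Bernoulli-link variant.
* The cv-mode partition depends on the fold granularity (1–2 trials held
  out); fractions from different fold schemes are not interchangeable.
* With few repeating trials the GP interpolation of φ to held-out trials
  is the dominant source of NS-level generalization; for designs without
  temporal structure in the drift it degrades to shrinkage toward zero.
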