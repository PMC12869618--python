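# ndtwkit

Timing-invariant amplitude disparity for multichannel BOLD-like time
series, and the dynamics of the brain states it reveals.

Correlation-based functional connectivity conflates two different things:
*when* two regional signals fluctuate (timing) and *how much* they
fluctuate (amplitude). When haemodynamic lags, stretching or shrinking
misalign two otherwise amplitude-matched signals, correlation drops even
though their amplitudes agree; conversely a genuine amplitude imbalance
between two tightly phase-locked networks is invisible to correlation.
`ndtwkit` implements the complementary measure: align the pair on a common
timescale first, then quantify what alignment cannot remove — the residual
amplitude disparity.

## The metric

For two series `x` (length N) and `y` (length M), a warping path
`φ = (φ_x(τ), φ_y(τ))`, τ = 1..L, is any monotone, anchored traversal of
the index grid with unit steps, restricted to a Sakoe–Chiba band
`|i − j| ≤ w`. With the γ-parameterized pointwise cost

    λ_γ(a, b) = |a − b|^γ,          γ > 0

dynamic programming finds the path minimizing the cumulative cost. The
toolkit reports

* `D  = Σ_τ λ_γ(x(φ_x(τ)), y(φ_y(τ)))` — the DTW distance (for γ = 2, the
  energy of the aligned difference signal), and
* `Dn = D / L` — normalized DTW (nDTW), the mean aligned cost, comparable
  across pairs with different path lengths. Low Dn is *convergence*
  (proportionate amplitudes after timescale alignment), high Dn
  *divergence*.

γ tunes sensitivity: γ > 1 emphasizes large amplitude disparities, γ < 1
small ones (γ = 1.5 is the default). The window half-width `w` is tied to
the band-pass filter's low −3 dB point `f3db` through
`f3db = 0.88 / ((N_w/2 − 1)·TR)` solved for the window length `N_w`
(45 samples at f3db = 0.01 Hz, TR = 2 s), which always meets or exceeds
the ideal-filter bound of one full wavelength (100 s at 0.01 Hz).

Downstream, dropping the summation/normalization gives a per-timepoint
disparity trace whose mean reproduces Dn (PCHIP-resampled to the original
length), and the traces of all channel pairs feed a state analysis:
city-block k-means over pooled timepoints, elbow selection of k, Markov
transition matrices of the state sequences, stationary distribution π
(πP = π), spectral gap 1 − |λ₂|, total-variation mixing time, entropy
rate −Σᵢ π(i) Σⱼ P(i,j) log₂ P(i,j), per-state dwell time and occupancy,
and a perturbation analysis of individual transition probabilities.
Phase-randomization surrogates (including a band-residual scheme that
randomizes only fast 0.15–0.198 Hz content) and composite test–retest
reliability statistics (`trt = 1 − |t|_within/|t|_between`) complete the
toolkit. Everything runs on synthetic data from the built-in generators.

## Worked example

A ten-subject synthetic cohort with a planted three-state schedule
(convergent / mixed / divergent amplitude imbalance between channel
pairs), pushed through the full pipeline:

```python
import numpy as np
from ndtwkit.synthetic_data import CohortSpec, gen_cohort
from ndtwkit.signal_prep import zscore
from ndtwkit.dtw_core import DtwParams
from ndtwkit.time_resolved import disparity_tensor
from ndtwkit import state_dynamics as sd
from ndtwkit import markov_metrics as mm

spec = CohortSpec(seed=7)  # 10 subjects x 8 channels x 160 timepoints, TR 2 s
panel, _, truth = gen_cohort(spec)
params = DtwParams(gamma=1.5, window=2)
tensor = disparity_tensor(zscore(panel), params)
model = sd.fit_states(sd.trim_edges(tensor, 5), k_range=range(1, 11), reps=10, seed=11)
display, roles = sd.orient_states(model)
print(f"selected k = {model.k}; state roles = {roles}")
labels = sd.split_labels(model, panel.n_subjects, tensor.shape[-1] - 10)
tms = [mm.transition_matrix(labels[s], model.k) for s in range(panel.n_subjects)]
agg = mm.aggregate_transition_matrix(tms)
summary = mm.chain_summary(agg.P)
```

Output:

```
selected k = 3; state roles = ['mixed', 'convergent', 'divergent']
aggregate transition matrix P:
[[0.91  0.053 0.037]
 [0.037 0.952 0.011]
 [0.038 0.009 0.953]]
stationary distribution pi = [0.295 0.383 0.322]
spectral gap               = 0.0570
mixing time (tol 1e-3)     = 69 steps
entropy rate               = 0.3730 bits (23.5% of log2(3))
subject 1 mean dwell (TRs) = [14.8  17.25  7.  ]
subject 1 occupancy (%)    = [49.333 46.     4.667]
```

The elbow rule picks k = 3 states, which orient into convergent, mixed
and divergent roles. Strong self-retention (diagonal of P near 0.95)
yields long dwell times; the small spectral gap means slow relaxation to
the stationary distribution (69 steps to come within total variation
10⁻³), and the entropy rate of 23.5% of its maximum reflects orderly,
persistent dynamics rather than random switching — all consistent with
the planted chain (self-retentions 0.96/0.94/0.96).

The same stages are scriptable from a shell: `ndtwkit simulate`,
`ndtwkit prep`, `ndtwkit ndtw`, `ndtwkit trdtw`, `ndtwkit states`,
`ndtwkit markov`, `ndtwkit surrogate`, `ndtwkit reliability`,
`ndtwkit run` (full pipeline from a YAML config). See `ndtwkit --help`.

## Limitations

Interpolation-based resampling of the disparity trace preserves the
pair-level mean only approximately; the error grows with γ and with the
path-length inflation the window permits (see `docs/methods.md` for the
quantitative picture and configuration sensitivity). The toolkit starts
from network time courses; volume-level fMRI preprocessing and ICA
decomposition are out of scope.
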