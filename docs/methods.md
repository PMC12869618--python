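# Methods

## The disparity metric

`ndtwkit` treats a pair of band-limited, z-scored signals as differing in
two separable ways: timing (lags, stretching, shrinking within a bounded
horizon) and amplitude. Windowed dynamic time warping removes the first
so that the second can be measured. The DP recursion is the classic
three-predecessor form over the cumulative cost matrix, with boundary
CM(0,0) = 0 and +∞ elsewhere (paths anchored at both ends), pointwise
cost λ_γ(a,b) = |a−b|^γ, and a Sakoe–Chiba band |i−j| ≤ w. Ties in the
predecessor argmin are broken deterministically — diagonal first, then
the vertical (i−1, j), then the horizontal (i, j−1) — both in the fill
and in backtracking, so identical inputs always produce the identical
path. The returned `WarpAlignment` stores the per-step costs λ_γ along
the path (not cumulative cell values), making D = Σ per-step cost an
identity and the time-resolved trace recoverable without re-alignment.
The cost matrix is materialized in full with +∞ outside the band; at the
series lengths this package targets (10²–10³ samples) that is a few
hundred kilobytes, and the numba-compiled kernel makes a 150-sample
alignment take well under a millisecond. Exactness is verified against
exhaustive enumeration of all banded monotone paths on small instances.

Normalization by the path length L (Dn = D/L, the mean aligned cost)
makes pairs with different L comparable; for γ = 2 it is the power of the
aligned difference signal. Infeasible windows (|N−M| > w) and non-finite
inputs are rejected.

### Window rule

The alignment horizon should cover the slowest meaningful temporal
deformation the data can carry. For an ideal filter with low cutoff f_lo,
the longest wavelength is 1/f_lo (100 s at 0.01 Hz) and maximal
anti-correlation needs a half-wavelength shift (50 s); one such shift per
warping direction motivates a total window of one full wavelength. Real
(Butterworth) filters leak below the cutoff, so the window is instead
derived from the −3 dB point: f3db = 0.88 / ((N_w/2 − 1)·TR), solved for
the window length N_w, with half-width w = round(N_w/2). At f3db =
0.01 Hz and TR = 2 s this gives N_w = 90 samples (180 s) ≥ the 100-s
ideal bound. The formula is isolated in `dtw_window_from_cutoff` and the
ideal-filter arithmetic in `ideal_window_bound_seconds`, so an
alternative reading can be swapped in. The rule is monotone decreasing in
both f3db and TR and clamps to w = 1 (with a warning) for degenerate
cutoffs at or above Nyquist.

## Signal preparation

Band-pass filtering uses a minimum-order Butterworth design
(`scipy.signal.buttord`/`butter`) with ≤ 3 dB passband ripple and ≥ 30 dB
stopband attenuation, applied forward–backward (`sosfiltfilt`) so the net
response is zero-phase with amplitude |H(f)|². Stopband edges are not
part of the published design contract; the defaults are stop_lo = f_lo/2
and stop_hi = min(f_hi + 0.05 Hz, 0.98·Nyquist), recorded in the
serializable `BandpassSpec`. Filtering does not trim edge transients —
trimming happens once, before state clustering. z-scoring is per subject
and channel over time (population sd), rejects constant channels by
name, and is idempotent and affine-invariant.

## Time-resolved disparity

Dropping summation and normalization from Dn leaves the per-step trace
Dtr(τ) = |x(φ_x(τ)) − y(φ_y(τ))|^γ, whose mean equals Dn exactly. Path
lengths differ between pairs, so the trace is interpolated back to the
original length N with PCHIP — monotone, shape-preserving, no overshoot
below the local data range (hence non-negativity survives), continuous
first derivatives. The abscissa is the path index 1..L and the queries
are N uniform points spanning [1, L]; Eq-level alternatives (interpolating
over warped time ½(φ_x+φ_y), querying at the inverse warping positions,
or resampling the warping functions themselves and re-evaluating the
cost) were all evaluated and are 2–10× less accurate at preserving the
mean, so the path-index scheme is the default and only implementation.

Mean preservation after resampling is approximate. On i.i.d. standard-
Gaussian pairs the median percentage error scales roughly as c(γ, w)/√N
and grows with γ (rougher traces interpolate worse): about 0.7% at γ = 1
and 1.2% at γ = 1.5 for N = 150 with w = 45, shrinking with tighter
windows (shorter paths) and longer signals. The package's logged validation configuration is N = 150,
γ = 1.5, w = 45; `scripts/acceptance.py` recomputes the 10,000-pair
median under it. Rough traces (white-noise-like inputs) are the
worst case — smooth band-limited signals interpolate better.

A caveat for state analyses: uniform resampling of the path index maps
trace samples back to original time only approximately; where the path
wanders off-diagonal the trace timeline can be locally offset by a few
samples. This blurs state-transition boundaries (see the cohort
generator's design notes below).

## Surrogates

Phase randomization draws one uniform random phase sequence per subject
and adds it to the FFT of every channel identically (DC and Nyquist bins
excluded to keep the output real). This preserves each channel's
amplitude spectrum and all cross-spectra to machine precision — hence the
full Pearson correlation matrix and all circular autocorrelations — while
destroying phase-dependent structure. An independent-phases mode exists
for diagnostics only.

The band-residual scheme isolates fast-fluctuation effects: Z =
phase-randomized wide-band (F1) panel; Y = Z filtered with the same F2
design used for the original narrow-band data; X = Z − Y (randomized fast
residual); surrogate = X + original F2 panel. No explicit high-pass is
used because a non-ideal filter would ring at the 0.15 Hz edge. By
construction the surrogate equals the original F2 data wherever the F2
filter's net response is identity; in the transition band a finite-order
filter genuinely shares content between Y and X, so equality claims (and
the tests) are stated over the deep passband (net response ≥ 0.99),
with Hann-windowed spectra to keep leakage from the residual band out of
the comparison.

Null testing accepts either one observed statistic per pair — the
empirical surrogate-rank p-value (1 + #{at least as extreme})/(n+1) — or
an observed distribution per pair, compared by Wilcoxon rank-sum;
Benjamini–Hochberg correction is applied across pairs in both cases.

## Reliability

Within-subject variability is the paired-t magnitude per pair,
|t|_within = |mean(d)| / (sd(d)/√n); between-subject variability is a
non-parametric analogue computed on session 1, median(|s₁ᵢ − mean(s₁)|) /
(IQR/√n). The composite trt = 1 − |t|_within/|t|_between approaches 1 for
reliable metrics. Printed forms of these denominators are ambiguous
between /n and /√n; √n (the t-statistic convention) is the default, the
literal variant is available via `use_sqrt_n=False`. Degenerate cases are
explicit: all-zero differences give |t|_within = 0 (perfect consistency),
zero sd with nonzero mean and zero IQR give +∞ sentinels with warnings.
Both statistics are scale-invariant, so trt is too. Method comparison
ranks trt across pairs (rank 1 = most reliable), with paired signed-rank
tests and BH correction across method pairs.

## State dynamics

The disparity tensor (subjects × pairs × timepoints) is trimmed by 5
timepoints per edge — anchored alignment biases the trace ends — and
pooled into a samples × features matrix (every timepoint of every subject
is a sample; channel pairs are features). Clustering is city-block
k-means with per-feature **median** centroid updates (the L1-optimal
center), best of 20 random initializations by default, deterministic
under seed; empty clusters are re-seeded from the worst-fit sample, and a
degenerate all-identical input keeps its previous centers rather than
producing NaNs.

k is chosen from the WSS curve (within-cluster sum of city-block
distances) by a frozen drop-ratio elbow rule: with Δ(k) = WSS(k) −
WSS(k+1), pick the first k maximizing Δ(k−1)/Δ(k) — the point where the
preceding drop most dominates the following one, i.e. the sharpest bend
of the first derivative. On the reference curve [100, 40, 20, 18, 17,
16.5] the rule returns 3. A curve with no bend (all ratios ≈ 1) returns
the smallest interior k with a warning flag. The rule is deliberately
simple and unit-tested because any elbow criterion is a convention.

For display, centroids are oriented as −(centroid − median of all
centroid entries) so positive values mean convergence; states are ranked
by mean display value into convergent (highest), divergent (lowest) and
mixed roles, ties broken by state index; raw centroids are never
modified. Per-state pair maps keep the top ceil(5% · n_pairs) pairs of
the dominant sign, or the union of the top 2.5% positive and 2.5%
negative for mixed states (69 pairs at 5% of 1378).

## Markov analytics

State sequences are modelled as first-order chains: counts → row-
normalized P per subject; the aggregate matrix row-normalizes the summed
counts (count-weighted; the mean-of-P alternative is a flag). Rows never
visited stay all-zero and mark the subject non-ergodic; such subjects are
excluded from chain summaries (dwell/occupancy are still computed).
Ergodicity = strong connectivity + aperiodicity of the P > 0 digraph
(networkx); finite irreducible chains are positive recurrent. π is the
left eigenvector at eigenvalue 1 refined by a constrained least-squares
solve of the balance equations, cross-checked against power iteration in
tests. The spectral gap is 1 − |λ₂| with λ₂ the second-largest eigenvalue
by modulus (complex pairs possible for k ≥ 3). Mixing time is the
smallest t with TV(μ₀Pᵗ, π) ≤ tol (default 10⁻³), TV = ½·L1; the default
start is the simplex vertex of the least-probable state — the vertex
farthest from π in TV. The entropy rate is −Σᵢ π(i) Σⱼ P(i,j) log₂ P(i,j)
with 0·log 0 = 0, reported also as a percentage of log₂ k (100% iff every
row is uniform).

Perturbation analysis increments one cell at a time by ε, renormalizes
the row, and records the percentage change in spectral gap and entropy
rate; ε is drawn log-uniformly from [10⁻³, 10⁻¹], one ε per sample
applied uniformly across cells, with an optional exclusion mask for
structurally absent transitions. The hot loop bypasses graph-based
ergodicity checks (adding mass cannot destroy ergodicity of an ergodic
base chain).

## Synthetic data

Three generator families define the study conditions.

**Modulated sinusoid pairs** probe the metric's selectivity: y =
(1 + a·depth·m(t))·sin(2πft + φ·p(t)) against x = sin(2πft), with slow
unit sinusoidal modulators at 0.005 Hz, base 0.02 Hz, 600 s at TR = 2 s.
The amplitude index a scales a shallow envelope drift (depth 0.15 per
unit index) so that even a = 1 leaves Pearson r ≥ 0.99 — the regime where
correlation is blind while nDTW rises strictly. The phase index φ is the
peak phase excursion in radians; by φ = 2 the correlation collapses below
0.25 while alignment absorbs ≥ 90% of the apparent (unaligned) pointwise
disparity. Two discrete-sampling facts shape these designs: fractional-
sample timing distortions leave an irreducible aligned-disparity floor
(integer-grid alignment cannot null them), and deep amplitude modulation
necessarily lowers correlation (r = 1/√(1 + a²/2) for a zero-mean unit
modulator with swing a) — so "correlation flat" and "nDTW phase-stable"
are claims about gentle modulation regimes, which is what the defaults
generate.

**Band-limited noise** (Gaussian noise low-passed to a fraction of
Nyquist, unit variance) drives the bandwidth sweep: disparity between
independent draws grows as the band widens toward Nyquist while their
correlation stays near zero. Below ~0.2 of Nyquist the behavior is
non-monotone — very smooth independent signals hold long same-sign
excursions that no bounded window can align — so sweeps start at 0.2.

**Planted-state cohorts** exercise the full pipeline. Each subject
follows a hidden ergodic 3-state chain (self-retentions 0.96/0.94/0.96 by
default, dwell ≈ 17–25 TRs). All channels ride one slow band-limited
carrier (5% of Nyquist) through channel-specific bounded random warps
(±1 sample), so every pair is timing-confounded; the second channel of
each of four channel groups adds a state-dependent fast imbalance
m·(−1)ᵗ with m = 0.05 (convergent, all groups), 0.7 (mixed, half the
groups) or 1.0 (divergent, all groups), plus optional white measurement
noise (sd 0.02 default). The Nyquist-edge alternation is the design's
key property: a monotone alignment must visit every sample of the
partner and the slow carrier cannot bridge an alternating offset inside
a small window, so the planted imbalance is irreducible by warping —
it is exactly the "timing-invariant amplitude disparity" the metric
measures, while being invisible in a correlation analysis of the slow
content. Two deliberately rejected alternatives are instructive:
multiplicative whole-channel gains are largely erased by per-channel
z-scoring (which re-centers any one-sided gain), and slow multiplicative
envelopes are partially "cheated" by the aligner near carrier zeros,
where a small time shift can match amplitudes. The emission therefore
does not emulate haemodynamics or 1/f noise; what passing recovery tests
show is that the pipeline correctly extracts state-structured amplitude
imbalance planted in the regime the metric is designed for, not that it
would denoise arbitrary real data.

Recovery analyses use window w = max_warp + 1 = 2 (wide enough to undo
the planted warps, tight enough not to blur transition boundaries through
path-length inflation) and γ = 1.5. With measurement noise disabled (the
clean-recovery condition the validation suite checks, at the default
cohort dimensions of 10 subjects × 160 timepoints per group) the pipeline
returns k = 3 with ≥ 90% per-timepoint label accuracy and re-estimates
the planted transition matrix within three binomial standard errors.

All generators route every draw through one seeded `numpy` Generator per
call; identical seeds give identical outputs bit-for-bit.

## Numerical choices and degenerate inputs

* DTW tie-breaks and k-means re-seeding are deterministic; all stochastic
  stages require explicit seeds (the pipeline config validates this).
* Zero-variance channels, non-finite values, infeasible windows,
  too-short series for filtering or trimming, and non-ergodic chains all
  raise errors naming the offending subject/channel where applicable;
  reliability sentinels (0 for 0/0 consistency, +∞ for zero spread) warn
  instead of raising because they are meaningful summaries.
* Problem sizes in the test suite and acceptance script (10,000 alignment
  pairs at N = 150; cohorts of 10–20 subjects × 160 timepoints; 1,000
  random chains) were chosen as the smallest sizes at which the checked
  statistics are stable; the numba DP kernel makes the largest of them a
  matter of seconds.

## Known limitations

* PCHIP resampling preserves the trace mean only to ~1% at the default
  configuration (see above); analyses that need the exact identity should
  use the pre-resampling trace, whose mean equals Dn to machine
  precision.
* The trace's mapping back to original time is approximate wherever the
  warping path inflates; state boundaries blur by a few samples under
  wide windows.
* nDTW between very smooth independent signals is itself noisy (few
  effective degrees of freedom); bandwidth sweeps and null calibrations
  are only meaningful above ~0.2 of Nyquist at these series lengths.
* The k-medians solver is exact in its update steps but, like all
  k-means-family algorithms, only locally optimal; determinism comes from
  seeding, not from global optimality.
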