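# Methods

## Model

All Φ quantities are computed under a stationary Gaussian model of the
lagged state pair (X(t−τ), X(t)) of a channel subset.  A window of T frames
yields N = T − τ pairs (x(t−τ), x(t)); each side is mean-centred per channel
and maximum-likelihood covariances (divide by N) give Σ_past, Σ_present and
the cross covariance Σ_cross = Cov[X(t−τ), X(t)].  A ridge (default
1e−8 × the mean diagonal variance) is added to both covariance diagonals so
that near-degenerate windows — including the perfectly correlated limit —
remain invertible; truly constant channels are flagged rather than analysed.

Mutual information is the Gaussian closed form
I = ½ ln(|Σ_past||Σ_present| / |Σ_joint|), in nats.  Nats are used
everywhere.

## Mismatched decoding and Φ*

For a bipartition π, the mismatched decoder factorises the conditional over
the blocks: q(y|x) = Π_b p(y_b | x_b), where each factor is the linear
regression of the block's present on the block's own past.  The information
transmissible through this decoder at temperature β is

Ĩ(β) = E_p[ ln ( q(y|x)^β / E_{x'}[q(y|x')^β] ) ],

a closed-form Gaussian integral.  Writing A' for the block-diagonal
regression matrix and Σ' for its block-diagonal residual covariance, with
Q(β) = Σ_past⁻¹ + β A'ᵀΣ'⁻¹A' and G = Σ'⁻¹A':

Ĩ(β) = −β/2 · tr(Σ'⁻¹ C) + ½ ln(|Q| |Σ_past|) + ½ (β tr(Σ'⁻¹Σ_present)
        − β² tr(Q⁻¹ GᵀΣ_present G)),

where C is the decoder's residual second moment under the *true* joint
distribution.  The implementation builds A' and Σ' for all partitions at
once by masking the covariances with the same-block indicator (a masked
matrix inverts block-wise), and the correctness of the whole expression is
pinned against an independent Monte-Carlo + Gauss–Hermite oracle on 2-node
models in the test suite (agreement within 3 standard errors at 10⁵
samples).

I* = max_β Ĩ(β) is found by golden-section search on β ∈ (10⁻⁶, 32] with a
fixed iteration count (final bracket < 10⁻¹⁰); Ĩ(β) is smooth and unimodal
for these decoders, and the search runs vectorised across every
(subset, partition) problem of a window simultaneously.  Φ*(π) = I − I*,
clipped by nothing: small negative values at the 10⁻⁹ level are numerical
and the tests bound them explicitly.

The MIP minimises Φ* over all 2^(n−1) − 1 unordered bipartitions
(63 for seven channels); ties resolve to the lexicographically first
partition of the canonical enumeration.

## Complexes

Every subset T with |T| ≥ 2 (120 for seven channels) gets Φ_MIP(T) from its
restricted covariance sub-blocks.  A *complex* is a T with
Φ_MIP(T) > 10⁻¹⁰ exceeding the Φ_MIP of every strict superset; a *main
complex* is a complex containing no other complex.  ΣΦ over main complexes
and the strongest main complex summarise each window.

A caveat documented deliberately: for Φ* with a minimum over bipartitions,
complexes can *partially overlap* (adding a weakly attached node can lower
the minimum cut), and then (i) main complexes may share nodes and (ii) the
containment shortcut can differ from the direct "local maximum" definition.
The package keeps the standard definitions and asserts the relations that
are theorems — every direct main complex satisfies the containment
criterion, and the two coincide whenever no two complexes partially
overlap — while the strict exclusivity property is exercised (and observed
to fail on random models) in the acceptance suite.  On the synthetic
cohorts used here the dominant main complexes are disjoint in practice.

## Pipeline

Recordings are 900 s at 250 Hz, seven channels in the fixed order RES, ECG,
EDA, Fz, Cz, Pz, Oz.  Step t's analysis window covers frames
[(t+1)·250 − L, (t+1)·250) — right-aligned, so a 900 s recording yields
exactly 900 steps regardless of the window length L (250 by default; 500
and 750 are supported, with the leading frames before the recording start
zero-filled, which touches at most the first two steps).  Steps are
labelled pre/stim/post by thirds.  Windows containing a constant channel
are flagged missing and excluded from statistics, never imputed.

Φ series are detrended by subtracting the least-squares line fitted over
the whole per-condition series before any phase statistic; detrended Φ can
be negative.  Detrending couples the phases slightly, which makes the null
phase contrast conservative (measured type-I ≈ 0.02 at α = 0.05); the Welch
machinery itself is exactly calibrated, and both facts are unit-tested.
A trailing moving average (150 steps) exists for display only.

The analysis lag defaults to τ = 50 frames (0.2 s).  The τ-scan recomputes
mean whole-system Φ_MIP over a lag grid and picks the argmax (ties to the
smallest τ).  The scan uses its own window of 1000 frames: with the 250
frame analysis window the number of lagged pairs would shrink from 250 to
≈ 0 across a 0–250 scan and the small-sample upward bias of Φ̂ — roughly
d²/2N nats for d model dimensions and N pairs, ≈ 0.02 nats for the default
window — would dominate the profile.  With the long window the bias is flat
and the interaction delay is recovered.

## Synthetic cohorts

The generator produces the statistical structure the estimator assumes —
no more.  Dynamics per recording:

x(t) = diag(A)·x(t−1) + offdiag(A)·x(t−L) + ε,   ε ~ N(0, I)

with self-memory 0.55, intra-body and intra-brain couplings 0.10,
body↔brain couplings 0.03, and the interaction delay L = 50 frames (this
delayed coupling is what makes τ ≈ 50 identifiable; couplings acting at lag
one with these magnitudes would leave nothing to detect at τ = 50).
Stability is verified on the companion form before simulation (spectral
radius ≈ 0.996 at baseline, checked < 1 for every modified matrix).
Burn-in of 1000 frames is discarded.  Blocks are 900 s with
rest/stimulus/rest thirds; during the stimulus the off-diagonal coupling is
modified with gain κ = κ_condition · h_i (κ_SYNC = 1, κ_ASYNC = 0.5;
h_i log-normal with mean 1, σ = 0.35):

* Oz couplings scaled by (1 − 0.5 κ) — the occipital channel decouples;
* body↔brain couplings scaled by (1 − 0.3 κ) — global integration drops;
* EDA↔RES coupling increased by 0.15 κ, saturating at 0.35 — a body
  subsystem integrates.  The saturation is purely a stability guard; within
  the realistic gain range the boost is linear, which keeps the
  subject-level SYNC−ASYNC response monotone in h_i (a hard early cap would
  invert the ordering for high-gain subjects).

Ratings: the SYNC−ASYNC difference of items Q1–Q3 is
5 + 40·(κ_SYNC,i − κ_ASYNC,i) + N(0, 5²) on the 0–100 scale (clipped);
Q4–Q6 and Q9 sit near 50; Q7–Q8 carry a small condition effect (slope 10)
so that the extended index behaves like its empirical counterpart.

What the generator does **not** emulate: ECG/respiration waveform
morphology, EEG spectra, non-stationarity beyond the phase switch, artifact
structure, or measurement noise floors.  Passing recovery tests therefore
demonstrates that the estimator chain detects coupling-structure changes of
realistic size under Gaussian assumptions — not that it would behave
identically on raw physiology.

## Statistics

Phase contrasts pool detrended window values across subjects and use
Welch's t-test (pooling matches the very large degrees of freedom such
designs report; per-subject means remain available).  Frequencies of MIP
cuts and strongest main complexes are computed per subject and then
averaged, so no subject dominates; their stim-minus-pre differences sum to
zero per condition.  p-values are raw — no multiple-testing correction is
applied anywhere, and downstream consumers should correct as appropriate.
The subject score s(Φ_MIP) subtracts each condition's mean pre-stimulus
ΣΦ baseline, then sums SYNC−ASYNC differences over stimulus steps; it is
invariant to per-condition additive constants and antisymmetric under
swapping conditions.  A peak–end variant (mean of maximum and final
stimulus value) is provided as an alternative summary.

## Problem sizes

Exhaustive Φ on one seven-channel window costs ~1,000 β line-searches
(966 subset-partition combinations plus the whole-system MIP), ≈ 0.14 s.
Cohort-level runs therefore analyse every 10th window step (90 of 900 per
recording); the acceptance script uses 22 subjects × 2 conditions at the
full 225,000 frames per block with that stride, and a 75,000-frame
zero-effect null cohort.  The in-suite recovery test uses the same full-length
blocks and stride.  These strides and
block lengths are cost choices only; all defaults in the library remain the
full-scale settings.

## Numerical and design notes

* Covariance estimator: maximum likelihood (divide by N), per-window
  mean-centred — the choice is immaterial to detrended contrasts.
* Ridge is relative by default so channels with very different scales are
  treated uniformly; pass an absolute value to override.
* β bracket (10⁻⁶, 32]: the maximiser sits near 1 for near-matched
  decoders and grows for strongly mismatched ones; no case near the upper
  edge has been observed.
* Degenerate inputs: τ = 0 makes the joint covariance singular up to the
  ridge (the present *is* the past); the scan handles it, but per-window
  analysis at τ = 0 is not meaningful.
* Singletons are excluded from the complex search (Φ is undefined below
  two channels).
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; a recording is a pure function of
  (seed, subject, condition), independent of generation order.
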