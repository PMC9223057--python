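# Methods

This note records the models, conventions, and numerical choices behind
`somnowave`, and what the synthetic-data experiments do and do not show.

## Filter-bank design

**Problem.**  Find an orthonormal two-channel FIR filter bank — low-pass
h[0..L−1] with Σh² = 1, double-shift orthogonality Σₙ h[n]h[n+2k] = δ[k],
high-pass g[n] = (−1)ⁿ h[L−1−n] — with K vanishing moments
(Σ (−1)ⁿ nᵏ h[n] = 0, k < K) and the best joint time-frequency
localisation achievable at that length.  Defaults: L = 18, K = 3.

**Localisation metrics.**  Mean-squared duration
σ_t² = Σ (n − n̄)² h[n]² with n̄ the energy centroid; mean-squared bandwidth
σ_ω² = ∫₀^π ω²|H(ω)|²dω / ∫₀^π |H(ω)|²dω (the low-pass spectrum is even,
so this is the variance about ω = 0).  Both are reported by
`DesignedFilterBank`; σ_ω² is evaluated by Simpson quadrature on a
`frequency_grid_size`-point grid (default 4097; doubling the grid moves the
value by < 1e−6).

**Half-band SDP.**  All design freedom lives in the product filter
P(ω) = |H(ω)|², a symmetric half-band sequence (centre tap 1, even
off-centre taps 0).  We factor P = B_K · R with B_K(ω) = (2cos(ω/2))^{2K}
carrying the vanishing-moment zero exactly, and represent the residual
cosine polynomial R ≥ 0 by a Gram matrix G ⪰ 0 (R(ω) = v(ω)ᴴ G v(ω)).
Half-band equalities are linear in G.  Because the half-band structure
fixes ∫₀^π P = π, the bandwidth σ_ω² of every spectral factor is *linear*
in G, giving a small semidefinite program (matrix dimension L − K).  It is
solved by a dense infeasible-start Newton barrier method (`_sdp.py`) —
exact for this problem class, deterministic, and fast at these sizes
(≤ 2 s per solve on one core).

**Why not pure minimum bandwidth.**  Minimising σ_ω² alone produces
equiripple-like products with stopband touching zeros; their spectral
factors have long, oscillatory impulse responses, and the best factor's
σ_t·σ_ω (1.276 at L = 18) is *worse* than the plain Daubechies filter of
equal length (1.192).  The design goal is the minimum *product* σ_t·σ_ω, so
`design_filter_bank` sweeps a convex scalarisation: minimise
σ_ω²-objective + λ · Σₖ k² p[k]² (the energy duration of the half-band
sequence itself) over a fixed λ grid
{0, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1, 3, 10}.  λ = 0 is the pure
minimum-bandwidth design (still exposed directly as `design_halfband`'s
default, and verified against a brute-force lattice sweep at L = 4);
large λ approaches the maximally-flat (Daubechies) product, whose factors
are well localised in time.  For each λ the product is factorized and the
minimum-duration factor kept; the sweep winner minimises σ_t·σ_ω.  At
L = 18, K = 3 the winner (λ = 3) achieves σ_t·σ_ω ≈ 0.6546 vs 1.1922 for
db9.  The sweep grid is fixed a priori; the design stays deterministic.

**Spectral factorization.**  Roots of the product polynomial are computed
after synthetic-division removal of the known order-2K zero at z = −1
(high-multiplicity roots scatter badly under companion-matrix rooting),
then Newton-refined against the *un-deflated* polynomial.  Off-circle roots
are grouped into conjugate/reciprocal sets (relative pairing tolerance
1e−7); near-unit-circle roots (touching zeros) are clustered by angle, and
each cluster contributes half its multiplicity to every factor.  Each of
the ≤ 2^(#groups) enumerated factors is refined by a damped Newton
iteration on autocorr(h) = p, normalised to Σh² = 1 with Σh > 0, and
deduplicated; candidates are returned in lexicographic order so
minimum-duration ties (e.g. a factor and its reversal) break
deterministically toward the lexicographically smallest sequence.  The
selected factor is finally polished by a Gauss-Newton projection onto the
exact orthogonality + vanishing-moment manifold, leaving residuals at
machine precision (≈ 1e−16).

## Wavelet decomposition

Five analysis stages (periodic extension, decimate by 2) yield one
approximation and five detail bands per epoch.  Because the half-band
property makes the cyclically-wrapped filter rows orthonormal for *any*
even length, perfect reconstruction and exact energy conservation hold at
every stage; odd intermediate lengths (e.g. 1500 → 750 → 375) are
right-padded with one zero, the pad recorded and dropped on inversion.
Epochs are transformed at each channel's native rate (3750 samples at
125 Hz, 1500 at 50 Hz) — no resampling.  At 125 Hz the six bands cover
≈ 0–2, 2–3.9, 3.9–7.8, 7.8–15.6, 15.6–31.3, 31.3–62.5 Hz, aligning with
the classical delta/theta/alpha-sigma/beta EEG bands.

## Tsallis-entropy features

The per-band feature is the q = 2 Tsallis entropy TE = 1 − Σ pᵢ² of the
coefficient energy distribution pᵢ = xᵢ²/Σxⱼ².  Normalising to a
probability vector makes TE scale invariant and bounded in [0, 1 − 1/N],
which is what a nonextensive entropy of a distribution requires; the
literal unnormalised sum Σ(xᵢ − xᵢ²) is retained as `mode="raw"` because
the formulation is sometimes applied directly to coefficients, but it is
scale dependent and not used by the pipeline.  An all-zero band is
degenerate: TE is defined as 0 and a warning logged.  Feature columns are
channel-major, coarse-to-fine (`<channel>_a5, _d5, ..., _d1`).

Interpretation: Gaussian noise gives TE ≈ 1 − 3/N; a sustained rhythm in a
band pushes TE up toward 1 − 1.5/N; transient bursts (spindles, EMG
twitches, eye-movement deflections) concentrate energy in few coefficients
and pull TE down.  Stage discrimination therefore rests on *where* in the
band hierarchy each stage is rhythmic vs bursty, not on amplitude.

## PSG input conventions

EDF (16-bit) signals are read/written by a minimal reader/writer with
1-second records; physical scaling is chosen per channel from the data
range.  Channels are z-scored over the whole recording ("normalised for
segmentation"); epochs are 0-based half-open 30-s windows.  Annotations may
be a CSV (`epoch_index,stage`) or an XML subset (a sequence of
`SleepStage` elements); R&K tokens, AASM tokens and numeric codes (0=W,
1–4=S1–S4, 5=REM, 9=unscored) are accepted.  S3/S4 map to N3; the 3-class
scheme merges N1/N2/N3 into N.  Signal/annotation epoch-count mismatches
truncate to the shorter with a warning; movement/unscored epochs are
dropped with a logged count.

## Classifier and evaluation

Bagged decision trees: each of `n_trees` (default 30) CART trees is grown
on a bootstrap resample of the training set (same size, with replacement),
unlimited depth, Gini impurity, minimum leaf 1 — the canonical bagging
configuration; the ensemble size is pinned for reproducibility.  Prediction
averages tree probabilities; ties break toward the more prevalent training
class.  Validation is a single stratified 10% holdout (stratification
protects the rare N1 stage from vanishing out of the test set; no class
rebalancing is applied).  Cohen's κ is computed from the confusion counts
with chance agreement from marginal products, defined as 0 when p_e = 1.
The channel sweep evaluates the fifteen standard combinations (five
singletons, the EEG pair, EMG/EOG pairs and triple, EEG-anchored
combinations, full montage) with a shared split seed.

The holdout is epoch-wise, not subject-wise: adjacent epochs of one
recording can land in train and test, which inflates accuracy relative to
leave-one-subject-out validation.  This is a known caveat of the protocol,
not a bug.

## Synthetic data

The generator exists so every pipeline stage is testable without
access-restricted clinical cohorts.  A first-order Markov chain over
(W, N1, N2, N3, REM) — self-transition 0.85, remainder split over
neighbours in that order — produces the hypnogram; signals are unit
pink noise plus stage signatures with all frequencies and amplitudes in the
single `STAGE_SIGNATURES` block: W 8–12 Hz alpha + frequent EMG bursts +
same-polarity blinks; N1 4–7 Hz theta + slow rolling eye movements;
N2 11–16 Hz spindle bursts (~1 s Gaussian envelope); N3 high-amplitude
0.5–2 Hz slow waves (bleeding into the EOG leads); REM low-amplitude mixed
EEG, EMG atonia, and mirrored (conjugate) EOG deflections.  Signature
amplitudes are RMS ratios against the noise floor, all scaled by `snr`
(default 3), so `snr = 0` collapses every stage to identically distributed
noise.  The tonic EMG level is also snr-scaled for the same reason.

What this does and does not show: the generator encodes textbook stage
phenomenology as *clean, stationary* signatures; it contains no artifacts,
no inter-subject variability, no ambiguous transitional epochs, and its
class structure is far more separable than clinical PSG.  Passing the
end-to-end recovery test (≥90% 3-class, ≥80% 5-class at snr 3, 5000
epochs; chance level at snr 0) demonstrates that the filter, transform,
features and classifier are wired correctly and that the features carry
stage information — it is not evidence of clinical-grade accuracy.

## Problem sizes and numerical tolerances

The end-to-end experiments use 5000 epochs (≈ 42 h of sleep) — ample for
stable holdout estimates (test n = 500) while keeping the whole suite
comfortably fast on one core.  Key tolerances: SDP duality gap 1e−9;
orthogonality residual < 1e−8 (achieved ≈ 1e−16 after polishing); moment
residual < 1e−6; perfect reconstruction < 1e−10 (achieved ≈ 1e−15);
spectral-factor reproduction of the product < 1e−8; root-pairing relative
tolerance 1e−7 with a 1e−4 unit-circle band.

## Known limitations

* The bandwidth/duration trade-off is scanned on a fixed 10-point λ grid,
  not optimised continuously; the reported σ_t·σ_ω is minimal over that
  grid.
* Spectral factorization enumerates up to 2^(#reciprocal-groups)
  candidates; fine for L ≤ ~40, combinatorial beyond.
* EDF support covers the classic 16-bit continuous layout only (no EDF+
  embedded annotations).
* Epoch-wise holdout (see above); no subject-level generalisation claims.
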