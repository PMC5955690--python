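# Methods

This note documents the models, numerical choices and limitations of the
package; it states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Task and behavior generator

The session is the cued go-nogo-change design: three cue conditions (EG,
EC, EN) at probability 1/3 each, a 100-ms cue, 1-s inter-stimulus
interval, 100-ms target, inter-trial interval jittered uniformly in
1.3–1.6 s, and a standard-hand switch halfway through (counterbalanced
across subjects). The full design is 6 blocks × 160 trials = 960 trials;
with exact allocation, 160/3 is not an integer, so blocks receive
53/53/54 trials per condition with the remainder rotating across blocks
(condition totals 320 each), and the 25% rare targets inside EC/EN are
allocated exactly across the session.

Reaction times are shifted log-normal, `X = shift + LogN(mu, sigma)` with
`sigma = 0.4` fixed and `shift`/`mu` solved from the target mean ± SD —
a right-skewed family appropriate for RT data, parameterized directly by
the reported group moments (go 250±100 ms, no-change 358±76, no-nogo
354±84, change 403±88). Error generation is per-trial Bernoulli: premature
presses per cue condition (9.8% / 0.45% / 0.34%), omissions and choice
errors per derived condition, and a 13% failed-inhibition rate on nogo
trials. Learning/practice effects and the practice blocks are not modeled.
The premature-error inferential test uses the three cue conditions
(F with 2 numerator df); the original report prints a 4-df F for this
comparison whose factor levels are not enumerable from three conditions.

## EEG simulator

**Montage.** 64 electrodes of the extended 10–20 system on an ideal unit
sphere, constructed geometrically (18° = 10% arc steps; intermediate
electrodes at quarter fractions of the midline→ring great-circle arcs),
plus earlobe references A1/A2 carrying near-zero signal so re-referencing
is exercised. No digitized positions exist for the modeled study.

**Sources.** Each source is band-limited Gaussian noise (FFT-masked white
noise with 1-Hz cosine tapers, unit RMS) — not a sinusoid, so band power
rather than a line spectrum carries the effects — multiplied by a
piecewise-linear amplitude envelope (μV) that may differ by derived
condition and by standard hand, and projected through a Gaussian-in-
angular-distance topography (default width 0.45 rad). Background noise is
1/f^α pink noise (α = 1), half of it spatially smoothed across the cap
(0.35-rad kernel) to emulate volume-conduction-like inter-channel
correlation; per-channel RMS is 3 μV. Optional square-pulse artifacts
(2% of trials, 150 μV) exercise the amplitude rejector.

**Phase coupling.** A coupled source replays its seed source's *analytic
signal* rotated by a per-trial von-Mises phase offset. Rotating the
analytic signal preserves the spectrum exactly, so the injected offset
survives downstream band-passing; the expected PLV of concentration κ is
I1(κ)/I0(κ) (`inject_coupling_level`), inverted numerically when a target
PLV is specified. Measured PLV is attenuated by ~0.02–0.03 relative to
this expectation by additive noise and by phase noise at carrier-envelope
nulls; this is measurement attenuation, not estimator bias.

**Injected effect structure** (amplitude factors; power change =
factor² − 1): contralateral mu/beta desynchronize in every condition,
earlier and deeper when the standard action is certain (EG); ipsilateral
mu rises for EG (×1.15), stays at baseline for EN, falls for EC (×0.70);
ipsilateral beta falls for EC only; a target-locked prefrontal beta burst
at F5/F6 scales go (×1.15) < no-change/no-nogo (×1.35) < change/nogo
(×1.60); C4→F6 (and mirrored C3→F5) alpha coupling has expected PLV 0.6
for EG/EN and 0.2 for EC on the ipsilateral side, 0.6 contralateral.
Magnitudes are configuration describing a plausible effect pattern, not
claims about the true physiological effect sizes. Per-subject log-normal
gains (SD 0.15) on each source create between-subject variance. The null
configuration equalizes every condition-dependent parameter while keeping
the overall source structure.

**What the simulator does not emulate,** hence what a green test does not
establish: ocular/muscle artifacts beyond square pulses (the modeled
study removed ocular components by ICA; none are synthesized, so ICA is
out of scope), realistic volume conduction through head tissue, electrode
impedance drift, and any coupling between behavior (RTs) and the EEG
sources — the power–RT correlation is therefore genuinely null in the
synthetic world, matching the modeled study's null report.

## Preprocessing

Fixed order: earlobe re-reference → filter → epoch → baseline → reject.
Filters are a 4th-order Butterworth high-pass at 0.5 Hz cascaded with a
Q = 30 IIR notch at 50 Hz, applied forward–backward (zero phase; the
source names cutoffs only). Epochs are half-open `[onset−1, onset+2)` s —
750 samples at 250 Hz, onset at index 250 — with the mean of the 100 ms
before the locking event subtracted per channel. Rejection compares
post-baseline voltages against ±80 μV on any analysis channel (the
convention is configurable; the source is silent on it) and is idempotent;
subjects with strictly more than 30% rejected trials are excluded. No
software anti-alias low-pass is added below the 125-Hz Nyquist.

## Current source density

Spherical splines of order m = 4 with N = 50 Legendre terms (three-term
recurrence via `numpy.polynomial.legendre`) and regularization
λ = 1e-5 — conventional defaults; the modeled study names only the spline
order. The transform solves `(G + λI)c + c0·1 = v, Σc = 0` once as a
cached linear operator and outputs `−H c`, which maps a surface harmonic
Y_n onto ≈ −n(n+1)·Y_n, i.e. the sign of the true surface Laplacian; the
scale is arbitrary CSD units on a unit-radius head and cancels in percent-
change power. Convergence: 50 vs 200 terms changes g(x) by <1e-6 on
x ∈ [−1, 0.95]; halving λ changes smooth-map outputs by <2% RMS.

## Time-frequency analysis

The analysis wavelet at frequency f is the complex Morlet mother (f_b = 1,
f_c = 1.5) compressed by the scale a = f_c/f and L2-renormalized — the
standard continuous-wavelet convention consistent with the `cmor1-1.5`
parameterization. Energy is the squared magnitude of the convolution.
Samples with <95% kernel-energy overlap are edge-flagged; a frequency
errors out only when its 95%-energy support cannot fit in the epoch at all
(minimum usable frequency ≈ 0.98 Hz on 3-s epochs, so the conventional
1–40 Hz grid runs, with 1–2 Hz fully edge-flagged). Baseline
normalization is percent change, `100·(P−B)/B`, with B the −250..−50 ms
time-mean of the *condition-averaged* energy (grand-average
normalization; per-trial normalization is available but not default — the
source does not state which it used). Percent change was chosen over dB to
match how the figures of the modeled study are labeled. The replica
configuration restricts the frequency grid to 9–25 Hz (1-Hz steps), the
union of the analyzed mu and beta bands, purely for runtime; the grid is
configuration.

Hemisphere flipping swaps left/right homologue channels of left-hand-
standard trials (midline unchanged, involutive) for sensorimotor analyses
only; prefrontal analyses use unflipped data, as in the modeled study.

## Phase-locking value

Phases come from a zero-phase 4th-order Butterworth band-pass (9–14 Hz)
followed by the analytic signal. Edge margins of one cycle of the band's
low edge are flagged and the 900–1100 ms analysis window must clear them
(the pipeline computes phases on a segment with a ≥0.5-s guard, which
dominates per-subject runtime otherwise). PLV is computed per time sample
and averaged over the window — the standard reading of an ambiguous
description. Because the estimator is positively biased at small N, trial
counts are equalized across conditions by seeded subsampling before
comparisons. Spatial spread of a strong seed source produces high PLV at
many electrodes (volume conduction). Because the injected mu source is
condition-dependent in amplitude, this spread-driven PLV is itself
condition-dependent: in the effect configuration the EC-vs-EG contrast is
significant at many connections beyond the injected frontal coupling, with
the largest drop at the injected site. This mirrors the power-confound
problem of real scalp PLV analyses; the qualitative acceptance check asks
for the injected frontal decoupling (correct site and sign), not for
exclusivity. In the null configuration source amplitudes are equalized and
the confound vanishes, which is what the type-I calibration verifies.

## Statistics

All tests are two-sided. `paired_t` returns t = 0, p = 1 for identical
samples and a flagged degenerate result for constant nonzero differences.
BH-FDR is the step-up rule with families matching the source analyses:
the nine 100-ms bins of one contrast × hemisphere, or the seed→electrode
connections of one PLV contrast. Greenhouse–Geisser ε uses Box's formula
on the double-centered condition covariance, clipped to [1/(k−1), 1], with
ε = 1 exactly for two levels; ANOVAs report uncorrected df with corrected
probabilities. The Wilcoxon signed-rank test drops zero differences,
enumerates all 2^n sign assignments (conditional on observed midranks) for
n ≤ 15, and uses the normal approximation with continuity and tie
corrections otherwise; with ties the enumeration is the governing exact
reference (tabulated "exact" distributions assume untied ranks). These
routines are authored in-package because the replicated inferential layer
needs their degenerate-input behavior; they are cross-checked in the test
suite against scipy, statsmodels and pingouin.

## Replica study and scaled world

The replica cohort is the stated n = 22 subjects, each simulated on a
scaled session of 2 blocks × 36 trials (24 per cue condition, exact 25%
rare targets → 6 change and 6 nogo trials) so the full 20-seed end-to-end
acceptance run fits a 15-minute single-CPU budget; the full 960-trial
session remains available (`--full`). Single-subject ROI power estimates
at 24 trials carry ~±20 percentage points of envelope sampling noise —
this is the realistic regime in which only the group statistics, not
single subjects, resolve the effects. One global seed expands to
per-stage, per-subject substreams via `numpy.random.SeedSequence` spawn
keys, so stages rerun independently yet reproducibly, and file-based
stages write hash-linked manifests that detect tampered upstream
artifacts.

## Known limitations

* The EDF+ writer/reader supports exactly the subset this package emits
  (EDF+C, 1-s records, one annotation signal); it is not a general reader.
* The spherical-spline electrode cap covers the upper sphere only, so
  harmonic-recovery correlations degrade slowly with harmonic order
  (>0.95 for n ≤ 3 on this montage).
* No occipital/attentional effects are simulated or analyzed (explicitly
  unreported in the modeled study), no source localization, and no
  cluster-based permutation statistics.
* Trial-boundary phase-offset switches introduce brief transients between
  trials; analysis windows sit ≥0.6 s away from them.
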