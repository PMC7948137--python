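# Methods

## Signal model and the LSA filter

The filter assumes that at a given post-stimulus time point the signal
at a reference electrode B and at any other electrode A decomposes as
S_B = W_B + L_B and S_A = λ·W_B + L_A, with W the field of a single
widespread source that is maximal (in amplitude and in trial-by-trial
variability) at B, L the local contributions, and |λ| < 1.  Across
trials, λ′ = cov{S_A; S_B}/var{S_B} converges to λ as var{W_B} grows,
so S_A − λ′·S_B ≈ L_A − λ·L_B ≈ L_A when L_B is small.  The output is
therefore interpretable only where those assumptions hold: a window
with one dominant widespread component that varies from trial to trial,
and a reference electrode far enough from the local activity of
interest that L_B ≈ 0.

Implementation choices:

* λ′ is the centered covariance over variance — identically the OLS
  slope with intercept; the n−1 normalization cancels in the ratio.
  The subtraction, however, is applied to the **uncentered** signals,
  S_A − λ′·S_B, exactly as the model is written; a common mean offset
  therefore survives filtering.  The cross-trial covariance between the
  output and the reference is exactly zero either way (an OLS identity
  the tests check at 1e−10 relative).
* λ′ is estimated independently per electrode and per time point; no
  temporal smoothing, no clipping of λ′ to (−1, 1) even though the
  model assumes |λ| < 1 — large estimates are informative diagnostics.
* No intercept is subtracted from the output (only the slope term),
  mirroring the subtraction formula rather than the full regression
  prediction.
* The reference channel's output is exactly zero and λ′(ref) ≡ 1.
* Fewer than 2 trials is an error; fewer than 20 triggers a warning
  (robust estimation needs roughly 20–30 trials per condition).  A
  reference with zero cross-trial variance at an in-window time point
  is an error — if the widespread activity does not vary from trial to
  trial there is nothing to regress out, and silently passing data
  through would mix semantics.
* Reference selection: `select_reference` picks the channel maximizing
  the absolute grand average within the window.  Under per-electrode
  gain noise the argmax may land on an immediate neighbor of the true
  field maximum (the widespread field is nearly flat at its peak); this
  is harmless for filtering — λ′ adapts — and the user can always pass
  the reference explicitly, which matches how the electrode is chosen
  by eye on real grand-average maps.

## Stationary comparators

VR subtracts the vertex signal; AR subtracts the instantaneous channel
mean; CD subtracts the mirror electrode across the sagittal midline
(label grammar: odd ↔ even digit, z-labels map to themselves).  All are
linear with weights fixed a priori.

The surface Laplacian follows the spherical-spline construction: the
interpolation kernel g(x) = (1/4π) Σₙ (2n+1)/(n(n+1))^m Pₙ(x) truncated
at 80 Legendre terms with spline order m = 3, a smoothing constant of
1e−5 added to the diagonal of the interpolation matrix, and the
Laplacian read out through h(x) = (1/4π) Σₙ (2n+1)/(n(n+1))^(m−1) Pₙ(x)
scaled by the inverse squared head radius (output in µV/cm², radius
from the montage).  m = 3 and 80 terms are kept as defaults for
consistency with the simulation study this package reproduces, although
m = 4 is the more common literature default; both are exposed in
`SplineParams`.  The sign convention matches the usual CSD readout (a
potential peak maps to a CSD extremum of the same sign); the test suite
verifies agreement with MNE-Python's independent implementation to
machine precision at matched parameters.  A singular interpolation
system raises an error suggesting larger smoothing.

## Montage

The shipped cap is a 120-channel International 10-5 layout: the
standard 10-10 electrodes (digits ≤ 8) plus FCCz, plus intermediate
("h") positions filled in order of proximity to the vertex, with FCC3h,
FCC4h, FFC5h and FFC6h always included.  Positions derive from the
standard 10-5 electrode table distributed with MNE-Python, projected
onto the best-fit sphere and symmetrized so mirror pairs are exact
reflections across the sagittal plane x = 0 (x toward the right ear,
y toward the nasion, z up).  `scripts/build_montage.py` regenerates the
table.

Scalp distances are geodesic arc lengths on the sphere — the natural
parameterization for a 2-D Gaussian "on the scalp" — and the sphere
radius (8.82 cm) is calibrated once so that the cap radius, the maximal
geodesic distance between any electrode and Cz, equals 14.7 cm.  The
calibrated radius is the distance scale of the whole simulation; it is
slightly below the 9.2–9.5 cm often quoted for adult heads because the
shipped cap extends ~5° past the equator through the temporal rows.
Mirror pairing is computed from the label grammar and validated
geometrically in the tests; montage invariants (unique labels, positions
within 5% of the sphere) are enforced at construction.

## The simulator

One simulated "ERP" is a single time point drawn over 40 trials and 120
channels (the epoch container still carries a sample axis, so the same
code path serves multi-sample real data).  Each electrode records

```
data[k, c] = gain_c · ( Σ_s (1 + σ_amp·z_{s,k}) · field_s[c]
                        + σ_glob·M·g_k )
```

* `field_s`: Gaussian fields on the scalp, parameterized by geodesic
  distance.  Defaults: widespread −20 µV at Cz with SD half a cap
  radius; local −1 µV at C3 with SD 20% of a cap radius; the
  three-local-source variant adds +1 µV (SD 20%) and −0.7 µV (SD 30%).
  The extra centers (C4 and P7) are this package's choice — two roughly
  mirror-located opposite-polarity sources plus a posterior one, the
  arrangement in which CD merges real sources with their spurious
  mirror images; a midline variant puts the local source at Fz.
* amplitude noise z ~ N(0,1) per source per trial, σ_amp = 1 — note a
  source can flip sign on individual trials; this is deliberate (the
  distribution is used exactly as specified, untruncated) and is the
  neural variability LSA exploits, so it is never rescaled;
* global noise g ~ N(0,1), σ_glob = 1 µV, identical at all electrodes
  within a trial (fully spatially correlated);
* conductance gain gain_c ~ N(1, 0.05·M), per channel, fixed across
  trials, multiplying the total signal (a property of the
  electrode-skin interface, hence applied last);
* M is the nonneural multiplier (1 by default; 2/4/6/8 in the
  robustness sweep) and scales only the global and conductance SDs.

Draw order is fixed (per-source deviates in list order, then global,
then gains) from one seeded generator, so a config plus seed pins the
data bit-for-bit.  A mediolateral cap shift (in mm) displaces the true
electrode positions before the fields are evaluated while labels stay
nominal — data from a misplaced cap analyzed as if in place.

What the simulator does *not* emulate: temporal waveforms and their
latencies, dipolar forward physics and volume conduction, spatially
correlated sensor noise, artifacts, or correlated local sources driven
by a shared subcortical input.  Passing tests therefore demonstrate the
algebra and the statistical behavior of the filters under the stated
field-plus-noise model, not performance on recorded EEG.

## Evaluation harness

`compare_filters` simulates one epoch set, applies the requested
filters (LSA reference auto-selected), and scores each filtered
grand-average map against the summed true local fields by Pearson
correlation over channels — scale-free on purpose, since SL changes
units and LSA changes gain.  RMS residuals are reported in µV (for SL
after z-scoring both maps, as a unitless shape residual).  For
configurations without local sources the correlation is undefined and
reported as None; the lateralized residual (max |grand average| over
off-midline channels) carries the false-positive comparisons.  The
`minimum_t_test` helper reports mean ± SE and a one-tailed (negative
direction) one-sample t test of per-subject amplitudes at a component
minimum, the convention for reporting component minima on real cohorts;
the minimum channel is meant to be identified on the across-subject
grand average, then read per subject at that channel.

Problem sizes: the replicate studies in the tests and the acceptance
script use 100 seeds × 40 trials × 120 channels × 1 sample, and the
noise-robustness sweep 20–25 seeds per multiplier — enough for the
binomial and mean criteria they feed (e.g., ±0.3 µV SE on the grand
mean vertex amplitude) while keeping the whole suite at a few seconds.

## Known limitations

* LSA removes exactly one widespread component per run; nothing is
  iterated for multiple simultaneous widespread sources.
* The analysis window is user input; no automatic detection of "the
  interval where most electrodes share polarity".
* λ′ estimates inherit regression noise O(1/√n_trials); with very few
  trials the filtered maps degrade before the error guards trigger.
* The spherical head model is idealized; no realistic-geometry
  Laplacian, no MRI-based positions.
* Recorded-data claims (component amplitudes at specific electrodes)
  are outside what simulations can certify; the package reads real
  epoch files but attaches no performance claim to them.
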