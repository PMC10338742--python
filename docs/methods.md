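# Methods

## The measurement model

A plane-parallel chamber scanned through a water phantom reads, at nominal
depth z (its entrance-window inner surface), a signal proportional to the
dose at the *effective* depth z + Δz divided by the water/air stopping-power
ratio there. The analysis chain inverts this: raw electrometer readings are
corrected depth-by-depth for ion recombination and polarity, session curves
are averaged, and the shift Δz is found by minimizing

rms(Δz)² = (1/n) Σᵢ [ D_w(zᵢ + Δz) − s_w,air(z*, R50) · M̄(zᵢ) ]²

over a uniform grid of candidate shifts. D_w is the reference PDD
interpolated between its scan points; M̄ is the averaged, corrected chamber
ionization reading. The minimization is a pure grid search — the physical
resolution of the method is the grid step, and a sub-grid refinement would
suggest precision the data do not carry. Ties are broken toward the smallest
|Δz| (the null hypothesis of no shift).

### Conventions that the literature leaves open

* **Stopping-power depth argument z\*.** The ratio should describe the
  electron spectrum at the depth actually sampled, so the default is the
  *shifted* convention z\* = zᵢ + Δz. The *nominal* convention z\* = zᵢ is
  implemented and switchable (`EPOMConfig.sp_depth_convention`); analyzing
  shifted-convention data under the nominal convention produces a systematic
  shift error that grows with R50, which the test suite demonstrates as a
  diagnostic. Every report states the convention used.
* **Amplitude matching.** Default: both curves normalized to 100 at their
  maxima (`normalize_max`), the standard relative-dosimetry convention.
  Because anchoring the amplitude at a single point can bias the RMS when
  that point is noisy, a per-shift least-squares scale (`fit_scale`) is also
  available; noise-free the two agree exactly.
* **Evaluation window.** Nominal chamber depths from 0.1 cm to z/R50 = 1.2.
  Points whose *shifted* depth leaves the reference curve's measured support
  or the stopping-power validity window are excluded per shift; a shift
  retaining fewer than `min_points` (default 10) usable depths is dropped
  from the grid with a warning and recorded in the result. This per-shift
  windowing is what makes positive shifts evaluable at all near z/R50 = 1.2,
  at the cost of n varying by a few points across the grid — negligible
  against the distal-falloff signal that dominates the objective.

## Physics components

* **Stopping-power ratio.** Burns' rational-function fit
  s_w,air(z, R50) = (1.0752 − 0.50867x + 0.08867x² − 0.08402y) /
  (1 − 0.42806x + 0.064627x² + 0.003085x³ − 0.12460y), x = ln R50, y = z/R50,
  valid for 0.02 ≤ y ≤ 1.2. Evaluation outside the window raises; the fit is
  never extrapolated. The transcription is gated by a test comparing it at
  the reference depth against the independent published closed form
  s_w,air(z_ref) = 1.253 − 0.1487·R50^0.214 at 24 beam qualities across
  R50 = 2.40–8.82 cm; the two published parameterizations agree within 0.25%
  (observed maximum 0.17%), while a typo in any coefficient moves the ratio
  by an order of magnitude more.
* **Corrections.** kpol = (|M⁺| + |M⁻|)/(2|M|); kS from the pulsed-beam
  two-voltage quadratic with the protocol coefficient table for
  V1/V2 ∈ {2.0, 2.5, 3.0, 3.5, 4.0, 5.0} (every row sums to 1 within 10⁻³,
  asserted). Both are applied multiplicatively to the operating-voltage
  reading per depth; depth-independent factors cancel in normalization and
  provably cannot move Δz.
* **Beam quality.** R50 is read off the reference dose curve by monotone
  interpolation and root bracketing; the I50→R50 protocol conversion and a
  fixed-point iteration (convert → recompute R50, tolerance 0.001 cm, max 20
  iterations) support ionization-only data sets.
* **Interpolation.** All resampling uses monotone shape-preserving piecewise
  cubics (PCHIP): exact at knots, overshoot-free on the steep distal edge
  where ordinary cubic splines ring. Measured curves are never extrapolated;
  session averaging resamples onto the union grid restricted to the depth
  interval common to all sessions.

## The synthetic campaign

The generator stands in for the water tank. The reference PDD is an analytic
family — raised-sine build-up from a surface fraction to 100 at z_max,
a falloff exp(−((z−z_max)/λ)^p) whose λ and p are solved in closed form so
the curve crosses exactly 50 at R50 and ~0.5% at R_p, plus a linear
bremsstrahlung-like tail. It is *not* a transport-physics surrogate: the aim
is controllable truth for parameter recovery, not spectral fidelity.

Chamber scans invert the analysis chain exactly: the ideal signal is
D(z+Δz_true)/s_w,air(z+Δz_true, R50), the two-voltage channel pair is built
from the inverse of the recombination quadratic so `correct_scan` recovers
the kS profile to 10⁻⁶, and the polarity pair encodes kpol exactly.
Noise is multiplicative Gaussian per channel (scanning-system
repeatability), default σ = 0.3%; sessions are independent noise
realizations of the same truth (no systematic positioning offsets by
default). Correction profiles are gently depth-dependent
(kS = 1.002 + 0.004·z/R50, kpol = 0.998 + 0.005·z/R50), within the sanity
bands the validator enforces.

Study conditions (the generator defaults): four beams with R50 = 2.40, 4.93,
7.37 and 8.82 cm (the 6 and 22 MeV values anchor the validated range; the
middle two are typical clinical values, R_p from the empirical
1.271·R50 − 0.23); type-level true mean shifts 0.104, 0.040 and 0.012 cm for
NACP-02, Roos and Advanced Markus; mean-zero per-energy offsets giving each
type its minimum at 6 MeV, maximum at 18 MeV and spreads of 0.026, 0.020 and
0.021 cm; serial-to-serial scatter 0.003 cm (1σ); 3 serials, 3 sessions,
0.1 cm scan step, 400/200 V voltage pair.

**What passing does and does not show.** Recovery of these truths
demonstrates the estimator's correctness and its noise behaviour at the
stated conditions. It does not validate detector physics the generator does
not contain: real perturbation-factor depth dependence, setup drift between
sessions, or the true near-peak curvature of clinical beams. In particular
the analytic PDD is deliberately flat just beyond z_max (C¹ construction),
so the dose difference at the reference depth computed from synthetic curves
(≈0.08 percentage points at its largest) is smaller than what real 6 MeV
beams show; the quantity is reported as computed, as a structural
illustration rather than a clinical estimate.

## Aggregation

Per chamber type: serial means over energies; the type mean is the mean of
serial means; the SD is the sample SD (n−1) over all (serial, energy) values,
with the SD over serial means reported separately because either definition
is defensible; energy means over serials and their max−min spread. The
pipeline order is correct → average → fit: correction must precede averaging
because the two-voltage channels of different sessions cannot be averaged as
curves, and the two orders agree in the noise-free limit.

## Problem sizes and determinism

The shipped campaign (108 scans, 36 fits, 31-point shift grid) analyzes in
under a second; the acceptance script, including 140 noisy recovery fits and
50 brute-force oracle cases, runs in a few seconds. All randomness flows
from explicit seeds through `numpy` SeedSequence spawning, so identical
configurations reproduce byte-identical scan files and reports.

## Known limitations

* Burns' fit is the only stopping-power model shipped (alternatives can be
  loaded as coefficient dictionaries, but no other published fit is bundled).
* Only pulsed-beam recombination is supported; continuous beams and
  saturation-curve (Jaffé) analysis are out of scope.
* Vendor binary scan formats are not parsed; two plain-text dialects are.
* The grid search reports the global grid minimum; multimodality is only
  checked diagnostically (noise-free synthetic landscapes are unimodal).
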