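# epomfit

Determination of the **effective point of measurement (EPOM)** of
plane-parallel ionization chambers (NACP-02, Roos, Advanced Markus) in
clinical electron beams, from water-tank depth-scan data.

## The problem

Electron-beam dosimetry protocols place a plane-parallel chamber's reference
point at the inner surface of its entrance window. In reality the depth
offset Δz that makes the chamber's reading best represent dose to water lies
*inside* the air cavity, varies with beam energy, and differs between chamber
models. Getting Δz wrong tilts every percentage depth-dose (PDD) curve the
chamber measures and biases reference dosimetry at the protocol depth
z_ref = 0.6·R50 − 0.1 cm.

The EPOM is determined experimentally by comparing the chamber's corrected
depth-ionization curve against a reference PDD measured with an
energy-independent detector (a synthetic-diamond detector in practice). The
optimal shift minimizes the root-mean-square deviation

```
rms(Δz)² = (1/n) Σᵢ [ D_w(zᵢ + Δz) − s_w,air(zᵢ + Δz, R50) · M̄_det(zᵢ) ]²
```

over a uniform Δz grid (0.01 cm steps, −0.10 … +0.20 cm), where D_w is the
reference PDD, M̄_det the session-averaged chamber ionization reading at
nominal depth zᵢ (corrected depth-by-depth for ion recombination kS and
polarity kpol via the two-voltage protocol method), and s_w,air the water/air
mean restricted mass collision stopping-power ratio in the Burns
parameterization, valid for 0.02 ≤ z/R50 ≤ 1.2. Evaluation runs from 0.1 cm
below the surface down to z/R50 = 1.2; a positive Δz points from the window
toward the cavity.

Because the original water-tank scans are not publicly archived, the package
ships a seeded synthetic generator that emulates the full campaign (3 chamber
types × 3 serials × 4 energies with R50 from 2.40 to 8.82 cm × repeat
sessions) with known ground truth, so every pipeline stage is testable and
the study-level statistics are reproducible end to end.

## Worked example

```python
import epomfit as ef

beam = ef.SyntheticBeam.nominal("12")                       # R50 = 4.93 cm
ref = ef.make_reference_pdd(beam, ef.default_reference_grid(beam))
truth = ef.SyntheticTruth(dz_true=0.07, noise_sigma=0.003, seed=1)
raw = ef.make_chamber_scan(ref, truth, beam)                # raw 2-voltage scan

pdi, profile = ef.correct_scan(raw)                         # apply kS, kpol
result = ef.find_epom(ref, pdi, beam.r50)
print(f"dz_opt = {result.dz_opt:+.2f} cm  (rms = {result.rms_min:.3f}, "
      f"n = {result.n_points})")
```

prints

```
dz_opt = +0.07 cm  (rms = 0.389, n = 58)
```

i.e. the fit recovers the simulated 0.07 cm shift from a noisy scan; the RMS
is in percentage points of the normalized curves and `n` is the number of
depths inside the evaluation window.

The full campaign lives in the numbered drivers:

```sh
python analysis/01_simulate_study.py        # scans -> scratch/study/
python analysis/02_fit_epom.py              # 36 fits -> results/
python analysis/03_summarize_shifts.py      # type means/SDs vs truth
python analysis/04_reference_depth_impact.py
```

With the default configuration this recovers type-level mean shifts of
0.107 ± 0.012, 0.048 ± 0.011 and 0.018 ± 0.012 cm for NACP-02, Roos and
Advanced Markus (truth: 0.104, 0.040, 0.012 cm plus seeded serial scatter),
with the largest type-mean recovery error at 0.004 cm — well under the
0.01 cm grid resolution.

An `epomfit` console command exposes the same steps
(`simulate`, `fit-epom`, `run-study`, `summarize`); see `epomfit --help`.

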