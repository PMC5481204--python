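# baseflip

Detecting protein-induced DNA base flipping from time-resolved
fluorescence and coordinates.

## The problem

Some DNA-binding enzymes — methyltransferases, glycosylases,
transposases — rotate a base out of the double helix ("base flipping")
as part of their mechanism.  A crystal structure can show a flipped
base, but only as a static snapshot; whether flipping is dynamic in
solution is tested with the fluorescent adenine analogue
2-aminopurine (2AP).  2AP emission is strongly quenched by base
stacking, so the excited-state lifetime distribution of a 2AP-labelled
duplex reports the conformational ensemble of the probed position.

The TCSPC (time-correlated single photon counting) decay of
intra-helical 2AP is described by a four-exponential law

    I(t) = Σᵢ Aᵢ exp(−t/τᵢ),   i = 1..4,

where the lifetimes τᵢ mark conformational states — highly stacked
(τ₁ ≈ 30–80 ps), partially stacked (τ₂ ≈ 0.5 ns, τ₃ ≈ 2 ns) and
extra-helical/unstacked (τ₄ ≈ 7.5–10 ns) — and the fractional
amplitude (A-factor) Aᵢ is the occupancy of state i.  Protein-induced
transfer of occupancy from the stacked to the unstacked component is
the solution signature of dynamic base flipping.

`baseflip` provides, for this analysis:

* a decay/IRF reconvolution model (analytic for Gaussian IRFs,
  circular-FFT over the laser repetition period for measured IRF
  histograms);
* a synthetic TCSPC generator reproducing the study conditions of the
  Mos1 transposase strand transfer complex experiments (80 ps FWHM
  IRF, 4.75 MHz repetition, 375/390 nm emission, Poisson noise), with
  the published decay parameters of the TP1 (target adenine) and TP13
  (control) duplexes as generating truth;
* weighted iterative-reconvolution fitting, single-curve and global
  (lifetimes shared across emission wavelengths), with multi-start,
  BIC component-count selection and uncertainty estimates;
* conformer population analysis producing a
  `dynamic_flipping` / `no_change` / `indeterminate` verdict;
* coordinate-based geometry: Watson–Crick pairing, helical-axis
  fitting, duplex bend angle, flipped-base detection and protein–DNA
  contact classification for PDB/mmCIF files, plus a synthetic B-DNA
  fixture builder.

See `docs/methods.md` for the model, parameter defaults and
limitations.

## Worked example

Simulate the TP1 duplex (2AP at the target adenine) with and without
transposase, fit globally and compare conditions:

```python
from baseflip import AcquisitionSettings, FitOptions, fit_global, build_report
from baseflip.simulate import simulate_experiment
from baseflip.io import decay_parameter_table

settings = AcquisitionSettings(seed=1)        # 1e7 photons, 80 ps IRF
fits = {}
for sample in ["TP1_free", "TP1_bound"]:
    measurements = simulate_experiment([sample], settings)   # 375 + 390 nm
    fits[sample] = fit_global(measurements, settings.irf, 4, FitOptions(seed=1))

print(decay_parameter_table(fits))
print(build_report(fits["TP1_free"], fits["TP1_bound"]).summary())
```

Output:

```
sample       | A1     tau1       | A2     tau2       | A3     tau3       | A4     tau4
--------------------------------------------------------------------------------------------
TP1_free     | 0.760  50 ps      | 0.089  490 ps     | 0.090  1.99 ns    | 0.060  7.49 ns
TP1_bound    | 0.382  79 ps      | 0.156  499 ps     | 0.154  2.02 ns    | 0.308  9.70 ns

Conformer population analysis
--------------------------------
  free: stacked: 76.0%, intermediate: 18.0%, unstacked: 6.0%
 bound: stacked: 38.2%, intermediate: 31.0%, unstacked: 30.8%
transfer (bound - free): stacked: -37.8 pts, intermediate: +13.0 pts, unstacked: +24.8 pts
brightness ratio (proxy): 4.80
verdict: dynamic_flipping
```

Free TP1 is dominated by the stacked state (76%, τ₁ = 50 ps) with 6%
unstacked; with transposase bound the stacked population falls to ~38%
while the unstacked state (τ₄ = 9.7 ns) rises to ~31% — a large,
specific population transfer that the analysis calls dynamic base
flipping.  The brightness ratio is the amplitude-weighted-lifetime
proxy for the steady-state intensity increase accompanying unstacking.
Running the same comparison for the TP13 control returns `no_change`.

The same from the shell:

```
baseflip pipeline --seed 1 --out run/
```

writes the simulated histograms, a JSON report with full provenance
and the table above to `run/`.

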