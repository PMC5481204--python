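# Methods

## Scientific setting

`baseflip` implements the computational half of a fluorescence +
structural test for protein-induced DNA base flipping, modelled on the
analysis applied to the Mos1 transposase strand transfer complex (STC).
The fluorescent adenine analogue 2-aminopurine (2AP) replaces an
adenine of interest in a DNA duplex; its emission is strongly quenched
by base stacking, so the distribution of its excited-state lifetimes
reports the distribution of local duplex conformations.  Decays are
recorded by time-correlated single photon counting (TCSPC) and
described by a multi-exponential law

    I(t) = sum_{i=1..4} A_i exp(-t / tau_i),

with lifetimes `tau_i` ordered ascending and fractional amplitudes
(A-factors) `A_i` summing to 1.  The field's standard reading for
intra-helical 2AP is four components: a highly stacked conformation
(tau ~ 30-80 ps, typically the majority), two imperfectly stacked
intra-helical conformations (tau ~ 0.5 and ~2 ns), and an unstacked,
extra-helical, solvent-exposed conformation (tau ~ 7.5-10 ns).  A
protein-driven transfer of A-factor weight from the stacked to the
unstacked component, at the probed position only, is the solution-phase
signature of dynamic base flipping.

## Decay model and reconvolution

A recorded histogram is the decay convolved with the instrument
response function (IRF), sampled per channel, with Poisson counting
noise and a flat background.  Amplitudes are stored normalised; the
absolute intensity is carried by `scale`, defined as the **expected
signal photons inside the acquisition window**.  With a 50 ns window
and lifetimes up to ~10 ns a small fraction of emission falls beyond
the window (and wraps to later parts of the 210.5 ns repetition
period); defining `scale` in-window makes the conservation property
(`sum(expected) - n*background == scale`) exact rather than
approximate, and has no effect on fitted A-factors or lifetimes, which
are determined by the shape.

Two convolution routes are provided:

* **Gaussian IRF (analytic).**  Each component's channel content is a
  difference of exponentially-modified-Gaussian CDFs, computed with a
  numerically stable `erfcx` formulation.  Emission excited by earlier
  pulses is added in closed form: one repetition period after
  excitation the Gaussian is fully integrated, so the pulse-train sum
  is geometric.  Keeping this tail analytic (instead of truncating a
  sum at a lifetime-dependent term count) keeps the model smooth in
  tau, which the derivative-based fitter requires.  This route is
  exact to float precision (tested at 1e-6 relative against an
  independent `scipy.stats.exponnorm` oracle).
* **Measured IRF histogram (discrete).**  The IRF is placed on an
  extended grid covering one repetition period and convolved with the
  channel-integrated periodic decay by circular FFT, so wrap-around is
  exact by construction.  Channel mass is treated as acting at the
  channel start, which makes a delta IRF the exact identity element.
  Relative to the continuous route this convention sits half a channel
  earlier and carries an O(dt^2) binning approximation (~0.2-0.5% near
  the rise at 12.2 ps channels); both effects are absorbed by the
  fitted IRF shift.

The simulator uses the Gaussian route, matching how the experiment's
IRF is characterised (an ~80 ps FWHM figure, not a recorded IRF
histogram).

## Synthetic data generator

`simulate` emulates the study's acquisition: 317 nm excitation at
4.75 MHz (repetition period 210.53 ns), emission at 375 and 390 nm,
Gaussian IRF of 80 ps FWHM centred at 2 ns, 4096 channels spanning
50 ns (12.2 ps/channel), 1e7 signal photons per decay, 10 background
counts per channel, independent Poisson noise per channel.  The photon
budget is what is needed to resolve a 30 ps component under an 80 ps
IRF; the channel width keeps >2 channels under the shortest lifetime.

The generating truth per sample (amplitudes; lifetimes in ns):

| sample     | A-factors                  | lifetimes              |
|------------|----------------------------|------------------------|
| TP1_free   | 0.76, 0.09, 0.09, 0.06     | 0.05, 0.5, 2.0, 7.5    |
| TP1_bound  | 0.38, 0.155, 0.155, 0.31   | 0.08, 0.5, 2.0, 9.7    |
| TP13_free  | 0.90, 0.05, 0.04, 0.01     | 0.03, 0.5, 2.0, 9.0    |
| TP13_bound | = TP13_free                | = TP13_free            |

The dominant and longest components are published values; the
intermediate components are not published in full, so they carry the
canonical intermediate lifetimes (0.5 and 2 ns) with the residual
amplitude assigned as above (for TP1, split equally).  They are
stand-ins and are labelled as such wherever reported.  TP13 is
identical with and without protein because the experiment found its
decay parameters essentially unchanged by binding.

Per-wavelength A-factors may be tilted by a configurable
`spectral_factor` (default 0: both wavelengths share the truth);
lifetimes are always identical across wavelengths — the structure
global analysis assumes.  Per-measurement seeds are derived from the
master seed by SHA-256 hashing of (master, label, wavelength), so
seeds never collide and every measurement is independently
reproducible.

What the generator does **not** emulate: detector afterpulsing,
dead-time and pile-up, wavelength-dependent IRF drift, scattered
excitation light, and any real spectral dependence of the A-factors.
Passing recovery tests therefore demonstrate the estimator is correct
and well-calibrated under the model's own assumptions, not that those
assumptions hold for any particular instrument.

## Fitting

Weighted least squares with Neyman weights `1/max(counts, 1)` (the
Poisson variance estimate, standard TCSPC practice), solved by a
trust-region reflective method.  Constraints are structural:
lifetimes are optimised in log-space with bounds
[channel/5, repetition period]; amplitudes pass through a softmax so
every iterate sums to 1; `scale` is optimised in log-space; the
background is fitted (fixable) and bounded at 0; a sub-channel IRF
shift (±5 channels) is fitted by default.  Fitted components are
sorted ascending on output.

Numerical choices that matter:

* finite-difference step 1e-4 in solver space — with the default
  square-root-of-epsilon step the Jacobian is noise-dominated and the
  trust region collapses prematurely;
* multi-start (default 3): one data-driven start (log-spaced lifetimes
  between one channel and a tenth of the period, equal amplitudes,
  background from the pre-rise channels) plus log-normal jittered
  lifetime sets; the best chi-squared is kept.  The four-component
  problem has genuine local minima (e.g. two short components merging)
  that the jittered starts escape;
* convergence at relative objective change < 1e-10 or 1e5 evaluations;
  non-convergence is reported via a flag, not an exception;
* background initialisation falls back to the lowest-decile mean when
  a record has no pre-rise region, because a grossly overestimated
  background leaves the scale gradient numerically invisible.

Global fits share one lifetime vector across measurements while each
measurement keeps its own A-factors, scale, background and shift; the
objective is the concatenated weighted residual vector.  A global fit
of one measurement is identical to a single fit.  Parameter
uncertainties come from the Gauss-Newton covariance (pseudo-inverse of
J'J) propagated to physical parameters by the delta method.

Component-count selection uses BIC computed from the weighted
chi-squared (`chi2 + k ln N`), choosing the smallest n within a margin
(default 10) of the minimum — preferred over nested F-tests, which are
ill-behaved at the n = 4 boundary.

## Conformer analysis

Fitted components are classified by lifetime: stacked below 0.2 ns,
unstacked at or above 4 ns, intermediate between (configurable).  These
boundaries separate the canonical stacked (30-80 ps) and unstacked
(7.5-10 ns) lifetimes from the intermediates (0.5/2 ns) with wide
margins on both sides.  A-factors are read directly as fractional
occupancies, summed per state and averaged over wavelengths.

The free-vs-bound comparison reports per-state population transfer in
percentage points.  The verdict is `dynamic_flipping` when the
unstacked state gains >= 15 points and the stacked state loses >= 15
points, `no_change` when both transfers are below 5 points in
magnitude, otherwise `indeterminate`.  The 15/5 thresholds are sized
from the observed effect (~25-point unstacked gain at the target
position) versus the control (~0), leaving wide margins in both
directions.

The bound/free ratio of amplitude-weighted lifetimes
(`sum A_i tau_i`) is reported as a **proxy** for the relative
steady-state brightness (it assumes equal radiative rates and carries
the stand-in intermediate amplitudes), so it is used as a
direction-and-magnitude consistency check — the analysis requires it
to exceed 4 for TP1, not to equal the measured ten-fold steady-state
increase exactly.

## DNA geometry

* **Base pairs** are found geometrically: purine N1 to pyrimidine N3
  within 3.5 A and glycosidic bonds (C1' to N9/N1) pointing towards
  each other (antiparallel test); greedy assignment by ascending
  distance, each nucleotide in at most one pair.
* **Pair centres** are glycosidic-nitrogen midpoints — robust to
  missing phosphates at nicks.
* **Helical axes** are total-least-squares lines through ordered pair
  centres, oriented 5'->3' along the reference strand.
* **Bend angle** is the deflection between the two arm axes with both
  oriented in the same 5'->3' sense: straight duplex = 0 deg.  The arms
  are caller-specified residue ranges flanking the apex.  Because bend
  conventions differ between programs, validation against any external
  figure should allow several degrees.
* **Flipped bases** are unpaired nucleotides whose glycosidic nitrogen
  lies more than 8 A (configurable) from the local helical axis,
  fitted to the nearest pair centres.  In ideal B-DNA that nitrogen
  sits ~4 A from the axis, so 8 A cleanly separates intra-helical from
  extra-helical without catching breathing or fraying.
* **Contacts** use heavy atoms only (no hydrogens assumed): any
  protein N/O within 3.5 A of a DNA N/O is a hydrogen bond; Lys NZ and
  Arg NH1/NH2/NE within 4.0 A of a phosphate oxygen are salt bridges.

Geometry tests run exclusively on programmatically generated synthetic
B-DNA fixtures (3.38 A rise, 36 deg twist, skeletal nucleotides with
backbone phosphate, C1' and the two informative nitrogens).  These are
labelled synthetic stand-ins: they validate the operations'
geometric contracts (pairing, axis recovery, constructed bends of
known angle, rigid-motion invariance, planted contacts at known
distances), not crystallographic realism.  Deposited structures in
PDB/mmCIF format can be analysed with the same operations when
available locally.

## Problem sizes

Recovery experiments use the full study conditions (4096 channels,
1e7 photons, two wavelengths, four components, ten replicate seeds);
one three-start global fit takes a few seconds.  Solver-behaviour unit
tests use reduced records (256-2048 channels, 1e4-1e6 photons), which
exercise the same code paths at lower statistical resolution.

## Known limitations

* Weighted least squares, not Poisson maximum likelihood: at very low
  counts per channel Neyman weights bias the reduced chi-squared a few
  per cent above 1; at the study's count levels the effect is
  negligible.
* The intermediate-component truth values are stand-ins; quantities
  that depend on them (notably the brightness proxy) are checked
  directionally, not for exact equality.
* No modelling of anisotropy, time-resolved spectra, or detector
  artefacts.
* The geometry module performs no refinement or density handling and
  assumes standard atom naming (N9/N1/N3, C1', OP1/OP2).
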