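# Methods

`skinmech` analyses in vivo skin extension tests of the kind performed with a
two-pad traction device glued to the forearm: a mobile pad stretches the skin
at constant speed to a target engineering strain, holds it there while the
force relaxes, and (optionally) an LC-OCT or ultrasound probe between the
pads images the tissue at rest and under stretch.  Three analysis chains are
implemented, plus the synthetic generators used to validate them.

## Stress conversion

The measured tangential force is converted to engineering stress through the
effective cross-section `S = e·l`, where `l` is the pad width (42 mm by
default) and `e` the skin thickness recruited by the extension (1.2 mm,
surface to hypodermis, as observed by depth imaging).  The default geometry
gives `S = 50.4 mm²`; `σ = F/S` with SI units internally (Pa, s, m) and
mm/kPa conversions at the interface boundary.

## Viscoelastic identification (`rheology`)

**Model.** A generalized Maxwell network of order 1 or 2: equilibrium spring
`E0` in parallel with branches `(E_i, η_i)`; `τ_i = η_i/E_i`.  In Prony form
the relaxation modulus is

    Y(t) = E0_inst · (1 − Σ_i p_i (1 − e^(−t/τ_i)))        ("standard")

with `E0_inst = E0 + Σ E_i` the instantaneous modulus and
`p_i = E_i/E0_inst`.  `Y(0) = E0_inst` and `Y(∞) = E0_inst(1 − Σ p_i) = E0`.
An alternative algebraic form sometimes seen in the skin literature,

    Y(t) = E0_inst · (1 − Σ_i p_i e^(−t/τ_i))              ("as_printed")

*increases* with time, which contradicts both the physics of stress
relaxation and the description of `E0` as an instantaneous modulus.  The
standard form is therefore the default; the rising form is kept behind the
`form="as_printed"` flag so the two can be compared.  Both satisfy the
step-strain identity `σ(t) = Y(t)·ε0` exactly.

**Forward model.** Stress under an arbitrary strain history follows the
Boltzmann hereditary integral `σ(t) = Y(t)ε(0) + ∫₀ᵗ Y(t−ζ) ε̇(ζ) dζ`.  On a
sampled strain history the integral is evaluated by attributing each strain
increment to its interval midpoint; the exponential kernel turns this into
an O(n) internal-variable recursion per branch (an IIR filter on uniform
grids).  The scheme is exact for step strains and second-order accurate on
smooth ramps (halving the step quarters the error; verified by test).

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) over
`(E0_inst, p_i, τ_i)`.  Positivity and `Σ p_i < 1` are enforced by
construction — the optimizer works with the total relaxed fraction
`s = Σ p_i ∈ (0,1)` and, for two branches, a split fraction `f ∈ (0,1)` —
and `E0` and `τ` are fitted in log10; terms are reported sorted by `τ`
(ascending), which resolves the branch-permutation ambiguity.  Relaxation
times are box-bounded to `[0.01, 1000] s` by default.  The starting point is
deterministic and data-driven: `E0_inst` from the within-cycle stress peak
over the imposed strain, `s` from the peak-to-plateau drop, `τ` log-spaced
at 0.5 s and 10 s.  The default fit window is the hold segment only (the
30 s relaxation part of the record carries most of the information about
`τ` and the plateau); `full_cycle` fits ramp + hold.  Either way the model
stress is evaluated over the *full* strain history from t = 0, so multi-cycle
memory is handled correctly while residuals stay in the chosen window.
Records with several cycles are fitted per cycle and the per-cycle
parameters averaged (term-wise after τ-sorting).

Measured: noiseless synthetic records are recovered within 1 % relative
(both 1- and 2-branch); at 1 % additive noise the median worst-parameter
error over 20 records is ≈ 0.3 % (1 branch) and ≈ 4 % (2 branches, the τ/p
trade-off of the slow branch dominating).

## Bilinear elastic moduli (`bilinear`)

Skin loading curves show two quasi-linear regimes — compliant fibre
uncrimping (slope `E1`), then stiff fibre recruitment (slope `E2 > E1`).
The detector grows an OLS window from each end of the curve, keeping the
longest prefix/suffix whose coefficient of determination stays at or above
`r2_min` (default 0.995) and covers at least `min_frac` (default 0.15) of
the samples; overlapping windows are truncated at the overlap midpoint.
Because the greedy suffix can absorb a few pre-break samples while staying
above the R² threshold, a refinement pass intersects the two window lines
and re-anchors the windows strictly below/above the intersection strain,
iterated to a fixed point (≤ 4 passes).  On exactly bilinear data the
recovered slopes then match construction to better than 1e−9 relative with
R² = 1; a single straight line splits into two halves with equal slopes.
Intercepts are free parameters (Hooke's law is applied to the slopes only);
the reported break strain is the intersection of the two fitted lines.
Curves are canonicalized by a lexicographic (strain, stress) sort, making
the fit invariant to permutations of duplicate-strain samples.

Measured: at 1 % multiplicative noise the median slope error over 50 random
stiffening curves is ≈ 0.3 %, and the detected break strain is within
±0.001 of truth at 0.5 % noise.

## Spectral-centroid strain and Poisson's ratio (`spectral`)

Stretching a textured tissue image rescales its spatial-frequency content,
so per-axis strain can be read off the shift of the spectral centre of
gravity.  For an ROI the pipeline removes the mean, applies a separable Hann
window, takes the 2-D DFT with physical frequency axes `u = i/(MΔx)`,
`v = j/(NΔy)` (cycles/µm), and computes the magnitude-weighted mean
frequency over the strictly positive half-axis up to Nyquist:

    u_xc = Σ u·|F(u,v)| / Σ |F(u,v)|   over bins with u > 0 (all v),

and symmetrically for `v_yc`.  The denominator is the plain magnitude sum
(a centre of gravity); the DC bin is excluded by construction, which also
makes the centroid invariant to affine intensity changes `a·f + b`.  The
centroid wavelength is `λ = K/u` with `K = 1` (cycles-per-length
convention); strains are ratios of wavelengths,

    ε_x = (λx1c − λx0c)/λx0c,   ε_y = (λy1c − λy0c)/λy0c,

so they are invariant to `K` (asserted numerically for `K = 2π`).  Axis
convention: x is the image column axis and stretch direction, y the row
axis (depth); elongation along x gives `ε_x > 0`, thinning in depth
`ε_y < 0`.  Poisson's ratio is `ν = −ε_y/ε_x`, undefined at `ε_x = 0`.

Windowing matters: the stretched member of an image pair is not periodic on
its crop, and without a window spectral leakage from the crop edges drags
the centroid far off (a true 0.30 stretch measured as ≈ −0.05 in a
windowless check).  With the Hann default, imposed stretches
`ε_x ∈ [0.05, 0.30]`, `ε_y ∈ [−0.095, 0]` on 256²-px band-limited textures
are recovered with median error ≤ 0.004 and per-image s.d. ≤ 0.008 —
comfortably inside the ±0.02 tolerance used throughout the tests.  The
window is configurable (`window=None`) because the exhaustive brute-force
centroid oracles are defined on the plain DFT.

ROIs are user-supplied, axis-aligned, 0-based half-open pixel rectangles
(automatic layer segmentation is out of scope).  The autocorrelation images
used to visualize layer stretching are periodic (Wiener–Khinchin: inverse
transform of the power spectrum of the demeaned image), normalized to 1 at
zero lag and centred.

**Reference layer values.** The per-layer strain pairs bundled in
`REFERENCE_LAYER_STRAINS` (epidermis +0.22/−0.095 through fascia
+0.0618/−0.025) are in vivo reference measurements for arm-axis extension;
they drive the default layered fixture and the worked examples.  Their
ratios give ν ≈ 0.43, 0.41, 0.46, 0.40 for epidermis, superficial dermis,
hypodermis and fascia, and a five-layer mean of 0.40 — the whole-skin
Poisson's ratio.  The deep-dermis pair is internally inconsistent with its
published ratio (−(−0.059)/0.193 ≈ 0.31, not 0.46); the package reports the
recomputed value and excludes that layer from the per-layer consistency
checks (the five-layer mean rounds to 0.4 either way).

## Synthetic data (`synthetic`)

The generators define the study conditions the analyses are validated
under; all are pure functions of (spec, seed).

* **Relaxation records** — forward hereditary-integral stress for the
  default protocol (1 mm/s pad speed, 20 mm gap → strain rate 0.05/s; 20 %
  target strain, hence a 4 s ramp; 30 s hold; 3 cycles), sampled at 50 Hz,
  plus additive Gaussian noise scaled to the peak stress (sensor-like;
  default 1 %).  Cycles are separated by an instantaneous release to zero
  strain; no inter-cycle recovery period is modelled.
* **Loading curves** — continuous piecewise-linear stress with
  multiplicative Gaussian noise (default 1 %), break at 10 % strain.
* **Textures** — band-limited Gaussian random fields; the band (default
  0.04–0.12 cycles/µm at 1 µm pitch) is applied per axis rather than as a
  radial annulus so that the marginal centroid of each axis sits mid-band.
  Imposed stretches are cubic-spline resamplings under the affine map
  `(x, y) → ((1+ε_x)x, (1+ε_y)y)`, cropped to the mapped support (no
  padding, so no out-of-support content contaminates the spectrum).
* **Layered images** — vertical stacks of textures, one imposed strain pair
  per layer; both states are cropped to the same fixed windows, so one ROI
  list serves both images (a staring probe over deforming tissue).
* **Synthetic cohort** — for directional studies, each subject's
  across-lines (135°) parameters are drawn around population means
  (`E0 ≈ 210 kPa`, `E1 ≈ 417 kPa`), and the along-lines (45°) parameters
  multiply the same subject's values by anisotropy ratios (≈ 3.2× stiffness,
  jittered ±10 %), so directional dominance holds for every subject by
  construction.  Relaxation times are drawn in a plausible 1–6 s range:
  published branch-viscosity values of a few hundred Pa·s against branch
  moduli of hundreds of kPa would imply τ ≈ 0.6 ms, unresolvable within a
  30 s hold and inconsistent with visible relaxation over tens of seconds,
  so the generator treats τ (not η) as the primary draw and derives
  η = τ·E.

What the generators do **not** emulate: ultrasound speckle statistics or
LC-OCT optics, tissue nonlinearity in the relaxation forward model (the
hereditary integral is linear; the bilinear loading curves are a separate
generator), drift or pad slippage, inter-cycle recovery, and auxetic
in-plane behaviour (positive ε_y under stretch, as reported along the
natural tension lines) — the texture machinery can produce such pairs, but
no physical model of the effect is asserted.  Passing closed-loop tests
therefore demonstrates correctness of the estimators under these idealized
conditions, not performance on clinical images.

## Pipeline and reports (`pipeline`, CLI)

`run_relaxation_analysis` composes, per record: stress conversion →
per-cycle Prony fit (averaged, then converted back to branch parameters
`E0, E_i, η_i`) → bilinear moduli from the first loading ramp.  Group means
± s.d. are reported per direction; group differences can be annotated with
a Kruskal–Wallis p-value (delegated to `scipy.stats.kruskal` — the
distributions are not assumed normal).  `run_strain_analysis` produces the
per-layer `ε_x, ε_y, ν` table, optionally with dispersion over several
side-by-side areas per layer (default 5 when requested, emulating repeated
measurements over different regions of one image).  Per-file and per-ROI
failures are logged and recorded in the report; the run continues.  Reports
embed the seed and a configuration hash, and re-running a configuration
reproduces byte-identical CSVs.

Note that two unrelated quantities share the `E1/E2` names, as is common in
this literature: the *rheological* branch moduli (kPa, from the relaxation
fit) and the *elastic* bilinear slopes (MPa, from the loading ramp).  The
report keeps them in separate columns (`E1_kPa` vs `E1_MPa`).

## Problem sizes and numerical choices

Defaults chosen for the package's studies: records at 50 Hz (≈ 1 700
samples per cycle; 2 000-sample holds at 67 Hz in the recovery studies),
textures 256×256 px, brute-force spectral oracles on ≤ 64×64 images,
recovery studies over 20 seeds (50 for slopes).  Tolerances: strain
recovery ±0.02 absolute (median), Prony recovery 1 % noiseless / 5 % at 1 %
noise (median), slopes 3 % at 1 % noise (median), oracle agreement 1e−9,
parameter round-trips 1e−12 relative, step identity at machine precision.
Degenerate inputs are rejected with typed errors (constant images, zero
records, non-monotone grids, overweight Prony series, non-tiling layers).

## Known limitations

* Creep records are not fitted (no creep analysis chain), and unloading /
  hysteresis of the loading curve is out of scope.
* The spectral method measures a single global scale shift per axis and ROI;
  it cannot resolve within-ROI strain gradients, rotations or shear, and is
aliased by any texture change that is not a geometric rescaling (speckle
  decorrelation, out-of-plane motion).
* Poisson's ratios are meaningful only within the elastic assumption
  `ν = −ε_y/ε_x`; at the 20–37 % strains involved this is a convention, not
  a small-strain guarantee.
* The group-level in vivo dispersions cannot be reproduced without raw
  records; the synthetic cohort reproduces orderings (anisotropy,
  bilinearity) rather than published group means.
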