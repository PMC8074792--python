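# Methods

This note records the models behind each pipeline, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical and design choices made where the field's conventions left the
design open.

## Ratiometric dipole-potential readouts

The membrane dipole potential cannot be measured with electrodes in intact
cells; both readouts here are ratiometric fluorescence surrogates and are
reported as dimensionless ratios, never converted to millivolts.

**F66 emission ratio.** The excited state of the 3-hydroxyflavone probe F66
partitions between a normal (N\*) and a proton-transfer tautomer (T\*) form;
the balance shifts with the intramembrane electric field, so the per-cell
emission ratio R = I_N / I_T falls as the dipole potential rises. The ratio
is computed *per event* and then averaged — not as mean(I_N)/mean(I_T) —
because the per-cell ratio is the quantity whose population statistics are
reported. Events with I_T ≤ 0 have no defined ratio; they are excluded and
counted, never clamped, and an all-excluded sample is an error. The sample
summary is the arithmetic mean with the sample SD (n−1); a median option
exists because heavy-tailed dye-loading distributions can make the mean
sensitive to outliers, but the mean is the default per the field's
convention. A warning (not an error) is raised below 20,000 events — the
conventional floor for a stable per-sample mean — so that small synthetic
desk tests remain usable. Dose–response tables divide each treated sample by
its replicate-matched vehicle control; exactly one control per replicate is
required, and ambiguity is an error listing the candidates.

**di-8-ANEPPS excitation ratio.** R_exc = ∫(410–440 nm) / ∫(490–520 nm) of
the excitation spectrum at fixed emission. Integrals are trapezoidal with
the integrand linearly interpolated exactly onto the band limits: the
trapezoid rule is exact for the piecewise-linear interpolant of a sampled
spectrum, and edge interpolation makes adjacent bands exactly additive
(band(a,b) + band(b,c) = band(a,c)). Band limits are inclusive. No smoothing
is applied by default — smoothing silently changes ratios. Blank
subtraction is available and optional; negative post-subtraction intensities
are retained and flagged rather than clipped, so that band integrals remain
unbiased.

## Membrane fluidity (TMA-DPH anisotropy)

Steady-state L-format anisotropy r = (Ivv − G·Ivh)/(Ivv + 2G·Ivh) with
G = Ihv/Ihh. For nonnegative intensities and a positive denominator r is
mathematically confined to [−0.5, 1]; values outside the photophysically
plausible steady-state window [−0.2, 0.4] are *flagged* with a warning but
returned, since instrument blanks or scatter artifacts can legitimately
produce them and rejection would bias session QC. The G factor is treated as
a per-session instrument constant with a per-sample override (the
measurement protocol does not tie G to samples); per-component blank
subtraction is applied before the formulas when blanks are provided.

## Membrane hydration (generalized polarization imaging)

GP = (I_blue − I_red)/(I_blue + I_red) per pixel, averaged over membrane
pixels. Pixels with blue + red ≤ 0 after background subtraction have no
defined GP and are excluded (and reported as an invalid fraction); negative
individual channels are otherwise kept so the exclusion rule is exactly
"undefined denominator", which preserves GP ∈ [−1, 1] wherever defined.
Background is a per-channel scalar, by default the median over the
background-seeded watershed region — robust to the occasional bright debris
pixel and reproducible.

**Segmentation.** Membrane pixels come from a manually seeded watershed.
The relief is the gradient magnitude of the summed two-channel image after
light Gaussian smoothing (σ = 1 px, configurable to 0 for noiseless input):
the bright membrane rim is flat in its middle and steep at both edges, so on
the gradient relief it forms a basin walled in by ridges at the two
intensity transitions, and membrane seeds claim it without leaking. An
inverted-intensity relief (rim as the deepest basin) was evaluated first and
rejected: nothing bounds the rim basin at its edges, so on the flat interior
and background plateaus the long rim front out-floods the pointwise
interior/background seeds and the membrane label leaks across most of the
image. The watershed line itself runs along the transition pixels, which mix
membrane and non-membrane signal; `mean_gp` therefore excludes a 1-px
boundary band of the membrane label by default (skipped when it would empty
the region, e.g. 1-px-thin structures, and never applied to an explicit
user-supplied mask such as a lysosome co-stain mask). Ties in the flood are
broken deterministically in row-major scan order; identical inputs give
identical masks. Pixel coordinates are 0-based (row, column); the channel
order of TIFF inputs is fixed by the manifest, never guessed from metadata.

## Uptake / escape kinetics

Model: total uptake U(t) = U_max(1 − e^(−k_u t)) (saturating first-order
surface-limited entry), cytosolic pool dC/dt = k_e (U − C) with C(0) = 0,
endo-lysosomal pool E = U − C, and signals F_AF = E + C + b,
F_NF = q·E + C + b with quench factor q ∈ [0, 1] and baseline b. The linear
ODE has the closed form C = U_max[1 − (k_u e^(−k_e t) − k_e e^(−k_u t))/(k_u − k_e)],
with the (1 + kt)e^(−kt) limit taken when |k_u − k_e| ≤ 10⁻⁹·max(k_u, k_e).
Default rates k_u = 0.02 s⁻¹, k_e = 0.002 s⁻¹, q = 0.05, b = 0.1·U_max:
these place AF saturation in the 100–300 s range, delay the NF rise, and
give the characteristic early dip / late rise of the NF/AF ratio — the
qualitative signature of endocytic uptake followed by slow endo-lysosomal
escape of a quenched fluorophore.

**Binning.** Default is non-overlapping (tumbling) 10-s windows anchored at
t = 0, with a centered sliding-average mode (1-s step) also exposed; both
readings of a "10-s window" appear in practice and neither is claimed to be
canonical. Tumbling is the default because its bins are statistically
independent, which the endpoint tests rely on. Empty bins carry count 0 and
are excluded downstream. Each channel is normalized to its own first
non-empty window (self-normalization precedes ratioing), so the NF/AF ratio
starts at 1 and is driven by quenching, not labeling stoichiometry.

**Fitting.** The model is fitted to the normalized AF and NF traces jointly
by least squares. Two matching choices matter: (1) the model is averaged
across each bin (a bin mean averages the curve over the window; evaluating
at bin centers leaves a convexity bias of a few percent in the early bins);
(2) the model is normalized by its own first-window average, mirroring the
data. U_max is not identifiable from normalized traces and is fixed at 1.
The baseline is fitted as a bounded free parameter in units of U_max — it
cannot be pinned from the normalized trace alone, because normalization maps
the first window to 1 regardless of b. Parameters are optimized as
(log k_u, log k_e, logit q, log b) to enforce positivity and q ∈ (0, 1),
with Levenberg–Marquardt from a nominal start plus ≥ 8 seeded log-uniform
random starts (seed recorded in the fit report); the best residual wins.
Flat traces are rejected as unidentifiable before fitting, and traces
shorter than 600 s are rejected as too short to separate k_u from k_e.

**Endpoint comparison** extracts the per-replicate trace value in the bin
containing t_eval (default 900 s) and delegates to one-way ANOVA + Tukey.
Replicates, not cells, are the statistical unit throughout.

## Group statistics

Classical fixed-effects one-way ANOVA (p from F with k−1, N−k df; the
all-values-identical case returns F = 0, p = 1 flagged degenerate rather
than NaN), Tukey HSD with studentized-range adjusted p values
(Tukey–Kramer standard errors for unbalanced groups; scipy's
studentized-range distribution supplies the tail probabilities), and OLS
regression reporting R² as the squared Pearson correlation with the slope
p value from t on n−2 df. The significance threshold defaults to p < 0.05
and is exposed. No correction is applied across separate analyses — Tukey
already controls the family-wise error within one comparison family.

## Synthetic generators

All generators are pure functions of a `SimulationConfig` whose seed is
mandatory; the same config is bit-reproducible. The dipole surrogate
`dp_param` is abstract and unitless — the readouts are never calibrated to
potential, so the generators encode *directions and orderings only* (e.g.
the treatment panel ALA < control < SA ≈ GLA < 7DHC < cholesterol < 6KC).

* **F66 populations.** Tautomer fraction f_T = 1/(1 + e^(−(ln 2 + dp))):
  logistic keeps f_T ∈ (0, 1), any monotone link would do, and the ln 2
  intercept makes the noiseless control ratio exactly (1−f_T)/f_T = 1/2.
  Dye load is lognormal (σ = 0.35, a typical cytometry loading spread) with
  5% multiplicative detector noise; live/apoptotic/necrotic/debris
  subpopulations (default 85/10/5/0%) occupy distinct scatter clusters, and
  the viability markers are lognormal with a ×80 positive/negative
  separation.
* **Excitation spectra.** A Gaussian peak (σ = 40 nm, amplitude 1000) whose
  center shifts −10 nm per dp unit from 470 nm, sampled at 1 nm over
  380–550 nm; at dp = 0.5 the center is 465 nm, the mirror point of the two
  30-nm bands, so R_exc = 1 exactly without noise.
* **Polarized reads** invert the anisotropy formulas algebraically, so the
  noiseless pipeline must recover (G, r) to machine precision.
* **Uptake streams.** Poisson arrivals (20 events/s) over the run; each
  event's AF and NF values are the model curves at its arrival time times a
  *shared* per-cell lognormal factor (labeling is proportional, so the
  factor cancels in the ratio) and independent 5% measurement noise; 5% of
  events are DAPI-positive with dimmer signals and are gated out upstream.
* **Membrane images.** 10–15 non-overlapping disk cells (radius 16 px, rim
  3 px) on a 256×256 canvas; structural intensity 1.0 on the rim, 0.3
  inside, plus a flat ambient background (GP 0) so scalar background
  subtraction is exercised; the blue/red split encodes gp_true on the rim
  and gp_interior (−0.3) inside; Poisson photon noise at ~2000 expected rim
  photons per channel pair. Seeds (one rim, one interior, one background
  point per cell plus the image corners) and the true rim mask are returned.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: instrument spectral response and compensation error,
autofluorescence, photobleaching, cell-shape irregularity and membrane
ruffling (cells are ideal disks), point-spread blur, drift in event rate,
direct (non-endocytic) membrane translocation of the peptide, and any
quantitative dose → dipole-potential mapping. The tests demonstrate that the
*pipelines* are correct and that the *directions* of the readouts follow
from the encoded physics; they do not validate biological effect sizes.

## Event-table conventions

CSV interchange is comma-separated, header mandatory, '.' decimal, UTF-8,
and bit-exact on round trip. FCS support is deliberately narrow: 3.0/3.1
list-mode read with float or unsigned-integer data (integers converted to
float on read), 3.1 float write; a `Time` parameter with `$TIMESTEP` is
mapped to per-event seconds. Spectral compensation uses the convention
observed = true · S with unit diagonal (a convention must be fixed; this is
the common spillover-matrix orientation), solving rather than explicitly
inverting S. Gates are closed regions — boundary events are kept — for
determinism under the common cytometry convention; gating is idempotent and
every gate appends a report (kept count, fraction) to the table log. Events
with non-finite intensities are dropped at read time with a logged count,
since every downstream ratio requires finite values. Viability quadrants
call an event marker-positive strictly above the threshold; the
double-negative quadrant is the living fraction.

## Problem sizes and tolerances

The test suite runs entirely on synthetic data at desk scale, chosen to
keep the full run around half a minute on one CPU while leaving the
statistical checks well-powered: 20,000-event populations where the
per-sample floor matters (50 seeded repeats for the direction checks),
10,000 null simulations for ANOVA calibration (the observed rejection rate
is compared at ±0.006, about 2.75 binomial SE), 500 repeats for Tukey power
at a 5-pooled-SD shift, 200 repeats of the 2×5-replicate endpoint power
study, and 256×256 images for the GP recovery checks (|bias| < 0.03
criterion; the implementation achieves < 0.005). Oracle agreements are
asserted at the precision the oracle supports: 10⁻¹⁰ for algebraic
identities, 10⁻⁶·U_max against RK4 at dt = 0.1 s, 0.1% against 0.01-nm
fine-grid integration.

## Known limitations

* FCS write targets a single float list-mode layout; exotic FCS features
  (multiple data segments, bit-packed integers, analysis segments) are out
  of scope.
* The watershed quality depends on seed placement as in any manually seeded
  method; no automatic seeding is provided.
* The two-compartment fit assumes the endocytic route only; a parallel
  direct-translocation pathway would bias k_u upward and is not modeled.
* Tukey HSD assumes approximately normal replicate values with common
  variance; no nonparametric fallback is provided.
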