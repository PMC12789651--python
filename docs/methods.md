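# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic data do and do not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Synthetic scenes

The generator exists so that every downstream stage can be tested against
known ground truth at the geometry real nest photographs have: a 1024×1024
linear-reflectance raster at 12 px/mm containing three eggs, a 40 mm ruler
segment (480 px) and a 96 px grey patch rendered at exactly the configured
reflectance (default 0.20).

**Backgrounds.** The achromatic field is `base_luminance` + band-limited
Gaussian noise (log-Gaussian spectral annulus centred at
1/`grain_scale_px`, ≈1.5 octaves wide) + elliptical "pebbles" with
independent Gaussian luminance offsets. Colour is the habitat hue scaled by
the field, so the noise-free configuration reproduces `hue_rgb` exactly and
band-limited noise plus pebbles control contrast (a PC1-like axis) and
granularity (a PC2-like axis) independently. Defaults make the two habitat
classes differ the way open-coast nesting substrates do: beach
(reflectance 0.55, noise s.d. 0.05, grain 4 px ≈ sand, few low-contrast
pebbles, yellowish hue) versus salt marsh (0.38, 0.09, grain 14 px, nine
times the pebble density at up to 26 px radius with doubled contrast,
reddish-brown hue). Salt marsh is therefore darker, higher-contrast and
coarser by construction.

**Eggs.** Filled ellipses (semi-axes 95×66 px ≈ 32 mm length at 12 px/mm)
with maculation as Poisson-placed dark discs (default 6 per 10³ px²,
radius 1–3 px) plus 1–2 px wide random-walk "wisps". No quantitative
maculation statistics exist for this species, so spot density/size are free
parameters, not estimates. When `egg_luminance_offset` is set (default
−0.10), each composed egg patch is shifted so its within-mask mean
luminance equals the scene's background mean plus the offset — the
configured contrast is then exactly recoverable by pixel averaging, which
is what the parameter-recovery tests rely on.

**Optics.** The composed scene is convolved with a Gaussian point-spread
(σ = 1.5 px) before optional sensor noise. A raster with pixel-sharp edges
carries energy up to the Nyquist limit that no f/11 photograph has
(diffraction plus Bayer demosaicing alone imply a multi-pixel PSF at the
sensor pitches involved); without this step the finest log-Gabor bands are
unrealistically sensitive to the interpolation used during rescaling.
Fiducials are re-stamped sharp after the blur — only the grey patch's mean
and the ruler's extent matter downstream.

**What is not emulated:** shadows and 3-D shading, egg outline cues,
spatially varying illumination, nest-material addition, and any correlation
between egg appearance and habitat (eggs are drawn from one distribution in
both habitats). Passing tests therefore demonstrate that the measurement
chain recovers configured contrasts and orderings — not that real eggs are
or are not cryptic.

## Calibration and receptor catches

Grey calibration applies per-channel gains `0.20 / mean(grey_c)`; a single
step both normalises exposure and white-balances. It is idempotent and the
per-channel (rather than single global) gain is a deliberate choice.

Rescaling measures the ruler as the longer side of its mask's bounding box,
resamples image and masks by nearest neighbour (preserving label sets and
the sharp maculation edges) to 12 px/mm, refuses implied resolutions more
than ±20 % from target, and permits upscaling only behind an explicit flag.

Spectral machinery lives on a 400–700 nm grid at 5 nm (finer than the 10 nm
filters such calibrations are measured with, and cheap). Sensitivities come
from the Govardovskii A1 nomogram at configurable λmax — camera R/G/B at
600/540/460 nm; avian double cone 570, L 605, M 537, S 477 with oil-droplet
long-pass cutoffs 460/560/505/445 nm (logistic edge, 8 nm slope); carnivore
L 558, S 430; human L 566, M 541, S 441. These defaults are conventions
standing in for published curves; every λmax and cutoff is a parameter. No
ultraviolet/violet channel is modelled: a three-channel camera cannot
separate a violet cone from the short-wave cone, and the analysis is
deliberately restricted to what such imagery supports.

Quantum catches are normalised so a perfect reflector catches 1. The
RGB→cone map is the full 10-term quadratic (intercept, linear, squares,
cross-terms) fitted by least squares on a bank of 200 synthetic reflectance
spectra (linear ramp + 1–3 Gaussians of 70–220 nm width, clipped to [0, 1])
under D65, with a fixed seeded 75/25 hold-out split reporting per-cone R².
The spectra are deliberately very smooth: natural reflectance spectra are
band-limited and effectively low-dimensional, and it is that smoothness
that makes a quadratic three-channel map accurate (held-out R² > 0.99 per
cone under the defaults). A 430 nm-peaked cone is the hardest case — much
of its sensitivity lies where the camera barely sees — which is why the
blue sensor default sits at 460 nm, at the violet end of typical CMOS blue
channels.

## Colour metrics

Opponent channels use the Michelson form `(A−B)/(A+B)`: intensity-invariant,
bounded in [−1, 1], and isolated in one function so an alternative opponency
can be swapped in. Carnivore luminance is the L-cone catch (the long-wave
mechanism dominates dichromat achromatic vision) — a documented convention.
Human colour is CIE L\*a\*b\* via linear-sRGB→XYZ (D65). Region colour is
mean-then-transform: catches are pooled over the region before opponency,
matching the spatial pooling that precedes opponency when a patch is viewed
from a distance at which its internal pattern is unresolvable.

One luminance plane (CIE Y of the calibrated image) feeds the texture
analysis for all systems; across regions the avian double-cone, carnivore L
and CIE Y luminances correlate far above 0.9, so per-system texture would
triple the cost for no information.

## Texture

Log-Gabor filters are built in the frequency domain: Gaussian on
log-frequency (σ/f = 0.55 ≈ 2 octaves) × Gaussian on angle (22.5° spacing,
spacing/σ = 1.2), single-sided so the inverse transform is an analytic
signal and |response| is the quadrature-pair envelope. Zero DC is enforced
exactly. Scale s1 is the finest (3 px wavelength; 0.25 mm) with doubling up
to s6 (96 px; 8 mm) — maculation dot to pebble scale. Orientation o1
responds to modulation along the horizontal image axis and successive
orientations turn anticlockwise; the labelling is a convention and carries
no analysis weight.

Filtering runs once over the whole image and region pooling happens on the
magnitude, which keeps mask edges from contaminating the spectrum and lets
the 30 regions of a scene share one FFT. The feature is
`ln(max(mean |response|, 1e-8))`; pooled-then-log (rather than per-pixel
log) is the chosen order, kept behind an explicit `log_mode` switch so the
alternative can be exercised in sensitivity analyses. Regions nearer to the border than half the largest
wavelength trigger a recorded (non-fatal) warning.

PCA is computed on the correlation matrix of the pooled egg + background
table across both habitats — one shared space, never refitted per habitat —
with ddof = 1 standardisation, eigenvalue > 1 retention (never fewer than
one), and each component oriented so its loading sum is non-negative. The
analysis tables use a fixed four-component score block for structural
comparability; the retention count is reported alongside.

## Sampling design

One of the three eggs (chosen uniformly per scene) becomes the template for
27 background samples: translations only, orientation preserved, drawn
uniformly over the valid-offset set by rejection (budget 10⁵ draws) so that
every sample lies fully inside the image and off the exclusion zone (eggs,
ruler, chart, each dilated by 5 px — the field protocol excludes the nest
scrape but states no margin, so the 5 px is a declared convention). Samples
may overlap each other: nothing in the design forbids it, and 27 egg-areas
cannot always be packed disjointly. Per-scene seeds derive from the global
seed XOR a CRC of the nest id, so scene processing order is irrelevant.
Each scene contributes exactly 3 + 27 = 30 rows, fixing the egg prevalence
at 0.1 and the all-background accuracy at 0.9.

## Statistics

All mean comparisons are REML linear mixed models with a per-photograph
random intercept (statsmodels `MixedLM`; the default BFGS optimiser is
used deliberately — L-BFGS was observed to stall at the zero-variance
boundary on clearly non-singular data). Satterthwaite dfs are computed by
the delta method, `df = 2(c'Cc)² / (∇' A ∇)`, with the gradient of the
coefficient variance and the observed information of an own restricted
log-likelihood evaluated numerically (central differences, relative steps
1e-4 / 1e-3) at the REML estimates; per-group Woodbury identities keep this
O(n). The implementation reproduces lmerTest's dfs on fixture data. When
the nest variance estimate collapses (σ²_nest < 1e-6 σ²_resid) the result is
flagged singular and the residual df used. Standardised effects z-score the
response over the analysis stratum before fitting, so a two-level effect
reads as a difference in standardised means.

Pillai's trace is `tr(H(H+E)⁻¹)` from one-way between/within SSCP matrices,
with the standard approximate-F transformation; the object-type × location
interaction row uses statsmodels' MANOVA. Habitat comparisons run on
per-nest cell means (between-nest questions), within-habitat comparisons on
raw samples; the result grid reports the dfs these choices imply rather
than tuning to any external table. No multiple-testing correction is
applied anywhere; the joint MANOVA is the texture family's type-I
protection.

The discrimination model is a logistic regression with a per-nest Gaussian
random intercept, fitted by maximising a Laplace approximation to the
marginal likelihood (exact one-dimensional per-group modes, curvature
correction, L-BFGS over fixed effects and log σ). No frequentist binomial
GLMM exists in the Python stack, so the fitter is written here and
cross-checked against lme4's `glmer` in the test suite (agreement to ~1e-3
on coefficients). Leave-one-nest-out predictions use fixed effects only —
the held-out nest is unseen, so its random intercept sits at its zero
expectation, the only coherent prediction for a new group. Training folds
whose slopes exceed 8 on the standardised scale are treated as
(quasi-)separated, refitted with a ridge of 1e-4 on the slopes (intercept
unpenalised) and flagged; with "colour + texture" feature sets separation
is expected, not exceptional. Confusion matrices threshold at 0.5; the
no-information rate is the majority-class share of the evaluated table (0.9
by design) and accuracy is tested against it one-sided by exact binomial.
ROC curves are empirical over all distinct thresholds; the trapezoidal AUC
equals Mann–Whitney concordance, which a brute-force pair-counting test
asserts.

## Acuity

A pattern element of width w mm viewed by an observer resolving a cycles
per degree is treated as one full cycle, giving a maximum resolvable
distance `d = (w/1000) · a · 180/π` metres. The one-cycle (not half-cycle)
convention is forced by back-calculation: it is the only convention that
simultaneously reproduces the benchmark 4.2 m / 1.7 m / 0.5 m at
73 / 30 / 8.7 cpd for a 1 mm element.

## Problem sizes and determinism

The package's own validation runs at deliberately chosen sizes: most unit
properties use one or two 1024² scenes; table-shape checks run the full
88-scene campaign (28 beach + 60 salt marsh); mixed-model calibration uses
200 recovery and 400 null replicates simulated at the table level (30
scenes each) rather than through image rendering, because the property
under test is the estimator's, not the renderer's. Every stochastic step —
scene generation, spectra bank, hold-out split, sampling plans — is a pure
function of explicit seeds; re-running a configuration reproduces feature
tables byte-identically, and the pipeline reuses on-disk intermediates only
when the stored provenance hash matches the configuration.

## Known limitations

- The mapping from images to catches assumes inputs already linearised;
  camera response characterisation from RAW sensor data is out of scope.
- No receptor-noise (JND) discrimination model: the analysis is
  distributional (signal-detection over measured features), not
  threshold-based.
- Synthetic eggs and substrates are statistically, not photometrically,
  realistic; absolute classification accuracies on synthetic data are
  properties of the configured generator, and only orderings and calibrated
  error rates carry meaning.
- The Laplace GLMM uses a single scalar random intercept; random slopes are
  not supported (nor needed by the design).
- 16-bit scene images are written as TIFF; the PNG encoder available in the
  supported environments cannot write 16-bit RGB.
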