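# Methods

This note documents the models, conventions, defaults, and deliberate design
choices behind `mmwi`, in the spirit of a model-documentation page: what the
code assumes, why each tunable is set where it is, and what the synthetic
experiments do and do not establish.

## Dielectric model and sign convention

Every tissue is a single-relaxation Debye medium

ε(f) = ε∞ + Δε / (1 + iωτ) − i σ_s / (ω ε₀),  ω = 2πf,

under the e^{+iωt} time convention, so passive media have Im ε ≤ 0 and plane
waves e^{−ikz} decay with the principal square root n = √ε (Im n ≤ 0).  The
reconstruction module uses the same convention; mixing conventions flips
propagation into exponential growth, which is why it is fixed package-wide.

Default parameters (dimensionless ε∞ and Δε, τ in ps, σ_s in S/m):

| tissue | ε∞ | Δε | τ | σ_s |
|---|---|---|---|---|
| dermis | 4.0 | 32.0 | 6.9 | 0.10 |
| subcutaneous fat | 2.5 | 6.0 | 13.0 | 0.03 |
| lesion (benign baseline) | 4.0 | 36.0 | 7.2 | 0.20 |

These sit inside published millimeter-wave ranges for wet skin and fat.  A
malignant lesion multiplies Δε and σ_s by (1 + contrast); `contrast` is the
generator's central tunable (default 0.3).  The biological rationale is the
elevated water and biochemical content of malignant tissue; the default
magnitude is a plausible study condition, not a claim of clinical fidelity.

## Forward model and cohort generator

Reflection sweeps come from the exact transfer-matrix (recursive Fresnel)
solution for a layered half-space at normal incidence, with the antenna
standoff contributing a free-space round-trip phase.  The background skin is
dermis (thickness ~N(1.5, 0.1²) mm, Δε jittered by 5%) over semi-infinite
fat; the lesion replaces the top 0.8–1.4 mm of the stack inside a lateral
disc (radius U(2, 4) mm, center within ±1.5 mm of the aperture center).  A
scan position "sees" the lesion when the disc intersects the 4 × 8 mm
antenna field-of-view rectangle centered on the position — the illumination
kernel is binary, which ignores beam taper.

Receiver noise is additive circular complex Gaussian with standard deviation
`noise_level × mean |S11|` per band (default 2%).  Interference artifacts are
multiplicative Hann-shaped notches, 3 samples wide, 90% deep (~20 dB),
placed at random interior frequencies of random positions; the default
cohort mirrors the emulated clinical design: 136 lesions in the study
composition (93 benign / 43 malignant over 9 diagnosis types, 4 body-site
classes) plus 10 extra scans carrying notches, 146 scans total.  All
randomness flows from a single `numpy` generator per call, so cohorts are
byte-reproducible from the seed.

What the generator does **not** emulate: curved skin surfaces, antenna beam
patterns and coupling, VNA error terms, subject motion, intra-lesion
heterogeneity, and site-dependent skin structure (body-site labels are
metadata only).  Tests that pass on this cohort therefore demonstrate the
correctness and information flow of the *analysis*, not clinical accuracy.

## UWB synthesis and validity filtering

Calibration is the pointwise complex ratio of a raw sweep to a reference
sweep; the built-in reference is the analytic metal-plate return (Γ = −1 at
the surface through the same standoff), which normalizes to the incident
field and removes the standoff phase.  The two sub-bands are concatenated on
their merged grid; at the shared 51 GHz endpoint the two samples are
averaged (symmetric and continuous; the bands are calibrated, so both
samples estimate the same reflectivity).

The validity filter compares each magnitude spectrum against a running
median (window 11 samples) and flags a lesion when any contiguous run of
samples sits strictly more than 6 dB below the baseline while being
narrower than 5 samples — deep *and* narrow, the signature of accidental
interference rather than tissue response, whose spectral features are broad
at these layer thicknesses.  Both thresholds are exposed; equality at the
threshold keeps the lesion (strict inequality).

The Nyquist aperture-sampling helper reports c/(2f) free-space; at the
100 GHz reference it reproduces the hardware's 1.5 mm step, while at the
110 GHz band edge the bound is 1.36 mm — the CLI prints both, since a 1.5 mm
step is formally slightly coarser than λ/2 at the top of the band.

## Image reconstruction

The primary method is frequency-domain back-propagation (matched-filter
focusing): every voxel accumulates Σ_pos Σ_f S(f, pos)·exp(+2i k(f) d) with
a Hann spectral window, where the ray from antenna to voxel is split into a
free-space segment (standoff) with k₀ and a tissue segment with
k(f) = 2πf·Re√ε(f)/c from the dermis Debye model.  Refraction at the
interface is ignored (near field, small angles).  Two deliberate choices:

- **Phase-only focusing.**  Using the complex k would multiply voxels by
  exp(2|Im k|d) — a gain of order 10⁴ at 2.4 mm depth in dermis — drowning
  the image in exponentially amplified clutter.  The dispersive *delay* is
  what matters for focusing; attenuation is not inverted.
- **Antenna-footprint gating.**  The sub-band antennas are directive with a
  stated 4 × 8 mm field of view.  At 20 mm standoff over a 10.5 mm aperture,
  isotropic back-propagation has ~5 mm lateral resolution and smears each
  return over voxels the antenna never illuminated; each position therefore
  contributes only to voxels inside its footprint (disable with
  `fov_gating=False` for the plain isotropic sum).

The independent cross-check, `das_reference`, is a classical time-domain
delay-and-sum at constant permittivity: spectra are resampled to a uniform
grid, inverse-FFT'd into analytic impulse responses, shifted to each voxel's
round-trip delay by linear interpolation, and summed (with the same
footprint gating).  On constant-ε point-target scenes the two methods must
— and in the tests do — locate the peak at the same voxel.

Default voxel grid: lateral pitch = scan increment / oversampling factor;
depth pitch c/(4B√ε′) (half the in-tissue range resolution for the 98 GHz
bandwidth, i.e. 2× oversampled), 20 depth samples.  With the 8 × 6 aperture
this yields ~10³ intensity values per cube, the regime the feature stage is
designed for.

## Penetration depth

Two lateral probes per image — lesion center and lesion margin, taken from
the generator metadata in the pipeline and free parameters in the API.  For
each probe, the depth profiles of 30 adjacent lateral positions (along the
longer lateral axis, window clipped at the cube edge; an error if fewer than
30 exist) are averaged per depth; the profile's own depth-mean is the
threshold, and the region depth is the last depth down to which the profile
stays ≥ the threshold.  The image depth is the mean of the two regions, and
cubes are cropped there (at least one slice always survives; a zero-depth
estimate warns).  Consequences of the conventions: a constant cube keeps its
full depth (≥, not >), the estimate is invariant to positive rescaling of
the cube, truncation is idempotent, and the "sum over columns" variant
(`mode="sum"`) yields identical depths to the per-depth mean because profile
and threshold scale by the same column count — both are exposed because the
procedure's prose admits either reading.

## 3D-PCA features

Stage 1 unfolds every cube into (lateral points × lesions) rows of depth
profiles, linearly resampled to a common length (default 20) because
truncation leaves depths unequal; a PCA (numpy SVD on the column-centered
matrix, ratios = normalized squared singular values, loading signs fixed so
each column's largest element is positive) retains the smallest k₁ depth
modes whose cumulative explained variance exceeds 80%.  Stage 2 concatenates
each lesion's per-point stage-1 scores into one row and a second PCA across
lesions keeps `k_final` = 6 components — the per-lesion features.  The
composition of the two stages is an exact affine map of the unfolded data
(verified against an explicitly composed matrix in the tests), so held-out
lesions are projected with training means and loadings only; a single-stage
PCA on flattened voxels is available as `scheme="flat"` for comparison.
Degenerate cohorts (identical cubes) surface as a zero-variance error, and
`k_final` above the stage-2 rank is an error rather than padded.

## Classification and evaluation

Malignancy scores in [0, 1]: LDA Gaussian posterior; KNN malignant-neighbor
fraction; SVMs via a Platt sigmoid — a logistic regression fit to the
training fold's decision values (no inner CV split; test folds never touch
calibration, and this keeps the exhaustive search tractable); MLP output
activation (one hidden layer of 10 logistic units, fixed seed, max 2000
iterations — the architecture is a package choice).  The Gaussian-SVM kernel
width uses the median pairwise-distance heuristic.  The SVM margin grid is
0.1–4.0 in steps of 0.1 (a margin parameter must be positive, so the grid
starts one step above zero); KNN uses K ∈ {1, 3, 5, 7}.

Leave-one-out cross-validation refits the full 3D-PCA model on every fold's
training lesions and projects the held-out lesion with those loadings; a
deliberately leaky variant (PCA fit once on all lesions) exists only so the
tests can demonstrate that leakage changes the scores.  ROC curves use all
distinct score thresholds; AUC is the trapezoid integral, equal to pairwise
concordance with ties counted ½.  The operating point maximizes the Youden
index with ties broken toward sensitivity (a closest-to-corner criterion
would be a one-line change).  Confusion counts dichotomize at score > 0.5
(strict), and per-diagnosis accuracies round half away from zero — the
convention that reproduces the emulated study's printed cohort percentages
(note 20/43 rounds to 47%).

Learning-curve extrapolation (RRS) draws stratified subsamples at several
sizes, averages the LOO misclassification rate over repetitions, and fits
e(n) = a + b·n^(−α) by bounded least squares (a ∈ [0, 1]); the plateau `a`
is the reported large-cohort error.  ROC comparison bootstraps each result
stratified within class (a resample can therefore never lose a class; the
degenerate-resample counter exists for interface completeness and stays 0)
and reports a two-sided p-value with add-one smoothing; `subgroup_compare`
applies the same machinery to a body-site subset (e.g. head-only lesions)
against the full cohort.  Repeated-sweep
reproducibility is the per-frequency variance of magnitude across repeats as
a percent of the squared mean, with spectral-minimum positions listed per
repeat.

## Synthetic-study sizes and what the tests show

The contrast-recovery study (`mmwi.pipeline.contrast_study`) runs the whole
chain — simulate, synthesize, reconstruct, depth-truncate, feature-extract,
LOO-CV with per-fold PCA refits, LDA on all six PCs — on balanced cohorts of
28 lesions (14 per class) at contrasts 0, 0.2, and 0.5, 20 replicate seeds
each, with 64 frequencies per band and 8 × 6 × 12 voxel cubes.  These sizes
are a deliberate desk-scale compromise: large enough that leave-one-out AUC
measures signal recovery rather than small-fold variance (at 10 per class
the per-cohort AUC carried ≈0.05–0.07 of pure evaluation noise), small
enough that the three-level study completes in minutes on one CPU.  Expected
behavior, verified by the acceptance suite: chance-level AUC at zero
contrast, monotone increase with contrast, and >0.95 mean AUC at contrast
0.5 — a planted-signal recovery statement about the pipeline, not a
clinical-performance claim.

## Known limitations

- Binary illumination kernel and straight-ray propagation; no refraction,
  beam taper, or multiple scattering between lesion and layer interfaces.
- The depth-probe locations come from generator metadata in the pipeline;
  there is no lesion segmentation.
- Platt calibration without an inner CV split can be optimistic on tiny
  training folds when the SVM separates them perfectly; scores remain valid
  for ranking (AUC) where monotone transforms cancel.
- The exhaustive PC-subset search reports the best configuration per family
  selected on the same LOO scores it reports — the selection itself is not
  nested-cross-validated, mirroring the emulated protocol.
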