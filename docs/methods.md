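# Methods

This note documents the models, parameters and design decisions behind
`protonselect`, and what the synthetic test-bed does and does not show
about clinical data.

## Synthetic pelvic phantoms

The unit of simulation is a labelled voxel patient on a 48×64×48–64 grid
(default 48×64×64 at 2.5 mm isotropic; axes are (z, y, x) = superior→
inferior, anterior→posterior, patient-right→left, positions at voxel
centres). Anatomy is parametric: the prostate + seminal-vesicle clinical
target (CTV1) is an ellipsoid (≈16×14×17 mm semi-axes); the rectum is a
tube (radius ≈11 mm) placed posterior to the CTV with a 0–4.5 mm gap (mean
1.5 mm); the rectum wall is the shell of rectum voxels within 3 mm
(configurable) of the outer surface, computed by a Euclidean distance
transform with physical spacing; bladder, femoral heads, colon and
intestine are ellipsoids/tubes in their anatomical positions. Dual-dose-
gradient cases add an annular pelvic lymph-node band (CTV2). Intensities
are CT-like (soft tissue ≈1000, bone 1400, bowel gas low) with seeded
noise.

Planning targets come from anisotropic margin expansion of the CTVs: a
voxel joins the PTV when, along every axis, its signed distance to some
CTV voxel centre is within the margin for that anatomical direction
(superior/inferior/left/right/anterior 1.0 cm and posterior 0.5 cm for
PTV1; 1.0/1.0/0.7/0.7/0.7/0.5 cm for PTV2). The per-axis test makes the
expansion separable, so it is implemented as an exact asymmetric
whole-voxel dilation with ⌊margin/spacing⌋ layers per direction; tests
verify it against an O(V²) per-voxel oracle. With the posterior margin at
0.5 cm and the rectum abutting the CTV, the PTV reaches into the anterior
rectum wall — the geometric fact the whole decision problem lives on.

Per-patient variability multiplies a set of jitters (target size and
position, rectum radius and gap, bladder size) by a single
`anatomy_variability` scale. Two choices deserve emphasis:

* the cranio-caudal target position varies with 5 mm standard deviation
  (clipped at ±12 mm). Inter-patient cranio-caudal variation of this order
  is what real cohorts show; it also means a voxelwise cohort-mean dose
  map is an honest (not artificially strong or weak) baseline.
* the prostate–rectum gap and rectum geometry jitters are sized so the
  photon rectum-wall V6300cGy spans roughly 0–30% across a cohort, which
  maps through the logistic model to photon NTCPs from below the 10%
  step-1 threshold up to ≈50%. A cohort therefore contains photon-obvious
  cases, marginal cases and clearly proton-favoured cases — the mix the
  selection rule exists to sort. Cohort-level flags (anticoagulant use,
  prevalence 0.2 by default; dual-gradient fraction 0.5; PTV2 level 45 or
  50 Gy with equal probability) are sampled from the cohort seed; none of
  these prevalences carries a fidelity claim.

## Surrogate planning engine

The engine is a ray-trace / dose-painting surrogate for a treatment-
planning system, not an inverse optimiser. For each beam the body is
traced with parallel rays in the axial plane and a depth-dose kernel is
accumulated within the target's beam's-eye aperture (opened one ray-bin
beyond the projection):

* photon: full 360° arc at 10° steps; kernel rises from 0.35 at the skin
  to 1.0 at 15 mm, then decays as exp(−0.005 d) — the shape of a
  megavoltage beam;
* proton: the four clinical gantry angles (90°, 270°, 150°, 210°) with
  rays binned at the 6 mm spot spacing; each ray gets a Bragg kernel whose
  range is the distal target edge plus a 6 mm margin, entrance plateau
  0.30, Gaussian distal falloff below 5% within 6 mm. Proton doses are
  treated directly as cGy[RBE].

The "optimiser" is a blend: a target-conformal component (the prescription
painted into each PTV and smoothed by a penumbra kernel, scaled so the 4th
percentile of in-target dose sits just above the prescription, capped at
1.035× to respect the 7000 cGy rectum maximum) is combined by voxelwise
maximum with the ray-traced bath scaled to 0.70× prescription. Dual-
gradient plans paint both levels and take the maximum in the overlap.
Penumbra sigmas are anisotropic — (3, 6) mm (cranio-caudal, in-plane) for
photons, (2.5, 3) mm for protons — because field edges along the patient
axis are collimator-defined and sharper than the in-plane penumbra; the
proton in-plane value being half the photon one carries the Bragg-gradient
advantage the selection method exploits. A small multiplicative noise
(0.2%, seeded) stands in for optimiser variability. Compliance with the
clinical criteria table (target V ≥ 95% per protocol, ≥ 90% acceptable
variation; OAR Dmax/V_D limits) is evaluated on every plan; failure to
reach 90% coverage is reported in the plan metadata rather than raised.

The engine makes no claim of dosimetric fidelity to clinical plans — only
of satisfying the plan-criteria structure and exhibiting the photon-bath
vs Bragg-falloff contrast (on default cohorts the proton body integral
dose is 20–45% lower per case).

## Dosimetry and fractionation

All doses are cGy internally. V_D uses exact voxel counting with a closed
lower bound (≥ threshold); the binned cumulative DVH is for reporting and
never feeds the complication model. The fractionation correction is the
standard linear-quadratic EQD2, D·(d + α/β)/(2 + α/β) with d = D/n in Gy,
α/β = 3 Gy for late rectal toxicity (config-exposed); at 67.5 Gy in 25
fractions it maps the prescription to 76.95 Gy, so the 6300 cGy EQD2
threshold corresponds to ≈5884 cGy physical. Which fractionation the
original V6300 predictor assumes is the main fidelity risk of this chain,
so both the α/β and the transform are explicit parameters. Dose-prediction
error is the prescription-normalised mean absolute error, averaged first
over ROI voxels within a case and then over cases with equal weight.

## Complication models and the decision rule

The operative model is logistic: S = −3.07 + 0.79·anticoagulant +
0.12·V6300cGy(rectum wall, EQD2, %), NTCP = 1/(1 + e^(−S)). A variant of
the logistic formula with a minus sign in the denominator appears in some
printed sources; it is not a probability (it exceeds 1 for positive S) and
is available only behind an `as_printed` audit flag. The LKB model is
provided for completeness as Φ((gEUD − TD50)/(m·TD50)) with gEUD_a =
(mean Dᵃ)^(1/a); its defaults (TD50 76.9 Gy, m 0.13, a 8.33) are
literature-style placeholder values for late rectal toxicity and are
config values, not fitted quantities.

The two-step rule: photon NTCP ≤ 10% (strict "exceeds" comparator) selects
photon at step 1 without evaluating the proton branch — implemented with a
lazy provider so a counting probe can verify the proton plan is never
touched. Otherwise ΔNTCP = photon − proton (percentage points) selects
proton only when it exceeds 10 points. Both comparators and thresholds are
configurable; negative ΔNTCP (proton worse) selects photon.

## Dose predictor

A slice-wise (2-D) encoder–decoder regression: inputs are three aligned
channels per axial slice — CT min-max normalised to [0, 1]; a structure
map coding each ROI as a distinct level in (0, 1] with the most specific
structure winning overlaps; and a DPTV map carrying prescription/PTV1-dose
inside each planning target (1.0 in PTV1, e.g. 0.667 for a 45-in-67.5 Gy
PTV2) and 0 elsewhere. The encoder is a 7×7 stem convolution with 2×2
max-pooling and four stages of residual bottleneck blocks (1×1, 3×3, 1×1;
projection skips on shape change); stages two and three stride by 2, so
the deepest features sit at 1/8 of the input resolution. The decoder is
three fractionally-strided deconvolutions (kernel 4, stride 2 — an
overlapping, smooth reconstruction basis) and a 1×1 head; when internal
padding to a multiple of 8 leaves a shape mismatch the output is
interpolated to the input grid. The full-depth configuration (3, 4, 23, 5
blocks, 64 base filters, canonical 1/4 bottleneck width) is constructible;
tests and the pipeline train a narrow variant (1, 1, 2, 1 blocks, 8 base
filters, 1/2 bottleneck width — narrow stages need proportionally wider
3×3 paths) with ≈24k parameters.

Training is Adam on mean-squared error of prescription-normalised dose,
learning rate 1e-2 with cosine decay to 5% over the run (30 epochs, batch
8 by default), fully seeded: weight init, shuffling and therefore entire
training trajectories are bit-reproducible on one CPU. Desk-scale choices:
training uses slices intersecting a target plus three slices of margin
(the dose transition zone), on a central window that crops 8 voxels from
each in-plane edge; prediction runs every body slice on the same window
and leaves the periphery at zero. Cross-validation partitions the cohort
into k seeded near-equal folds (numpy array_split of a permutation, so 48
cases give 10/10/10/9/9), trains per fold on engine doses as ground truth,
and reports per-fold and pooled MAE per ROI next to the voxelwise
training-mean-dose baseline any learned model must beat.

The network, convolution/deconvolution layers and optimiser are written in
numpy with explicit backward passes (verified against numerical gradients
at 1e-7), which keeps the package free of deep-learning framework
dependencies and makes determinism trivial.

## Evaluation

Proton selection is the positive class: sensitivity = TP/(TP+FN),
specificity = TN/(FP+TN), accuracy = concordant/total. ROC needs a
continuous score and no canonical one exists for a gated two-step rule, so
the default score is the predicted ΔNTCP, with step-1-gated cases scored
min(ΔNTCP, NTCP_photon − 10) so they rank below every step-2 case; the
choice is documented and overridable, and the report also prints
(SEN+SPE)/2, the AUC a binary-only analysis would give. AUC is the
trapezoidal integral of the threshold-swept curve, identical to the
Mann–Whitney statistic with midrank ties (tested against exhaustive pair
counting). Paired comparisons (predicted vs engine V6300 and NTCP per
modality) use the two-tailed paired t-test; Shapiro–Wilk normality (on
differences) and Levene variance checks are attached as advisory
information and never switch the test. Degenerate inputs are defined:
identical samples give t = 0, p = 1; a constant nonzero difference is
flagged degenerate.

## What the synthetic test-bed shows — and what it does not

Passing tests demonstrate that every computational step is correct against
independent oracles, that the pipeline is deterministic end to end, that
the engines produce criteria-compliant, modality-contrasted plans, and
that the predictor genuinely learns anatomy-dependent dose (it beats the
cohort-mean baseline on held-out cases under fivefold cross-validation).
They do not demonstrate clinical dosimetric fidelity: phantom anatomy is
parametric, the engine is not an inverse optimiser, and cohort-level
numbers (accuracy, AUC, MAE, NTCP means) produced by
`scripts/acceptance.py` characterise this synthetic regime at its stated
problem size (16 cases, fivefold CV, 20-epoch training), not any clinical
cohort. The logistic model's coefficients are fixed inputs; no refitting
to cohort data is attempted. Known limitations: 2-D slice-wise prediction
cannot capture residual cranio-caudal dose coupling; the engine has no
heterogeneity corrections, robust optimisation or deliverability
constraints; absolute-volume DVHs and DICOM-RT I/O are out of scope.
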