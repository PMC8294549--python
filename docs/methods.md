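# Methods

This note documents the models, conventions, numerical choices and
limitations behind `depthbench`.

## Registration model

The device (depth camera) and reference (marker-based) systems each report
3-D coordinates in their own frame.  We assume the relation between the two
frames is a *proper rigid* motion — rotation plus translation, no scale, no
reflection — applied in row-vector convention:

    p_M = p_D · R + t,   RᵀR = I, det R = +1.

Given n ≥ 3 label-matched board markers, (R, t) is the exact least-squares
minimiser of Σ‖p_D,i·R + t − p_M,i‖², obtained in closed form: center both
point sets, take the SVD UΣVᵀ of the 3×3 cross-covariance of the centered
device and reference coordinates, and set R = U·diag(1, 1, sign det(UVᵀ))·Vᵀ,
t = p̄_M − p̄_D·R.  The determinant sign correction guarantees a rotation even
when the unconstrained orthogonal optimum would be a reflection (e.g.
mirrored input).  Correspondence is by *marker label* only — board labels
follow a row-major grid convention (`r01c01` = top-left as seen from the
reference camera) — so occluded markers simply drop out of the label
intersection and are reported in `labels_excluded`.

Alignment quality is the mean Euclidean residual over the matched markers
(`Er_R`, cm).  Landmark tracking error is the Euclidean distance `Er`
between the reference position and the transformed device position, with
per-axis absolute differences; by construction Er² = Δx² + Δy² + Δz².

**Degenerate input.** Fewer than 3 matched labels raises an
"insufficient correspondences" error.  The rotation is under-determined when
the matched reference points are collinear or coincident; we flag this when
the *second* singular value of the centered reference matrix falls below
1e−8 × the largest.  Planar configurations are explicitly fine — the
alignment board itself is a plane, and the det-sign correction resolves the
reflection ambiguity a plane leaves open.

## Aggregation conventions

- Every (subject, trial) record carries equal weight; per-landmark means are
  taken over subjects and trials jointly, the overall mean over all records.
- The overall SD of Er is the dispersion of the per-landmark mean values
  (the quantity the per-landmark bar charts display); per-record SDs are
  available from the per-landmark table.
- The sub-threshold fraction (default threshold 2 cm) is computed over
  per-axis error values by default (`threshold_basis="axis"`), switchable to
  3-D `Er` values.
- Landmark→camera assignment (front camera sees anterior landmarks, back
  camera posterior ones) is explicit configuration, never inferred from
  geometry.  Missing or unmatched observations are excluded with a warning,
  never imputed.

## Reliability model

With k repeated trials of the same measurement on n units (landmarks), the
two-way ANOVA decomposition gives mean squares MSR (rows/units), MSC
(columns/trials) and MSE.  Two single-measurement ICC forms are implemented:

- absolute agreement (default): (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)
  — the ICC(2,1)/ICC(A,1) point estimate; sensitive to systematic
  trial-to-trial shifts;
- consistency: (MSR − MSE) / (MSR + (k−1)MSE) — ICC(3,1)/ICC(C,1).

Confidence intervals use the classical closed forms: exact F limits for the
consistency form, Satterthwaite-df F limits for absolute agreement.  Both
forms are selectable because reliability reports in this field frequently
leave the form unstated; the form actually used is printed with every
result.  Cronbach's α = k/(k−1)·(1 − Σ trial variances / total-score
variance) and SEM = SD·√(1 − α) with SD the pooled sample SD of all cells
(the common convention when a report says only "the SD").  α outside [0, 1]
is clamped (with a warning) before the square root; negative α can occur
with anticorrelated trials.  Qualitative bands: ICC < 0.5 poor, [0.5, 0.75)
moderate, [0.75, 0.9] good, > 0.9 excellent (the conventional bands overlap
at the edges; we fix these half-open intervals).

The default trial matrix has 32 rows of subject-averaged per-landmark
errors; (subject, landmark) rows are available via a flag
(`average_subjects=False`), since pooling conventions differ between
reports.  A matrix whose rows carry no variance — all errors identical, as
in a noise-free simulation — has an undefined ICC; the result then carries
the explicit status "degenerate: no between-unit variance" instead of a
number.  Between-unit variance is judged zero when it is < 1e−12 of the
total variation *or* when the total SD is below 1e−9 cm (relative to the
mean magnitude): sub-nano-cm spread is float residue, not signal.

## Synthetic-session generator

The generator emulates a static-standing validation session:

- **Board**: 10×10 grid, 10 cm pitch (exact), 110 cm plate, placed by an
  arbitrary rigid pose; captured once per camera by both systems.
- **Body**: 32 named landmarks on a standing template built for a 1.68 m
  stature (scaled isotropically per subject by N(1, 0.04), with a small
  lateral/depth stance offset).  The coordinates are plausible
  anthropometric fixture values, not measurements.
- **Cameras**: front and back device frames related to the reference frame
  by configurable ground-truth rigid transforms (defaults: ~180°-rotated
  front camera at 2.5 m, back camera behind, both 0.75 m high, with small
  deliberate misalignments).
- **Noise**: device observations get zero-mean per-axis Gaussian noise
  *in the device's own frame* (sensor-frame depth noise; switchable in
  principle by transforming sigmas), with σ_z > σ_x, σ_y by default because
  depth (line-of-sight) range estimation dominates RGB-D error.  The
  marginal per-axis SD σ splits into a *persistent per-(subject, landmark)
  bias* √(σ² − σ_jitter²) plus independent per-trial jitter σ_jitter
  (manual re-selection variability, default 0.2 cm — a modeling choice, as
  no measured value exists).  This split is what makes repeated trials agree
  far better with each other than with truth, producing realistic ICC > 0.9.
  The reference system gets σ = 0.01 cm drawn once per subject (the
  gold-standard capture is not re-selected between trials), so reliability
  statistics are not degenerate by default.  Board markers can be occluded
  from the device with a configurable probability.

**Preset calibration.** The two presets are calibrated analytically to the
error magnitudes of a second-generation time-of-flight camera pair
(`KINECT_LIKE`) and a stereoscopic pair (`REALSENSE_LIKE`): per-axis sigmas
follow E|e| = σ√(2/π) applied to typical reported per-axis mean absolute
errors (ToF: x 1.10, z 1.86 cm → σ = 1.379, 2.331; stereo: x 1.62, z 3.52 cm
→ σ = 2.031, 4.412), the unreported y-sigma is solved so the expected 3-D
norm matches the overall means (2.80 / 5.14 cm → σ_y = 1.459, 2.946), and
board sigmas are solved so E‖ε‖ matches the board residuals (0.59 / 3.77 cm)
while keeping the landmark noise's z/x inflation ratio.  The stereo preset's
larger jitter (0.45 cm vs 0.2 cm) follows from its reported
between-landmark SD and ICC via ICC = σ_b²/(σ_b² + σ_w²).  These are
first-moment calibrations assuming independent Gaussian axes; they are not
expected to reproduce every derived statistic exactly.

**What the simulator does not model**: correlated (e.g. distance- or
angle-dependent) depth bias fields, landmark-specific visibility/soft-tissue
effects, lens distortion, pixel-level selection mechanics, subject sway
between systems.  Passing tests on synthetic data therefore validate the
*pipeline arithmetic and statistics*, not any particular camera's field
accuracy.

`expected_error_norm` provides the test oracle E‖ε‖ for per-axis Gaussian
noise by Monte-Carlo (with standard error); for isotropic σ it equals the
chi(3) mean σ·√2·Γ(2)/Γ(3/2) ≈ 1.5958·σ, which the tests cross-check.

## Numerical and interface choices

- Canonical unit: cm everywhere in memory; files declare cm/mm/m and are
  converted on read.  CSV floats are written at full precision (`repr`) and
  parsed with round-trip precision; XLSX round trips are exact only to
  ~1e-12 relative (spreadsheet float serialisation), which the tests treat
  as numerically identical.
- Transform validation tolerance: orthonormality and det(R)=+1 to 1e−6 at
  construction; fitted transforms are accurate to ~1e−9 and tested tighter.
- Rotation sampling for simulations: uniform via normalized quaternions.
- Determinism: every stochastic routine takes a seed or Generator; a session
  is bit-identical for the same seed.  Output files embed the seed and a
  SHA-256 config digest so any report can be regenerated.
- Problem sizes: the shipped analyses use the demonstration-scale design
  (3 subjects × 2 trials × 32 landmarks, 100 board markers per camera);
  convergence/calibration tests use enlarged synthetic cohorts (up to 60
  subjects) where tighter Monte-Carlo tolerances are needed.

## Known limitations

- One alignment per camera per session: repeated board re-selection per
  trial (and hence a per-trial residual spread) is not modeled; the reported
  residual SD across alignment steps in a real session has no synthetic
  counterpart beyond the per-camera spread.
- ICC CIs assume the classical normal-theory ANOVA model; no bootstrap
  alternative is provided.
- The ingest path for externally produced workbooks depends entirely on a
  user-supplied sheet descriptor; no layout auto-detection is attempted.
- Only k-trial test–retest designs are supported; inter-rater designs are
  out of scope.
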