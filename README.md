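# depthbench

Benchmark the 3-D landmark-location accuracy of a marker-less depth-camera
motion tracking system (DCMTS) against a marker-based optical reference
system (MMTS).

Depth cameras (time-of-flight or stereoscopic RGB-D sensors) are an
attractive low-cost alternative to multi-camera reflective-marker rigs for
ergonomics and biomechanics, but before their coordinates can be trusted the
question is always: *how far off is each body landmark, in cm, along which
axis?*  `depthbench` implements a simple, systematic answer for practitioners:

1. **Registration.** A planar *alignment board* — a 110 cm square plate with
   a 10×10 grid of reflective markers at 10 cm pitch — is captured by both
   systems simultaneously.  From the labeled correspondences the proper rigid
   transform (R, t) mapping device coordinates `p_D` into the reference frame
   is fitted in closed form (SVD of the cross-covariance, i.e. the
   Kabsch/absolute-orientation solution, reflection-safe):

   ```
   p_M ≈ p_D · R + t,        Er_R = (1/n) Σᵢ ‖ p_D,i · R + t − p_M,i ‖
   ```

   The mean residual `Er_R` quantifies alignment quality.
2. **Error metrics.** Each of 32 anatomical landmarks (front/back head, C7,
   acromia, elbows, wrists, hands, ASIS/PSIS, knees, ankles, heels, toes),
   observed per subject and trial by the front or back device camera, is
   mapped through its camera's transform; the tracking error is the Euclidean
   distance `Er = ‖p_M − p_{D→M}‖` plus per-axis absolute differences
   (x lateral, y vertical, z depth), aggregated per landmark and overall.
3. **Reliability.** Repeating the manual marker-center selection gives k ≥ 2
   error values per landmark; test–retest agreement is quantified by the
   two-way ANOVA intraclass correlation coefficient (ICC, absolute-agreement
   or consistency form) with exact F-based 95% CI, Cronbach's α, and
   SEM = SD·√(1 − α).
4. **Simulation.** A synthetic-session generator with known ground-truth
   transforms and an anisotropic (depth-inflated) Gaussian noise model makes
   the whole pipeline testable without hardware, including presets calibrated
   to the error magnitudes typical of a time-of-flight and a stereoscopic
   camera pair.

## Worked example

Generate a synthetic session (two cameras, 3 subjects, 2 trials, Kinect-like
noise), benchmark it, and check trial-to-trial reliability:

```bash
$ depthbench simulate --out demo --seed 7
wrote synthetic session (3 subjects x 2 trials) to demo

$ depthbench benchmark --session-dir demo --out demo_report
records: 192 (32 landmarks)
alignment residual Er_R [back]: 0.54 cm
alignment residual Er_R [front]: 0.60 cm
overall mean (SD) error Er: 2.73 (0.72) cm
  x-axis mean (SD): 0.98 (0.53) cm
  y-axis mean (SD): 1.21 (0.46) cm
  z-axis mean (SD): 1.78 (0.77) cm
per-landmark mean Er range: 1.44 to 4.36 cm
errors below 2 cm (axis basis): 79%
wrote demo_report/report.json, per_landmark.csv, records.csv

$ depthbench reliability demo_report/records.csv
ICC form: two-way mixed effects, absolute agreement, single measurement (ICC(A,1)/ICC(2,1))
Er: ICC 0.98 (95% CI 0.96-0.99), SEM 0.07 cm [excellent]
x-axis: ICC 0.95 (95% CI 0.90-0.97), SEM 0.09 cm [excellent]
y-axis: ICC 0.96 (95% CI 0.92-0.98), SEM 0.07 cm [excellent]
z-axis: ICC 0.98 (95% CI 0.96-0.99), SEM 0.08 cm [excellent]
```

Reading the output: the two coordinate frames were aligned to ~0.6 cm mean
board residual; the depth camera locates a body landmark to 2.73 cm on
average, with the depth (z) axis the dominant error source — the signature of
RGB-D range estimation; 79% of the per-axis errors are under 2 cm; and the
two manual-selection trials agree almost perfectly (ICC > 0.9, "excellent"),
so the benchmark itself is repeatable.

The same pipeline runs on real captures: point `depthbench align` /
`depthbench benchmark --config` at `label,x,y,z` marker CSVs and a
`landmark,subject,trial,system,camera,x,y,z` table (units cm/mm/m declared in
the file or config), or ingest a whole XLSX workbook via
`depthbench.io.read_session_workbook` with a sheet-descriptor mapping.

## Library use

```python
from depthbench import estimate_rigid_transform, run_benchmark, icc
from depthbench.synthetic import simulate_session, KINECT_LIKE, KINECT_BOARD

syn = simulate_session(noise=KINECT_LIKE, board_noise=KINECT_BOARD, seed=1)
report, records, alignments = run_benchmark(syn.session, return_details=True)
print(report.overall_mean_er, report.axis_mean)
```

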