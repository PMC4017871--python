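# Methods

## Scope and data model

The package analyses single trials of the seated reach-and-drink task:
labelled 3-D marker trajectories sampled at 60 Hz in a lab frame with X
pointing forward (subject toward glass), Y to the subject's left, Z up,
origin at the table-edge midpoint (table surface Z = 0), units mm. Eight
markers are functionally required — HAND (3rd metacarpal head of the
grasping hand, the end-effector), WRIST, ELBOW (lateral epicondyle),
SHOULDER (acromion, grasping side), C7, MOUTH (head marker near the
mouth), GLASS_TOP and GLASS_BOTTOM. Every index below depends only on
these eight; extra markers in a file are carried through untouched. The
two glass markers are this package's own addition: the glass
inclination needed to delimit the drinking phase has to be measured
from something, and a top-rim/bottom pair is the minimal instrumented
glass.

File formats: the binary C3D standard (own compact codec, Intel byte
order, float32 or scaled-int16 point storage; float32 quantisation
bounds C3D round-trip fidelity at ~1e-4 mm, whereas the TSV dialect
round-trips at 1e-9 mm) and a human-readable TSV dialect (`# key=value`
header lines for fs/side/subject metadata, `<label>_x/_y/_z` columns).
Missing marker samples are linearly interpolated up to 6 consecutive
frames (100 ms); longer gaps are an error, not silently filled.
`mirror_trial` negates Y and flips the side label so left- and
right-affected subjects pool into one analysis; every index is
invariant under it.

## Preprocessing

Each coordinate is low-pass filtered with a five-point triangular
smooth, kernel (1, 2, 3, 2, 1)/9, applied once; at the record edges the
kernel is renormalised over in-range taps, so the DC gain is exactly 1
everywhere. Velocities are central differences scaled by fs (one-sided
at the ends); the hand's tangential speed is the Euclidean norm of the
3-D velocity — the resultant, not a single component, since submovement
corrections need not align with the reach axis.

## Event detection

The five events are defined descriptively (onset of any body motion,
grasp, glass at the lips tilted ≥ ~45°, end of drinking, glass back on
the table); automation requires explicit criteria, all configurable in
`SegmentationConfig`:

- **T1** — hand or C7 speed above 20 mm/s for 5 consecutive frames,
  then backtracked along the falling edge to the rest floor.
- **T2** — first frame with hand–GLASS_TOP distance < 50 mm and hand
  speed < 50 mm/s, refined by following the speed descent to its
  minimum (the grasp settle).
- **T3** — first frame ≥ T2 with GLASS_TOP–MOUTH distance < 50 mm and
  glass inclination ≥ 30° (entry criterion; the nominal drinking tilt
  is ~45°).
- **T4** — first frame ≥ T3 where the T3 condition ceases for 5 frames.
- **T5** — glass-bottom height within 10 mm of the table and glass
  speed < 50 mm/s, refined to the settle frame.

Because a smooth stop crosses any finite speed threshold strictly
before it ends, threshold crossings alone are biased by several frames,
and the bias grows with slower approaches. Two refinements remove it:

1. **Rest-calibrated signal choice.** The pre-onset rest period
   estimates the marker-noise speed floor. On clean records (raw rest
   speed ≤ 0.5 mm/s) settles are located on the raw central-difference
   speed, whose post-stop tail is a single frame, giving frame-exact
   settles for any movement speed. On noisy records the differentiated
   noise floor of the raw signal (≈ 25 mm/s at 1 mm RMS marker noise)
   would swamp the criteria, so detection speeds use three triangular
   passes on the coordinates (floor ≈ 6 mm/s), except the T2 settle
   signal which keeps one pass so that between-submovement speed dips
   survive.
2. **Changepoint settle fit (T5, noisy records).** A minimum-jerk stop
   ends with speed ∝ (t₅ − t)². The terminal descent (samples between
   the noise floor and 100 mm/s) is fit with that model for every
   candidate stop frame, scoring also the post-descent residuals, and
   the best-fitting frame is the settle. Extrapolating the descent is
   far less biased than thresholding it.

On simulated trials these criteria localise every event within ±1 frame
noise-free and within ±4 frames at 1 mm RMS marker noise for the
preset strategies. An operator can bypass detection entirely with an
events sidecar file (TSV `event<TAB>frame`), mirroring studies where
events are marked by inspection.

## Indexes

"Forward displacement" is always the net change of the X coordinate
between two event frames — positions at events, not path lengths. Over
RG, with Δh, Δs, Δc the hand/shoulder/C7 forward displacements:
AE = 100(Δh−Δs)/Δh, TF = 100·Δc/Δh, TA = 100(Δs−Δc)/Δh, summing to
100 identically. A reach with Δh below 50 mm is rejected as degenerate
rather than returning unstable ratios. The elbow angle is the included
angle at the ELBOW marker between the directions to SHOULDER and WRIST
(180° = full extension); ROM = max − min over RG, so the zero
convention cancels. Mouth displacements MD12/MD23/MD13 are the MOUTH
marker's X changes over RG, BGM and their concatenation. The arm
contribution in BGM and TBGT reuses the AE construction on the phase
window with signs preserved (both displacements are typically negative
in BGM): it measures the share of hand motion not explained by
shoulder (trunk) motion, the construct's intent in all three phases.

**Movement units** are strict local maxima of the hand tangential speed
above 50 mm/s. Two additional rules keep noise ripples from counting:
a minimum prominence of 10 mm/s (computed within the phase window) and
a minimum separation of 100 ms from the previously accepted peak
(scanning left to right). A flat-topped peak — two exactly equal
samples, which symmetric profiles produce at this sampling — counts
once, at its first sample. The smoothing depth of the NMU speed signal
is again rest-calibrated: two triangular passes on clean records, five
on noisy ones (deep smoothing on clean data attenuates short
submovement peaks below the 50 mm/s threshold; on noisy data the
Rayleigh noise floor masks that attenuation while ripples must be
suppressed). The combined reaching + bringing count is computed over
the concatenated [T1, T3) window, not the sum of per-phase counts, so
a peak straddling T2 is not double-counted.

## Statistics

Per protocol each participant contributes the mean of 3 trials. Groups
are compared index-by-index with a two-sided Mann-Whitney U test,
U = min(U_a, U_b) from midranks. For pooled n ≤ 14 the tail is exact:
all C(n, n_a) group-label assignments are enumerated, the one-sided
tail P(U_a ≤ U_obs) is doubled and capped at 1. Ties are handled by
computing U on midranks both for the observation and for every
enumerated assignment, which is the correct permutation null for tied
data. Larger samples fall back to the normal approximation with tie
correction (scipy). At n = 6 + 6 the smallest attainable two-sided p is
2/924 ≈ 0.00216 — reached exactly when the groups' ranges are disjoint
— which is why printed bounds like p < 0.0002 at these sizes require
an exact tail. Medians use the midpoint convention for even n; no
multiple-testing correction is applied, matching the original
single-battery protocol. The report has 15 rows: 7 reaching indexes, 4
bringing, 2 putting-back, the combined NMU, and the overall mouth
displacement MD13.

## Synthetic-trial generator

The generator is the package's oracle, not a biomechanical claim about
patients. Transports are superpositions of minimum-jerk submovements
s(τ) = D(10τ³ − 15τ⁴ + 6τ⁵), the standard model of point-to-point
reaches (unimodal speed, peak 1.875·D/T). Submovements are chained
without overlap, so the commanded count equals the number of speed
peaks by construction; amplitudes are drawn (seeded) to sum to the
commanded displacement with every nominal peak ≥ 80 mm/s and the final
reaching submovement ≥ 90 mm, which keeps every intermediate stop
outside grasping distance of the glass.

The reach decomposition is imposed directly: C7 advances tf % and the
shoulder (tf+ta) % of the commanded hand forward displacement, each on
a single minimum-jerk profile over RG. The mouth rides with C7 and
returns by the fraction ρ of its forward excursion during BGM:
ρ ≈ 1 encodes the trunk-return strategy (backward mouth displacement
equal to the forward one), ρ ≈ 0 the forward-displaced-posture
strategy. During TBGT the trunk leans forward again by the
complementary share of the commanded putting-back arm contribution.
The elbow marker is placed on the perpendicular bisector of the
shoulder–wrist chord so that the included angle sweeps the commanded
excursion exactly, whatever the chord length. The glass tilts 0→45°
with a 0.3 s minimum-jerk ramp positioned so the 30° detection
criterion is crossed exactly at the commanded T3 (and back at T4).
Marker noise is isotropic Gaussian per frame and axis with the
commanded 3-D radial RMS (per-axis σ = RMS/√3), default 0.5 mm —
typical optoelectronic accuracy. Anthropometry is one fixed default
skeleton; the indexes depend only on displacements and angles.

Cohort simulation draws per-subject parameters uniformly within
group-specific ranges (defaults follow the reference study's reported
patient and control index ranges: reaching duration 1.62–3.54 s vs
1.09–1.41 s, arm elongation −9.27–35.83 % vs 34.10–69.50 %, and so on),
three repetitions per subject differing in noise and submovement
amplitudes. Problem sizes throughout (6 + 6 subjects × 3 trials,
100-trial recovery sweeps, 1000-case exact-test enumerations) keep any
full run in seconds while exercising every code path.

### What the generator does and does not emulate

It reproduces the geometry, phase structure, event signatures,
decomposition identities and submovement-count semantics of the task,
with realistic noise. It does not model grasp aperture, joint dynamics,
spasticity, marker soft-tissue artefact, or trial-to-trial variability
beyond parameter draws and noise. Passing recovery tests therefore
shows the *analysis* is correct and noise-tolerant under the stated
conditions; it does not validate the detector against human-marked
events on real recordings.

## Numerical choices and degenerate inputs

Tolerances: contribution identity asserted to 1e-9 of a percent;
MD13 = MD12 + MD23 exact by construction (stored as the sum). Glass
markers closer than 1 mm, elbow marker pairs closer than 1 mm, reaches
under 50 mm, empty groups and empty NMU windows all raise typed errors;
partial index records are never returned. Detection is fully
deterministic; re-running any analysis is bitwise identical.

## Known limitations

- 60 Hz sampling bounds event resolution; at the combined extremes of
  submovement rate (4 per second) and 1 mm RMS noise the 2–3-frame
  grasp-settle dip sits at the detection threshold, and in about 0.2 %
  of random strategy draws T2 locks onto the following submovement dip
  one interval late. Slow approaches under heavy noise carry an
  irreducible settle ambiguity of a few frames.
- The exact-test branch enumerates up to C(14,7) = 3432 assignments;
  the implementation is not meant for large-sample exact inference.
- C3D support covers the Intel/point-data subset of the standard (no
  analog channels, no DEC/MIPS byte orders).
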