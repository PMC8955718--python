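# Methods

This note documents the models, parameter choices and numerical decisions
behind `speedkin`, and what the synthetic-data tests do and do not establish
about real video.

## Coordinate conventions

Input files use native image pixels (y down). Immediately after reading, the
pipeline flips every y to a y-up, wall-aligned convention (`y' = H − y`), so
that positive vertical velocity always means upward motion; all internal
series, the ground-truth record and the exports are y-up. Frames are
0-indexed; times are `frame / fps` seconds. Wall coordinates are metres along
the wall plane (the 5° overhang is folded into the plane; it is recorded in
`WallGeometry` but no geometry is derived from it, and the stored 30-panel
count is likewise informational only).

## Camera-shift estimation

Matched feature pairs between consecutive frames are filtered in two stages:
pairs with |Δx| > 3 px are discarded (the tripod camera only rotates
vertically), then pairs whose Δy falls outside a median ± 3·(1.4826·MAD) band
are discarded (the climber's own features move differently from the wall).
The per-frame shift is γᵢ = −mean(Δy) of the survivors (y-up: wall content
moving down ⇔ camera panning up). Frames without survivors carry the previous
γ forward and are flagged, keeping the estimator causal. The thresholds
(3 px, k = 3) are conventional robust-statistics defaults; both are
configurable.

## Scale calibration

Hold detections are linked across frames by pan-compensated nearest-neighbour
association (a wall-fixed hold is stationary after adding the cumulative
camera shift back). Tracks of hand holds, ordered by compensated height, are
aligned to the route map by sliding the sequence of consecutive-distance
ratios (and x/y slopes) along the map's own sequence and minimising the
summed squared residuals; this works because the hand-hold ladder is
non-uniformly spaced. Identified pairs give one direct scale sample per frame
— the widest-separated visible pair, via s = ½(|Δx_px|/|Δx_m| +
|Δy_px|/|Δy_m|), falling back to a single axis when the map distance along
the other vanishes.

The model s(α) = A·cos α with the recurrence α ← (γ/B)·cos α + α is fitted to
those samples by bounded trust-region least squares over (A, B, α₀). The loss
is non-convex in α₀, so the solver restarts from a 5 × 3 grid of
(α₀ ∈ {−0.4…0.4} rad, B ∈ {2·10³, 5·10³, 2·10⁴} px) and keeps the best
iterate. A is started at max(s_meas) (cos α ≤ 1 forces A ≥ s). B is bounded
below by Σ|γ|/π — a camera cannot sweep more than half a turn over one run —
which keeps the recurrence out of its chaotic small-B regime. The physical
quantities behind A and B (pixel pitch, focal length, wall distance) are not
separately identifiable and are never reported individually. With 5%
multiplicative noise on the scale samples the amplitude is recovered to a
few percent in the median, but individual replicates can land on a
monotone-decreasing branch of the model that fits the noisy samples equally
well — a genuine identifiability limit, not a solver failure.

## Kinematics

Keypoints below the confidence threshold (default 0.1) count as missing and
are filled by linear interpolation (nearest-valid at the ends); keypoints
with fewer than two valid samples stay missing and are logged. The COG is
C = Σ_b m_b·(j_{p,b} + r_b·x_b) over 12 segments. The printed form of this
summation is ambiguous about parenthesisation; the implementation multiplies
each segment's mass fraction by its centre-of-mass *position* (proximal joint
plus r_b along the segment), since only then does Σ m_b = 1 normalise the
sum — the alternative reading (weights on the segment vector only, joints
unweighted) would not return a position. The segment ↔ keypoint mapping
(head = nose→neck, trunk = neck→mid-hip, limbs proximal→distal, foot =
ankle→big toe) follows standard biomechanics convention; the bundled mass
fractions and centre ratios are the classic male cadaver-study values, with
bilateral segments each carrying the per-side fraction so the twelve sum to
one. No athlete-specific anthropometry is attempted.

Metric velocity compensates the pan before scaling:
v_y = (Δy_px + γ)·φ/s, v_x = Δx_px·φ/s (γ is vertical only). Absolute metric
positions are anchored at the earliest identified hold sighting and integrate
the camera height as Σ γ/s.

Joint angles (elbows, knees) are plain 2D vector angles in [0°, 180°],
rotation/translation/scale invariant. The shoulder–hip ("SH") angle is
implemented as the inclination of the mid-shoulder → mid-hip axis against the
wall's vertical — **one concrete interpretation** of a trunk-lean parameter;
other readings (e.g. shoulder-line vs hip-line torsion) are possible and
would need only a different series definition.

## Filtering

Smoothing uses a zero-phase (forward–backward) Butterworth low-pass of order
4, so event times read off the filtered curve are not lagged. The filter is
applied to the keypoint **coordinate** tracks, which are then differentiated
— the standard biomechanics order of operations. Filtering the velocity
directly was tried and rejected: limb transfers between holds produce
~5–8 m/s velocity "bells" whose sharp flanks make the zero-phase filter ring
into the adjacent zero-velocity plateaus, corrupting exactly the signal the
contact detector needs. The default cutoff is a fixed 6 Hz (appropriate for
human movement sampled at 24 fps); a spectral auto-selection — the frequency
below which 95% of the DC-removed energy lies — is available via
`lowpass_cutoff_hz="auto"`, but is a poor default here because the COG
velocity of a near-constant-speed climb is noise-dominated, which drives the
energy criterion toward the noise band.

## Contact detection

On the filtered limb-speed curve (wrists for hands; big toe for feet, ankle
when the toe is mostly unobserved), candidate contacts are the connected
regions with speed < ε (default 0.15 m/s). Each region is extended outward
while the speed stays below a hysteresis level of 2ε — at σ = 2 px keypoint
noise the plateau noise floor sits almost exactly at ε, so without hysteresis
noise wiggles split and truncate contacts — and then expanded to the
neighbouring inflection points of the curve (sign changes of the discrete
second difference, located at the half-sample and rounded toward the
contact): the descending-edge inflection marks the touch, the ascending-edge
inflection the release. Boundary inflections must themselves lie on a real
speed edge (≥ 2ε), because the zero-phase filter pre-rings ahead of a large
move and plants spurious near-zero inflections just outside the plateau. The
search is capped at the adjacent major maximum; an edge without any
inflection (a pure concave arch, or the series end) keeps the hysteresis
edge as its boundary. Finally, two candidate intervals merge unless the limb
actually travelled between them — the speed in the gap must reach
max(2ε, 15% of the series maximum), which separates multi-metre-per-second
transfer moves from sub-0.5 m/s noise excursions by an order of magnitude.

The exported interval is inflection-to-inflection (it deliberately includes
the final reach and initial release phases and is therefore systematically
wider than the stationary span); the contiguous sub-ε span is exported
alongside as an auxiliary column. Touched holds are assigned by
pan-compensated proximity at the interval midpoint, within a radius of
1.2 × the median detected hold width.

## HSV hold segmentation

The classical (detector-free) segmenter maps RGB to HSV, thresholds a
wraparound-safe hue band (default red, 0.95–0.08) with image-adaptive
saturation/value quantile thresholds — value adapts to a moving spotlight,
which scales V but not H — cleans the mask with morphological opening and
closing (disk radius 2), and keeps connected components above a minimum area.
The saturation threshold is floored at 0.2 so that near-gray (wall, chalk)
pixels, whose hue is numerically 0 and falls inside the red band, can never
enter the mask when coloured holds occupy only a small image fraction.

## Sections and run parameters

Wall sections default to Start = hand holds 1–5, Middle I = 6–8, Middle II =
6–12, End = 12–20; each section is the time window between the first touches
of its boundary holds, and sections whose boundary hold was never touched are
marked unavailable rather than guessed. The End-section bounds extrapolate
the published scheme for the lower wall and are user-overridable. Path length
integrates the filtered COG speed; SpeedSectionEnd averages the last three
frames of the section (a single frame is noise-dominated). The run's end time
runs from a start trigger — COG speed above 0.3 m/s sustained for 3 frames,
both configurable, since no standard start event exists in the data — to the
first touch of the top hold.

Run synchronization shifts two runs' time axes so a chosen hold's first touch
is t = 0 in both, and optionally warps one axis onto the other piecewise-
linearly through the shared hold-touch times.

## The synthetic generator

The generator emulates the study conditions end to end: a climber ascending
from the start pad at 1.5 m/s (with a 15% sinusoidal speed modulation, period
2.5 s, as a mild realism term; modulation 0 gives the constant-velocity
condition), hands dwelling on the hold ladder while the COG traverses a
[−0.85, 0] m reach window around each hold (feet reuse the ladder lower, at
[+0.45, +1.30] m) — contact times of ≈ 0.5–0.8 s, realistic for elite runs —
with quintic-smoothstep (minimum-jerk) transfers whose velocity vanishes at
both plateau edges; only dwells whose touch *and* release fall inside the run
are scheduled, since a contact truncated by the recording has no event to
detect. The skeleton is a 25-keypoint stick figure around the pelvis centre;
the ground-truth COG is the anthropometric COG of that pose (the COG is an
affine combination of keypoints, so it commutes with the affine camera).

The camera projects p_px = centre + sᵢ·(p_m − cam_i) with sᵢ = A·cos αᵢ
(defaults A = 400 px/m, B = 5000 px, α₀ = −0.2 rad, 1280×720 at 24 fps),
where α integrates the same recurrence the calibrator inverts; in tracking
mode γᵢ = sᵢ·Δy_COG keeps the athlete vertically centred, or an explicit α
schedule can be prescribed. Keypoints get N(0, σ²) noise (σ = 2 px) and 5%
i.i.d. dropout; detections get σ/2 centre jitter; match pairs are static wall
points displaced by exactly −γᵢ plus a 20% outlier fraction with horizontal
displacement — matcher outliers, not Gaussian jitter, are the failure mode
the shift estimator must survive. One modelling consequence: the per-frame
affine projection makes the compensation identity v ≡ 0 for a static climber
exact only when s is constant between frames, so the identity test prescribes
an alternating ±α pan (constant s, nonzero γ every frame); under a varying-s
pan the identity holds to first order, which is also the regime of the
published velocity equation.

What passing these tests shows: the pipeline inverts its own generative
assumptions — exactly at σ = 0, and stably under realistic keypoint noise,
dropout and outlier rates. What they do not show: robustness to the ways real
video violates those assumptions — pose-estimator identity switches and
gross mislocalisations, perspective foreshortening beyond the affine model,
horizontal pan and roll, motion blur, occlusion by the other athlete, or
detector misses clustered in time. The bundled route map is a constructed,
approximately-IFSC-like layout (non-uniform ladder spacings over 1.0–15.0 m),
not the official coordinates; analyses of real video should supply a measured
map via `--route-map`.

## Problem sizes and determinism

Default synthetic runs are 6 s (144 frames); the constant-velocity condition
uses 7 s so the Middle II boundary (hold 12) is reached. These sizes make the
full test suite and the acceptance script each run in well under a minute
while leaving every stage's recovery target measurable. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; a (config,
seed) pair reproduces byte-identical artifacts, and repeated analyses of the
same run export byte-identical CSVs.
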