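# speedkin

Markerless 2D kinematics of **speed-climbing** runs from monocular video
features: given per-frame human-pose keypoints (OpenPose BODY_25 JSON) and
climbing-hold detections (any object detector's boxes as CSV), `speedkin`
estimates the panning camera's motion, calibrates the pixel-to-metre scale
against the standardized 15 m route map, and computes joint angles,
centre-of-gravity (COG) kinematics and hold contact times — the quantities
coaches use to compare athletes and techniques across different recordings.
It is aimed at sports scientists and climbing analysts who have video-derived
detections but no calibrated camera and no sensors on the wall.

## The model

The speed wall is identical worldwide (15 m × 3 m per lane, 5° overhang,
20 hand + 11 foot holds at fixed positions), and competition cameras sit on a
tripod, rotating vertically to keep the athlete centred. Three ideas make
uncalibrated video metrically useful:

1. **Camera shift.** Between consecutive frames every static wall feature
   moves by a common vertical pixel offset γᵢ. Matched feature pairs are
   filtered to vertical, mutually consistent displacements (|Δx| ≤ tol, then
   a median ± k·MAD band) and averaged per frame.

2. **Scale.** The pixel-per-metre scale follows the camera angle,

       sᵢ = A·cos(αᵢ),   αᵢ₊₁ = (γᵢ / B)·cos(αᵢ) + αᵢ,

   with amplitude *A* (px/m), gain *B* (px) and start angle α₀ fitted by
   bounded nonlinear least squares to direct scale measurements
   s = ½(|Δx_px|/|Δx_m| + |Δy_px|/|Δy_m|) taken from pairs of identified
   holds whose true separation the route map provides.

3. **Kinematics.** The COG is the segment-mass-weighted sum over 12 body
   segments, C = Σ_b m_b·(j_{p,b} + r_b·x_b), using a standard male
   anthropometric table (m_b mass fraction, r_b centre-of-mass ratio, x_b the
   segment vector from its proximal joint j_{p,b}). Camera-compensated metric
   velocity is vᵢ = (Cᵢ₊₁ − Cᵢ + γᵢ)·φ / sᵢ at frame rate φ. A limb parked on
   a hold has near-zero speed, so contacts are read off the filtered
   limb-speed curve as valleys bounded by the neighbouring inflection points;
   touched holds are identified by proximity to the tracked hold boxes.

A synthetic-climb generator (`speedkin synth` / `speedkin.synthetic`)
produces pose JSON, match pairs, detections and a full ground-truth record
for a simulated ascent under exactly these assumptions, and backs every test
in the suite.

## Worked example

Generate a synthetic 6 s run (144 frames at 24 fps, 2 px keypoint noise, 5%
dropout, 20% match outliers) and analyze it:

```
$ speedkin synth --seed 7 --out demo/run
wrote 144 frames to demo/run

$ speedkin analyze --pose demo/run/pose --detections demo/run/detections.csv \
      --matches demo/run/matches.csv --out demo/out
frames: 144  contacts: 21  scale A: 400.0 px/m
```

The generator's camera had A = 400 px/m, B = 5000 px, α₀ = −0.2 rad; the fit
recovers A = 400.02 px/m, α₀ = −0.217 rad (`demo/out/run_summary.json`).
`demo/out/contacts.csv` starts:

```
limb,hold_kind,hold_id,t_touch_s,t_release_s,duration_s,...
left_hand,hand,1,0.0833,0.6250,0.5417,...
left_hand,hand,3,0.8750,1.5833,0.7083,...
left_hand,hand,5,1.9167,2.6667,0.7500,...
```

i.e. the left hand gripped hand-holds 1, 3, 5, … with contact times around
0.5–0.75 s — matching the simulated dwell schedule hold for hold. The other
exports are `cog.csv` (pixel/metric COG and velocity), `angles.csv` (elbow,
knee and trunk shoulder–hip angles), `camera.csv` (γ per frame), `scale.csv`
(α, fitted and measured s) and `parameters.csv` (end time, per-section path /
speed statistics, contact-time and trunk-angle statistics).

`speedkin compare demo/out demo/out2 --at-hold 5` time-aligns two exported
runs at a shared hold and prints the piecewise-linear warp knots.

Real recordings are analyzed the same way: export OpenPose JSON per frame,
dump your hold detector's boxes as `frame,class,x,y,w,h,confidence`, and your
feature matcher's pairs as `frame,x_prev,y_prev,x_curr,y_curr`.

## Limitations

2D only: all kinematics live in the wall plane; out-of-plane motion projects
into it. The camera model assumes a vertically rotating tripod — horizontal
pan, roll and lens distortion are not modelled. Feature detection, pose
estimation and hold detection themselves are upstream tools; `speedkin`
consumes their outputs.
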