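# Methods

## Scope and intent

`optoloop` models the software of a closed-loop all-optical cardiac mapping
rig, with the heart, camera and projector replaced by deterministic stand-ins.
The object of study is the *control loop* — frame hand-off, the ROI detector,
the stimulation protocol, and their failure modes under load — not cardiac
electrophysiology per se. The tissue model is therefore deliberately the
simplest one that produces physically plausible input for that loop.

## The virtual heart

### Wave model

Tissue is an activation-time (eikonal-style) model on the camera grid rather
than a reaction–diffusion PDE. A stimulus at time t captures every
non-refractory pixel under its mask; from the captured set, each remaining
pixel is assigned an arrival time t + d/CV, where d is the Euclidean distance
between pixel centers to the nearest captured pixel
(`scipy.ndimage.distance_transform_edt`) and CV the conduction velocity. An
arrival activates its pixel only if the pixel has been recovered for at least
the refractory period; otherwise the arrival is discarded. This choice trades
curvature effects, restitution and true re-entry around refractory obstacles
for determinism, speed and analytic testability: activation times are exactly
d/CV, so wave-speed recovery and the loop-period closed form can be asserted
to tight tolerances. For the apex→base geometry used throughout, discarding
blocked arrivals (rather than diffracting around the refractory tail) is
adequate, and is a stated simplification.

### Action potential and optics

Each pixel follows a piecewise-linear template V(τ): a linear upstroke
(default 2 ms) to 1, a plateau (40 ms), a linear repolarization ramp (20 ms)
back to 0. Refractoriness (default 70 ms) must be at least upstroke + plateau.
Fluorescence is rendered per frame as a point sample at frame time (the
exposure only sets the frame interval; the detector operates on per-frame ROI
means, so exposure-window integration would add nothing the loop can see):

    F = F0 * (1 - s * V(tau)) + N(0, sigma * F0)

rounded half-away-from-zero and clipped to 16 bits. The dye signal is
negative-going (depolarized tissue is darker), with sensitivity s = 4% of F0
by default. Per-pixel noise is independent Gaussian with sigma = 0.4% of F0,
chosen so the mean over the default 4-pixel detection ROI has a standard
deviation of ~0.2% of F0 — the upper end of realistic ROI-level shot noise at
rest; real sensors add structured noise (dark current, fixed-pattern, photon
shot scaling with signal) that this model does not attempt.

Default geometry: 128×128 px over 10×10 mm (px = 78.125 µm), mm origin at the
outer corner of pixel (0, 0), x along columns, y along rows, rectangle
selections half-open in mm. The stimulation spot is a 1 mm circle at the apex
(5.0, 9.5) mm; the detection ROI is 0.1 × 0.3 mm at the base, which maps to
1 × 4 pixels at this resolution (the ROI's pixel dimensions and alignment are
configurable, since rounding a 0.1 mm window onto a 78 µm grid is inherently
alignment-dependent).

## The event engine

Both loops run on an integer-microsecond simulated clock; simulated time is
authoritative (no wall-clock threading), which makes every session
bit-reproducible from its configuration and seed.

- The camera free-runs: frame k is rendered and published at exactly
  k · exposure_us.
- The camera→IL hand-off is a single-slot mailbox: publishing over an unread
  frame counts it as lost. The IL reads the slot at max(il_free, publish
  time); on an exact tie with the next publish, the read wins, so an IL cost
  equal to the exposure is still loss-free. The steady-state loss fraction
  under constant IL cost c > exposure e is 1 − e/c.
- Each stacked frame is offered to the RTL at the moment it lands in RAM
  (read time + IL cost). It is skipped as `protocol-window` if the detector
  is disarmed (intentional), as `rtl-busy` if the RTL is still processing an
  earlier frame (capacity), or `rtl-off` in free-run mode; otherwise it is
  analyzed and the detection, if any, is stamped at the RTL completion time.
- A detection disarms the detector, schedules the light pulse at
  t + pre-delay (the tissue is excited once, at pulse onset; channel kinetics
  are ignored and the pulse width only shapes the log and the re-arm time),
  and re-arms with an empty buffer after pre + pulse + post. The buffer reset
  is applied at the trigger, which is observationally equivalent to resetting
  at the window's end because no sample reaches the detector while disarmed.

The detector itself is a shift register of up to `buffer_len` past ROI means
(default 10 — at 1–2 ms exposure this spans a murine upstroke while keeping
the comparison window short). A depolarization is declared when any
(bᵢ − m)/bᵢ strictly exceeds Th; only positive variations (fluorescence
drops) count, and the triggering mean is not appended. The error-rate metrics
mirror the accounting classes: IL error = lost/produced; RTL error =
rtl-busy/(acquired − protocol-window), excluding intentional skips from both
sides so the metric measures capacity rather than protocol design.

## Period closed form

Each tachycardia cycle decomposes as pre-delay + travel + detection latency:
travel is the spot-to-ROI distance over CV, and the latency is the fraction
Th/s of the upstroke (the time for ΔF/F to reach threshold) plus at most one
frame interval of sampling quantization. `predict_period` returns the
interval obtained from the nearest/farthest ROI pixel; it assumes zero
processing costs, noise off, and a period longer than the refractory period
(otherwise the spot is not recaptured and the rhythm dies).

That last assumption dictates a study-condition choice in the period sweep:
at pre-delay 50 ms with CV ≥ 0.5 mm/ms the loop period (~62–68 ms) would fall
below the default 70 ms refractoriness, so the sweep uses a faster-recovering
tissue (plateau 25 ms, ramp 15 ms, refractory 45 ms), keeping every swept
period above refractoriness while respecting the template's constraints.

## Offline analysis

`offline_detect` replays the identical detector semantics over a recorded
trace, skipping samples strictly inside blanked intervals and clearing the
buffer at each interval's end; with the protocol windows from the session log
it reproduces the online detection times exactly on zero-cost runs, which is
the package's oracle-equivalence check. The activation-map estimator assigns
each pixel the midpoint of the frame pair with the steepest fluorescence
*decrease* (matching the dye polarity; a 50%-crossing estimator would need a
per-pixel baseline first), gated by a minimum signal excursion (default half
the full AP depth); a linear fit of distance versus activation time recovers
CV to well under 5% at 1 ms sampling.

## Problem sizes and numerical choices

The stability recording is 3 simulated minutes at 2 ms exposure (90,000
frames), the stress recordings 90 s, matching the instrument's own test
protocol; oracle-equivalence runs use 2 s windows per seed, and wave-recovery
analyses a single 40 ms wave at 1 ms sampling — each long enough for the
quantity it measures. Timestamps are integer microseconds (sub-millisecond
protocol steps need better than ms resolution; integers keep the engine
exact); tissue arrival times are floats. TIFF output is single-image,
uncompressed, 16-bit grayscale, one file per frame named by its zero-padded
12-digit timestamp, so lexicographic order is chronological for sessions up
to ~11.5 days; round trips are bit-exact. Fluorescence rounding is
half-away-from-zero before clipping.

## Known limitations

- No ionic model: no APD restitution, rate adaptation, curvature, or
  source–sink effects; light intensity does not modulate excitability (LED
  drive settings are logged but physically inert).
- The single-slot hand-off is one plausible loss mechanism; a camera library
  with deeper buffering would lose frames differently (slot depth beyond 1 is
  not modelled).
- Noise is white and Gaussian per pixel; no photobleaching, motion, or
  illumination drift, so passing detector tests here does not bound
  false-trigger rates on real recordings with structured artefacts.
- The wall-clock/threaded operating mode of a real rig is out of scope; all
  timing claims are about the simulated clock.
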