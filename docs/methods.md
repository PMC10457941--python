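# Methods

This note records the models, numerical choices and assumptions behind
`impactkin`, and what the synthetic campaigns do and do not demonstrate.

## Signal model and frames

All kinematics live in a right-handed ISO-style anatomical head frame:
x anterior, y left, z superior. Sensor channels are related to it by a
constant 3×3 rotation supplied in configuration. Units are SI internally
(m/s², rad/s, rad/s²); accelerations cross the API boundary in g where a
device would report them, with 1 g = 9.80665 m/s².

A `TimeSeries3` is a uniformly sampled (N, 3) array with a rate, a start
time, a unit tag and a frame tag. `HeadKinematics` bundles the three
centre-of-mass series (linear acceleration, rotational velocity, rotational
acceleration) for one event.

## Mouthguard chain

Stages, in fixed order: (1) the 1666 Hz gyroscope is linearly interpolated
onto the 1 kHz accelerometer timebase; (2) both channels are rotated into
the head frame; (3) rotational velocity is low-pass filtered; (4) rotational
acceleration is the five-point-stencil derivative of the *filtered*
velocity; (5) linear acceleration is filtered and transformed to the centre
of mass using the filtered rotational kinematics.

Assumptions the device documentation leaves open, decided here:

* **Filter phase.** The 160 Hz 4th-order Butterworth is applied zero-phase
  (forward–backward), which doubles the effective order and preserves peak
  timing — essential for the peak-based time alignment downstream. Edges are
  padded by reflection with pad length ≥ 3× the filter order.
* **Gyroscope resampling.** Linear interpolation. The signal is later
  band-limited to 160 Hz, far below either Nyquist rate; the interpolation
  error bound h²·max|f″|/8 is ~4e-3 relative for a 50 Hz component at
  1666 Hz, and smaller after filtering.
* **Stencil edges.** The first/last two samples use one-sided second-order
  differences, keeping series length without extrapolation. Interior samples
  use the five-point central stencil, exact for polynomials of degree ≤ 4.
* **Rotation before filtering.** Filtering is linear and the rotation is
  sample-wise constant, so the order is mathematically irrelevant; it is
  fixed (rotate first) for reproducibility.
* **Filter-before-stencil.** For an ideal LTI chain differentiation and
  filtering commute; on finite windows they differ through edge handling,
  and on a real device the intervening nonlinearities (clipping,
  quantization) break commutativity. The chain fixes filter-first.
* **Trigger.** Raw (unfiltered) sensor-frame axes, |a| > 10 g on any single
  axis; the window is 10 ms pre to 94 ms post, the trigger sample belonging
  to the post segment (105 samples at 1 kHz). A trigger earlier than 10 ms
  into the record truncates the window and flags `missing_pretrigger`.
* **Saturation.** |sample| ≥ full scale counts as saturated (a clipped
  sample reads exactly full scale): ±400 g accelerometer, ±35 rad/s
  gyroscope, checked on the raw channels.
* **Lever arm.** The sensor-to-CoM vector defaults to (0, 0, −0.08) m in
  the head frame — a nominal dentition offset, configurable and never
  hard-coded, since real mounting geometry is device- and subject-specific.

QC policy: gyroscope (or accelerometer) saturation excludes a trial from
all analysis; a missing pre-trigger keeps the trial for peak statistics but
removes it from time-series (RMSE) statistics, whose aligned window needs
the full lead-in.

## Reference headform chain

The nine 50 kHz channels (centre triax plus three orthogonal two-channel
arms at ρ = 0.0635 m, configurable) are zero-phase filtered at 1 kHz, the
angular acceleration is obtained from half-differences of opposing channels
(centripetal terms cancel pairwise, so the inversion is exact and linear for
rigid motion), angular velocity follows by cumulative trapezoidal
integration from ω = 0 at the window start (a dropped headform begins in
spin-free free fall), and the centre triax is the CoM linear acceleration.

Outputs are decimated to 1 kHz (every 50th sample; the 1 kHz cutoff is at
the decimated Nyquist) for paired comparison with the mouthguard. **Peak
metrics are read from the native-rate filtered series before decimation**:
sampling a 6 ms biphasic pulse at 1 kHz can miss its true peak by up to
~13% purely through sampling phase, which would corrupt the reference
against which the mouthguard is judged.

## Virtual drop-test rig

Ground truth for one impact of duration T (impact onset 50 ms into the
record, ≥100 ms of quiet tail):

* linear CoM acceleration: haversine `a(t) = A sin²(πt/T)` along a unit
  direction;
* rotational acceleration: single-cycle sine `α(t) = P sin(2πt/T)` about a
  unit axis, with `P = πV/T`, so rotational velocity rises to its peak V at
  T/2 and returns to zero at T — the direction reversal characteristic of
  oblique impacts.

Impact locations map to head-frame directions (front: −x/+z, rotation about
y; side: +y/+z, rotation about x; rear mirrors front; rear-side is the 45°
blend). The speed→magnitude maps are linear between the envelope extremes
16 g / 11.3 rad/s at 2 m/s and 171 g / 41.5 rad/s at 8 m/s; durations are
drawn uniformly from 6–18 ms, floored at `πV/12,000` so the derived
rotational pulse amplitude never exceeds 12,000 rad/s².

Virtual sensors sample the exact rigid-body field
`a(r) = a_com + α×r + ω×(ω×r)` at their mounting position, rotate it into
the sensor frame, resample to the device rate, then apply Gaussian noise,
12-bit mid-tread quantization over the full-scale range, and clipping.
Default imperfections: accelerometer noise 0.3 g SD, gyroscope noise
0.03 rad/s SD, mounting misalignment up to 2° about a random axis (unknown
to the processing chain, which uses the nominal rotation), quantization on.
These are plausible device-scale magnitudes chosen once; they are not a
calibrated model of any particular hardware. Gravity is omitted: a dropped
headform is in free fall (sensors read ~0 g) and impact magnitudes dwarf
1 g; the switch is a one-line change in the sensor model if needed.

### Campaign presets

* **Default campaign** (`default_campaign`): 80 trials, random
  location/speed draws over 4 locations × speeds 2–8 m/s, durations
  6–18 ms, full noise model. Speeds above ~6.7 m/s drive the rotational
  velocity past the ±35 rad/s gyroscope range; those trials saturate and are
  excluded by QC, as in a real drop matrix that brackets the sensor's range.
* **Noise-free verification campaign** (`noise_free_campaign`): the
  4 locations × {2, 4, 6} m/s grid, no noise/quantization/misalignment,
  durations 15–18 ms. Speeds stay below the gyroscope range so all 12
  trials survive QC, and durations sit where the 160 Hz filter passes the
  pulse to better than 2%, so the ≤2% end-to-end recovery check verifies
  the implementation rather than measuring designed filter attenuation.

### What the rig does and does not emulate

The pulses are idealizations: real impacts have multi-lobe, asymmetric
acceleration histories whose spectral content lies almost entirely below
160 Hz even at 6 ms durations, whereas the single-cycle sine concentrates
rotational energy exactly at f = 1/T. Consequently the virtual mouthguard
loses far more of a 6 ms pulse's rotational-acceleration peak (~44%) than
real devices lose on real 6 ms impacts (mean relative errors near 7%). The
rotational-acceleration concordance of the noisy campaign (CCC ≈ 0.82–0.94
across seeds) is therefore dominated by this designed spectral mismatch,
not by the noise model. Passing campaigns demonstrate numerical correctness
and end-to-end consistency of the chains — not field validity of any real
device, and not the behaviour of real signals under bite/shout noise, which
the rig does not model.

## Agreement battery

* **Alignment.** Threshold alignment shifts each trace so 10 ms before its
  10 g resultant crossing is t = 0 (35 ms compared, 35 samples at 1 kHz).
  Peak alignment — used for RMSE/nRMSE — takes the raw mouthguard
  accelerometer axis with the largest absolute value (ties broken in
  x, y, z order) and applies a single window from 10 ms before to 25 ms
  after that raw peak to both systems on the common timebase.
* **CCC.** Lin's estimator with population (1/n) moments; CI via the
  Fisher z-transform with Lin's asymptotic variance. The combined validity
  figure is the unweighted mean of the three per-metric CCCs.
* **Bland–Altman.** Differences ATD − iMG (positive bias = mouthguard
  underestimation), expressed as percentages of the reference value; limits
  are bias ± 1.96 × sample SD; bias CI by Student's t.
* **OLP regression.** Reduced-major-axis slope `sign(r)·s_y/s_x`; slope CI
  `b(√(B+1) ± √B)` with `B = F₀.₉₅(1, n−2)(1−r²)/(n−2)`; intercept CI from
  the slope CI endpoints. Fixed bias ⇔ intercept CI excludes 0;
  proportional bias ⇔ slope CI excludes 1.
* **Relative error.** Reported with the absolute-value convention
  `|ATD − iMG|/ATD × 100` (mean ± SD); the signed mean is computed and
  serialized alongside, since published summaries are ambiguous about the
  convention and the two differ exactly when errors change sign across
  trials.
* **RMSE/nRMSE.** Per trial on resultant traces over the peak-aligned 35 ms
  window, normalized by the reference's range within the window; the report
  carries across-trial mean ± SD. RMSE is invariant under adding a common
  constant to both traces; nRMSE is not, because its denominator tracks the
  reference's range.

Degenerate inputs (zero variance, flat reference, fewer than 3 usable
pairs) raise typed errors rather than returning NaNs.

## Numerical tolerances used in the tests

Oracle tolerances are derived from the numerics, not tuned: stencil
truncation `h⁴·max|f⁽⁵⁾|/30`, linear-interpolation bound `h²·max|f″|/8`,
trapezoid O(h²), array-inversion round-off ≤ 1e-6 rad/s² at 50 kHz, and the
zero-phase filter's stop-band gain evaluated from its own design (|H|²).
Campaign-level checks use the problem sizes above (12 and 80 trials at a
50 kHz master rate), which keep the full suite and the acceptance script in
the seconds range on one CPU.

## Known limitations

* The rig's pulse family cannot reproduce the full joint distribution of
  published drop matrices (e.g. a 1330 rad/s² rotational peak with an 11.3
  rad/s velocity peak would need a ~27 ms duration, outside the 6–18 ms
  envelope).
* No orientation tracking or gravity compensation; the sensor-to-head
  rotation is constant per event.
* On-field artifacts (bite, shout, device rattle) and helmet/anvil contact
  mechanics are out of scope; impacts are prescribed pulses.
* The mouthguard's 160 Hz filter attenuation of short biphasic pulses is
  inherent to the prescribed chain; consumers comparing against it should
  treat short-duration rotational-acceleration peaks as lower bounds.
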