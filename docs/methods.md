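# Methods

This note records the modeling choices behind `echospace`: the governing
equations and their discretization, the signal chain from excitation to
echo incidence point, what the synthetic generators emulate, and the
numerical decisions made where the design was genuinely open.

## Acoustic model

The solver integrates 2D linear acoustics — pressure p and particle
velocity u on a staggered Cartesian grid, advanced leapfrog-style:

    p_ij^{n+1}       = p_ij^n − (κ_ij Δt/Δ) (div u)^{n+1/2}
    u_face^{n+1/2}   = u_face^{n−1/2} − (Δt/(ρ_face Δ)) (grad p)^n

with face densities the arithmetic mean of the two adjacent cells.

**Constant-speed media.** The per-cell modulus defaults to κ = ρ c₀²
with one global reference speed c₀ = 340 m/s, so every medium
propagates at c₀ and differs only in its characteristic impedance ρc₀.
An acrylic plate (ρ ≈ 1.18 × 10³ kg/m³) is then ~915 times harder than
air — reflection coefficient 0.998, effectively rigid — while the
explicit scheme stays stable at a single Courant number (c₀Δt/Δ = 0.57
at the full-resolution defaults; the 2D bound is 1/√2). This is the
only self-consistent reading of the scheme: taking acrylic's physical
bulk modulus literally would put a 2730 m/s medium inside a grid tuned
for 340 m/s and the stated Courant number could not have been stable.
`use_material_modulus=True` restores physical moduli (with the
stability bound then governed by the fastest medium), and
`rigid_obstacles=True` switches obstacles to hard (zero-velocity)
inclusions. Consequences of the constant-speed default: all delay
arithmetic (pairing window, ellipse inversion, geometric oracle)
consistently uses c₀ = 340 m/s, and the tabulated air modulus
(142 kPa, which would imply 331.8 m/s) only matters in the
material-modulus mode.

**Boundaries.** The outer boundary uses the Mur second-order one-way
condition, first-order diagonal updates at the corners. Two practical
amendments proved necessary: (1) where a dense obstacle touches the
boundary (plates attached to the corridor wall) the second-order
stencil is unstable, so boundary cells whose stencil sees dense cells
fall back to first-order Mur, and dense boundary cells themselves are
truncated rigidly (pressure mirrored from the interior neighbor);
(2) the grid size is rounded up only beyond a small tolerance, because
float fuzz in the scene extent would otherwise insert a spurious
one-cell air slit between a wall-attached plate and the boundary — a
resonant defect that also destabilizes the run. Only geometric
spreading attenuates the waves; air absorption is not modeled.

**Sources and receivers.** Each emission injects the excitation
additively ("soft" source) at the two cells nearest the nostril
positions (±1.25 mm perpendicular to the heading). Two in-phase sources
half a wavelength apart at 68 kHz radiate a broadside pattern: strongest
forward *and* backward along the heading, weakest along the pair axis.
(The forward/backward symmetry is why obstacles behind the emitter are
removed before simulating — `occlude_behind` drops every plate lying
entirely behind the line through the emission point perpendicular to
the heading.) Receivers sample the pressure at the cells nearest the
ear positions (±10 mm); at the default resolution the placement error
is tiny against the ~5 mm wavelength. Both ear traces are normalized by
the direct wave's peak — one common factor, so interaural level
differences survive — making later amplitudes interpretable as levels
relative to the emitted call heard at the ear.

## Signals

* **Excitation:** a time-symmetric truncated sinc, flat to 110 kHz,
  0.073 ms long (rectangular truncation; a Hann taper is available).
  Receiver traces under this excitation are the impulse responses.
* **Call:** three harmonics of a fundamental sweeping linearly
  34 → 25 kHz over 2 ms; first and third harmonics 40 dB below the
  second. Convolving the impulse responses with the call synthesizes
  the echoes the ears would hear. No absolute SPL calibration is
  attempted; all amplitudes are relative.

## Echo detection and localization

**Matched filter.** Each ear's echo is cross-correlated with the call
and normalized by the call's autocorrelation peak; peaks above 0.02
count as echoes. Two realities complicate the textbook picture. First,
an FM sweep's compressed pulse has range sidelobes around −13 dB, and
the three-harmonic structure adds ambiguity combs, so any strong echo
would spawn spurious threshold crossings; peak extraction therefore
uses CLEAN-style iterative subtraction — find the strongest envelope
peak, subtract the unit-echo reference response at that (fractional)
delay, repeat — followed by a joint least-squares polish of all
component positions and complex amplitudes (per-component local error
windows, so a strong neighbor's residual cannot drag a weak echo).
Second, the ideal excitation is not what the field delivers: the soft
source, the 2D cylindrical afterglow and grid dispersion color the
wavelet. The unit-echo reference is therefore *measured* by a cached
free-field calibration run (same source pair, receiver down-range, the
trace cut exactly at the nominal arrival so the solver's small delay
bias is absorbed into the template). Edge-diffracted echoes carry an
additional ~e^{±iπ/4}/√f coloring, so diffraction-colored template
variants participate in the polish and each component keeps the best
fit.

**Amplitude scale.** The 0.02 threshold is applied on a scale where the
strongest post-gate echo is 1 (a common factor for both ears). The
alternative — relative to the direct wave — would discard edge echoes
(~0.013 of the direct level) wholesale; the working threshold's purpose
is to detect almost all genuine peaks, which the strongest-echo scale
achieves for any source level. A floor (`min_echo_level`, default 1%
of the direct wave) prevents boundary debris from being amplified to
full scale when a pulse has no real echoes.

**Direct-wave handling.** The emitted call reaches the ears within the
head geometry's travel time plus the excitation length — well before
the first obstacle echo *in the impulse-response domain* — so the
direct wave is excised there (zero + short cosine ramp) before the call
is convolved in. Its near-field, dual-source waveform matches no
far-field template and would otherwise dominate and destabilize the
extraction. Obstacles closer than roughly half the excised window
(≈5 cm at desk scale) are inside the direct window and undetectable.

**Timing refinement.** The call's effective bandwidth (the dominant
second harmonic's sweep) limits delay precision, and the ellipse
inversion amplifies interaural-delay errors by roughly range over ear
separation. Detection and amplitudes therefore come from the call
correlation, but each detected delay is re-timed on the broadband
impulse response (same CLEAN machinery, wavelet-autocorrelation
template), and each paired echo's interaural difference is refined once
more as the average of the per-ear estimate and a direct binaural
cross-correlation of the two ears' broadband windows (window ≈ twice
the wavelet-correlation main lobe). The two estimators err through
different mechanisms — template mismatch versus window truncation — and
their mean is the steadier value. The residual interaural bias floor is
of order ±1 µs, i.e. a few millimeters of lateral position at desk
scale; geometries with strongly overlapping echoes can show larger
errors.

**Pairing and inversion.** Left/right peaks are matched one-to-one
minimizing the total |t_l − t_r| (Hungarian assignment; equivalent to
greedy matching in the common cases but optimal in ties), keeping only
pairs within the interaural window. The library default window is the
documented 2.5 mm/340 m/s = 7.4 µs (derived from the *source*
separation); desk-scale configurations use the geometric bound from the
20 mm ear separation (≈59 µs), because full-size ears on a scaled scene
receive off-axis echoes with interaural delays the narrow window would
reject outright. In the emission-local frame (ears on the x axis,
heading along +y) both delay ellipses are axis-aligned with centers on
the inter-ear axis; eliminating y² leaves a quadratic in x solved in
closed form, and the forward root (+y) is kept. When two forward
intersections exist, the one nearer the previous accepted point of the
same pulse wins, then the one nearer the emission axis. Points are
assigned to the nearest plate within 2 cm, else marked unlocalized.

## Synthetic scenes and the geometric oracle

The generators emulate the study conditions: a 4.5 m × 1.5 m corridor
with three 1 m plates alternating left/right 1 m apart; slalom flights
sampled at 125 frames/s (C² spline through waypoints that pass each
plate's free inner edge on the open side, constant speed 4 m/s at full
scale, waypoint offsets widened automatically until the sampled path
genuinely keeps the requested clearance); pulse trains with inter-pulse
intervals uniform in 40–80 ms aimed near the flight direction with
±0.1 rad jitter. All randomness is seeded.

Desk-scale variants shrink the geometry by 1/5 and run at Δ = 1 mm,
1/Δt = 0.5 MHz. The call/excitation band is scaled by 0.3 — the ratio
of grid spacings — so the number of cells per wavelength matches the
full-resolution setup; the excitation duration stretches by the inverse
factor. Ear and nostril offsets stay at their anatomical values.

The **geometric oracle** predicts first-order echoes without waves:
circles return one direct echo from the near-surface point; plates
return a specular echo when the image-source path to each ear reflects
within the segment (reflection taken at the near *face*, since plates
have thickness) plus an edge echo from each visible face corner.
Delays are exact path lengths over c₀; amplitudes are a crude inverse
square of mean path, qualitative only. The oracle covers single-bounce
paths; the FDTD also contains multiple scattering the oracle does not
predict.

The validation fixture (`one_plate_fixture`) is deliberately shaped so
each first-order echo can be verified individually: a single plate in a
0.9 m × 0.6 m domain (wide enough that residual boundary reflections
arrive after the last first-order echo), grid-aligned (a tilted plate
rasterizes into staircase steps whose diffraction rivals the true edge
echoes at this grid spacing), one cell thick (thicker plates return
near/back-corner doublets that a point-scatterer model mis-times), with
the emitter 85 mm off the face aimed 40% along the plate so all
per-ear delay separations exceed the matched filter's resolution. On
this fixture the chain reproduces every oracle delay within ~1.3% and
every incidence point within ~1.6 grid cells.

What passing these checks does *not* show: performance on real
recordings (motion, noise, 3D effects, real head acoustics are absent),
robustness to heavily overlapping echoes (closely spaced scatterers
merge below the call's resolution and localize to intermediate phantom
points), or calibrated echo levels.

## Behavioral analyses

Turn rate: positions are interpolated with cubic splines (optional
smoothing-spline regularization for noisy tracks), the heading is the
velocity angle, and the turn rate is the centered difference of the
unwrapped heading at 1 ms. Direction series: per pulse, the emission
heading (pulse direction) or the bearing of the highest-amplitude
incidence point (echo direction), minus the instantaneous flight
direction; leftward angles positive; pulses without points contribute
gaps, not zeros. Lagged correlation: Pearson r between the direction
samples and the turn rate read at (pulse time + τ), τ from −100 to
+600 ms in 10 ms steps; confidence bands via the Fisher transform
z(r) ± z_{α/2}/√(n−3) mapped back through tanh; lags with fewer than
four pairs are reported missing; τ_max is the arg-max lag. Edge
distances: points assigned to a plate are projected on the plate axis;
the distance to the free inner edge is kept when ≤ half the plate
length (boundary inclusive), with per-group means ± SE and tidy tables
for external model fitting — mixed-effects modeling itself is out of
scope. The pulses-affected estimate divides a correlation-peak lag
difference by the mean inter-pulse interval; note this stationary-onset
convention differs from counting pulses after an emission by roughly
half an interval (renewal inspection bias).

## Problem sizes

Tests and the acceptance script use the desk-scale settings throughout:
single-pulse scenes of roughly 900 × 600 cells for ~1000 steps, small
propagation domains for the solver unit checks, 1000 Monte-Carlo
replicates for the Fisher coverage, and a handful of pulses for the
end-to-end corridor pipeline. The full-resolution corridor
(15000 × 5000 cells at 0.3 mm) is supported by the same code path but
is a batch-scale computation.
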