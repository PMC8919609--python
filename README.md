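# echospace

Acoustic simulation and binaural echo localization for echolocating bats
in obstacle corridors.

A flying horseshoe bat perceives its surroundings through the echoes of
its own sonar emissions. To study what such a bat could actually hear,
this package reconstructs its *echo space*: for every emitted pulse it
simulates the sound field in the flight corridor, computes the echoes
arriving at the two ears, and inverts the left/right echo delays into
the 2D points the echoes came from — the echo incidence points. The
behavioral layer then relates those points to flight: how close they
cluster to obstacle edges, and how strongly (and at what time lag) the
echo direction predicts the animal's turn rate.

## Method

**Wave simulation.** A 2D staggered-grid finite-difference time-domain
(FDTD) solver integrates the linear acoustics equations

    ∂p/∂t + ρc₀² ∇·u = 0,        ∂u/∂t + (1/ρ) ∇p = 0

leapfrog-style with a Courant number c₀Δt/Δ ≈ 0.57 (defaults Δ = 0.3 mm,
1/Δt = 2 MHz, c₀ = 340 m/s) and Mur second-order absorbing boundaries.
Each emission is modeled as two in-phase point sources 1.25 mm left and
right of the emission point (the nostrils; the separation is half the
half-wavelength of the 68 kHz call component, creating forward/backward
directivity), driven by a sinc excitation flat to 110 kHz. Pressure
recorded 10 mm left and right of the emission point (the ears) gives the
two impulse responses; convolving them with the bat's terminal-FM call
(three harmonics, fundamental sweeping 34 → 25 kHz over 2 ms) yields
realistic ear echoes.

**Localization.** Each ear's echo is cross-correlated with the call,
normalized by the call's autocorrelation peak; correlation peaks above
0.02 are extracted (a CLEAN-style iterative subtraction with a measured
unit-echo template keeps range sidelobes from masquerading as echoes).
Left/right peaks are paired within the maximum interaural travel-time
window, and each pair (t_r, t_l) is inverted geometrically: the locus of
scatterers with round-trip delay t to one ear is an ellipse with the
emission point and that ear as foci and semi-major axis t·c₀/2; the echo
incidence point is the forward intersection of the left and right
ellipses.

**Behavioral analysis.** The turn rate is the 1 ms-resolution time
derivative of the flight heading. Pulse and echo direction series
(relative to the instantaneous flight direction) are correlated with
the turn rate over lags −100…+600 ms in 10 ms steps; 95% confidence
bands come from the Fisher transform, ±z_{α/2}/√(n−3), and τ_max is the
lag of maximal correlation. Edge-distance tables keep incidence points
on the inner half of each obstacle plate, and a lag difference divided
by the mean inter-pulse interval estimates how many emissions later an
echo's information surfaces in behavior.

A geometric echo oracle (image-source specular points plus edge
diffraction from plate corners, exact path-length delays) provides an
independent reference for validating the whole chain, and synthetic
scene/track/pulse generators reproduce the study conditions — a
4.5 m × 1.5 m corridor with three 1 m plates alternating left/right —
plus 1/5-scale desk variants that run in seconds.

## Worked example

Predict and then measure the three first-order echoes of a single plate
(specular reflection plus diffraction from both edges) on the
desk-scale fixture:

```python
import numpy as np
from echospace.scene import EarGeometry
from echospace.synthetic import (
    geometric_echo_oracle, one_plate_fixture, scaled_localize_config,
)
from echospace.localize import localize_pulse

scene, pulse = one_plate_fixture()          # desk-scale plate + one emission
oracle = geometric_echo_oracle(scene, pulse, EarGeometry(pulse))
points = localize_pulse(scene, pulse, scaled_localize_config())

for echo in oracle:
    print(f"predicted {echo.path_type:9s} at ({echo.point[0]:.4f}, {echo.point[1]:.4f}) m")
for pt in points:
    err = min(np.hypot(pt.x - e.point[0], pt.y - e.point[1]) for e in oracle)
    print(f"localized ({pt.x:.4f}, {pt.y:.4f}) m  amplitude {pt.amplitude:.2f}  error {err*1e3:.1f} mm")
```

prints

```
predicted specular  at (0.5520, 0.2780) m
predicted edge      at (0.5520, 0.1900) m
predicted edge      at (0.5520, 0.4100) m
localized (0.5530, 0.2778) m  amplitude 1.00  error 1.0 mm
localized (0.5536, 0.1901) m  amplitude 0.07  error 1.6 mm
localized (0.5530, 0.4101) m  amplitude 0.05  error 1.0 mm
```

The full wave simulation plus matched filtering recovers every
geometrically predicted echo to within about one grid cell (1 mm at
this resolution): the strong specular reflection and — the acoustically
interesting part — the weak echoes re-radiated by the plate's free
edges, which is what makes edges localizable by sonar at all.

The same chain is scriptable from the shell:

```sh
echospace demo --preset wall --out demo/    # scene + track + pulses + oracle CSV
echospace localize --scene demo/scene.yaml --track demo/track.csv \
    --pulses demo/pulses.csv --out points.csv
echospace analyze --points points.csv --scene demo/scene.yaml \
    --track demo/track.csv --pulses demo/pulses.csv --out report/
```

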