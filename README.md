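# actinmech

Coarse-grained mechanics of filamentous actin (F-actin): a Langevin
spring-network simulator of the helical filament lattice, a calibration
suite that pins the network stiffnesses to measured filament mechanics, and
the shape-analysis pipeline used to detect and quantify **supercoils** —
filament regions whose centre axis itself corkscrews into a helix, as
produced by myosin-scale compressive forces.

## Who this is for

Cytoskeletal biophysicists and structural biologists who want to simulate
micron-scale actin filaments under force protocols (tethering, constant
tension/compression, force release, stochastic motor firing, end torque,
mechanical severing) and to quantify filament shape — from simulations,
tomogram traces, or 2D projection traces — with one consistent toolkit.

## The model in brief

Each actin protomer is a point mass on the canonical lattice (rise
h = 2.78 nm, twist β = −166.67°, radius r = 1.6 nm; two right-handed
strands forming a left-handed genetic helix). Bonded interactions:

* harmonic bonds to the four nearest neighbours — diagonal i↔i+1 and
  longitudinal i↔i+2, V = ½k_l(l−l₀)²;
* six harmonic angles per interior subunit, V = ½k_θ(θ−θ₀)²;
* two dihedrals per subunit, V = k_φ[1−cos(φ−φ₀)].

Bonds break irreversibly past structure-derived critical lengths

    l_diag = √(2r²(1−cos|β|)+h²) ≤ 4.5247 nm,   l_long = 2√((r sin|β|)²+h²) ≤ 6.5519 nm,

which models mechanical severing. Stiffnesses are calibrated to a
31 pN/nm stretch stiffness, a 9 µm persistence length via the
tangent-correlation relation ln⟨cos α(i,i+n)⟩ = −L_n/P, and a cumulative
twist-variance growth of 0.6 deg² per subunit; flexural rigidity follows as
B_s = P·k_B·T. Supercoils are detected by sliding-window (300 nm / 25 nm)
PCA of the filament centre axis: peak-to-peak PC2 amplitude ≥16 nm with
pitch (twice the peak–trough PC1 distance) in 75–350 nm. A Boltzmann
curvature model P(κ) ∝ exp(−αL_pLκ²/2) describes unloaded-filament
curvature statistics, with α a fitted proxy for effective persistence
length.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Simulate a 400-subunit filament under 40 pN of compression and quantify the
supercoil it forms:

```python
import numpy as np
from actinmech import (HelicalGeometry, SimConfig, build_filament,
                       constant_end_force, run, DEFAULT_POTENTIALS)
from actinmech.traces import frame_supercoil_calls

lattice = build_filament(HelicalGeometry(n_subunits=400), DEFAULT_POTENTIALS)
protocol = constant_end_force(40.0, "compression")   # 8 pN per end subunit
config = SimConfig(n_steps=250_000, gamma=2.0, frame_interval=1000, seed=1)
traj = run(lattice, config, protocol)

calls = frame_supercoil_calls(traj.frames, burn_in_frac=0.5)
amp = np.median([c.amplitude_nm for c in calls])
pitches = [c.pitch_nm for c in calls if c.is_supercoil]
print(f"median amplitude {amp:.1f} nm, "
      f"supercoil fraction {np.mean([c.is_supercoil for c in calls]):.2f}, "
      f"median pitch {np.median(pitches):.0f} nm")
```

```
median amplitude 18.4 nm, supercoil fraction 0.88, median pitch 256 nm
```

The filament buckles under compression and winds into a supercoil: the
median peak-to-peak amplitude (18.4 nm over the second half of the run,
still growing) is well above both the thermal baseline (~7.5 nm) and the
16 nm supercoil cut-off, 88% of the late frames classify as supercoiled,
and the pitch settles near the buckling-wavelength scale
2π√(B_s/F) ≈ 250–270 nm. The same trajectory can be
analysed from the command line: `actinmech simulate --preset compression
--force 40 --out traj.h5` followed by `actinmech analyze --traj traj.h5
--out metrics.csv`.

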