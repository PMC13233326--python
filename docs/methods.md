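# Methods

## The model

F-actin is represented as a chain of point subunits, one per protomer
centroid, arranged on the canonical two-strand helical lattice: subunit *i*
sits at cylindrical coordinates (r, i·β, i·h) with rise h = 2.78 nm, twist
β = −166.67° (two right-handed strands intertwining into a left-handed
genetic helix) and radius r = 1.6 nm. Mechanics come from a bonded spring
network:

* **Bonds.** Each subunit is connected to its four nearest neighbours:
  *diagonal* bonds i↔i+1 (cross-strand, along the genetic helix, rest
  length 4.2226 nm) and *longitudinal* bonds i↔i+2 (same strand, rest
  length 5.6087 nm), with harmonic energy ½k_l(l−l₀)².
* **Angles.** Each interior subunit is the vertex of six harmonic angles
  ½k_θ(θ−θ₀)² — all C(4,2) pairs of its four bonded neighbours
  {i−2, i−1, i+1, i+2}. Exactly six per particle, symmetric, and built only
  from declared bonds.
* **Dihedrals.** Each subunit originates two torsions k_φ[1−cos(nφ−φ₀)]
  with multiplicity n = 1: the short-pitch quadruplet (i, i+1, i+2, i+3)
  along the genetic helix and a long-pitch *span* (i, i+1, i+3, i+4) that
  crosses to the opposite strand and back around one longitudinal step. A
  pure same-strand quadruplet (i, i+2, i+4, i+6) was rejected: its three
  bond vectors are nearly collinear (≈3.4° apart), so the torsion angle is
  ill-conditioned and its force diverges whenever thermal bending makes
  them momentarily collinear — in practice the integration explodes at any
  time step. The strand-crossing span resists rotation of the long-pitch
  path with well-separated bond directions.

All equilibrium values (l₀, θ₀, φ₀) are measured from the generated
canonical coordinates, never entered by hand, so geometry and topology
cannot drift apart. Subunit internal deformations and nucleotide-state
effects are outside the model's scope.

**Rupture.** Mechanical severing is modelled by irreversibly deleting any
bond whose instantaneous length exceeds a structure-derived critical value:
the maxima of the closed forms

    l_diag = sqrt(2r²(1−cos|β|) + h²)        l_long = 2·sqrt((r·sin|β|)² + h²)

over the deformed-lattice parameter box h ∈ [2.5, 3.2] nm,
β ∈ [−177°, −154°]: 4.5247 nm for diagonal bonds (+7.2% over canonical) and
6.5519 nm for longitudinal bonds (+16.8%). Angles and dihedrals are
deactivated as soon as any bond along their path breaks; fragments never
re-anneal.

A bond severs when it stays beyond its critical length for a *dwell time*
(default 0.25 reduced time, ~50 steps; configurable, one step reproduces a
purely instantaneous rule). The dwell is load-bearing: with the stretch
stiffness calibrated to 31 pN/nm, the in-network diagonal-bond length
fluctuates with σ ≈ 0.07 nm, so the 0.302 nm rupture margin sits at only
~4.3σ and instantaneous every-step checks sever the filament *thermally*
within a few thousand steps under any condition — erasing the force
dependence of severing. Thermal excursions beyond threshold last ~0.05
reduced time and essentially never persist for the dwell, whereas a
mechanically driven crossing (the mean bond length pushed past threshold by
local curvature or strong tension) ruptures with negligible delay. No
redistribution of stiffness between the angle and dihedral networks
improves the margin at fixed persistence length, so sustained
overextension, not instantaneous crossing, is the operative severing
criterion in this parameterization. One consequence: at 10–40 pN of
tension the mean per-bond extension stays ~0.1 nm below threshold, so
tension-driven severing at those forces is a rare activated event beyond
desk-scale runs; severing under tension is exercised at a few hundred pN,
where the mean crosses the threshold.

## Units

Reduced units: length 1 nm, energy k_B·298 K = 4.114×10⁻²¹ J, mass one
actin monomer (42 kg/mol / N_A = 6.97×10⁻²³ kg). Derived:
time [t] = [l]·√([m]/2[E]) = 9.2×10⁻¹¹ s ≈ 0.1 ns and force
[F] = [E]/[l] = 4.11 pN, so a reduced force of 1.5 is ≈6 pN. All I/O is in
nm, degrees and pN; reduced units exist only inside the integrator.

## Integration

Langevin dynamics with the BAOAB splitting (velocity Verlet around an exact
Ornstein–Uhlenbeck friction/noise step). Defaults: dt = 0.005 reduced time
(0.46 ps), chosen so that ω_max·dt ≈ 0.5 for the stiffest network mode
(ω_max ≈ 100 from the Hessian) — validated by a T = 0 energy-conservation
test (drift < 0.1% over 10⁴ steps) and by thermal equipartition (total
potential energy within ~2–3% of (3N−6)·k_BT/2). A per-step displacement
guard aborts with a diagnostic if any subunit moves more than one subunit
diameter.

Friction: the physical reference is Stokes drag of water at room
temperature for a subunit-sized sphere, 6πηa with η = 0.89 mPa·s and
a = 2.78 nm → γ ≈ 61.5 reduced mass/time. Two deliberate departures, both
pure sampling accelerations:

* **Equilibrium measurements** (persistence length, twist variance) default
  to γ = 0.5 and start from a harmonic normal-mode equilibrium sample.
  Equilibrium ensembles are friction-independent; at water friction the
  slowest bending mode of a free 100-subunit filament relaxes in ≈5 µs
  (~10⁸ steps), so a cold start would never equilibrate at desk scale and
  biases the persistence length upward severalfold. A test verifies the
  friction-independence of the estimate.
* **Force-response (supercoil) runs** default to γ = 2. In the overdamped
  regime every mode's growth/relaxation rate scales as 1/γ uniformly, so
  this is a rescaling of time: buckling pathway, selected wavelength and
  rupture ordering are unchanged, only reached sooner. Stiff local modes
  become underdamped at low γ but their equilibrium statistics are
  untouched.

Constraints: permanently fixed subunits are pinned; a loaded end group is
rigid and non-rotating — forces, velocities and thermal kicks are averaged
over the group so it translates without deforming.

Determinism: one seeded RNG per run; identical (seed, config, protocol)
gives bit-identical trajectories.

## Calibration

Three mechanical targets pin the three stiffnesses, tuned sequentially and
iterated to convergence (k_l → k_θ → k_φ per cycle):

| target | value | fixes | protocol |
|---|---|---|---|
| stretch stiffness | 31 pN/nm (ADP F-actin) | k_l | 39-subunit filament, tensile force ladder at 0.298 K, low friction; slope of force vs equilibrium extension |
| persistence length | 9 µm (ADP F-actin) | k_θ | 100-subunit thermal run; ln⟨cos α(i,i+n)⟩ = −L_n/P along the centre axis, fit over the log-linear regime |
| cumulative twist-variance slope | 0.6 deg²/subunit | k_φ | same thermal runs; per-interface twist deviations accumulated along the filament, variance vs subunit index over the central 60 subunits |

The twist reference deserves comment. The cryo-EM profile this stage
emulates is external to this package, so the slope is configurable. It is
also not free: because the six angles and two dihedrals *jointly* resist
bending and torsion, the attainable cumulative slope at a fixed 9 µm
persistence length spans only ≈0.5–0.68 deg²/subunit. The default 0.6 sits
inside that window and corresponds to an effective torsional rigidity
within the published 2.8–8×10⁻²⁶ N·m² range for actin.

Two estimator routes exist for the scans:

* **Harmonic (Hessian) linear response** — instant and noise-free: stretch
  stiffness from a constrained compliance solve (with the pulled group
  rigid, matching the dynamic protocol); persistence length and twist
  variance from the equilibrium covariance k_BT·H⁺ propagated through the
  linearized centre-axis tangent / twist measurements.
* **Langevin measurement** — the protocol the targets refer to.

The two disagree in a physically meaningful way: the soft bending valley of
the stiff-angle network is curved, so the fluctuating ensemble is stiffer
than the harmonic expansion (measured persistence length ≈2.3× the harmonic
value at the same k_θ; the effect vanishes for the 0.298 K stretch
protocol, where the two routes agree to ~1%). The shipped default
stiffnesses were therefore produced with the *dynamic* estimator
(`calibrate(..., estimator="dynamic")`, seeds fixed per scan point); the
harmonic route remains available for fast exploration and as an
order-of-magnitude cross-check in the tests.

Flexural rigidity is reported as B_s = P·k_B·T (the linear map between
persistence length and rigidity).

The shipped defaults, recovered with the dynamic estimator, are
k_l = 35.0 (energy/nm², i.e. ≈144 pN/nm per bond), k_θ = 1332.7
(energy/rad²) and k_φ = 310.9 (energy), with Langevin-measured
stretch stiffness 30.5 pN/nm, persistence length 9.06 µm and cumulative
twist-variance slope 0.60 deg²/subunit.

## Force protocols

Declarative schedules compiled to integrator arrays:

* tethering of zero/one/two ends (thermal controls);
* constant end force: first five subunits fixed, last five a rigid
  non-rotating group carrying the stated *total* force (10–40 pN) split
  equally, directed along the instantaneous anchor→end axis (follower
  force, so compression keeps pushing toward the anchor after buckling; a
  fixed-direction variant can be expressed with explicit vectors);
* force-then-release: events truncated at the release step, tethers kept;
* stochastic motors: five subunits drawn from the lower half of the
  filament, each pushed or pulled axially at 6 pN for a random duration
  (uniform 5–25% of the run); finished motors re-fire on a fresh subunit so
  about five stay active; concurrent events never share a subunit; bond
  breaking disabled. The first five subunits are tethered (the source
  protocol does not state the tethering; this choice matches the other
  force conditions);
* end torque: first two subunits fixed; the rotation axis is defined by the
  midpoints of the last three subunits, levers are the projections of the
  two terminal subunits off that axis, and the per-subunit force (80 or
  800 pN) acts along lever×axis, recomputed every step.

## Shape quantification

The filament centre axis is traced per frame by the two-strand midpoint
construction: c_i = midpoint(subunit i, midpoint(subunits i−1, i+1)). For
the canonical twist this leaves a ≈0.02 nm radial residual (it vanishes
only at β = 180°), negligible against every cut-off used.

A 300 nm sliding window stepped by 25 nm is PCA-decomposed; peaks and
troughs of PC2 against PC1 are detected with a 1 nm prominence floor; the
window's peak-to-peak amplitude is the largest |ΔPC2| between neighbouring
opposite extrema and the pitch is twice their PC1 separation. A frame is a
supercoil when its maximal window amplitude is ≥16 nm (about twice the
filament diameter) and, where bounds are enabled, the pitch lies in
75–350 nm. Note a geometric limitation discovered with ideal fixtures: the
window PCA self-centres a lone extremum, so an ideal helix with pitch
above ≈2×(window/2) = 300 nm never exposes a neighbouring peak–trough pair
to a 300 nm window — consistent with the 350 nm upper pitch bound marking
the edge of the measurable range. Eccentricity comes from a direct
least-squares ellipse fit (scikit-image) to the PC2–PC3 projection of the
maximal-amplitude window, with a PCA axis-ratio fallback for degenerate
fits; the phase offset between the PC1–PC2 and PC1–PC3 oscillations is
reported as a fraction of the wavelength (0.25 for an ideal circular
helix). Trace alignment centres each trace on its largest-|PC2| extremum,
sign-normalizes so the centre is a trough, end-flips inverted
decompositions, and averages on a common 350 nm grid.

2D traces (projection-image scale) use the same windowing in the plane,
with a 325 nm minimum contour retention rule. Signed curvature is the
analytic curvature of a fitted smoothing spline sampled at 1.296 nm
(three pixels at 4.32 Å/px); supercoil segment selection requires both a
≥20 nm run of κ ≥ +1.5 µm⁻¹ and one of κ ≤ −1.5 µm⁻¹ on the same filament
after trimming 21.6 nm (50 px) from each end — excluding straight and
uniplanar-curving filaments.

## Helical-parameter measurement

For protomer chains (e.g. rigid-body-fitted centroids), a smoothing spline
is fit through the midpoint axis with the local radius allowed to vary
along the length (separate univariate spline), which suppresses spurious
twist on deformed lattices. Rise is the axis path length between
consecutive protomer projections (projections are refined to sub-grid
accuracy by a parabolic fit of the squared distance). Twist is the angular
increment of the protomer radial vector expressed in a rotation-minimizing
(parallel-transported) frame — raw Frenet frames are undefined on straight
segments, and transport prevents axis curvature from leaking into twist.
On simulation frames a faster segment-projection estimator is used: both
subunits of an interface are projected onto the plane perpendicular to the
local centre-axis segment and the signed angle between the projections is
the twist; its linearization underlies the harmonic twist-variance
estimate. The canonical lattice measures 27.8 Å / −166.67° to well within
0.2 Å / 0.2°.

## Curvature statistics

The Boltzmann curvature model assigns bending energy
E = ½k_BT·L_p·L·κ² to a segment of length L and curvature κ, giving a
discrete Gaussian probability P(κ) ∝ exp(−αL_pLκ²/2) over a configurable
symmetric grid (the normalization sum and grid are discretization choices;
the exponent is negative, as required for normalizability). α is a
dimensionless proxy for a different effective persistence length; only the
product αL_pL is identifiable, which the fit respects. α̂ is the
maximum-likelihood value under the discretized model; degenerate all-zero
data reports an unbounded α with a warning.

## Synthetic data

Every generator returns (data, ground truth): ideal/noisy circular and
elliptical supercoil traces (amplitude 2R, pitch p, eccentricity
√(1−1/ar²), phase offset 0.25), planar sines, straight traces, discrete
wormlike chains with tangent correlations e^(−s/P) (step 0.96 nm, the
tomogram resampling convention), rise/twist-modulated protomer lattices
(constant canonical profiles reproduce `build_filament` exactly), and 2D
sine/arc/straight curves with analytic curvature. Noise is isotropic
Gaussian displacement per point — deliberately *not* an imaging model (no
projection, CTF or detector statistics), so passing tests demonstrate
estimator correctness on clean-to-moderately-noisy traces, not robustness
to raw micrograph artefacts.

## Problem sizes and what the desk-scale runs show

Simulated conditions use a 400-subunit filament (~1.1 µm) for thermal
controls and force response, 100 subunits for persistence/twist
calibration, 39 for stretch, with 2000-frame thermal runs and
rupture-length-limited compression durations at reduced friction (see
above). These sizes reproduce the calibration targets within their stated
tolerances, the <10% thermal supercoil prevalence, the
compression-vs-tension ordering with release behaviour, and a pooled
compression supercoil pitch near 275 nm, but with far fewer statistically
independent samples than the source study's five replicates per condition
— expect ±10–20% run-to-run scatter on the stochastic quantities.

## Known limitations

* No excluded volume, hydrodynamic coupling, inter-filament interactions,
  annealing or subunit exchange.
* The filament is polarity-free; motor protocols cannot encode
  barbed/pointed asymmetries.
* The harmonic estimators underestimate the simulated bending stiffness
  (curved soft-mode valley); they are scan/cross-check tools, not the
  calibration standard.
* The angle/dihedral topology is a reasoned reconstruction (exactly six
  angles and two dihedrals per subunit as specified), and the cumulative
  twist-variance target is a configurable stand-in for an external
  reference profile.
* 2D analysis consumes coordinate traces; mask/skeleton image import is out
  of scope.
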