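# Methods

## The problem

Externally shelled cephalopods (ammonoids, nautilids) are rigid bodies whose
conch geometry fixes a tradeoff between hydrostatic stability and pitch
maneuverability.  A neutrally buoyant body whose center of mass M sits a
distance below its center of buoyancy B experiences a restoring moment when
tilted; the dimensionless stability index

    S_t = |B − M| / V_wd^(1/3)

normalises that separation by the cube root of the displaced volume V_wd so
bodies of different size are comparable.  The package implements the full
computational chain used to study this experimentally with counterweighted
physical replicas: the design math that imparts a chosen S_t mechanically,
the mesh integrals that supply V_wd, B and moments of inertia, the kinematic
analysis that turns 3D-tracked rocking into damping and frequency estimates,
a forward simulator that generates such data with known ground truth, and
the coiling-parameter morphospace statistics used to extrapolate the
tradeoff across fossil faunas.

## Counterweight design (hydrostatics)

A replica is assembled from components of distinct materials; each is a
point specification (mass in g, center in cm).  The design identities are
elementary statics:

- total center of mass: mass-weighted mean of component centers, applied per
  principal direction;
- neutral buoyancy: printed-body mass = displaced mass − all other masses;
- printed-body placement: moment balance
  `D_PETG = (M·Σm_i − Σ D_i m_i) / m_PETG`, verified by the round-trip
  property that reassembling the components recovers the target center to
  1e-9 cm;
- counterweight travel `D = (m_wd/m_bc)·S_t·V_wd^(1/3)` and screw turns
  `R = D / P_t` (pitch accepted in mm/rev, 0.5 mm/rev default).  The mass
  ratio magnifies the counterweight's range of motion relative to the
  resulting center shift, which is what makes sub-millimetre separations
  mechanically attainable; `turns_to_center_shift` exposes the inverse map
  for calibration-error analysis.

Units are cgs throughout (g, cm, s).  Water density defaults to 1.000 g/cm³
with a config override; the frame is right-handed, z up, origin at B; the
counterweight moves along −z.  Infeasibility (travel exceeding the chamber,
components heavier than the displaced mass) raises or is flagged — never
clamped.

## Mesh integrals (meshgeom)

Volume, volume centroid and axial second moments of a closed triangle mesh
are computed exactly by summing signed origin-tetrahedra (divergence
theorem).  For a face (a, b, c) the signed volume is det(a,b,c)/6, the first
moment det·(a+b+c)/24, and the second-moment matrix
`(det/120)·(Σ v vᵀ + (Σv)(Σv)ᵀ)`.  The moment of inertia about an arbitrary
axis is assembled from V, the first moment and S, so the parallel-axis
theorem holds to rounding.  Watertightness is enforced combinatorially
(every directed edge matched by exactly one reverse edge) with offending
edges named in the error; inward-wound meshes are flipped with a warning.
Orientation comes from face winding only, never stored normals.  File
loading (STL/OBJ) is delegated to trimesh; the integrals are cross-checked
against trimesh and analytic solids in the tests.

## Angle extraction and oscillation fitting (kinematics)

Two markers on the body's vertical axis give per-frame differences
(Δx, Δy, Δz).  The corrected angle

    θ = sign(Δx) · arccot( Δz / √(Δx² + Δy²) )   (degrees)

uses the full horizontal offset, so a rocking plane that precesses in yaw
still yields the true tilt, not the apparent in-camera-plane tilt.  Two
caveats are inherent to this construction and are documented rather than
patched:

- the sign is referenced to the +x direction, so the *signed* angle is
  yaw-invariant only within a quarter turn (|yaw| < 90°); the magnitude is
  invariant under all yaw.  When Δx = 0 exactly the sign is taken from the
  previous valid frame (continuity), and a perfectly vertical axis is 0°.
- the horizontal norm is convex in coordinate noise, so the observed
  magnitude carries a positive bias of order σ√(π/2)/d (~1° at the default
  noise), which acts as a floor once the oscillation has decayed into it.
  Fitted damping is biased low when the trace spends much time at that
  floor; simulator-recovery checks therefore use release amplitudes well
  above it.

The angle trace is fit by nonlinear least squares (scipy trust-region
reflective, tolerances 1e-14) to

    θ_d(t) = θ₀ e^(−γt) cos(ωt)            θ₀ in deg, γ in 1/s, ω in rad/s.

Initialisation is deterministic: θ₀ from the first sample, ω from the
dominant nonzero FFT peak of the (gap-interpolated, mean-removed) trace, γ
from a log-linear fit to the |peak| envelope.  Gaps are excluded from the
fit, never interpolated.  95% intervals are asymptotic t-based from the
Jacobian at the optimum.  A pooled variant fits all trials of one model
jointly with shared (γ, ω) and per-trial θ₀.

The model has no phase term, matching the printed form.  A release from
rest actually follows θ₀(ω₀/ω)e^(−γt)cos(ωt − φ) with tanφ = γ/ω, so the
3-parameter fit absorbs the phase lag into γ and ω with an O(γ/ω) bias (~1%
at the default damping ratio).  An optional phase parameter
(`fit_phase=True`) removes this bias and also makes the fit invariant to
time-origin shifts; consistency tests against linearised theory enable it,
default analysis does not.

Derived quantities: the angular-velocity series is the closed-form
derivative θ₀e^(−γt)(−γcos ωt − ω sin ωt); time-to-threshold is the envelope
crossing ln(θ₀/θ_thr)/γ (envelope, not last zero-crossing — the envelope is
monotone and insensitive to phase); both the damped ω and the natural
ω₀ = √(ω² + γ²) are reported, since drag-free pendulum periods correspond
to the latter.

## Forward simulator (synthetic_data)

Dynamics: `I θ¨ = −m_wd g S_t V_wd^(1/3) sin θ − c θ˙` integrated with
DOP853, rtol 1e-9 / atol 1e-12, sampled at the camera frame rate through
dense output (never step coincidence).  The pivot is the center of buoyancy
(a neutrally buoyant body rotates about its center of volume to first
order); drag is linear in angular velocity so the linearised system matches
the fitted model exactly, with γ = c/(2I) and ω = √(ω₀² − γ²) as ground
truth.  Disturbances — yaw precession, lateral current drift, vertical
buoyancy drift — are kinematic overlays on the marker positions, present to
stress the angle correction, not coupled into the dynamics.  Gaussian noise
is added per marker coordinate.  One seed drives everything; trial
substreams come from `numpy.random.SeedSequence.spawn`, so output is
byte-identical across runs.

Defaults describe the target experimental setting: displaced mass/volume
985 g / 985 cm³ (a ~15 cm conch), release 55°, 23.975 frames/s, 12 s
duration, markers 12 cm apart, coordinate noise 0.15 cm (a few pixels of a
4k two-camera reconstruction at ~2 m), precession 2°/s, current drift
0.5 cm/s, buoyancy drift 0.1 cm/s, gravity 980.665 cm/s².

The four-morphotype fixture suite uses the examined stability indices
(Nautilus 0.043, oxycone 0.068, serpenticone 0.015, sphaerocone 0.006) at
the shared volume.  Inertia is a shape factor times (2/3)mr² (thin shell of
the volume-equivalent sphere, r ≈ 6.2 cm): oxycone 1.25, serpenticone 1.10,
Nautilus 1.00, sphaerocone 0.90 — compressed shapes hold mass farther from
the pitch axis.  Per-profile drag constants (c/I = 0.80, 0.70, 0.36, 0.40
s⁻¹ respectively) are free parameters chosen so the stable pair damps about
twice as fast as the unstable pair, the linear-drag stand-in for
velocity-dependent hydrodynamic losses; absolute damping levels of the real
models are not reproduced (their drag coefficients are unknown), only the
directional contrast is meaningful.  With these settings the suite's
linearised frequencies are ≈ 4.1/4.6 rad/s for the stable pair versus
2.3/1.6 rad/s for the unstable pair.

What passing tests show, and what they do not: the generator exercises the
full observation chain (precession, drifts, noise, alternating release
directions) but omits translation–rotation coupling, added-mass and
quadratic drag, wake interaction, and marker occlusion patterns of real
footage, so parameter-recovery results bound estimator behaviour under the
stated noise model only, not under every pool condition.

## Morphospace statistics (morphospace)

Coiling records carry whorl expansion W ≥ 1, umbilical exposure U ∈ [0, 1)
and thickness ratio Th > 0; W proxies hydrostatic stability and the
compression ratio 1 − Th proxies hydrodynamic stability.  Ternary
coordinates default to plain normalisation of the endmember scores
(W − 1, U, Th) — each zero at its opposing edge — with a componentwise
scaling hook for published rescaling constants.  Summaries are per-group
fixed-width histograms (12 bins over the pooled range, configurable),
medians and IQRs.

Group comparisons are rank-based: Dunn's pairwise z on Kruskal–Wallis
pooled midranks with tie correction,

    z_ij = (R̄_i − R̄_j) / √( (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j) ),

with Holm adjustment by default (raw p also reported), and the Wilcoxon
rank-sum test for two groups — exact by enumeration of rank assignments for
pooled n ≤ 12 (valid under ties via midranks), tie-corrected normal
approximation otherwise.  α = 0.05 throughout.  The synthetic table
generator draws right-skewed baselines (lognormal W and Th, beta U) with
per-group location shifts; the default two-group contrast (ΔW = 0.5 at
n = 50) is detectable with power > 0.8, which the tests verify empirically.

## Problem sizes

Simulation-based tests use 12 s trials at 23.975 frames/s (~288 frames),
100-replicate recovery ensembles, 15-trial morphotype suites, and 1000-case
algebraic property sweeps — sizes at which every result in the suite is
recomputed from scratch at test time.

## Known limitations

- The rocking model omits hydrodynamic added mass and quadratic drag; the
  option for quadratic drag was considered and dropped because the fitted
  model is linear and the contrast of interest is directional.
- Fitted ω under large-amplitude release (55°) sits a few percent below the
  linearised value (pendulum anharmonicity); comparisons with linear theory
  are made at small amplitude.
- The ternary transform is the plain normalisation; published morphospace
  rescalings must be supplied via `scaling` if exact figure reproduction is
  wanted.
- The signed angle's yaw invariance is limited to |yaw| < 90° by its printed
  sign convention; long precessing records should be split at quarter-turn
  boundaries before fitting.
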