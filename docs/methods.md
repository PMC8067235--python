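# Methods

`probemech` simulates the mechanical interaction between a skull-fixed
fiber implant and breathing brain tissue, reduces the strain fields to
damage statistics, and quantifies periprobe immunofluorescence.  This note
records the model, its assumptions, the numerical choices, and what the
desk-scale results do and do not show.

## Tissue and probe constitutive models

Brain tissue is isotropic, homogeneous and nearly incompressible
hyperelastic, with the first-order Ogden strain-energy density in
principal stretches

    W = (mu1/alpha1) (lbar1^a1 + lbar2^a1 + lbar3^a1 - 3) + kappa/2 (J-1)^2,

where `lbar_l = J^(-1/3) lambda_l` and `J = lambda1 lambda2 lambda3`.  The
constants `mu1 = 8.1`, `alpha1 = 15.7` describe the CA3SR region of the
adult rodent hippocampus; `mu1` is interpreted in Pa, giving an initial
shear modulus `mu0 = mu1*alpha1/2 ≈ 63.6 Pa` — the extreme softness
characteristic of hippocampal tissue (ground-state Young's modulus
`E0 = 3 mu0 ≈ 191 Pa`).  Units are config-exposed.  Incompressibility is
enforced by the quadratic volumetric penalty with `kappa = 1e5 * mu0` by
default (type invariant: at least `1e4 * mu0`); at the stress levels of
the micromotion problem this keeps `|J - 1|` below ~1e-5.

Probe materials are linearly elastic (Saint-Venant–Kirchhoff in the
finite-strain setting) with supplier constants: steel `E = 1.93e11 Pa`,
silica `6.63e10`, polycarbonate `2.30e9`, hydrogel (HydroMed D4, fully
hydrated) `3.76e6`, all 4–9 orders stiffer than the tissue.  What
distinguishes them mechanically is bending compliance: a 400 µm hydrogel
fiber's cantilever stiffness (~0.5 N/m over 3 mm) is comparable to the
restoring stiffness of the surrounding tissue annulus (~1 N/m), so a
hydrogel probe rides along with the tissue, while steel, silica and PC are
effectively rigid — the physical origin of the material orderings.

## Domain, meshing, contact

The tissue is a 1×1×6 mm block (z ∈ [−3, 3] mm), the probe spans
z ∈ [0, 3] mm with its tip plane at z = 0, and all cross-sections are
normalized to the area of the 400-µm-diameter circle, `S = 0.04π mm²`
(ellipse aspect ratios 1:1/1:2/1:3; square; octagon = five squares of side
c plus four right-isoceles corner triangles, area 7c²; rounded square =
five squares plus four quadrants, area (5+π)c²).

Meshing is a structured butterfly (O-grid) scheme: a Coons-patch core
inside the section, transition rings out to the section boundary, and
radially graded quad rings to the outer square, extruded along z with
grading refined at the tip plane.  Probe and tissue are separate bodies
whose interface discretizations coincide node-for-node at t = 0.  Named
presets: `tiny` (~970 elements), `reduced` (~1 800, bulk 160 µm / contact
60 µm), `fine` (~4 100), `reference` (the study-scale 80 µm / 23.5 µm
discretization, ~70 k elements — far beyond desk scale).  All presets use
trilinear hexahedra with selective reduced integration (full 2×2×2
quadrature for the isochoric term, element-centroid quadrature for the
volumetric penalty), which avoids volumetric locking in the
incompressible limit; quadratic elements were not implemented — at desk
scale the accuracy bottleneck is the interface resolution, not the
polynomial order, and the measured preset-to-preset stability of the ROI
statistics (below) supports this.

Contact is node-to-node across the coincident interface (relative motions
are micrometers, far below the element size, so small-slide kinematics
with fixed reference normals are exact for practical purposes).  Both
contact laws are C1-smooth, which proved decisive for Newton robustness:

- normal: `p = (x + sqrt(x² + eps²))/2` with `x = lambda − kn A g`, a
  softplus-smoothed unilateral law on a gap scale of 0.01 µm;
- tangential: `t = trial/(1 + s⁴)^(1/4)`, `s = |trial|/(mu p)` — elastic
  stick for `s ≪ 1`, saturation at the Coulomb bound `mu p` for `s ≫ 1`
  (within 1% once `s > 3`), with the consistent (nonsymmetric) tangent
  including the slip–pressure coupling.

Penalty stiffness defaults to `30 E0 / h_contact` scaled from the tissue
neighbor-element stiffness; augmented-Lagrange pressure updates (up to 3
per step) keep penetration below 1% of the contact element size.  The
block-on-slab verification fixture recovers `F_t/F_n = COF` to three
decimals at slip.

## Loading and time integration

The micromotion waveform `11.4 sin(2πt) + 2 sin(8πt)` µm (respiration at
1 Hz, vascular pulsatility at 4 Hz) is prescribed as the normal
displacement component of the outer tissue faces, with the same global
sign on opposite faces, so the far tissue translates quasi-rigidly
relative to the skull-fixed probe and all strain localizes at the
interface.  This reading was chosen over an in-phase inward-normal
"squeeze" (which remains available via `BoundaryLoad.mode`) on
quantitative grounds: a squeeze of this amplitude would impose a *uniform
far-field* equivalent strain of ~0.05 on an incompressible 1-mm block,
making the entire ROI "critical" and putting the ROI-mean strain far above
the reported values, whereas the translation reading reproduces the small
critical volumes, the ROI means, and the concentration of strain at the
probe tip and top.  The four lateral faces and the bottom are driven; the
top tissue surface, where the probe enters and is cemented to the skull,
is left free — driving it as well pins a one-element tissue layer between
two kinematic constraints at the fixed probe top, which is numerically
unsolvable at realistic penalties and is precisely the region whose
"inconsistent, asymmetric outliers" motivate excluding z > 2.9 mm from
every statistic.

Time integration is quasi-static by default: at 1–4 Hz and micrometer
amplitudes, inertial forces are ~1e-6 of elastic forces (shear wavespeed
~0.25 m/s gives wavelengths of centimeters against a 6 mm domain).  An
implicit HHT-α integrator (numerical damping α = −0.05, lumped mass) is
available via `SimulationConfig(quasi_static=False)`.  Adaptive stepping
covers the 1 s period with steps in [0.1, 10] ms, growing on fast
convergence and cutting back on failure; friction history is committed
per converged step.

The nonlinear solver is a line-searched modified Newton: Jacobian
factorizations (reverse-Cuthill-McKee + natural-order SuperLU in symmetric
mode) are reused while the residual contracts, with refactorization
triggered by slow contraction; a trust-region-style increment cap (5% of
the contact element size) keeps trial steps inside the convergence basin
of the violently nonlinear Ogden energy (`alpha1 = 15.7`); a backtracking
line search on the residual norm suppresses the two-cycles that contact
switches can induce.  Convergence is declared at 1e-4 of the running force
scale of the trajectory (about 50× tighter than common commercial-code
force tolerances); static verification solves use 1e-10.

## Strain reduction and critical region

Log (Hencky) strain is evaluated at Gauss points, volume-averaged per
element and then volume-weighted onto nodes.  The damage surrogate is the
equivalent (von Mises effective) strain with effective Poisson ratio
ν′ = 0.5 (incompressible tissue; configurable — the convention of the
original commercial-solver output is not printed).  Statistics follow the
study design: the ROI is the axial slab within 500 µm of the tip plane
(including tissue below the tip); nodes above z = 2.9 mm are excluded
everywhere; the per-node peak over the simulated period defines the peak
field; the critical region collects tissue elements with any nodal peak
≥ 0.05, and its volume is the alpha-shape volume of their centroids with
the radius rule α = min(enclosing-sphere radius of the points, maximum
element characteristic length of the mesh, longest-edge convention).  The
alpha-shape filter keeps Delaunay tetrahedra whose *smallest enclosing
ball* has radius ≤ α — identical to the circumradius criterion for
well-shaped tetrahedra but bounded for slivers, so the shape equals the
convex hull exactly once α reaches the cloud's enclosing radius.  Path
profiles sample the peak field along the x = y diagonal at the top
(z = 2.9), mid (1.5) and tip (0) planes, folded and averaged across the
two sides by distance from the probe surface.

## Histology quantification and synthetic images

The image pipeline mirrors the study protocol exactly: ten 50 × 2348 µm
bands stacked upward from the manually supplied tip center; per band, the
probe track is the longest below-threshold run of column means containing
the band center (threshold: median − 2 scaled-MADs, configurable); column
means are folded at the track edges into left/right distance profiles
(distance origin at the track edge, pixel centers at half-pixel offsets);
sides then bands are averaged on a common grid; the profile is normalized
to the mean beyond 500 µm and binned into ten 50 µm intervals.  Group
statistics use one-way ANOVA + Tukey HSD on whole-region means (750 µm ×
1000 µm rectangle, 550 µm above / 200 µm below the tip) and two-way ANOVA
(material × bin) with per-bin Tukey tests.  Bands with no detectable track
are dropped; statistics require 8 of 10 valid bands.

Synthetic images emulate the structure this pipeline assumes: a
low-intensity vertical track with a tip, intensity
`B (1 + A exp(−d/λd))` decaying with horizontal distance d from the track
edge, additive Gaussian noise, 16-bit clipping (defaults: 2 µm/px,
1500×3000 px, B = 2000, σ = 100, track 400 µm; exponential decay chosen
as the simplest monotone model matching observed profile shapes, λd =
120 µm).  They are *not* microscopy renderings: no cellular texture,
depth-dependent background, section-to-section registration error, or
channel bleed-through.  Passing recovery tests therefore demonstrates
that the pipeline is unbiased and noise-stable under its own model
assumptions, not that it is robust to every real-world artifact.  Group
studies inject material-specific amplitudes ordered steel > silica > PC >
hydrogel (3.0/2.2/1.5/0.7), mirroring the chronic-response ordering.

## Desk-scale protocol and known biases

All shipped simulations run at desk scale (minutes per scenario on one
CPU).  The protocol: `tiny` mesh preset; peak-strain statistics from the
first quarter-period (0.25 s, through the 11.4 µm respiration crest);
critical-volume scenarios extended to 0.30 s (through the global 12.66 µm
extremum at t = 0.285 s — without it no tissue reaches the 0.05 threshold
at this scale).  The second half of the 1 s period mirrors the first up
to sign; a full-period validation run puts its peak ~8–11% above the
quarter-period value (friction-history asymmetry), a bias accepted in
exchange for a 3–4× cost reduction.  Ordering comparisons use a monotone
respiration-only ramp to 0.15 s, which preserves the material, friction
and geometry orderings at a fraction of the cost.

Measured resolution dependence: the hydrogel-baseline peak ROI strain
changes by <1% between the `tiny` and `reduced` presets (0.0473 vs
0.0469), so desk-scale statistics are internally converged.  Against the
reference-resolution study values, the ROI-*mean* peak agrees closely
(0.0167–0.0190 vs 0.0161) while ROI-*peak* values come out at roughly
half the printed magnitudes.  Since this gap survives refinement, it is
attributed to representation differences rather than discretization:
the equivalent-strain convention of the commercial solver (an effective
Poisson ratio of 0 would scale all values ×1.5), nodal averaging of
linear-element strains at the tip-edge concentration versus extrapolated
quadratic-element output, and the residual ambiguity in the prescribed
micromotion vector.  All *relative* results — material, friction and
geometry orderings, stiff-probe insensitivity, strain localization — are
insensitive to these factors and are the package's validated claims.

## Limitations

- No viscoelasticity, poroelasticity, anisotropy or temperature
  dependence in the tissue model; no insertion mechanics (the probe
  starts perfectly conforming in its void).
- Contact assumes initially coincident surfaces; no self-contact or
  large-slide detection.
- Trilinear elements under-resolve the tip-edge strain concentration at
  desk scale; absolute peak strains are biased low there.
- The IHC generator's simplifications listed above.
- The friction direction: the study reports peak strain and critical
  volume *decreasing* with COF, while this model produces a mild increase
  (higher friction transfers more shank shear into the tissue under the
  translation-type load).  The reported direction plausibly requires a
  load component that pressurizes the contact normally so that friction
  shields tip slip; with the printed boundary-condition description this
  could not be established independently, and the discrepancy is reported
  rather than fitted away.  All other orderings reproduce.
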