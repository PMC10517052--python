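# Methods

`pahemo` implements the in-silico side of a porcine pulmonary-artery
pressure-sensor (PAPS) study: quantify the pre-interventional vessel
geometry, virtually implant the sensor body at an observed pose, impose
subject-specific pulsatile inflow, compute wall-shear-derived thrombosis
surrogates (TAWSS, OSI, RRT, thresholded risk areas, trans-device pressure
drop), and run the paired cohort statistics. The one deliberate
substitution is the flow solver: the commercial transient 3-D turbulent
finite-volume simulation of the original workflow is replaced by an exact
analytic pulsatile-tube (Womersley) solution mapped per branch, so that
every downstream stage is testable against closed forms on a desk-scale
machine. What that substitution does and does not preserve is spelled out
below.

## Vessel geometry

Meshes are triangulated surfaces in millimetres with one region label per
face (`MPA`, `LPA`, `RPA`, `BRANCH`, `DEVICE`, and inlet/outlet caps).
Watertightness (every edge shared by exactly two faces, all face areas
positive) is a hard precondition for any stage that treats the surface as
a fluid-domain boundary.

Centerlines are computed as shortest paths on a wall-distance-weighted
graph over interior voxels (edge weight `step / d_wall²`, which drives the
path onto the medial axis), followed by a per-point medial refinement:
each point is pushed away from its nearest surface point within the plane
perpendicular to the local tangent, with a geometrically shrinking step
(18 iterations, initial step = one voxel pitch). Radii are exact
point-to-triangle distances to the *wall* faces (caps excluded, so end
radii stay physical). On a straight tube this recovers the axis to
~1e-3 mm and the radius to the mesh faceting error; on a 90° torus bend
the arc length is recovered to 0.01 %. The algorithm is a means to an
accuracy contract, not an interface: any method meeting the tube/torus
tolerances would be acceptable.

Per-segment measurements: length is the arc length of the interval, the
mean diameter is the arithmetic mean of inscribed-sphere diameters sampled
every 0.5 mm of arc (the underlying study does not state its averaging
convention; arithmetic point-mean at fixed spacing is the simplest
defensible choice and is what the linear-taper oracle in the tests pins
down). The bifurcation angle is the angle between least-squares take-off
directions fitted over the first 10 mm of each branch leaving the junction
(configurable; no fit length is stated in the source tables). Surface
areas are exact sums of `½|cross|` face areas, reported in cm²
(1 cm² = 100 mm²), caps always excluded.

## Virtual implantation

Registration is point-to-point ICP with a Kabsch/SVD inner step,
minimising the RMS of point-to-nearest-target distances — the objective
the study names. The RMS trace is monotone non-increasing because both
alternating steps (correspondence, closed-form transform) are exact
minimisations; the tests assert this on every run. Constructed rigid
transforms (25–35° rotations plus translations) are recovered to 1e-6.

The Boolean subtraction of the device from the lumen is evaluated on a
signed-distance grid: `phi_fluid = max(phi_lumen, −phi_device)`, extracted
with marching cubes. The environment provides no exact mesh-Boolean
backend, and an SDF Boolean has the advantage of unconditional
watertightness; its cost is surface placement accuracy of roughly a tenth
of the grid pitch (default 0.4–0.6 mm). Signs are obtained by scan-line
parity counting over grid columns (robust for watertight input; the grid
origin carries a deterministic sub-voxel offset so no scan line passes
through a mesh vertex or edge), magnitudes by exact point-to-triangle
distances in a two-voxel band around the surface and a Euclidean distance
transform elsewhere. Volume arithmetic (`V_fluid = V_lumen − V_device`
for an interior device) is conserved to ~0.03 % at the default pitch; the
acceptance bound is 1 %.

Blood-exposed vs wall-contact device areas are *not* read off the
extracted surface: the original device faces are classified against the
lumen interior (centroid strictly inside → exposed), so
`exposed + contact = total` holds exactly and a fully interior device is
exactly fully exposed.

Placement classification follows the study's taxonomy: a device is
OPTIMAL when its wall-contact face stays within a gap threshold
(default 1.0 mm — no figure is given in the source, 1 mm is half the
device height) of the vessel wall along its full length, it does not sit
inside a side branch, and its footprint does not cover a branch ostium.
Each violated condition is reported as a reason (`SKEWED`, `IN_BRANCH`,
`COVERING_BRANCH`). Placement in the MPA is an independent flag, not a
non-optimality reason — mirroring the cohort, where a wall-apposed MPA
device is counted in the optimal group. The optional snap correction
translates the device along its contact normal onto the wall, capped at
2 mm (the study mentions "slight corrections" without a magnitude; the
cap is a declared guess).

## Boundary conditions

Heart rate and cardiac output come either from the packaged cohort table
(nearest weight, ties to the lowest case id) or from allometric power laws
`HR = c·W^b` fitted by least squares in log space to that table. The
table is not a strict function of weight (two 65 kg animals differ in HR),
which is precisely why both modes exist: lookup reproduces the printed
rows, the allometric fit smooths them.

The inflow waveform is a constrained template: a half-cosine systolic lobe
peaking at Qmax, a smooth early-diastolic dicrotic dip to −5 % of Qmax
(0.15 T long), and a flat late-diastolic baseline. Mean flow and stroke
volume are a single constraint (SV = mean·T), so only one parameter can be
eliminated by it: the baseline level is solved in closed form from the
*discrete* sample sums (making the CO constraint exact at the sample
level), while the systolic duty fraction is a free shape parameter
(default 0.40 T, seeded ±10 % jitter to emulate inter-animal curve-shape
variability); bisection on the duty fraction is a fallback when the
closed-form baseline leaves its feasible band. The canonical sampling
step is Δt = 1 ms; other steps use periodic cubic resampling. Waveform
invariants (mean, peak, SV, period, all to 0.5 %) are asserted for the
10 cohort profiles and 300 random feasible draws.

Blood: ρ = 1050 kg/m³ with Carreau–Yasuda viscosity
μ(γ̇) = μ∞ + (μ0−μ∞)[1+(λγ̇)^a]^((n−1)/a), defaults
μ0 = 0.16 Pa·s, μ∞ = 0.0035 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128 — the
coefficient set of the rheology reference the study cites (the source
paper does not print them; the values are configurable). The
peak-systolic Reynolds number uses the high-shear viscosity μ∞ (the
appropriate plateau at arterial peak-flow shear rates):
Re = ρ·v·D/μ∞ with bulk velocity v = Qmax/(πD²/4). Over the packaged
cohort the minimum is ≈ 2.6·10³, consistent with the transitional/
turbulent regime (> 2000) the study argues from.

## Synthetic flow stand-in

The flow model is laminar, Newtonian at μ∞, and straight-tube analytic:
the inflow waveform is decomposed into K = 12 flow-rate harmonics (the
reconstruction RMS is reported and is < 1 % of Qmax for template
waveforms), and each harmonic contributes the exact Womersley wall-shear
and pressure-gradient amplitudes (Λ = i^{3/2}α, α = R√(kωρ/μ); harmonic 0
is Poiseuille: τ = 4μQ/(πR³), dp/dz = −8μQ/(πR⁴)). Verification is
two-route: the steady and quasi-steady (α ≪ 1) limits against Poiseuille
closed forms, and the full pulsatile solution against an independent
finite-difference radial solver — second-order discretisation of the
axisymmetric momentum equation solved per harmonic as a bordered system
whose extra unknown is the pressure gradient enforcing the flow rate, with
no Bessel functions anywhere (agreement ≈ 0.1 % RMS; the acceptance bound
is 2 %). The analytic velocity profile also integrates back to Q(t) to
0.5 %, closing the flow-consistency loop.

In the pipeline the tube solution is mapped per branch: the trunk carries
the full flow, the two main branches split it by cross-sectional area,
each face receives the axial WSS vector of its branch, and the pressure
field integrates the harmonic gradients along the branch axes
(continuous at the junction). Side branches carry a weak (0.1×) shear —
they are the model's low-WSS regions — and device-imprint faces carry a
mildly accelerated (1.3×) host shear, consistent with the observation
that device surfaces see somewhat higher TAWSS than the vessel wall.
These two factors are plausibility knobs, not calibrated physics.

The device wake is modelled as an added oscillatory tangential WSS
component on faces in a cylinder sector (default 120°, three device
lengths) downstream of the device tail, amplitude tapering linearly with
distance, per-face random phase (seeded). The added component's temporal
mean is forced to exactly zero, which yields the two provable properties
the tests assert: per-face mean-WSS vectors (hence TAWSS direction sums)
are conserved to 1e-12, and OSI strictly increases on every perturbed
face.

What the stand-in does **not** reproduce: turbulence, secondary and
recirculating 3-D flow, and realistic OSI spatial distributions. Because
the tube solution reverses its wall shear coherently over the whole
circumference during the diastolic dip, surface OSI in the synthetic
pipeline (~0.3) is far higher than the ~0.08 of real 3-D PA simulations,
where shear reversal is localised. Passing pipeline tests therefore
demonstrate correctness of the machinery (geometry, Boolean, indices,
statistics, reproducibility), not fidelity of absolute index levels on
real anatomies. The cohort-level statistical structure of the study is
instead emulated by the dedicated cohort-metric generator (below), and
the published index values themselves are reproduced from the packaged
tables, not re-simulated.

The synthetic PA geometry is a union of capped-cylinder signed-distance
fields (trunk along +z, two branches splitting symmetrically at the
requested bifurcation angle, optional seeded side branches), extracted by
marching cubes. Defaults follow the cohort geometry (trunk Ø 23.8 mm,
branches Ø 13.6/14.9 mm, angle 80°); trunk/branch lengths default to
60/70 mm, enough to fit devices and pressure probes while keeping grids
small. Ground-truth centerlines, segment dimensions and ostium circles
are returned for oracle use; generation is bit-reproducible per seed.

The cohort-metric generator draws paired tables: pre ~ positive-truncated
Normal(mean, SD), post = pre + Normal(shift, shift SD), device metrics
from their own truncated-normal law, all from one seed. Its calibration
is itself tested: paired-t type-I error over 2000 seeded null replicates
at n = 10 lies in [0.04, 0.06] (measured 0.052), and generator means are
recovered within 3 standard errors over 1000 replicates.

## Hemodynamic indices

Per face over N equidistant steps covering one cycle:
TAWSS = (1/N)Σ‖WSS_t‖; OSI = ½(1 − ‖Σ WSS_t‖ / Σ‖WSS_t‖) ∈ [0, 0.5]
(0 for direction-constant histories, 0.5 for zero-mean harmonic
oscillation; an all-zero history gets OSI 0 via a division guard);
RRT = 1/((1−2·OSI)·TAWSS), reported as missing (NaN) where OSI = 0.5 or
TAWSS = 0 rather than as infinity. Values live at face centroids;
non-equidistant input must be resampled before summation so the printed
formulas stay exact. Kernels are vectorised but are checked against
explicit per-step loop oracles to 1e-12, and are invariant under rigid
motion and cyclic rotation of the time samples.

Surface averages are area-weighted (Σ A_f x_f / Σ A_f; configurable to
unweighted for sensitivity checks). Threshold areas use strict
inequalities — WSS < 0.5 Pa (low shear), OSI > 0.2 (high oscillation) —
matching the printed conventions, so a face exactly at the threshold does
not count; `below` and `above` partition the region area exactly for
tie-free fields.

The trans-device pressure drop places probes 10 mm up- and downstream of
the device span along the host centerline, averages per-face static
pressure in a thin station band (half-width 1.5 mm) as a cross-section
surrogate, time-averages over the cycle (configurable to peak systole),
and converts with 1 mmHg = 133.322 Pa. Negative drops are legal outputs
(static pressure recovery over an expanding cross-section). The steady
Poiseuille closed form 8μLQ/(πR⁴) is reproduced to 2 %.

## Cohort statistics

Descriptive reporting is gated by Shapiro–Wilk at α = 0.05: mean ± SD if
normal, median [IQR] otherwise; constant samples are flagged degenerate.
SDs use the n−1 denominator throughout (validated: the pre TAWSS SD of
the packaged table reproduces the printed 0.47 only with n−1). Paired
comparisons: two-sided paired t, or Wilcoxon signed rank with exact null
enumeration for n ≤ 25 (validated against exhaustive 2^n sign-assignment
enumeration for n ≤ 8); the summary-reproduction path uses the normal
approximation without continuity correction, the convention of the
commercial package used for the published analysis, which is what
reproduces the printed p-values (0.005, 0.059). The effect size is
Glass's Δ (mean difference over the pre SD) — the estimator is not named
in the source, but this one reproduces the printed 0.22 for TAWSS from
the table and is labelled in every report. Quantiles use the weighted-
average definition h = p(n+1) (again the commercial-package convention;
it reproduces the printed IQR bounds 0.29–1.06 exactly/within 0.01).
No multiplicity correction is applied, matching the source analysis.

`reproduce_summary()` recomputes 82 published summaries from the packaged
tables and compares each at the printed precision with round-half-away-
from-zero. 74 strict checks pass with zero mismatches. Eight entries are
reported as known-discrepancy *notes* rather than checks, because the
published value is arithmetically inconsistent with the published
per-case table it summarises: the OSI SDs 0.17/0.16 (the table implies
0.016), the OSI effect size and paired significance (destroyed by the
table's 2-decimal rounding), the overall PA area 152.0 (table mean
151.7), the MPA diameter 23.8 (table mean 23.86), the post-TAWSS SD 0.49
(table: 0.498), the post/paired lWSSa SDs, and one Wilcoxon p (0.047 vs
0.050 from the rounded table). The non-optimal grouping assigns the
ambiguous second MPA device to the LPA-listed column — the unique
assignment that reproduces both printed group means (2.55/3.85 Pa).

## Orchestration and reproducibility

Each case runs geometry → implantation → boundary conditions → flow →
indices from a single `CaseConfig`; all randomness derives from one seed
expanded per stage via CRC-32 of the stage name (kept below 2³¹).
Reports are JSON with sorted keys; identical configs give byte-identical
reports, asserted in the tests by re-running cases. Timestamped run logs
are written separately so they never perturb report bytes. The default
cohort uses marching-cubes pitch 0.9 mm (≈ 30 k faces), Boolean pitch
0.6 mm, 80 time steps and 12 harmonics per case — sizes chosen so a full
10-case cohort completes in under two minutes on one CPU while keeping
the analytic-oracle agreement comfortably inside its bounds; all pitches
and step counts are config fields.

STL round-trips re-index the vertex soup on load (restoring
watertightness); labels persist in a sidecar CSV because STL has no
attributes. The legacy-VTK export is a minimal text writer for
visualisation only.

## Known limitations

* The stand-in flow is laminar, Newtonian and branchwise-1-D; absolute
  TAWSS/OSI levels on synthetic anatomies are not comparable to 3-D CFD
  on real geometries (see above), and the synthetic pressure drop lacks
  turbulent and form losses, so it is much smaller than the published
  0.7 mmHg cohort mean (which is reproduced from the tables instead).
* The SDF Boolean trades exact surface position (±~pitch/10) for
  guaranteed watertightness; contact/exposed areas avoid this error by
  classifying original device faces.
* Centerline extraction assumes a tubular topology reachable from the
  source; it has no loop handling.
* Automatic anatomical labelling of raw meshes is out of scope: labels
  come from the generator or the user.
* Fluid–structure interaction, fixation wires, device migration and
  image segmentation are out of scope by design.
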