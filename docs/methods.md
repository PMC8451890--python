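# Methods

`airwaymorph` measures tracheobronchial airway trees from segmented
micro-CT-style binary volumes of lung casts, and validates every stage
against voxelised phantoms whose geometry is known analytically.  This note
records the models, the conventions and the numerical choices, in the
spirit of a lab notebook for the package.

## The measurement model

A cast volume is reduced to a centerline network, the network is cleaned of
the exception classes cast scans exhibit, and each branch is reported with
the quantities aerosol-dosimetry programs consume:

* **Airway length** — the straight-line (chord) distance between the two
  bifurcation nodes of a branch, in mm.  The chord, not the arc length,
  matches how manual morphometry with straight-line calipers defines
  length, and how bifurcation-node schematics draw it.
* **Hydraulic diameter** — `4·A/P` averaged over cross-sections taken
  perpendicular to the local centerline tangent.  For a circular section
  this equals the geometric diameter; for irregular lumina it is the
  quantity airflow resistance actually depends on.  A cross-section that
  crosses another branch's centerline is discharged.  When no section
  survives — branch shorter than its diameter, or strongly bent — the
  branch is flagged and its diameter recorded as zero; generation averages
  then substitute the parent's diameter.
* **Branch angle** — the angle between the parent's and the daughter's
  node-to-node vectors; a straight continuation scores 0°.
* **Inclination to gravity** — the angle to a gravity vector constructed
  anatomically: gravity is assumed perpendicular to the trachea and lying
  in the plane spanned by the trachea and the mean direction of the two
  main bronchi.  With `t` the trachea unit vector and `b` the normalised
  bronchi average, `g ∝ b − (b·t)t`, oriented so `g·b ≥ 0`.  The trachea is
  therefore at 90° to gravity by construction, the convention under which
  rodents are held in inhalation exposure studies.  Note that `g` is the
  *normalised small residual* of `b` perpendicular to `t`; when the bronchi
  average is nearly parallel to the trachea the construction degenerates
  and the code rejects it.
* **Raabe binary label / generation** — the trachea is "1"; each daughter
  appends "1" if it is the larger-diameter (major) daughter, else "2".
  Generation = number of digits.  Labelling uses the measured hydraulic
  diameters (with the parent-substitution rule for flagged branches); ties
  break on subtree branch count, then on the lexicographically smaller
  distal-node coordinate, so labelling is deterministic.

## Volume processing

Threshold (≥ level), optional integer-factor block resampling (majority
vote, ties to foreground so thin branches survive), morphological opening
with a ball element (removes artificial contacts between branches created
by limited resolution), a small closing, and largest-26-connected-component
selection.  The ball radius is interpreted as *radius* in current-grid
pixels: with a resample factor of 2 and a 2-pixel element this gives the
4-original-voxel opening bandwidth, and the workflow accuracy estimate is
twice the bandwidth: `2 × se_pixels × resample_factor × voxel_size` — 52.8
μm, "about 50 μm", at the reference settings (6.6 μm, 2, 2).  Detail finer
than this is lost by design; phantom dimensions keep all diameters well
above it.

The closing step (radius 1 by default) is there because voxelisation of two
surfaces that approach closely creates background slivers that are tunnels
under the 26-connected-foreground / 6-connected-background digital
topology; topology-preserving thinning then dutifully produces a skeleton
cycle out of nothing.  A one-pixel closing fills the sliver.  We verified
this on phantoms whose mask had Euler number 0 at 26-connectivity but 1 at
6-connectivity — i.e. the "handle" existed only in the adjacency
convention.

## Centerline extraction

Skeletonisation is 3D topology-preserving parallel thinning
(`skimage.morphology.skeletonize`, Lee's method), yielding a one-voxel
curve skeleton.  Skeleton voxels with ≥ 3 neighbours are clustered into
junction nodes (clusters merge within 2 voxels, node at the centroid);
degree-1 voxels are terminals; the paths between them become branch
polylines in mm.  The root is the terminal whose incident branch is widest
(the trachea), overridable with a hint.

Raw thinning has two systematic defects that would dominate the error
budget, and the package corrects both:

* **Free-end retraction.** Thinning retracts a free tube end by about one
  radius — and can consume a thick, short stub entirely.  Terminal branches
  are therefore extended: the end tangent is fitted over the last ~2 local
  radii of polyline, and the end marched outward, re-centred on the ridge
  of the distance transform each step while in the tube body, then straight
  once inside the cap zone (re-centring there would slide sideways along
  the cap and hook the polyline).  Guards stop the march if the local
  radius grows (the march has left its tube).
* **Junction clumping.** Thinning produces a clump of junction voxels whose
  centroid is a biased node estimate.  After smoothing, each junction node
  is re-placed at the least-squares intersection of straight lines fitted
  to the incident centerlines over the window 1–3 local radii from the
  node.  Where the node has two outgoing daughters, only the daughter lines
  are used — their intersection pins the node in all directions, whereas
  the incoming parent line constrains nothing along its own axis.
  Displacement is capped at two local radii and ill-conditioned
  (near-parallel) fits are skipped.

Polyline smoothing is a moving average with pinned endpoints (window 5 by
default).  A parametric spline would be contract-equivalent; recovery of
the measured quantities, not curve identity, is what the tests check.

## Network quality control

Four exception classes are detected and resolved deterministically, each
action logged to an audit trail that stands in for an operator's visual
inspection:

* **Closed loops** (residual contacts): the cycle edge with the smallest
  mean local diameter is removed — contact bridges are thinner than true
  airways.
* **Spurs** (annular-ligament-style nubs): terminal branches shorter than
  `max(4 voxels, 1.5 × local parent radius)` are pruned; the root branch
  and trifurcation intermediates are exempt.
* **Spurious (degree-2) nodes**: removed by concatenating the two incident
  branches; polyline length is conserved.
* **Trifurcations**: a node with three daughters is split into two
  bifurcations; the two daughters with the most similar departure
  directions move to the new node.  The intermediate airway is recorded
  with length 0.1 mm, branch angle 0°, and the parent's diameter — the
  standard bookkeeping convention for apparent trifurcations.  Because a
  curve skeleton renders a true three-way split as two bifurcations joined
  by a branch much shorter than the local radius, internal branches with
  chord < `max(3 voxels, 1.5 × local mean radius)` are recognised as the
  same phenomenon and flagged as intermediates; clean trees keep internal
  chords several radii long, so the two regimes are well separated.

## Hydraulic-diameter discretisation

Stations are spaced every 2 voxels of arc length, excluding half a local
radius at each end (bifurcation flare).  At each station a square plane of
half-width 2 × local radius is sampled at half-voxel resolution by
trilinear interpolation of the mask; the 0.5-isocontour enclosing the
centerline point gives the section polygon (shoelace area, polyline
perimeter).  The sampled plane is smoothed with a Gaussian of σ = 1.5 plane
pixels first: the raw trilinear isocontour is jagged at the sampling scale,
which inflates the perimeter and deflates `4A/P` by 6–8% on circular
sections; with smoothing the bias is under 1% on circles and under 3% on
square ducts.  A station is discharged when any other branch's dense
polyline passes within the plane half-width in-plane and half a station
step along the normal.

## The synthetic casts

Phantoms are recursive bifurcating trees at mouse-like scale: tracheal
diameter 1.2 mm, per-generation diameter ratio 0.75, branch length = 2.5 ×
diameter (within the L/D range reported for mouse conducting airways; at
2.0 the minor terminal branches of deep generations are engulfed by their
parent junction zones and thinning cannot form their endpoints, so 2.5 is
the default), trachea 1.5 × longer than that rule (anatomically the trachea
is proportionally long, and a short tracheal stub is fragile under
thinning).  The minor/major daughter diameter ratio defaults to 0.8, branch
angles to 33° (major daughters deviate 0.7 × that), and the main bronchi
dive dorsally so the gravity construction is far from degenerate.
Bifurcation-plane azimuths alternate by 90° per generation with per-branch
jitter; candidate azimuths are redrawn (deterministically, from the
branch's own substream) until every non-adjacent pair of branches keeps
0.15 mm of surface clearance, so phantoms never self-touch unless artifacts
are injected deliberately.

Branches are capsules; exposed ends (terminal tips, the proximal tracheal
stub) are cut flat at the true endpoint so ground-truth length is exactly
the node-to-node distance the measurement defines.  Rasterisation has an
analytic volume oracle (π r² L within voxelisation error).  One seeded
generator with substreams keyed by the branch label makes pruning one
subtree leave all others bit-identical.

Artifact injection covers the defect classes real cast scans exhibit: thin
touching-branch bridges (below the opening bandwidth), thick bridges that
survive opening and create true loops, lateral spur nubs, and a third
daughter at a bifurcation.  The injector solves small placement problems so
the defect actually materialises at voxel scale: bridges connect
mid-sections whose surfaces have a minimum gap (a bridge inside a junction
lens changes nothing), spur nubs point into the clearest background
direction, and the extra trifurcation daughter leaves along the normal of
the daughters' plane — any direction closer than ~60° to an existing branch
merges with it for a millimetre before surfacing.

What the phantoms do **not** emulate: grayscale micro-CT physics (noise,
beam hardening, partial volume), airway wall tissue, lobe-specific anatomy
(e.g. strain-specific medial-lobe turns are representable via the curvature
knob but not calibrated), non-circular lumen cross-sections, and real
annular-ligament geometry.  Passing tests demonstrate correct geometry
processing and bookkeeping, not segmentation robustness on real scans.

## Accuracy, tolerances, and what the tests assert

On clean phantoms with all diameters ≥ 8 voxels and lengths ≥ 1.5 ×
diameter, the pipeline recovers per-branch length within max(2 voxels, 3%),
diameter within 5% (typically < 1%), and branch/gravity angles within 5°
(typically < 3°).  The residual error budget is junction-node placement
(±1–2 voxels along ambiguous directions) plus terminal-cap localisation
(±1 voxel).  Under rigid 90°-multiple rotations of the input volume the
same anatomy-defined scalars are recovered within slightly wider bounds
(3 voxels / 5% / 6°): parallel thinning is not exactly rotation-equivariant,
so rotation invariance holds at method tolerance, not at float precision.
Gravity angles deserve a caveat: because `g` is a normalised residual,
small errors in the bronchi directions are amplified by one over the
residual's magnitude; with the default phantom carina (bronchi diving
~35–55° dorsally) the amplification is modest and gravity angles are stable
to a few degrees.

Statistical comparisons follow the conventional recipes: through-origin
least squares (`slope = Σxy/Σx²`) with the ordinary mean-centred Pearson r
reported alongside the uncentred R² (they answer different questions — the
uncentred R² describes the forced fit, r the association); one-way
fixed-effects ANOVA across strains on per-cast generation means (casts are
the replicates; using branches as replicates would pseudo-replicate within
cast and is exposed only as an explicit alternative); paired t tests with
Bonferroni correction (`m` = number of comparisons, reported explicitly).
Degenerate inputs (zero-variance differences, identical groups) are flagged
rather than silently propagated as NaN.

Manual gravity-angle conventions sometimes fold the angle to [0, 90]; the
comparison stage exposes `fold_gravity` for that, default off.

## Problem sizes

The test-suite and acceptance phantoms run at 30–40 μm voxels (grids up to
~330³), where the smallest branch diameters span 5–13 voxels.  This is the
package's chosen desk-scale operating point: it keeps a full six-generation
tree (63 airways) through the complete pipeline in about 1–2 minutes while
preserving every geometric regime the method must handle.  Finer grids
improve the voxel-scale error terms proportionally.  The automatic tracheal
measurement is flagged `root_stub` because scans of real casts begin at the
trachea base and measure only a stub; phantom tracheas are complete, so the
flag is informational.

## Known limitations

* Junction localisation is the accuracy bottleneck; occasional individual
  branches touch the stated tolerance at 30 μm.
* Branch angles of daughters of a trifurcation intermediate are measured
  against the short intermediate's noisy direction — the same limitation
  manual bookkeeping has.
* The loop-resolution rule (remove thinnest cycle edge) is a heuristic; a
  contact bridge thicker than a true airway would defeat it.
* Hydraulic diameters of branches shorter than ~2 diameters rest on very
  few stations; the zero-flag/parent-substitution path is exercised instead.
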