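# Methods

## The reference leg

Clinical body-surface mapping studies standardize lesions onto a
hand-drawn template derived from a 3D photograph.  `itmap` replaces the
drawing with a parametric surface so that areas, zone memberships,
landmark positions and surface distances are all computable and exactly
reproducible: a tube of elliptical cross-sections swept along an
L-shaped centerline — foot (horizontal), a quarter-circle ankle bend,
lower leg with a calf bulge, thigh — capped at the toes and proximal
thigh.  Default dimensions (cm) approximate an adult limb: foot length
24, foot half-width 4.5, half-height 3.5, ankle radius 4, lower leg 38
with calf radius 5.5, thigh 40 with radius 7.5.  The canonical frame is
a left leg with +z proximal, +y anterior, +x medial.

Bone landmarks are placed analytically at frame-axis meridians (the
circumferential resolution must be a multiple of 4 so those meridians
pass through vertices): patella at the anterior knee, medial/lateral
malleolus at the ankle ring, toe tips 1 and 5 at the medial/lateral toe
rim.  Their coordinates are closed-form in the shape parameters and
independent of mesh resolution, which is what the registration tests
exploit.

Joint posture is a construction-time choice (the canonical mesh is a
straightened leg); it is not a runtime correction.

## Drainage territories

The four territories of the distal lower limb — posterolateral (red),
posteromedial (yellow), anterolateral (green), anteromedial (blue,
including the toes) — are modeled as angular sectors of the
cross-section around the limb axis.  The published boundaries exist
only as colored regions in a figure, so the sector meridians are
configurable; the default is four equal 90° sectors centered on the
anteromedial / anterolateral / posterolateral / posteromedial
directions (boundaries at the medial, anterior, lateral and posterior
meridians).  Sector labeling: the circle is cut at the sorted meridians
into half-open arcs [mᵢ, mᵢ₊₁); each arc takes the territory whose
canonical center direction (45°, 135°, 225°, 315°, measured from +x
medial toward +y anterior) lies inside it.  A face centroid exactly on
a meridian therefore belongs to the counter-clockwise sector — the
documented tie-break.

Two anatomical overrides: toe-region faces (distal quarter of the foot
by default) are always anteromedial, and plantar faces default to
anteromedial but are configurable (`plantar_zone=None` disables the
override) because toe and plantar drainage have not been resolved
anatomically.  On the thigh the same angular rule extends the sectors
proximally so that zone assignment is total on the mesh; anatomically
the territories are established only distally, which is why the lesion
generator refuses thigh primaries.

The 2D templates are orthographic projections (lateral, medial,
anterior, dorsal); only front-facing faces contribute to a view, and
zone polygons are clipped in enumeration order so that within a view
they are interior-disjoint and tile the silhouette exactly.  Points on
shared 2D boundaries resolve to the lower-enumeration zone.

## Standardization of patient coordinates

Right-sided acquisitions are reflected across the sagittal plane
(x → −x) so a left leg is always analyzed; the reflection is an exact
involution and the `side` field keeps recording the anatomical origin.
Landmark registration is rigid — rotation plus translation, six degrees
of freedom, no scaling — via the closed-form orthogonal least-squares
(Kabsch) solution with reflection correction; at least three
non-collinear shared landmarks are required.  An optional uniform-scale
(7-DOF, Umeyama) mode exists for cohorts with large size variation but
is off by default, since the standardization protocol this implements
is rigid.  Registered points are snapped to the nearest point of the
reference surface (exhaustive nearest-triangle query); the snap
distance is recorded per lesion and lesions farther than 3 cm (default)
are flagged unmappable and excluded rather than silently assigned.

## Geodesic distances

Skin-surface distance is approximated by Dijkstra on a graph over the
mesh: nodes are vertices plus 2^(r+1)−1 Steiner points per edge at
refinement level r (default 3); within each triangle all boundary nodes
are pairwise connected in the face plane; and nodes of adjacent
triangles are additionally linked at their unfolded-across-the-shared-
edge straight-line length whenever that line crosses the edge (a
one-level window, the exact two-face geodesic).  Query points enter as
temporary nodes with the same in-face and window links.  Node sets are
nested across levels, so path length is non-increasing in refinement;
endpoint order is canonicalized so distance(a,b) equals distance(b,a)
bit-exactly.

Accuracy against analytic oracles: worst error ≈ 0.1% on a planar patch
for separations of at least two edge lengths (below that scale the
discretization dominates and errors can reach ~1%), and ≈ 0.3% against
the developed arc on a cylinder at the default mesh density — ample for
distances reported to 0.1 cm.  The graph path is a valid surface path,
so it upper-bounds the polyhedral geodesic; on smooth surfaces the
polyhedral approximation itself can slightly undercut the true smooth
geodesic (the cylinder error is negative).

## Concordance and statistics

The primary's territory defines the expected territory for all of that
patient's ITM (one drainage pathway per primary; dual-pathway cases are
not modeled).  Concordance fraction f = ITM in territory / total ITM;
categories full (f ≥ 0.90), partial (0.50 ≤ f < 0.90), none
(f < 0.50); printed percentages use half-up rounding.

Site comparison and continuous covariates share one rank-test engine:
Mann–Whitney U with tie-corrected variance and the normal approximation
without continuity correction (the asymptotic default of standard
clinical software; on the published ordinal counts it gives z = −2.69,
p = 0.007).  If ties exhaust the rank variance the test is degenerate
and reported as z = 0, p = 1.  An exact enumeration mode (total n ≤ 22)
is provided; at very small samples the asymptotic and exact p can
differ by far more than rounding (worst observed ≈ 0.5 at 4 vs 4 with
heavy ties), so small-sample work should use the exact mode.

Contingency tests are Pearson chi-square without continuity correction.
Logistic models use the clinical coding: age ≥ 55 vs < 55, subtype with
SSM reference (melanoma of unknown primary excluded — it has no
primary-tumor covariates), Breslow thickness ≥ 1.0 vs < 1.0 mm,
ulceration present vs absent, site with foot reference.  Records
missing a covariate are dropped from models containing it.  Effects are
reported as odds ratios with 95% Wald intervals (some published tables
label such columns "hazard ratio"; no time-to-event model is involved
and the quantities here are odds ratios).  Complete separation or
non-convergence is flagged on the estimate, never silent.

## The synthetic generator

No patient-level data accompany the study this package models, so the
generator defines the study conditions under which everything is
validated.

Cohort: covariate marginals follow the published cohort (31% male, age
≈ N(56, 16²) truncated to 18–97, subtype shares SSM/NM/ALM/NOS/MUP ≈
61/17/12/9/1%, log-normal Breslow thickness with median 1.2 mm,
ulceration 22%, site mix foot/lower leg/thigh ≈ 20/42/38%).  The ITM
outcome is drawn from a logistic model whose default coefficients are
the published multivariate odds ratios (NM 2.6, ALM 2.7, NOS 1.7,
thickness ≥ 1 mm 5.7, ulceration 2.1, age ≥ 55 1.5, lower leg 1.8,
thigh 0.6) with intercept −2.6; age and thickness are rounded to
reporting precision before the outcome draw so the recorded covariates
are exactly the generative ones.  Missingness (thickness 2%, ulceration
3%, plus the MUP rule) is applied after the outcome draw and
independently of it.

Lesions: the primary is area-uniform over its site's faces.  Each ITM
falls in the primary's territory with probability φ (site-specific:
`phi_foot`, `phi_leg`) and otherwise area-uniform over the other three
territories; placement is proximally biased (80% of ITM proximal to the
primary, the published marginal) with an exponential axial decay of
20 cm so distances land in the published 2–70 cm envelope.  Scar-center
localization is emulated by 0.5 cm tangential jitter, resampled if it
would flip the intended in/out-of-territory state — φ is therefore the
exact per-ITM territory probability.  ITM counts per patient follow the
published category distribution (1–5 / 6–10 / 11–20 / >20 at
42/22/17/19%, the >20 category capped at 30).  Observed data are the
true positions pushed through a random rigid motion (and mirroring for
the ~50% right-sided patients) with 0.2 cm landmark noise.  Randomness
is keyed per (seed, patient), so single patients regenerate stably
under cohort-size changes.

The preset `paper_like_config` solves φ analytically (binomial
marginalized over the count distribution, Brent root-finding) so the
expected full-match share is 71% on the lower leg (φ ≈ 0.921) and 20%
on the foot (φ ≈ 0.708).  A single-φ mechanism reproduces the
full-match shares but not the published partial/none split — with a
mean in-territory fraction near 0.7 most foot patients land in the
partial band, whereas the clinical foot data are bimodal.  That is a
structural limitation of treating φ as one homogeneous Bernoulli rate
per site (e.g. no per-patient heterogeneity from surgically disrupted
drainage), not a fitting target of this package.

What passing simulations do and do not show: they validate the
machinery — mapping is exact under noise-free acquisition, the site
test holds its nominal size, the logistic model recovers its
coefficients — under idealized geometry (one canonical limb shape, no
posture variation, no photographic annotation error beyond the modeled
jitter and landmark noise).  They do not validate the anatomical truth
of the territory boundaries on real limbs.

## Validation design and problem sizes

The test suite and the acceptance script use a 16-segment reference
mesh (≈1700 faces), geodesic refinement 2–3, 500 category-level
replicates for the size of the site comparison, 200 cohorts of n = 2000
for logistic recovery, and 30 pipeline replicates at cohort scale
(31 + 15 patients) for the full-match medians — sizes at which the
Monte-Carlo error of each reported quantity is small against its
tolerance.  Type-I error of the site comparison is calibrated at the
category level (ITM count, then a Binomial(n, φ) in-territory count),
which is exactly the distribution the surface-level generator induces;
coverage of the logistic Wald intervals is assessed pooled over the
eight coefficients (1600 intervals), since per-coefficient coverage at
200 replicates carries ±1.5% binomial noise.

## Numerical conventions and degenerate inputs

- Percentages: half-up rounding (`round_half_up`), matching the
  published tables.
- Zone tie-breaks: counter-clockwise sector at a 3D meridian;
  lower-enumeration zone on a 2D boundary.
- Collinear or <3 landmarks: degenerate-configuration error.  Mixed
  sides in one patient: input error.  Zero or multiple primaries:
  patient unevaluable, excluded and listed.  Empty ITM list:
  concordance undefined, patient excluded.  Zero contingency marginal:
  degenerate-table error.
- Determinism: identical parameters and seeds give byte-identical
  meshes, templates, cohorts and pipeline reports.

## Known limitations

- The leg is a smooth tube: no toes as separate digits, no heel
  protrusion, no posture articulation; the foot's drainage complexity
  (interdigital injection sites, plantar ambiguity) is reduced to two
  configurable overrides.
- Territory boundaries are an explicit approximation (equal 90°
  sectors) to anatomy published only as colored figures; they are
  configurable but not calibrated.
- Registration is rigid; shape mismatch between patient and reference
  is absorbed by surface snapping, not by deformable alignment.
- The generator's φ is a homogeneous per-site rate; surgically altered
  drainage is representable only as a lower φ.
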