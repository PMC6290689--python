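# Methods

## Scope and model

`aneuvar` post-processes per-team submissions of a vascular CFD challenge:
a triangulated lumen surface carrying a per-vertex WSS-magnitude field
(steady or time-averaged pulsatile fields are treated identically) and
planar velocity cross-sections. Submissions are assumed co-registered;
region definitions (clipping planes, slice planes, outlet slices, seeds)
are supplied per submission and applied identically to every team.
Segmentation, registration, CFD solving and time-resolved metrics (OSI and
relatives) are out of scope.

Units are fixed by convention: mm (coordinates), Pa (WSS), cm/s (velocity),
mL/s (flow), cP (viscosity), g/cm³ (density). Conversions use exact factors
(1 cP = 10⁻³ Pa·s, 1 mL/s = 10⁻⁶ m³/s, mm²·cm/s = 10⁻² mL/s).

## Geometry

**Clipping** uses exact triangle splitting (Sutherland–Hodgman per
triangle) with linear interpolation of vertex fields onto cut vertices, so
kept + discarded area reproduces the original to round-off and region areas
carry no whole-triangle resolution bias — this matters because LSA is an
area fraction. After clipping, the connected component nearest the supplied
seed point is selected; this is how one set of planes isolates the sac and
parent band on every team's surface.

**Sections.** Plane–mesh intersections are chained into closed loops; the
loop whose centroid is nearest the plane origin is taken as the lumen
contour (slice origins are placed inside the target vessel). Area comes
from the shoelace formula in an in-plane orthonormal basis, and
`D = 2√(A/π)`. Velocity patches are integrated with linear (per-triangle
vertex-average) quadrature: vector data contribute `v·n` (only the
through-plane component matters); magnitude-only submissions fall back to
`|v|`, and the result carries a mode tag. Per-slice areas and velocities
are arithmetically averaged (1–5 slices) before deriving `D` and `Q`.

**Surface averages** use vertex-lumped areas (one third of incident
triangle area): exactly conservative and simple to test.

## Hemodynamic parameters

`Re = ρV̄D/μ` and `τ_P = 32μQ/(πD³)` are evaluated in SI. The Poiseuille
formula includes the factor π — the standard fully-developed laminar-tube
form. Sac metrics: AWSS is the vertex-area-weighted mean, MWSS the maximum
vertex value (no percentile capping — the definition is the sac maximum),
and LSA the area fraction below the threshold, computed on sub-triangle
regions bounded by the linear isocontour of the interpolated field; the
vertex-lumped estimate is retained as a cross-check (`lsa_lumped`) and the
two converge under refinement. Thresholds default to 0.4 Pa (absolute) and
κ = 0.1 × parent WSS (relative); both are configuration keys.

Derived quantities (wss_ratio, starred metrics) are computed per case and
only then averaged across cases — never as ratios of case-averages.

### Exact normalization arithmetic

Normalized parameters (AWSS*, MWSS*, LSA*) are computed in exact
dyadic-rational arithmetic: numerators and denominators are accumulated as
integer mantissa/exponent sums (doubles are dyadic rationals) and rounded
once at the end. Consequently a uniform rescaling of the WSS field that is
itself exact in floating point cancels *identically* — the normalized
metrics are bit-identical, not merely close. Generated WSS fields are
quantized to float32 (the native precision of CFD surface exports), which
makes small-integer rescalings such as ×10 exact in float64. LSA*
comparisons and isocontour parameters are likewise evaluated rationally,
so the same cancellation holds for the relative-threshold area fraction.

## Cohort statistics

Dispersion is summarized as median, Q1–Q3 and CoD = (Q3−Q1)/(Q3+Q1),
extended to the 10th/90th percentiles since the IQR by construction covers
only half the cohort. The default quantile estimator is linear
interpolation at rank p(n+1) clamped to [1, n] (the "exclusive"
convention of GraphPad Prism); the estimator is an argument
(`exclusive`/`inclusive`/`linear`) so conventions can be compared. CoD is
scale-invariant but not location-invariant (tested).

Case-average statistics drop a team entirely if *any* case is missing for
the parameter — the strict rule that makes WSS-derived and
velocity-derived N differ in an incomplete cohort. Intra-team differences
use the symmetric percent difference 200·|b−a|/(a+b). Normality screening
is the D'Agostino–Pearson omnibus (`scipy.stats.normaltest`, n ≥ 8);
group comparisons use tie-corrected Kruskal–Wallis with Dunn's post hoc
z-tests. The familywise adjustment for Dunn is Bonferroni by default
(Holm and unadjusted are options) since the convention is not fixed by the
analysis design; a fully degenerate input (all values identical) returns
H = 0, p = 1 rather than an error. Rank-ordering assigns rank 1 to the
lowest value, breaks ties deterministically by case-label order (flagged),
and "consensus" at a rank requires strictly more than half of the ranked
teams. The reported-vs-computed QA check is OLS with intercept (forcing
through the origin was considered and rejected as less diagnostic;
R² is the squared Pearson correlation).

## Synthetic cohort

The generator builds an idealized aneurysm from analytic primitives so
that every metric has a closed form — the entire point of the module;
realism enters through the perturbation model, not the shape. The
reference geometry is a straight parent tube (default D₀ = 2.45 mm,
30 mm long, Q₀ = 2.40 mL/s — normal adult MCA levels), a spherical sac
(S₀ = 8 mm) offset from the tube axis, and two outlet branch tubes
(outflow split 0.65). The primitives overlap rather than being
boolean-united: no metric in scope needs a watertight union, and each
clipped region keeps its closed form. The five default cases vary
calibre, sac size, flow and split mildly; the fourth case carries a
single inflow slice (the others five).

Velocity sections carry the parabolic profile v(ρ) = 2V̄(1−(2ρ/D)²); the
parent WSS field is r·τ_P with a configurable shape factor r (default 1;
r ≈ 1.5 mimics the not-fully-developed profiles of real parent arteries).
The sac field is linear in u = (1−cosθ)/(1−cosθ_max), the fraction of cap
area between the apex and polar angle θ: w(u) = τ_sac·(s_apex + (s_neck −
s_apex)·u) with defaults s_apex = 0.02, s_neck = 1.10 (chosen so
AWSS* = 0.56, a mid-range value for sac-to-parent ratios). Because u is
uniform over cap area, AWSS = τ_sac·(s_apex+s_neck)/2, MWSS = τ_sac·s_neck
and LSA(τ) = clip((τ/τ_sac − s_apex)/(s_neck − s_apex), 0, 1) — verified
against adaptive quadrature to 10⁻⁶. The sac-delineation plane is aligned
with a sphere vertex ring (mesh-conforming clip), which keeps the rim
field values unperturbed by interpolation; mesh resolution is a single
parameter (circumferential vertex count, default 64) and all recovery
errors decrease as O(h²).

Per team, the perturbation model draws: a diameter factor
ε ~ lognormal(0, σ_D) with σ_D = 0.034 (echoing a 3.4% inter-team diameter
CoD) applied as a uniform geometric scale; an inflow scaling law Q = Q₀·εⁿ
with n ∈ {0, 1, 2, 3, other} at frequencies 6/2/10/4/4 out of 26 ("other"
is implemented as n = 1.5, a mid-range power law); viscosity
{3.5, 3.7, 4.0} cP at 12/2/12; density uniform in 1.05–1.06 g/cm³ (22/26)
or 1.00–1.05 (4/26); independent lognormal WSS-level factors η_parent and
η_sac (σ = 0.15, standing in for solver/segmentation differences — chosen
to give normalized-metric dispersion of the order seen between real
teams); and a 3/26 chance of providing velocity magnitudes instead of
vectors. Questionnaire metadata (experience 5/13/8 high/medium/low,
steady 15/26, MCA inlet 17/26) is sampled at the same frequencies. Teams
and datasets are independent config values (`n_teams` defaults to 28
datasets). Same seed + config gives byte-identical cohorts.

Because Q is tied to the diameter factor, inflow-driven variability in
this model is modest (flow CoD of a few percent, versus tens of percent
among real teams who choose flow rates freely); the WSS-level noise terms
are what carry most of the sac-metric dispersion. What passing tests show
is therefore that the *pipeline* recovers and summarizes a known
variability structure exactly — not that the generator reproduces every
variance component of real multi-team data. Real submissions also differ
in morphology, neck delineation, smoothing and model extent, none of
which the idealized geometry emulates.

## Numerical choices and problem sizes

Planarity tolerance for sections: 10⁻⁶ × patch diameter. Clip-plane
normals are unit to 10⁻⁹. Degenerate triangles contribute zero area. Ties
in ranking are broken by case-label order and flagged. Report tables round
CoD and %diff to integers while raw values are always retained. Test and
acceptance runs use the default resolution (64) for single-submission
checks and convergence pairs (48/96), and a reduced resolution (32) for
the 200-team dispersion cohort, where discretization bias is common to
all teams and cancels in CoD; these sizes keep the full suite under half
a minute while leaving every tolerance dominated by the property being
tested.

## Known limitations

- Idealized tube+sphere geometry: no bleb/daughter-sac morphology, no
  neck irregularity, no model-extent variation.
- The sac WSS profile is monotone from apex to neck; real sacs show
  impingement maxima whose MWSS can sit an order of magnitude above AWSS.
- Steady fields only; pulsatility enters only as "time-averaged" input.
- The exact-rational normalization guarantees bit-level scale invariance
  only when the field rescaling itself is exact in floating point (true
  for float32-quantized fields and small integer factors).
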