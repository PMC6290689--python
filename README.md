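# aneuvar

**Inter-team variability analysis of aneurysm wall-shear-stress predictions
from image-based CFD.**

When different research teams run the full patient-specific CFD pipeline —
segmentation, boundary conditions, solver — on the *same* medical images of
an intracranial aneurysm, their predicted wall shear stress (WSS) fields can
differ substantially. `aneuvar` implements the centralized analysis used to
quantify that variability in multi-team challenge settings: it reduces each
team's submitted lumen surface (with a per-vertex WSS-magnitude field) and
velocity cross-sections to a standardized set of parent-artery and
aneurysm-sac hemodynamic parameters, and then summarizes agreement across
teams nonparametrically. A synthetic virtual-challenge generator with
closed-form ground truth makes the whole pipeline testable end to end
without any patient data.

It is written for researchers in computational hemodynamics who need
objective, reproducible post-processing of vascular CFD surface data.

## The quantities computed

Parent (MCA) segment, from lumen areas `A` and mean through-plane
velocities `V̄` averaged over 1–5 transverse slices:

- effective diameter `D = 2√(A/π)` (circular cross-section assumption)
- flow rate `Q = A·V̄`, Reynolds number `Re = ρV̄D/μ`
- Poiseuille WSS `τ_P = 32μQ/(πD³)` and the CFD-calculated WSS `τ_c`
  (area-weighted mean over a consistently clipped parent band), plus their
  ratio `τ_c/τ_P`
- outflow division: fraction of outlet flow through the dominant branch

Aneurysm sac, isolated with the same clipping planes for every team
(triangles are split exactly along the planes):

- `AWSS` (sac-averaged WSS, Pa), `MWSS` (sac maximum, Pa)
- `LSA`: sac area fraction with WSS below 0.4 Pa, measured on exact
  sub-triangle isocontours
- normalized counterparts `AWSS* = AWSS/τ_c`, `MWSS* = MWSS/τ_c`, and
  `LSA*` with the relative threshold `0.1·τ_c`

Cohort statistics: median, interquartile range and the quartile coefficient
of dispersion `CoD = (Q3−Q1)/(Q3+Q1)` (plus 10th/90th percentiles),
"case-average" statistics with a strict missing-data rule,
D'Agostino–Pearson normality screening, Kruskal–Wallis with Dunn's post hoc
tests, symmetric intra-team percent differences, rank-order consensus
across teams, and an OLS quality-assurance regression.

## Worked example

```bash
python examples/01_reference_recovery.py
```

builds the idealized reference aneurysm (a 2.45 mm parent tube carrying
2.40 mL/s with an 8 mm spherical sac), runs the full mesh pipeline, and
compares against closed forms:

```
parameter            pipeline  closed form   err %
diameter (mm)          2.4480       2.4500   0.080
flow rate (mL/s)       2.3930       2.4000   0.291
Poiseuille WSS         5.8152       5.8181   0.050
calculated WSS         5.8181       5.8181   0.000
WSS ratio (-)          1.0005       1.0000   0.050
AWSS (Pa)              3.2588       3.2581   0.021
LSA (-)                0.0449       0.0451   0.494
```

Every parameter is recovered to well under 1%; the WSS ratio ≈ 1.00 says
the averaged parent-band WSS of a fully developed tube matches the
Poiseuille estimate. `examples/02_cohort_variability.py` samples a
28-team virtual cohort and shows how normalization by parent WSS cancels
the inflow-driven part of the spread; `examples/03_rank_consensus_and_tests.py`
demonstrates rank-order consensus and the Kruskal–Wallis/Dunn layer.

The same pipeline is scriptable from the shell:

```bash
aneuvar generate --out cohort/ --seed 1 --n-teams 28
aneuvar metrics --cohort cohort/ --out metrics.csv
aneuvar summarize --metrics metrics.csv --out summaries/
```

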