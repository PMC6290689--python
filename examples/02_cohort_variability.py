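"""Inter-team variability of a virtual challenge cohort.

Samples 28 virtual team submissions of one case (diameter scale, inflow
scaling law Q ~ D^n, viscosity, density and WSS-level noise all drawn from
menus with realistic frequencies), runs the pipeline on each, and
summarizes the spread of every parameter with the quartile coefficient of
dispersion CoD = (Q3-Q1)/(Q3+Q1).

A second cohort switches the per-team WSS-level noise off, so the teams
differ *only* in inflow magnitude, diameter scale and blood properties:
there the sac WSS still varies, but its parent-normalized counterpart
AWSS* collapses to a constant — normalization removes exactly the
inflow-driven part of the variability.
"""

from aneuvar import BloodProperties, compute_submission, summary
from aneuvar.synthetic import PerturbationConfig, ReferenceCase, sample_cohort

params = ("flow_rate", "poiseuille_wss", "calculated_wss", "awss", "mwss",
          "lsa", "awss_star", "mwss_star", "lsa_star")


def cohort_values(pert, seed):
    subs = sample_cohort(ReferenceCase(), pert, n_teams=28, seed=seed)
    values = {p: [] for p in params}
    for sub in subs:
        props = BloodProperties(density=sub.meta.density,
                                viscosity=sub.meta.viscosity)
        r = compute_submission(sub.mesh, sub.sections, sub.regions, props)
        for p in params:
            v = getattr(r.parent, p, None)
            values[p].append(v if v is not None else getattr(r.sac, p))
    return values


print("full perturbation menu (28 teams):")
values = cohort_values(PerturbationConfig(), seed=7)
print(f"{'parameter':16s} {'median':>8s} {'Q1-Q3':>17s} {'CoD %':>6s}")
for p in params:
    s = summary(values[p])
    print(f"{p:16s} {s.median:8.3f} {s.q1:8.3f}-{s.q3:8.3f} "
          f"{100 * s.cod:6.1f}")

print("\ninflow/property perturbations only (WSS-level noise off):")
quiet = PerturbationConfig(wss_noise_sd=0.0, magnitude_only_prob=0.0)
values_q = cohort_values(quiet, seed=7)
for p in ("awss", "awss_star"):
    s = summary(values_q[p])
    print(f"{p:16s} CoD = {100 * s.cod:8.4f} %")

print("\nWith WSS noise off, AWSS still varies (teams assume different flow"
      "\nrates and viscosities) but AWSS* is constant to discretization"
      "\nprecision: dividing by each team's own parent WSS cancels the"
      "\ninflow-driven variability. In the full cohort, independent parent-"
      "\nand sac-field noise is what keeps AWSS* dispersed.")
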