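"""Virtual-challenge generator: idealized aneurysm geometry with analytic fields.

The reference "patient" is an idealized MCA bifurcation aneurysm built from
analytic primitives — a straight parent tube (diameter ~2.4 mm), a spherical
sac (~8 mm) offset from the tube axis, and two outlet branch tubes — so that
every hemodynamic parameter in scope has a closed form.  A cohort of virtual
team submissions is produced by perturbing, per team, the segmentation scale
(lognormal diameter factor), the inflow-scaling law Q ~ D^n, blood viscosity
and density (menu frequencies mirroring the real challenge questionnaire),
and the WSS field level (independent lognormal factors for the parent and
sac fields, standing in for solver/segmentation differences).

Sac WSS profile: with u = (1 - cos(theta)) / (1 - cos(theta_max)) the
fraction of cap area between the apex and polar angle theta, the field is
linear in u, w(u) = tau_sac * (s_apex + (s_neck - s_apex) * u).  Because u
is uniformly distributed over the cap area, every area statistic is a 1-D
integral with uniform weight:

    AWSS = tau_sac * (s_apex + s_neck) / 2
    MWSS = tau_sac * s_neck
    LSA(tau) = clip((tau/tau_sac - s_apex) / (s_neck - s_apex), 0, 1)

WSS vertex fields are quantized to float32 (the native precision of CFD
surface exports); the sac-delineation plane is aligned with a sphere vertex
ring so the sac clip is mesh-conforming.  Together these make the
normalized-metric invariance under an exact uniform field rescaling hold to
the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from .errors import GeometryGenerationError
from .hemodynamics import (
    BloodProperties,
    ParentMetrics,
    SacMetrics,
    SectionSet,
    SubmissionMetrics,
    KAPPA_DEFAULT,
    TAU_LOW_DEFAULT,
    poiseuille_wss,
    reynolds,
)
from .io_formats import (
    ClipPlaneDef,
    CrossSectionPatch,
    OutletSliceDef,
    RegionSet,
    SlicePlaneDef,
    SurfaceMesh,
    TeamMeta,
    read_regions,
    read_section,
    read_surface,
    write_regions,
    write_section,
    write_surface,
)

__all__ = [
    "ReferenceCase",
    "PerturbationConfig",
    "TruthRecord",
    "VirtualSubmission",
    "make_reference",
    "sample_cohort",
    "oracle_metrics",
    "scale_wss_fields",
    "default_cases",
    "save_submission",
    "load_submission",
]


@dataclass
class ReferenceCase:
    """Parameters of one idealized aneurysm case (all closed-form testable)."""

    case_id: str = "case1"
    parent_diameter: float = 2.45    # mm, cohort-median MCA calibre
    sac_diameter: float = 8.0        # mm
    parent_length: float = 30.0      # mm (~12 diameters of tube)
    outlet_diameters: tuple = (2.0, 1.6)   # mm
    outflow_split: float = 0.65      # fraction of flow to dominant branch
    flow_rate: float = 2.40          # mL/s, normal adult MCA level
    props: BloodProperties = field(default_factory=BloodProperties)
    resolution: int = 64             # circumferential vertex count
    n_slices: int = 5
    wss_shape_factor: float = 1.0    # parent WSS / Poiseuille WSS (r~1.5
    #                                  emulates not-fully-developed profiles)
    s_apex: float = 0.02             # sac WSS at dome apex / parent WSS
    s_neck: float = 1.10             # sac WSS at neck rim / parent WSS
    sac_cap_cos: float = -0.5        # cos(theta_max) of the sac cap (120 deg)
    sac_offset_factor: float = 0.7   # sac centre at tube_radius + f * sac_radius

    def validate(self) -> None:
        rt = self.parent_diameter / 2.0
        rs = self.sac_diameter / 2.0
        zc = rt + self.sac_offset_factor * rs
        if zc - rs >= rt:
            raise GeometryGenerationError("sac sphere does not reach the tube")
        if zc + rs * self.sac_cap_cos <= rt:
            raise GeometryGenerationError(
                "sac neck plane intersects the parent tube; raise the sac "
                "offset or shrink the cap")
        if not 0 < self.s_apex < self.s_neck:
            raise GeometryGenerationError("need 0 < s_apex < s_neck")
        if not 1 <= self.n_slices <= 5:
            raise GeometryGenerationError("slice count must be in 1..5")


@dataclass
class PerturbationConfig:
    """Per-team perturbation menus, with frequencies mirroring the real cohort.

    Of 26 teams: inflow scaling exponents n = 0/1/2/3/other occurred
    6/2/10/4/4 times; viscosities 3.5/3.7/4.0 cP occurred 12/2/12 times;
    density was 1.05-1.06 g/cm^3 for 22 and 1.00-1.05 for 4; three teams
    provided velocity magnitudes only.  ``sigma_d`` is the relative s.d. of
    the lognormal per-team diameter factor (default 0.034, echoing the 3.4%
    diameter CoD); ``wss_noise_sd`` is the s.d. of the independent lognormal
    factors applied to the parent and sac WSS fields.
    """

    sigma_d: float = 0.034
    scaling_exponents: tuple = (0, 1, 2, 3, "other")
    scaling_probs: tuple = (6 / 26, 2 / 26, 10 / 26, 4 / 26, 4 / 26)
    other_exponent: float = 1.5
    viscosities: tuple = (3.5, 3.7, 4.0)
    viscosity_probs: tuple = (12 / 26, 2 / 26, 12 / 26)
    density_range: tuple = (1.05, 1.06)
    density_other_range: tuple = (1.00, 1.05)
    density_other_prob: float = 4 / 26
    wss_noise_sd: float = 0.15
    magnitude_only_prob: float = 3 / 26
    experience_probs: tuple = (5 / 26, 13 / 26, 8 / 26)  # high/medium/low
    steady_prob: float = 15 / 26
    inlet_mca_prob: float = 17 / 26

    def __post_init__(self) -> None:
        for probs in (self.scaling_probs, self.viscosity_probs,
                      self.experience_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("menu probabilities must sum to 1")
        if self.sigma_d < 0 or self.wss_noise_sd < 0:
            raise ValueError("sigma values must be >= 0")


@dataclass
class TruthRecord:
    """Sampled perturbations + the quantities they imply, all closed-form."""

    case_id: str
    team_id: str
    diameter: float          # mm (team's parent diameter, eps * D0)
    flow_rate: float         # mL/s (Q0 * eps^n)
    viscosity: float         # cP
    density: float           # g/cm^3
    eps: float               # diameter scale factor
    exponent: float          # inflow-scaling exponent actually applied
    eta_parent: float        # parent-field WSS noise factor
    eta_sac: float           # sac-field WSS noise factor
    shape_factor: float      # parent WSS / Poiseuille WSS
    s_apex: float
    s_neck: float
    outflow_split: float
    is_magnitude_only: bool = False

    def to_dict(self) -> dict:
        return {k: (bool(v) if isinstance(v, (bool, np.bool_)) else
                    v if isinstance(v, str) else float(v))
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


@dataclass
class VirtualSubmission:
    """One virtual team's dataset: mesh + sections + regions + metadata.

    ``truth`` records every sampled perturbation, from which
    :func:`oracle_metrics` recomputes all expected metrics in closed form.
    """

    mesh: SurfaceMesh
    sections: SectionSet
    regions: RegionSet
    meta: TeamMeta
    truth: TruthRecord


# --------------------------------------------------------------------------
# primitive meshes
# --------------------------------------------------------------------------

def _tube(radius: float, x0: float, x1: float, n_circ: int, n_ax: int,
          direction: np.ndarray | None = None,
          origin: np.ndarray | None = None):
    """Open cylinder surface along ``direction`` (default +x from (x0,0,0))."""
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    stations = np.linspace(x0, x1, n_ax + 1)
    if direction is None:
        axis = np.array([1.0, 0.0, 0.0])
        base = np.array([0.0, 0.0, 0.0])
    else:
        axis = np.asarray(direction, dtype=float)
        axis = axis / np.linalg.norm(axis)
        base = np.asarray(origin, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    circ = radius * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
    pts = (base[None, None, :] + stations[:, None, None] * axis[None, None, :]
           + circ[None, :, :]).reshape(-1, 3)
    tris = []
    for j in range(n_ax):
        a = j * n_circ + np.arange(n_circ)
        b = j * n_circ + (np.arange(n_circ) + 1) % n_circ
        c = a + n_circ
        d = b + n_circ
        tris.append(np.stack([a, b, d], axis=1))
        tris.append(np.stack([a, d, c], axis=1))
    return pts, np.vstack(tris).astype(np.int64)


def _sphere(center: np.ndarray, radius: float, n_theta: int, n_phi: int):
    """UV sphere; returns (points, triangles, cos_theta per vertex, ring z's).

    Ring i sits at polar angle theta_i = i*pi/n_theta measured from the +z
    apex; all ring-i vertices share one computed z value, so a clip plane
    through a ring is exactly mesh-conforming.
    """
    cx, cy, cz = center
    pts = [np.array([cx, cy, cz + radius])]
    cos_t = [1.0]
    ring_z = {}
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    for i in range(1, n_theta):
        theta = np.pi * i / n_theta
        ct, st = np.cos(theta), np.sin(theta)
        z = cz + radius * ct
        ring_z[i] = z
        ring = np.stack([cx + radius * st * np.cos(phi),
                         cy + radius * st * np.sin(phi),
                         np.full(n_phi, z)], axis=1)
        pts.append(ring)
        cos_t.append(np.full(n_phi, ct))
    pts.append(np.array([cx, cy, cz - radius]))
    cos_t.append(-1.0)
    points = np.vstack([np.atleast_2d(p) for p in pts])
    cos_theta = np.concatenate([np.atleast_1d(c) for c in cos_t])

    tris = []
    first = lambda i: 1 + (i - 1) * n_phi  # noqa: E731
    # apex fan
    a = np.arange(n_phi)
    tris.append(np.stack([np.zeros(n_phi, int), first(1) + a,
                          first(1) + (a + 1) % n_phi], axis=1))
    for i in range(1, n_theta - 1):
        top = first(i) + a
        top2 = first(i) + (a + 1) % n_phi
        bot = first(i + 1) + a
        bot2 = first(i + 1) + (a + 1) % n_phi
        tris.append(np.stack([top, bot, bot2], axis=1))
        tris.append(np.stack([top, bot2, top2], axis=1))
    south = len(points) - 1
    tris.append(np.stack([first(n_theta - 1) + a,
                          np.full(n_phi, south, int),
                          first(n_theta - 1) + (a + 1) % n_phi], axis=1))
    return points, np.vstack(tris).astype(np.int64), cos_theta, ring_z


def _disc(center: np.ndarray, normal: np.ndarray, radius: float,
          n_r: int, n_phi: int):
    """Triangulated disc; returns (points, triangles, radial distances)."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, normal)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    pts = [np.asarray(center, dtype=float)]
    rho = [0.0]
    for j in range(1, n_r + 1):
        r = radius * j / n_r
        ring = (center + r * np.outer(np.cos(phi), e1)
                + r * np.outer(np.sin(phi), e2))
        pts.append(ring)
        rho.append(np.full(n_phi, r))
    points = np.vstack([np.atleast_2d(p) for p in pts])
    rho = np.concatenate([np.atleast_1d(r) for r in rho])
    first = lambda j: 1 + (j - 1) * n_phi  # noqa: E731
    a = np.arange(n_phi)
    tris = [np.stack([np.zeros(n_phi, int), first(1) + a,
                      first(1) + (a + 1) % n_phi], axis=1)]
    for j in range(1, n_r):
        top = first(j) + a
        top2 = first(j) + (a + 1) % n_phi
        bot = first(j + 1) + a
        bot2 = first(j + 1) + (a + 1) % n_phi
        tris.append(np.stack([top, bot, bot2], axis=1))
        tris.append(np.stack([top, bot2, top2], axis=1))
    return points, np.vstack(tris).astype(np.int64), rho


def _q32(arr: np.ndarray) -> np.ndarray:
    """Quantize to float32 precision (native precision of CFD exports)."""
    return np.asarray(arr, dtype=np.float32).astype(np.float64)


# --------------------------------------------------------------------------
# submission assembly
# --------------------------------------------------------------------------

def _build_submission(case: ReferenceCase, team_id: str, eps: float,
                      exponent: float, viscosity: float, density: float,
                      eta_parent: float, eta_sac: float,
                      is_magnitude_only: bool,
                      meta: TeamMeta) -> VirtualSubmission:
    case.validate()
    res = int(case.resolution)
    rt = eps * case.parent_diameter / 2.0
    rs = eps * case.sac_diameter / 2.0
    length = eps * case.parent_length
    diameter = eps * case.parent_diameter
    q = case.flow_rate * eps ** exponent
    tau_p = poiseuille_wss(viscosity, q, diameter)
    tau_parent_field = eta_parent * case.wss_shape_factor * tau_p
    tau_sac = eta_sac * case.wss_shape_factor * tau_p

    # parent tube
    n_ax = 4 * res
    tube_pts, tube_tris = _tube(rt, 0.0, length, res, n_ax)
    tube_wss = np.full(len(tube_pts), tau_parent_field)

    # sac sphere, apex pointing +z, neck plane on a vertex ring
    n_theta = 3 * max(4, res // 3)
    zc = rt + case.sac_offset_factor * rs
    center = np.array([length * 2.0 / 3.0, 0.0, zc])
    sph_pts, sph_tris, cos_theta, ring_z = _sphere(center, rs, n_theta, res)
    i_cap = int(round(np.arccos(case.sac_cap_cos) / (np.pi / n_theta)))
    i_cap = min(max(i_cap, 2), n_theta - 2)
    z_cap = ring_z[i_cap]
    cos_cap = np.cos(np.pi * i_cap / n_theta)
    u = (1.0 - cos_theta) / (1.0 - cos_cap)
    sph_wss = tau_sac * (case.s_apex + (case.s_neck - case.s_apex) * u)
    if z_cap <= rt:
        raise GeometryGenerationError(
            "sac neck plane intersects the parent tube at this resolution")

    # outlet branches off the distal end
    branch_dirs = [np.array([np.cos(a), np.sin(a), 0.0])
                   for a in (np.radians(35.0), np.radians(-35.0))]
    end = np.array([length, 0.0, 0.0])
    branch_len = 8.0 * eps
    parts_pts = [tube_pts, sph_pts]
    parts_tris = [tube_tris, sph_tris]
    parts_wss = [tube_wss, sph_wss]
    for d_out, direction in zip(case.outlet_diameters, branch_dirs):
        bp, bt = _tube(eps * d_out / 2.0, 0.0, branch_len,
                       max(8, res // 2), max(8, res // 2),
                       direction=direction, origin=end)
        parts_pts.append(bp)
        parts_tris.append(bt)
        parts_wss.append(np.full(len(bp), tau_parent_field))

    offsets = np.cumsum([0] + [len(p) for p in parts_pts[:-1]])
    points = np.vstack(parts_pts)
    tris = np.vstack([t + o for t, o in zip(parts_tris, offsets)])
    wss = _q32(np.concatenate(parts_wss))
    mesh = SurfaceMesh(points, tris, {"wss": wss})

    # velocity cross-sections: parabolic profile v(rho) = 2*V*(1-(rho/R)^2)
    area_true = np.pi * rt ** 2
    v_mean = 100.0 * q / area_true  # cm/s
    n_r = max(4, res // 4)
    xs = np.linspace(length / 6.0, length * 3.0 / 10.0, case.n_slices) \
        if case.n_slices > 1 else np.array([length * 7.0 / 30.0])
    inflow = []
    for x in xs:
        dp, dt, rho = _disc(np.array([x, 0.0, 0.0]), [1.0, 0.0, 0.0],
                            rt, n_r, res)
        prof = 2.0 * v_mean * (1.0 - (rho / rt) ** 2)
        if is_magnitude_only:
            vel = _q32(np.abs(prof))
        else:
            vel = _q32(np.stack([prof, np.zeros_like(prof),
                                 np.zeros_like(prof)], axis=1))
        inflow.append(CrossSectionPatch(dp, dt, [1.0, 0.0, 0.0], vel,
                                        is_magnitude_only=is_magnitude_only))

    outlets = {}
    outlet_defs = []
    labels = ["M2-dominant", "M2-minor"]
    fracs = [case.outflow_split, 1.0 - case.outflow_split]
    for lbl, frac, d_out, direction in zip(labels, fracs,
                                           case.outlet_diameters, branch_dirs):
        r_out = eps * d_out / 2.0
        c = end + 0.5 * branch_len * direction
        dp, dt, rho = _disc(c, direction, r_out, n_r, res)
        v_out = 100.0 * (frac * q) / (np.pi * r_out ** 2)
        prof = 2.0 * v_out * (1.0 - (rho / r_out) ** 2)
        if is_magnitude_only:
            vel = _q32(np.abs(prof))
        else:
            vel = _q32(prof[:, None] * direction[None, :])
        outlets[lbl] = CrossSectionPatch(dp, dt, direction, vel,
                                         is_magnitude_only=is_magnitude_only)
        outlet_defs.append(OutletSliceDef(lbl, c, direction))

    band_lo = length / 3.0
    band_hi = band_lo + 1.2 * diameter
    regions = RegionSet(
        sac_planes=[ClipPlaneDef([center[0], 0.0, z_cap], [0.0, 0.0, 1.0], +1)],
        parent_band_planes=[
            ClipPlaneDef([band_lo, 0.0, 0.0], [1.0, 0.0, 0.0], +1),
            ClipPlaneDef([band_hi, 0.0, 0.0], [1.0, 0.0, 0.0], -1),
        ],
        slice_planes=[SlicePlaneDef([x, 0.0, 0.0], [1.0, 0.0, 0.0]) for x in xs],
        outlet_slices=outlet_defs,
        dominant_outlet=labels[0],
        sac_seed=center + np.array([0.0, 0.0, rs]),
        parent_seed=np.array([(band_lo + band_hi) / 2.0, 0.0, 0.0]),
    )

    truth = TruthRecord(
        case_id=case.case_id, team_id=team_id,
        diameter=diameter, flow_rate=q, viscosity=viscosity, density=density,
        eps=eps, exponent=float(exponent),
        eta_parent=eta_parent, eta_sac=eta_sac,
        shape_factor=case.wss_shape_factor,
        s_apex=case.s_apex, s_neck=case.s_neck,
        outflow_split=case.outflow_split,
        is_magnitude_only=is_magnitude_only,
    )
    return VirtualSubmission(mesh=mesh, sections=SectionSet(inflow, outlets),
                             regions=regions, meta=meta, truth=truth)


def make_reference(case: ReferenceCase) -> VirtualSubmission:
    """The unperturbed reference submission (eps = 1, no WSS noise)."""
    meta = TeamMeta(team_id="ref", experience="high",
                    viscosity=case.props.viscosity,
                    density=case.props.density,
                    inflow_scaling_exponent=0)
    return _build_submission(case, "ref", eps=1.0, exponent=0.0,
                             viscosity=case.props.viscosity,
                             density=case.props.density,
                             eta_parent=1.0, eta_sac=1.0,
                             is_magnitude_only=False, meta=meta)


def sample_cohort(case: ReferenceCase, pert: PerturbationConfig,
                  n_teams: int, seed: int) -> list[VirtualSubmission]:
    """Draw a reproducible cohort of perturbed virtual submissions.

    Each team draws a diameter factor eps ~ lognormal(0, sigma_d), a scaling
    law (so Q = Q0 * eps^n), viscosity, density, WSS noise factors, and
    questionnaire metadata.  Same seed + config -> byte-identical cohort.
    """
    if n_teams < 3:
        raise ValueError("need at least 3 teams")
    rng = np.random.default_rng(seed)
    subs = []
    for t in range(n_teams):
        team_id = f"vt{t + 1:02d}"
        eps = float(rng.lognormal(0.0, pert.sigma_d)) if pert.sigma_d > 0 else 1.0
        law = rng.choice(len(pert.scaling_exponents), p=pert.scaling_probs)
        law_label = pert.scaling_exponents[law]
        exponent = (pert.other_exponent if law_label == "other"
                    else float(law_label))
        visc = float(pert.viscosities[rng.choice(len(pert.viscosities),
                                                 p=pert.viscosity_probs)])
        if rng.random() < pert.density_other_prob:
            dens = float(rng.uniform(*pert.density_other_range))
        else:
            dens = float(rng.uniform(*pert.density_range))
        if pert.wss_noise_sd > 0:
            eta_p = float(rng.lognormal(0.0, pert.wss_noise_sd))
            eta_s = float(rng.lognormal(0.0, pert.wss_noise_sd))
        else:
            eta_p = eta_s = 1.0
        mag_only = bool(rng.random() < pert.magnitude_only_prob)
        experience = ("high", "medium", "low")[
            rng.choice(3, p=pert.experience_probs)]
        meta = TeamMeta(
            team_id=team_id, experience=experience,
            temporal_scheme="steady" if rng.random() < pert.steady_prob
            else "pulsatile",
            inlet_location="MCA" if rng.random() < pert.inlet_mca_prob
            else "ICA",
            inflow_scaling_exponent=law_label,
            viscosity=visc, density=dens)
        subs.append(_build_submission(
            case, team_id, eps=eps, exponent=exponent, viscosity=visc,
            density=dens, eta_parent=eta_p, eta_sac=eta_s,
            is_magnitude_only=mag_only, meta=meta))
    return subs


def oracle_metrics(truth: TruthRecord,
                   tau_low: float = TAU_LOW_DEFAULT,
                   kappa: float = KAPPA_DEFAULT) -> SubmissionMetrics:
    """Closed-form expected metrics for a ground-truth record (no mesh).

    Independent of the mesh pipeline: every quantity is evaluated from the
    analytic geometry and the linear-in-u sac profile.
    """
    d = truth.diameter
    q = truth.flow_rate
    area = np.pi * (d / 2.0) ** 2
    vel = 100.0 * q / area
    props = BloodProperties(density=truth.density, viscosity=truth.viscosity)
    tau_p = poiseuille_wss(truth.viscosity, q, d)
    tau_c = truth.eta_parent * truth.shape_factor * tau_p
    tau_sac = truth.eta_sac * truth.shape_factor * tau_p
    parent = ParentMetrics(
        diameter=d, flow_rate=q, velocity=vel,
        reynolds=reynolds(vel, d, props),
        poiseuille_wss=tau_p, calculated_wss=tau_c,
        wss_ratio=tau_c / tau_p,
        flow_division=truth.outflow_split,
    )
    ds = truth.s_neck - truth.s_apex
    mean_s = (truth.s_apex + truth.s_neck) / 2.0

    def lsa_of(threshold: float) -> float:
        return float(np.clip((threshold / tau_sac - truth.s_apex) / ds, 0.0, 1.0))

    awss = tau_sac * mean_s
    mwss = tau_sac * truth.s_neck
    lsa = lsa_of(tau_low)
    lsa_star = lsa_of(kappa * tau_c)
    sac = SacMetrics(
        awss=awss, mwss=mwss, lsa=lsa,
        awss_star=awss / tau_c, mwss_star=mwss / tau_c, lsa_star=lsa_star,
        lsa_lumped=lsa, lsa_star_lumped=lsa_star,
        tau_low=tau_low, kappa=kappa,
    )
    return SubmissionMetrics(parent=parent, sac=sac)


def scale_wss_fields(sub: VirtualSubmission, factor: float) -> VirtualSubmission:
    """Return a copy of a submission with all WSS fields multiplied by ``factor``.

    Because generated fields are float32-quantized, multiplication by small
    integers (e.g. 10) is exact in float64.
    """
    mesh = sub.mesh.copy()
    mesh.vertex_fields["wss"] = mesh.vertex_fields["wss"] * factor
    return VirtualSubmission(mesh=mesh, sections=sub.sections,
                             regions=sub.regions, meta=sub.meta,
                             truth=sub.truth)


def default_cases(resolution: int = 64) -> list[ReferenceCase]:
    """Five idealized cases with mildly varying calibre, sac size and split.

    Case 4 carries a single inflow slice (the others five), mirroring the
    one-slice analysis of the real challenge's fourth case.
    """
    specs = [
        ("case1", 2.55, 8.5, 2.60, 0.66, 5),
        ("case2", 2.45, 7.5, 2.30, 0.62, 5),
        ("case3", 2.50, 8.0, 2.45, 0.72, 5),
        ("case4", 2.30, 8.0, 2.20, 0.58, 1),
        ("case5", 2.35, 7.8, 2.35, 0.65, 5),
    ]
    return [ReferenceCase(case_id=cid, parent_diameter=d, sac_diameter=s,
                          flow_rate=q, outflow_split=f, n_slices=ns,
                          resolution=resolution)
            for cid, d, s, q, f, ns in specs]


# --------------------------------------------------------------------------
# on-disk cohort layout
# --------------------------------------------------------------------------

def save_submission(sub: VirtualSubmission, directory: str | Path) -> None:
    """Write one submission (surface, sections, regions, truth) to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_surface(sub.mesh, d / "surface.vtk",
                  title=f"{sub.truth.case_id} {sub.truth.team_id}")
    for i, patch in enumerate(sub.sections.inflow):
        write_section(patch, d / f"slice{i + 1}.vtk")
    for lbl, patch in sub.sections.outlets.items():
        write_section(patch, d / f"outlet_{lbl}.vtk")
    write_regions(sub.regions, d / "regions.yaml")
    meta = sub.meta
    doc = {
        "team": meta.team_id,
        "case": sub.truth.case_id,
        "meta": {
            "experience": meta.experience,
            "temporal_scheme": meta.temporal_scheme,
            "inlet_location": meta.inlet_location,
            "inflow_scaling_exponent": meta.inflow_scaling_exponent,
            "viscosity": float(meta.viscosity),
            "density": float(meta.density),
        },
        "truth": sub.truth.to_dict(),
        "outlets": list(sub.sections.outlets.keys()),
        "n_slices": len(sub.sections.inflow),
    }
    with open(d / "submission.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_submission(directory: str | Path) -> VirtualSubmission:
    """Read a submission directory written by :func:`save_submission`."""
    d = Path(directory)
    with open(d / "submission.yaml") as fh:
        doc = yaml.safe_load(fh)
    mesh = read_surface(d / "surface.vtk", require_wss=True)
    regions = read_regions(d / "regions.yaml")
    inflow = [read_section(d / f"slice{i + 1}.vtk")
              for i in range(int(doc["n_slices"]))]
    outlets = {lbl: read_section(d / f"outlet_{lbl}.vtk")
               for lbl in doc["outlets"]}
    m = doc["meta"]
    meta = TeamMeta(team_id=doc["team"], experience=m["experience"],
                    temporal_scheme=m["temporal_scheme"],
                    inlet_location=m["inlet_location"],
                    inflow_scaling_exponent=m["inflow_scaling_exponent"],
                    viscosity=m["viscosity"], density=m["density"])
    truth = TruthRecord.from_dict(doc["truth"])
    return VirtualSubmission(mesh=mesh, sections=SectionSet(inflow, outlets),
                             regions=regions, meta=meta, truth=truth)
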