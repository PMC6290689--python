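"""Per-submission parent-artery and aneurysm-sac hemodynamic parameters.

Parent artery (MCA): effective diameter from slice area, flow rate
Q = area x velocity, Reynolds number Re = rho*V*D/mu, Poiseuille WSS
tau_P = 32*mu*Q/(pi*D^3), and the CFD-calculated WSS averaged over a
consistently clipped parent segment.  Sac: AWSS (area-averaged WSS
magnitude), MWSS (maximum vertex WSS), LSA (area fraction below an
absolute 0.4 Pa threshold), and their parent-normalized counterparts
AWSS*, MWSS* and LSA* (relative threshold 0.1 x parent WSS).

Normalized parameters are computed in exact dyadic-rational arithmetic
with a single final rounding, so a common positive rescaling of the WSS
field that is itself exact in floating point (e.g. x10 on float32-quantized
fields) leaves AWSS*/MWSS*/LSA* bit-identical — the mechanism by which
normalization removes inflow-driven variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from ._exact import exact_dot, exact_sum
from .errors import (
    AneuvarError,
    EmptyRegionError,
    FieldMissingError,
    NormalizationError,
    SeedPointError,
)
from .geometry import (
    clip_by_planes,
    mean_velocity,
    multi_slice_average,
    patch_area,
    triangle_areas,
    vertex_areas,
)
from .io_formats import CrossSectionPatch, RegionSet, SurfaceMesh, TeamMeta

__all__ = [
    "BloodProperties",
    "ParentMetrics",
    "SacMetrics",
    "SectionSet",
    "SubmissionMetrics",
    "reynolds",
    "poiseuille_wss",
    "parent_calculated_wss",
    "sac_metrics",
    "outflow_division",
    "compute_submission",
    "TAU_LOW_DEFAULT",
    "KAPPA_DEFAULT",
]

TAU_LOW_DEFAULT = 0.4   # Pa, absolute low-shear threshold
KAPPA_DEFAULT = 0.1     # relative low-shear threshold factor (x parent WSS)


@dataclass
class BloodProperties:
    """Blood density (g/cm^3) and dynamic viscosity (cP).

    Values outside physiological sanity bounds (rho in (0.9, 1.2),
    mu in (1, 10)) are accepted with a warning.
    """

    density: float = 1.06
    viscosity: float = 3.5

    def __post_init__(self) -> None:
        if not 0.9 < self.density < 1.2:
            warnings.warn(f"density {self.density} g/cm^3 outside sanity bounds",
                          stacklevel=2)
        if not 1.0 < self.viscosity < 10.0:
            warnings.warn(f"viscosity {self.viscosity} cP outside sanity bounds",
                          stacklevel=2)


@dataclass
class ParentMetrics:
    """Parent-artery (MCA) inflow/outflow parameters for one submission.

    Velocity-derived entries are None when a team provided no velocity data.
    """

    diameter: float | None = None        # mm
    flow_rate: float | None = None       # mL/s
    velocity: float | None = None        # cm/s
    reynolds: float | None = None        # -
    poiseuille_wss: float | None = None  # Pa
    calculated_wss: float | None = None  # Pa
    wss_ratio: float | None = None       # calculated : Poiseuille
    flow_division: float | None = None   # fraction to dominant outlet


@dataclass
class SacMetrics:
    """Aneurysm-sac WSS parameters for one submission."""

    awss: float                 # Pa
    mwss: float                 # Pa
    lsa: float                  # fraction of sac area below tau_low
    awss_star: float            # AWSS / parent WSS
    mwss_star: float            # MWSS / parent WSS
    lsa_star: float             # fraction below kappa * parent WSS
    lsa_lumped: float           # vertex-lumped LSA cross-check
    lsa_star_lumped: float      # vertex-lumped LSA* cross-check
    tau_low: float = TAU_LOW_DEFAULT
    kappa: float = KAPPA_DEFAULT


def reynolds(velocity: float, diameter: float, props: BloodProperties) -> float:
    """Reynolds number from velocity (cm/s), diameter (mm) and blood properties.

    Evaluated in SI: Re = (V*1e-2)*(D*1e-3)*(rho*1e3)/(mu*1e-3).
    """
    return ((velocity * 1e-2) * (diameter * 1e-3) * (props.density * 1e3)
            / (props.viscosity * 1e-3))


def poiseuille_wss(viscosity: float, flow_rate: float, diameter: float) -> float:
    """Poiseuille wall shear stress tau_P = 32*mu*Q/(pi*D^3) in Pa.

    Inputs: viscosity cP, flow rate mL/s, diameter mm.  The standard
    fully-developed laminar-tube form, including the factor pi.
    """
    mu = viscosity * 1e-3        # Pa s
    q = flow_rate * 1e-6         # m^3/s
    d = diameter * 1e-3          # m
    return 32.0 * mu * q / (np.pi * d ** 3)


def _area_weighted_mean_exact(mesh: SurfaceMesh, field_name: str) -> Fraction:
    w = mesh.require_field(field_name)
    if w.ndim != 1:
        raise FieldMissingError(f"field {field_name!r} is not scalar")
    va = vertex_areas(mesh)
    total = exact_sum(va)
    if total <= 0:
        raise EmptyRegionError("surface has zero area")
    return exact_dot(va, w) / total


def parent_calculated_wss(parent_band: SurfaceMesh) -> float:
    """Vertex-area-weighted mean WSS magnitude (Pa) over the clipped MCA band."""
    return float(_area_weighted_mean_exact(parent_band, "wss"))


def _classify_below(w: np.ndarray, thr: Fraction) -> np.ndarray:
    """Boolean mask w_i < thr, exact at the float/rational boundary."""
    t = float(thr)
    lo = np.nextafter(t, -np.inf)
    hi = np.nextafter(t, np.inf)
    below = w < lo
    ambiguous = np.flatnonzero((w >= lo) & (w <= hi))
    for i in ambiguous:
        below[i] = Fraction(float(w[i])) < thr
    return below


def _lsa_isocontour(mesh: SurfaceMesh, w: np.ndarray, below: np.ndarray,
                    thr: Fraction) -> Fraction:
    """Exact sub-triangle area fraction with linearly interpolated WSS < thr.

    Each cut triangle contributes the fraction of its own area on the
    low-shear side of the linear isocontour; the fraction is a rational
    function of vertex values only, so no square roots enter and a common
    exact rescaling of (w, thr) cancels identically.
    """
    areas = triangle_areas(mesh)
    tris = mesh.triangles
    nb = below[tris].sum(axis=1)
    full = nb == 3
    cut = (nb == 1) | (nb == 2)

    num = exact_sum(areas[full])
    wf = [Fraction(float(v)) for v in w.tolist()]
    for ti in np.flatnonzero(cut):
        i, j, k = (int(v) for v in tris[ti])
        b = below[[i, j, k]]
        if nb[ti] == 1:
            lone = (i, j, k)[int(np.flatnonzero(b)[0])]
            others = [v for v in (i, j, k) if v != lone]
            f = Fraction(1)
            for o in others:
                f *= (thr - wf[lone]) / (wf[o] - wf[lone])
        else:
            lone = (i, j, k)[int(np.flatnonzero(~b)[0])]
            others = [v for v in (i, j, k) if v != lone]
            f = Fraction(1)
            for o in others:
                f *= (wf[lone] - thr) / (wf[lone] - wf[o])
            f = 1 - f
        num += f * Fraction(float(areas[ti]))
    return num


def sac_metrics(sac: SurfaceMesh, parent_wss: float | Fraction,
                tau_low: float = TAU_LOW_DEFAULT,
                kappa: float = KAPPA_DEFAULT) -> SacMetrics:
    """Compute AWSS, MWSS, LSA and their parent-normalized counterparts.

    ``parent_wss`` may be passed as an exact Fraction (as the pipeline does
    internally) so that normalization cancels a common field scale exactly.
    LSA is computed on exactly-split sub-triangles at the threshold
    isocontour; the vertex-lumped estimate is kept as a cross-check
    (``lsa_lumped``/``lsa_star_lumped``).
    """
    p = parent_wss if isinstance(parent_wss, Fraction) else Fraction(float(parent_wss))
    if p <= 0:
        raise NormalizationError("parent WSS must be positive for normalization")
    w = sac.require_field("wss")
    if w.ndim != 1:
        raise FieldMissingError("'wss' field is not scalar")
    va = vertex_areas(sac)
    total_vertex = exact_sum(va)
    total_tri = exact_sum(triangle_areas(sac))
    if total_tri <= 0:
        raise EmptyRegionError("sac has zero area")

    awss_frac = exact_dot(va, w) / total_vertex
    mwss = float(np.max(w))

    thr_abs = Fraction(float(tau_low))
    thr_rel = Fraction(float(kappa)) * p

    below_abs = _classify_below(w, thr_abs)
    below_rel = _classify_below(w, thr_rel)
    lsa = _lsa_isocontour(sac, w, below_abs, thr_abs) / total_tri
    lsa_star = _lsa_isocontour(sac, w, below_rel, thr_rel) / total_tri
    lsa_lumped = (exact_sum(va[below_abs]) / total_vertex) if below_abs.any() \
        else Fraction(0)
    lsa_star_lumped = (exact_sum(va[below_rel]) / total_vertex) if below_rel.any() \
        else Fraction(0)

    return SacMetrics(
        awss=float(awss_frac),
        mwss=mwss,
        lsa=float(lsa),
        awss_star=float(awss_frac / p),
        mwss_star=float(Fraction(mwss) / p),
        lsa_star=float(lsa_star),
        lsa_lumped=float(lsa_lumped),
        lsa_star_lumped=float(lsa_star_lumped),
        tau_low=float(tau_low),
        kappa=float(kappa),
    )


def outflow_division(outlet_flows: Mapping[str, float], dominant: str) -> float:
    """Fraction of total outlet flow carried by the dominant branch."""
    if len(outlet_flows) < 2:
        raise ValueError("need at least two outlets")
    if dominant not in outlet_flows:
        raise ValueError(f"dominant outlet {dominant!r} not among outlets")
    flows = {k: float(v) for k, v in outlet_flows.items()}
    if any(v < 0 for v in flows.values()):
        raise ValueError("outlet flows must be non-negative")
    total = sum(flows.values())
    if total <= 0:
        raise ValueError("total outlet flow must be positive")
    return flows[dominant] / total


@dataclass
class SectionSet:
    """Velocity cross-sections for one submission: inflow slices + outlets."""

    inflow: list[CrossSectionPatch] = field(default_factory=list)
    outlets: dict[str, CrossSectionPatch] = field(default_factory=dict)


@dataclass
class SubmissionMetrics:
    """Full metric record for one (team, case) submission."""

    parent: ParentMetrics
    sac: SacMetrics | None
    notes: list[str] = field(default_factory=list)

    def as_records(self) -> list[tuple[str, float]]:
        rows: list[tuple[str, float]] = []
        for name in ("diameter", "flow_rate", "velocity", "reynolds",
                     "poiseuille_wss", "calculated_wss", "wss_ratio",
                     "flow_division"):
            v = getattr(self.parent, name)
            if v is not None:
                rows.append((name, float(v)))
        if self.sac is not None:
            for name in ("awss", "mwss", "lsa", "awss_star", "mwss_star",
                         "lsa_star"):
                rows.append((name, float(getattr(self.sac, name))))
        return rows


def compute_submission(mesh: SurfaceMesh, sections: SectionSet,
                       regions: RegionSet, props: BloodProperties,
                       meta: TeamMeta | None = None,
                       tau_low: float = TAU_LOW_DEFAULT,
                       kappa: float = KAPPA_DEFAULT,
                       team: str | None = None,
                       case: str | None = None) -> SubmissionMetrics:
    """Run the full per-submission analysis.

    Steady and time-averaged pulsatile WSS fields are treated identically.
    A submission missing velocity data still yields the WSS-derived parent
    and sac parameters; a submission whose sac cannot be isolated yields
    parent metrics with ``sac=None`` and an explanatory note.
    """
    label = f"team={team or (meta.team_id if meta else '?')} case={case or '?'}"
    notes: list[str] = []
    parent = ParentMetrics()
    try:
        if sections.inflow:
            slices = [(patch_area(p), mean_velocity(p)) for p in sections.inflow]
            avg = multi_slice_average(slices)
            parent.diameter = avg.diameter
            parent.velocity = avg.velocity
            parent.flow_rate = avg.flow_rate
            parent.reynolds = reynolds(avg.velocity, avg.diameter, props)
            parent.poiseuille_wss = poiseuille_wss(props.viscosity,
                                                   avg.flow_rate, avg.diameter)
        else:
            notes.append("no velocity data: velocity-derived parameters missing")

        band = clip_by_planes(mesh, regions.parent_band_planes,
                              regions.parent_seed)
        tau_c = _area_weighted_mean_exact(band, "wss")
        parent.calculated_wss = float(tau_c)
        if parent.poiseuille_wss:
            parent.wss_ratio = parent.calculated_wss / parent.poiseuille_wss

        if len(sections.outlets) >= 2:
            flows = {}
            for lbl, p in sections.outlets.items():
                flows[lbl] = patch_area(p) * mean_velocity(p).value * 1e-2
            parent.flow_division = outflow_division(flows,
                                                    regions.dominant_outlet)
        elif sections.inflow:
            notes.append("fewer than two outlet slices: no outflow division")

        sac: SacMetrics | None = None
        try:
            sac_mesh = clip_by_planes(mesh, regions.sac_planes, regions.sac_seed)
            sac = sac_metrics(sac_mesh, tau_c, tau_low=tau_low, kappa=kappa)
        except (EmptyRegionError, SeedPointError) as exc:
            notes.append(f"sac region missing: {exc}")
    except AneuvarError as exc:
        raise type(exc)(f"[{label}] {exc}") from exc
    return SubmissionMetrics(parent=parent, sac=sac, notes=notes)
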