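"""Elastic-foundation (bed-of-springs) contact model of the medial
tibiofemoral compartment.

The medial femoral condyle is an analytic rigid surface: two convex
circular arcs in the sagittal plane (a flatter anterior arc engaged at low
knee flexion and a tighter posterior arc engaged at higher flexion) and a
single convex arc in the frontal plane.  The tibial plateau is concave in
both planes.  Cartilage is a uniform 5 mm foundation of independent
nonlinear springs on a regular grid over the plateau; each element obeys

    sigma = -E_eff * ln(1 - eps),      eps = compression / thickness,

a logarithmic stiffening law whose stress diverges as an element is fully
compressed.  There is no lateral coupling between elements and no
translational femoral kinematics: loading is applied purely by lowering the
flexion axis toward the tibia until the summed spring force matches a
target compressive force (monotone, so the equilibrium depth is unique and
found by bisection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "KneeGeometry",
    "CartilageMaterial",
    "ContactMesh",
    "ContactSolution",
    "ContactSolverError",
    "build_mesh",
    "element_strain",
    "element_stress",
    "femoral_surface_height",
    "solve_contact",
]

GRAVITY = 9.81  # m/s^2, used for BW -> N conversion throughout the package

ModulusRule = Literal["tibial", "series", "arithmetic"]


class ContactSolverError(RuntimeError):
    """Raised when the axis-depth solve cannot reach the target force."""


@dataclass(frozen=True)
class KneeGeometry:
    """Arc radii and mesh layout of the medial compartment (all mm).

    The frontal-plane tibial radius and the two sagittal femoral radii are
    literature values; the femoral frontal radius and the sagittal tibial
    concavity are not published for this model family and are calibrated so
    that a typical walking load (~2.7 BW) produces peak strains near 0.2
    (see docs/methods.md).  Conformity of the two arc pairs controls how
    much of the plateau engages, and hence the strain magnitude at a given
    force.
    """

    tibial_frontal_radius: float = 21.0
    femoral_sagittal_radius_anterior: float = 35.0
    femoral_sagittal_radius_posterior: float = 18.9
    femoral_frontal_radius: float = 20.8
    tibial_sagittal_radius: float = 36.5
    arc_transition_flexion: float = 30.0  # degrees
    cartilage_thickness: float = 5.0
    element_spacing: float = 0.5
    mesh_dims: tuple[int, int] = (111, 66)  # AP x ML elements
    meniscus_coverage: float = 0.46

    def __post_init__(self) -> None:
        for name in (
            "tibial_frontal_radius",
            "femoral_sagittal_radius_anterior",
            "femoral_sagittal_radius_posterior",
            "femoral_frontal_radius",
            "tibial_sagittal_radius",
            "cartilage_thickness",
            "element_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.meniscus_coverage <= 1.0):
            raise ValueError("meniscus_coverage must lie in [0, 1]")
        if len(self.mesh_dims) != 2 or any(int(d) < 1 for d in self.mesh_dims):
            raise ValueError("mesh_dims must be two positive integers")

    @property
    def n_elements(self) -> int:
        return int(self.mesh_dims[0]) * int(self.mesh_dims[1])


@dataclass(frozen=True)
class CartilageMaterial:
    """Layer moduli (MPa) and the rule combining them per element.

    modulus_rule:
      * ``"tibial"``   — springs represent the tibial cartilage layer:
        10.1 MPa under the meniscus, 4.0 MPa uncovered.  Default, because
        the stress/strain operating points this model is validated against
        imply an effective modulus of ~10.2 MPa at the loaded periphery.
      * ``"series"``   — harmonic mean of the femoral and tibial layer
        moduli (two springs in series sharing the foundation thickness).
      * ``"arithmetic"`` — arithmetic mean of the same pair.

    The meniscus modulus and Poisson ratio are carried as metadata; the
    independent-spring foundation has no lateral coupling, so neither
    enters the force computation.
    """

    femoral_modulus: float = 8.6
    tibial_uncovered_modulus: float = 4.0
    tibial_covered_modulus: float = 10.1
    meniscus_modulus: float = 1.3
    poisson_ratio: float = 0.45
    modulus_rule: ModulusRule = "tibial"

    def __post_init__(self) -> None:
        for name in (
            "femoral_modulus",
            "tibial_uncovered_modulus",
            "tibial_covered_modulus",
            "meniscus_modulus",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.modulus_rule not in ("tibial", "series", "arithmetic"):
            raise ValueError(f"unknown modulus_rule {self.modulus_rule!r}")

    def effective_modulus(self, covered: np.ndarray) -> np.ndarray:
        """Per-element effective modulus (MPa) given the coverage mask."""
        tib = np.where(
            covered, self.tibial_covered_modulus, self.tibial_uncovered_modulus
        )
        if self.modulus_rule == "tibial":
            return tib.astype(float)
        if self.modulus_rule == "series":
            return 2.0 / (1.0 / self.femoral_modulus + 1.0 / tib)
        return 0.5 * (self.femoral_modulus + tib)


@dataclass(frozen=True)
class ContactMesh:
    """Regular grid of spring elements over the tibial plateau."""

    x_ap: np.ndarray  # (n_ap, n_ml) element-centre AP coordinates, mm
    y_ml: np.ndarray  # (n_ap, n_ml) element-centre ML coordinates, mm
    element_area: float  # mm^2
    covered: np.ndarray  # bool, True where beneath the meniscus
    modulus: np.ndarray  # MPa, effective per-element modulus
    geometry: KneeGeometry
    material: CartilageMaterial

    @property
    def n_elements(self) -> int:
        return int(self.x_ap.size)

    @property
    def covered_fraction(self) -> float:
        return float(np.mean(self.covered))


@dataclass(frozen=True)
class ContactSolution:
    """Equilibrium state of the foundation at a matched compressive force.

    ``stressed_volume`` is loaded area x unloaded thickness; the
    ``weibull_effective_volume`` down-weights elements by
    (eps_i / eps_peak)**weibull_exponent, the weakest-link reduction of an
    inhomogeneously strained foundation to an equivalent uniformly strained
    volume at the peak strain (used by the failure stage).
    """

    axis_depth: float  # mm lowered from the unloaded height
    flexion_angle: float  # degrees
    compression: np.ndarray  # mm, per element
    strain: np.ndarray  # per element, in [0, 1)
    stress: np.ndarray  # MPa, per element
    total_force: float  # N
    peak_stress: float  # MPa
    peak_strain: float
    loaded_area: float  # mm^2
    stressed_volume: float  # mm^3 (loaded area x thickness)
    weibull_effective_volume: float  # mm^3
    mesh: ContactMesh = field(repr=False)

    def effective_volume(self, weibull_exponent: float = 14.3) -> float:
        """Weakest-link effective stressed volume for a given exponent."""
        return _weibull_volume(
            self.strain, self.mesh.element_area,
            self.mesh.geometry.cartilage_thickness, weibull_exponent,
        )


def build_mesh(
    geometry: KneeGeometry | None = None,
    material: CartilageMaterial | None = None,
) -> ContactMesh:
    """Mesh the tibial plateau and assign per-element moduli.

    Meniscus coverage is assigned to the outermost elements (largest
    normalised Chebyshev distance from the plateau centre, ties broken
    deterministically) until the covered fraction matches
    ``geometry.meniscus_coverage`` to the nearest element.
    """
    geometry = geometry or KneeGeometry()
    material = material or CartilageMaterial()
    n_ap, n_ml = (int(d) for d in geometry.mesh_dims)
    sp = geometry.element_spacing
    x = (np.arange(n_ap) - (n_ap - 1) / 2.0) * sp
    y = (np.arange(n_ml) - (n_ml - 1) / 2.0) * sp
    x_ap, y_ml = np.meshgrid(x, y, indexing="ij")

    covered = np.zeros(x_ap.shape, dtype=bool)
    n_cov = int(round(geometry.meniscus_coverage * x_ap.size))
    if n_cov > 0:
        x_half = max(float(np.max(np.abs(x))), sp)
        y_half = max(float(np.max(np.abs(y))), sp)
        ring = np.maximum(np.abs(x_ap) / x_half, np.abs(y_ml) / y_half)
        # threshold at the n_cov-th outermost element, keeping whole tie
        # groups so the covered band stays mirror-symmetric in both axes
        # (fraction matches the target to within one element row)
        threshold = np.sort(ring.ravel())[::-1][n_cov - 1]
        covered = ring >= threshold

    modulus = material.effective_modulus(covered)
    return ContactMesh(
        x_ap=x_ap,
        y_ml=y_ml,
        element_area=sp * sp,
        covered=covered,
        modulus=modulus,
        geometry=geometry,
        material=material,
    )


def element_strain(compression: float | np.ndarray, thickness: float):
    """Engineering strain of a foundation element, compression / thickness.

    Compression at or beyond the unloaded thickness is a singular state of
    the logarithmic law and raises.
    """
    compression = np.asarray(compression, dtype=float)
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if np.any(compression < 0):
        raise ValueError("compression must be non-negative")
    if np.any(compression >= thickness):
        raise ValueError(
            "compression reached the cartilage thickness (strain cap): "
            "the constitutive law is singular at strain 1"
        )
    out = compression / thickness
    return float(out) if out.ndim == 0 else out


def element_stress(strain: float | np.ndarray, effective_modulus):
    """Compressive stress sigma = -E * ln(1 - eps), MPa."""
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0) or np.any(strain >= 1):
        raise ValueError("strain must lie in [0, 1)")
    out = -np.asarray(effective_modulus, dtype=float) * np.log1p(-strain)
    return float(out) if out.ndim == 0 else out


def _sagitta(radius: float, offset: np.ndarray) -> np.ndarray:
    """Height drop of a circular arc at lateral offset from its apex.

    Beyond the arc's physical extent the surface is treated as infinitely
    far away (no contact possible).
    """
    offset = np.asarray(offset, dtype=float)
    out = np.full(offset.shape, np.inf)
    inside = np.abs(offset) < radius
    out[inside] = radius - np.sqrt(radius * radius - offset[inside] ** 2)
    return out


def _gap_field(mesh: ContactMesh, flexion_angle: float) -> np.ndarray:
    """Unloaded femur-tibia surface separation over the mesh, mm.

    The sagittal femoral arc is selected by the flexion threshold (the
    anterior, flatter arc below ``arc_transition_flexion``; the posterior
    arc at or above it).  Because each arc is circular and rotation about
    the flexion axis maps a circular arc onto itself, flexion enters only
    through this arc selection.  The gap in each anatomical plane is the
    differential sagitta of the convex femoral arc inside the concave
    tibial arc, and the two contributions add.
    """
    g = mesh.geometry
    if flexion_angle < g.arc_transition_flexion:
        r_fem_sag = g.femoral_sagittal_radius_anterior
    else:
        r_fem_sag = g.femoral_sagittal_radius_posterior
    gap_sag = _sagitta(r_fem_sag, mesh.x_ap) - _sagitta(
        g.tibial_sagittal_radius, mesh.x_ap
    )
    gap_front = _sagitta(g.femoral_frontal_radius, mesh.y_ml) - _sagitta(
        g.tibial_frontal_radius, mesh.y_ml
    )
    gap = np.clip(gap_sag, 0.0, None) + np.clip(gap_front, 0.0, None)
    return np.where(np.isfinite(gap), gap, np.inf)


def femoral_surface_height(
    x_ap: float | np.ndarray,
    y_ml: float | np.ndarray,
    flexion_angle: float,
    axis_depth: float,
    geometry: KneeGeometry | None = None,
) -> float | np.ndarray:
    """Height of the rigid femoral surface above the tibial subchondral
    plane at a point, mm.

    With ``axis_depth = 0`` (the unloaded height) the surface grazes the
    cartilage at the contact centre: the returned height there equals the
    unloaded cartilage thickness.  Lowering the axis (``axis_depth > 0``)
    translates the whole surface rigidly toward the tibia.
    """
    geometry = geometry or KneeGeometry()
    material = CartilageMaterial()
    x = np.atleast_1d(np.asarray(x_ap, dtype=float))
    y = np.atleast_1d(np.asarray(y_ml, dtype=float))
    x, y = np.broadcast_arrays(x, y)
    # a throwaway single-point "mesh" reuses the gap construction
    mesh = ContactMesh(
        x_ap=x, y_ml=y, element_area=geometry.element_spacing ** 2,
        covered=np.zeros(x.shape, bool),
        modulus=np.full(x.shape, material.tibial_uncovered_modulus),
        geometry=geometry, material=material,
    )
    gap = _gap_field(mesh, flexion_angle)
    height = geometry.cartilage_thickness + gap - axis_depth
    return float(height[0]) if np.ndim(x_ap) == 0 and np.size(height) == 1 else height


def _weibull_volume(
    strain: np.ndarray, element_area: float, thickness: float, exponent: float
) -> float:
    peak = float(np.max(strain)) if strain.size else 0.0
    if peak <= 0:
        return 0.0
    loaded = strain > 0
    w = (strain[loaded] / peak) ** exponent
    return float(np.sum(w) * element_area * thickness)


def solve_contact(
    target_force: float,
    flexion_angle: float,
    geometry: KneeGeometry | None = None,
    material: CartilageMaterial | None = None,
    mesh: ContactMesh | None = None,
    tol: float = 0.5,
    max_iter: int = 200,
    strain_cap: float = 0.995,
) -> ContactSolution:
    """Find the flexion-axis depth at which the foundation carries
    ``target_force`` (N) and return the full field solution.

    The total force is strictly increasing in depth, so the equilibrium is
    unique; it is bracketed between the unloaded height and the depth at
    which the most compressed element reaches ``strain_cap``, then located
    by bisection until the force residual is within ``tol`` (N).
    """
    if target_force < 0:
        raise ValueError("target_force must be non-negative")
    if mesh is None:
        mesh = build_mesh(geometry, material)
    g = mesh.geometry
    h = g.cartilage_thickness
    gap = _gap_field(mesh, flexion_angle)
    area = mesh.element_area
    E = mesh.modulus

    def total(depth: float) -> float:
        eps = np.clip(depth - gap, 0.0, None) / h
        if not np.any(eps > 0):
            return 0.0
        return float(np.sum(-E * np.log1p(-np.minimum(eps, strain_cap))) * area)

    def fields(depth: float):
        comp = np.clip(depth - gap, 0.0, None)
        eps = comp / h
        return comp, eps

    finite_gap = gap[np.isfinite(gap)]
    if finite_gap.size == 0:
        raise ContactSolverError("femoral surface never overlies the mesh")
    lo = float(np.min(finite_gap))  # unloaded height: first touch
    hi = lo + strain_cap * h
    if target_force == 0.0:
        comp, eps = fields(lo)
        stress = np.where(eps > 0, -E * np.log1p(-eps), 0.0)
        return _pack(lo, flexion_angle, comp, eps, stress, area, h, mesh)

    f_hi = total(hi)
    if f_hi < target_force - tol:
        raise ContactSolverError(
            f"target force {target_force:.1f} N unreachable before the "
            f"strain cap; maximum achievable ~{f_hi:.1f} N"
        )

    a, b = lo, hi
    depth = 0.5 * (a + b)
    for _ in range(max_iter):
        depth = 0.5 * (a + b)
        resid = total(depth) - target_force
        if abs(resid) <= tol:
            break
        if resid > 0:
            b = depth
        else:
            a = depth
    else:
        raise ContactSolverError(
            f"no convergence to |residual| <= {tol} N in {max_iter} iterations"
        )

    comp, eps = fields(depth)
    stress = np.where(eps > 0, -E * np.log1p(-np.minimum(eps, strain_cap)), 0.0)
    return _pack(depth, flexion_angle, comp, eps, stress, area, h, mesh)


def _pack(depth, flexion_angle, comp, eps, stress, area, h, mesh) -> ContactSolution:
    loaded_area = float(np.sum(eps > 0) * area)
    return ContactSolution(
        axis_depth=float(depth),
        flexion_angle=float(flexion_angle),
        compression=comp,
        strain=eps,
        stress=stress,
        total_force=float(np.sum(stress) * area),
        peak_stress=float(np.max(stress)) if stress.size else 0.0,
        peak_strain=float(np.max(eps)) if eps.size else 0.0,
        loaded_area=loaded_area,
        stressed_volume=loaded_area * h,
        weibull_effective_volume=_weibull_volume(eps, area, h, 14.3),
        mesh=mesh,
    )
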