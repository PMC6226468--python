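"""Exact volumes of spherical shells, sphere-sphere lenses and shell-shell
intersections, plus the planar triangle utilities used to convert fitted
distance pairs into side-chain orientations.

All lengths are in Angstrom, volumes in Angstrom^3, angles in degrees at the
public surface (radians internally).

The shell-shell intersection is the geometric kernel of the FDQ (fluorophore-
distance-quencher) construction: the fluorophore and quencher centroid
densities live on concentric spherical shells of thickness ``dr`` about their
anchor atoms, and the quenching probability at anchor separation ``d`` is
assembled from the pairwise intersection volumes of those shells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShellSpec",
    "LensSpec",
    "TriangleResult",
    "shell_volume",
    "lens_volume",
    "ball_overlap_volume",
    "shell_intersection_volume",
    "angle_from_distances",
    "planar_coordinates",
    "mc_volume_oracle",
]

#: Length of a C-C single bond (Angstrom); the Trp C-alpha to C-beta distance.
CC_BOND = 1.54

_CONCENTRIC_TOL = 1e-9


@dataclass(frozen=True)
class ShellSpec:
    """A spherical shell: maximal radius and thickness (both Angstrom)."""

    max_radius: float
    thickness: float

    def __post_init__(self) -> None:
        if not (self.max_radius >= self.thickness > 0):
            raise ValueError(
                f"require max_radius >= thickness > 0, got "
                f"max_radius={self.max_radius}, thickness={self.thickness}"
            )

    @property
    def volume(self) -> float:
        return shell_volume(self.max_radius, self.thickness)


@dataclass(frozen=True)
class LensSpec:
    """Two overlapping spheres: center separation and the two radii."""

    center_separation: float
    radius_a: float
    radius_b: float

    def __post_init__(self) -> None:
        for name in ("center_separation", "radius_a", "radius_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TriangleResult:
    """Cys Calpha position relative to the Trp Calpha-Cbeta axis.

    ``angle`` is the Calpha-Walpha-Wbeta angle in degrees; ``(x, y)`` are the
    Cys Calpha coordinates on the plane where the Trp Calpha sits at the
    origin and the Trp Cbeta at ``(0, cc)``.
    """

    angle: float
    x: float
    y: float
    cc: float = CC_BOND


def shell_volume(rho: float, dr: float) -> float:
    """Volume of a spherical shell with maximal radius ``rho``, thickness ``dr``.

    V = (4*pi/3) * [rho^3 - (rho - dr)^3].
    """
    if dr <= 0 or rho < dr:
        raise ValueError(f"require rho >= dr > 0, got rho={rho}, dr={dr}")
    return (4.0 * math.pi / 3.0) * (rho**3 - (rho - dr) ** 3)


def lens_volume(spec: LensSpec) -> float:
    """Volume of the lens formed by two overlapping spheres.

    With center separation chi and radii psi, omega:

        V = pi (psi + omega - chi)^2
            (chi^2 + 2 chi psi - 3 psi^2 + 2 chi omega - 3 omega^2
             + 6 psi omega) / (12 chi)

    Caller must guarantee |psi - omega| <= chi <= psi + omega; the formula is
    singular at chi = 0 (concentric spheres must be special-cased upstream).
    """
    chi, psi, omega = spec.center_separation, spec.radius_a, spec.radius_b
    if chi < _CONCENTRIC_TOL:
        raise ValueError("lens formula is singular for concentric spheres (chi ~ 0)")
    if not (abs(psi - omega) - 1e-12 <= chi <= psi + omega + 1e-12):
        raise ValueError(
            f"spheres neither overlap partially nor touch: chi={chi}, psi={psi}, omega={omega}"
        )
    return (
        math.pi
        * (psi + omega - chi) ** 2
        * (chi**2 + 2 * chi * psi - 3 * psi**2 + 2 * chi * omega - 3 * omega**2 + 6 * psi * omega)
        / (12.0 * chi)
    )


def ball_overlap_volume(d: float, a: float, b: float) -> float:
    """Intersection volume of two solid balls (radii ``a``, ``b``, centers ``d`` apart).

    Clamps the disjoint and fully-contained cases, so it is defined for every
    non-negative ``d`` (including concentric). A radius <= 0 denotes an empty
    ball. This is the building block from which every branch of the shell
    intersection case table is assembled.
    """
    if a <= 0 or b <= 0:
        return 0.0
    if d >= a + b:
        return 0.0
    if d <= abs(a - b):
        rmin = min(a, b)
        return (4.0 * math.pi / 3.0) * rmin**3
    return lens_volume(LensSpec(d, a, b))


def shell_intersection_volume(d: float, shell_a: ShellSpec, shell_b: ShellSpec) -> float:
    """Intersection volume of two spherical shells with centers ``d`` apart.

    Dispatches the case table for shells K (max radius R) and kappa (max
    radius r), shared thickness dr:

    * 0 when the shells cannot touch (d >= R + r; one shell strictly inside
      the other's cavity; concentric with R != r),
    * the full shell volume when concentric with R = r,
    * a single lens at the outer-touch boundary d = R + r - dr,
    * two-term lens differences when one inner sphere is swallowed,
    * four-term inclusion-exclusion otherwise.

    For continuous ``d`` the named boundary equalities become interval
    membership; the clamped :func:`ball_overlap_volume` realises exactly that
    dispatch.
    """
    if d < 0:
        raise ValueError("center separation d must be non-negative")
    dr_a, dr_b = shell_a.thickness, shell_b.thickness
    if not math.isclose(dr_a, dr_b, rel_tol=0, abs_tol=1e-12):
        raise ValueError(f"shells must share thickness, got {dr_a} and {dr_b}")
    dr = dr_a
    R, r = shell_a.max_radius, shell_b.max_radius

    if d < _CONCENTRIC_TOL:
        # concentric: shells coincide iff R == r (on the common dr grid)
        if math.isclose(R, r, rel_tol=0, abs_tol=1e-12):
            return shell_volume(R, dr)
        # identical thickness, different radii: overlap only if the radial
        # intervals (R-dr, R] and (r-dr, r] intersect
        lo, hi = max(R - dr, r - dr), min(R, r)
        if hi <= lo:
            return 0.0
        return (4.0 * math.pi / 3.0) * (hi**3 - lo**3)

    v = (
        ball_overlap_volume(d, R, r)
        - ball_overlap_volume(d, R - dr, r)
        - ball_overlap_volume(d, R, r - dr)
        + ball_overlap_volume(d, R - dr, r - dr)
    )
    # inclusion-exclusion can leave ~1e-12 negative dust at branch boundaries
    return max(v, 0.0)


def angle_from_distances(d_aa: float, d_ab: float, cc: float = CC_BOND) -> float:
    """Calpha-Walpha-Wbeta angle (degrees) by the law of cosines.

    ``d_aa`` is the Cys Calpha - Trp Calpha distance, ``d_ab`` the Cys Calpha -
    Trp Cbeta distance and ``cc`` the Trp Calpha-Cbeta bond length. An angle
    below 90 deg means the side-chain points toward the labelled site.
    """
    if min(d_aa, d_ab, cc) <= 0:
        raise ValueError("all distances must be positive")
    cos_theta = (cc**2 + d_aa**2 - d_ab**2) / (2.0 * cc * d_aa)
    if abs(cos_theta) > 1.0 + 1e-9:
        raise ValueError(
            f"triangle inequality violated: sides cc={cc}, d_aa={d_aa}, d_ab={d_ab}"
        )
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_theta))))


def planar_coordinates(d_aa: float, angle: float, cc: float = CC_BOND) -> TriangleResult:
    """Cys Calpha coordinates with Trp Calpha at the origin, Cbeta at (0, cc).

    x = d_aa cos(pi/2 - theta), y = d_aa sin(pi/2 - theta), theta in degrees.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"angle must be in [0, 180] degrees, got {angle}")
    theta = math.radians(angle)
    x = d_aa * math.cos(math.pi / 2.0 - theta)
    y = d_aa * math.sin(math.pi / 2.0 - theta)
    return TriangleResult(angle=angle, x=x, y=y, cc=cc)


def mc_volume_oracle(
    region_predicate,
    bounding_box,
    n_points: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Rejection-sampling volume estimate with its standard error.

    ``region_predicate`` maps an (n, 3) coordinate array to a boolean mask;
    ``bounding_box`` is ((xlo, xhi), (ylo, yhi), (zlo, zhi)). Used as the
    independent oracle for the analytic volume formulas.
    """
    if n_points < 10_000:
        raise ValueError("n_points must be at least 10^4 for a meaningful SE")
    box = np.asarray(bounding_box, dtype=float)
    if box.shape != (3, 2) or np.any(box[:, 1] <= box[:, 0]):
        raise ValueError("bounding_box must be three non-degenerate (lo, hi) pairs")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(box[:, 0], box[:, 1], size=(n_points, 3))
    inside = np.asarray(region_predicate(pts), dtype=bool)
    box_volume = float(np.prod(box[:, 1] - box[:, 0]))
    p = inside.mean()
    estimate = p * box_volume
    se = box_volume * math.sqrt(max(p * (1.0 - p), 0.0) / n_points)
    return estimate, se


def shell_pair_predicate(d: float, shell_a: ShellSpec, shell_b: ShellSpec):
    """Predicate for points inside both shells (centers at origin and (d,0,0)).

    Convenience for cross-checking :func:`shell_intersection_volume` against
    :func:`mc_volume_oracle`.
    """

    def predicate(pts: np.ndarray) -> np.ndarray:
        ra = np.linalg.norm(pts, axis=1)
        rb = np.linalg.norm(pts - np.array([d, 0.0, 0.0]), axis=1)
        in_a = (ra <= shell_a.max_radius) & (ra > shell_a.max_radius - shell_a.thickness)
        in_b = (rb <= shell_b.max_radius) & (rb > shell_b.max_radius - shell_b.thickness)
        return in_a & in_b

    return predicate
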