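"""Force and pressure profiles from the free-energy profile.

The force exerted on the tube is the negative derivative of the free
energy with respect to tube displacement.  The profile G(z) is smoothed by
a least-squares fourth-order polynomial (the first ~1 nm of displacement
is excluded: the tube motion there is too small for the coarse model to
resolve a derivative) and the 95% confidence band follows from the fit's
coefficient covariance propagated through the derivative.  The terminal
branch of the force curve comes from the measured stiffness of the
contracted sheath (extension spring constant, default 117 pN/nm); the
crossing of the two curves estimates the maximum force.  Dividing force by
the spike-tube cross-sectional area gives the mean pressure driving
membrane penetration.

Unit conventions: displacement nm, energy kcal/mol, force pN;
1 kcal/mol/A = 69.479 pN applied exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dmad.builder import AssemblyModel
from dmad.errors import DomainError, FitError, InputError
from dmad.geometry import LatticeSpec

__all__ = [
    "ForceProfile",
    "tube_displacement",
    "force_from_profile",
    "spring_branch_and_intersection",
    "cross_section_area",
    "mean_pressure",
    "KCAL_PER_MOL_PER_ANGSTROM_TO_PN",
    "PN_PER_NM2_TO_ATM",
]

#: 1 kcal/mol/A in pN (kcal->J, /N_A, /1e-10 m)
KCAL_PER_MOL_PER_ANGSTROM_TO_PN = 69.479
#: 1 pN/nm^2 = 1e6 Pa; in atm (1 atm = 101325 Pa)
PN_PER_NM2_TO_ATM = 1.0e6 / 101325.0


@dataclass
class ForceProfile:
    """Force vs tube displacement with a 95% confidence band."""

    displacement: np.ndarray  # nm, 0 = extended
    force: np.ndarray  # pN
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    poly_coeffs: np.ndarray  # quartic fit of G(displacement), kcal/mol vs nm
    poly_cov: np.ndarray
    fit_mask: np.ndarray  # points used in the fit
    afm_spring_constant: float = 117.0  # pN/nm
    intersection_force: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.displacement) <= 0.0):
            raise InputError("displacement must be strictly increasing")


def tube_displacement(lam_rows: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """Axial tube motion for each intermediate, nm (positive as the sheath shortens).

    The tube follows the top sheath layer: displacement = z_ext^N - z^N.
    """
    lam_rows = np.clip(np.asarray(lam_rows, dtype=float), 0.0, 1.0)
    top = spec.layers[-1]
    z_top = top.z_ext + lam_rows[:, -1] * (top.z_cnt - top.z_ext)
    return (top.z_ext - z_top) / 10.0


def _derivative_band(coeffs: np.ndarray, cov: np.ndarray, z: np.ndarray) -> np.ndarray:
    """1-sigma of dG/dz from the coefficient covariance (highest degree first)."""
    deg = len(coeffs) - 1
    # dG/dz = sum_k c_k * (deg-k) * z^(deg-k-1); gradient wrt c_k
    grad = np.stack(
        [(deg - k) * z ** np.maximum(deg - k - 1, 0) * (1.0 if deg - k > 0 else 0.0)
         for k in range(len(coeffs))],
        axis=1,
    )
    var = np.einsum("ij,jk,ik->i", grad, cov, grad)
    return np.sqrt(np.maximum(var, 0.0))


def force_from_profile(
    displacement: np.ndarray,
    energy: np.ndarray,
    degree: int = 4,
    exclude_below: float = 1.0,
    afm_spring_constant: float = 117.0,
) -> ForceProfile:
    """Quartic fit of G(z) and its negative derivative as the force curve.

    ``displacement`` in nm, ``energy`` in kcal/mol.  Points with
    displacement < ``exclude_below`` nm are excluded from the fit (but the
    returned profile is evaluated from the first fitted point on).  The 95%
    CI comes from the coefficient covariance of the least-squares fit.
    """
    z = np.asarray(displacement, dtype=float)
    g = np.asarray(energy, dtype=float)
    if z.shape != g.shape or z.ndim != 1:
        raise InputError("displacement and energy must be matching 1-D arrays")
    mask = z >= exclude_below
    if mask.sum() < degree + 2:
        raise FitError(
            f"need >= {degree + 2} profile points beyond {exclude_below} nm, "
            f"got {int(mask.sum())}"
        )
    zf, gf = z[mask], g[mask]
    coeffs, cov = np.polyfit(zf, gf, degree, cov=True)
    dcoeffs = np.polyder(coeffs)
    conv = KCAL_PER_MOL_PER_ANGSTROM_TO_PN / 10.0  # kcal/mol/nm -> pN
    zu = np.unique(zf)  # strictly increasing evaluation grid
    fu = -np.polyval(dcoeffs, zu) * conv
    su = _derivative_band(coeffs, cov, zu) * conv
    return ForceProfile(
        displacement=zu,
        force=fu,
        ci95_low=fu - 1.96 * su,
        ci95_high=fu + 1.96 * su,
        poly_coeffs=coeffs,
        poly_cov=cov,
        fit_mask=mask,
        afm_spring_constant=afm_spring_constant,
    )


def spring_branch_and_intersection(
    profile: ForceProfile, z_final: float, spring_constant: float | None = None
) -> float | None:
    """Force at the crossing of the model force curve with the AFM spring branch.

    The contracted sheath behaves as a linear extension spring anchored at
    the fully contracted displacement ``z_final``: F_s(z) = k (z_final - z).
    Returns the force at the first crossing inside the profile domain
    extended to ``z_final``, or None if the curves do not cross.
    """
    k = spring_constant if spring_constant is not None else profile.afm_spring_constant
    z0 = profile.displacement[0]
    z1 = max(z_final, profile.displacement[-1])
    z = np.linspace(z0, z1, 2001)
    dcoeffs = np.polyder(profile.poly_coeffs)
    conv = KCAL_PER_MOL_PER_ANGSTROM_TO_PN / 10.0
    f_model = -np.polyval(dcoeffs, z) * conv
    f_spring = k * (z_final - z)
    diff = f_model - f_spring
    sign = np.sign(diff)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        return None
    i = crossings[0]
    # linear interpolation of the crossing point
    w = diff[i] / (diff[i] - diff[i + 1])
    zc = z[i] + w * (z[i + 1] - z[i])
    return float(k * (z_final - zc))


def cross_section_area(
    model: AssemblyModel | tuple[np.ndarray, np.ndarray],
    z_plane: float,
    slab: float = 2.0,
    roles: tuple[str, ...] = ("tube",),
) -> float:
    """Convex-hull area of a horizontal slice, nm^2.

    Atoms within ``slab``/2 of ``z_plane`` (Angstrom) are projected onto the
    xy plane as circles of their van der Waals radii; the area is the convex
    hull of those circles.  ``model`` may be an AssemblyModel (sliced over
    the given roles, default the tube/spike) or a raw (xyz, radii) pair.
    Returns 0 for an empty slab.
    """
    from shapely.geometry import MultiPoint, Point
    from shapely.ops import unary_union

    if slab <= 0.0:
        raise DomainError("slab must be positive")
    if isinstance(model, AssemblyModel):
        atoms, _, role_of = model.atoms()
        sel = np.isin(role_of, roles)
        xyz, radii = atoms.xyz[sel], atoms.vdw_radius[sel]
    else:
        xyz, radii = model
        xyz = np.asarray(xyz, dtype=float)
        radii = np.asarray(radii, dtype=float)
    in_slab = np.abs(xyz[:, 2] - z_plane) <= slab / 2.0
    if not np.any(in_slab):
        return 0.0
    pts = xyz[in_slab, :2]
    rr = radii[in_slab]
    shapes = [
        Point(x, y).buffer(r, quad_segs=64) if r > 0.0 else Point(x, y)
        for (x, y), r in zip(pts, rr)
    ]
    hull = unary_union([MultiPoint([]).union(s) for s in shapes]).convex_hull
    return float(hull.area) / 100.0  # A^2 -> nm^2


def mean_pressure(force: float, area: float) -> float:
    """Mean pressure across a cross section, atm (force pN, area nm^2)."""
    if area <= 0.0:
        raise DomainError("area must be positive")
    return force / area * PN_PER_NM2_TO_ATM


def integrate_force(profile: ForceProfile) -> float:
    """Work of the fitted force over its displacement domain, kcal/mol.

    By construction this equals -(G(z_end) - G(z_start)) of the quartic fit
    up to quadrature error; exposed for energy-force consistency checks.
    """
    conv = KCAL_PER_MOL_PER_ANGSTROM_TO_PN / 10.0
    z = np.linspace(profile.displacement[0], profile.displacement[-1], 20001)
    dcoeffs = np.polyder(profile.poly_coeffs)
    f = -np.polyval(dcoeffs, z) * conv
    return float(np.trapezoid(f, z) / conv)
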