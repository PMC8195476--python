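"""Layer-wise propagation of the contracted fraction (the DMAD dynamics).

Contraction starts from a small perturbation of the baseplate-proximal
layer and propagates up the stack.  At iteration j the contracted fraction
of layer i is advanced by

* a parabolic velocity term v = v_max * (lam - lam^2) evaluated at the
  previous iteration and mixed with neighbouring layers through the
  intra-strand coupling k1 (weights 1 : k1 with normalisation 1 + k1 at the
  two ends, 1 : k1 : k1 with normalisation 1 + 2 k1 in the interior);
* an inter-strand spring term k2 * s^2, where s is the stretch (positive
  part of the excess over the resting distance) of the inter-strand link to
  the layer below; the bottom layer is retarded by the stretch above it,
  interior layers feel the difference of the stretches below and above,
  and the top layer is pulled by the stretch below it;
* a drag term D * d, where d is the COM displacement of the previous
  iteration.

lam is clamped at 1 from above; there is no lower clamp (faithful to the
update rules), but negative values are truncated at 0 when converting to
poses, with a warning.  The dynamics is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dmad.errors import DomainError, InputError, NumericalError
from dmad.geometry import LatticeSpec

__all__ = [
    "PropagationParams",
    "Trajectory",
    "IntegrityReport",
    "initial_perturbation",
    "subunit_velocity",
    "propagation_step",
    "run_propagation",
    "contraction_wavelength",
    "integrity_check",
    "sample_rows",
    "trajectory_to_frame",
]


@dataclass(frozen=True)
class PropagationParams:
    """Parameters of the propagation dynamics.

    k1 : dimensionless intra-strand coupling in [0, 1]; 1 = rigid (synchronous).
    k2 : inter-strand coupling, Angstrom^-2.
    drag : D, Angstrom^-1, retards baseplate-distal subunits.
    perturbation : P, initial contracted fraction of the bottom layer
        (default 1/1000 of the total motion).
    v_max : maximum fraction of the geodesic path traversed per iteration
        (default 0.05).
    """

    k1: float = 0.7
    k2: float = 2.5e-4
    drag: float = 5.0e-4
    perturbation: float = 1.0e-3
    v_max: float = 0.05
    max_iterations: int = 100_000
    completion_tolerance: float = 1.0e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.k1 <= 1.0):
            raise DomainError(f"k1 must be in [0, 1], got {self.k1}")
        if self.k2 < 0.0:
            raise DomainError("k2 must be >= 0")
        if self.drag < 0.0:
            raise DomainError("drag must be >= 0")
        if not (0.0 < self.perturbation <= 0.01):
            raise DomainError("perturbation must be in (0, 0.01]")
        if self.v_max <= 0.0:
            raise DomainError("v_max must be > 0")
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")


@dataclass
class Trajectory:
    """Result of a propagation run.

    ``lam_matrix`` is (n_iterations, n_layers); ``b_matrix`` / ``s_matrix`` /
    ``d_matrix`` hold the inter-strand COM distances, stretches and
    per-iteration displacements (Angstrom).  Column 0 of b and s is NaN:
    the bottom layer has no inter-strand link below it and the update rules
    never reference it.  ``reaction_coordinate`` is the per-iteration mean of
    lam over layers.
    """

    params: PropagationParams
    spec: LatticeSpec
    lam_matrix: np.ndarray
    b_matrix: np.ndarray
    s_matrix: np.ndarray
    d_matrix: np.ndarray
    converged: bool

    @property
    def n_iterations(self) -> int:
        return self.lam_matrix.shape[0]

    @property
    def n_layers(self) -> int:
        return self.lam_matrix.shape[1]

    @property
    def reaction_coordinate(self) -> np.ndarray:
        return self.lam_matrix.mean(axis=1)


@dataclass(frozen=True)
class IntegrityReport:
    """Outcome of the mesh-integrity screen of a trajectory."""

    passed: bool
    max_vertical_separation: float
    max_interstrand_distance: float
    threshold: float
    first_violation: tuple[int, int] | None  # (iteration index, layer index), 0-based


def initial_perturbation(params: PropagationParams, n_layers: int) -> np.ndarray:
    """Initial contracted fractions lam_1^i = P * k1^(i-1), i = 1..n_layers."""
    if n_layers < 2:
        raise DomainError("n_layers must be >= 2")
    return params.perturbation * params.k1 ** np.arange(n_layers, dtype=float)


def subunit_velocity(lam_prev, v_max: float):
    """Parabolic velocity profile: zero at both end states, v_max/4 at lam=0.5."""
    lam_prev = np.asarray(lam_prev, dtype=float)
    out = v_max * (lam_prev - lam_prev**2)
    return float(out) if out.ndim == 0 else out


class _LatticeArrays:
    """Vectorized end-state geometry of a lattice, for the inner loop."""

    def __init__(self, spec: LatticeSpec):
        a = spec.arrays()
        self.r_ext = a["r_ext"]
        self.r_cnt = a["r_cnt"]
        self.z_ext = a["z_ext"]
        self.z_cnt = a["z_cnt"]
        self.theta0 = a["theta0"]
        self.sweep = a["theta_sweep"]
        self.offset = spec.interstrand_azimuth_offset

    def cartesian(self, lam: np.ndarray, extra_azimuth: float = 0.0) -> np.ndarray:
        """COM cartesian coordinates of every layer at fractions ``lam``.

        lam is used as-is (linear extrapolation below 0 mirrors the update
        rules, which have no lower clamp).
        """
        r = self.r_ext + lam * (self.r_cnt - self.r_ext)
        th = self.theta0 + lam * self.sweep + extra_azimuth
        z = self.z_ext + lam * (self.z_cnt - self.z_ext)
        return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)

    def interstrand_b(self, lam: np.ndarray) -> np.ndarray:
        """b^i: distance from layer i to its inter-strand partner below (NaN for i=1)."""
        own = self.cartesian(lam)
        below = self.cartesian(lam, extra_azimuth=self.offset)
        b = np.full(len(lam), np.nan)
        b[1:] = np.linalg.norm(own[1:] - below[:-1], axis=1)
        return b


def propagation_step(
    lam_prev: np.ndarray,
    s_prev: np.ndarray,
    d_prev: np.ndarray,
    params: PropagationParams,
    geom: _LatticeArrays,
    b0: np.ndarray,
    iteration: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One iteration of the update rules.

    Velocities are evaluated at the *new* iteration (from lam of the previous
    one); stretches and displacements enter with their previous-iteration
    values.  Returns (lam, b, s, d) for the new iteration.
    """
    k1, k2, drag = params.k1, params.k2, params.drag
    n = len(lam_prev)
    v = subunit_velocity(lam_prev, params.v_max)

    lam = np.empty(n)
    lam[0] = lam_prev[0] + (v[0] + k1 * v[1]) / (1.0 + k1) - k2 * s_prev[1] ** 2 - drag * d_prev[0]
    if n > 2:
        i = np.arange(1, n - 1)
        lam[i] = (
            lam_prev[i]
            + (v[i] + k1 * v[i - 1] + k1 * v[i + 1]) / (1.0 + 2.0 * k1)
            + k2 * (s_prev[i] ** 2 - s_prev[i + 1] ** 2)
            - drag * d_prev[i]
        )
    lam[-1] = (
        lam_prev[-1]
        + (v[-1] + k1 * v[-2]) / (1.0 + k1)
        + k2 * s_prev[-1] ** 2
        - drag * d_prev[-1]
    )
    lam = np.minimum(1.0, lam)

    if not np.all(np.isfinite(lam)):
        raise NumericalError(
            f"nonfinite contracted fraction at iteration {iteration}", iteration=iteration
        )

    b = geom.interstrand_b(lam)
    s = np.maximum(0.0, b - b0)  # NaN propagates for layer 1, never referenced
    with np.errstate(invalid="ignore"):
        s = np.where(np.isnan(b), np.nan, s)
    d = np.linalg.norm(geom.cartesian(lam) - geom.cartesian(lam_prev), axis=1)
    return lam, b, s, d


def run_propagation(params: PropagationParams, spec: LatticeSpec) -> Trajectory:
    """Iterate the dynamics until the top layer reaches its contracted pose.

    The stop criterion generalizes "top-layer radius reached its contracted
    value" to fractional completion: lam_top >= 1 - completion_tolerance.
    If the motion stalls, the trajectory is returned with converged=False
    and a warning (not an exception).
    """
    if spec.n_layers < 2:
        raise InputError("propagation needs at least 2 layers")
    geom = _LatticeArrays(spec)
    n = spec.n_layers
    b0 = geom.interstrand_b(np.zeros(n))

    lam = initial_perturbation(params, n)
    b = geom.interstrand_b(lam)
    with np.errstate(invalid="ignore"):
        s = np.where(np.isnan(b), np.nan, np.maximum(0.0, b - b0))
    d = np.zeros(n)

    lam_rows, b_rows, s_rows, d_rows = [lam], [b], [s], [d]
    converged = lam[-1] >= 1.0 - params.completion_tolerance
    for j in range(2, params.max_iterations + 1):
        try:
            with np.errstate(over="raise", invalid="raise"):
                lam, b, s, d = propagation_step(lam, s, d, params, geom, b0, j)
        except (NumericalError, FloatingPointError):
            warnings.warn(
                f"numerical overflow at iteration {j}; trajectory truncated "
                "(motion diverged under the given couplings/drag)",
                stacklevel=2,
            )
            break
        lam_rows.append(lam)
        b_rows.append(b)
        s_rows.append(s)
        d_rows.append(d)
        if lam[-1] >= 1.0 - params.completion_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"propagation did not complete within {params.max_iterations} iterations "
            f"(top-layer fraction {lam_rows[-1][-1]:.4f})",
            stacklevel=2,
        )
    if any(np.any(row < 0.0) for row in lam_rows):
        warnings.warn(
            "negative contracted fractions occurred; they are truncated at 0 "
            "when converting to poses",
            stacklevel=2,
        )
    return Trajectory(
        params=params,
        spec=spec,
        lam_matrix=np.array(lam_rows),
        b_matrix=np.array(b_rows),
        s_matrix=np.array(s_rows),
        d_matrix=np.array(d_rows),
        converged=converged,
    )


def contraction_wavelength(
    traj: Trajectory, hi: float = 0.98, lo: float = 0.02
) -> int | None:
    """Smallest layer count separating near-contracted from near-extended subunits.

    For each iteration, find the topmost layer with lam >= hi and the lowest
    layer above it with lam <= lo; their index difference is that iteration's
    wavelength.  Returns the minimum over iterations, or None when no
    iteration contains both (synchronous contraction: infinite wavelength).
    """
    best: int | None = None
    for row in traj.lam_matrix:
        hi_idx = np.nonzero(row >= hi)[0]
        if hi_idx.size == 0:
            continue
        top_hi = hi_idx.max()
        lo_idx = np.nonzero(row[top_hi + 1 :] <= lo)[0]
        if lo_idx.size == 0:
            continue
        wl = int(lo_idx.min() + 1)
        if best is None or wl < best:
            best = wl
    return best


def integrity_check(traj: Trajectory, spec: LatticeSpec | None = None) -> IntegrityReport:
    """Screen a trajectory for mesh-breaking COM separations.

    Checks, at every iteration, the intra-strand vertical COM separation
    |z^i - z^{i+1}| and the inter-strand COM distance b against
    ``spec.max_com_separation`` (55 Angstrom for pyocin: larger separations
    disintegrate the handshake domain).
    """
    spec = spec if spec is not None else traj.spec
    geom = _LatticeArrays(spec)
    thr = spec.max_com_separation
    max_dz = 0.0
    max_b = 0.0
    first: tuple[int, int] | None = None
    for j, lam in enumerate(traj.lam_matrix):
        z = geom.z_ext + lam * (geom.z_cnt - geom.z_ext)
        dz = np.abs(np.diff(z))
        b = traj.b_matrix[j]
        bmax = np.nanmax(b) if np.any(np.isfinite(b)) else 0.0
        max_dz = max(max_dz, float(dz.max()))
        max_b = max(max_b, float(bmax))
        if first is None:
            bad_dz = np.nonzero(dz > thr)[0]
            with np.errstate(invalid="ignore"):
                bad_b = np.nonzero(b > thr)[0]
            if bad_dz.size or bad_b.size:
                layer = int(min([*bad_dz.tolist(), *bad_b.tolist()]))
                first = (j, layer)
    return IntegrityReport(
        passed=first is None,
        max_vertical_separation=max_dz,
        max_interstrand_distance=max_b,
        threshold=thr,
        first_violation=first,
    )


def sample_rows(traj: Trajectory, n_frames: int = 100) -> np.ndarray:
    """Indices of ~n_frames iterations evenly spaced in reaction coordinate.

    The first and last iterations are always included; indices are unique
    and sorted.  Used to pick the intermediates whose energies are
    evaluated.
    """
    rc = traj.reaction_coordinate
    targets = np.linspace(rc[0], rc[-1], n_frames)
    idx = np.searchsorted(rc, targets)
    idx = np.clip(idx, 0, len(rc) - 1)
    idx[0], idx[-1] = 0, len(rc) - 1
    return np.unique(idx)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format table (iteration, layer, lam, r, theta, z, kappa, b, s, d)."""
    geom = _LatticeArrays(traj.spec)
    a = traj.spec.arrays()
    rows = []
    for j, lam in enumerate(traj.lam_matrix):
        lam_pose = np.maximum(0.0, lam)
        rows.append(
            pd.DataFrame(
                {
                    "iteration": j + 1,
                    "layer": np.arange(1, traj.n_layers + 1),
                    "lam": lam,
                    "r": a["r_ext"] + lam_pose * (a["r_cnt"] - a["r_ext"]),
                    "theta": a["theta0"] + lam_pose * a["theta_sweep"],
                    "z": a["z_ext"] + lam_pose * (a["z_cnt"] - a["z_ext"]),
                    "kappa": lam_pose * a["kappa_cnt"],
                    "b": traj.b_matrix[j],
                    "s": traj.s_matrix[j],
                    "d": traj.d_matrix[j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
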