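"""Extrapolating a 12-layer fragment pathway to the full-length machine.

Two empirical regularities make the extrapolation possible: (1) for a given
(k1, k2, D) set, the energy of a nonterminal sheath layer (layers 3..N-2)
is a function of its contracted fraction alone, independent of its position
in the strand; (2) the contribution of the four terminal layers (two
bottom, two top), whose interfaces are incompletely engaged, is the same in
a structure of any length.  The full-length profile is therefore a sum of
per-layer energy-vs-lambda curves learned from the short fragment, with
the interior curve's layer-to-layer standard deviation propagated (root
sum of squares, independence assumed) as the extrapolation error band.

Because the inter-strand and drag terms depend on the distance traveled
along the geodesics, transferring (k2, D) to a longer machine rescales
k2 by X^2 and D by X, where X is the ratio of mean geodesic path lengths
(short over full); k1 multiplies velocities, which are path-free, and is
not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from dmad.errors import DomainError, InputError
from dmad.geometry import LatticeSpec
from dmad.propagation import PropagationParams, Trajectory, integrity_check

__all__ = [
    "LayerEnergyCurve",
    "EnergyProfile",
    "extract_layer_curves",
    "rescale_params",
    "full_length_profile",
    "feasibility_screen",
]

LAM_GRID = np.linspace(0.0, 1.0, 101)

_TERMINAL_ROLES = ("bottom-terminal-1", "bottom-terminal-2", "top-terminal-2", "top-terminal-1")


@dataclass
class LayerEnergyCurve:
    """Energy of one layer class vs its contracted fraction, on a 101-point grid."""

    lam_grid: np.ndarray
    mean_energy: np.ndarray  # kcal/mol per subunit-layer
    sd: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lam_grid) <= 0.0):
            raise InputError("lam_grid must be strictly increasing")
        if abs(self.mean_energy[0]) > 1e-9:
            raise InputError("curves are relative to the extended state: mean(0) must be 0")
        if np.any(self.sd < 0.0):
            raise InputError("sd must be nonnegative")

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.lam_grid[0] - 1e-12) or np.any(lam > self.lam_grid[-1] + 1e-12):
            raise DomainError("contracted fraction outside the curve grid [0, 1]")
        return np.interp(lam, self.lam_grid, self.mean_energy)

    def sd_at(self, lam: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(lam, dtype=float), self.lam_grid, self.sd)


@dataclass
class EnergyProfile:
    """Free energy vs reaction coordinate with an uncertainty band."""

    reaction_coordinate: np.ndarray
    energy: np.ndarray  # kcal/mol, extended state == 0
    sd: np.ndarray
    lam_rows: np.ndarray  # (n_frames, n_layers) poses behind each point


def _interp_layer(lam_t: np.ndarray, e_t: np.ndarray) -> np.ndarray:
    """Energy of one layer interpolated onto the common lambda grid."""
    order = np.argsort(lam_t, kind="mergesort")
    x = lam_t[order]
    y = e_t[order]
    # collapse duplicate lambda values (stalled layers) by averaging
    ux, inv = np.unique(np.round(x, 12), return_inverse=True)
    uy = np.zeros(len(ux))
    cnt = np.zeros(len(ux))
    np.add.at(uy, inv, y)
    np.add.at(cnt, inv, 1.0)
    uy /= cnt
    return np.interp(LAM_GRID, ux, uy)


def extract_layer_curves(
    lam_rows: np.ndarray, per_layer_energy: np.ndarray
) -> dict[str, LayerEnergyCurve]:
    """Learn per-layer-class energy curves from a 12-layer pathway.

    ``lam_rows`` is (n_frames, 12) and ``per_layer_energy`` the matching
    per-layer energies relative to the extended state.  Interior layers
    (3..10) are pooled into a mean +/- SD curve; the four terminal layers
    keep individual curves (roles bottom-terminal-1/2 from the baseplate,
    top-terminal-1/2 from the distal end).  The interior SD is the error
    source of the extrapolation.
    """
    lam_rows = np.asarray(lam_rows, dtype=float)
    per_layer_energy = np.asarray(per_layer_energy, dtype=float)
    if lam_rows.ndim != 2 or lam_rows.shape[1] < 12:
        raise InputError("extraction requires a 12-layer trajectory")
    if lam_rows.shape != per_layer_energy.shape:
        raise InputError("lam rows and per-layer energies must align")
    n_layers = lam_rows.shape[1]
    lam_rows = np.clip(lam_rows, 0.0, 1.0)
    layer_curves = np.stack(
        [
            _interp_layer(lam_rows[:, li], per_layer_energy[:, li])
            for li in range(n_layers)
        ]
    )
    layer_curves -= layer_curves[:, :1]  # anchor every layer at 0 for lam=0
    interior = layer_curves[2 : n_layers - 2]
    curves = {
        "interior": LayerEnergyCurve(
            lam_grid=LAM_GRID.copy(),
            mean_energy=interior.mean(axis=0),
            sd=interior.std(axis=0, ddof=1),
            role="interior",
        )
    }
    for role, li in zip(_TERMINAL_ROLES, (0, 1, n_layers - 2, n_layers - 1)):
        curves[role] = LayerEnergyCurve(
            lam_grid=LAM_GRID.copy(),
            mean_energy=layer_curves[li],
            sd=np.zeros_like(LAM_GRID),
            role=role,
        )
    return curves


def rescale_params(params12: PropagationParams, x_ratio: float) -> PropagationParams:
    """Transfer (k2, D) to a machine with different geodesic path lengths.

    k2 scales by x_ratio^2, D by x_ratio; k1 is untouched (velocities do
    not depend on the path).
    """
    if x_ratio <= 0.0:
        raise DomainError("x_ratio must be positive")
    return replace(params12, k2=params12.k2 * x_ratio**2, drag=params12.drag * x_ratio)


def layer_roles(n_layers: int) -> list[str]:
    roles = ["bottom-terminal-1", "bottom-terminal-2"]
    roles += ["interior"] * (n_layers - 4)
    roles += ["top-terminal-2", "top-terminal-1"]
    return roles


def full_length_profile(
    lam_rows: np.ndarray,
    curves: dict[str, LayerEnergyCurve],
) -> EnergyProfile:
    """Sum the per-layer curves over a full-length trajectory's lam rows.

    G(intermediate) = sum over layers of curve(role(layer))(lam_layer),
    with the interior curve applied to layers 3..N-2.  The SD band is the
    root of the summed interior variances (standard propagation of
    uncertainty under independence); it vanishes wherever the interior
    layers were homogeneous.
    """
    lam_rows = np.asarray(lam_rows, dtype=float)
    if lam_rows.ndim != 2 or lam_rows.shape[1] < 12:
        raise InputError("full-length profile needs >= 12 layers")
    if np.any(lam_rows < -1e-12) or np.any(lam_rows > 1.0 + 1e-12):
        raise DomainError(
            "contracted fractions outside [0, 1]: the layer curves are only "
            "defined on the unit interval"
        )
    lam_rows = np.clip(lam_rows, 0.0, 1.0)
    roles = layer_roles(lam_rows.shape[1])
    energy = np.zeros(lam_rows.shape[0])
    var = np.zeros(lam_rows.shape[0])
    for li, role in enumerate(roles):
        c = curves[role]
        energy += c(lam_rows[:, li])
        var += c.sd_at(lam_rows[:, li]) ** 2
    return EnergyProfile(
        reaction_coordinate=lam_rows.mean(axis=1),
        energy=energy - energy[0],
        sd=np.sqrt(var),
        lam_rows=lam_rows,
    )


def feasibility_screen(traj: Trajectory, spec: LatticeSpec | None = None):
    """Mesh-integrity screen of a (full-length) trajectory.

    Delegates to the propagation integrity check (COM separations against
    ``max_com_separation``); the report carries the rejection reason.
    """
    return integrity_check(traj, spec)


def transition_state_diagnostics(profile: EnergyProfile) -> dict:
    """Reported (not asserted) features of the transition state."""
    idx = int(np.argmax(profile.energy))
    return {
        "transition_index": idx,
        "reaction_coordinate": float(profile.reaction_coordinate[idx]),
        "bottom_layer_fraction": float(profile.lam_rows[idx, 0]),
        "top_layer_fraction": float(profile.lam_rows[idx, -1]),
    }
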