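"""Building atomic/bead models of contraction intermediates.

A subunit template is stored in its COM frame (COM at the origin, azimuth-0
orientation).  Internal flexibility between the end states is carried by a
morph series: 101 conformations obtained by linear Cartesian interpolation
of the COM-removed, rotation-factored end states (frame 0 = extended,
frame 100 = contracted).  Placement of a subunit at contracted fraction lam
selects morph frame round(100*lam), rotates it by kappa about the fixed
(omega, phi) axis, rotates the result to its azimuth about the helical
axis, and translates the COM to its cylindrical position.  Symmetry
expansion replicates every layer ``symmetry_order`` times; the tube moves
as one rigid body following the top sheath layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from dmad.errors import DomainError, InputError
from dmad.geometry import LatticeSpec, LayerEndStates, Pose, pose_at_fraction

__all__ = [
    "AtomSet",
    "MorphSeries",
    "AssemblyModel",
    "build_morph",
    "morph_frame_for",
    "place_subunit",
    "build_intermediate",
    "clash_pairs",
]


@dataclass
class AtomSet:
    """A flat collection of atoms (or beads) with per-atom metadata.

    ``element`` may be a chemical element symbol or the pseudo-element "BD"
    for coarse beads.  Coordinates are Angstrom.
    """

    element: np.ndarray  # (n,) str
    name: np.ndarray  # (n,) str
    residue_index: np.ndarray  # (n,) int
    residue_name: np.ndarray  # (n,) str
    chain_id: np.ndarray  # (n,) str
    xyz: np.ndarray  # (n, 3) float
    vdw_radius: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise InputError("atom coordinates must be finite")
        if np.any(self.vdw_radius <= 0.0):
            raise InputError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def com(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def with_xyz(self, xyz: np.ndarray) -> "AtomSet":
        return AtomSet(
            element=self.element,
            name=self.name,
            residue_index=self.residue_index,
            residue_name=self.residue_name,
            chain_id=self.chain_id,
            xyz=np.asarray(xyz, dtype=float),
            vdw_radius=self.vdw_radius,
        )

    @staticmethod
    def concatenate(parts: list["AtomSet"]) -> "AtomSet":
        return AtomSet(
            element=np.concatenate([p.element for p in parts]),
            name=np.concatenate([p.name for p in parts]),
            residue_index=np.concatenate([p.residue_index for p in parts]),
            residue_name=np.concatenate([p.residue_name for p in parts]),
            chain_id=np.concatenate([p.chain_id for p in parts]),
            xyz=np.concatenate([p.xyz for p in parts]),
            vdw_radius=np.concatenate([p.vdw_radius for p in parts]),
        )

    @staticmethod
    def from_beads(
        xyz: np.ndarray,
        radius: float,
        element: str = "BD",
        chain_id: str = "A",
        residue_name: str = "BEA",
    ) -> "AtomSet":
        n = len(xyz)
        return AtomSet(
            element=np.full(n, element, dtype=object),
            name=np.array([f"B{i+1}" for i in range(n)], dtype=object),
            residue_index=np.arange(1, n + 1),
            residue_name=np.full(n, residue_name, dtype=object),
            chain_id=np.full(n, chain_id, dtype=object),
            xyz=np.asarray(xyz, dtype=float),
            vdw_radius=np.full(n, float(radius)),
        )


@dataclass
class MorphSeries:
    """101 conformations of one subunit spanning extended (0) to contracted (100)."""

    template: AtomSet  # atom metadata shared by all frames
    frames: np.ndarray  # (101, n_atoms, 3)

    def __post_init__(self) -> None:
        if self.frames.shape[0] != 101:
            raise InputError("a morph series holds exactly 101 frames")
        if self.frames.shape[1] != len(self.template):
            raise InputError("morph frames must match the template atom count")


def build_morph(ext: AtomSet, cnt: AtomSet) -> MorphSeries:
    """Linear Cartesian morph between two conformations of the same subunit.

    The end states are superposed (COM removal + least-squares rotation of
    the contracted onto the extended conformation) before interpolating, so
    the morph carries only internal flexibility; the rigid-body part of the
    motion lives in the Pose.  Frames are in the extended conformation's
    COM frame.
    """
    if len(ext) != len(cnt):
        raise InputError(
            f"atom lists differ: {len(ext)} vs {len(cnt)} atoms"
        )
    mismatched = [
        (str(a), str(b))
        for a, b in zip(ext.name, cnt.name)
        if a != b
    ]
    if mismatched:
        raise InputError(f"atom lists differ in names: {mismatched[:5]} ...")
    x0 = ext.xyz - ext.com
    x1 = cnt.xyz - cnt.com
    if len(ext) >= 3:
        rot, _ = Rotation.align_vectors(x0, x1)
        x1 = rot.apply(x1)
    w = np.linspace(0.0, 1.0, 101)[:, None, None]
    frames = (1.0 - w) * x0[None] + w * x1[None]
    return MorphSeries(template=ext, frames=frames)


def morph_frame_for(lam: float) -> int:
    """Morph frame index for contracted fraction lam: round-half-up of 100*lam."""
    if not (0.0 <= lam <= 1.0):
        raise DomainError(f"lam must be in [0, 1], got {lam}")
    return int(math.floor(100.0 * lam + 0.5))


def _axis_vector(omega: float, phi: float) -> np.ndarray:
    return np.array(
        [math.sin(omega) * math.cos(phi), math.sin(omega) * math.sin(phi), math.cos(omega)]
    )


def place_subunit(
    morph: MorphSeries,
    pose: Pose,
    layer: LayerEndStates,
    strand: int,
    symmetry_order: int,
) -> np.ndarray:
    """Coordinates of one subunit placed at its pose on a given strand.

    The rigid transform is R_z(theta_tot) . R_axis(kappa) applied to the
    COM-removed morph frame, followed by translation of the COM to
    cylindrical (r, theta_tot, z) with theta_tot = pose.theta +
    strand * 2*pi/symmetry_order.  Intra-subunit geometry is preserved to
    machine precision.
    """
    if not (0 <= strand < symmetry_order):
        raise DomainError(f"strand must be in [0, {symmetry_order}), got {strand}")
    frame = morph.frames[morph_frame_for(max(0.0, min(1.0, pose.lam)))]
    frame = frame - frame.mean(axis=0)
    axis = _axis_vector(layer.axis_omega, layer.axis_phi)
    rot = Rotation.from_rotvec(axis * pose.kappa)
    theta_tot = pose.theta + strand * 2.0 * math.pi / symmetry_order
    rz = Rotation.from_euler("z", theta_tot)
    placed = rz.apply(rot.apply(frame))
    com = np.array(
        [pose.r * math.cos(theta_tot), pose.r * math.sin(theta_tot), pose.z]
    )
    return placed + com


@dataclass
class AssemblyModel:
    """One contraction intermediate: placed subunits keyed by (layer, strand, role).

    ``role`` is "sheath" or "tube"; the tube is stored as a single rigid body
    under key (0, 0, "tube").  ``provenance`` records the lam row used.
    """

    spec: LatticeSpec
    subunits: dict[tuple[int, int, str], np.ndarray]
    sheath_template: AtomSet
    tube_template: AtomSet | None
    lam_row: np.ndarray

    def atoms(self) -> tuple[AtomSet, np.ndarray, np.ndarray]:
        """Flatten to one AtomSet plus per-atom layer index and role arrays.

        For the tube, the layer index is inferred from each tube atom's
        nearest extended-state sheath layer plane (tube rings are generated
        per layer by the synthetic fixtures, so this is exact there).
        """
        parts, layers, roles = [], [], []
        for (layer, strand, role), xyz in sorted(
            self.subunits.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])
        ):
            if role == "sheath":
                tmpl = self.sheath_template.with_xyz(xyz)
                parts.append(tmpl)
                layers.append(np.full(len(tmpl), layer))
                roles.append(np.full(len(tmpl), "sheath", dtype=object))
            else:
                tmpl = self.tube_template.with_xyz(xyz)
                parts.append(tmpl)
                z_planes = np.array([lay.z_ext for lay in self.spec.layers])
                ring = np.argmin(
                    np.abs(xyz[:, 2][:, None] - z_planes[None, :]), axis=1
                ) + 1
                layers.append(ring)
                roles.append(np.full(len(tmpl), "tube", dtype=object))
        return (
            AtomSet.concatenate(parts),
            np.concatenate(layers),
            np.concatenate(roles),
        )


def clash_pairs(
    xyz: np.ndarray,
    radii: np.ndarray,
    group: np.ndarray,
    factor: float = 0.6,
) -> list[tuple[int, int]]:
    """Pairs of atoms from different groups closer than factor*(r_i + r_j)."""
    tree = cKDTree(xyz)
    cutoff = factor * 2.0 * radii.max()
    out = []
    for i, j in tree.query_pairs(cutoff):
        if group[i] == group[j]:
            continue
        if np.linalg.norm(xyz[i] - xyz[j]) < factor * (radii[i] + radii[j]):
            out.append((min(i, j), max(i, j)))
    return sorted(out)


def build_intermediate(
    lam_row: np.ndarray,
    spec: LatticeSpec,
    sheath_morph: MorphSeries,
    tube_template: AtomSet | None = None,
    tube_rotates: bool = True,
    clash_factor: float = 0.6,
    with_clashes: bool = False,
) -> AssemblyModel | tuple[AssemblyModel, list[tuple[int, int]]]:
    """Place all sheath subunits (and the tube) for one lam row.

    Negative lam values are truncated at 0 with a warning before posing.
    The tube follows the top sheath layer: translated by its Delta-z and,
    when ``tube_rotates`` (default), rotated about the helical axis by its
    Delta-theta.
    """
    lam_row = np.asarray(lam_row, dtype=float)
    if len(lam_row) != spec.n_layers:
        raise InputError("lam row length must equal the layer count")
    if np.any(lam_row < 0.0):
        warnings.warn("negative contracted fractions truncated at 0 for posing", stacklevel=2)
        lam_row = np.maximum(0.0, lam_row)
    if sheath_morph is None:
        raise InputError("a sheath morph template is required")
    subunits: dict[tuple[int, int, str], np.ndarray] = {}
    for li, layer in enumerate(spec.layers):
        pose = pose_at_fraction(layer, float(lam_row[li]))
        for strand in range(spec.symmetry_order):
            subunits[(layer.layer_index, strand, "sheath")] = place_subunit(
                sheath_morph, pose, layer, strand, spec.symmetry_order
            )
    if tube_template is not None:
        top = spec.layers[-1]
        lam_top = float(lam_row[-1])
        dz = lam_top * (top.z_cnt - top.z_ext)
        dth = lam_top * top.theta_sweep if tube_rotates else 0.0
        xyz = tube_template.xyz
        if dth != 0.0:
            xyz = Rotation.from_euler("z", dth).apply(xyz)
        subunits[(0, 0, "tube")] = xyz + np.array([0.0, 0.0, dz])
    model = AssemblyModel(
        spec=spec,
        subunits=subunits,
        sheath_template=sheath_morph.template,
        tube_template=tube_template,
        lam_row=lam_row,
    )
    if not with_clashes:
        return model
    atoms, _, _ = model.atoms()
    keys = sorted(model.subunits, key=lambda k: (k[2], k[0], k[1]))
    group = np.concatenate(
        [np.full(len(model.subunits[k]), gi) for gi, k in enumerate(keys)]
    )
    # atoms() sorts identically, so group labels align with the flattened atoms
    clashes = clash_pairs(atoms.xyz, atoms.vdw_radius, group, factor=clash_factor)
    return model, clashes
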