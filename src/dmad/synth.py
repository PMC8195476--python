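"""Download-free synthetic test inputs.

The lattice generator emulates a two-state 6-start helical sheath-tube
assembly: the extended state is long and narrow (rise 43 A per layer), the
contracted state half the length and wider (rise 21.5 A, larger radius and
twist), so the default 28-layer machine shortens by ~60 nm — the geometric
regime of an R-type pyocin.  Subunits are reproducible pseudo-random bead
clusters sized so that inter-subunit contact areas grow from the extended
to the contracted state; under the default solvation parameters the
contracted end state is therefore the global minimum and mid-path strand
hyper-extension produces a positive activation barrier.  The generator also
produces first-order kinetics time courses with Arrhenius-distributed rates
for the kinetics module.

All fixtures are bit-reproducible from (config, seed); nothing is
downloaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dmad.builder import AtomSet, MorphSeries, build_morph
from dmad.errors import DomainError
from dmad.geometry import LatticeSpec, LayerEndStates

__all__ = [
    "SyntheticLatticeConfig",
    "LatticeFixture",
    "make_lattice",
    "simulate_timecourses",
    "GAS_CONSTANT_KCAL",
]

#: gas constant, kcal/mol/K
GAS_CONSTANT_KCAL = 1.98720e-3


@dataclass(frozen=True)
class SyntheticLatticeConfig:
    """Geometry and bead parameters of the synthetic two-state lattice.

    Defaults give a 12-layer fragment of a pyocin-scale machine: per-layer
    rise halves on contraction (43 -> 21.5 A), the sheath COM radius grows
    (42 -> 60 A) and the per-layer twist increases (0.40 -> 0.56 rad), with
    a 0.6-rad subunit rotation about the helical axis.  ``mesh_tolerance``
    is the COM separation at which the fictional bead mesh loses contact
    (roughly twice the subunit half-extent plus slack); it becomes the
    lattice's ``max_com_separation``.
    """

    n_layers: int = 12
    rise_ext: float = 43.0
    rise_cnt: float = 21.5
    twist_ext: float = 0.40
    twist_cnt: float = 0.56
    radius_ext: float = 42.0
    radius_cnt: float = 60.0
    kappa_cnt: float = 0.6
    axis_omega: float = 0.0
    axis_phi: float = 0.0
    beads_per_subunit: int = 10
    bead_radius: float = 8.0
    subunit_spread: float = 21.0  # ellipsoidal cluster half-extent, A
    tube_radius: float = 30.0
    tube_beads_per_ring: int = 6
    tube_bead_radius: float = 7.0
    mesh_tolerance: float = 70.0  # COM separation breaking the bead mesh, A
    internal_flex: float = 0.0  # A of end-state conformational difference
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rise_ext",
            "rise_cnt",
            "radius_ext",
            "radius_cnt",
            "bead_radius",
            "subunit_spread",
            "tube_radius",
            "tube_bead_radius",
        ):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"{name} must be positive")
        if self.n_layers < 2:
            raise DomainError("n_layers must be >= 2")


@dataclass
class LatticeFixture:
    """A generated lattice: spec plus the templates the builder consumes."""

    config: SyntheticLatticeConfig
    spec: LatticeSpec
    sheath_morph: MorphSeries
    tube_template: AtomSet


def _layer_end_states(cfg: SyntheticLatticeConfig) -> tuple[LayerEndStates, ...]:
    layers = []
    for i in range(cfg.n_layers):
        theta0 = i * cfg.twist_ext
        theta_cnt = i * cfg.twist_cnt
        layers.append(
            LayerEndStates(
                layer_index=i + 1,
                r_ext=cfg.radius_ext,
                r_cnt=cfg.radius_cnt,
                theta0=theta0,
                theta_sweep=theta_cnt - theta0,
                z_ext=i * cfg.rise_ext,
                z_cnt=i * cfg.rise_cnt,
                axis_omega=cfg.axis_omega,
                axis_phi=cfg.axis_phi,
                kappa_cnt=cfg.kappa_cnt,
            )
        )
    return tuple(layers)


def _bead_cluster(cfg: SyntheticLatticeConfig, rng: np.random.Generator) -> np.ndarray:
    """Reproducible ellipsoidal bead cluster in the subunit COM frame.

    Half-extents (radial, azimuthal, axial) are chosen so neighbouring
    subunits barely touch in the extended lattice and pack tightly in the
    contracted one.
    """
    half = np.array([cfg.subunit_spread, cfg.subunit_spread, cfg.subunit_spread * 0.9])
    pts = rng.uniform(-1.0, 1.0, size=(cfg.beads_per_subunit, 3)) * half
    return pts - pts.mean(axis=0)


def make_lattice(cfg: SyntheticLatticeConfig | None = None) -> LatticeFixture:
    """Generate the lattice spec, the sheath bead morph and the tube template.

    The extended and contracted subunit conformations are identical (the
    morph is degenerate) unless ``internal_flex`` is nonzero, in which case
    the contracted conformation is perturbed by a reproducible random
    displacement of that magnitude.
    """
    cfg = cfg or SyntheticLatticeConfig()
    rng = np.random.default_rng(cfg.seed)
    layers = _layer_end_states(cfg)
    spec = LatticeSpec(layers=layers, max_com_separation=cfg.mesh_tolerance)

    cluster = _bead_cluster(cfg, rng)
    ext = AtomSet.from_beads(cluster, cfg.bead_radius, chain_id="S")
    if cfg.internal_flex > 0.0:
        bump = rng.normal(scale=cfg.internal_flex / math.sqrt(3.0), size=cluster.shape)
        cnt = AtomSet.from_beads(cluster + bump, cfg.bead_radius, chain_id="S")
    else:
        cnt = AtomSet.from_beads(cluster.copy(), cfg.bead_radius, chain_id="S")
    morph = build_morph(ext, cnt)

    ring_angles = 2.0 * math.pi * np.arange(cfg.tube_beads_per_ring) / cfg.tube_beads_per_ring
    tube_xyz = []
    for i, lay in enumerate(layers):
        a = ring_angles + i * cfg.twist_ext
        ring = np.stack(
            [
                cfg.tube_radius * np.cos(a),
                cfg.tube_radius * np.sin(a),
                np.full(len(a), lay.z_ext),
            ],
            axis=1,
        )
        tube_xyz.append(ring)
    tube = AtomSet.from_beads(
        np.concatenate(tube_xyz), cfg.tube_bead_radius, chain_id="T", residue_name="TUB"
    )
    return LatticeFixture(config=cfg, spec=spec, sheath_morph=morph, tube_template=tube)


def simulate_timecourses(
    Ea: float,
    lnA: float,
    temperatures,
    noise_sd: float = 0.0,
    n_points: int = 60,
    t_max: float = 40.0,
    n_halflives: float | None = None,
    seed: int = 0,
    s0: float = 1.0,
    s_inf: float = 0.0,
) -> pd.DataFrame:
    """First-order contraction time courses with Arrhenius-distributed rates.

    k(T) = exp(lnA - Ea / (R T)), signal(t) = s_inf + (s0 - s_inf) e^{-k t}
    plus Gaussian noise of ``noise_sd``.  Ea in kcal/mol, T in Kelvin, t in
    the unit implied by lnA (minutes for the default pipeline).  Fully
    deterministic given ``seed``.

    With ``n_halflives`` set, each temperature is observed over its own
    window of that many half-lives (the experimental habit of recording
    until the reaction completes); the rate estimates then carry identical
    relative errors across temperatures.  Otherwise a common ``t_max``
    window is used.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if np.any(temperatures <= 0.0):
        raise DomainError("temperatures must be positive (Kelvin)")
    rng = np.random.default_rng(seed)
    frames = []
    for T in temperatures:
        k = math.exp(lnA - Ea / (GAS_CONSTANT_KCAL * T))
        window = n_halflives * math.log(2.0) / k if n_halflives is not None else t_max
        t = np.linspace(0.0, window, n_points)
        signal = s_inf + (s0 - s_inf) * np.exp(-k * t)
        if noise_sd > 0.0:
            signal = signal + rng.normal(scale=noise_sd, size=len(t))
        frames.append(
            pd.DataFrame({"time": t, "signal": signal, "temperature": T, "rate_true": k})
        )
    return pd.concat(frames, ignore_index=True)
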