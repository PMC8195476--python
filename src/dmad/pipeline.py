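"""End-to-end orchestration of the contraction analysis.

The canonical workflow:

1. generate (or load) the two-end-state lattice and subunit templates;
2. grid-search (k1, k2, D) on the short fragment and select the optimal
   pathway (lowest barrier, intact mesh, no substantial local minima);
3. learn per-layer energy-vs-fraction curves from the optimal fragment
   pathway;
4. rescale (k2, D) by the geodesic path ratio, propagate the full-length
   machine, screen feasibility, and extrapolate the energy profile;
5. derive the force profile, the AFM-spring crossing, the tube
   cross-section and the mean pressure.

Each stage is a thin call into the corresponding module; this file only
wires them together so the CLI and the reproduction script stay small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dmad import extrapolate, force, search
from dmad.energy import SolvationParams, profile_energies
from dmad.errors import InputError
from dmad.geometry import path_ratio
from dmad.propagation import (
    PropagationParams,
    Trajectory,
    contraction_wavelength,
    run_propagation,
    sample_rows,
)
from dmad.synth import LatticeFixture, SyntheticLatticeConfig, make_lattice

__all__ = ["FragmentResult", "FullLengthResult", "run_fragment", "run_full_length"]


@dataclass
class FragmentResult:
    fixture: LatticeFixture
    params: PropagationParams
    trajectory: Trajectory
    lam_rows: np.ndarray
    profile: pd.DataFrame
    activation_energy: float
    transition_index: int
    dG_total: float
    wavelength: int | None
    curves: dict


def run_fragment(
    fixture: LatticeFixture,
    params: PropagationParams,
    energy_params: SolvationParams | None = None,
    n_frames: int = 100,
) -> FragmentResult:
    """Propagate one parameter set on a fragment and score its energetics."""
    energy_params = energy_params or SolvationParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = run_propagation(params, fixture.spec)
    idx = sample_rows(traj, n_frames)
    lam_rows = np.vstack([np.zeros(fixture.spec.n_layers), traj.lam_matrix[idx]])
    prof = profile_energies(
        lam_rows, fixture.spec, fixture.sheath_morph, fixture.tube_template, energy_params
    )
    e = prof["energy"].to_numpy()
    ea, ts = search.activation_energy(e)
    layer_cols = [c for c in prof.columns if c.startswith("E_layer_")]
    curves = extrapolate.extract_layer_curves(
        np.clip(lam_rows, 0.0, 1.0), prof[layer_cols].to_numpy()
    )
    return FragmentResult(
        fixture=fixture,
        params=params,
        trajectory=traj,
        lam_rows=lam_rows,
        profile=prof,
        activation_energy=float(ea),
        transition_index=int(ts),
        dG_total=float(e[-1]),
        wavelength=contraction_wavelength(traj),
        curves=curves,
    )


@dataclass
class FullLengthResult:
    fixture: LatticeFixture
    params: PropagationParams
    x_ratio: float
    trajectory: Trajectory
    profile: extrapolate.EnergyProfile
    feasible: bool
    activation_energy: float
    activation_sd: float
    dG_total: float
    wavelength: int | None
    force_profile: force.ForceProfile
    displacement: np.ndarray
    intersection_force: float | None
    cross_section_nm2: float
    pressure_atm: float
    transition: dict


def run_full_length(
    fragment: FragmentResult,
    full_config: SyntheticLatticeConfig | None = None,
    full_fixture: LatticeFixture | None = None,
    energy_params: SolvationParams | None = None,
    n_frames: int = 100,
    afm_spring_constant: float = 117.0,
    exclude_below_nm: float = 1.0,
) -> FullLengthResult:
    """Extrapolate a fragment pathway to the full-length machine.

    The coupling and drag constants are rescaled by the geodesic path
    ratio X (k2 by X^2, D by X), the full machine is propagated, screened
    against the mesh tolerance, and its energy profile assembled from the
    fragment's per-layer curves.  Force, spring-crossing, cross-section and
    pressure follow.
    """
    if full_fixture is None:
        if full_config is None:
            from dataclasses import replace

            full_config = replace(fragment.fixture.config, n_layers=28)
        full_fixture = make_lattice(full_config)
    if full_fixture.spec.n_layers < 12:
        raise InputError("full-length lattice must have >= 12 layers")
    x = path_ratio(fragment.fixture.spec, full_fixture.spec)
    params_full = extrapolate.rescale_params(fragment.params, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = run_propagation(params_full, full_fixture.spec)
    feas = extrapolate.feasibility_screen(traj)
    idx = sample_rows(traj, n_frames)
    lam_rows = np.vstack(
        [np.zeros(full_fixture.spec.n_layers), np.clip(traj.lam_matrix[idx], 0.0, 1.0)]
    )
    prof = extrapolate.full_length_profile(lam_rows, fragment.curves)
    ea, ts_idx = search.activation_energy(prof.energy)
    ea_sd = float(prof.sd[ts_idx])

    disp = force.tube_displacement(lam_rows, full_fixture.spec)
    fprof = force.force_from_profile(
        disp,
        prof.energy,
        exclude_below=exclude_below_nm,
        afm_spring_constant=afm_spring_constant,
    )
    z_final = float(disp[-1])
    f_cross = force.spring_branch_and_intersection(fprof, z_final)

    # tube cross section at the mid-height of the contracted machine
    from dmad.builder import build_intermediate

    model = build_intermediate(
        lam_rows[-1],
        full_fixture.spec,
        full_fixture.sheath_morph,
        full_fixture.tube_template,
    )
    z_mid = 0.5 * (full_fixture.spec.layers[0].z_ext + full_fixture.spec.layers[-1].z_cnt)
    # slab wide enough to always catch one bead tube ring (ring spacing = rise_ext)
    slab = max(2.0, full_fixture.config.rise_ext + 2.0)
    area = force.cross_section_area(model, z_plane=z_mid, slab=slab)
    peak_force = float(np.max(fprof.force))
    pressure = force.mean_pressure(peak_force, area) if area > 0 else float("nan")

    return FullLengthResult(
        fixture=full_fixture,
        params=params_full,
        x_ratio=x,
        trajectory=traj,
        profile=prof,
        feasible=bool(feas.passed),
        activation_energy=float(ea),
        activation_sd=ea_sd,
        dG_total=float(prof.energy[-1]),
        wavelength=contraction_wavelength(traj),
        force_profile=fprof,
        displacement=disp,
        intersection_force=f_cross,
        cross_section_nm2=float(area),
        pressure_atm=float(pressure),
        transition=extrapolate.transition_state_diagnostics(prof),
    )
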