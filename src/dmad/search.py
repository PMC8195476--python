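"""Grid search over the (k1, k2, D) parameter space.

The most probable contraction pathway is taken to be the one with the
lowest activation energy among pathways that keep the inter-subunit mesh
intact and have no substantial local minima (semi-contracted intermediates
are not observed experimentally, so a deep basin along the way disqualifies
a pathway).  The search is an exhaustive, deterministic grid scan — there
is no gradient-based optimisation over the couplings.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dmad.builder import AtomSet, MorphSeries
from dmad.energy import SolvationParams, profile_energies
from dmad.errors import DmadError, FitError, InputError
from dmad.geometry import LatticeSpec
from dmad.propagation import (
    PropagationParams,
    contraction_wavelength,
    integrity_check,
    run_propagation,
    sample_rows,
)

__all__ = [
    "SearchGrid",
    "activation_energy",
    "detect_local_minima",
    "grid_search",
    "fit_surface",
    "select_best",
    "DEFAULT_K1_GRID",
    "DEFAULT_K2_GRID",
    "DEFAULT_DRAG_GRID",
]

# defaults bracket the coupling regime of a pyocin-like machine
# (around k1 ~ 0.7, k2 ~ 2.5e-4 A^-2, D ~ 5e-4 A^-1)
DEFAULT_K1_GRID = (0.5, 0.625, 0.75, 0.875, 1.0)
DEFAULT_K2_GRID = (0.0, 1.0e-4, 2.5e-4, 5.0e-4, 1.0e-3)
DEFAULT_DRAG_GRID = (0.0, 2.5e-4, 5.0e-4, 1.0e-3)


@dataclass
class SearchGrid:
    """Results of a grid scan: one row per (k1, k2, drag) triple."""

    k1_values: tuple
    k2_values: tuple
    drag_values: tuple
    results: pd.DataFrame
    depth_threshold: float


def activation_energy(profile: np.ndarray) -> tuple[float, int]:
    """Barrier height above the extended reference and its profile index.

    The profile must start at the extended state (reference 0); for a
    monotonically decreasing (barrierless) profile this returns (0, 0).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise InputError("empty energy profile")
    rel = profile - profile[0]
    idx = int(np.argmax(rel))
    return float(max(0.0, rel[idx])), idx


def detect_local_minima(
    profile: np.ndarray, depth_threshold: float = 10.0
) -> list[tuple[int, float]]:
    """Interior minima with a substantial escape barrier.

    A point below both neighbours is a candidate; its depth is the climb to
    the highest downstream point (the barrier that must be crossed to
    continue contraction).  Minima with depth >= ``depth_threshold``
    (kcal/mol) are reported; monotone profiles give an empty list.
    """
    profile = np.asarray(profile, dtype=float)
    out = []
    for i in range(1, len(profile) - 1):
        if profile[i] < profile[i - 1] and profile[i] < profile[i + 1]:
            barrier = float(profile[i + 1 :].max())
            depth = barrier - float(profile[i])
            if depth >= depth_threshold:
                out.append((i, depth))
    return out


def grid_search(
    spec: LatticeSpec,
    sheath_morph: MorphSeries,
    tube_template: AtomSet | None,
    k1_values=DEFAULT_K1_GRID,
    k2_values=DEFAULT_K2_GRID,
    drag_values=DEFAULT_DRAG_GRID,
    energy_params: SolvationParams | None = None,
    base_params: PropagationParams | None = None,
    n_frames: int = 100,
    depth_threshold: float = 10.0,
    cache_dir: str | Path | None = None,
) -> SearchGrid:
    """Propagate and score one pathway per (k1, k2, drag) triple.

    Rows are produced in deterministic ``itertools.product`` order.  A
    pathway whose dynamics diverges is recorded with its error note rather
    than aborting the scan.  With ``cache_dir`` set, finished rows are
    stored as JSON keyed by the parameter triple and reused on resume.
    """
    if not (len(k1_values) and len(k2_values) and len(drag_values)):
        raise InputError("parameter grids must be nonempty")
    energy_params = energy_params or SolvationParams()
    base = base_params or PropagationParams()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for k1, k2, drag in itertools.product(k1_values, k2_values, drag_values):
        key = f"k1={k1!r}_k2={k2!r}_D={drag!r}"
        cfile = cache / f"{key}.json" if cache is not None else None
        if cfile is not None and cfile.exists():
            rows.append(json.loads(cfile.read_text()))
            continue
        row = {
            "k1": k1,
            "k2": k2,
            "drag": drag,
            "converged": False,
            "Ea": np.nan,
            "dG_total": np.nan,
            "Ea_fraction": np.nan,
            "wavelength": None,
            "integrity_pass": False,
            "has_local_minimum": None,
            "error": "",
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = PropagationParams(
                    k1=k1,
                    k2=k2,
                    drag=drag,
                    perturbation=base.perturbation,
                    v_max=base.v_max,
                    max_iterations=base.max_iterations,
                    completion_tolerance=base.completion_tolerance,
                )
                traj = run_propagation(params, spec)
                row["converged"] = bool(traj.converged)
                wl = contraction_wavelength(traj)
                row["wavelength"] = None if wl is None else int(wl)
                row["integrity_pass"] = bool(integrity_check(traj).passed)
                idx = sample_rows(traj, n_frames)
                lam_rows = np.vstack([np.zeros(spec.n_layers), traj.lam_matrix[idx]])
                prof = profile_energies(
                    lam_rows, spec, sheath_morph, tube_template, energy_params
                )
                e = prof["energy"].to_numpy()
                ea, _ = activation_energy(e)
                row["Ea"] = float(ea)
                row["dG_total"] = float(e[-1])
                row["Ea_fraction"] = float(ea / abs(e[-1])) if e[-1] != 0.0 else np.nan
                row["has_local_minimum"] = bool(
                    detect_local_minima(e, depth_threshold)
                )
        except (DmadError, FloatingPointError, OverflowError) as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        if cfile is not None:
            cfile.write_text(json.dumps(row))
        rows.append(row)
    results = pd.DataFrame(rows)
    return SearchGrid(
        k1_values=tuple(k1_values),
        k2_values=tuple(k2_values),
        drag_values=tuple(drag_values),
        results=results,
        depth_threshold=depth_threshold,
    )


def select_best(grid: SearchGrid) -> pd.Series:
    """Best pathway: minimum Ea among intact, minimum-free, converged rows.

    Ties are broken by smaller \\|k2\\| then smaller drag (deterministic).
    """
    df = grid.results
    ok = df[
        df["converged"]
        & df["integrity_pass"]
        & (df["has_local_minimum"] == False)  # noqa: E712 — None must not pass
        & np.isfinite(df["Ea"].astype(float))
    ]
    if ok.empty:
        raise InputError("no feasible pathway in the grid")
    ok = ok.sort_values(["Ea", "k2", "drag"], kind="mergesort")
    return ok.iloc[0]


def fit_surface(results: pd.DataFrame, degree: int = 3) -> dict:
    """Least-squares bivariate polynomial surface Ea/|dG| = f(k1, k2).

    ``results`` must hold a single drag value.  Returns the coefficient
    table (monomial exponents -> coefficient) plus residuals.  Exact for
    inputs generated from a polynomial of the same degree.
    """
    df = results.dropna(subset=["Ea_fraction"])
    n_coeff = (degree + 1) * (degree + 2) // 2
    if len(df) < n_coeff:
        raise FitError(
            f"need >= {n_coeff} points for a degree-{degree} bivariate surface"
        )
    k1 = df["k1"].to_numpy(float)
    k2 = df["k2"].to_numpy(float)
    y = df["Ea_fraction"].to_numpy(float)
    # scale k2 to O(1) for conditioning
    k2_scale = np.max(np.abs(k2)) or 1.0
    k2s = k2 / k2_scale
    monomials = [(a, b) for a in range(degree + 1) for b in range(degree + 1 - a)]
    A = np.stack([k1**a * k2s**b for a, b in monomials], axis=1)
    coeff, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < len(monomials):
        raise FitError("rank-deficient design matrix in surface fit")
    resid = y - A @ coeff
    return {
        "monomials": monomials,
        "coefficients": coeff,
        "k2_scale": k2_scale,
        "residual_norm": float(np.linalg.norm(resid)),
        "residuals": resid,
    }


def evaluate_surface(fit: dict, k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Evaluate a fitted surface at (k1, k2) points."""
    k1 = np.asarray(k1, dtype=float)
    k2s = np.asarray(k2, dtype=float) / fit["k2_scale"]
    out = np.zeros(np.broadcast(k1, k2s).shape)
    for (a, b), c in zip(fit["monomials"], fit["coefficients"]):
        out = out + c * k1**a * k2s**b
    return out
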