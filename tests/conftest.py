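"""Shared fixtures: toy lattices, bead assemblies, and a cached fragment run."""

import math
import warnings

import numpy as np
import pytest

from dmad.geometry import LatticeSpec, LayerEndStates
from dmad.pipeline import run_fragment
from dmad.propagation import PropagationParams
from dmad.synth import SyntheticLatticeConfig, make_lattice


def make_layer(
    layer_index=1,
    r_ext=100.0,
    r_cnt=120.0,
    theta0=0.0,
    theta_sweep=0.5,
    z_ext=40.0,
    z_cnt=20.0,
    axis_omega=0.0,
    axis_phi=0.0,
    kappa_cnt=1.0,
):
    """LayerEndStates helper that silences the radial-expansion advisory."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LayerEndStates(
            layer_index=layer_index,
            r_ext=r_ext,
            r_cnt=r_cnt,
            theta0=theta0,
            theta_sweep=theta_sweep,
            z_ext=z_ext,
            z_cnt=z_cnt,
            axis_omega=axis_omega,
            axis_phi=axis_phi,
            kappa_cnt=kappa_cnt,
        )


def toy_spec(n_layers=3, rise_ext=40.0, rise_cnt=20.0, r=100.0, sweep=0.0, **kw):
    """Cylindrical toy lattice: constant radius, pure axial contraction."""
    layers = [
        make_layer(
            layer_index=i + 1,
            r_ext=r,
            r_cnt=r,
            theta0=0.0,
            theta_sweep=sweep,
            z_ext=i * rise_ext,
            z_cnt=i * rise_cnt,
            kappa_cnt=0.0,
            **kw,
        )
        for i in range(n_layers)
    ]
    return LatticeSpec(layers=tuple(layers))


@pytest.fixture(scope="session")
def fixture12():
    """Default 12-layer synthetic lattice."""
    return make_lattice(SyntheticLatticeConfig(n_layers=12))


@pytest.fixture(scope="session")
def fixture28():
    return make_lattice(SyntheticLatticeConfig(n_layers=28))


@pytest.fixture(scope="session")
def fragment_result(fixture12):
    """A shared fragment run on a delayed pathway whose contraction wave is
    longer than the fragment (the regime the extrapolation machinery targets)."""
    return run_fragment(
        fixture12, PropagationParams(k1=0.875, k2=2.5e-4, drag=0.0), n_frames=30
    )


def scalar_reference_propagation(params, spec, n_iterations):
    """Plain-Python transcription of the layer-update rules (test oracle).

    Deliberately scalar and index-by-index, mirroring the documented update
    order: velocities from the previous iteration's fractions, stretches and
    displacements from the previous iteration, clamp at 1 from above.
    Returns the lam matrix for ``n_iterations`` iterations.
    """
    k1, k2, D = params.k1, params.k2, params.drag
    P, vmax = params.perturbation, params.v_max
    N = spec.n_layers
    lay = spec.layers
    off = spec.interstrand_azimuth_offset

    def cart(i, lam, extra=0.0):
        r = lay[i].r_ext + lam * (lay[i].r_cnt - lay[i].r_ext)
        th = lay[i].theta0 + lam * lay[i].theta_sweep + extra
        z = lay[i].z_ext + lam * (lay[i].z_cnt - lay[i].z_ext)
        return (r * math.cos(th), r * math.sin(th), z)

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    def b_of(lams):
        out = [float("nan")]
        for i in range(1, N):
            out.append(dist(cart(i, lams[i]), cart(i - 1, lams[i - 1], off)))
        return out

    b0 = b_of([0.0] * N)
    lam = [P * k1**i for i in range(N)]
    b = b_of(lam)
    s = [float("nan")] + [max(0.0, b[i] - b0[i]) for i in range(1, N)]
    d = [0.0] * N
    rows = [list(lam)]
    for _ in range(2, n_iterations + 1):
        v = [vmax * (lam[i] - lam[i] ** 2) for i in range(N)]
        new = [0.0] * N
        new[0] = min(
            1.0, lam[0] + (v[0] + k1 * v[1]) / (1 + k1) - k2 * s[1] ** 2 - D * d[0]
        )
        for i in range(1, N - 1):
            new[i] = min(
                1.0,
                lam[i]
                + (v[i] + k1 * v[i - 1] + k1 * v[i + 1]) / (1 + 2 * k1)
                + k2 * (s[i] ** 2 - s[i + 1] ** 2)
                - D * d[i],
            )
        new[N - 1] = min(
            1.0,
            lam[N - 1] + (v[N - 1] + k1 * v[N - 2]) / (1 + k1) + k2 * s[N - 1] ** 2 - D * d[N - 1],
        )
        d = [dist(cart(i, new[i]), cart(i, lam[i])) for i in range(N)]
        lam = new
        b = b_of(lam)
        s = [float("nan")] + [max(0.0, b[i] - b0[i]) for i in range(1, N)]
        rows.append(list(lam))
    return np.array(rows)
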