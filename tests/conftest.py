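"""Shared fixtures: solved oxygen fields on the standard synthetic networks.

All fixtures are session-scoped because the reference solves (and the
finite-difference oracle runs) dominate the suite's runtime; tests treat
them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from oxyfuse import (
    discretize,
    generate_parallel_array,
    generate_single_vessel,
    generate_tumor_like_network,
    solve_reference_field,
    tumor_params,
)
from oxyfuse.reference_solver import fd_oracle
from oxyfuse.vasculature import brain_network_preset
from oxyfuse.physiology import brain_params

KROGH_KWARGS = dict(length=120.0, radius=6.0, flow=8.0e5, inlet_sao2=0.95)
PARALLEL_KWARGS = dict(n_vessels=25, spacing=125.0, jitter=10.0, length=100.0,
                       inlet_sao2_range=(0.75, 0.95))
PARALLEL_SEED = 11
TUMOR_SEED = 3
BRAIN_SEED = 5


@pytest.fixture(scope="session")
def params():
    return tumor_params()


@pytest.fixture(scope="session")
def krogh_solved(params):
    """Single straight vessel centered in a 120 µm cube, solved."""
    net = generate_single_vessel(**KROGH_KWARGS)
    lattice, sources = discretize(net)
    solution = solve_reference_field(net, lattice, sources, params)
    return net, lattice, sources, solution


@pytest.fixture(scope="session")
def krogh_fd(krogh_solved, params):
    net, _lattice, sources, _sol = krogh_solved
    return fd_oracle(net, params, sources, spacing=3.0)


@pytest.fixture(scope="session")
def four_vessel_solved(params):
    """2x2 parallel array in a 240x240x120 µm box, solved."""
    net = generate_parallel_array(4, spacing=120.0, jitter=8.0, length=120.0, seed=7)
    lattice, sources = discretize(net)
    solution = solve_reference_field(net, lattice, sources, params)
    return net, lattice, sources, solution


@pytest.fixture(scope="session")
def four_vessel_fd(four_vessel_solved, params):
    net, _lattice, sources, _sol = four_vessel_solved
    return fd_oracle(net, params, sources, spacing=3.0)


@pytest.fixture(scope="session")
def parallel_solved(params):
    """5x5 vessel array at 125 µm spacing: the fusion-fidelity fixture."""
    net = generate_parallel_array(seed=PARALLEL_SEED, **PARALLEL_KWARGS)
    lattice, sources = discretize(net)
    solution = solve_reference_field(net, lattice, sources, params)
    return net, lattice, sources, solution


@pytest.fixture(scope="session")
def tumor_solved(params):
    """Tortuous tumor-like bed in the 990x810x150 µm window-chamber domain."""
    net = generate_tumor_like_network(seed=TUMOR_SEED)
    lattice, sources = discretize(net)
    solution = solve_reference_field(net, lattice, sources, params)
    return net, lattice, sources, solution


@pytest.fixture(scope="session")
def brain_solved():
    """Dense normal-tissue bed in the 150x160x140 µm brain domain."""
    p = brain_params()
    net = brain_network_preset(seed=BRAIN_SEED)
    lattice, sources = discretize(net)
    solution = solve_reference_field(net, lattice, sources, p)
    return net, lattice, sources, solution, p


def interior_rms(net, lattice, fd_lattice, margin: float = 10.0,
                 vessel_margin: float = 15.0) -> float:
    """RMS difference between the lattice field and the FD field, evaluated
    at lattice points at least ``vessel_margin`` from every vessel axis and
    ``margin`` from the domain boundary."""
    pts = lattice.points()
    d_axis = np.full(len(pts), np.inf)
    for seg in net.segments:
        a, b = net.segment_endpoints(seg)
        u = (b - a) / np.linalg.norm(b - a)
        rel = pts - a
        t = np.clip(rel @ u, 0.0, np.linalg.norm(b - a))
        d = np.linalg.norm(rel - t[:, None] * u, axis=1)
        d_axis = np.minimum(d_axis, d)
    lo, hi = net.domain_box
    d_bnd = np.minimum((pts - lo).min(axis=1), (hi - pts).min(axis=1))
    sel = (d_axis >= vessel_margin) & (d_bnd >= margin)
    fd_at = map_coordinates(fd_lattice.lpo2, fd_lattice.fractional_index(pts).T,
                            order=1, mode="nearest")
    diff = lattice.lpo2.ravel()[sel] - fd_at[sel]
    return float(np.sqrt(np.mean(diff**2)))
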