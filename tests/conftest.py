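"""Shared ground-truth fixtures.

Everything is generated at run time by the Brownian-dynamics simulator with
fixed seeds, so expensive trajectory sets are session-scoped and reused by
the unit, property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import permeakit as pk
from permeakit.milestoning import CellPartition, CellSampling
from permeakit.pmf import DiffusionProfile, PMFProfile, UmbrellaWindow

KT300 = 0.5961612775922495  # kcal/mol at 300 K (k_B in kcal/mol/K times 300)


@pytest.fixture(scope="session")
def barrier():
    """The canonical symmetric channel barrier: 4 kcal/mol, sigma 2.5 Å."""
    return pk.GaussianBarrier(4.0, 0.0, 2.5)


@pytest.fixture(scope="session")
def barrier_profiles(barrier):
    """Analytic PMF/D profiles of the canonical barrier on a fine grid."""
    zg = np.linspace(-12.0, 12.0, 4801)
    pmf = PMFProfile(zg, barrier.energy(zg), bulk_region=(-12.0, -11.0))
    d = DiffusionProfile(zg, np.full_like(zg, 0.02))
    return pmf, d


@pytest.fixture(scope="session")
def umbrella_windows(barrier):
    """13 umbrella windows (k=2.5, 2 Å spacing, 40 ns each) over the barrier."""
    windows = []
    for i, c in enumerate(np.arange(-12.0, 12.1, 2.0)):
        cfg = pk.SimConfig(dt=0.01, n_steps=4_000_000, seed=100 + i,
                           output_stride=50, initial_z=float(c), domain=(-16.0, 16.0))
        ts = pk.simulate(barrier, pk.ConstantDiffusion(0.02),
                         [pk.HarmonicBias(2.5, float(c))], cfg)
        windows.append(UmbrellaWindow(float(c), 2.5, ts))
    return windows


@pytest.fixture(scope="session")
def ou_windows():
    """Pure harmonic (OU) windows at 5 centers: flat w, D=0.02, k=2.5.

    200 ns each, so the window-estimator statistics (relative s.e. of τ
    about √(4τ/T) ≈ 1.5%) sit well inside the recovery tolerances.
    """
    windows = []
    for i, c in enumerate((-8.0, -4.0, 0.0, 4.0, 8.0)):
        cfg = pk.SimConfig(dt=0.01, n_steps=20_000_000, seed=500 + i,
                           output_stride=50, initial_z=c, domain=(c - 8.0, c + 8.0))
        ts = pk.simulate(pk.FlatPotential(), pk.ConstantDiffusion(0.02),
                         [pk.HarmonicBias(2.5, c)], cfg)
        windows.append(UmbrellaWindow(c, 2.5, ts))
    return windows


def make_cell_samplings(potential, partition: CellPartition, n_steps: int,
                        output_stride: int, seed0: int, k_wall: float = 10.0,
                        D: float = 0.02) -> list[CellSampling]:
    """Soft-wall confined trajectories, one per Voronoi cell."""
    edges = np.asarray(partition.edges)
    out = []
    for c in range(partition.n_cells):
        lo, hi = float(edges[c]), float(edges[c + 1])
        cfg = pk.SimConfig(dt=0.01, n_steps=n_steps, seed=seed0 + c,
                           output_stride=output_stride,
                           initial_z=0.5 * (lo + hi), domain=(lo - 2.0, hi + 2.0))
        ts = pk.simulate(potential, pk.ConstantDiffusion(D),
                         [pk.FlatBottomBias(k_wall, lo, hi)], cfg)
        out.append(CellSampling(c, ts))
    return out


@pytest.fixture(scope="session")
def milestoning_partition():
    """12 cells of 2 Å spanning the canonical barrier domain [-12, 12]."""
    return CellPartition(tuple(np.arange(-12.0, 12.1, 2.0)))


@pytest.fixture(scope="session")
def milestoning_samplings(barrier, milestoning_partition):
    """400 ns per cell at 0.2 ps recording stride (soft walls k=10)."""
    return make_cell_samplings(barrier, milestoning_partition,
                               n_steps=40_000_000, output_stride=20, seed0=400)


FIELD_BOX = (-15.0, 15.0)   # periodic box for voltage runs, Å
FIELD_D = 0.1               # Å²/ps


@pytest.fixture(scope="session")
def voltage_runs():
    """Steady-state constant-field runs of one ion at four voltages."""
    runs = {}
    for i, V in enumerate((-0.3, -0.15, 0.15, 0.3)):
        cfg = pk.SimConfig(dt=0.01, n_steps=15_000_000, seed=50 + i,
                           output_stride=50, domain=FIELD_BOX)
        runs[V] = pk.simulate_field(pk.FlatPotential(),
                                    pk.ConstantDiffusion(FIELD_D), 1.0, V, cfg)
    return runs


@pytest.fixture(scope="session")
def stride_samplings(barrier, milestoning_partition):
    """200 ns per cell at 0.1 ps stride with stiff (k=100) soft walls.

    This set mirrors the hard-confinement protocol whose recording-stride
    bias the sensitivity scan characterises.
    """
    return make_cell_samplings(barrier, milestoning_partition,
                               n_steps=20_000_000, output_stride=10, seed0=700,
                               k_wall=100.0)
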