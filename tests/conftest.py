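"""Shared fixtures: the standard desk-scale implant cross-section and
closed-form oracle helpers (Terzaghi series, semi-infinite diffusion)."""

from __future__ import annotations

import numpy as np
import pytest

from osseoheal import (
    GeometryConfig,
    LoadSpec,
    TissueLibrary,
    make_bone_implant_model,
    make_bone_tooth_model,
    make_patch_bar,
)
from osseoheal.mechanics import FLUID_BULK_MODULUS


@pytest.fixture(scope="session")
def toy_cfg() -> GeometryConfig:
    """Standard desk-scale cross-section (~1800 elements)."""
    return GeometryConfig(mesh_size=0.5, refinement_factor=2.0)


@pytest.fixture(scope="session")
def _toy_models(toy_cfg):
    lib = TissueLibrary()
    return make_bone_implant_model(toy_cfg, lib), make_bone_tooth_model(toy_cfg, lib)


@pytest.fixture()
def toy_implant_model(_toy_models):
    return _toy_models[0].copy()


@pytest.fixture()
def toy_tooth_model(_toy_models):
    return _toy_models[1].copy()


@pytest.fixture()
def default_load() -> LoadSpec:
    return LoadSpec()


def terzaghi_pressure_ratio(z_over_h: float, tv: float, terms: int = 500) -> float:
    """Closed-form excess pore pressure ratio p/p0 at depth fraction Z, time Tv."""
    m = np.arange(terms)
    mm = np.pi * (2 * m + 1) / 2
    return float(np.sum(2 / mm * np.sin(mm * z_over_h) * np.exp(-mm * mm * tv)))


def consolidation_coefficient(e_gpa: float, nu: float, k: float, porosity: float) -> float:
    """cv in m^2/s including fluid-compressibility storage."""
    e_pa = e_gpa * 1e9
    m_c = e_pa * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    s0 = porosity / FLUID_BULK_MODULUS
    return k / (s0 + 1.0 / m_c)


def run_terzaghi(n_elements: int, tv_values, n_steps: int = 60):
    """Numerical vs analytic mid-depth pressure ratios on the column fixture.

    Returns a list of (numeric, analytic) pairs, one per Tv.
    """
    from osseoheal import make_consolidation_column
    from osseoheal.mechanics import solve_poroelastic_step

    e_gpa, nu, k, por, height = 0.001, 0.17, 1e-14, 0.8, 0.01
    col = make_consolidation_column(n_elements, height, e_gpa, nu, k, por)
    cv = consolidation_coefficient(e_gpa, nu, k, por)
    load = lambda dt: LoadSpec(mode="force", magnitude=10.0, angle_deg=0.0, load_duration=dt)
    # initial (undrained) pressure from a nearly instantaneous step
    f0 = solve_poroelastic_step(col, load(1e-6))
    y = col.nodes[:, 1] * 1e-3
    p0 = float(np.median(f0.nodal_pressure[y < 0.9 * height]))
    out = []
    for tv in tv_values:
        t_end = tv * height**2 / cv
        dt = t_end / n_steps
        fld = None
        for _ in range(n_steps):
            fld = solve_poroelastic_step(col, load(dt), initial=fld)
        mid = int(np.argmin(np.abs(y - height / 2)))
        z = (height - y[mid]) / height
        out.append((fld.nodal_pressure[mid] / p0, terzaghi_pressure_ratio(z, tv)))
    return out


def constant_stimulus_bar():
    """Short callus bar under displacement control whose S_TD sits in the
    mature-bone band all 70 days.

    One element across the loading direction keeps the axial strain exactly
    load-controlled (Delta/L) however stiff the tissue becomes, and the
    x-uniform state produces no fluid flow; cells enter from the left edge.
    """
    length = 0.4  # mm: cells saturate the bar well within the healing period
    bar = make_patch_bar(
        length=length, height=0.2, nx=1, ny=4,
        young_modulus=0.001, poisson_ratio=0.17, permeability=1e-14, as_callus=True,
    )
    # strain 3e-3 -> S_TD ~ 0.13..0.17, inside (0.010, 0.266]
    delta_um = 3e-3 * length * 1e3  # 1.2 um
    load = LoadSpec(magnitude=delta_um, direction=(1, 0), load_duration=1e5)
    return bar, load
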