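"""Shared fixtures: tiny Monte Carlo populations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from qboldsim.experiments import FidelityTier, build_archive
from qboldsim.monte_carlo import (
    PhaseArchive,
    WalkConfig,
    accrue_phase,
    run_population,
)
from qboldsim.parameters import default_params
from qboldsim.vessel_geometry import build_vessel_system, choose_sphere_radius

# deliberately tiny: fast regression-scale populations, not study conditions
TEST_TIER = FidelityTier(
    n_protons_total=600, n_protons_keep=400, n_vessels_target=250, duration=80.0
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def small_archive(params) -> PhaseArchive:
    """Mid-radius (22.5 um) population where diffusion effects are strong."""
    physics, blood, _ = params
    return build_archive(22.5, 0.03, physics, blood, seed=42, tier=TEST_TIER)


@pytest.fixture(scope="session")
def small_rc5_archive(params) -> PhaseArchive:
    """Small-radius (5 um) population, deep in the diffusion-narrowed regime."""
    physics, blood, _ = params
    tier = FidelityTier(
        n_protons_total=700, n_protons_keep=300, n_vessels_target=250, duration=80.0
    )
    return build_archive(5.0, 0.03, physics, blood, seed=42, tier=tier)


@pytest.fixture(scope="session")
def static_archive(params) -> PhaseArchive:
    """Population of perfectly static protons (pure static dephasing).

    Built by hand (zero-diffusion walks at the sphere centre) so that the
    static-regime identities hold exactly.
    """
    physics, blood, _ = params
    cfg = WalkConfig(duration=80.0, n_protons_total=200, n_protons_keep=150)
    from qboldsim.monte_carlo import PhaseBasis

    basis = PhaseBasis(
        Y=blood.Y,
        Hct=blood.Hct,
        delta_chi=physics.delta_chi,
        B0=physics.B0,
        gamma=physics.gamma,
    )
    Rs = choose_sphere_radius(200.0, 0.03, 250, seed=0)
    walk = np.zeros((cfg.n_fine + 1, 3))
    rng = np.random.default_rng(2024)
    rows = []
    n_discarded = 0
    n_simulated = 0
    while len(rows) < cfg.n_protons_keep:
        system = build_vessel_system(200.0, 0.03, Rs, seed=rng)
        n_simulated += 1
        try:
            rows.append(accrue_phase(walk, system, basis, cfg))
        except RuntimeError:
            n_discarded += 1
    return PhaseArchive(
        increments=np.array(rows),
        basis=basis,
        cfg=cfg,
        Rc=200.0,
        Vf=0.03,
        Rs=Rs,
        D=0.0,
        seed=2024,
        n_discarded=n_discarded,
        n_simulated=n_simulated,
    )
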