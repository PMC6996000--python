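"""Deterministic small-scale fixtures for fast, exact testing.

Single-cylinder configurations with a closed-form field offset, ideal SDR
decay curves for fit-recovery checks, and static-proton populations.
Everything is generated in code from explicit parameters; nothing is read
from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qboldsim.monte_carlo import PhaseBasis, phase_prefactor
from qboldsim.qbold_fit import sdr_signal
from qboldsim.signal_synthesis import SequenceProtocol, SignalCurve
from qboldsim.vessel_geometry import VesselSystem

__all__ = [
    "SingleCylinderFixture",
    "single_cylinder_fixture",
    "ideal_sdr_curve",
]


@dataclass(frozen=True)
class SingleCylinderFixture:
    """One cylinder through the origin plus a static proton.

    ``kernel`` is the closed-form geometric field factor
    (Rc/r)^2 cos(2 phi) sin^2(theta) at the proton position, so the
    instantaneous frequency offset is ``phase_prefactor(basis) * kernel``
    in rad/ms.
    """

    system: VesselSystem
    point: np.ndarray
    Rc: float
    r: float
    theta: float
    phi: float
    kernel: float

    def offset(self, basis: PhaseBasis) -> float:
        """Instantaneous frequency offset (rad/ms) at the proton."""
        return phase_prefactor(basis) * self.kernel

    def static_walk(self, n_fine: int) -> np.ndarray:
        """A zero-diffusion walk pinned at the proton position."""
        return np.tile(self.point, (n_fine + 1, 1))


def single_cylinder_fixture(
    Rc: float,
    r: float,
    theta: float,
    phi: float,
    sphere_radius: float = 1e6,
) -> SingleCylinderFixture:
    """Cylinder at angle ``theta`` to B0 (z) with a proton at (r, phi).

    The proton sits in the plane through the origin orthogonal to the
    cylinder axis, at perpendicular distance ``r`` and angle ``phi`` from
    the projection of B0 onto that plane. Requires r >= Rc (the field
    expression only holds outside the vessel).
    """
    if r < Rc:
        raise ValueError("proton must lie outside the vessel (r >= Rc)")
    axis = np.array([np.sin(theta), 0.0, np.cos(theta)])
    if abs(np.sin(theta)) < 1e-12:
        # axis parallel to B0: phi is conventionally 0, offset vanishes
        u1 = np.array([1.0, 0.0, 0.0])
        u2 = np.array([0.0, 1.0, 0.0])
    else:
        u1 = np.array([-np.cos(theta), 0.0, np.sin(theta)])
        u2 = np.cross(axis, u1)
    point = r * (np.cos(phi) * u1 + np.sin(phi) * u2)
    kernel = (Rc / r) ** 2 * np.cos(2.0 * phi) * np.sin(theta) ** 2
    chord = 2.0 * sphere_radius
    system = VesselSystem(
        origins=np.zeros((1, 3)),
        axes=axis[None, :],
        radius=Rc,
        sphere_radius=sphere_radius,
        target_vf=0.0,
        achieved_vf=(np.pi * Rc**2 * chord) / (4.0 / 3.0 * np.pi * sphere_radius**3),
        seed=None,
        chords=np.array([chord]),
    )
    return SingleCylinderFixture(
        system=system,
        point=point,
        Rc=Rc,
        r=r,
        theta=theta,
        phi=phi,
        kernel=float(kernel),
    )


def ideal_sdr_curve(
    R2p: float,
    V0: float,
    S0: float,
    R2: float,
    protocol: SequenceProtocol,
) -> SignalCurve:
    """Exact SDR decay curve for a protocol (oracle for fit recovery)."""
    taus = np.asarray(protocol.tau_values)
    echo_times = np.array([protocol.echo_time(t) for t in taus])
    mags = np.array(
        [
            sdr_signal(t, tE, S0, R2, R2p, V0)
            for t, tE in zip(taus, echo_times)
        ]
    )
    return SignalCurve(
        tau_values=taus,
        magnitudes=mags,
        compartment="total",
        t2_applied=True,
        echo_times=echo_times,
        provenance={"model": "sdr", "R2p": R2p, "V0": V0, "S0": S0, "R2": R2},
    )
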