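"""Numba inner loops for phase accrual and vessel-entry detection.

The magnetic field offset outside an infinite cylinder perturber is
proportional to (Rc/r)^2 * sin^2(theta) * cos(2*phi). With the main field
along z and a unit cylinder axis ``a`` this equals
``Rc^2 * (2*t^2 - sin^2(theta) * r^2) / r^4`` where ``d`` is the vector
from a point on the axis to the proton, ``proj = d.a``,
``r^2 = |d|^2 - proj^2`` and ``t = d_z - a_z * proj`` (the component of
the perpendicular offset along the projection of z onto the transverse
plane). The kernels below accumulate this purely geometric factor times
the step duration; the physical prefactor 2*pi*gamma*B0*(1-Y)*Hct*dchi
is applied by the caller.
"""

from __future__ import annotations

import numba
import numpy as np

ENTERED = 1
CLEAN = 0


@numba.njit(fastmath=True, nogil=True)
def accrue_geometry_phase(
    fine_pos: np.ndarray,
    origins: np.ndarray,
    axes: np.ndarray,
    az: np.ndarray,
    sin2: np.ndarray,
    Rc: float,
    thresh: float,
    nsub: int,
    dt_fine: float,
    coarse_per_bin: int,
    out: np.ndarray,
) -> int:
    """Accumulate per-storage-bin geometric phase increments along a walk.

    The field is evaluated at the position ending each coarse interval
    (``nsub`` fine steps). A coarse step is re-evaluated on the fine grid
    whenever either of its bounding coarse positions lies within the
    proximity region ``Rc^2 / r^2 > thresh`` of any vessel; the coarse
    contribution is then replaced by the sum over its fine sub-steps.
    Returns ENTERED as soon as any checked position lies inside a vessel
    (r < Rc), CLEAN otherwise. ``out`` must be zero-initialised with
    length (number of coarse steps) / coarse_per_bin.
    """
    N = origins.shape[0]
    F = fine_pos.shape[0] - 1
    C = F // nsub
    Rc2 = Rc * Rc
    dt_coarse = dt_fine * nsub

    px = fine_pos[0, 0]
    py = fine_pos[0, 1]
    pz = fine_pos[0, 2]
    prev_flag = False
    for i in range(N):
        dx = px - origins[i, 0]
        dy = py - origins[i, 1]
        dz = pz - origins[i, 2]
        proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
        r2 = dx * dx + dy * dy + dz * dz - proj * proj
        if r2 < Rc2:
            return ENTERED
        if Rc2 > thresh * r2:
            prev_flag = True

    for c in range(1, C + 1):
        idx = c * nsub
        px = fine_pos[idx, 0]
        py = fine_pos[idx, 1]
        pz = fine_pos[idx, 2]
        flag = False
        om = 0.0
        for i in range(N):
            dx = px - origins[i, 0]
            dy = py - origins[i, 1]
            dz = pz - origins[i, 2]
            proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
            r2 = dx * dx + dy * dy + dz * dz - proj * proj
            if r2 < Rc2:
                return ENTERED
            if Rc2 > thresh * r2:
                flag = True
            t = dz - az[i] * proj
            om += Rc2 * (2.0 * t * t - sin2[i] * r2) / (r2 * r2)

        if flag or prev_flag:
            contrib = 0.0
            base = (c - 1) * nsub
            for s in range(1, nsub + 1):
                qx = fine_pos[base + s, 0]
                qy = fine_pos[base + s, 1]
                qz = fine_pos[base + s, 2]
                omf = 0.0
                for i in range(N):
                    dx = qx - origins[i, 0]
                    dy = qy - origins[i, 1]
                    dz = qz - origins[i, 2]
                    proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
                    r2 = dx * dx + dy * dy + dz * dz - proj * proj
                    if r2 < Rc2:
                        return ENTERED
                    t = dz - az[i] * proj
                    omf += Rc2 * (2.0 * t * t - sin2[i] * r2) / (r2 * r2)
                contrib += omf * dt_fine
        else:
            contrib = om * dt_coarse

        out[(c - 1) // coarse_per_bin] += contrib
        prev_flag = flag

    return CLEAN


@numba.njit(fastmath=True, nogil=True)
def walk_enters_vessel(
    fine_pos: np.ndarray,
    origins: np.ndarray,
    axes: np.ndarray,
    Rc: float,
    thresh: float,
    nsub: int,
) -> int:
    """Entry-only variant: coarse positions always, fine near vessels."""
    N = origins.shape[0]
    F = fine_pos.shape[0] - 1
    C = F // nsub
    Rc2 = Rc * Rc

    px = fine_pos[0, 0]
    py = fine_pos[0, 1]
    pz = fine_pos[0, 2]
    prev_flag = False
    for i in range(N):
        dx = px - origins[i, 0]
        dy = py - origins[i, 1]
        dz = pz - origins[i, 2]
        proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
        r2 = dx * dx + dy * dy + dz * dz - proj * proj
        if r2 < Rc2:
            return ENTERED
        if Rc2 > thresh * r2:
            prev_flag = True

    for c in range(1, C + 1):
        idx = c * nsub
        px = fine_pos[idx, 0]
        py = fine_pos[idx, 1]
        pz = fine_pos[idx, 2]
        flag = False
        for i in range(N):
            dx = px - origins[i, 0]
            dy = py - origins[i, 1]
            dz = pz - origins[i, 2]
            proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
            r2 = dx * dx + dy * dy + dz * dz - proj * proj
            if r2 < Rc2:
                return ENTERED
            if Rc2 > thresh * r2:
                flag = True
        if flag or prev_flag:
            base = (c - 1) * nsub
            for s in range(1, nsub):
                qx = fine_pos[base + s, 0]
                qy = fine_pos[base + s, 1]
                qz = fine_pos[base + s, 2]
                for i in range(N):
                    dx = qx - origins[i, 0]
                    dy = qy - origins[i, 1]
                    dz = qz - origins[i, 2]
                    proj = dx * axes[i, 0] + dy * axes[i, 1] + dz * axes[i, 2]
                    r2 = dx * dx + dy * dy + dz * dz - proj * proj
                    if r2 < Rc2:
                        return ENTERED
        prev_flag = flag

    return CLEAN
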