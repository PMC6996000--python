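"""Proton random walks, vessel-entry handling and phase accrual.

Each simulated proton gets a fresh vessel system, performs a Gaussian
random walk from the centre of the system, and accrues phase from the
susceptibility field of all vessels. Phase increments are stored on a
coarse (default 2 ms) grid at a nominal oxygenation basis; because the
phase is linear in (1 - Y), the stored archive can later be re-scaled to
any target oxygenation without re-simulation.

Walks that carry the proton inside a vessel are discarded (non-permeable
vessels); the population keeps the first ``n_protons_keep`` clean protons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import h5py
import numpy as np

from qboldsim import _kernels
from qboldsim.parameters import BloodTissueParams, PhysicsParams
from qboldsim.vessel_geometry import (
    VesselSystem,
    build_vessel_system,
    choose_sphere_radius,
)

__all__ = [
    "WalkConfig",
    "PhaseBasis",
    "PhaseArchive",
    "simulate_walk",
    "detect_entry",
    "accrue_phase",
    "run_population",
    "entry_fraction",
    "phase_prefactor",
]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and storage discretisation (all times in ms).

    ``dt_fine`` (20 us) is the native step of the walk; the field is
    evaluated every ``dt_coarse`` (200 us) except close to vessels
    (``Rc^2/r^2 > proximity_threshold``) where the fine grid is used.
    Phase is stored in ``dt_store`` (2 ms) bins over ``duration``.
    """

    dt_fine: float = 0.02
    dt_coarse: float = 0.2
    dt_store: float = 2.0
    duration: float = 120.0
    proximity_threshold: float = 0.04
    n_protons_total: int = 10000
    n_protons_keep: int = 5000

    def __post_init__(self) -> None:
        for num, den, what in (
            (self.dt_coarse, self.dt_fine, "dt_fine must divide dt_coarse"),
            (self.dt_store, self.dt_coarse, "dt_coarse must divide dt_store"),
            (self.duration, self.dt_store, "dt_store must divide duration"),
        ):
            ratio = num / den
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValueError(what)
        if self.n_protons_keep > self.n_protons_total:
            raise ValueError("n_protons_keep must not exceed n_protons_total")
        if self.proximity_threshold <= 0:
            raise ValueError("proximity_threshold must be positive")

    @property
    def n_sub(self) -> int:
        """Fine steps per coarse step."""
        return round(self.dt_coarse / self.dt_fine)

    @property
    def coarse_per_bin(self) -> int:
        return round(self.dt_store / self.dt_coarse)

    @property
    def n_coarse(self) -> int:
        return round(self.duration / self.dt_coarse)

    @property
    def n_fine(self) -> int:
        return round(self.duration / self.dt_fine)

    @property
    def n_intervals(self) -> int:
        """Number of phase storage bins."""
        return round(self.duration / self.dt_store)


@dataclass(frozen=True)
class PhaseBasis:
    """Nominal physical basis at which archive increments were accrued."""

    Y: float
    Hct: float
    delta_chi: float
    B0: float
    gamma: float


def phase_prefactor(basis: PhaseBasis) -> float:
    """Physical phase scale 2*pi*gamma*B0*(1-Y)*Hct*dchi in rad/ms.

    Multiplying the geometric field kernel (dimensionless) by this factor
    and by the step duration in ms gives the phase increment in radians.
    """
    per_second = (
        2.0 * np.pi * basis.gamma * basis.B0 * (1.0 - basis.Y) * basis.Hct * basis.delta_chi
    )
    return per_second * 1e-3


@dataclass
class PhaseArchive:
    """Per-proton phase increments on the storage grid at a nominal basis.

    ``increments`` has shape (n_protons_kept, n_intervals) in radians.
    The archive is oxygenation-agnostic up to the exact linear rescaling
    by (1 - Y_target)/(1 - Y_nominal), and its ensemble magnitude can be
    rescaled to other volume fractions through the log-signal identity.
    """

    increments: np.ndarray
    basis: PhaseBasis
    cfg: WalkConfig
    Rc: float
    Vf: float
    Rs: float
    D: float
    seed: int
    n_discarded: int
    n_simulated: int

    @property
    def n_protons(self) -> int:
        return self.increments.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.increments.shape[1]

    @property
    def entry_fraction(self) -> float:
        """Fraction of simulated walks that entered a vessel."""
        return self.n_discarded / self.n_simulated

    def save(self, path: str | Path) -> None:
        """Persist to HDF5 (bit-exact round trip)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("increments", data=self.increments)
            meta = f.create_group("meta")
            for key, value in asdict(self.basis).items():
                meta.attrs[f"basis_{key}"] = value
            for key, value in asdict(self.cfg).items():
                meta.attrs[f"cfg_{key}"] = value
            for key in ("Rc", "Vf", "Rs", "D", "seed", "n_discarded", "n_simulated"):
                meta.attrs[key] = getattr(self, key)

    @classmethod
    def load(cls, path: str | Path) -> "PhaseArchive":
        with h5py.File(path, "r") as f:
            increments = f["increments"][...]
            attrs = dict(f["meta"].attrs)
        basis = PhaseBasis(**{k[6:]: float(attrs[k]) for k in attrs if k.startswith("basis_")})
        cfg_fields = {k[4:]: attrs[k] for k in attrs if k.startswith("cfg_")}
        cfg = WalkConfig(
            dt_fine=float(cfg_fields["dt_fine"]),
            dt_coarse=float(cfg_fields["dt_coarse"]),
            dt_store=float(cfg_fields["dt_store"]),
            duration=float(cfg_fields["duration"]),
            proximity_threshold=float(cfg_fields["proximity_threshold"]),
            n_protons_total=int(cfg_fields["n_protons_total"]),
            n_protons_keep=int(cfg_fields["n_protons_keep"]),
        )
        return cls(
            increments=increments,
            basis=basis,
            cfg=cfg,
            Rc=float(attrs["Rc"]),
            Vf=float(attrs["Vf"]),
            Rs=float(attrs["Rs"]),
            D=float(attrs["D"]),
            seed=int(attrs["seed"]),
            n_discarded=int(attrs["n_discarded"]),
            n_simulated=int(attrs["n_simulated"]),
        )


def simulate_walk(
    cfg: WalkConfig, D: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian random walk from the origin at fine resolution.

    Returns positions of shape (n_fine + 1, 3) in um, starting at the
    origin, with independent per-axis steps ~ Normal(0, sqrt(2*D*dt_fine)).
    ``D = 0`` yields a static proton.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    n = cfg.n_fine
    pos = np.empty((n + 1, 3))
    pos[0] = 0.0
    if D == 0.0:
        pos[1:] = 0.0
        return pos
    sigma = np.sqrt(2.0 * D * cfg.dt_fine)
    np.cumsum(rng.standard_normal((n, 3)) * sigma, axis=0, out=pos[1:])
    return pos


def _system_arrays(system: VesselSystem) -> tuple[np.ndarray, ...]:
    origins = np.ascontiguousarray(system.origins)
    axes = np.ascontiguousarray(system.axes)
    az = axes[:, 2].copy()
    sin2 = 1.0 - az**2
    return origins, axes, az, sin2


def detect_entry(
    walk: np.ndarray, system: VesselSystem, cfg: WalkConfig | None = None
) -> bool:
    """True iff the walk passes inside any vessel.

    Positions are checked on the coarse grid everywhere and on the fine
    grid for proximity-flagged segments, mirroring the phase-accrual
    refinement rule.
    """
    cfg = cfg or WalkConfig()
    origins, axes, _, _ = _system_arrays(system)
    status = _kernels.walk_enters_vessel(
        np.ascontiguousarray(walk),
        origins,
        axes,
        system.radius,
        cfg.proximity_threshold,
        cfg.n_sub,
    )
    return status == _kernels.ENTERED


def accrue_phase(
    walk: np.ndarray,
    system: VesselSystem,
    basis: PhaseBasis,
    cfg: WalkConfig,
) -> np.ndarray:
    """Phase increments (rad) per storage interval for one clean walk.

    The frequency offset sums the cylinder field kernel over all vessels,
    evaluated at coarse-interval end positions, with fine-grid
    re-evaluation of proximity-flagged steps. Raises if the walk enters a
    vessel (such walks must be discarded, not phased).
    """
    n_bins = round((walk.shape[0] - 1) * cfg.dt_fine / cfg.dt_store)
    out = np.zeros(n_bins)
    origins, axes, az, sin2 = _system_arrays(system)
    status = _kernels.accrue_geometry_phase(
        np.ascontiguousarray(walk),
        origins,
        axes,
        az,
        sin2,
        system.radius,
        cfg.proximity_threshold,
        cfg.n_sub,
        cfg.dt_fine,
        cfg.coarse_per_bin,
        out,
    )
    if status == _kernels.ENTERED:
        raise RuntimeError(
            "walk passes inside a vessel; it must be flagged and discarded"
        )
    return out * phase_prefactor(basis)


def run_population(
    Rc: float,
    Vf: float,
    cfg: WalkConfig,
    physics: PhysicsParams,
    blood: BloodTissueParams,
    seed: int,
    *,
    n_vessels_target: int = 1300,
    sphere_radius: float | None = None,
    require_full: bool = True,
) -> PhaseArchive:
    """Simulate a proton population and archive its phase increments.

    A fresh vessel system is generated for every proton. Protons are
    simulated (up to ``cfg.n_protons_total``) until ``cfg.n_protons_keep``
    clean walks have been kept; walks entering a vessel are discarded and
    counted. The archive stores increments at the nominal basis
    (``blood.Y``, ``blood.Hct``, physics constants).

    With ``require_full=False`` the population may end with fewer kept
    protons than requested (useful for entry-fraction studies); otherwise
    exhausting the proton budget raises.
    """
    master = np.random.SeedSequence(seed)
    calib_ss, protons_ss = master.spawn(2)
    if sphere_radius is None:
        sphere_radius = choose_sphere_radius(
            Rc, Vf, n_vessels_target, seed=np.random.default_rng(calib_ss)
        )

    basis = PhaseBasis(
        Y=blood.Y,
        Hct=blood.Hct,
        delta_chi=physics.delta_chi,
        B0=physics.B0,
        gamma=physics.gamma,
    )
    pref = phase_prefactor(basis)
    n_bins = cfg.n_intervals
    kept = np.empty((cfg.n_protons_keep, n_bins))
    n_kept = 0
    n_discarded = 0
    n_simulated = 0
    children = protons_ss.spawn(cfg.n_protons_total)
    for child in children:
        if n_kept >= cfg.n_protons_keep:
            break
        rng = np.random.default_rng(child)
        system = build_vessel_system(Rc, Vf, sphere_radius, seed=rng)
        walk = simulate_walk(cfg, blood.D, rng)
        origins, axes, az, sin2 = _system_arrays(system)
        out = np.zeros(n_bins)
        status = _kernels.accrue_geometry_phase(
            walk,
            origins,
            axes,
            az,
            sin2,
            Rc,
            cfg.proximity_threshold,
            cfg.n_sub,
            cfg.dt_fine,
            cfg.coarse_per_bin,
            out,
        )
        n_simulated += 1
        if status == _kernels.ENTERED:
            n_discarded += 1
        else:
            kept[n_kept] = out * pref
            n_kept += 1

    if n_kept < cfg.n_protons_keep:
        if require_full:
            raise RuntimeError(
                f"only {n_kept} clean protons among {n_simulated} simulated; "
                f"{cfg.n_protons_keep} requested"
            )
        kept = kept[:n_kept]

    return PhaseArchive(
        increments=kept,
        basis=basis,
        cfg=cfg,
        Rc=Rc,
        Vf=Vf,
        Rs=float(sphere_radius),
        D=blood.D,
        seed=int(seed),
        n_discarded=n_discarded,
        n_simulated=n_simulated,
    )


def entry_fraction(
    Rc: float,
    Vf: float,
    n_walks: int,
    physics: PhysicsParams,
    blood: BloodTissueParams,
    seed: int,
    *,
    cfg: WalkConfig | None = None,
    n_vessels_target: int = 1300,
    sphere_radius: float | None = None,
) -> float:
    """Fraction of ``n_walks`` random walks that pass inside a vessel.

    Runs the population machinery with phase accrual but keeps nothing;
    only the discard bookkeeping is used.
    """
    base = cfg or WalkConfig()
    cfg = replace(base, n_protons_total=n_walks, n_protons_keep=n_walks)
    archive = run_population(
        Rc,
        Vf,
        cfg,
        physics,
        blood,
        seed,
        n_vessels_target=n_vessels_target,
        sphere_radius=sphere_radius,
        require_full=False,
    )
    return archive.entry_fraction
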