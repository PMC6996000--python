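"""Random cylinder vessel networks and proton-vessel geometry.

Vessels are modelled as randomly oriented, infinitely long cylinders of a
single radius ``Rc`` confined to a sphere of radius ``Rs``. Origin points
alternate between the surface of the sphere and its interior (exact
half-and-half split), giving an approximately homogeneous vessel density.
Each vessel occupies ``pi * Rc**2 * chord`` where ``chord`` is the length
of its axis line inside the sphere; vessels are added until a target blood
volume fraction is reached.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cylinder",
    "VesselSystem",
    "sample_origin",
    "sample_orientation",
    "choose_sphere_radius",
    "build_vessel_system",
    "perpendicular_geometry",
]

_MAX_VESSELS = 10**6


@dataclass(frozen=True)
class Cylinder:
    """An infinite cylinder: a point on its axis, a unit axis, a radius (um)."""

    origin: np.ndarray
    axis: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-12:
            raise ValueError("cylinder axis must be a unit vector")
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")


@dataclass
class VesselSystem:
    """A set of cylinders inside a sphere, with achieved volume fraction.

    Arrays ``origins`` and ``axes`` have shape (n_vessels, 3); ``radius``
    is the common vessel radius (um), ``sphere_radius`` the bounding
    sphere radius (um). ``achieved_vf`` is the summed cylinder volume
    divided by the sphere volume and always reaches or overshoots
    ``target_vf`` by less than the volume fraction of the last vessel.
    """

    origins: np.ndarray
    axes: np.ndarray
    radius: float
    sphere_radius: float
    target_vf: float
    achieved_vf: float
    seed: int | None = None
    chords: np.ndarray = field(default=None, repr=False)

    @property
    def n_vessels(self) -> int:
        return self.origins.shape[0]

    @property
    def cylinders(self) -> list[Cylinder]:
        return [
            Cylinder(self.origins[i], self.axes[i], self.radius)
            for i in range(self.n_vessels)
        ]

    def to_csv(self, path: str | Path) -> None:
        """One row per cylinder plus a commented metadata header."""
        df = pd.DataFrame(
            {
                "origin_x": self.origins[:, 0],
                "origin_y": self.origins[:, 1],
                "origin_z": self.origins[:, 2],
                "axis_x": self.axes[:, 0],
                "axis_y": self.axes[:, 1],
                "axis_z": self.axes[:, 2],
                "radius_um": np.full(self.n_vessels, self.radius),
            }
        )
        header = (
            f"# sphere_radius_um={self.sphere_radius!r}\n"
            f"# target_vf={self.target_vf!r}\n"
            f"# achieved_vf={self.achieved_vf!r}\n"
            f"# seed={self.seed!r}\n"
        )
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        Path(path).write_text(header + buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "VesselSystem":
        text = Path(path).read_text()
        meta = {}
        lines = text.splitlines()
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line.lstrip("# ").partition("=")
            meta[key] = eval(value)  # noqa: S307 - values written by to_csv (repr of float/int/None)
        df = pd.read_csv(io.StringIO("\n".join(lines[n_header:])))
        origins = df[["origin_x", "origin_y", "origin_z"]].to_numpy()
        axes = df[["axis_x", "axis_y", "axis_z"]].to_numpy()
        radius = float(df["radius_um"].iloc[0])
        sys = cls(
            origins=origins,
            axes=axes,
            radius=radius,
            sphere_radius=meta["sphere_radius_um"],
            target_vf=meta["target_vf"],
            achieved_vf=meta["achieved_vf"],
            seed=meta["seed"],
        )
        sys.chords = _chord_lengths(origins, axes, sys.sphere_radius)
        return sys


def sample_origin(
    Rs: float, on_surface: bool, rng: np.random.Generator
) -> np.ndarray:
    """Draw a vessel origin on, or uniformly within, a sphere of radius Rs.

    A direction is taken from a 3-vector of standard normals (isotropic
    after normalisation); surface points are scaled to radius ``Rs``,
    interior points additionally by ``U**(1/3)`` with ``U ~ Uniform(0,1)``
    so the density is uniform in volume.
    """
    if Rs <= 0:
        raise ValueError("Rs must be positive")
    x = rng.standard_normal(3)
    x /= np.linalg.norm(x)
    if on_surface:
        return Rs * x
    return Rs * rng.uniform() ** (1.0 / 3.0) * x


def sample_orientation(rng: np.random.Generator) -> np.ndarray:
    """Isotropic unit vector from normalised standard normals."""
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _chord_lengths(origins: np.ndarray, axes: np.ndarray, Rs: float) -> np.ndarray:
    """Length of each axis line's segment inside the sphere |x| <= Rs.

    For a line o + t*a with |a| = 1 the intersection satisfies
    t^2 + 2 t (o.a) + |o|^2 - Rs^2 = 0; the chord is t+ - t- =
    2*sqrt((o.a)^2 - |o|^2 + Rs^2).
    """
    oa = np.einsum("ij,ij->i", origins, axes)
    disc = oa**2 - np.einsum("ij,ij->i", origins, origins) + Rs**2
    return 2.0 * np.sqrt(np.maximum(disc, 0.0))


def choose_sphere_radius(
    Rc: float,
    Vf: float,
    N_target: int = 1300,
    *,
    mean_chord_factor: float = 1.0,
    calibrate: bool = True,
    seed: int = 0,
) -> float:
    """Sphere radius giving ~``N_target`` vessels at volume fraction Vf.

    Uses N * pi * Rc^2 * Lbar = Vf * (4/3) * pi * Rs^3 with the mean chord
    length Lbar = ``mean_chord_factor`` * Rs, i.e.
    Rs = Rc * sqrt(3 N c / (4 Vf)). With ``calibrate`` one pilot system is
    built at that radius and Rs rescaled by ``sqrt(N_target / N_obs)``
    (vessel count scales as Rs^2 when Lbar is proportional to Rs).
    """
    if Rc <= 0 or not 0 < Vf < 1:
        raise ValueError("require Rc > 0 and 0 < Vf < 1")
    Rs = Rc * np.sqrt(3.0 * N_target * mean_chord_factor / (4.0 * Vf))
    if Rs <= Rc:
        raise ValueError("computed sphere radius does not exceed vessel radius")
    if calibrate:
        pilot = build_vessel_system(Rc, Vf, Rs, seed=seed)
        Rs *= np.sqrt(N_target / pilot.n_vessels)
        if Rs <= Rc:
            raise ValueError("calibrated sphere radius does not exceed vessel radius")
    return float(Rs)


def build_vessel_system(
    Rc: float,
    Vf: float,
    Rs: float,
    seed: int | np.random.Generator = 0,
) -> VesselSystem:
    """Accumulate random cylinders until the target volume fraction Vf.

    Origins alternate deterministically surface/interior (exact
    half-and-half at any count); orientations are isotropic. Each vessel's
    volume is pi*Rc^2 times its axis chord length through the sphere;
    accumulation stops at the first vessel reaching or exceeding
    ``Vf * (4/3) pi Rs^3``. Degenerate zero-chord vessels are redrawn.
    """
    if Rs <= Rc:
        raise ValueError("sphere radius must exceed vessel radius")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    sphere_volume = 4.0 / 3.0 * np.pi * Rs**3
    target_volume = Vf * sphere_volume

    origins_parts: list[np.ndarray] = []
    axes_parts: list[np.ndarray] = []
    chords_parts: list[np.ndarray] = []
    total = 0.0
    count = 0
    batch = 256
    while True:
        # vectorised batch of candidate vessels, surface/interior by parity
        dirs = rng.standard_normal((batch, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        u = rng.uniform(size=batch) ** (1.0 / 3.0)
        parity = (count + np.arange(batch)) % 2  # 0 -> surface, 1 -> interior
        scale = np.where(parity == 0, 1.0, u)
        origins = Rs * scale[:, None] * dirs
        axes = rng.standard_normal((batch, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        chords = _chord_lengths(origins, axes, Rs)
        ok = chords > 0.0
        origins, axes, chords = origins[ok], axes[ok], chords[ok]

        volumes = np.pi * Rc**2 * chords
        cum = total + np.cumsum(volumes)
        hit = np.nonzero(cum >= target_volume)[0]
        if hit.size:
            k = hit[0] + 1
            origins_parts.append(origins[:k])
            axes_parts.append(axes[:k])
            chords_parts.append(chords[:k])
            total = cum[hit[0]]
            count += k
            break
        origins_parts.append(origins)
        axes_parts.append(axes)
        chords_parts.append(chords)
        total = cum[-1] if volumes.size else total
        count += origins.shape[0]
        if count > _MAX_VESSELS:
            raise RuntimeError(
                f"volume fraction {Vf} not reached after {_MAX_VESSELS} vessels"
            )

    return VesselSystem(
        origins=np.concatenate(origins_parts),
        axes=np.concatenate(axes_parts),
        radius=Rc,
        sphere_radius=Rs,
        target_vf=Vf,
        achieved_vf=total / sphere_volume,
        seed=seed_val,
        chords=np.concatenate(chords_parts),
    )


def perpendicular_geometry(
    point: np.ndarray,
    cyl: Cylinder,
    B0_dir: np.ndarray = (0.0, 0.0, 1.0),
) -> tuple[float, float, float]:
    """Proton-vessel geometry (r, theta, phi) for the cylinder field term.

    ``r`` is the perpendicular distance from ``point`` to the cylinder
    axis line; ``theta`` in [0, pi/2] the angle between axis and the main
    field direction; ``phi`` the angle, in the plane orthogonal to the
    axis, between the point's radial direction and the projection of the
    field direction onto that plane. When the axis is parallel to the
    field the projection vanishes and phi = 0 is returned by convention
    (the field term vanishes through sin^2(theta) anyway); likewise on the
    axis (r = 0) where the radial direction is undefined.
    """
    point = np.asarray(point, dtype=float)
    b = np.asarray(B0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    a = cyl.axis
    d = point - cyl.origin
    proj = d @ a
    rel_perp = d - proj * a
    r = float(np.linalg.norm(rel_perp))
    cos_t = abs(float(a @ b))
    theta = float(np.arccos(np.clip(cos_t, 0.0, 1.0)))
    b_perp = b - (b @ a) * a
    nb = np.linalg.norm(b_perp)
    if nb < 1e-15 or r < 1e-15:
        return r, theta, 0.0
    cos_phi = float(rel_perp @ b_perp) / (r * nb)
    phi = float(np.arccos(np.clip(cos_phi, -1.0, 1.0)))
    return r, theta, phi
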