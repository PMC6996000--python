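"""Physical and physiological constants shared by every simulation stage.

Conventions used throughout the package:

* times are in **milliseconds** at the public interface; conversion to
  seconds happens only inside formula evaluation,
* lengths are in micrometres, diffusivities in um^2/ms,
* the blood susceptibility difference ``delta_chi`` is the CGS-convention
  value (dimensionless, ~0.27e-6) and is plugged literally into the field
  and relaxation formulas together with their 4*pi/3 and 4*pi geometry
  factors — no SI conversion is performed anywhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "PhysicsParams",
    "BloodTissueParams",
    "PhysiologyState",
    "default_params",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class PhysicsParams:
    """Scanner and susceptibility constants.

    Attributes
    ----------
    B0 : float
        Main magnetic field strength (T).
    gamma : float
        Proton gyromagnetic ratio (rad s^-1 T^-1).
    delta_chi : float
        Volume susceptibility difference between fully deoxygenated and
        fully oxygenated blood, CGS convention (dimensionless).
    """

    B0: float = 3.0
    gamma: float = 2.675e8
    delta_chi: float = 0.27e-6

    def __post_init__(self) -> None:
        for name in ("B0", "gamma", "delta_chi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BloodTissueParams:
    """Blood and tissue properties.

    Attributes
    ----------
    Hct : float
        Haematocrit (fraction of blood volume occupied by red cells).
    Y : float
        Blood oxygen saturation (fraction); the nominal venous value.
    T2_t : float
        Tissue transverse relaxation time (ms).
    T2_b0 : float
        Intrinsic blood T2 when fully oxygenated (ms).
    R_rbc : float
        Characteristic red-blood-cell size (um).
    D_b : float
        Blood water diffusion coefficient (um^2 ms^-1).
    D : float
        Tissue water diffusion coefficient (um^2 ms^-1).
    """

    Hct: float = 0.4
    Y: float = 0.6
    T2_t: float = 80.0
    T2_b0: float = 189.0
    R_rbc: float = 2.6
    D_b: float = 2.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Hct <= 1.0:
            raise ValueError("Hct must lie in [0, 1]")
        if not 0.0 <= self.Y <= 1.0:
            raise ValueError("Y must lie in [0, 1]")
        for name in ("T2_t", "T2_b0", "D", "D_b", "R_rbc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PhysiologyState:
    """Baseline physiology of the simulated voxel.

    Attributes
    ----------
    E0 : float
        Oxygen extraction fraction (fraction).
    V0 : float
        Deoxygenated blood volume fraction (fraction of tissue volume).
    Ya : float
        Arterial oxygen saturation (fraction).
    kappa : float
        Capillary saturation weighting factor towards the arterial value.
    rho : float
        Brain tissue density (g ml^-1).
    """

    E0: float = 0.4
    V0: float = 0.03
    Ya: float = 0.98
    kappa: float = 0.4
    rho: float = 1.04

    def __post_init__(self) -> None:
        for name in ("E0", "V0", "Ya", "kappa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be strictly positive")


def default_params() -> tuple[PhysicsParams, BloodTissueParams, PhysiologyState]:
    """Return the default parameter set used across the simulation study.

    3 T field, gamma = 2.675e8 rad/s/T, CGS susceptibility difference
    0.27 ppm, Hct = 40%, tissue D = 1 um^2/ms and T2 = 80 ms, blood
    T2 (fully oxygenated) = 189 ms, red-cell scale 2.6 um with blood
    D = 2 um^2/ms, arterial saturation 98%, capillary weighting 0.4 and
    tissue density 1.04 g/ml.
    """
    return PhysicsParams(), BloodTissueParams(), PhysiologyState()


_RECORD_TYPES = {
    "PhysicsParams": PhysicsParams,
    "BloodTissueParams": BloodTissueParams,
    "PhysiologyState": PhysiologyState,
}

_Record = PhysicsParams | BloodTissueParams | PhysiologyState


def save_params(records: dict[str, _Record], path: str | Path) -> None:
    """Dump parameter records to a flat YAML/JSON key-value file.

    ``records`` maps record-type names (e.g. ``"PhysicsParams"``) to
    instances; the file nests one flat mapping per record with keys named
    exactly as the dataclass fields. Format is chosen by extension
    (``.json`` -> JSON, otherwise YAML).
    """
    payload = {}
    for kind, rec in records.items():
        if kind not in _RECORD_TYPES:
            raise ValueError(f"unknown parameter record type {kind!r}")
        payload[kind] = dataclasses.asdict(rec)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))


def load_params(path: str | Path) -> dict[str, _Record]:
    """Inverse of :func:`save_params`; round trip is lossless."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out: dict[str, _Record] = {}
    for kind, fields in payload.items():
        if kind not in _RECORD_TYPES:
            raise ValueError(f"unknown parameter record type {kind!r}")
        out[kind] = _RECORD_TYPES[kind](**fields)
    return out
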