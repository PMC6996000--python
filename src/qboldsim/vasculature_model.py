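"""Compartmental model of the cortical vasculature (sheep-brain morphometry).

Eleven compartments — five arteriolar orders (a1..a5), one capillary bed
(c) and five venular orders (v5..v1) — each described by a vessel radius,
length and count. Treating each population as cylinders gives relative
blood volume fractions; scaling by a total cerebral blood volume (CBV)
gives absolute fractions. Arterioles carry arterial saturation, venules
the venous saturation Yv = Ya (1 - E0), and capillaries an intermediate
value weighted towards the venous end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VascularCompartment",
    "VascularModel",
    "sheep_model",
    "relative_fractions",
    "venous_saturation",
    "capillary_saturation",
    "dhb_content",
]


@dataclass(frozen=True)
class VascularCompartment:
    """One vessel population: radius/length in um, count, optional Y."""

    label: str
    vessel_type: str
    radius: float
    length: float
    count: float
    Y: float | None = None

    def __post_init__(self) -> None:
        if self.vessel_type not in ("arteriole", "capillary", "venule"):
            raise ValueError("vessel_type must be arteriole, capillary or venule")
        if min(self.radius, self.length, self.count) <= 0:
            raise ValueError("radius, length and count must be positive")

    @property
    def volume(self) -> float:
        """Total cylinder volume of the population (um^3)."""
        return self.count * np.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class VascularModel:
    """Ordered collection of vascular compartments."""

    compartments: tuple[VascularCompartment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))

    def __iter__(self):
        return iter(self.compartments)

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.compartments]

    @property
    def radii(self) -> np.ndarray:
        return np.array([c.radius for c in self.compartments])

    def deoxygenated_fraction(self) -> float:
        """Capillary-plus-venous share of total blood volume.

        Used as the working ground truth for DBV: DBV_true = CBV times
        this fraction.
        """
        fractions = relative_fractions(self, include_arterioles=True)
        return float(
            sum(
                f
                for f, c in zip(fractions, self.compartments)
                if c.vessel_type != "arteriole"
            )
        )

    def with_saturations(
        self, E0: float, Ya: float = 0.98, kappa: float = 0.4
    ) -> "VascularModel":
        """Assign per-compartment oxygen saturations for a given OEF."""
        Yv = venous_saturation(Ya, E0)
        Yc = capillary_saturation(kappa, Ya, Yv)
        per_type = {"arteriole": Ya, "capillary": Yc, "venule": Yv}
        return VascularModel(
            tuple(replace(c, Y=per_type[c.vessel_type]) for c in self.compartments)
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "label": [c.label for c in self.compartments],
                "vessel_type": [c.vessel_type for c in self.compartments],
                "radius_um": [c.radius for c in self.compartments],
                "length_um": [c.length for c in self.compartments],
                "count": [c.count for c in self.compartments],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VascularModel":
        df = pd.read_csv(path)
        return cls(
            tuple(
                VascularCompartment(
                    label=row["label"],
                    vessel_type=row["vessel_type"],
                    radius=row["radius_um"],
                    length=row["length_um"],
                    count=row["count"],
                )
                for _, row in df.iterrows()
            )
        )


# radius (um), length (um), count per compartment, arterial-to-venous order
_SHEEP_TABLE = (
    ("a1", "arteriole", 60.0, 5390.0, 1880.0),
    ("a2", "arteriole", 30.0, 2690.0, 1.5e4),
    ("a3", "arteriole", 15.0, 1350.0, 1.15e5),
    ("a4", "arteriole", 10.0, 900.0, 3.92e5),
    ("a5", "arteriole", 5.0, 450.0, 3.01e6),
    ("c", "capillary", 2.8, 600.0, 5.92e7),
    ("v5", "venule", 7.5, 450.0, 3.01e6),
    ("v4", "venule", 15.0, 900.0, 3.92e5),
    ("v3", "venule", 22.5, 1350.0, 1.15e5),
    ("v2", "venule", 45.0, 2690.0, 1.5e4),
    ("v1", "venule", 90.0, 5390.0, 1880.0),
)


def sheep_model() -> VascularModel:
    """The eleven-compartment sheep-brain vascular model (saturations unset)."""
    return VascularModel(
        tuple(VascularCompartment(*row) for row in _SHEEP_TABLE)
    )


def relative_fractions(
    model: VascularModel, include_arterioles: bool = True
) -> np.ndarray:
    """Per-compartment relative blood volume fractions (sum to 1).

    Volumes are cylinder volumes count * pi * r^2 * length. With
    ``include_arterioles=False`` arteriolar compartments get fraction 0
    and the remainder is normalised over capillary + venous volume.
    """
    volumes = np.array(
        [
            c.volume if include_arterioles or c.vessel_type != "arteriole" else 0.0
            for c in model.compartments
        ]
    )
    return volumes / volumes.sum()


def venous_saturation(Ya: float, E0: float) -> float:
    """Venous oxygen saturation Yv = Ya (1 - E0)."""
    if not (0.0 <= Ya <= 1.0 and 0.0 <= E0 <= 1.0):
        raise ValueError("Ya and E0 must lie in [0, 1]")
    return Ya * (1.0 - E0)


def capillary_saturation(kappa: float, Ya: float, Yv: float) -> float:
    """Capillary saturation Yc = kappa Ya + (1 - kappa) Yv."""
    if not (0.0 <= kappa <= 1.0 and 0.0 <= Ya <= 1.0 and 0.0 <= Yv <= 1.0):
        raise ValueError("inputs must lie in [0, 1]")
    return kappa * Ya + (1.0 - kappa) * Yv


def dhb_content(V0: float, Hct: float, E0: float, rho: float) -> float:
    """Deoxyhaemoglobin content (ml dHb per 100 g tissue).

    100 * V0 * rho * (Hct / 0.03) * E0 — a labelling quantity only; it
    feeds no estimator. The 0.03 converts haematocrit to haemoglobin
    content per unit blood volume.
    """
    if min(V0, Hct, E0, rho) < 0:
        raise ValueError("inputs must be non-negative")
    return 100.0 * V0 * rho * (Hct / 0.03) * E0
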