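"""ASE/GESSE signal synthesis from phase archives and scaling identities.

A spin-echo experiment refocuses the phase accrued before the refocusing
pulse; the net phase at acquisition is the difference between the phase
sums on either side of the refocusing point. Given a phase archive on the
storage grid, any ASE (fixed echo time tE, refocusing pulse shifted by
tau/2) or GESSE (fixed spin-echo time tSE, shifted acquisition) protocol
whose timings land on that grid can be synthesised without re-simulation.

Three exact identities accelerate parameter studies:

* oxygenation: phase is linear in (1 - Y), so stored increments rescale
  by (1 - Y_target) / (1 - Y_nominal);
* blood volume: the extravascular log-magnitude is proportional to the
  volume fraction, ``S = exp(-Vf * f(Rc, tau))``;
* multiple radii: signals of independently simulated radius populations
  multiply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qboldsim.monte_carlo import PhaseArchive

__all__ = [
    "SequenceProtocol",
    "SignalCurve",
    "recombine",
    "extravascular_signal",
    "scale_volume",
    "equivalent_radius",
    "combine_radii",
    "total_signal",
    "apply_t2_weighting",
]


@dataclass(frozen=True)
class SequenceProtocol:
    """ASE or GESSE timing specification (all times in ms).

    For ASE the echo time ``tE`` is fixed and the spin echo moves
    (tSE = tE - tau); for GESSE the spin echo ``tSE`` is fixed and the
    acquisition moves (tE = tSE + tau).
    """

    kind: str
    tau_values: tuple[float, ...]
    tE: float | None = None
    tSE: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ASE", "GESSE"):
            raise ValueError("kind must be 'ASE' or 'GESSE'")
        object.__setattr__(self, "tau_values", tuple(float(t) for t in self.tau_values))
        if self.kind == "ASE":
            if self.tE is None:
                raise ValueError("ASE protocol requires tE")
            if any(abs(t) > self.tE for t in self.tau_values):
                raise ValueError("ASE requires -tE <= tau <= tE")
        else:
            if self.tSE is None:
                raise ValueError("GESSE protocol requires tSE")
            if any(t < -self.tSE / 2 for t in self.tau_values):
                raise ValueError("GESSE requires tSE + tau >= tSE/2")

    @classmethod
    def ase(cls, tE: float, tau_values) -> "SequenceProtocol":
        return cls(kind="ASE", tau_values=tuple(tau_values), tE=tE)

    @classmethod
    def gesse(cls, tSE: float, tau_values) -> "SequenceProtocol":
        return cls(kind="GESSE", tau_values=tuple(tau_values), tSE=tSE)

    def echo_time(self, tau: float) -> float:
        """Acquisition time tE for a given tau (varies only for GESSE)."""
        return self.tE if self.kind == "ASE" else self.tSE + tau

    def spin_echo_time(self, tau: float) -> float:
        """Spin-echo time tSE for a given tau (varies only for ASE)."""
        return self.tE - tau if self.kind == "ASE" else self.tSE

    def indices(self, tau: float, dt: float) -> tuple[int, int]:
        """Storage-grid indices (m, n): refocusing split and acquisition.

        ASE: m = (tE - tau) / (2 dt), n = tE / dt.
        GESSE: m = tSE / (2 dt), n = (tSE + tau) / dt.
        Raises when either index is non-integer on the grid or the
        ordering 0 <= m <= n is violated.
        """
        if self.kind == "ASE":
            m = (self.tE - tau) / (2.0 * dt)
            n = self.tE / dt
        else:
            m = self.tSE / (2.0 * dt)
            n = (self.tSE + tau) / dt
        mi, ni = round(m), round(n)
        if abs(m - mi) > 1e-9 or abs(n - ni) > 1e-9:
            raise ValueError(
                f"tau={tau} ms does not land on the {dt} ms storage grid "
                f"(m={m}, n={n})"
            )
        if not 0 <= mi <= ni:
            raise ValueError(f"invalid echo indices m={mi}, n={ni} for tau={tau}")
        return mi, ni


@dataclass
class SignalCurve:
    """Signal magnitudes on a tau grid, with provenance.

    Magnitudes follow the convention of unit initial transverse
    magnetisation, so they lie in (0, 1]. ``t2_applied`` records whether
    the compartment's T2 decay factor has been applied (it must never be
    applied twice). ``echo_times`` carries the acquisition time per tau
    so T2 weighting can be applied after the fact.
    """

    tau_values: np.ndarray
    magnitudes: np.ndarray
    compartment: str = "extravascular"
    t2_applied: bool = False
    echo_times: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.tau_values.shape != self.magnitudes.shape:
            raise ValueError("tau_values and magnitudes must have equal shape")
        if self.echo_times is not None:
            self.echo_times = np.asarray(self.echo_times, dtype=float)

    def magnitude_at(self, tau: float) -> float:
        idx = np.nonzero(np.isclose(self.tau_values, tau))[0]
        if idx.size == 0:
            raise KeyError(f"tau={tau} ms not on curve grid")
        return float(self.magnitudes[idx[0]])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "tau_ms": self.tau_values,
                "magnitude": self.magnitudes,
                "compartment": self.compartment,
                "t2_applied": self.t2_applied,
            }
        )
        df.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tau_ms": self.tau_values.tolist(),
            "magnitude": self.magnitudes.tolist(),
            "compartment": self.compartment,
            "t2_applied": self.t2_applied,
            "echo_times_ms": None
            if self.echo_times is None
            else self.echo_times.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def recombine(
    archive: PhaseArchive, protocol: SequenceProtocol, tau: float
) -> np.ndarray:
    """Net phase per kept proton at spin-echo displacement ``tau``.

    phi(tau) = sum_{j<=m} dphi_j - sum_{m<j<=n} dphi_j, with (m, n) from
    the protocol's index formulas on the archive's storage grid.
    """
    m, n = protocol.indices(tau, archive.cfg.dt_store)
    if n > archive.n_intervals:
        raise ValueError(
            f"protocol needs {n} storage intervals, archive has {archive.n_intervals}"
        )
    inc = archive.increments
    return inc[:, :m].sum(axis=1) - inc[:, m:n].sum(axis=1)


def extravascular_signal(
    archive: PhaseArchive,
    protocol: SequenceProtocol,
    Y_target: float,
    T2_t: float | None = None,
    apply_t2: bool = False,
) -> SignalCurve:
    """Ensemble extravascular signal magnitude over the protocol's taus.

    Stored increments are first rescaled by
    lambda = (1 - Y_target) / (1 - Y_nominal) (phase linearity in 1 - Y),
    then recombined per tau; the magnitude is |mean_k exp(i phi_k)| over
    the kept protons. T2 weighting exp(-tE / T2_t) is applied iff
    ``apply_t2`` (tE varies with tau for GESSE).
    """
    if not 0.0 <= Y_target < 1.0:
        raise ValueError("Y_target must lie in [0, 1)")
    if archive.basis.Y >= 1.0:
        raise ValueError("archive nominal oxygenation must be below 1")
    lam = (1.0 - Y_target) / (1.0 - archive.basis.Y)
    taus = np.asarray(protocol.tau_values)
    mags = np.empty(taus.size)
    for k, tau in enumerate(taus):
        phi = lam * recombine(archive, protocol, tau)
        mags[k] = np.abs(np.exp(1j * phi).mean())
    echo_times = np.array([protocol.echo_time(t) for t in taus])
    curve = SignalCurve(
        tau_values=taus,
        magnitudes=mags,
        compartment="extravascular",
        t2_applied=False,
        echo_times=echo_times,
        provenance={
            "kind": protocol.kind,
            "Rc_um": archive.Rc,
            "Vf": archive.Vf,
            "Y": Y_target,
            "Y_nominal": archive.basis.Y,
            "n_protons": archive.n_protons,
        },
    )
    if apply_t2:
        if T2_t is None:
            raise ValueError("apply_t2 requires T2_t")
        curve = apply_t2_weighting(curve, T2_t)
    return curve


def apply_t2_weighting(curve: SignalCurve, T2: float) -> SignalCurve:
    """Multiply by exp(-tE / T2); refuses to apply T2 twice."""
    if curve.t2_applied:
        raise ValueError("T2 weighting already applied to this curve")
    if curve.echo_times is None:
        raise ValueError("curve carries no echo times")
    return SignalCurve(
        tau_values=curve.tau_values,
        magnitudes=curve.magnitudes * np.exp(-curve.echo_times / T2),
        compartment=curve.compartment,
        t2_applied=True,
        echo_times=curve.echo_times,
        provenance={**curve.provenance, "T2_ms": T2},
    )


def scale_volume(
    curve: SignalCurve, Vf_nominal: float, Vf_target: float
) -> SignalCurve:
    """Rescale a T2-free extravascular curve to another volume fraction.

    Uses S = exp(-Vf * f(Rc, tau)): the log-magnitude scales by
    Vf_target / Vf_nominal.
    """
    if curve.t2_applied:
        raise ValueError("volume scaling must precede T2 weighting")
    if curve.compartment != "extravascular":
        raise ValueError("volume scaling applies to extravascular curves")
    if np.any(curve.magnitudes <= 0):
        raise ValueError("volume scaling requires strictly positive magnitudes")
    ratio = Vf_target / Vf_nominal
    return SignalCurve(
        tau_values=curve.tau_values,
        magnitudes=np.exp(ratio * np.log(curve.magnitudes)),
        compartment="extravascular",
        t2_applied=False,
        echo_times=curve.echo_times,
        provenance={**curve.provenance, "Vf": Vf_target, "Vf_nominal": Vf_nominal},
    )


def equivalent_radius(Rc: float, D_ref: float, D_target: float) -> float:
    """Radius giving the same characteristic diffusion time at D_target.

    tau_D ~ Rc^2 / D, so Rc_eq = Rc * sqrt(D_target / D_ref); e.g.
    doubling D is equivalent to increasing the radius by sqrt(2).
    """
    if Rc <= 0 or D_ref <= 0 or D_target <= 0:
        raise ValueError("all arguments must be positive")
    return Rc * float(np.sqrt(D_target / D_ref))


def combine_radii(curves: list[SignalCurve]) -> SignalCurve:
    """Pointwise product of T2-free extravascular curves (multi-radius).

    Curves must already be scaled for their oxygenation and absolute
    volume fraction and share the same tau grid.
    """
    if not curves:
        raise ValueError("need at least one curve")
    ref = curves[0]
    mags = np.ones_like(ref.magnitudes)
    for c in curves:
        if c.t2_applied:
            raise ValueError("combine_radii requires T2-free curves")
        if not np.allclose(c.tau_values, ref.tau_values):
            raise ValueError("mismatched tau grids")
        mags = mags * c.magnitudes
    return SignalCurve(
        tau_values=ref.tau_values.copy(),
        magnitudes=mags,
        compartment="extravascular",
        t2_applied=False,
        echo_times=None if ref.echo_times is None else ref.echo_times.copy(),
        provenance={"combined_from": [c.provenance for c in curves]},
    )


def total_signal(S_EV: SignalCurve, S_IV: SignalCurve, Vf: float) -> SignalCurve:
    """Volume-weighted total signal (1 - Vf) S_EV + Vf S_IV.

    Both inputs must carry their T2 weighting and share the tau grid.
    """
    if not np.allclose(S_EV.tau_values, S_IV.tau_values):
        raise ValueError("mismatched tau grids")
    if not (S_EV.t2_applied and S_IV.t2_applied):
        raise ValueError("total signal requires T2-weighted compartments")
    return SignalCurve(
        tau_values=S_EV.tau_values.copy(),
        magnitudes=(1.0 - Vf) * S_EV.magnitudes + Vf * S_IV.magnitudes,
        compartment="total",
        t2_applied=True,
        echo_times=None if S_EV.echo_times is None else S_EV.echo_times.copy(),
        provenance={"Vf": Vf},
    )
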