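import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qboldsim.monte_carlo import PhaseArchive, PhaseBasis, WalkConfig
from qboldsim.signal_synthesis import (
    SequenceProtocol,
    SignalCurve,
    apply_t2_weighting,
    combine_radii,
    equivalent_radius,
    extravascular_signal,
    recombine,
    scale_volume,
    total_signal,
)


def _archive_from_increments(inc: np.ndarray, dt_store: float = 2.0,
                             Y: float = 0.6) -> PhaseArchive:
    """Wrap explicit increments into an archive for recombination tests."""
    n_bins = inc.shape[1]
    cfg = WalkConfig(
        duration=n_bins * dt_store, n_protons_total=inc.shape[0],
        n_protons_keep=inc.shape[0],
    )
    basis = PhaseBasis(Y=Y, Hct=0.4, delta_chi=0.27e-6, B0=3.0, gamma=2.675e8)
    return PhaseArchive(
        increments=inc, basis=basis, cfg=cfg, Rc=10.0, Vf=0.03, Rs=500.0,
        D=1.0, seed=0, n_discarded=0, n_simulated=inc.shape[0],
    )


class TestProtocol:
    def test_ase_index_formulas(self):
        protocol = SequenceProtocol.ase(80.0, [0.0, 16.0])
        assert protocol.indices(16.0, 2.0) == (16, 40)
        assert protocol.indices(0.0, 2.0) == (20, 40)

    def test_gesse_index_formulas(self):
        protocol = SequenceProtocol.gesse(60.0, [-20.0, 0.0, 40.0])
        assert protocol.indices(0.0, 2.0) == (15, 30)
        assert protocol.indices(40.0, 2.0) == (15, 50)

    def test_off_grid_tau_rejected(self):
        protocol = SequenceProtocol.ase(80.0, [3.0])
        with pytest.raises(ValueError):
            protocol.indices(3.0, 2.0)

    def test_ase_tau_range_enforced(self):
        with pytest.raises(ValueError):
            SequenceProtocol.ase(60.0, [70.0])

    def test_echo_times(self):
        ase = SequenceProtocol.ase(80.0, [0.0, 16.0])
        gesse = SequenceProtocol.gesse(60.0, [0.0, 16.0])
        assert ase.echo_time(16.0) == 80.0
        assert ase.spin_echo_time(16.0) == 64.0
        assert gesse.echo_time(16.0) == 76.0
        assert gesse.spin_echo_time(16.0) == 60.0


class TestRecombine:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        omega=st.floats(-0.2, 0.2),
        tau=st.sampled_from([-40.0, -16.0, 0.0, 8.0, 24.0, 60.0]),
    )
    def test_static_proton_phase_is_minus_omega_tau(self, omega, tau):
        # constant offset: ASE net phase reduces to -omega * tau
        inc = np.full((1, 40), omega * 2.0)
        archive = _archive_from_increments(inc)
        protocol = SequenceProtocol.ase(60.0, [tau])
        phi = recombine(archive, protocol, tau)
        assert phi[0] == pytest.approx(-omega * tau, abs=1e-12)

    def test_spin_echo_cancels_constant_increments(self):
        inc = np.random.default_rng(0).normal(size=(5, 1)) * np.ones((5, 40))
        archive = _archive_from_increments(inc)
        protocol = SequenceProtocol.ase(80.0, [0.0])
        assert np.allclose(recombine(archive, protocol, 0.0), 0.0, atol=1e-12)

    def test_protocol_longer_than_archive_rejected(self):
        archive = _archive_from_increments(np.zeros((2, 10)))  # 20 ms
        protocol = SequenceProtocol.ase(40.0, [0.0])
        with pytest.raises(ValueError):
            recombine(archive, protocol, 0.0)


class TestExtravascularSignal:
    def test_single_proton_has_unit_magnitude(self):
        inc = np.random.default_rng(1).normal(size=(1, 40)) * 0.05
        archive = _archive_from_increments(inc)
        protocol = SequenceProtocol.ase(60.0, [0.0, 16.0, 32.0])
        curve = extravascular_signal(archive, protocol, 0.6)
        assert np.allclose(curve.magnitudes, 1.0, atol=1e-12)

    def test_nominal_oxygenation_is_identity(self, small_archive):
        protocol = SequenceProtocol.ase(60.0, [0.0, 16.0, 32.0])
        a = extravascular_signal(small_archive, protocol, small_archive.basis.Y)
        lam = 1.0
        phi = lam * recombine(small_archive, protocol, 16.0)
        direct = np.abs(np.exp(1j * phi).mean())
        assert a.magnitude_at(16.0) == pytest.approx(direct, rel=1e-14)

    def test_ase_symmetry_exact_for_static_protons(self, static_archive):
        taus = np.arange(-40.0, 40.0 + 1e-9, 8.0)
        protocol = SequenceProtocol.ase(40.0, taus)
        curve = extravascular_signal(static_archive, protocol, 0.6)
        pos = curve.magnitudes[taus > 0]
        neg = curve.magnitudes[taus < 0][::-1]
        assert np.array_equal(pos, neg)

    def test_ase_symmetry_with_diffusion_within_mc_error(self, small_archive):
        taus = np.arange(-32.0, 32.0 + 1e-9, 8.0)
        protocol = SequenceProtocol.ase(40.0, taus)
        curve = extravascular_signal(small_archive, protocol, 0.6)
        pos = curve.magnitudes[taus > 0]
        neg = curve.magnitudes[taus < 0][::-1]
        assert np.max(np.abs(pos - neg)) < 0.05

    def test_gesse_maximum_shifts_negative_with_diffusion(self, small_rc5_archive):
        protocol = SequenceProtocol.gesse(40.0, [-8.0, 8.0])
        curve = extravascular_signal(small_rc5_archive, protocol, 0.6)
        # more signal before the spin echo than after, by the diffusion
        # asymmetry of the GESSE sequence at small radii
        assert curve.magnitude_at(-8.0) > curve.magnitude_at(8.0)

    def test_t2_weighting_applied_once(self, small_archive):
        protocol = SequenceProtocol.ase(60.0, [0.0, 16.0])
        bare = extravascular_signal(small_archive, protocol, 0.6)
        weighted = extravascular_signal(
            small_archive, protocol, 0.6, T2_t=80.0, apply_t2=True
        )
        assert np.allclose(
            weighted.magnitudes, bare.magnitudes * np.exp(-60.0 / 80.0)
        )
        with pytest.raises(ValueError):
            apply_t2_weighting(weighted, 80.0)


class TestScalingIdentities:
    def test_equivalent_radius_values(self):
        assert equivalent_radius(5.0, 1.0, 2.0) == pytest.approx(7.07, abs=0.005)
        assert equivalent_radius(5.0, 1.3, 1.3) == 5.0
        # the printed diffusivity range upper end: +4.4% radius
        assert 100 * (equivalent_radius(1.0, 1.0, 1.09) - 1) == pytest.approx(
            4.4, abs=0.05
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ratio=st.floats(0.1, 5.0))
    def test_volume_scaling_is_log_linear(self, ratio):
        taus = np.array([0.0, 16.0, 32.0])
        mags = np.array([0.9, 0.7, 0.5])
        curve = SignalCurve(tau_values=taus, magnitudes=mags)
        scaled = scale_volume(curve, 0.03, 0.03 * ratio)
        assert np.allclose(scaled.magnitudes, mags**ratio)

    def test_volume_scaling_identity_and_double(self):
        curve = SignalCurve(
            tau_values=np.array([0.0, 8.0]), magnitudes=np.array([0.8, 0.6])
        )
        same = scale_volume(curve, 0.03, 0.03)
        twice = scale_volume(curve, 0.03, 0.06)
        assert np.allclose(same.magnitudes, curve.magnitudes)
        assert np.allclose(twice.magnitudes, curve.magnitudes**2)

    def test_volume_scaling_requires_t2_free(self):
        curve = SignalCurve(
            tau_values=np.array([0.0]), magnitudes=np.array([0.5]),
            t2_applied=True,
        )
        with pytest.raises(ValueError):
            scale_volume(curve, 0.03, 0.06)

    def test_combining_two_copies_equals_double_volume(self):
        curve = SignalCurve(
            tau_values=np.array([0.0, 8.0]), magnitudes=np.array([0.9, 0.7])
        )
        combined = combine_radii([curve, curve])
        doubled = scale_volume(curve, 0.03, 0.06)
        assert np.allclose(combined.magnitudes, doubled.magnitudes)

    def test_combined_curve_below_components(self):
        a = SignalCurve(np.array([0.0, 8.0]), np.array([0.9, 0.7]))
        b = SignalCurve(np.array([0.0, 8.0]), np.array([0.95, 0.8]))
        c = combine_radii([a, b])
        assert np.all(c.magnitudes <= a.magnitudes)
        assert np.all(c.magnitudes <= b.magnitudes)

    def test_combine_rejects_mismatched_grids(self):
        a = SignalCurve(np.array([0.0, 8.0]), np.array([0.9, 0.7]))
        b = SignalCurve(np.array([0.0, 12.0]), np.array([0.9, 0.7]))
        with pytest.raises(ValueError):
            combine_radii([a, b])

    def test_tau_d_equivalence_exact_under_joint_scaling(self, params):
        # simultaneously scaling Rc by sqrt(k) and D by k leaves the walk
        # geometry relative to the vessels unchanged: identical signals
        from qboldsim.experiments import FidelityTier, build_archive

        physics, blood, _ = params
        tier = FidelityTier(120, 80, 120, 40.0)
        a1 = build_archive(10.0, 0.03, physics, blood, seed=9, tier=tier)
        blood2 = dataclasses.replace(blood, D=2.0)
        a2 = build_archive(
            equivalent_radius(10.0, 1.0, 2.0), 0.03, physics, blood2,
            seed=9, tier=tier,
        )
        protocol = SequenceProtocol.ase(40.0, [0.0, 8.0, 16.0, 24.0])
        c1 = extravascular_signal(a1, protocol, 0.6)
        c2 = extravascular_signal(a2, protocol, 0.6)
        assert np.allclose(c1.magnitudes, c2.magnitudes, rtol=1e-9)


class TestTotalSignal:
    def _pair(self):
        taus = np.array([0.0, 16.0])
        ev = SignalCurve(taus, np.array([0.4, 0.3]), "extravascular", True,
                         echo_times=np.full(2, 60.0))
        iv = SignalCurve(taus, np.array([0.06, 0.05]), "intravascular", True,
                         echo_times=np.full(2, 60.0))
        return ev, iv

    def test_volume_weighting_limits(self):
        ev, iv = self._pair()
        assert np.allclose(total_signal(ev, iv, 0.0).magnitudes, ev.magnitudes)
        assert np.allclose(total_signal(ev, iv, 1.0).magnitudes, iv.magnitudes)

    def test_small_volume_fraction_bound(self):
        ev, iv = self._pair()
        tot = total_signal(ev, iv, 0.03)
        assert np.all(np.abs(tot.magnitudes - ev.magnitudes)
                      <= 0.03 * np.abs(iv.magnitudes - ev.magnitudes) + 1e-15)

    def test_requires_t2_weighted_inputs(self):
        ev, iv = self._pair()
        bare = SignalCurve(ev.tau_values, ev.magnitudes, "extravascular", False)
        with pytest.raises(ValueError):
            total_signal(bare, iv, 0.03)
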