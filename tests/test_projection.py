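"""Normal-mode projection, dipole decomposition, helicity-frozen
spectra and event-aligned correlation functions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluorspec.constants import C_CM_PER_FS, KB
from fluorspec.projection import (
    decompose_dipole,
    event_aligned_acf,
    helicity_frozen_spectrum,
    masked_power_spectrum,
    mode_spectra,
    project_onto_modes,
)
from fluorspec.spectra import DipoleTrace, power_spectrum
from fluorspec.synth import (
    GeneratorConfig,
    gen_mode_dynamics,
    langevin_mode,
    telegraph_process,
)
from fluorspec.trajectory import Trajectory


def _two_frame_traj(system, coords):
    """Minimal trajectory holding one test geometry (duplicated)."""
    return Trajectory(
        np.stack([coords, coords]),
        dt=1.0,
        masses=system.masses,
        charges=system.charges,
    )


class TestProjection:
    def test_reference_frame_projects_to_zero(self, helical_system):
        traj = _two_frame_traj(helical_system, helical_system.refs.x_ref_plus)
        mt = project_onto_modes(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        assert np.all(mt.helicity_used == 1)
        assert np.abs(mt.q).max() < 1e-10

    @pytest.mark.parametrize("j", [3, 20, 40])
    def test_single_mode_displacement_recovered_exactly(self, helical_system, j):
        a = 0.05
        coords = (
            helical_system.refs.x_ref_plus
            + a * helical_system.modes_plus.cart_disp[j]
        )
        traj = _two_frame_traj(helical_system, coords)
        mt = project_onto_modes(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        assert mt.q[j, 0] == pytest.approx(a, abs=1e-10)
        others = np.abs(mt.q[:, 0])
        others[j] = 0.0
        assert others.max() < 1e-10

    def test_recovery_invariant_under_rigid_transform(self, helical_system):
        j, a = 20, 0.05
        coords = (
            helical_system.refs.x_ref_plus
            + a * helical_system.modes_plus.cart_disp[j]
        )
        R = Rotation.from_euler("zx", [37.0, 12.0], degrees=True).as_matrix()
        moved = coords @ R.T + np.array([5.0, -3.0, 1.0])
        traj = _two_frame_traj(helical_system, moved)
        mt = project_onto_modes(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        assert mt.q[j, 0] == pytest.approx(a, abs=1e-8)
        others = np.abs(mt.q[:, 0])
        others[j] = 0.0
        assert others.max() < 1e-8

    def test_minus_helicity_frames_use_minus_reference(self, helical_system):
        traj = _two_frame_traj(helical_system, helical_system.refs.x_ref_minus)
        mt = project_onto_modes(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        assert np.all(mt.helicity_used == -1)
        assert np.abs(mt.q).max() < 1e-10


class TestDipoleDecomposition:
    def test_static_reference_molecule(self, helical_system):
        traj = _two_frame_traj(helical_system, helical_system.refs.x_ref_minus)
        dec = decompose_dipole(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        assert np.allclose(dec.mu_total, dec.mu_rb, atol=1e-10)
        assert np.abs(dec.mu_vib).max() < 1e-10
        assert np.abs(dec.residual).max() < 1e-10

    def test_linear_regime_frame_by_frame(self, helical_system):
        """|mu_vib_k| = |mu_k| |q_k| for small single-mode motion, with
        residual far below the total dipole."""
        j = 40
        amps = 0.03 * np.sin(np.linspace(0, 2 * np.pi, 16))
        coords = np.stack(
            [
                helical_system.refs.x_ref_plus
                + a * helical_system.modes_plus.cart_disp[j]
                for a in amps
            ]
        )
        traj = Trajectory(
            coords, 1.0, helical_system.masses, helical_system.charges
        )
        dec = decompose_dipole(
            traj,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        mu_k = helical_system.modes_plus.transition_dipoles[j]
        expected = np.abs(amps) * np.linalg.norm(mu_k)
        measured = np.linalg.norm(dec.mu_vib[j], axis=1)
        assert np.allclose(measured, expected, atol=1e-12)
        assert (
            np.abs(dec.residual).max()
            < 1e-6 * np.abs(dec.mu_total).max()
        )

    def test_eckart_decomposition_is_exact_at_any_amplitude(self, helical_system):
        """With the mass-weighted all-atom fit the optimality conditions
        coincide with the Eckart conditions, so the fitted displacement
        has no rigid component and the point-charge dipole decomposes
        exactly -- even for large-amplitude motion."""
        for a in (0.05, 0.4, 1.0):
            coords = helical_system.refs.x_ref_plus + a * (
                helical_system.modes_plus.cart_disp[40]
                + helical_system.modes_plus.cart_disp[20]
            )
            traj = _two_frame_traj(helical_system, coords)
            dec = decompose_dipole(
                traj,
                helical_system.refs,
                helical_system.modes_minus,
                helical_system.modes_plus,
            )
            assert np.abs(dec.residual).max() < 1e-12

    def test_carbon_fit_residual_grows_linearly(self, helical_system):
        """The unit-weight carbon-subset fit (the usual choice for
        force-field trajectories) leaks a first-order rigid-rotation
        component into the fitted displacement, so its decomposition
        residual grows linearly with displacement amplitude."""
        amps = np.geomspace(0.02, 0.4, 6)
        residuals = []
        for a in amps:
            coords = helical_system.refs.x_ref_plus + a * (
                helical_system.modes_plus.cart_disp[40]
                + helical_system.modes_plus.cart_disp[20]
                + helical_system.modes_plus.cart_disp[10]
            )
            traj = _two_frame_traj(helical_system, coords)
            dec = decompose_dipole(
                traj,
                helical_system.refs,
                helical_system.modes_minus,
                helical_system.modes_plus,
                fit="carbons",
            )
            residuals.append(np.linalg.norm(dec.residual[0]))
        slope = np.polyfit(np.log(amps), np.log(residuals), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestModeSpectra:
    def test_two_separated_modes_decompose_within_1_percent(self, helical_system):
        cfg = GeneratorConfig(n_steps=2**15, flip_rate=0.0, seed=7)
        dyn = gen_mode_dynamics(cfg, system=helical_system)
        dec = decompose_dipole(
            dyn.trajectory,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
            mode_indices=np.array([40, 47]),
        )
        out = mode_spectra(dec, nperseg=4096)
        assert out["cross_term_fraction"] < 0.01
        total_int = out["total_vib"].integrate()
        sum_int = out["sum_of_modes"].integrate()
        assert sum_int == pytest.approx(total_int, rel=0.01)

    def test_correlated_degenerate_modes_flagged(self):
        """Two modes driven by the same forcing produce a large
        cross-term, reported rather than hidden."""
        rng = np.random.default_rng(0)
        T, dt = 2**14, 1.0
        q = langevin_mode(1100.0, 2.0, 1.0, T, dt, rng)
        mu = np.array([[1.0, 0.0, 0.0], [0.8, 0.6, 0.0]])
        from fluorspec.projection import DipoleDecomposition

        mu_vib = np.stack([np.outer(q, mu[0]), np.outer(q, mu[1])])
        dec = DipoleDecomposition(
            mu_total=mu_vib.sum(axis=0),
            mu_rb=np.zeros((T, 3)),
            mu_vib=mu_vib,
            residual=np.zeros((T, 3)),
            dt=dt,
            frequencies=np.array([1100.0, 1100.0]),
        )
        out = mode_spectra(dec, nperseg=2048)
        assert out["cross_term_fraction"] > 0.05


class TestHelicityFrozenSpectrum:
    def test_no_flips_full_equals_frozen(self, helical_system):
        cfg = GeneratorConfig(n_steps=2**16, flip_rate=0.0, seed=3)
        dyn = gen_mode_dynamics(cfg, system=helical_system)
        k_local = int(np.argmax(np.linalg.norm(dyn.mu_plus, axis=1)))
        full = masked_power_spectrum(
            dyn.mode_dipole_trace(k_local), cfg.dt, nperseg=4096, derivative=True
        )
        mu2 = np.sum(dyn.mu_minus[k_local] ** 2)
        s_q = masked_power_spectrum(
            dyn.q[k_local], cfg.dt, nperseg=4096, derivative=True
        )
        assert np.allclose(full.values, mu2 * s_q.values, rtol=1e-8)

    def test_zero_rotation_angle_no_difference(self, helical_system):
        cfg = GeneratorConfig(
            n_steps=2**16, flip_rate=1.0, dipole_rotation_angle=0.0, seed=3
        )
        dyn = gen_mode_dynamics(cfg, system=helical_system)
        k_local = int(np.argmax(np.linalg.norm(dyn.mu_plus, axis=1)))
        full = masked_power_spectrum(
            dyn.mode_dipole_trace(k_local), cfg.dt, nperseg=4096, derivative=True
        )
        mu2 = np.sum(dyn.mu_minus[k_local] ** 2)
        s_q = masked_power_spectrum(
            dyn.q[k_local], cfg.dt, nperseg=4096, derivative=True
        )
        assert np.allclose(full.values, mu2 * s_q.values, rtol=1e-8)

    def test_helicity_frozen_spectrum_op(self, helical_system):
        cfg = GeneratorConfig(n_steps=2**15, flip_rate=0.0, seed=5)
        dyn = gen_mode_dynamics(cfg, system=helical_system)
        mt = project_onto_modes(
            dyn.trajectory,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        k = int(dyn.mode_indices[-1])
        spec = helicity_frozen_spectrum(
            mt, helical_system.modes_minus, k, nperseg=4096
        )
        assert spec.metadata["frozen"]
        nu0 = helical_system.modes_plus.frequencies[k]
        assert abs(spec.nu[np.argmax(spec.values)] - nu0) < 10.0


def _telegraph_dipole(nu0, gamma_ps, k_ps, angle_deg, T, dt, rng):
    """Mode-level dipole with telegraph-rotated transition dipole."""
    q = langevin_mode(nu0, gamma_ps, 1.0, T, dt, rng)
    h, times = telegraph_process(k_ps, T, dt, rng)
    mu_p = np.array([1.0, 0.0, 0.0])
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    mu_m = np.array([c, s, 0.0])
    mu = np.where((h > 0)[:, None], mu_p[None], mu_m[None]) * q[:, None]
    return mu, q, times


class TestBroadeningMechanism:
    def test_fwhm_excess_matches_telegraph_rate(self):
        """180-degree dipole rotation at telegraph rate k broadens the
        vibrational band by 4k/(2 pi c) on top of the frozen width."""
        from fluorspec.pipeline import _spectrum_fwhm

        rng = np.random.default_rng(11)
        T, dt, nu0, gamma = 2**19, 1.0, 1218.0, 0.5
        k = 0.6  # per ps
        n_mol = 6
        acc_full = acc_frozen = None
        for _ in range(n_mol):
            mu, q, _ = _telegraph_dipole(nu0, gamma, k, 180.0, T, dt, rng)
            s_full = masked_power_spectrum(mu, dt, nperseg=2**16, derivative=True)
            s_frozen = masked_power_spectrum(q, dt, nperseg=2**16, derivative=True)
            acc_full = s_full.values if acc_full is None else acc_full + s_full.values
            acc_frozen = (
                s_frozen.values if acc_frozen is None else acc_frozen + s_frozen.values
            )
        from fluorspec.spectra import Spectrum

        full = Spectrum(s_full.nu, acc_full / n_mol, "power")
        frozen = Spectrum(s_frozen.nu, acc_frozen / n_mol, "power")
        f_full, _ = _spectrum_fwhm(full, nu0, "full")
        f_frozen, _ = _spectrum_fwhm(frozen, nu0, "frozen")
        expected = 4.0 * (k / 1000.0) / (2.0 * np.pi * C_CM_PER_FS)
        assert f_full - f_frozen == pytest.approx(expected, rel=0.10)

    def test_event_aligned_acf_reverses_sign_at_180deg_flip(self):
        """A 180-degree dipole reversal makes the conditional ACF flip
        sign at the event: correlation before the flip, anticorrelation
        after."""
        rng = np.random.default_rng(4)
        T, dt = 2**18, 1.0
        mu, q, times = _telegraph_dipole(1218.0, 0.5, 0.5, 180.0, T, dt, rng)
        out = event_aligned_acf(mu, times, dt, offset=200.0, window=2000.0)
        assert out.n_events >= 20
        t = out.t_fs
        before = t < 150.0
        after = (t > 300.0) & (t < 800.0)
        cc_before = np.corrcoef(out.conditional[before], out.unconditional[before])[0, 1]
        cc_after = np.corrcoef(out.conditional[after], out.unconditional[after])[0, 1]
        assert cc_before > 0.9
        assert cc_after < -0.9

    def test_event_aligned_envelope_collapses_at_90deg_flip(self):
        """At 90 degrees the rotated dipole is orthogonal to the
        original, so the conditional envelope collapses after the
        event."""
        rng = np.random.default_rng(4)
        T, dt = 2**18, 1.0
        mu, q, times = _telegraph_dipole(1218.0, 0.5, 0.5, 90.0, T, dt, rng)
        out = event_aligned_acf(mu, times, dt, offset=200.0, window=2000.0)
        t = out.t_fs
        after = (t > 300.0) & (t < 800.0)
        assert (
            out.conditional_envelope[after].mean()
            < 0.5 * out.unconditional_envelope[after].mean()
        )

    def test_event_aligned_acf_with_0deg_rotation_matches_unconditional(self):
        rng = np.random.default_rng(4)
        T, dt = 2**18, 1.0
        mu, q, times = _telegraph_dipole(1218.0, 0.5, 0.5, 0.0, T, dt, rng)
        out = event_aligned_acf(mu, times, dt, offset=200.0, window=2000.0)
        diff = np.abs(out.conditional - out.unconditional)
        # single-origin conditional averages are noisy; compare coarse
        # envelopes
        assert (
            np.mean(out.conditional_envelope)
            == pytest.approx(np.mean(out.unconditional_envelope), rel=0.25)
        )

    def test_no_events_warns_and_returns_unconditional_decay(self):
        rng = np.random.default_rng(2)
        T, dt, gamma = 2**20, 1.0, 0.5
        q = langevin_mode(1218.0, gamma, 1.0, T, dt, rng)
        mu = np.outer(q, [1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="no usable events"):
            out = event_aligned_acf(mu, np.array([]), dt, window=4000.0)
        assert out.conditional is None
        # the damped-cosine ACF envelope decays at gamma/2 within 5 %
        t = out.t_fs
        sel = (t > 100.0) & (t < 1500.0)
        rate = -np.polyfit(
            t[sel], np.log(np.abs(out.unconditional_envelope[sel])), 1
        )[0]
        assert rate == pytest.approx(gamma / 2000.0, rel=0.05)


class TestRotationInvariance:
    def test_spectra_invariant_under_global_rotation(self, helical_system, rng):
        cfg = GeneratorConfig(n_steps=2**13, flip_rate=0.0, seed=9)
        dyn = gen_mode_dynamics(cfg, system=helical_system)
        R = Rotation.random(rng=rng).as_matrix()
        rotated = Trajectory(
            np.einsum("xy,tay->tax", R, dyn.trajectory.coordinates.astype(float)),
            cfg.dt,
            helical_system.masses,
            helical_system.charges,
        )
        mt0 = project_onto_modes(
            dyn.trajectory,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        mt1 = project_onto_modes(
            rotated,
            helical_system.refs,
            helical_system.modes_minus,
            helical_system.modes_plus,
        )
        s0 = power_spectrum(mt0.q[40], dt=cfg.dt, window="hann")
        s1 = power_spectrum(mt1.q[40], dt=cfg.dt, window="hann")
        assert np.allclose(s0.values, s1.values, rtol=1e-4, atol=1e-10 * s0.values.max())
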