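"""Spin-dynamics unit and property tests.

Closed-form oracles: the ESR relation from CODATA constants, the
hyperfine eigenstructure of a two-spin-1/2 contact coupling, and a
restricted S/T0-subspace yield computation for the high-field plateau.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import constants as codata

from rydmr.constants import G_FREE_ELECTRON, esr_field, gamma_mhz_per_mt
from rydmr.errors import (IntegrationError, InvalidParameterError,
                          SpinSpaceSizeError)
from rydmr.spin_core import (FieldConfig, RadicalPairSystem,
                             build_hamiltonian, hamiltonian_parts,
                             initial_density, mary_curve, propagate,
                             rydmr_spectrum, singlet_projector,
                             singlet_yield, triplet_projector)


def closed_form_esr_mt(f_mhz, g):
    """Independent oracle: B0 = h f / (g muB), straight from CODATA."""
    return codata.h * f_mhz * 1e6 / (g * codata.value("Bohr magneton")) * 1e3


class TestEsrField:
    @pytest.mark.parametrize("f_mhz", [0.0, 300.0, 447.0, 450.0, 600.0])
    def test_matches_closed_form(self, f_mhz):
        assert esr_field(f_mhz) == pytest.approx(
            closed_form_esr_mt(f_mhz, G_FREE_ELECTRON), rel=1e-12)

    def test_printed_values(self):
        # 447 MHz -> 15.95 mT; 450 MHz -> 16.06 mT
        assert esr_field(447.0) == pytest.approx(15.95, abs=0.005)
        assert esr_field(450.0) == pytest.approx(16.06, abs=0.005)

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            gamma_mhz_per_mt(0.0)
        with pytest.raises(ValueError):
            gamma_mhz_per_mt(-2.0)


class TestHamiltonian:
    def test_pure_zeeman_diagonal(self):
        sys0 = RadicalPairSystem(hf1=(), hf2=())
        h = build_hamiltonian(sys0, FieldConfig(b0=10.0))
        off_diag = h - np.diag(np.diag(h))
        assert np.allclose(off_diag, 0)
        # splitting between adjacent electron Zeeman levels = gamma * B0
        evals = np.sort(np.linalg.eigvalsh(h))
        gamma = gamma_mhz_per_mt(G_FREE_ELECTRON)
        assert evals[-1] - evals[0] == pytest.approx(2 * gamma * 10.0,
                                                     rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(b0=st.floats(0, 30), b1=st.floats(0, 1), a=st.floats(0.1, 3),
           theta=st.floats(0, np.pi / 2), t=st.floats(0, 1e-8))
    def test_hermitian(self, b0, b1, a, theta, t):
        sys1 = RadicalPairSystem(hf1=(a,), hf2=())
        h = build_hamiltonian(sys1, FieldConfig(b0=b0, b1=b1, theta=theta,
                                                rf_on=b1 > 0), t=t)
        assert np.allclose(h, h.conj().T)

    def test_single_nucleus_zero_field_spectrum(self):
        # one proton, a = 1 mT, B0 = 0: contact coupling a*S1.I gives the
        # two-spin-1/2 manifold  {+a/4 (triplet), -3a/4 (singlet)}, each
        # doubled by the spectator electron
        sys1 = RadicalPairSystem(hf1=(1.0,), hf2=())
        h = build_hamiltonian(sys1, FieldConfig(b0=0.0))
        gamma = gamma_mhz_per_mt(G_FREE_ELECTRON)
        evals = np.sort(np.linalg.eigvalsh(h))
        expected = np.sort([gamma * 0.25] * 6 + [-gamma * 0.75] * 2)
        assert np.allclose(evals, expected, atol=1e-9)

    def test_nuclear_cap(self):
        with pytest.raises(SpinSpaceSizeError):
            RadicalPairSystem(hf1=(1.0, 1.0, 1.0), hf2=(1.0, 1.0))

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            RadicalPairSystem(k_s=-1.0)
        with pytest.raises(InvalidParameterError):
            RadicalPairSystem(g1=3.0)
        with pytest.raises(InvalidParameterError):
            FieldConfig(b0=-1.0)


class TestPropagate:
    def test_closed_system_conserves_trace(self):
        sys0 = RadicalPairSystem(hf1=(1.0,), hf2=(), k_s=0.0, k_t=0.0)
        tr = propagate(sys0, FieldConfig(b0=1.0), t_max=5e-8)
        assert np.allclose(tr.trace, 1.0, atol=1e-9)

    def test_rf_flag_with_zero_b1_is_identity(self):
        sys1 = RadicalPairSystem(hf1=(1.0,), hf2=())
        a = propagate(sys1, FieldConfig(b0=2.0, b1=0.0, rf_on=True),
                      t_max=5e-8)
        b = propagate(sys1, FieldConfig(b0=2.0, b1=0.0, rf_on=False),
                      t_max=5e-8)
        assert np.allclose(a.p_singlet, b.p_singlet, atol=1e-12)

    @pytest.mark.parametrize("hf1,hf2", [((1.0,), ()), ((1.0,), (0.5,))])
    def test_expm_and_rk4_agree(self, hf1, hf2):
        """Matrix-exponential and fine-step propagation as mutual oracles."""
        sys_ = RadicalPairSystem(hf1=hf1, hf2=hf2)
        cfg = FieldConfig(b0=2.0)
        y1 = propagate(sys_, cfg, t_max=3e-7, dt=2e-10,
                       integrator="expm").yields(sys_)
        y2 = propagate(sys_, cfg, t_max=3e-7, dt=2e-10,
                       integrator="rk4").yields(sys_)
        assert abs(y1.phi_s - y2.phi_s) < 1e-6
        assert abs(y1.phi_t - y2.phi_t) < 1e-6

    def test_unknown_integrator(self):
        with pytest.raises(InvalidParameterError):
            propagate(RadicalPairSystem(), FieldConfig(), t_max=1e-8,
                      integrator="euler")


class TestSingletYield:
    def test_no_mixing_channels(self):
        # without hyperfine, RF or relaxation there is no S-T interconversion
        singlet_born = RadicalPairSystem(hf1=(), hf2=(),
                                         initial_state="singlet")
        y = singlet_yield(singlet_born, FieldConfig(b0=5.0))
        assert y.phi_s == pytest.approx(1.0, abs=1e-9)
        triplet_born = RadicalPairSystem(hf1=(), hf2=(),
                                         initial_state="triplet")
        y = singlet_yield(triplet_born, FieldConfig(b0=5.0))
        assert y.phi_s == pytest.approx(0.0, abs=1e-9)

    def test_resolvent_matches_fine_grid_integration(self):
        """Infinite-time resolvent vs brute-force dense time-grid integral."""
        sys_ = RadicalPairSystem(hf1=(1.0,), hf2=(), k_s=3e7, k_t=3e7,
                                 initial_state="singlet")
        exact = singlet_yield(sys_, FieldConfig(b0=0.0))
        # window of 12 recombination lifetimes leaves a ~1e-6 tail
        brute = singlet_yield(sys_, FieldConfig(b0=0.0), t_max=4e-7)
        assert exact.phi_s == pytest.approx(brute.phi_s, abs=1e-4)

    @pytest.mark.parametrize("b0", [0.0, 2.0, 15.95, 30.0])
    def test_yield_conservation(self, default_system, b0):
        y = singlet_yield(default_system, FieldConfig(b0=b0))
        assert y.phi_s + y.phi_t + y.phi_relax == pytest.approx(1.0,
                                                                abs=1e-6)


class TestMaryCurve:
    def test_no_hyperfine_flat(self):
        sys0 = RadicalPairSystem(hf1=(), hf2=())
        df = mary_curve(sys0, [0.0, 5.0, 10.0, 20.0])
        assert np.ptp(df.phi_s.values) < 1e-9

    def test_triplet_born_decreases_to_plateau(self, default_system):
        grid = np.array([0.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0, 30.0])
        phi = mary_curve(default_system, grid).phi_s.values
        assert phi[-1] < phi[0]          # high field below zero field
        # monotone decrease once B0 exceeds all hyperfine couplings
        beyond = phi[grid >= 1.5]
        assert np.all(np.diff(beyond) <= 1e-6)

    def test_empty_grid_rejected(self, default_system):
        with pytest.raises(InvalidParameterError):
            mary_curve(default_system, [])

    def test_plateau_matches_restricted_subspace(self, one_proton):
        """High-field yields reduce to an S/T0 two-level computation."""
        b0 = 50.0
        full = singlet_yield(one_proton, FieldConfig(b0=b0)).phi_s

        h0, _ = hamiltonian_parts(one_proton, FieldConfig(b0=b0))
        up, dn = np.array([1.0, 0]), np.array([0, 1.0])
        s_vec = (np.kron(up, dn) - np.kron(dn, up)) / np.sqrt(2)
        t0_vec = (np.kron(up, dn) + np.kron(dn, up)) / np.sqrt(2)
        basis = np.zeros((8, 4))
        for j, e in enumerate((s_vec, t0_vec)):
            for k in range(2):
                nuc = np.zeros(2)
                nuc[k] = 1.0
                basis[:, 2 * j + k] = np.kron(e, nuc)
        h_r = basis.T @ h0 @ basis
        p_s = basis.T @ singlet_projector(one_proton) @ basis
        p_t = basis.T @ triplet_projector(one_proton) @ basis
        ident = np.eye(4)
        lv = -2j * np.pi * (np.kron(h_r, ident) - np.kron(ident, h_r.T))
        for k, proj in ((one_proton.k_s * 1e-6, p_s),
                        (one_proton.k_t * 1e-6, p_t)):
            lv -= 0.5 * k * (np.kron(proj, ident) + np.kron(ident, proj.T))
        rho0 = basis.T @ initial_density(one_proton) @ basis
        x = np.linalg.solve(lv, -rho0.reshape(-1))
        phi_restricted = one_proton.k_s * 1e-6 * np.real(
            p_s.reshape(-1) @ x)
        assert full == pytest.approx(phi_restricted, rel=5e-3)


class TestRydmrSpectrum:
    def test_zero_b1_gives_zero_difference(self, one_proton):
        df = rydmr_spectrum(one_proton, [14.0, 15.95, 18.0], b1=0.0,
                            f_rf=447.0)
        assert np.allclose(df.dphi_s.values, 0.0)

    def test_extremum_at_esr_field(self, one_proton):
        res = esr_field(447.0)
        grid = np.arange(res - 1.5, res + 1.55, 0.25)
        df = rydmr_spectrum(one_proton, grid, b1=0.25, f_rf=447.0)
        peak_b0 = df.b0_mT[df.dphi_s.abs().idxmax()]
        assert abs(peak_b0 - res) <= 0.25

    def test_parallel_drive_is_flat(self, one_proton):
        res = esr_field(447.0)
        grid = np.arange(res - 1.0, res + 1.05, 0.5)
        perp = rydmr_spectrum(one_proton, grid, b1=0.25, f_rf=447.0,
                              theta=np.pi / 2)
        par = rydmr_spectrum(one_proton, grid, b1=0.25, f_rf=447.0,
                             theta=0.0)
        ratio = par.dphi_s.abs().max() / perp.dphi_s.abs().max()
        assert ratio < 0.05

    def test_weak_drive_amplitude_monotone(self, one_proton):
        res = esr_field(447.0)
        amps = []
        off = singlet_yield(one_proton, FieldConfig(b0=res)).phi_s
        for b1 in (0.07, 0.15, 0.25, 0.37):
            on = singlet_yield(one_proton,
                               FieldConfig(b0=res, b1=b1, f_rf=447.0,
                                           rf_on=True)).phi_s
            amps.append(on - off)
        assert np.all(np.diff(amps) >= 0)

    def test_weak_drive_fwhm_monotone(self, one_proton):
        res = esr_field(447.0)
        grid = np.arange(res - 2.0, res + 2.05, 0.25)
        widths = []
        for b1 in (0.1, 0.25, 0.4):
            df = rydmr_spectrum(one_proton, grid, b1=b1, f_rf=447.0)
            y = df.dphi_s.values
            half = y.max() / 2
            above = grid[y >= half]
            widths.append(above[-1] - above[0])
        assert np.all(np.diff(widths) >= 0)

    def test_rotating_frame_matches_floquet_at_resonance(self, one_proton):
        res = esr_field(447.0)
        cfg = FieldConfig(b0=res, b1=0.25, f_rf=447.0, rf_on=True)
        full = singlet_yield(one_proton, cfg, method="floquet")
        fast = singlet_yield(one_proton, cfg, method="rotating")
        assert fast.phi_s == pytest.approx(full.phi_s, abs=5e-3)
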