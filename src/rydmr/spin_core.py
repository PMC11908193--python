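"""Spin-correlated radical-pair dynamics under static and RF magnetic fields.

Model
-----
Two electron spins (one per radical), each optionally hyperfine-coupled to
spin-1/2 nuclei, evolve in Liouville space under

    H(t) = g1*muB/h * B0 * S1z + g2*muB/h * B0 * S2z
         + sum_i a_i * gamma_host * I_i . S_host
         + B1 * sin(2*pi*f_RF*t) * (gamma_1 * S1 + gamma_2 * S2) . n_hat

with spin-selective Haberkorn recombination (rate kS on the singlet
projector, kT on the triplet projector) and an optional isotropic
depolarizing relaxation channel at rate kRelax.  Exchange and dipolar
couplings are fixed at zero.  Internally fields are in mT, frequencies in
MHz and time in microseconds.

Reaction yields are the time-integrated recombination fluxes

    phiS = kS * int Tr(P_S rho(t)) dt,    phiT = kT * int Tr(P_T rho(t)) dt.

For time-independent Hamiltonians (RF off) the infinite-time yields are
obtained exactly from the Liouvillian resolvent, int_0^inf rho dt =
-L^{-1} rho(0).  With RF on, the reference path builds a stroboscopic
one-RF-period propagator from piecewise-constant matrix exponentials and
sums the geometric series over periods; a rotating-frame secular
approximation (valid for B1 << B0 and B0 large against the hyperfine
couplings, theta = pi/2) is available as a fast path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .constants import G_FREE_ELECTRON, esr_field, gamma_mhz_per_mt
from .errors import IntegrationError, InvalidParameterError, SpinSpaceSizeError

__all__ = [
    "RadicalPairSystem",
    "FieldConfig",
    "YieldResult",
    "Trajectory",
    "esr_field",
    "build_hamiltonian",
    "hamiltonian_parts",
    "propagate",
    "singlet_yield",
    "mary_curve",
    "rydmr_spectrum",
]

_INITIAL_STATES = ("singlet", "triplet", "T0")

#: Default number of piecewise-constant sub-steps per RF period.
RF_STEPS_PER_PERIOD = 32


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RadicalPairSystem:
    """A two-radical spin system with isotropic hyperfine couplings.

    Parameters
    ----------
    g1, g2:
        Electron g-factors (dimensionless, within [1.5, 2.5]).
    hf1, hf2:
        Isotropic hyperfine coupling constants (mT), one per spin-1/2
        nucleus on radical 1 / radical 2.
    k_s, k_t:
        Singlet / triplet recombination rate constants (s^-1).
    k_relax:
        Isotropic spin relaxation (depolarization) rate (s^-1).
    initial_state:
        "singlet", "triplet" (equal incoherent T-1/T0/T+1 mixture, the
        default, matching a triplet-born pair) or "T0".
    max_nuclei:
        Cap on the total nucleus count; keeps the joint Hilbert space
        desk-scale (dimension 4 * 2**n <= 64 at the default cap of 4).
    """

    g1: float = G_FREE_ELECTRON
    g2: float = G_FREE_ELECTRON
    hf1: tuple[float, ...] = (1.0,)
    hf2: tuple[float, ...] = (0.5,)
    k_s: float = 3.0e7
    k_t: float = 3.0e6
    k_relax: float = 0.0
    initial_state: str = "triplet"
    max_nuclei: int = 4

    def __post_init__(self):
        object.__setattr__(self, "hf1", tuple(float(a) for a in self.hf1))
        object.__setattr__(self, "hf2", tuple(float(a) for a in self.hf2))
        for name in ("k_s", "k_t", "k_relax"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("g1", "g2"):
            g = getattr(self, name)
            if not (1.5 <= g <= 2.5):
                raise InvalidParameterError(
                    f"{name}={g} outside the physical window [1.5, 2.5]")
        if self.initial_state not in _INITIAL_STATES:
            raise InvalidParameterError(
                f"initial_state must be one of {_INITIAL_STATES}")
        if self.n_nuclei > self.max_nuclei:
            raise SpinSpaceSizeError(
                f"{self.n_nuclei} nuclei exceed the cap of {self.max_nuclei}")

    @property
    def n_nuclei(self) -> int:
        return len(self.hf1) + len(self.hf2)

    @property
    def dim(self) -> int:
        """Joint electron-nuclear Hilbert-space dimension."""
        return 4 * 2 ** self.n_nuclei


@dataclass(frozen=True)
class FieldConfig:
    """Static + RF magnetic field settings.

    theta is the angle between B0 and B1 (0 = parallel, pi/2 =
    perpendicular); B0 defines the laboratory z axis.
    """

    b0: float = 0.0          # mT
    b1: float = 0.0          # mT
    f_rf: float = 447.0      # MHz
    theta: float = np.pi / 2  # rad
    rf_on: bool = False

    def __post_init__(self):
        if self.b0 < 0 or self.b1 < 0:
            raise InvalidParameterError("B0 and B1 must be non-negative")
        if self.rf_on and self.f_rf <= 0:
            raise InvalidParameterError("f_rf must be positive when RF is on")
        if not (0.0 <= self.theta <= np.pi / 2 + 1e-12):
            raise InvalidParameterError("theta must lie in [0, pi/2]")


@dataclass(frozen=True)
class YieldResult:
    """Recombination yields of a radical pair.

    phi_relax is the fraction that did not recombine through either
    spin-selective channel within the integration window (zero for the
    infinite-time resolvent solution whenever both rates are positive).
    """

    phi_s: float
    phi_t: float
    phi_relax: float
    t_grid: np.ndarray | None = None

    def __post_init__(self):
        total = self.phi_s + self.phi_t + self.phi_relax
        if not np.isclose(total, 1.0, atol=1e-6):
            raise IntegrationError(
                f"yields sum to {total:.8f}, outside 1 +/- 1e-6")


@dataclass(frozen=True)
class Trajectory:
    """Density-operator trajectory summary from :func:`propagate`."""

    t: np.ndarray            # microseconds
    p_singlet: np.ndarray    # Tr(P_S rho(t))
    p_triplet: np.ndarray    # Tr(P_T rho(t))
    trace: np.ndarray        # Tr rho(t)
    rho_final: np.ndarray

    def yields(self, system: RadicalPairSystem) -> YieldResult:
        """Integrate recombination fluxes over the stored window."""
        from scipy.integrate import simpson
        phi_s = system.k_s * 1e-6 * float(simpson(self.p_singlet, x=self.t))
        phi_t = system.k_t * 1e-6 * float(simpson(self.p_triplet, x=self.t))
        return YieldResult(phi_s, phi_t, float(self.trace[-1]),
                           t_grid=self.t * 1e-6)


# --------------------------------------------------------------------------
# operators
# --------------------------------------------------------------------------

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)


@lru_cache(maxsize=32)
def _site_operators(n_spins: int):
    """Cartesian spin-1/2 operators for each site of an n-spin register."""
    ops = []
    for i in range(n_spins):
        triple = []
        for s in (_SX, _SY, _SZ):
            op = np.array([[1.0 + 0j]])
            for j in range(n_spins):
                op = np.kron(op, s if j == i else np.eye(2))
            triple.append(op)
        ops.append(tuple(triple))
    return tuple(ops)


@lru_cache(maxsize=64)
def _projectors(n_nuclei: int):
    """Singlet/triplet electron projectors on the joint space."""
    ops = _site_operators(2 + n_nuclei)
    s1, s2 = ops[0], ops[1]
    dim = 4 * 2 ** n_nuclei
    s1_dot_s2 = sum(a @ b for a, b in zip(s1, s2))
    p_s = 0.25 * np.eye(dim) - s1_dot_s2
    p_t = np.eye(dim) - p_s
    return p_s.real, p_t.real


def singlet_projector(system: RadicalPairSystem) -> np.ndarray:
    return _projectors(system.n_nuclei)[0]


def triplet_projector(system: RadicalPairSystem) -> np.ndarray:
    return _projectors(system.n_nuclei)[1]


def initial_density(system: RadicalPairSystem) -> np.ndarray:
    """Initial density operator (unit trace) for the configured spin state."""
    n = system.n_nuclei
    p_s, p_t = _projectors(n)
    if system.initial_state == "singlet":
        rho = p_s
    elif system.initial_state == "triplet":
        rho = p_t
    else:  # T0: |T0><T0| on the electrons, maximally mixed nuclei
        t0 = np.zeros(4)
        t0[1] = t0[2] = 1 / np.sqrt(2)  # (|ud> + |du>)/sqrt2
        rho = np.kron(np.outer(t0, t0), np.eye(2 ** n))
    return (rho / np.trace(rho)).astype(complex)


def hamiltonian_parts(system: RadicalPairSystem, field: FieldConfig):
    """Static part H0 and RF amplitude part H1 of the Hamiltonian (MHz).

    The full Hamiltonian is ``H(t) = H0 + sin(2*pi*f_RF*t) * H1`` with H1
    identically zero when the RF drive is off or B1 = 0.
    """
    n = system.n_nuclei
    ops = _site_operators(2 + n)
    g = (gamma_mhz_per_mt(system.g1), gamma_mhz_per_mt(system.g2))
    electrons = (ops[0], ops[1])

    h0 = field.b0 * (g[0] * electrons[0][2] + g[1] * electrons[1][2])
    site = 2
    for radical, couplings in enumerate((system.hf1, system.hf2)):
        for a in couplings:
            h0 = h0 + g[radical] * a * sum(
                si @ ii for si, ii in zip(electrons[radical], ops[site]))
            site += 1

    if field.rf_on and field.b1 > 0:
        ax = np.sin(field.theta)
        az = np.cos(field.theta)
        h1 = field.b1 * (
            g[0] * (ax * electrons[0][0] + az * electrons[0][2])
            + g[1] * (ax * electrons[1][0] + az * electrons[1][2]))
    else:
        h1 = np.zeros_like(h0)
    return h0, h1


def build_hamiltonian(system: RadicalPairSystem, field: FieldConfig,
                      t: float = 0.0) -> np.ndarray:
    """Hamiltonian (MHz) on the joint space at laboratory time t (seconds)."""
    h0, h1 = hamiltonian_parts(system, field)
    if field.rf_on and field.b1 > 0:
        return h0 + np.sin(2 * np.pi * field.f_rf * 1e6 * t) * h1
    return h0


# --------------------------------------------------------------------------
# Liouvillians (row-major vectorization: vec(A rho B) = (A kron B^T) vec rho)
# --------------------------------------------------------------------------

def _liouvillian(system: RadicalPairSystem, h: np.ndarray) -> np.ndarray:
    dim = h.shape[0]
    ident = np.eye(dim)
    lv = _coherent_part(h)
    p_s, p_t = _projectors(system.n_nuclei)
    for k, proj in ((system.k_s * 1e-6, p_s), (system.k_t * 1e-6, p_t)):
        if k:
            lv = lv - 0.5 * k * (np.kron(proj, ident) + np.kron(ident, proj.T))
    kr = system.k_relax * 1e-6
    if kr:
        vec_i = ident.reshape(-1)
        lv = lv - kr * (np.eye(dim * dim)
                        - np.outer(vec_i, vec_i) / dim)
    return lv


def _coherent_part(h: np.ndarray) -> np.ndarray:
    ident = np.eye(h.shape[0])
    return -2j * np.pi * (np.kron(h, ident) - np.kron(ident, h.T))


def _trace_vector(dim: int) -> np.ndarray:
    return np.eye(dim).reshape(-1)


def _solve_or_lstsq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        x = np.linalg.solve(a, b)
        if np.all(np.isfinite(x)):
            return x
    except np.linalg.LinAlgError:
        pass
    # singular Liouvillian: population trapped in a non-recombining subspace;
    # the least-squares solution integrates only the decaying component
    return np.linalg.lstsq(a, b, rcond=None)[0]


def _resolvent_yields(system: RadicalPairSystem, lv: np.ndarray,
                      rho0: np.ndarray) -> YieldResult:
    p_s, p_t = _projectors(system.n_nuclei)
    x = _solve_or_lstsq(lv, -rho0.reshape(-1))
    phi_s = system.k_s * 1e-6 * float(np.real(p_s.reshape(-1) @ x))
    phi_t = system.k_t * 1e-6 * float(np.real(p_t.reshape(-1) @ x))
    phi_s = min(max(phi_s, 0.0), 1.0)
    phi_t = min(max(phi_t, 0.0), 1.0)
    return YieldResult(phi_s, phi_t, max(0.0, 1.0 - phi_s - phi_t))


# --------------------------------------------------------------------------
# stroboscopic RF-period propagator
# --------------------------------------------------------------------------

def _step_expm_with_integral(lv: np.ndarray, dt: float):
    """exp(L dt) together with int_0^dt exp(L s) ds via a block exponential."""
    d2 = lv.shape[0]
    block = np.zeros((2 * d2, 2 * d2), dtype=complex)
    block[:d2, :d2] = lv * dt
    block[:d2, d2:] = np.eye(d2) * dt
    m = expm(block)
    return m[:d2, :d2], m[:d2, d2:]


@lru_cache(maxsize=128)
def _period_maps(system: RadicalPairSystem, field: FieldConfig,
                 n_steps: int = RF_STEPS_PER_PERIOD):
    """One-RF-period propagator P and per-period yield-accumulation rows.

    Returns (P, w_s, w_t) such that, for a state rho at the start of a
    period, the integral of Tr(P_S rho(t)) over that period equals
    ``w_s @ vec(rho)`` (microsecond units), and rho one period later is
    ``P @ vec(rho)``.
    """
    h0, h1 = hamiltonian_parts(system, field)
    l0 = _liouvillian(system, h0)
    l1 = _coherent_part(h1)
    period = 1.0 / field.f_rf  # microseconds (f_rf in MHz)
    dt = period / n_steps
    p_s, p_t = _projectors(system.n_nuclei)
    c_s = p_s.reshape(-1).astype(complex)
    c_t = p_t.reshape(-1).astype(complex)

    prefix = np.eye(l0.shape[0], dtype=complex)
    w_s = np.zeros(l0.shape[0], dtype=complex)
    w_t = np.zeros(l0.shape[0], dtype=complex)
    for k in range(n_steps):
        t_mid = (k + 0.5) * dt
        lk = l0 + np.sin(2 * np.pi * field.f_rf * t_mid) * l1
        e_k, j_k = _step_expm_with_integral(lk, dt)
        w_s += (c_s @ j_k) @ prefix
        w_t += (c_t @ j_k) @ prefix
        prefix = e_k @ prefix
    return prefix, w_s, w_t


def _floquet_yields(system: RadicalPairSystem,
                    field: FieldConfig) -> YieldResult:
    p_period, w_s, w_t = _period_maps(system, field)
    rho0 = initial_density(system).reshape(-1)
    y = _solve_or_lstsq(np.eye(p_period.shape[0]) - p_period, rho0)
    phi_s = system.k_s * 1e-6 * float(np.real(w_s @ y))
    phi_t = system.k_t * 1e-6 * float(np.real(w_t @ y))
    phi_s = min(max(phi_s, 0.0), 1.0)
    phi_t = min(max(phi_t, 0.0), 1.0)
    return YieldResult(phi_s, phi_t, max(0.0, 1.0 - phi_s - phi_t))


# --------------------------------------------------------------------------
# rotating-frame fast path
# --------------------------------------------------------------------------

def _rotating_frame_yields(system: RadicalPairSystem,
                           field: FieldConfig) -> YieldResult:
    """Secular rotating-frame approximation (theta = pi/2, B1 << B0).

    The frame rotates both electrons at f_RF about z; the counter-rotating
    half of the linear drive and the non-secular hyperfine flip-flop terms
    are dropped (valid when B0 exceeds the hyperfine couplings).
    """
    if field.rf_on and abs(field.theta - np.pi / 2) > 1e-6:
        raise InvalidParameterError(
            "rotating-frame path requires theta = pi/2")
    n = system.n_nuclei
    ops = _site_operators(2 + n)
    g = (gamma_mhz_per_mt(system.g1), gamma_mhz_per_mt(system.g2))
    electrons = (ops[0], ops[1])
    f_ref = field.f_rf if field.rf_on else 0.0

    h = ((g[0] * field.b0 - f_ref) * electrons[0][2]
         + (g[1] * field.b0 - f_ref) * electrons[1][2])
    site = 2
    for radical, couplings in enumerate((system.hf1, system.hf2)):
        for a in couplings:
            h = h + g[radical] * a * (electrons[radical][2] @ ops[site][2])
            site += 1
    if field.rf_on and field.b1 > 0:
        h = h + 0.5 * field.b1 * (g[0] * electrons[0][0]
                                  + g[1] * electrons[1][0])
    lv = _liouvillian(system, h)
    return _resolvent_yields(system, lv, initial_density(system))


# --------------------------------------------------------------------------
# public dynamics API
# --------------------------------------------------------------------------

def propagate(system: RadicalPairSystem, field: FieldConfig, t_max: float,
              dt: float | None = None, integrator: str = "expm",
              trace_tol: float = 1e-7) -> Trajectory:
    """Evolve the density operator and record projector populations.

    Parameters
    ----------
    t_max, dt:
        Window and step, in seconds.  dt must resolve the fastest
        frequency present; the default is 1/(40 * f_max).
    integrator:
        "expm" (piecewise matrix exponential, exact per constant step) or
        "rk4" (classical fine-step explicit integration), two independent
        routes used as mutual oracles.
    """
    if t_max <= 0:
        raise InvalidParameterError("t_max must be positive")
    h0, h1 = hamiltonian_parts(system, field)
    rf_active = field.rf_on and field.b1 > 0
    f_max_mhz = max(
        np.max(np.abs(np.linalg.eigvalsh(h0))) * 2,
        field.f_rf if rf_active else 0.0, 1.0)
    t_max_us = t_max * 1e6
    dt_us = (dt * 1e6) if dt is not None else 1.0 / (40 * f_max_mhz)
    if rf_active:
        # snap the step to an integer division of the RF period
        period = 1.0 / field.f_rf
        n_sub = max(int(np.ceil(period / dt_us)), 8)
        dt_us = period / n_sub
    n_steps = max(int(np.ceil(t_max_us / dt_us)), 2)

    l0 = _liouvillian(system, h0)
    p_s, p_t = _projectors(system.n_nuclei)
    c_s, c_t = p_s.reshape(-1), p_t.reshape(-1)
    c_tr = _trace_vector(h0.shape[0])
    rho = initial_density(system).reshape(-1)

    t_out = np.empty(n_steps + 1)
    ps_out = np.empty(n_steps + 1)
    pt_out = np.empty(n_steps + 1)
    tr_out = np.empty(n_steps + 1)

    def record(i, t_us, v):
        t_out[i] = t_us
        ps_out[i] = np.real(c_s @ v)
        pt_out[i] = np.real(c_t @ v)
        tr_out[i] = np.real(c_tr @ v)

    record(0, 0.0, rho)
    if integrator == "expm":
        if rf_active:
            l1 = _coherent_part(h1)
            steps = [expm((l0 + np.sin(2 * np.pi * field.f_rf
                                       * (k + 0.5) * dt_us) * l1) * dt_us)
                     for k in range(n_sub)]
        else:
            steps = [expm(l0 * dt_us)]
        for i in range(1, n_steps + 1):
            rho = steps[(i - 1) % len(steps)] @ rho
            record(i, i * dt_us, rho)
    elif integrator == "rk4":
        l1 = _coherent_part(h1) if rf_active else None

        def deriv(t_us, v):
            out = l0 @ v
            if l1 is not None:
                out = out + np.sin(2 * np.pi * field.f_rf * t_us) * (l1 @ v)
            return out

        for i in range(1, n_steps + 1):
            t0 = (i - 1) * dt_us
            k1 = deriv(t0, rho)
            k2 = deriv(t0 + dt_us / 2, rho + dt_us / 2 * k1)
            k3 = deriv(t0 + dt_us / 2, rho + dt_us / 2 * k2)
            k4 = deriv(t0 + dt_us, rho + dt_us * k3)
            rho = rho + dt_us / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            record(i, i * dt_us, rho)
    else:
        raise InvalidParameterError(f"unknown integrator {integrator!r}")

    if np.any(tr_out > tr_out[0] * (1 + trace_tol) + trace_tol):
        raise IntegrationError("trace grew beyond tolerance; reduce dt")
    return Trajectory(t=t_out, p_singlet=ps_out, p_triplet=pt_out,
                      trace=tr_out, rho_final=rho.reshape(h0.shape))


def singlet_yield(system: RadicalPairSystem, field: FieldConfig,
                  t_max: float | None = None,
                  method: str = "auto") -> YieldResult:
    """Infinite-time (default) or finite-window recombination yields.

    method: "auto" picks the resolvent (RF off) or the stroboscopic
    Floquet path (RF on); "rotating" selects the rotating-frame secular
    approximation; "floquet" forces the stroboscopic path.
    """
    if t_max is not None:
        return propagate(system, field, t_max).yields(system)
    if method == "rotating":
        return _rotating_frame_yields(system, field)
    rf_active = field.rf_on and field.b1 > 0
    if method not in ("auto", "floquet"):
        raise InvalidParameterError(f"unknown method {method!r}")
    if not rf_active:
        h0, _ = hamiltonian_parts(system, field)
        return _resolvent_yields(system, _liouvillian(system, h0),
                                 initial_density(system))
    return _floquet_yields(system, field)


def mary_curve(system: RadicalPairSystem, b0_grid,
               method: str = "auto") -> pd.DataFrame:
    """Static-field (MARY) yield curve: yields vs B0 with the RF off."""
    b0_grid = np.asarray(b0_grid, dtype=float)
    if b0_grid.size == 0:
        raise InvalidParameterError("B0 grid is empty")
    if np.any(np.diff(b0_grid) <= 0):
        raise InvalidParameterError("B0 grid must be strictly increasing")
    rows = []
    for b0 in b0_grid:
        y = singlet_yield(system, FieldConfig(b0=b0, rf_on=False),
                          method=method)
        rows.append((b0, y.phi_s, y.phi_t, y.phi_relax))
    return pd.DataFrame(rows, columns=["b0_mT", "phi_s", "phi_t",
                                       "phi_relax"])


def rydmr_spectrum(system: RadicalPairSystem, b0_grid, b1: float,
                   f_rf: float, theta: float = np.pi / 2,
                   method: str = "auto") -> pd.DataFrame:
    """RF-on minus RF-off singlet-yield difference across a B0 grid.

    For theta = pi/2 the resonance extremum sits at
    ``esr_field(f_rf, g)``; for theta = 0 the drive commutes with the
    electron Zeeman interaction and the spectrum is flat (ESR selection
    rule).  Both branches of the difference use the same approximation
    level so the off branch cancels exactly when B1 = 0.
    """
    b0_grid = np.asarray(b0_grid, dtype=float)
    if b0_grid.size == 0:
        raise InvalidParameterError("B0 grid is empty")
    rows = []
    for b0 in b0_grid:
        off = singlet_yield(
            system, FieldConfig(b0=b0, b1=0.0, f_rf=f_rf, theta=theta,
                                rf_on=False),
            method="rotating" if method == "rotating" else "auto")
        if b1 > 0:
            on = singlet_yield(
                system, FieldConfig(b0=b0, b1=b1, f_rf=f_rf, theta=theta,
                                    rf_on=True), method=method)
        else:
            on = off
        rows.append((b0, on.phi_s - off.phi_s, on.phi_s, off.phi_s))
    return pd.DataFrame(rows, columns=["b0_mT", "dphi_s", "phi_s_on",
                                       "phi_s_off"])
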