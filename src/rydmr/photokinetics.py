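"""Minimal photocycle linking singlet yield to steady-state fluorescence.

The fluorescent protein population is split into two pools: the ground
state G (the only form excited to a fluorescing state) and a dark pool D
(protein engaged in the radical-pair photocycle).  Green excitation
drives G -> D at rate ``kForm = kForm0 * I520 / (1 + I520 / satI)``
(Michaelis-type saturation of the optical interaction); the dark pool
returns at ``kRet * returnWeight(phiS)``, where phiS is the singlet
recombination yield of the radical pair and returnWeight is monotone
non-decreasing — singlet pairs regenerate the ground state through the
reverse reaction, so a larger singlet yield means faster return.

Fluorescence is proportional to the ground-state fraction

    F = kRetEff / (kForm + kRetEff),

and any step change in the RF drive relaxes mono-exponentially between
the two steady states with time constant ``tau = 1/(kForm + kRetEff)``.
Blue (440 nm) photosensitization is treated as a precondition: the flavin
photoproduct is assumed present at fixed concentration and is not
modelled kinetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .spin_core import FieldConfig, RadicalPairSystem, singlet_yield

__all__ = ["PhotocycleModel", "RFSchedule", "steady_state_f", "mfe_curve",
           "step_response"]


def _default_return_weight(phi_s: float) -> float:
    # affine, monotone, bounded away from zero so the dark pool always returns
    return 0.5 + 0.5 * phi_s


@dataclass(frozen=True)
class PhotocycleModel:
    """Two-pool photocycle parameters.

    k_form0 : s^-1 per W/cm^2
        Radical-pair formation rate per unit green intensity.
    i520 : W/cm^2
        Green (520 nm) excitation intensity.
    sat_i : W/cm^2
        Saturation intensity of the optical interaction.
    k_ret : s^-1
        Base return rate from the dark pool.
    return_weight : callable
        Monotone non-decreasing map from singlet yield to the return-rate
        multiplier.
    """

    k_form0: float = 0.125
    i520: float = 0.5
    sat_i: float = 8.4
    k_ret: float = 0.52
    return_weight: Callable[[float], float] = _default_return_weight

    def __post_init__(self):
        for name in ("k_form0", "i520", "sat_i", "k_ret"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def k_form(self) -> float:
        """Saturating formation rate at the configured intensity (s^-1)."""
        return self.k_form0 * self.i520 / (1.0 + self.i520 / self.sat_i)

    def k_ret_eff(self, phi_s: float) -> float:
        return self.k_ret * self.return_weight(phi_s)

    def tau(self, phi_s: float) -> float:
        """Mono-exponential response time constant (s) at singlet yield phi_s."""
        return 1.0 / (self.k_form + self.k_ret_eff(phi_s))


@dataclass(frozen=True)
class RFSchedule:
    """Ordered, non-overlapping (t_start, t_end, B1) intervals in seconds.

    Outside every interval the RF amplitude is zero.  Switching is treated
    as instantaneous relative to the photocycle kinetics.
    """

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        iv = tuple((float(a), float(b), float(c)) for a, b, c in self.intervals)
        object.__setattr__(self, "intervals", iv)
        last = -np.inf
        for t0, t1, b1 in iv:
            if t1 <= t0:
                raise InvalidParameterError("interval end must exceed start")
            if t0 < last:
                raise InvalidParameterError(
                    "intervals must be ordered and non-overlapping")
            if b1 < 0:
                raise InvalidParameterError("B1 must be non-negative")
            last = t1

    def b1_at(self, t: float) -> float:
        for t0, t1, b1 in self.intervals:
            if t0 <= t < t1:
                return b1
        return 0.0

    def switch_times(self) -> list[float]:
        out = []
        for t0, t1, _ in self.intervals:
            out.extend((t0, t1))
        return out


def steady_state_f(model: PhotocycleModel, phi_s: float) -> float:
    """Steady-state ground-pool fraction (relative fluorescence).

    Closed form of the linear two-pool system; equals 1 when the
    formation rate vanishes (no depletion).
    """
    if not (0.0 <= phi_s <= 1.0):
        raise InvalidParameterError("phi_s must lie in [0, 1]")
    k_ret_eff = model.k_ret_eff(phi_s)
    k_form = model.k_form
    if k_form == 0:
        return 1.0
    return k_ret_eff / (k_form + k_ret_eff)


def mfe_curve(model: PhotocycleModel, system: RadicalPairSystem, b0_grid,
              b1: float = 0.0, f_rf: float = 447.0,
              theta: float = np.pi / 2, rf_on: bool = False,
              method: str = "auto") -> pd.DataFrame:
    """Fractional fluorescence change DeltaF/F versus static field.

    Composes the spin-dynamics singlet yield with the photocycle steady
    state and normalizes to the B0 = 0, RF-off fluorescence.
    """
    b0_grid = np.asarray(b0_grid, dtype=float)
    if b0_grid.size == 0:
        raise InvalidParameterError("B0 grid is empty")
    phi0 = singlet_yield(system, FieldConfig(b0=0.0, rf_on=False),
                         method="auto").phi_s
    f0 = steady_state_f(model, phi0)
    rows = []
    for b0 in b0_grid:
        cfg = FieldConfig(b0=b0, b1=b1 if rf_on else 0.0, f_rf=f_rf,
                          theta=theta, rf_on=rf_on and b1 > 0)
        phi = singlet_yield(system, cfg, method=method).phi_s
        f = steady_state_f(model, phi)
        rows.append((b0, f / f0 - 1.0, f, phi))
    return pd.DataFrame(rows, columns=["b0_mT", "df_over_f", "f_rel",
                                       "phi_s"])


def step_response(model: PhotocycleModel, phi_s_off: float, phi_s_on: float,
                  schedule: RFSchedule, t_grid) -> np.ndarray:
    """Fluorescence trace under an RF on/off schedule.

    Piecewise mono-exponential relaxation between the RF-off and RF-on
    steady states, continuous at every switch time; the trace starts at
    the steady state of the initial segment.  Returned values are
    ground-pool fractions on ``t_grid`` (seconds).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be increasing with >= 2 points")

    # segment boundaries: schedule switch points inside the grid span
    switches = [s for s in schedule.switch_times()
                if t_grid[0] < s < t_grid[-1]]
    bounds = [t_grid[0]] + sorted(set(switches)) + [t_grid[-1]]

    def level_and_tau(t):
        on = schedule.b1_at(t) > 0
        phi = phi_s_on if on else phi_s_off
        return steady_state_f(model, phi), model.tau(phi)

    out = np.empty_like(t_grid)
    f_start, _ = level_and_tau(bounds[0])
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        target, tau = level_and_tau(t0)
        sel = (t_grid >= t0) & (t_grid <= t1)
        out[sel] = target + (f_start - target) * np.exp(-(t_grid[sel] - t0)
                                                        / tau)
        f_start = target + (f_start - target) * np.exp(-(t1 - t0) / tau)
    return out
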