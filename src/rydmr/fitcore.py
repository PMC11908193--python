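"""Parameter extraction: field-sweep lineshapes, step responses, ESR line.

The field-sweep model is a sum of two Lorentzian components on a unit
baseline,

    F(B0) = 1 - A_m * B0^2 / (B0^2 + w_m^2)
              + A_r * w_r^2 / ((B0 - B0res)^2 + w_r^2),

a saturating dip centred at zero field (A_m is the maximum magnetic field
effect, w_m the half-saturation field B1/2) plus a narrow resonance peak
near the ESR field (A_r the RYDMR amplitude, FWHM = 2 w_r).  With the RF
drive off the resonance term is fixed at zero.

Step responses are fitted with a first-order exponential relaxation
between the RF-off and RF-on levels, with a single time constant pooled
across all on/off intervals.

Uncertainties come from the Jacobian-based covariance of the weighted
least-squares problem (inverse-variance weights when per-point errors are
available); replicate spread can be used instead by fitting replicate
sweeps individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import G_FREE_ELECTRON, esr_field, gamma_mhz_per_mt
from .errors import (DataError, FitError, InvalidParameterError,
                     UnidentifiableParameterError)
from .photokinetics import RFSchedule

__all__ = [
    "FieldSweep", "SweepFit", "StepFit", "EsrFit",
    "double_lorentzian", "fit_field_sweep", "fit_step_response",
    "coherence_metrics", "fit_esr_relation", "piecewise_exponential",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class FieldSweep:
    """An ordered (B0, relative fluorescence) series with field metadata."""

    b0: np.ndarray                 # mT, strictly increasing, >= 0
    f_rel: np.ndarray              # fraction of the zero-field RF-off level
    f_err: np.ndarray | None = None
    b1: float = 0.0                # mT
    f_rf: float = 447.0            # MHz
    theta: float = np.pi / 2
    rf_on: bool = False

    def __post_init__(self):
        self.b0 = np.asarray(self.b0, dtype=float)
        self.f_rel = np.asarray(self.f_rel, dtype=float)
        if self.f_err is not None:
            self.f_err = np.asarray(self.f_err, dtype=float)
            if self.f_err.shape != self.b0.shape:
                raise DataError("f_err shape mismatch")
        if self.b0.shape != self.f_rel.shape:
            raise DataError("b0 and f_rel must have equal length")
        if self.b0.size and (np.any(self.b0 < 0)
                             or np.any(np.diff(self.b0) <= 0)):
            raise DataError("b0 must be non-negative and strictly increasing")
        if np.any(self.f_rel <= 0):
            raise DataError("f_rel must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"b0_mT": self.b0, "f_rel": self.f_rel})
        if self.f_err is not None:
            df["f_err"] = self.f_err
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "FieldSweep":
        df = pd.read_csv(path)
        if not {"b0_mT", "f_rel"} <= set(df.columns):
            raise DataError("sweep CSV needs columns b0_mT, f_rel")
        return cls(b0=df["b0_mT"].to_numpy(),
                   f_rel=df["f_rel"].to_numpy(),
                   f_err=df["f_err"].to_numpy() if "f_err" in df else None,
                   **meta)


@dataclass
class SweepFit:
    """Fitted field-sweep parameters with standard errors and diagnostics."""

    mfe: float
    b_half: float
    rydmr_amp: float
    fwhm: float
    b0_res: float
    stderr: dict
    success: bool
    cost: float
    flags: tuple[str, ...] = ()
    residuals: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "mfe": self.mfe, "b_half": self.b_half,
            "rydmr_amp": self.rydmr_amp, "fwhm": self.fwhm,
            "b0_res": self.b0_res,
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "success": bool(self.success), "cost": float(self.cost),
            "flags": list(self.flags),
        }


@dataclass
class StepFit:
    """Fitted step-response parameters."""

    tau: float
    amplitude: float
    baseline: float
    stderr: dict
    success: bool
    cost: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"tau": self.tau, "amplitude": self.amplitude,
                "baseline": self.baseline,
                "stderr": {k: float(v) for k, v in self.stderr.items()},
                "success": bool(self.success), "cost": float(self.cost),
                "flags": list(self.flags)}


@dataclass
class EsrFit:
    """Line-through-origin fit of resonance field versus RF frequency."""

    slope: float          # mT per MHz
    slope_stderr: float
    g_estimate: float
    g_stderr: float

    def g_interval(self, n_sigma: float = 1.96) -> tuple[float, float]:
        return (self.g_estimate - n_sigma * self.g_stderr,
                self.g_estimate + n_sigma * self.g_stderr)


# --------------------------------------------------------------------------
# lineshape model
# --------------------------------------------------------------------------

def double_lorentzian(b0, mfe, b_half, rydmr_amp, fwhm, b0_res):
    """Unit baseline minus a saturating zero-field dip plus a resonance peak."""
    b0 = np.asarray(b0, dtype=float)
    w_r = fwhm / 2.0
    dip = mfe * b0 ** 2 / (b0 ** 2 + b_half ** 2)
    peak = rydmr_amp * w_r ** 2 / ((b0 - b0_res) ** 2 + w_r ** 2)
    return 1.0 - dip + peak


def _covariance_stderr(res, n_params: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    dof = max(res.fun.size - n_params, 1)
    s_sq = 2 * res.cost / dof
    j = res.jac
    try:
        cov = np.linalg.inv(j.T @ j) * s_sq
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.inf)


def fit_field_sweep(sweep: FieldSweep, rf_on: bool | None = None,
                    n_starts: int = 4, seed: int = 0) -> SweepFit:
    """Weighted least-squares fit of the double-Lorentzian sweep model.

    When the sweep was recorded with the RF off (``rf_on`` False, taken
    from the sweep metadata by default) the resonance term is fixed at
    zero and only the dip parameters are fitted.
    """
    if rf_on is None:
        rf_on = sweep.rf_on
    b0, f = sweep.b0, sweep.f_rel
    if b0.size < 8:
        raise DataError("need at least 8 sweep points")
    w = 1.0 / sweep.f_err if sweep.f_err is not None else np.ones_like(f)

    flags: list[str] = []
    f_tail = float(np.median(f[-max(3, b0.size // 10):]))
    mfe0 = float(np.clip(1.0 - f_tail, 1e-4, 0.999))
    # field where the dip reaches half depth, away from any resonance peak
    half_level = 1.0 - mfe0 / 2
    below = np.nonzero(f <= half_level)[0]
    bhalf0 = float(b0[below[0]]) if below.size else float(b0[-1] / 3)
    bhalf0 = max(bhalf0, float(b0[1]))

    if rf_on:
        res_guess = esr_field(sweep.f_rf)
        if not (b0[0] <= res_guess <= b0[-1]):
            raise UnidentifiableParameterError(
                "resonance region absent from the sweep grid")
        excess = f - double_lorentzian(b0, mfe0, bhalf0, 0.0, 1.0, 0.0)
        amp0 = float(np.clip(np.max(excess), 1e-4, 1.0))
        # half-saturation fields beyond the sweep range are not identifiable
        p0 = np.array([mfe0, bhalf0, amp0, 2.0, res_guess])
        lo = [0.0, 1e-3, 0.0, 1e-3, b0[0]]
        hi = [1.0, b0[-1], 1.0, b0[-1], b0[-1]]

        def resid(p):
            return w * (double_lorentzian(b0, *p) - f)
    else:
        p0 = np.array([mfe0, bhalf0])
        lo = [0.0, 1e-3]
        hi = [1.0, b0[-1]]

        def resid(p):
            return w * (double_lorentzian(b0, p[0], p[1], 0.0, 1.0, 0.0) - f)

    rng = np.random.default_rng(seed)
    best = None
    starts = [p0] + [np.clip(p0 * rng.uniform(0.5, 1.5, size=p0.size),
                             lo, hi) for _ in range(n_starts - 1)]
    for start in starts:
        try:
            r = least_squares(resid, start, bounds=(lo, hi), method="trf")
        except ValueError:
            continue
        if r.success and (best is None or r.cost < best.cost):
            best = r
    if best is None:
        raise FitError("field-sweep fit did not converge from any start")

    stderr_vals = _covariance_stderr(best, p0.size)
    noise = float(np.std(best.fun / w)) if b0.size > p0.size else 0.0
    if rf_on:
        mfe, b_half, amp, fwhm, b0_res = best.x
        stderr = dict(zip(("mfe", "b_half", "rydmr_amp", "fwhm", "b0_res"),
                          stderr_vals))
    else:
        mfe, b_half = best.x
        amp, fwhm, b0_res = 0.0, np.nan, np.nan
        stderr = dict(zip(("mfe", "b_half"), stderr_vals))
        stderr.update(rydmr_amp=0.0, fwhm=np.nan, b0_res=np.nan)

    # a dip (or peak) amplitude below its own detectability leaves the
    # corresponding width parameter unconstrained
    detect = max(3 * noise / np.sqrt(b0.size), 1e-4)
    if mfe < detect:
        flags.append("b_half_unidentifiable")
    if rf_on and amp < detect:
        flags.append("resonance_unidentifiable")

    return SweepFit(mfe=float(mfe), b_half=float(b_half),
                    rydmr_amp=float(amp), fwhm=float(fwhm),
                    b0_res=float(b0_res), stderr=stderr,
                    success=True, cost=float(best.cost),
                    flags=tuple(flags), residuals=best.fun / w)


# --------------------------------------------------------------------------
# step response
# --------------------------------------------------------------------------

def piecewise_exponential(t, baseline, amplitude, tau,
                          schedule: RFSchedule) -> np.ndarray:
    """First-order relaxation between ``baseline`` and ``baseline+amplitude``.

    The target level is ``baseline + amplitude`` inside RF-on intervals
    and ``baseline`` outside; the trace starts on the initial target and
    is continuous at every switch.
    """
    t = np.asarray(t, dtype=float)
    switches = [s for s in schedule.switch_times() if t[0] < s < t[-1]]
    bounds = [t[0]] + sorted(set(switches)) + [t[-1]]
    out = np.empty_like(t)
    level = lambda x: baseline + (amplitude if schedule.b1_at(x) > 0 else 0.0)
    f_start = level(bounds[0])
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        target = level(t0)
        sel = (t >= t0) & (t <= t1)
        out[sel] = target + (f_start - target) * np.exp(-(t[sel] - t0) / tau)
        f_start = target + (f_start - target) * np.exp(-(t1 - t0) / tau)
    return out


def fit_step_response(t, f, schedule: RFSchedule,
                      f_err=None) -> StepFit:
    """Least-squares fit of the pooled-tau piecewise exponential model."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size != f.size:
        raise DataError("t and f must have equal length")
    if t.size < 10:
        raise DataError("need at least 10 samples")
    if not any(t[0] <= s <= t[-1] for s in schedule.switch_times()):
        raise DataError("schedule has no transition inside the trace span")
    w = 1.0 / np.asarray(f_err, float) if f_err is not None \
        else np.ones_like(f)

    on = np.array([schedule.b1_at(x) > 0 for x in t])
    base0 = float(np.median(f[~on])) if np.any(~on) else float(f[0])
    amp0 = (float(np.median(f[on])) - base0) if np.any(on) else 0.0
    span = t[-1] - t[0]
    tau0 = max(span / 10, 1e-6)

    flags: list[str] = []
    min_len = min(t1 - t0 for t0, t1, _ in schedule.intervals)

    def resid(p):
        return w * (piecewise_exponential(t, p[0], p[1], p[2], schedule) - f)

    scale = float(np.max(np.abs(f))) or 1.0
    best = None
    for tau_start in (tau0, tau0 / 4, tau0 * 4):
        r = least_squares(resid, [base0, np.clip(amp0, -scale, scale),
                                  tau_start],
                          bounds=([0.0, -scale, 1e-9],
                                  [2 * scale, scale, 100 * span]),
                          method="trf")
        if r.success and (best is None or r.cost < best.cost):
            best = r
    if best is None:
        raise FitError("step-response fit did not converge")
    baseline, amplitude, tau = best.x
    stderr_vals = _covariance_stderr(best, 3)
    stderr = dict(zip(("baseline", "amplitude", "tau"), stderr_vals))

    noise = float(np.std(best.fun / w))
    # when the fitted model barely modulates within the trace, tau and
    # amplitude trade off freely (e.g. tau far beyond the record length)
    modulation = float(np.ptp(piecewise_exponential(
        t, baseline, amplitude, tau, schedule)))
    if modulation < 5 * max(noise, 1e-12) / np.sqrt(t.size) \
            or tau > 2 * span:
        flags.append("tau_unidentifiable")
    if min_len < tau / 2:
        flags.append("interval_shorter_than_half_tau")

    return StepFit(tau=float(tau), amplitude=float(amplitude),
                   baseline=float(baseline), stderr=stderr, success=True,
                   cost=float(best.cost), flags=tuple(flags))


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

def coherence_metrics(fwhm_mt: float,
                      g: float = G_FREE_ELECTRON) -> tuple[float, float]:
    """Resonance linewidth in frequency units and the coherence-time bound.

    deltaNu = g * muB * FWHM / h (MHz); tCoh = 1 / (pi * deltaNu) (ns).
    A vanishing linewidth maps to an infinite coherence time.
    """
    if fwhm_mt < 0:
        raise InvalidParameterError("fwhm must be positive")
    delta_nu = gamma_mhz_per_mt(g) * fwhm_mt
    if delta_nu == 0:
        return 0.0, np.inf
    t_coh_ns = 1e3 / (np.pi * delta_nu)
    return float(delta_nu), float(t_coh_ns)


def fit_esr_relation(points) -> EsrFit:
    """Least-squares line through the origin of (f_RF MHz, B0res mT) points.

    The slope is h/(g*muB) in mT/MHz, so the fitted slope yields a
    g-factor estimate ``g = h / (slope * muB)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DataError("need at least two (f_rf, b0_res) points")
    freq, b0 = pts[:, 0], pts[:, 1]
    if np.unique(freq).size < 2:
        raise UnidentifiableParameterError(
            "need at least two distinct RF frequencies")
    sxx = float(freq @ freq)
    slope = float(freq @ b0) / sxx
    resid = b0 - slope * freq
    dof = max(freq.size - 1, 1)
    slope_se = float(np.sqrt((resid @ resid) / dof / sxx))
    g_est = 1.0 / (slope * gamma_mhz_per_mt(1.0))
    g_se = g_est * slope_se / slope if slope > 0 else np.inf
    return EsrFit(slope=slope, slope_stderr=slope_se,
                  g_estimate=float(g_est), g_stderr=float(g_se))
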