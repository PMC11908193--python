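"""Synthetic measurements: field sweeps, RF step traces, worm phantoms.

Two generation paths exist.  The fast parametric path evaluates the
double-Lorentzian sweep model (or the piecewise-exponential step model)
directly, with presets taken from the printed study magnitudes — this is
the path used for calibrated parameter-recovery tests, since the true
radical-pair constants of the protein:flavin system are unknown.  The
physics-based path composes spin_core with photokinetics and is used for
qualitative-consistency checks.

Every generator is deterministic for a fixed seed and returns (or embeds)
the latent parameters it used, so recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import esr_field
from .errors import InvalidParameterError
from .fitcore import FieldSweep, double_lorentzian, piecewise_exponential
from .imaging import ImageStack
from .photokinetics import RFSchedule

__all__ = ["SweepPreset", "StepPreset", "PhantomSpec", "SWEEP_PRESETS",
           "STEP_PRESETS", "gen_sweep", "gen_step_trace", "gen_worm_stack",
           "default_phantom"]


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepPreset:
    """Ground-truth lineshape parameters plus noise and grid spec."""

    mfe: float = 0.20
    b_half: float = 5.0            # mT
    rydmr_amp: float = 0.08
    fwhm: float = 4.0              # mT
    b0_res: float = esr_field(447.0)
    snr: float = 50.0              # multiplicative Gaussian, sigma = 1/snr
    b0_start: float = 0.0
    b0_stop: float = 30.0
    b0_step: float = 0.25
    f_rf: float = 447.0

    def grid(self) -> np.ndarray:
        return np.arange(self.b0_start, self.b0_stop + self.b0_step / 2,
                         self.b0_step)


@dataclass(frozen=True)
class StepPreset:
    """Ground-truth step-response parameters and sampling."""

    tau: float = 2.5               # s
    amplitude: float = 0.05
    baseline: float = 1.0
    snr: float = 50.0
    rate_hz: float = 10.0
    t_span: float = 20.0           # s
    # RF on from 0-5 s and 10-15 s (b1 = 0.3 mT), off elsewhere
    intervals: tuple[tuple[float, float, float], ...] = (
        (0.0, 5.0, 0.3), (10.0, 15.0, 0.3))

    def schedule(self) -> RFSchedule:
        return RFSchedule(self.intervals)

    def t_grid(self) -> np.ndarray:
        n = int(round(self.t_span * self.rate_hz))
        return np.arange(n) / self.rate_hz


#: Named sweep presets; magnitudes follow the printed study results
#: (mScarlet-family MFE ~20%, mCherry ~1.5%, narrowest FWHM 2.7 mT,
#: resonance at the 447 MHz ESR field).  Immutable.
SWEEP_PRESETS: dict[str, SweepPreset] = {
    "mscarlet": SweepPreset(mfe=0.20, rydmr_amp=0.08, fwhm=4.0),
    "mcherry": SweepPreset(mfe=0.015, rydmr_amp=0.006, fwhm=4.0),
    "narrow": SweepPreset(mfe=0.20, rydmr_amp=0.08, fwhm=2.7, b0_step=0.2),
}

#: Step-response presets at low / high green intensity: tau ~2.5 s -> ~1.5 s
#: with a 2-fold amplitude increase.
STEP_PRESETS: dict[str, StepPreset] = {
    "low_intensity": StepPreset(tau=2.5, amplitude=0.05),
    "high_intensity": StepPreset(tau=1.5, amplitude=0.10),
}


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_sweep(preset: SweepPreset, seed: int, rf_on: bool = True) -> FieldSweep:
    """Evaluate the sweep lineshape on the preset grid and add noise."""
    rng = np.random.default_rng(seed)
    b0 = preset.grid()
    model = double_lorentzian(b0, preset.mfe, preset.b_half,
                              preset.rydmr_amp if rf_on else 0.0,
                              preset.fwhm, preset.b0_res)
    sigma = 1.0 / preset.snr if preset.snr > 0 else 0.0
    noisy = model * (1.0 + sigma * rng.standard_normal(b0.size)) \
        if sigma else model
    noisy = np.clip(noisy, 1e-6, None)
    err = (model * sigma) if sigma else None
    return FieldSweep(b0=b0, f_rel=noisy, f_err=err, b1=0.3 if rf_on else 0.0,
                      f_rf=preset.f_rf, rf_on=rf_on)


def gen_step_trace(preset: StepPreset, seed: int):
    """Noisy piecewise-exponential step trace; returns (t, f, schedule)."""
    rng = np.random.default_rng(seed)
    t = preset.t_grid()
    schedule = preset.schedule()
    model = piecewise_exponential(t, preset.baseline, preset.amplitude,
                                  preset.tau, schedule)
    sigma = 1.0 / preset.snr if preset.snr > 0 else 0.0
    f = model * (1.0 + sigma * rng.standard_normal(t.size)) if sigma else model
    return t, f, schedule


# --------------------------------------------------------------------------
# worm phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic widefield worm stack.

    Worm-shaped fluorescent objects (smooth random centerline stamped with
    disks of the given half-width) sit on a dim background; each worm's
    intensity is modulated across frames by its sweep preset evaluated at
    that frame's field condition.  Camera noise is Poisson (at the given
    photon gain) plus Gaussian read noise; an optional per-frame
    photobleaching decay multiplies all signal.
    """

    seed: int
    shape: tuple[int, int] = (96, 96)
    n_worms: int = 3
    half_width_px: float = 3.0
    n_segments: int = 40
    step_px: float = 2.5
    worm_intensity: float = 2000.0
    background: float = 50.0
    read_sigma: float = 2.0
    bleach_per_frame: float = 0.0  # fractional signal loss per frame
    preset: SweepPreset = SweepPreset(
        mfe=0.20, rydmr_amp=0.08, fwhm=4.0,
        b0_start=0.0, b0_stop=30.0, b0_step=2.0)
    n_repeats: int = 2
    n_resonance_extra: int = 6     # extra fine points across the resonance
    poisson_noise: bool = True

    def field_conditions(self) -> pd.DataFrame:
        """One sweep of RF-off then RF-on conditions (single repeat)."""
        coarse = self.preset.grid()
        res, w = self.preset.b0_res, self.preset.fwhm
        fine = np.linspace(res - w, res + w, self.n_resonance_extra)
        b0 = np.unique(np.round(np.concatenate([coarse, fine]), 6))
        rows = [(b, 0.0, False) for b in b0] + [(b, 0.3, True) for b in b0]
        return pd.DataFrame(rows, columns=["b0_mT", "b1_mT", "rf_on"])


def _worm_mask(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Stamp disks along a smoothed random-walk centerline."""
    h, w = spec.shape
    margin = 4 * spec.half_width_px
    for _ in range(200):
        y, x = rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)
        heading = rng.uniform(0, 2 * np.pi)
        pts = [(y, x)]
        ok = True
        for _ in range(spec.n_segments):
            heading += rng.normal(0.0, 0.35)
            y += spec.step_px * np.sin(heading)
            x += spec.step_px * np.cos(heading)
            if not (margin / 2 < y < h - margin / 2
                    and margin / 2 < x < w - margin / 2):
                ok = False
                break
            pts.append((y, x))
        if ok:
            break
    else:
        raise InvalidParameterError("could not place worm inside bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for (py, px) in pts:
        mask |= (yy - py) ** 2 + (xx - px) ** 2 <= spec.half_width_px ** 2
    return mask


def gen_worm_stack(spec: PhantomSpec):
    """Generate a phantom image stack with ground truth.

    Returns ``(stack, truth)`` where truth carries the per-worm boolean
    masks, the shared sweep preset and the noiseless modulation factors.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    worms = [_worm_mask(rng, spec) for _ in range(spec.n_worms)]

    conditions = spec.field_conditions()
    frames_meta = []
    profiles = np.zeros((spec.n_worms, h, w))
    for i, m in enumerate(worms):
        profiles[i][m] = spec.worm_intensity

    p = spec.preset
    images = []
    frame_idx = 0
    t_s = 0.0
    for rep in range(spec.n_repeats):
        for _, cond in conditions.iterrows():
            factor = double_lorentzian(
                np.array([cond.b0_mT]), p.mfe, p.b_half,
                p.rydmr_amp if cond.rf_on else 0.0, p.fwhm, p.b0_res)[0]
            signal = spec.background + factor * profiles.sum(axis=0)
            if spec.bleach_per_frame:
                signal = signal * (1.0 - spec.bleach_per_frame) ** frame_idx
            if spec.poisson_noise:
                img = rng.poisson(signal).astype(float)
            else:
                img = signal.copy()
            if spec.read_sigma:
                img = img + rng.normal(0.0, spec.read_sigma, size=signal.shape)
            images.append(np.clip(img, 0, None))
            frames_meta.append((frame_idx, cond.b0_mT, cond.b1_mT,
                                bool(cond.rf_on), rep, t_s))
            frame_idx += 1
            t_s += 1.0

    meta = pd.DataFrame(frames_meta, columns=["frame", "b0_mT", "b1_mT",
                                              "rf_on", "repeat", "t_s"])
    stack = ImageStack(frames=np.stack(images), meta=meta)
    truth = {
        "worm_masks": (np.stack(worms) if worms
                       else np.zeros((0, h, w), dtype=bool)),
        "preset": p,
        "conditions": conditions,
        "background": spec.background,
    }
    return stack, truth


def default_phantom(seed: int = 0, **overrides):
    """Convenience constructor for the default phantom specification."""
    return gen_worm_stack(replace(PhantomSpec(seed=seed), **overrides))
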