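# rydmr

Simulation and analysis of magnetically sensitive fluorescence from
protein:flavin radical pairs: magnetic field effects (MFE), reaction-
yield detected magnetic resonance (RYDMR), and their spatial mapping in
widefield fluorescence images.

Photoexcited flavin can form a spin-correlated radical pair with a
nearby partner on a fluorescent protein.  Hyperfine couplings drive
coherent singlet–triplet interconversion; only singlet pairs return the
protein to its fluorescent ground state.  A static field B0 Zeeman-
isolates the T±1 sublevels and dims the fluorescence; an RF field B1
perpendicular to B0 at the electron spin resonance condition

    f_ESR = g μB B0 / h        (B0 ≈ 15.95 mT at 447 MHz, g = 2.0023)

reconnects T±1 to T0 and brightens it again.  The package is for spin
chemists and quantum-biology experimentalists who need a tested
reference implementation of both the forward model and the parameter-
extraction pipeline.

What it provides:

- `rydmr.spin_core` — Liouville-space dynamics of a two-radical system
  with isotropic hyperfine couplings, Haberkorn recombination and
  depolarizing relaxation; exact resolvent yields with the RF off, a
  stroboscopic Floquet propagator with the RF on, and a rotating-frame
  fast path.  MARY curves and RYDMR spectra.
- `rydmr.photokinetics` — minimal two-pool photocycle linking singlet
  yield to steady-state fluorescence and mono-exponential RF step
  responses.
- `rydmr.fitcore` — the extraction procedures: double-Lorentzian field-
  sweep fits (MFE, B1/2, RYDMR amplitude, FWHM, B0res with standard
  errors), pooled-τ step-response fits, linewidth→coherence-time
  conversion, and the ESR line-center regression for g.
- `rydmr.imaging` — ROI sweeps, binned per-pixel MFE/RYDMR effect maps,
  edge maps and deterministic PNG overlays for TIFF stacks with CSV
  field-condition sidecars.
- `rydmr.synthgen` — seeded synthetic sweeps, step traces and worm-
  phantom image stacks with ground truth, so the entire pipeline is
  testable without instrument data.
- `rydmr` CLI — `simulate | fit-sweep | fit-step | map | synth`, with
  provenance-stamped JSON reports.

## Worked example

Generate a synthetic field sweep at the mScarlet-family preset (20% MFE,
8% RYDMR amplitude, resonance at the 447 MHz ESR field, SNR 50) and fit
it:

```python
from rydmr.synthgen import SWEEP_PRESETS, gen_sweep
from rydmr.fitcore import fit_field_sweep, coherence_metrics

sweep = gen_sweep(SWEEP_PRESETS["mscarlet"], seed=5)
fit = fit_field_sweep(sweep)
print(f"MFE       = {fit.mfe:.3f} +/- {fit.stderr['mfe']:.3f}")
print(f"B1/2      = {fit.b_half:.2f} +/- {fit.stderr['b_half']:.2f} mT")
print(f"RYDMR amp = {fit.rydmr_amp:.3f} +/- {fit.stderr['rydmr_amp']:.3f}")
print(f"FWHM      = {fit.fwhm:.2f} +/- {fit.stderr['fwhm']:.2f} mT")
print(f"B0res     = {fit.b0_res:.2f} +/- {fit.stderr['b0_res']:.2f} mT")
dn, tc = coherence_metrics(fit.fwhm)
print(f"linewidth = {dn:.1f} MHz -> coherence time {tc:.2f} ns")
```

prints

```
MFE       = 0.202 +/- 0.003
B1/2      = 4.67 +/- 0.18 mT
RYDMR amp = 0.094 +/- 0.007
FWHM      = 3.59 +/- 0.44 mT
B0res     = 15.70 +/- 0.13 mT
linewidth = 100.6 MHz -> coherence time 3.16 ns
```

The fitted MFE (fractional fluorescence reduction at saturating field)
and B1/2 (half-saturation field) recover the preset within their quoted
uncertainties; the resonance center sits at the ESR field for 447 MHz
within ~2 standard errors, and the linewidth converts to a coherence-
time bound of a few nanoseconds.  The same pipeline runs from the shell:

```bash
rydmr synth --kind sweep --preset mscarlet --seed 5 --out-prefix sw
rydmr fit-sweep --input sw.csv --out sw_fit.json
```

For imaging, `rydmr synth --kind stack` writes a worm-phantom TIFF plus
sidecar, and `rydmr map --images ... --meta ...` produces MFE/RYDMR maps
with edge-map overlays.

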