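# Methods

## Scope

`rydmr` models and analyses magnetically sensitive fluorescence in a
fluorescent-protein:flavin radical-pair system: static-field (MARY)
fluorescence curves, RF-driven resonance features (RYDMR) near the
electron spin resonance condition, their dynamic step responses, and
spatially resolved effect maps over widefield image stacks.  Because no
raw instrument data are available, a synthetic-data module emulates every
measurement type with known ground truth; all quantitative claims in the
test suite are claims about estimator correctness on those synthetic
conditions, not about any particular protein.

## Spin model

The radical pair is two electron spins, each optionally coupled to
spin-1/2 nuclei through isotropic hyperfine constants `a_i` (mT).  The
laboratory-frame Hamiltonian (frequency units, MHz; fields in mT;
`gamma(g) = g*muB/h`, always computed from CODATA constants) is

    H(t) = gamma1*B0*S1z + gamma2*B0*S2z
         + sum_i a_i*gamma_host*(I_i . S_host)
         + B1*sin(2*pi*f_RF*t) * (gamma1*S1 + gamma2*S2) . n_hat

with `n_hat` at angle theta to B0 (theta = pi/2: perpendicular drive).
Exchange and dipolar couplings are fixed at zero, consistent with the
smooth low-field behaviour the model targets.  Nuclear Zeeman terms and
spins above 1/2 are out of scope; the total nucleus count is capped at 4
(Hilbert dimension <= 64) to keep everything desk-scale.

Spin-selective recombination uses the Haberkorn form: anticommutator
decay at rate `kS` on the singlet projector and `kT` on the triplet
projector.  Relaxation is an isotropic depolarizing channel at `kRelax`
(rate toward the maximally mixed state).  "Uniform dephasing of all
coherences" is basis-dependent as a phrase; the depolarizing channel is
the basis-independent reading and is trace-preserving, so `phiRelax` is
defined as the unrecombined residual at the end of the integration
window (exactly 0 for infinite-time solutions when both rates are
positive).

### Yields

`phiS = kS * int Tr(P_S rho) dt` and analogously `phiT`.  Three routes:

- RF off: the Liouvillian is time-independent and the infinite-time
  integral is the resolvent `-L^{-1} rho0` — exact, no time grid.
- RF on (reference path): one RF period is split into 32
  piecewise-constant steps; each step contributes `exp(L_k dt)` and its
  time integral via a block matrix exponential.  The period propagator P
  and two per-period accumulation row vectors then give the infinite-
  horizon yields through the geometric series `(I - P)^{-1}` — a
  stroboscopic Floquet resolvent with no truncation error in time.
- Rotating frame (fast path): both electrons rotate at f_RF about z;
  counter-rotating drive and non-secular hyperfine flip-flop terms are
  dropped.  Valid for B1 << B0 and B0 large against the hyperfine
  couplings, and only for theta = pi/2.  Both the on- and off-branches
  of a spectrum use the same approximation so their difference is
  internally consistent.

`propagate` additionally offers trajectory output with two independent
integrators (piecewise matrix exponential, classical RK4); they agree in
yields to ~1e-9 on two-nucleus systems and serve as mutual oracles.
Singular Liouvillians (population trapped in a non-recombining subspace,
e.g. `kT = 0` without relaxation) fall back to a least-squares resolvent;
the defaults keep both rates positive so this path is exceptional.

### Default radical pair

The study system's g-factors, hyperfine constants and rates are not
published.  Defaults, chosen once as field-typical values:

| parameter | default | rationale |
|---|---|---|
| g1, g2 | 2.0023 | free electron; organic radicals deviate by <0.1% |
| hf1, hf2 | 1.0 mT, 0.5 mT (one proton each) | mT-scale couplings typical of flavin/amino-acid radicals |
| kS | 3e7 s^-1 | tens-of-ns singlet lifetime; sets a resonance width comparable to the measured mT-scale lines |
| kT | 3e6 s^-1 | slow triplet channel: the pair returns to the fluorescent ground state mainly through the singlet pathway |
| kRelax | 0 | relaxation stated only as "much slower"; off by default |
| initial state | triplet (equal T-1/T0/T+1 mixture) | triplet-born pair; singlet and T0 available |

With one proton per radical this reproduces the qualitative
phenomenology: the singlet yield falls monotonically with B0 beyond the
hyperfine scale toward a high-field plateau (T+/-1 isolation), a
perpendicular RF drive at `B0 = h f_RF/(g muB)` returns population
through T0 and raises the yield, and a parallel drive produces <5% of
that effect (selection rule).  A caveat worth recording: with a single
proton and no relaxation, the stretched states |T+1, up> and |T-1, down>
are exact zero-field eigenstates, which suppresses the zero-field
singlet yield below the high-field plateau for most rate choices — the
monotone-decreasing MARY curve is a genuine multi-nucleus (or
relaxation-assisted) effect, which is why the default carries one proton
on each radical.

## Photocycle model

Fluorescence is proportional to the ground-state pool G of a two-pool
scheme G <-> D: green light drives `G -> D` at
`kForm = kForm0*I520/(1 + I520/satI)` (saturating optical interaction),
and the dark pool returns at `kRet * w(phiS)` with
`w(phi) = 0.5 + 0.5*phi` (monotone: singlet recombination regenerates
the ground state).  Blue photosensitization is a precondition, not
modelled.  Steady state `F = kRetEff/(kForm + kRetEff)`; any RF step
relaxes mono-exponentially with `tau = 1/(kForm + kRetEff)`.

The four constants (`kForm0 = 0.125 s^-1 per W/cm^2`, `satI = 8.4
W/cm^2`, `kRet = 0.52 s^-1`, and the weight above) were solved in closed
form from the model's published operating points — tau ~2.5 s at I520 =
0.5 W/cm^2, tau ~1.5 s at 3.8 W/cm^2, and a 2-fold amplitude increase
between those intensities — so the model reproduces the decreasing tau
and the saturating, non-decreasing response amplitude within that
intensity range (the amplitude turns over slightly above ~4 W/cm^2,
where formation outpaces return).

## Fitting procedures

Field sweeps are fitted with the two-component lineshape

    F(B0) = 1 - MFE * B0^2/(B0^2 + B_half^2)
              + A_r * w_r^2/((B0 - B0res)^2 + w_r^2),

a saturating Lorentzian dip centred at zero field (so `B_half` is the
half-saturation field B1/2) plus a narrow Lorentzian resonance peak
(FWHM = 2 w_r).  With the RF off the peak is fixed at zero.  Weighted
(inverse-variance, when per-point errors exist) trust-region least
squares; B0res initialized at the ESR field for the sweep's RF
frequency, other starts from robust data features plus a small seeded
multi-start, lowest residual wins.  `B_half` is bounded by the sweep's
maximum field — a half-saturation field beyond the measured range is not
identifiable.  Standard errors come from the Jacobian covariance;
parameters whose amplitude falls below its detectability are flagged
unidentifiable rather than reported as precise.

Two known small-sample properties, measured on the synthetic conditions
and left uncorrected: (i) at mCherry-level contrast (1.5% dip against 2%
multiplicative noise) the MFE estimator carries a +5..8% relative bias
from the nonlinear MFE–B1/2 coupling (the median is unbiased); (ii) the
non-negativity of the resonance amplitude gives per-bin RYDMR maps a
positive noise floor at low SNR.  Nominal 95% confidence intervals cover
at >= 92% for all five parameters at SNR 50.

Step responses are fitted with a continuous piecewise exponential
relaxing between the RF-off level and RF-on level (baseline, amplitude,
one pooled tau); tau is flagged unidentifiable when the fitted model
barely modulates within the record or tau exceeds twice the record
length.

`coherence_metrics` converts a linewidth to frequency units,
`deltaNu = g*muB*FWHM/h`, and reports the coherence-time bound
`1/(pi*deltaNu)`.  For FWHM = 2.7 mT this gives 75.7 MHz and 4.2 ns.
Published figures pairing a 2.7 mT width with 72 MHz and 41 ns are not
mutually consistent with these definitions (41 ns would require ~7.8
MHz); the implementation reports the formula values and makes no attempt
to reproduce that chain.

`fit_esr_relation` regresses resonance field on RF frequency through the
origin; the slope is `h/(g muB)`, giving a g-factor estimate with its
standard error.

## Imaging

Stacks are multi-page TIFF plus a CSV sidecar (frame, b0_mT, b1_mT,
rf_on, repeat, t_s); field ordering is taken from metadata, never frame
order.  ROI sweeps average intensity over a mask per condition, average
repeats, and normalize to the B0 = 0 RF-off condition.  Effect maps bin
the image 4x4 (per-pixel fits are noise-dominated), mask bins below an
intensity threshold (default: 10th percentile of the above-background
distribution, background = median of the darkest 20% of pixels plus five
robust sigma), then fit the RF-off branch for MFE and the RF-on branch
for the RYDMR amplitude.  Repeat-spread error bars are used as weights
only with >= 3 repeats; with fewer, spread estimates are too noisy to
weight by.  An optional photobleach detrend fits a log-linear decay to
the interleaved B0 = 0 RF-off reference frames and divides it out —
exact for exponential bleaching.  Edge maps are Gaussian-smoothed Sobel
gradients, Otsu-thresholded and thinned; overlays are written as
deterministic RGBA PNGs (colormapped values, white edges, transparent
masked regions) with a JSON sidecar recording the rendered value range.

## Synthetic data

Two generation paths: a fast parametric path that evaluates the fitted
lineshape / step model directly (used for calibrated recovery tests,
since the true radical-pair constants are unknown), and a physics path
composing the spin and photocycle models (used for qualitative
consistency).  Sweep presets carry the published magnitudes — MFE 20%
(mScarlet family), 1.5% (mCherry), FWHM 2.7 mT (narrowest line),
resonance at the 447 MHz ESR field — with B1/2 = 5 mT and RYDMR
amplitude 0.08 chosen once as realistic where no value is printed.
Noise is multiplicative Gaussian at SNR 50.  Step presets: tau 2.5 s /
amplitude 0.05 (low intensity) and 1.5 s / 0.10 (high), sampled at 10 Hz
over 20 s with RF on during 0–5 s and 10–15 s.

The worm phantom stamps disks along smoothed random-walk centerlines
(default three worms, half-width 3 px, 96x96 frames, ~2000-count worms
on a 50-count background), modulates each worm by its sweep preset at
each frame's field condition, applies optional exponential bleaching,
then Poisson plus Gaussian read noise.  The default per-worm preset uses
the in-vitro-scale lineshape (MFE 0.20) rather than the ~4% in-vivo
level so recovery tests probe the estimator at workable SNR; pass a
custom preset for in-vivo-scale studies.  Not emulated: worm motion,
anatomy, optics (PSF), spectral bleed-through — so passing tests show
estimator correctness under the stated noise model, not robustness to
those effects.

## Problem sizes and numerical choices

Simulation tests use one- and two-nucleus systems (Hilbert dimension 8
and 16): resonance-location and selection-rule checks run on the
one-proton system over ~0.25 mT grids; recovery ensembles use 200 sweep
or 100 trace replicates; the phantom analysis uses a 96x96, 88-frame
stack.  Tolerances: yields conserve to 1e-6; the two propagators agree
to 1e-6; switch-time continuity to 1e-10; fit self-consistency to 1e-6
relative on noiseless input.  Ties in multi-start fits break by lowest
residual with fixed seeds, so every fit is deterministic.
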