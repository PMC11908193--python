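"""Physical constants and unit conversions.

Internal unit system: magnetic flux density in mT, frequency in MHz,
time in microseconds. The electron gyromagnetic ratio is always derived
from CODATA values of the Bohr magneton and the Planck constant — never
hard-coded as "28 MHz/mT".
"""

from scipy import constants as _codata

#: Planck constant, J s (CODATA).
PLANCK_H: float = _codata.h

#: Bohr magneton, J/T (CODATA).
BOHR_MAGNETON: float = _codata.value("Bohr magneton")

#: Free-electron g-factor, used wherever a g-value is needed but unstated.
G_FREE_ELECTRON: float = 2.0023


def gamma_mhz_per_mt(g: float) -> float:
    """Electron gyromagnetic ratio ``g*muB/h`` in MHz per mT.

    Parameters
    ----------
    g : dimensionless electron g-factor (must be positive).
    """
    if g <= 0:
        raise ValueError(f"g-factor must be positive, got {g}")
    # Hz/T -> MHz/mT is a factor 1e-9
    return g * BOHR_MAGNETON / PLANCK_H * 1e-9


def esr_field(f_rf_mhz: float, g: float = G_FREE_ELECTRON) -> float:
    """Static field (mT) satisfying the electron spin resonance condition.

    Inverts ``f_ESR = g * muB * B0 / h`` for B0: ``B0 = h * f_RF / (g * muB)``.

    Examples
    --------
    >>> round(esr_field(447.0), 2)
    15.95
    """
    if f_rf_mhz < 0:
        raise ValueError("RF frequency must be non-negative")
    return f_rf_mhz / gamma_mhz_per_mt(g)
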