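"""Physical constants used across the package.

Single source of truth: every module that needs h, mu_B, F or R imports
``CONST`` from here.  Values are CODATA, taken from :mod:`scipy.constants`.
"""

from dataclasses import dataclass

import scipy.constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants relevant to the resonance condition and Nernst law.

    Attributes
    ----------
    h : float
        Planck constant (J s).
    mu_B : float
        Bohr magneton (J/T).
    F : float
        Faraday constant (C/mol).
    R : float
        Molar gas constant (J/mol/K).
    """

    h: float = _sc.h
    mu_B: float = _sc.physical_constants["Bohr magneton"][0]
    F: float = _sc.physical_constants["Faraday constant"][0]
    R: float = _sc.R


CONST = PhysicalConstants()
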