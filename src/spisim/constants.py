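"""Bundled per-element constants used across the simulation.

The damage emulator and the diffraction stage need, per element: the atomic
number, atomic mass, a total photoabsorption cross section at the working
photon energy of 4.96 keV, an inner-shell (Auger/Coster-Kronig) hole
lifetime, typical ejected-electron energies, and the Cromer-Mann elastic
form-factor parameterization.  Bundling them as plain constants avoids an
electronic-structure dependency; values are standard tabulations rounded to
the precision that matters for a stochastic emulator.

Notes
-----
* Cross sections are subshell-summed photoabsorption values at 4.96 keV in
  Angstrom^2 (1 barn = 1e-8 A^2).  For Fe the K edge (7.11 keV) lies above
  the photon energy, so absorption is L-shell dominated.
* Hole lifetimes: O 4.9 fs and C 10.7 fs are the anchors for biomolecule
  constituents; heavier elements decay much faster.
* ``CM_COEFFS`` are the 4-Gaussian-plus-constant Cromer-Mann coefficients
  (International Tables vol. C); ``form_factor`` evaluates
  f(q) = sum_i a_i exp(-b_i (q/4pi)^2) + c with f(0) = Z.
"""

from __future__ import annotations

import numpy as np

# physical constants
HC_KEV_A = 12.39842            # h*c in keV * Angstrom
R_E_A = 2.8179403e-5           # classical electron radius in Angstrom
R_E2_A2 = R_E_A**2             # Thomson dsigma/dOmega scale, A^2/sr
COULOMB_EV_A = 14.3996         # e^2/(4 pi eps0) in eV * Angstrom
EV_A_AMU_ACC = 9.64853e-3      # 1 (eV/A)/amu in A/fs^2

PHOTON_ENERGY_KEV = 4.96       # working photon energy

# symbol -> (Z, mass_amu, sigma_ph_A2 at 4.96 keV, hole_lifetime_fs,
#            photoelectron_eV, auger_eV)
ELEMENT_DATA = {
    "H":  (1,  1.008,   1.0e-11, None,  4946.0, None),
    "C":  (6,  12.011,  3.91e-7, 10.7,  4676.0, 260.0),
    "N":  (7,  14.007,  8.23e-7, 6.4,   4550.0, 360.0),
    "O":  (8,  15.999,  1.55e-6, 4.9,   4417.0, 500.0),
    "P":  (15, 30.974,  2.24e-5, 1.4,   2815.0, 1850.0),
    "S":  (16, 32.06,   2.85e-5, 1.1,   2490.0, 2100.0),
    "Fe": (26, 55.845,  1.29e-4, 0.55,  4250.0, 600.0),
}

IMPACT_ELECTRON_EV = 20.0      # typical secondary-electron energy

# Cromer-Mann a1..a4, b1..b4, c
CM_COEFFS = {
    "H":  ([0.489918, 0.262003, 0.196767, 0.049879],
           [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C":  ([2.31000, 1.02000, 1.58860, 0.865000],
           [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N":  ([12.2126, 3.13220, 2.01250, 1.16630],
           [0.005700, 9.89330, 28.9975, 0.582600], -11.5290),
    "O":  ([3.04850, 2.28680, 1.54630, 0.867000],
           [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "P":  ([6.43450, 4.17910, 1.78000, 1.49080],
           [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
    "S":  ([6.90530, 5.20340, 1.43790, 1.58630],
           [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "Fe": ([11.7695, 7.35730, 3.52220, 2.30450],
           [4.76110, 0.307200, 15.3535, 76.8805], 1.03690),
}

KNOWN_ELEMENTS = tuple(ELEMENT_DATA)


def atomic_number(symbol: str) -> int:
    try:
        return ELEMENT_DATA[symbol][0]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}; "
                       f"known: {', '.join(KNOWN_ELEMENTS)}") from None


def atomic_mass(symbol: str) -> float:
    return ELEMENT_DATA[symbol][1]


def photoabsorption_cross_section(symbol: str) -> float:
    """Total photoabsorption cross section at 4.96 keV in A^2 (neutral atom)."""
    return ELEMENT_DATA[symbol][2]


def hole_lifetime(symbol: str):
    """Inner-shell hole lifetime in fs (``None`` for hydrogen: no Auger)."""
    return ELEMENT_DATA[symbol][3]


def form_factor(symbol: str, qmag: np.ndarray) -> np.ndarray:
    """Neutral-atom elastic form factor f(|q|), Cromer-Mann parameterization.

    ``qmag`` is |q| in inverse Angstrom with the |q| = 4 pi sin(theta)/lambda
    convention, so the tabulated argument is s = |q| / (4 pi).
    """
    a, b, c = CM_COEFFS[symbol]
    s2 = (np.asarray(qmag, dtype=float) / (4.0 * np.pi)) ** 2
    f = np.full_like(s2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def wavelength_A(photon_energy_keV: float) -> float:
    if photon_energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_A / photon_energy_keV
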