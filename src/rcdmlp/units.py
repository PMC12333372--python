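"""Physical constants and unit conversions.

Internal units throughout the model and simulation layers are eV, Angstrom,
and amu; free energies are converted to kcal/mol only at reporting time.
The internal time unit implied by (amu, A, eV) is sqrt(amu*A^2/eV) ~ 10.18 fs.
"""

KB_EV = 8.617333262e-5  # Boltzmann constant, eV/K
EV_TO_KCALMOL = 23.060548
KCALMOL_TO_EV = 1.0 / EV_TO_KCALMOL

# 1 fs expressed in the internal time unit sqrt(amu * A^2 / eV)
FS = 0.09822694750253305


def kt_ev(temperature: float) -> float:
    """kT in eV at the given temperature in kelvin."""
    return KB_EV * temperature


def kt_kcalmol(temperature: float) -> float:
    """kT in kcal/mol at the given temperature in kelvin."""
    return KB_EV * temperature * EV_TO_KCALMOL
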