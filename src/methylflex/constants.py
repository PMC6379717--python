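"""Physical constants and unit conventions used across the package.

Energies are kcal/mol, distances Angstrom, angles degrees unless a
function states otherwise.  Charges are exposed in elementary-charge
units; the Amber topology format stores them scaled by ``AMBER_CHARGE_SCALE``
(the square root of the Coulomb constant in Amber internal units).
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Amber prmtop charge scale factor: q_file = q_e * 18.2223.
AMBER_CHARGE_SCALE = 18.2223

#: Atomic masses used for mass-weighted centers, u.
MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.973762}


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB*T in kcal/mol at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
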