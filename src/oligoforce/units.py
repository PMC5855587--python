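"""Unit conventions and physical constants.

Internal units are fixed across the package: lengths in nm, forces in pN,
spring constants in nN/nm (the unit instrument vendors print), pulling speed
in um/s, temperature in K.  Conversions happen only at I/O boundaries.

A cantilever spring constant of ``k`` nN/nm equals ``1000 k`` pN/nm, so the
force on the tip is ``F [pN] = 1000 * k [nN/nm] * d [nm]`` with deflection
``d``.  During retraction an adhesive tether pulls the tip toward the surface,
giving negative deflection; reported unbinding forces are magnitudes.
"""

from scipy import constants as _const

#: Boltzmann constant in J/K (CODATA, exact by SI definition).
KB_J_PER_K: float = _const.k

#: Boltzmann constant in pN*nm/K (1 J = 1e21 pN*nm).
KB_PN_NM_PER_K: float = _const.k * 1e21

#: Avogadro's number, 1/mol.
N_AVOGADRO: float = _const.N_A

#: Joules per (pN * nm).
J_PER_PN_NM: float = 1e-21

PN_PER_NN: float = 1000.0


def thermal_energy_pn_nm(temperature_k: float) -> float:
    """Thermal energy k_B*T in pN*nm (~4.11 pN*nm at 298 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k} K")
    return KB_PN_NM_PER_K * temperature_k


def spring_constant_pn_per_nm(spring_constant_nn_per_nm: float) -> float:
    """Convert a spring constant from nN/nm to pN/nm."""
    return spring_constant_nn_per_nm * PN_PER_NN
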