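"""Unit system and physical constants.

Internal units: length in Å, energy in kcal/mol, mass in amu, charge in
elementary charges.  The derived time unit is sqrt(amu Å² / (kcal/mol))
≈ 48.89 fs, so the conventional CG timestep of 0.3 time units is ≈ 14.7 fs.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872

#: Coulomb constant e²/(4πε0), kcal·Å/mol/e².
COULOMB = 332.0637

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: One internal time unit in femtoseconds.
TIME_UNIT_FS = 48.89

#: Default uniform bead mass (amu); roughly the mean residue/nucleotide-site
#: mass.  Equilibrium sampling is mass-independent, so only integrator
#: stability depends on this choice.
DEFAULT_MASS = 110.0

#: Standard-state volume for 1 M concentration, Å³ per molecule.
STANDARD_VOLUME = 1661.0


def debye_length(ionic_strength: float, dielectric: float, temperature: float) -> float:
    """Debye screening length λ_D in Å.

    Parameters
    ----------
    ionic_strength : mol/L of 1:1 electrolyte.
    dielectric : relative permittivity (dimensionless).
    temperature : K.
    """
    import math

    if ionic_strength <= 0 or dielectric <= 0 or temperature <= 0:
        raise ValueError("ionic strength, dielectric and temperature must be positive")
    bjerrum = COULOMB / (dielectric * KB * temperature)  # Å
    # ion number density for a 1:1 electrolyte, ions/Å³
    n_ions = 2.0 * ionic_strength * AVOGADRO * 1e-27
    kappa_sq = 4.0 * math.pi * bjerrum * n_ions
    return 1.0 / math.sqrt(kappa_sq)
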