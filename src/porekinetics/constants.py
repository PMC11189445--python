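"""Physical constants and unit conversions used across the package.

Internal unit conventions: lengths in Å, times in ns, energies in kcal/mol,
voltages in mV, conductances in pS.
"""

#: Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

#: Default simulation temperature, K
T_DEFAULT = 298.0

#: Elementary charge, C
E_CHARGE = 1.602176634e-19

#: 1 eV in kcal/mol (CODATA); used to map q*V to an energy for a +1e cation
EV_TO_KCAL = 23.060548


def kT(temperature: float = T_DEFAULT) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return R_KCAL * temperature


def voltage_to_kcal(voltage_mv: float, charge_e: float = 1.0) -> float:
    """Energy drop q*V across the membrane in kcal/mol.

    ``voltage_mv`` is the applied transmembrane voltage in mV and
    ``charge_e`` the ion charge in units of e (+1 for K+).
    500 mV at +1e is 11.53 kcal/mol.
    """
    return charge_e * voltage_mv * 1e-3 * EV_TO_KCAL


#: Standard atomic masses (amu) for mass-weighted centroids of heavy atoms.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "K": 39.098, "NA": 22.990, "CL": 35.45, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "SE": 78.971,
}

#: Residue names recognised as water across common force-field conventions.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP3P", "SOL", "SPC", "TIP4"})

#: The 20 standard amino-acid residue names.
PROTEIN_RESNAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
})
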