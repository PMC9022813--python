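"""Physical constants and unit conventions.

All thermodynamic sums use the NN-literature conventions: enthalpies in
kcal/mol, entropies in cal/(mol K), temperatures in kelvin internally
(Celsius only at user interfaces).
"""

#: Gas constant, kcal/(mol K).
R_KCAL = 1.987204e-3

#: 0 degrees Celsius in kelvin.
T_ZERO_C = 273.15

#: Reference temperature for dG37 values, kelvin.
T37 = 310.15

#: Average single-strand molecular weight of a DNA L-mer (5'-OH), g/mol:
#: MW(L) = MW_PER_BASE * L + MW_OFFSET.
MW_PER_BASE = 303.7
MW_OFFSET = 79.0


def molecular_weight(length: int) -> float:
    """Average molecular weight (g/mol) of a single-stranded DNA ``length``-mer."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return MW_PER_BASE * length + MW_OFFSET


def mass_to_molar(c_mass_gl: float, length: int) -> float:
    """Convert a strand mass concentration (g/l) to molarity (mol/L)."""
    return c_mass_gl / molecular_weight(length)


def molar_to_mass(c_molar: float, length: int) -> float:
    """Convert strand molarity (mol/L) to mass concentration (g/l)."""
    return c_molar * molecular_weight(length)
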