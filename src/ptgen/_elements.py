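"""Chemical element bookkeeping: symbols and standard-table coordinates."""

# All IUPAC element symbols, indexed by atomic number - 1.
SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
]

KNOWN_SYMBOLS = frozenset(SYMBOLS)

# First 54 elements, hydrogen through xenon.
SYMBOLS_H_TO_XE = SYMBOLS[:54]


def _groups_h_to_xe():
    groups = {}
    main = {
        "H": 1, "He": 18,
        "Li": 1, "Be": 2, "B": 13, "C": 14, "N": 15, "O": 16, "F": 17, "Ne": 18,
        "Na": 1, "Mg": 2, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "Ar": 18,
    }
    groups.update(main)
    # periods 4 and 5 run straight through groups 1..18
    for offset, period in ((18, 4), (36, 5)):
        for g in range(1, 19):
            groups[SYMBOLS[offset + g - 1]] = g
    return groups


GROUP = _groups_h_to_xe()

PERIOD = {}
for z, sym in enumerate(SYMBOLS_H_TO_XE, start=1):
    if z <= 2:
        PERIOD[sym] = 1
    elif z <= 10:
        PERIOD[sym] = 2
    elif z <= 18:
        PERIOD[sym] = 3
    elif z <= 36:
        PERIOD[sym] = 4
    else:
        PERIOD[sym] = 5
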