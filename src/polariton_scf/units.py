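"""Unit conversion constants.

Internal representation is strictly atomic units (hartree, bohr); conversion
happens only at I/O boundaries (XYZ files in Angstrom, cavity frequency in eV).
"""

ANGSTROM_TO_BOHR = 1.0 / 0.52917721092
BOHR_TO_ANGSTROM = 0.52917721092
EV_TO_HARTREE = 1.0 / 27.211386
HARTREE_TO_EV = 27.211386
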