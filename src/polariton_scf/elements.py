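"""Element symbols and nuclear charges (H through Ar)."""

SYMBOLS = [
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBER = {s: i + 1 for i, s in enumerate(SYMBOLS)}


def atomic_number(symbol: str) -> int:
    """Nuclear charge for an element symbol (case-insensitive)."""
    key = symbol.strip().capitalize()
    if key not in ATOMIC_NUMBER:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return ATOMIC_NUMBER[key]
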