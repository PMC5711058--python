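"""Packaged reference data.

Published entrance/exit backscatter correction factor tables for two clinical
6 MV photon beams measured in water-equivalent slab phantoms at SSD 100 cm:

``clinac21ex``
    Varian Clinac 21EX (TPR20,10 = 0.669)
``synergy``
    Elekta Synergy (TPR20,10 = 0.687)

Each table carries a 4-field-size entrance block (backscatter thickness
1.5-31.5 cm at depth 1.5 cm) and a 4-field-size exit block (depth 6.5-31.5 cm
at backscatter thickness 1.5 cm), at the tabulated 3-decimal precision.
"""

from __future__ import annotations

from importlib import resources

from .beam_data import BCFTable, read_bcf_table

REFERENCE_MACHINES = ("clinac21ex", "synergy")


def load_reference_bcf(machine: str) -> BCFTable:
    """Load a packaged reference BCF table by machine name."""
    if machine not in REFERENCE_MACHINES:
        raise ValueError(f"unknown reference machine {machine!r}; choose from {REFERENCE_MACHINES}")
    ref = resources.files("transitdose.data") / f"bcf_{machine}.csv"
    with resources.as_file(ref) as path:
        return read_bcf_table(path)
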