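"""Oligonucleotide melting temperatures.

Nearest-neighbor duplex thermodynamics with the unified DNA parameter set
(Allawi & SantaLucia 1997) and a sodium-equivalent entropy salt correction
(SantaLucia 1998 / von Ahsen 2001), as implemented by Biopython.

For a SuperSelective primer only the 5' anchor hybridizes stably at the
annealing temperature, so its effective Tm is computed from the anchor
alone (:func:`superselective_tm`); bridge and foot are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import InputError
from .seq import validate_dna

MIN_TM_LENGTH = 8

#: Supported nearest-neighbor tables (Biopython names).
NN_TABLES = {
    "breslauer1986": "DNA_NN1",
    "sugimoto1996": "DNA_NN2",
    "allawi1997": "DNA_NN3",
    "santalucia2004": "DNA_NN4",
}


@dataclass(frozen=True)
class ThermoParams:
    """Hybridization conditions for Tm calculation.

    Parameters
    ----------
    nn_set:
        Nearest-neighbor parameter set; one of :data:`NN_TABLES`.
    monovalent_mM:
        Total monovalent cation concentration (Na+ equivalents), mM.
    divalent_mM:
        Mg2+ concentration, mM (folded into the Na+ equivalent per
        von Ahsen 2001).
    oligo_nM:
        Primer strand concentration, nM (primer in excess over template).
    """

    nn_set: str = "allawi1997"
    monovalent_mM: float = 50.0
    divalent_mM: float = 3.0
    oligo_nM: float = 250.0

    def __post_init__(self) -> None:
        if self.nn_set not in NN_TABLES:
            raise InputError(
                f"unknown nearest-neighbor set {self.nn_set!r}; "
                f"choose from {sorted(NN_TABLES)}"
            )
        if self.monovalent_mM <= 0:
            raise InputError("monovalent_mM must be > 0")
        if self.divalent_mM < 0:
            raise InputError("divalent_mM must be >= 0")
        if self.oligo_nM <= 0:
            raise InputError("oligo_nM must be > 0")


DEFAULT_THERMO = ThermoParams()


def compute_tm(seq: str, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor melting temperature of ``seq`` in degrees Celsius.

    ``seq`` must be >= 8 nt of unambiguous A/C/G/T. Deterministic in its
    inputs; the reverse complement has the same Tm (duplex symmetry).
    """
    up = validate_dna(seq, "Tm input")
    if len(up) < MIN_TM_LENGTH:
        raise InputError(
            f"Tm input must be >= {MIN_TM_LENGTH} nt, got {len(up)}"
        )
    table = getattr(_mt, NN_TABLES[thermo.nn_set])
    return float(
        _mt.Tm_NN(
            up,
            nn_table=table,
            dnac1=thermo.oligo_nM,
            dnac2=0,
            Na=thermo.monovalent_mM,
            Mg=thermo.divalent_mM,
            saltcorr=5,
        )
    )


def superselective_tm(primer, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Effective Tm of a SuperSelective primer: anchor-only policy."""
    return compute_tm(primer.anchor, thermo)
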