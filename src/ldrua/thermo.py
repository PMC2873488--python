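"""Oligonucleotide melting temperatures.

Duplex Tm is computed with the unified nearest-neighbor thermodynamic
parameter set (SantaLucia 2004) and monovalent-salt correction, at 50 mM Na+
and 0.25 uM probe strand (probe in excess over template).  Degenerate probes
are scored as the arithmetic mean Tm over their concrete expansions, which is
deterministic and symmetric in the expansion order.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.SeqUtils import MeltingTemp as _mt

from .iupac import expand_degenerate

#: default monovalent cation concentration, mM
DEFAULT_NA_MM = 50.0
#: default probe strand concentration, nM (0.25 uM)
DEFAULT_STRAND_NM = 250.0
#: cap on degenerate expansions averaged for one Tm
DEFAULT_EXPANSION_CAP = 256

MIN_TM_LENGTH = 8


@lru_cache(maxsize=200_000)
def _tm_concrete(seq: str, na_mM: float, strand_nM: float) -> float:
    return float(
        _mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=na_mM, dnac1=strand_nM, dnac2=0)
    )


def melting_temperature(
    seq: str,
    na_mM: float = DEFAULT_NA_MM,
    strand_nM: float = DEFAULT_STRAND_NM,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
) -> float:
    """Nearest-neighbor duplex Tm in deg C; mean over expansions if degenerate.

    Raises ``ValueError`` for sequences shorter than 8 nt, where the
    nearest-neighbor model is unreliable.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(f"sequence too short for NN Tm ({len(seq)} < {MIN_TM_LENGTH})")
    expansions = expand_degenerate(seq, cap=expansion_cap)
    return sum(_tm_concrete(e, na_mM, strand_nM) for e in expansions) / len(expansions)
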