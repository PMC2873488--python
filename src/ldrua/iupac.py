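"""IUPAC nucleotide ambiguity codes: expansion, encoding and degenerate matching.

The 15 non-empty subsets of {A, C, G, T} map bijectively onto the IUPAC
one-letter codes.  Degenerate probe/template comparison is done by set
intersection: two symbols are compatible iff their expansions share a base.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

#: code -> set of concrete bases it stands for
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

#: complement over the full ambiguity alphabet
COMPLEMENT: dict[str, str] = {
    code: _BASES_TO_IUPAC[frozenset({"TGCA"["ACGT".index(b)] for b in bases})]
    for code, bases in IUPAC_TO_BASES.items()
}

GAP_CHARS = frozenset("-.")


class CapacityError(ValueError):
    """Degenerate expansion would exceed the requested cap."""


def iupac_for(bases: Iterable[str]) -> str:
    """Return the unique IUPAC code whose expansion equals ``bases``.

    ``bases`` must be a non-empty subset of {A, C, G, T}.
    """
    key = frozenset(str(b).upper() for b in bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    if not key <= frozenset("ACGT"):
        raise ValueError(f"not a subset of ACGT: {sorted(key)}")
    return _BASES_TO_IUPAC[key]


def bases_for(symbol: str) -> frozenset[str]:
    """Expansion of a single IUPAC symbol (U treated as T)."""
    symbol = symbol.upper()
    if symbol == "U":
        symbol = "T"
    try:
        return IUPAC_TO_BASES[symbol]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {symbol!r}") from None


def degeneracy(seq: str) -> int:
    """Number of positions carrying an ambiguity code (expansion > 1 base)."""
    return sum(1 for c in seq if len(bases_for(c)) > 1)


def expansion_count(seq: str) -> int:
    """Product of per-position cardinalities (number of concrete expansions)."""
    n = 1
    for c in seq:
        n *= len(bases_for(c))
    return n


def expand_degenerate(seq: str, cap: int = 4096) -> list[str]:
    """All concrete sequences covered by an IUPAC string, in lexical position order.

    Raises :class:`CapacityError` if the expansion count exceeds ``cap``.
    """
    n = expansion_count(seq)
    if n > cap:
        raise CapacityError(f"{n} expansions exceed cap {cap}")
    pools = [sorted(bases_for(c)) for c in seq]
    return ["".join(p) for p in product(*pools)]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c.upper() if c.upper() != "U" else "T"] for c in reversed(seq))


def symbols_compatible(a: str, b: str) -> bool:
    """True iff the expansions of two IUPAC symbols intersect."""
    return bool(bases_for(a) & bases_for(b))


def sites_match(probe: str, window: str) -> bool:
    """Positionwise IUPAC-intersection match of equal-length strings."""
    if len(probe) != len(window):
        return False
    return all(symbols_compatible(p, w) for p, w in zip(probe, window))


def find_matches(probe: str, target: str) -> list[int]:
    """Start positions in ``target`` where ``probe`` matches by IUPAC intersection."""
    k = len(probe)
    return [i for i in range(len(target) - k + 1) if sites_match(probe, target[i : i + k])]
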