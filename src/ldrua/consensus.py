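"""Group consensus extraction from aligned 16S rRNA sequence sets.

A taxonomic target group is supplied as a multiple alignment of its member
sequences.  The group consensus calls the majority base per column when its
frequency reaches the calling cutoff (default 75%); otherwise the column is
encoded with the IUPAC ambiguity code covering every base above a minority
floor.  Columns dominated by gaps are dropped, so the consensus is the
ungapped template on which ligation probes are designed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .iupac import GAP_CHARS, IUPAC_TO_BASES, bases_for, iupac_for

_VALID_CHARS = frozenset(IUPAC_TO_BASES) | {"U"} | GAP_CHARS


class AlignmentError(ValueError):
    """Sequences of unequal length or otherwise malformed alignment."""


class AlphabetError(ValueError):
    """Characters outside the IUPAC nucleotide alphabet plus gap."""


class DegenerateColumnError(ValueError):
    """Alignment column with no countable (non-gap) characters."""


@dataclass
class AlignedGroup:
    """A named, aligned set of sequences acting as a positive or negative set."""

    group_name: str
    sequences: list[str]
    member_ids: list[str]
    role: str = "positive"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"group {self.group_name!r} is empty")
        norm = []
        for mid, seq in zip(self.member_ids, self.sequences):
            s = seq.upper().replace("U", "T")
            bad = set(s) - _VALID_CHARS
            if bad:
                raise AlphabetError(f"{mid}: illegal characters {sorted(bad)}")
            norm.append(s)
        lengths = {len(s) for s in norm}
        if len(lengths) != 1:
            raise AlignmentError(
                f"group {self.group_name!r}: unequal aligned lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentError(f"group {self.group_name!r}: zero-length alignment")
        self.sequences = norm

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class ConsensusSequence:
    """IUPAC consensus of an aligned group, with per-column base frequencies.

    ``kept_columns`` maps consensus positions back to original alignment
    columns (gap-majority columns are dropped).
    """

    group_name: str
    consensus: str
    column_frequencies: pd.DataFrame
    cutoff: float
    kept_columns: list[int] = field(default_factory=list)


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedGroup:
    """Read one aligned group from a multi-FASTA (or other AlignIO dialect) file.

    Input order and identifiers are preserved; lowercase bases and U are
    normalized.  The group name defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    return AlignedGroup(
        group_name=path.stem,
        sequences=[str(rec.seq) for rec in aln],
        member_ids=[rec.id for rec in aln],
    )


def column_base_counts(group: AlignedGroup) -> pd.DataFrame:
    """Fractional base counts per alignment column.

    An ambiguity code in an input sequence contributes 1/k to each of the k
    bases of its expansion; gaps are counted in a separate ``gap`` column.
    """
    n_cols = group.length
    counts = np.zeros((n_cols, 5))  # A C G T gap
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in group.sequences:
        for j, c in enumerate(seq):
            if c in GAP_CHARS:
                counts[j, 4] += 1.0
            else:
                bs = bases_for(c)
                w = 1.0 / len(bs)
                for b in bs:
                    counts[j, idx[b]] += w
    return pd.DataFrame(counts, columns=["A", "C", "G", "T", "gap"])


def extract_consensus(
    group: AlignedGroup,
    cutoff: float = 0.75,
    minor_floor: float = 0.05,
) -> ConsensusSequence:
    """Call the group consensus with IUPAC coding of polymorphic columns.

    Per column: the base reaching ``cutoff`` frequency is called directly;
    otherwise the IUPAC code covering all bases at frequency >= ``minor_floor``
    is emitted (bases below the floor are treated as noise).  Columns whose
    gap frequency reaches the cutoff are dropped; elsewhere gaps are excluded
    from the frequency normalization.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0.5, 1]")
    if not 0.0 <= minor_floor < cutoff:
        raise ValueError("minor_floor must be in [0, cutoff)")

    counts = column_base_counts(group)
    n = len(group)
    symbols: list[str] = []
    kept: list[int] = []
    freq_rows: list[np.ndarray] = []
    eps = 1e-9

    for j in range(group.length):
        row = counts.iloc[j]
        if row["gap"] / n >= cutoff - eps:
            continue  # gap-majority column: dropped from the consensus
        total = row[["A", "C", "G", "T"]].sum()
        if total <= 0:
            raise DegenerateColumnError(f"column {j} has no countable characters")
        freqs = row[["A", "C", "G", "T"]].to_numpy() / total
        top = freqs.max()
        if top >= cutoff - eps:
            # ties at exactly the cutoff resolve to the ambiguity code of all
            # tied bases (order-independent); with cutoff > 0.5 a tie is only
            # possible at the boundary
            winners = {b for b, f in zip("ACGT", freqs) if f >= top - eps}
            symbols.append(iupac_for(winners))
        else:
            covered = {b for b, f in zip("ACGT", freqs) if f >= minor_floor - eps}
            if not covered:
                covered = {b for b, f in zip("ACGT", freqs) if f > 0}
            symbols.append(iupac_for(covered))
        kept.append(j)
        freq_rows.append(freqs)

    freq_df = pd.DataFrame(freq_rows, columns=["A", "C", "G", "T"], index=kept)
    return ConsensusSequence(
        group_name=group.group_name,
        consensus="".join(symbols),
        column_frequencies=freq_df,
        cutoff=cutoff,
        kept_columns=kept,
    )


def degap(seq: str) -> str:
    """Remove alignment gap characters from a sequence."""
    return "".join(c for c in seq if c not in GAP_CHARS)
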