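"""Ligation probe-pair design against group consensus sequences.

Each target group gets a Discriminating Probe (DS, 5'-labelled, its 3' end on
the discriminating position) and a Common Probe (CP, 5'-phosphate, cZipCode
tail) annealing immediately downstream on the template.  Pairs must satisfy
length (25-60 nt), Tm (68 +/- 1 deg C per oligo) and degeneracy (<= 4 ambiguous
bases per oligo) constraints, perfectly match every positive-set sequence over
the DS+CP footprint, and be discriminated from the whole negative set by at
least one mismatch — the ligation junction at the DS 3' end being the
enforced discriminating position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .consensus import AlignedGroup, ConsensusSequence, degap, extract_consensus
from .iupac import GAP_CHARS, degeneracy, expansion_count, find_matches, sites_match
from .thermo import melting_temperature

#: negative set: id -> (possibly gapped) sequence
SequenceDB = Mapping[str, str]


@dataclass
class DesignConstraints:
    """Thermodynamic and structural probe constraints."""

    min_len: int = 25
    max_len: int = 60
    tm_target: float = 68.0
    tm_tol: float = 1.0
    max_degenerate: int = 4
    discrimination_window: int = 1
    expansion_cap: int = 256

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.tm_tol <= 0:
            raise ValueError("tm_tol must be positive")
        if self.max_degenerate < 0:
            raise ValueError("max_degenerate must be >= 0")


@dataclass
class ProbePair:
    """A DS/CP pair annotated with its template placement and thermodynamics."""

    probe_id: str
    target_group: str
    ds_seq: str
    cp_seq: str
    ds_tm: float
    cp_tm: float
    template_position: int  # start of DS on the (ungapped) consensus
    level: str = "probe"  # probe | sub-probe
    zipcode_id: str | None = None

    @property
    def ds_degenerate(self) -> int:
        return degeneracy(self.ds_seq)

    @property
    def cp_degenerate(self) -> int:
        return degeneracy(self.cp_seq)

    @property
    def footprint(self) -> str:
        """DS+CP concatenation as it sits on the template, 5'->3'."""
        return self.ds_seq + self.cp_seq

    @property
    def junction(self) -> int:
        """Index of the first CP base within the footprint."""
        return len(self.ds_seq)


@dataclass
class MatchReport:
    """Outcome of a specificity check for one probe pair."""

    probe_id: str
    positive_hits: list[str] = field(default_factory=list)
    positive_misses: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    negative_violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.positive_misses and not self.negative_violations


@dataclass
class ProbeSet:
    """Designed probe pairs plus per-group design failures."""

    pairs: list[ProbePair]
    failures: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def by_id(self) -> dict[str, ProbePair]:
        return {p.probe_id: p for p in self.pairs}


def enumerate_candidates(
    consensus: ConsensusSequence | str,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[ProbePair]:
    """All DS/CP pairs on a consensus satisfying the design constraints.

    Candidates are scanned over every (junction, DS length, CP length) triple
    with zero junction gap, and ordered by |mean(DS Tm, CP Tm) - tm_target|,
    then fewer total degenerate bases, then leftmost template position.
    """
    if isinstance(consensus, ConsensusSequence):
        group = consensus.group_name
        template = consensus.consensus
    else:
        group = "consensus"
        template = str(consensus).upper()
    c = constraints
    n = len(template)
    if n < 2 * c.min_len:
        return []

    tm_cache: dict[tuple[int, int], float | None] = {}

    def tm_of(start: int, length: int) -> float | None:
        key = (start, length)
        if key not in tm_cache:
            sub = template[start : start + length]
            if degeneracy(sub) > c.max_degenerate or expansion_count(sub) > c.expansion_cap:
                tm_cache[key] = None
            else:
                tm_cache[key] = melting_temperature(sub, expansion_cap=c.expansion_cap)
        return tm_cache[key]

    out: list[ProbePair] = []
    for junction in range(c.min_len, n - c.min_len + 1):
        for ds_len in range(c.min_len, min(c.max_len, junction) + 1):
            ds_start = junction - ds_len
            ds_tm = tm_of(ds_start, ds_len)
            if ds_tm is None or abs(ds_tm - c.tm_target) > c.tm_tol:
                continue
            for cp_len in range(c.min_len, min(c.max_len, n - junction) + 1):
                cp_tm = tm_of(junction, cp_len)
                if cp_tm is None or abs(cp_tm - c.tm_target) > c.tm_tol:
                    continue
                out.append(
                    ProbePair(
                        probe_id=f"{group}:{ds_start}+{ds_len}/{cp_len}",
                        target_group=group,
                        ds_seq=template[ds_start:junction],
                        cp_seq=template[junction : junction + cp_len],
                        ds_tm=ds_tm,
                        cp_tm=cp_tm,
                        template_position=ds_start,
                    )
                )
    out.sort(
        key=lambda p: (
            abs((p.ds_tm + p.cp_tm) / 2.0 - c.tm_target),
            p.ds_degenerate + p.cp_degenerate,
            p.template_position,
            len(p.ds_seq),
            len(p.cp_seq),
        )
    )
    return out


def _aligned_footprint(pair: ProbePair, member_aligned: str, kept_columns: Sequence[int]):
    """Slice a member's aligned characters at the footprint's consensus columns."""
    cols = kept_columns[pair.template_position : pair.template_position + len(pair.footprint)]
    return "".join(member_aligned[j] for j in cols)


def check_specificity(
    pair: ProbePair,
    positives: AlignedGroup | SequenceDB,
    negatives: SequenceDB,
    constraints: DesignConstraints = DesignConstraints(),
    kept_columns: Sequence[int] | None = None,
) -> MatchReport:
    """Positive perfect-match / negative 3'-mismatch report for one pair.

    A positive hit requires an IUPAC-intersection match of the full DS+CP
    footprint (at the design position when ``positives`` is the aligned group,
    anywhere otherwise); aligned members with a gap inside the footprint are
    skipped and reported.  A negative violation is a full-footprint match
    anywhere in a negative sequence — i.e. the negative lacks the required
    mismatch, in particular at the DS 3'-end junction window.
    """
    report = MatchReport(probe_id=pair.probe_id)
    footprint = pair.footprint

    if isinstance(positives, AlignedGroup):
        cols = list(kept_columns) if kept_columns is not None else list(range(positives.length))
        for mid, seq in zip(positives.member_ids, positives.sequences):
            window = _aligned_footprint(pair, seq, cols)
            if any(ch in GAP_CHARS for ch in window):
                report.skipped.append(mid)
            elif sites_match(footprint, window):
                report.positive_hits.append(mid)
            else:
                report.positive_misses.append(mid)
    else:
        for mid, seq in positives.items():
            if find_matches(footprint, degap(seq)):
                report.positive_hits.append(mid)
            else:
                report.positive_misses.append(mid)

    for nid, seq in negatives.items():
        if find_matches(footprint, degap(seq)):
            report.negative_violations.append(nid)
    return report


def design_probe_set(
    groups: Sequence[tuple[AlignedGroup, SequenceDB]],
    constraints: DesignConstraints = DesignConstraints(),
    cutoff: float = 0.75,
    minor_floor: float = 0.05,
    levels: Mapping[str, str] | None = None,
) -> ProbeSet:
    """One best-ranked passing DS/CP pair per target group.

    For each (positive group, negative set) pair the group consensus is
    extracted, candidates are enumerated in rank order and the first candidate
    passing :func:`check_specificity` is kept under the group's name.  Groups
    with no passing candidate are recorded as failures.  The taxonomic
    hierarchy of the negative sets (family/phylum consensi for high-level
    probes, other families for genus/species probes) is the caller's contract;
    :func:`hierarchical_negative_sets` builds them from annotated groups.
    """
    pairs: list[ProbePair] = []
    failures: dict[str, str] = {}
    for group, negatives in groups:
        cons = extract_consensus(group, cutoff=cutoff, minor_floor=minor_floor)
        candidates = enumerate_candidates(cons, constraints)
        if not candidates:
            failures[group.group_name] = "no candidate satisfies the design constraints"
            continue
        chosen = None
        for cand in candidates:
            rep = check_specificity(
                cand, group, negatives, constraints, kept_columns=cons.kept_columns
            )
            if rep.passed:
                chosen = cand
                break
        if chosen is None:
            failures[group.group_name] = "no candidate passes the specificity check"
            continue
        level = (levels or {}).get(group.group_name, "probe")
        pairs.append(
            replace(chosen, probe_id=group.group_name, target_group=group.group_name, level=level)
        )
    return ProbeSet(pairs=pairs, failures=failures)


def hierarchical_negative_sets(
    groups: Sequence[AlignedGroup],
    taxonomy: Mapping[str, tuple[str, str]],
) -> list[tuple[AlignedGroup, SequenceDB]]:
    """Build per-group negative sets respecting the taxonomic hierarchy.

    ``taxonomy`` maps group name -> (rank, family) where rank is ``"high"``
    (family/phylum/cluster probes) or ``"low"`` (genus/species probes).
    High-level targets are discriminated against the consensi of the other
    high-level groups; low-level targets against all member sequences of
    groups from other families.
    """
    consensi = {g.group_name: extract_consensus(g).consensus for g in groups}
    out: list[tuple[AlignedGroup, SequenceDB]] = []
    for g in groups:
        rank, family = taxonomy[g.group_name]
        negatives: dict[str, str] = {}
        for other in groups:
            if other.group_name == g.group_name:
                continue
            o_rank, o_family = taxonomy[other.group_name]
            if rank == "high":
                if o_rank == "high":
                    negatives[other.group_name] = consensi[other.group_name]
            else:
                if o_family != family:
                    for mid, seq in zip(other.member_ids, other.sequences):
                        negatives[f"{other.group_name}:{mid}"] = seq
        out.append((g, negatives))
    return out


def probe_set_summary(probe_set: ProbeSet) -> dict[str, float]:
    """n, Tm and length mean/SD over all DS and CP oligos, degeneracy counts."""
    if not probe_set.pairs:
        raise ValueError("empty probe set")
    tms = np.array([t for p in probe_set for t in (p.ds_tm, p.cp_tm)])
    lengths = np.array([L for p in probe_set for L in (len(p.ds_seq), len(p.cp_seq))])
    ddof = 1 if len(tms) > 1 else 0
    return {
        "n_pairs": float(len(probe_set)),
        "n_oligos": float(len(tms)),
        "tm_mean": float(tms.mean()),
        "tm_sd": float(tms.std(ddof=ddof)),
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std(ddof=ddof)),
        "n_pairs_no_degenerate": float(
            sum(1 for p in probe_set if p.ds_degenerate == 0 and p.cp_degenerate == 0)
        ),
    }
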