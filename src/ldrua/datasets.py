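"""Seeded synthetic fixtures: divergent 16S-like groups and template mixes.

These generators build the toy study material used by the test-bench and the
simulation pipeline: a set of phylogenetically divergent sequence groups
(each with its own signature substitutions, so every group has discriminating
sites against the others), aligned trivially at equal length, plus template
mixes emulating artificial amplicon mixtures.  Within-group variation is
modelled as shared polymorphic columns (called as IUPAC ambiguity codes in
the consensus); the perfectly conserved remainder mirrors the conserved
stretches on which real ligation probes are designed.  All output is a pure
function of the seed.
"""

from __future__ import annotations

import numpy as np

from .consensus import AlignedGroup
from .design import (
    DesignConstraints,
    ProbeSet,
    SequenceDB,
    design_probe_set,
)
from .simulate import TemplateMix

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def synthetic_group_alignments(
    n_groups: int = 6,
    members: int = 4,
    length: int = 240,
    divergence: float = 0.04,
    n_polymorphic: int = 3,
    seed: int = 0,
) -> list[AlignedGroup]:
    """Divergent aligned groups derived from one common ancestor.

    Each group substitutes ~``divergence`` of the ancestor positions with a
    different base (its signature), then ``n_polymorphic`` columns are made
    biallelic with half of the members carrying the alternative base.  Group
    members are otherwise identical, so the group consensus at the default
    75% cutoff matches every member over any probe footprint.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_sequence(rng, length)
    groups: list[AlignedGroup] = []
    for g in range(n_groups):
        seq = list(ancestor)
        n_sub = max(1, rng.binomial(length, divergence))
        for j in rng.choice(length, size=n_sub, replace=False):
            alternatives = [b for b in "ACGT" if b != seq[j]]
            seq[j] = alternatives[rng.integers(len(alternatives))]
        base = "".join(seq)
        member_seqs = [list(base) for _ in range(members)]
        poly_cols = rng.choice(length, size=min(n_polymorphic, length), replace=False)
        carriers = list(range(members))[: members // 2] if members > 1 else []
        for j in poly_cols:
            alternatives = [b for b in "ACGT" if b != base[j]]
            alt = alternatives[rng.integers(len(alternatives))]
            for m in carriers:
                member_seqs[m][j] = alt
        name = f"group{g + 1:02d}"
        groups.append(
            AlignedGroup(
                group_name=name,
                sequences=["".join(s) for s in member_seqs],
                member_ids=[f"{name}_m{m + 1}" for m in range(members)],
            )
        )
    return groups


def cross_group_negatives(
    groups: list[AlignedGroup],
) -> list[tuple[AlignedGroup, SequenceDB]]:
    """Each group against the member sequences of every other group."""
    out = []
    for g in groups:
        negatives = {
            f"{o.group_name}:{mid}": seq
            for o in groups
            if o.group_name != g.group_name
            for mid, seq in zip(o.member_ids, o.sequences)
        }
        out.append((g, negatives))
    return out


def design_synthetic_probe_set(
    groups: list[AlignedGroup],
    constraints: DesignConstraints = DesignConstraints(),
) -> ProbeSet:
    """Design one probe pair per synthetic group, all others as negatives."""
    return design_probe_set(cross_group_negatives(groups), constraints)


def group_templates(groups: list[AlignedGroup]) -> dict[str, str]:
    """One concrete template per group (its last member, gap-free by design).

    The last member never carries the alternative allele at polymorphic
    columns, so it is a clean representative amplicon of the group.
    """
    return {g.group_name: g.sequences[-1] for g in groups}


def make_mix(
    templates: dict[str, str],
    fmol: float | dict[str, float],
    background_ug: float = 0.0,
    label: str = "mix",
) -> TemplateMix:
    """Template mix with per-template amounts in fmol."""
    if isinstance(fmol, dict):
        amounts = fmol
    else:
        amounts = {t: float(fmol) for t in templates}
    return TemplateMix(
        templates={t: (seq, amounts.get(t, 0.0)) for t, seq in templates.items()},
        background_gdna_ug=background_ug,
        label=label,
    )


def water_control(templates: dict[str, str], label: str = "water") -> TemplateMix:
    """Negative-control mix: every template at 0 fmol."""
    return make_mix(templates, 0.0, label=label)


def synthetic_cohort(
    templates: dict[str, str],
    n_samples: int = 8,
    presence_prob: float = 0.65,
    fmol_range: tuple[float, float] = (5.0, 60.0),
    seed: int = 0,
) -> list[TemplateMix]:
    """Subject-like samples with distinct presence patterns and amounts.

    Each template is carried by a sample with probability ``presence_prob``
    at a uniform amount in ``fmol_range`` fmol (0 fmol otherwise), emulating
    the subject-specific complements of target groups seen in faecal
    fingerprints; every sample keeps at least one template.
    """
    rng = np.random.default_rng(seed)
    lo, hi = fmol_range
    mixes = []
    names = list(templates)
    for s in range(n_samples):
        present = rng.random(len(names)) < presence_prob
        if not present.any():
            present[rng.integers(len(names))] = True
        amounts = {
            t: float(rng.uniform(lo, hi)) if keep else 0.0
            for t, keep in zip(names, present)
        }
        mixes.append(make_mix(templates, amounts, label=f"subject{s + 1:02d}"))
    return mixes
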