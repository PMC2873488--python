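"""Universal Array model: ZipCode pool, subarray geometry and control spots.

A Universal Array is a grid of spotted ZipCode oligos, decoupled from assay
content: each ligation product is addressed to its spot by the cZipCode tail
on the Common Probe.  The default layout mirrors an 8-subarray slide where
each subarray spots 47 probe ZipCodes in quadruplicate plus 8 hybridization
controls, 6 ligation controls and 6 blanks (208 spots).

Spot type flags: 1 = hybridization control, 2 = ligation control,
3 = probe-assigned ZipCode, 4 = unused ZipCode, 5 = blank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TYPE_HYB = 1
TYPE_LIG = 2
TYPE_PROBE = 3
TYPE_UNUSED = 4
TYPE_BLANK = 5

#: hybridization-control address (cZip 66, 5'-Cy3 labelled oligo)
HYB_CONTROL_ZIP_ID = "zip66"
HYB_CONTROL_SEQUENCE = "GTTACCGCTGGTGCTGCCGCCGGTA"
LIG_CONTROL_ZIP_ID = "zipLIG"
BLANK_ZIP_ID = "blank"


class LayoutError(ValueError):
    """Grid capacity exceeded or inconsistent layout request."""


class ZipCapacityError(ValueError):
    """Fewer ZipCodes than probes to address."""


@dataclass(frozen=True)
class ZipCode:
    zip_id: str
    sequence: str  # empty for blanks
    role: str = "probe"  # probe | hybridization_control | ligation_control | blank | unused


@dataclass
class ArrayLayout:
    """Deterministic spot map of one slide.

    ``spots`` columns: subarray, row, col, zip_id, type_flag.
    """

    n_subarrays: int
    spots: pd.DataFrame
    replicates_per_zip: int
    control_replicates: tuple[int, int, int]  # hybridization, ligation, blank
    grid: tuple[int, int] = (16, 13)
    zip_roles: dict[str, str] = field(default_factory=dict)

    @property
    def spots_per_subarray(self) -> int:
        return int((self.spots["subarray"] == 0).sum())

    def probe_zip_ids(self) -> list[str]:
        mask = self.spots["type_flag"].isin([TYPE_PROBE, TYPE_UNUSED])
        return sorted(self.spots.loc[mask, "zip_id"].unique())


def default_zipcode_pool(
    n: int = 47, length: int = 25, seed: int = 66
) -> list[ZipCode]:
    """Deterministic pool of unique artificial ZipCode sequences.

    ZipCodes are address oligos, not biological sequences; a seeded uniform
    composition is adequate for simulation purposes.
    """
    rng = np.random.default_rng(seed)
    seqs: set[str] = set()
    pool: list[ZipCode] = []
    i = 1
    while len(pool) < n:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if seq in seqs or seq == HYB_CONTROL_SEQUENCE:
            continue
        seqs.add(seq)
        pool.append(ZipCode(zip_id=f"zip{i:02d}", sequence=seq, role="probe"))
        i += 1
    return pool


def assign_zipcodes(
    probe_set, pool: Sequence[ZipCode]
) -> dict[str, str]:
    """Injective, order-stable probe_id -> zip_id assignment.

    Probes are taken in probe-set order, ZipCodes in pool order, so re-runs
    with identical inputs give identical mappings.
    """
    usable = [z for z in pool if z.role in ("probe", "unused")]
    probes = [p.probe_id for p in probe_set]
    if len(usable) < len(probes):
        raise ZipCapacityError(
            f"{len(probes)} probes but only {len(usable)} assignable ZipCodes"
        )
    return {pid: z.zip_id for pid, z in zip(probes, usable)}


def build_layout(
    pool: Sequence[ZipCode] | int = 47,
    n_subarrays: int = 8,
    replicates_per_zip: int = 4,
    control_replicates: tuple[int, int, int] = (8, 6, 6),
    grid: tuple[int, int] = (16, 13),
    assigned_zip_ids: Sequence[str] = (),
) -> ArrayLayout:
    """Deterministic spot grid for every subarray of a slide.

    Spots are placed row-major: hybridization controls, then each probe
    ZipCode in pool order in ``replicates_per_zip`` adjacent spots, then
    ligation controls, then blanks.  ZipCodes in ``assigned_zip_ids`` are
    flagged as probe spots (3), the rest as unused (4).
    """
    if isinstance(pool, int):
        pool = default_zipcode_pool(pool)
    n_hyb, n_lig, n_blank = control_replicates
    if min(n_subarrays, replicates_per_zip) <= 0 or min(control_replicates) < 0:
        raise LayoutError("counts must be positive (controls may be zero)")
    total = len(pool) * replicates_per_zip + n_hyb + n_lig + n_blank
    rows, cols = grid
    if total > rows * cols:
        raise LayoutError(f"{total} spots exceed {rows}x{cols} grid capacity")

    assigned = set(assigned_zip_ids)
    per_sub: list[tuple[str, int]] = []
    per_sub += [(HYB_CONTROL_ZIP_ID, TYPE_HYB)] * n_hyb
    for z in pool:
        flag = TYPE_PROBE if z.zip_id in assigned else TYPE_UNUSED
        per_sub += [(z.zip_id, flag)] * replicates_per_zip
    per_sub += [(LIG_CONTROL_ZIP_ID, TYPE_LIG)] * n_lig
    per_sub += [(BLANK_ZIP_ID, TYPE_BLANK)] * n_blank

    records = []
    for s in range(n_subarrays):
        for k, (zip_id, flag) in enumerate(per_sub):
            records.append((s, k // cols, k % cols, zip_id, flag))
    spots = pd.DataFrame(records, columns=["subarray", "row", "col", "zip_id", "type_flag"])

    roles = {z.zip_id: ("probe" if z.zip_id in assigned else "unused") for z in pool}
    roles[HYB_CONTROL_ZIP_ID] = "hybridization_control"
    roles[LIG_CONTROL_ZIP_ID] = "ligation_control"
    roles[BLANK_ZIP_ID] = "blank"
    return ArrayLayout(
        n_subarrays=n_subarrays,
        spots=spots,
        replicates_per_zip=replicates_per_zip,
        control_replicates=control_replicates,
        grid=grid,
        zip_roles=roles,
    )


def zip_to_probe(assignment: Mapping[str, str]) -> dict[str, str]:
    """Invert a probe_id -> zip_id assignment."""
    inv = {z: p for p, z in assignment.items()}
    if len(inv) != len(assignment):
        raise ValueError("assignment is not injective")
    return inv
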