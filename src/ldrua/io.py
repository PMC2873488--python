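"""Tab-delimited and FASTA serialization of the toolkit's tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .array import ArrayLayout
from .consensus import ConsensusSequence
from .design import DesignConstraints, ProbePair, ProbeSet
from .simulate import SPOT_COLUMNS, TemplateMix

PROBE_COLUMNS = [
    "probe_id", "target_group", "level", "ds_seq", "cp_seq",
    "ds_tm", "cp_tm", "ds_degenerate", "cp_degenerate",
    "template_position", "zipcode_id",
]


def write_probe_set(probe_set: ProbeSet, path: str | Path) -> None:
    rows = [
        {
            "probe_id": p.probe_id, "target_group": p.target_group, "level": p.level,
            "ds_seq": p.ds_seq, "cp_seq": p.cp_seq, "ds_tm": p.ds_tm, "cp_tm": p.cp_tm,
            "ds_degenerate": p.ds_degenerate, "cp_degenerate": p.cp_degenerate,
            "template_position": p.template_position,
            "zipcode_id": p.zipcode_id or "",
        }
        for p in probe_set
    ]
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_set(path: str | Path) -> ProbeSet:
    df = pd.read_csv(path, sep="\t", dtype={"zipcode_id": str}, keep_default_na=False)
    pairs = [
        ProbePair(
            probe_id=r["probe_id"], target_group=r["target_group"], level=r["level"],
            ds_seq=r["ds_seq"], cp_seq=r["cp_seq"],
            ds_tm=float(r["ds_tm"]), cp_tm=float(r["cp_tm"]),
            template_position=int(r["template_position"]),
            zipcode_id=r["zipcode_id"] or None,
        )
        for _, r in df.iterrows()
    ]
    return ProbeSet(pairs=pairs)


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    layout.spots.to_csv(path, sep="\t", index=False)


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_call_table(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_call_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assignment(assignment: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["probe_id", "zip_id"]
    ).to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["probe_id"], df["zip_id"]))


def write_consensus(cons: ConsensusSequence, fasta_path: str | Path,
                    freq_path: str | Path | None = None) -> None:
    """Consensus as FASTA with per-column frequencies in a sidecar TSV."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{cons.group_name} cutoff={cons.cutoff}\n{cons.consensus}\n")
    if freq_path is not None:
        df = cons.column_frequencies.copy()
        df.index.name = "alignment_column"
        df.to_csv(freq_path, sep="\t")


def read_constraints(path: str | Path) -> DesignConstraints:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DesignConstraints(**data)


def read_mix(path: str | Path) -> TemplateMix:
    """Mix YAML: {label, background_gdna_ug, templates: {id: {sequence, fmol}}}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    templates = {
        tid: (entry["sequence"], float(entry["fmol"]))
        for tid, entry in data["templates"].items()
    }
    return TemplateMix(
        templates=templates,
        background_gdna_ug=float(data.get("background_gdna_ug", 0.0)),
        label=data.get("label", Path(path).stem),
    )


def read_group_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns group_name, role, fasta_path."""
    df = pd.read_csv(path, sep="\t")
    required = {"group_name", "role", "fasta_path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df
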