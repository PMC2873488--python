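"""Default probe annotation for the 30-target gut microbiota array.

Each probe targets a phylogenetically related group of the human intestinal
microbiota.  ECO classes: M = mutualistic symbiont, O = opportunist,
P = pathogen (O/P where both apply).  The ecological grouping used for
comprehensive relative-IF summaries is major mutualist / minor mutualist /
opportunistic pathogen.  Sub-probes are finer-resolution targets (species or
genus) nested under a broader probe on the array; they are excluded from
relative-contribution totals.
"""

from __future__ import annotations

import pandas as pd

# probe, eco, grouping, sub_probe, parent
_PROBES: list[tuple[str, str, str, bool, str]] = [
    ("Bacteroides/Prevotella", "M", "major", False, ""),
    ("Ruminococcus bromii et rel.", "M", "major", False, ""),
    ("Ruminococcus albus et rel.", "M", "major", False, ""),
    ("Faecalibacterium prausnitzii et rel.", "M", "major", False, ""),
    ("Oscillospira guillermondii et rel.", "M", "major", False, ""),
    ("Clostridium cluster IX", "M", "major", False, ""),
    ("Veillonella", "M", "major", True, "Clostridium cluster IX"),
    ("Clostridium cluster XIVa", "M", "major", False, ""),
    ("Eubacterium rectale et rel.", "M", "major", True, "Clostridium cluster XIVa"),
    ("Bifidobacteriaceae", "M", "minor", False, ""),
    ("Bifidobacterium longum et rel.", "M", "minor", True, "Bifidobacteriaceae"),
    ("Lactobacillaceae", "M", "minor", False, ""),
    ("Lactobacillus plantarum et rel.", "M", "minor", True, "Lactobacillaceae"),
    ("Lactobacillus casei et rel.", "M", "minor", True, "Lactobacillaceae"),
    ("Lactobacillus salivarius et rel.", "M", "minor", True, "Lactobacillaceae"),
    ("Bacillus clausii et rel.", "M", "minor", False, ""),
    ("Bacillus subtilis et rel.", "M", "minor", False, ""),
    ("Fusobacterium", "M", "minor", False, ""),
    ("Cyanobacteria", "M", "minor", False, ""),
    ("Clostridium cluster XI", "O", "opportunistic", False, ""),
    ("Clostridium difficile et rel.", "O", "opportunistic", True, "Clostridium cluster XI"),
    ("Clostridium cluster I and II", "O", "opportunistic", False, ""),
    ("Clostridium perfringens et rel.", "O", "opportunistic", True, "Clostridium cluster I and II"),
    ("Enterococcus faecalis et rel.", "O", "opportunistic", False, ""),
    ("Enterococcus faecium et rel.", "O", "opportunistic", False, ""),
    ("Bacillus cereus et rel.", "P", "opportunistic", False, ""),
    ("Enterobacteriaceae", "O/P", "opportunistic", False, ""),
    ("Yersinia enterocolitica et rel.", "O/P", "opportunistic", True, "Enterobacteriaceae"),
    ("Proteus", "O/P", "opportunistic", True, "Enterobacteriaceae"),
    ("Campylobacter", "P", "opportunistic", False, ""),
]


def default_probe_annotation() -> pd.DataFrame:
    """The 30-probe annotation table (probe, eco, grouping, sub_probe, parent)."""
    return pd.DataFrame(
        _PROBES, columns=["probe", "eco", "grouping", "sub_probe", "parent"]
    ).set_index("probe")


def ecology_map(annotation: pd.DataFrame | None = None) -> dict[str, tuple[str, str]]:
    """probe_id -> (eco class, grouping) over the whole probe set."""
    ann = default_probe_annotation() if annotation is None else annotation
    return {p: (row["eco"], row["grouping"]) for p, row in ann.iterrows()}
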