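"""In-silico LDR-Universal Array experiments.

The simulator is the package's synthetic-data generator.  It models the
cycled ligase detection reaction as a linear signal source: a probe pair
produces ``yield_per_fmol`` signal units per fmol of any template carrying a
perfectly matching DS+CP site (the junction base under the DS 3' end must
match exactly; the cycled amplification is collapsed into the linear
constant).  Spot fluorescence is drawn from a multiplicative lognormal noise
model around background + yield, with a per-spot pixel SD emitted so the
downstream conservative-null calling rule can be exercised.  Background
genomic DNA is inert: it only enters the fractional-abundance bookkeeping,
as in experiments where human gDNA dilutes the amplicon of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array import (
    TYPE_BLANK,
    TYPE_HYB,
    TYPE_LIG,
    TYPE_PROBE,
    TYPE_UNUSED,
    ArrayLayout,
    zip_to_probe,
)
from .design import ProbePair, ProbeSet
from .iupac import bases_for

SPOT_COLUMNS = ["sample_id", "subarray", "zip_id", "replicate", "IF", "pixel_sd", "type_flag"]


@dataclass
class TemplateMix:
    """A sample: concrete template sequences with molar amounts in fmol."""

    templates: dict[str, tuple[str, float]]
    background_gdna_ug: float = 0.0
    label: str = "sample"

    def __post_init__(self) -> None:
        for tid, (seq, fmol) in self.templates.items():
            if fmol < 0:
                raise ValueError(f"{tid}: negative amount")
            if any(len(bases_for(c)) != 1 for c in seq.upper().replace("U", "T")):
                raise ValueError(f"{tid}: template must be a concrete A/C/G/T sequence")

    def scaled(self, factor: float, label: str | None = None) -> "TemplateMix":
        return TemplateMix(
            templates={t: (s, a * factor) for t, (s, a) in self.templates.items()},
            background_gdna_ug=self.background_gdna_ug,
            label=label or self.label,
        )


@dataclass
class LigationParams:
    """Stringency and calibration of LDR product formation."""

    junction_window: int = 1  # exact-match nt at the DS 3' end
    body_mismatch_tolerance: int = 0  # mismatches tolerated outside the junction
    yield_per_fmol: float = 400.0  # signal units per fmol of matched template

    def __post_init__(self) -> None:
        if self.junction_window < 1:
            raise ValueError("junction_window must be >= 1")
        if self.body_mismatch_tolerance < 0:
            raise ValueError("body_mismatch_tolerance must be >= 0")


@dataclass
class NoiseParams:
    """Spot noise model: lognormal multiplicative around the expected level."""

    background_mean: float = 100.0  # a.u., expected blank level
    spot_cv: float = 0.15  # lognormal coefficient of variation
    pixel_sd_fraction: float = 0.10  # per-spot pixel SD as fraction of IF
    hyb_control_level: float = 5000.0  # a.u.
    lig_control_level: float = 1500.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_mean, self.spot_cv, self.pixel_sd_fraction) < 0:
            raise ValueError("noise parameters must be non-negative")


class ConfigurationError(ValueError):
    """Probe without an addressable ZipCode spot."""


def _matches_with_junction(
    pair: ProbePair, template: str, params: LigationParams
) -> bool:
    """True iff the template carries a ligatable DS+CP site.

    The junction window (last bases of the DS, where the ligase proofreads)
    must match exactly; at most ``body_mismatch_tolerance`` mismatches are
    tolerated elsewhere in the footprint.  Matching is IUPAC-aware for
    degenerate probe positions.
    """
    fp = pair.footprint
    k = len(fp)
    win_lo = pair.junction - params.junction_window
    win_hi = pair.junction  # footprint indices [win_lo, win_hi) are the junction
    t = template.upper().replace("U", "T")
    for start in range(len(t) - k + 1):
        body_mm = 0
        ok = True
        for i in range(k):
            if bases_for(fp[i]) & bases_for(t[start + i]):
                continue
            if win_lo <= i < win_hi:
                ok = False
                break
            body_mm += 1
            if body_mm > params.body_mismatch_tolerance:
                ok = False
                break
        if ok:
            return True
    return False


def ligation_yield(
    pair: ProbePair,
    template: str,
    amount_fmol: float,
    params: LigationParams = LigationParams(),
) -> float:
    """Expected LDR product signal from one template, linear in its amount."""
    if amount_fmol < 0:
        raise ValueError("amount must be >= 0")
    if amount_fmol == 0:
        return 0.0
    if _matches_with_junction(pair, template, params):
        return amount_fmol * params.yield_per_fmol
    return 0.0


def expected_probe_signals(
    probe_set: ProbeSet | Sequence[ProbePair],
    mix: TemplateMix,
    params: LigationParams = LigationParams(),
) -> dict[str, float]:
    """Noise-free expected yield per probe over all templates in the mix."""
    out: dict[str, float] = {}
    for pair in probe_set:
        out[pair.probe_id] = sum(
            ligation_yield(pair, seq, fmol, params)
            for seq, fmol in mix.templates.values()
        )
    return out


def _lognormal(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return mean.copy()
    sigma2 = np.log1p(cv * cv)
    mu = np.log(np.where(mean > 0, mean, 1.0)) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    return np.where(mean > 0, draws, 0.0)


def simulate_experiment(
    probe_set: ProbeSet | Sequence[ProbePair],
    layout: ArrayLayout,
    mix: TemplateMix,
    noise: NoiseParams = NoiseParams(),
    ligation: LigationParams = LigationParams(),
    assignment: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One spot-intensity table for the whole layout (one record per spot).

    Every subarray hybridizes the same mix, modelling technical replicate
    LDRs of one sample on one slide.  Output is bit-identical for identical
    inputs and seed.
    """
    pairs = list(probe_set)
    if assignment is None:
        assignment = {p.probe_id: p.zipcode_id for p in pairs}
    for pid, zid in assignment.items():
        if zid is None:
            raise ConfigurationError(f"probe {pid} has no assigned ZipCode")
    inv = zip_to_probe(assignment)
    layout_zips = set(layout.spots["zip_id"])
    missing = [z for z in inv if z not in layout_zips]
    if missing:
        raise ConfigurationError(f"assigned ZipCodes absent from layout: {missing}")

    signals = expected_probe_signals(pairs, mix, ligation)
    level_by_flag = {
        TYPE_HYB: noise.hyb_control_level,
        TYPE_LIG: noise.lig_control_level,
        TYPE_UNUSED: noise.background_mean,
        TYPE_BLANK: noise.background_mean,
    }

    spots = layout.spots
    expected = np.empty(len(spots))
    for i, (zid, flag) in enumerate(zip(spots["zip_id"], spots["type_flag"])):
        if flag == TYPE_PROBE:
            pid = inv.get(zid)
            expected[i] = noise.background_mean + (signals.get(pid, 0.0) if pid else 0.0)
        else:
            expected[i] = level_by_flag[flag]

    rng = np.random.default_rng(noise.seed if seed is None else seed)
    intensity = _lognormal(rng, expected, noise.spot_cv)
    out = spots.copy()
    out.insert(0, "sample_id", mix.label)
    out["IF"] = intensity
    out["pixel_sd"] = noise.pixel_sd_fraction * intensity
    out["replicate"] = out.groupby(["subarray", "zip_id"]).cumcount()
    return out[SPOT_COLUMNS]


def simulate_samples(
    probe_set: ProbeSet | Sequence[ProbePair],
    layout: ArrayLayout,
    mixes: Sequence[TemplateMix],
    noise: NoiseParams = NoiseParams(),
    ligation: LigationParams = LigationParams(),
    assignment: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hybridize one mix per subarray (sample i -> subarray i) on one slide."""
    if len(mixes) > layout.n_subarrays:
        raise ConfigurationError(
            f"{len(mixes)} samples exceed {layout.n_subarrays} subarrays"
        )
    base_seed = (noise.seed if seed is None else seed)
    frames = []
    for i, mix in enumerate(mixes):
        table = simulate_experiment(
            probe_set, layout, mix, noise, ligation, assignment,
            seed=(base_seed + 7919 * i) % (2**31),
        )
        table = table[table["subarray"] == i].copy()
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


#: average molar mass of one double-stranded base pair, g/mol
DEFAULT_DA_PER_BP = 650.0


def amplicon_mass(length_bp: float, amount_fmol: float, da_per_bp: float = DEFAULT_DA_PER_BP) -> float:
    """Mass in ng of an amplicon given its length and molar amount.

    ng = fmol * length_bp * da_per_bp / 1e6.  A ~1700 bp 16S amplicon at
    1 fmol weighs ~1.1 ng with the 650 g/mol/bp default.
    """
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if amount_fmol < 0:
        raise ValueError("amount must be >= 0")
    return amount_fmol * length_bp * da_per_bp / 1e6


def fractional_abundance(target_ng: float, background_ug: float) -> float:
    """Target mass as percent of the background DNA mass."""
    if background_ug <= 0:
        raise ZeroDivisionError("background mass must be positive")
    return 100.0 * target_ng / (background_ug * 1000.0)


def format_percent(value: float, decimals: int = 2) -> str:
    """Presentation rounding of a percentage, e.g. 0.01754 -> '0.02%'."""
    return f"{round(value, decimals):.{decimals}f}%"
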