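# Methods

This note documents the models, defaults and numerical choices behind
`ldrua`, and what the synthetic test-bench does and does not establish
about real data.

## Consensus extraction

A target group is an equal-length alignment of member 16S sequences.
Per column, base frequencies are computed over non-gap characters; an
ambiguity code in an input sequence contributes 1/k of a count to each of
the k bases it covers. The column is called as the majority base when its
frequency reaches the **calling cutoff** (default 0.75); otherwise the
IUPAC code covering every base at frequency ≥ the **minority floor**
(default 0.05) is emitted. Two parameters are deliberately exposed rather
than fixed, because only the 75% cutoff is a platform constant:

- *minority floor* — bases below 5% are treated as sequencing noise and
  excluded from the ambiguity code; raising it yields less degenerate
  probes at the cost of positive-set coverage.
- *gap policy* — columns whose gap frequency reaches the cutoff are
  dropped (probes are designed on ungapped consensi); gaps elsewhere are
  ignored in the normalization. A column with no countable character is an
  error rather than a silent `N`.

Ties at exactly the cutoff resolve to the ambiguity code of all tied
bases, which is order-independent and therefore deterministic.

## Thermodynamics

Duplex Tm uses the unified nearest-neighbor parameter set
(SantaLucia-type, the `DNA_NN3` table of Biopython's `MeltingTemp`) with
the entropic monovalent-salt correction at **50 mM Na⁺** and **0.25 µM**
probe strand in excess. The upstream probe-design tool this module
replaces does not publish its thermodynamic model, so the design target is
internal consistency — every emitted oligo within 68 ± 1 °C under the
documented model — not reproduction of any particular published probe
list. Degenerate oligos are scored as the arithmetic mean Tm over their
concrete expansions (capped at 256), a deterministic and
expansion-order-symmetric choice.

## Probe design

Candidates are enumerated exhaustively over every (junction, DS length,
CP length) triple with zero junction gap, filtered by length (25–60 nt),
per-oligo Tm (68 ± 1 °C) and per-oligo degeneracy (≤ 4). Ranking is a
total order: |mean(DS Tm, CP Tm) − 68| first, then fewer degenerate bases,
then leftmost position (ties broken by DS then CP length), so re-runs are
bit-identical.

The specificity filter is the platform's defining rule. A **positive hit**
requires an IUPAC-intersection match of the full DS+CP footprint — at the
design coordinates for aligned positive members (members with a gap inside
the footprint are skipped and reported, since no ungapped probe can cover
them), anywhere in the sequence for an unaligned database. A **negative
violation** is a full-footprint match anywhere in a negative sequence:
a mismatch at any footprint position, in particular under the
1-nt discrimination window at the DS 3' end, discriminates. The window
width is configurable; 1 nt reflects the ligase's junction fidelity.

Hierarchical negative sets follow the platform's convention: family- and
cluster-level targets are discriminated against the consensi of the other
high-level groups; genus/species targets against all member sequences of
other families.

## Array model

The Universal Array is content-agnostic: a deterministic grid of ZipCode
spots. Defaults mirror the platform geometry — 8 subarrays, 47 probe
ZipCodes in quadruplicate plus 8 hybridization controls, 6 ligation
controls and 6 blanks (208 spots per subarray) on a 16 × 13 grid — but
every count is a parameter and no total is hard-coded, because the printed
platform totals (a 49-ZipCode pool vs 208 spots with quadruplicates and
8/6/6 controls) only reconcile if 47 ZipCodes are actually spotted.
ZipCode assignment is ordered and injective, so layouts and assignments
are reproducible artifacts.

## LDR simulation (the synthetic-data generator)

The simulator emulates the platform's validation experiments: an
artificial amplicon mixture hybridized to one or more subarrays.

- **Ligation**: product signal is `yield_per_fmol` × template fmol when
  the template carries a footprint site matching exactly under the
  junction window (IUPAC-aware for degenerate probe positions), else zero.
  The cycled reaction is collapsed into the single linear constant because
  ligation is linear per cycle; `yield_per_fmol = 400` a.u. is calibrated
  so that the standard 50 fmol input yields specific SNR of order 200 and
  non-specific SNR of order 1–3, the magnitudes reported for the wet
  platform.
- **Noise**: spot IF is lognormal with arithmetic mean = background +
  yield and CV = `spot_cv` (default 0.15, a typical spot-level
  reproducibility for spotted arrays); blanks and unused ZipCodes sit at
  `background_mean` (100 a.u.); hybridization/ligation controls at fixed
  high levels. Per-spot pixel SD is emitted as `pixel_sd_fraction` × IF
  (default 0.10) so the +2SD conservative null is exercisable.
- **Background gDNA** is inert — it only enters fractional-abundance
  bookkeeping, mirroring experiments where human genomic DNA dilutes the
  target amplicon without hybridizing.
- Everything is a pure function of the seed; identical configuration and
  seed give bit-identical spot tables.

Unit conversions use 650 g·mol⁻¹ per base pair by default (configurable),
under which 1 fmol of a 1700 bp amplicon is 1.105 ng and the detection
limit against 6.3 µg of background DNA presents as 0.02%.

**What the generator does not model**: PCR amplification bias, rRNA
operon copy-number variation, cross-hybridization free energies, spatial
artefacts and image segmentation. Within-group sequence variation is
modelled as shared polymorphic columns only; real groups also carry
singleton variants that would force probe design into the conserved
stretches the generator idealizes. Passing tests therefore demonstrate the
correctness and calibration of the statistical pipeline, not field
performance on faecal samples.

## Signal calling

Per hybridization (one subarray), the null is the blank-spot population
with +2 × pixel SD added per spot — a conservative estimate. Replicates
below `outlier_factor` (2.5) × the adjusted null mean are discarded, but
never below `min_replicates` (2, since up to two of four replicates may
drop out), and if all replicates are below threshold none are excluded:
the probe simply tests absent. Retained replicates are tested against the
adjusted blank values with a **one-sided Welch t-test**; Welch rather than
pooled variance because signal and blank spreads differ by orders of
magnitude and no pooling assumption is warranted at n = 4 vs 6. Presence
is p < α with α = 0.01 (0.05 in sensitivity mode). The outlier reference
("the distribution mean") is read as the adjusted null mean — the only
distribution defined by the calling rule — but a switch to the raw blank
mean is provided. SNR denominators use the raw blank mean; the +2SD
inflation is part of the test's null only. No multiple-testing correction
is applied by default (per-probe α with a conservative null); a Bonferroni
option exists.

Degenerate numerics: a t-test over two zero-variance populations returns
p = 0 or 1 by mean comparison instead of NaN; fewer than `min_replicates`
replicates yields an "absent, untested" record with a reason flag.

## Fingerprint analysis

Binary fingerprints (1 = present) are clustered as numeric 0/1 vectors
with Euclidean distance and **Ward's method** — the classical
squared-Euclidean Ward criterion, with merge heights reported on scipy's
Euclidean scale; the variant name is recorded in the output because two
common Ward formulations differ. Tie-breaking is deterministic in input
order; trees are exported as newick with leaf order. Relative IF
contributions average per-probe mean IFs over one or two replicate
experiments, drop sub-probes (nested finer-resolution targets, to avoid
double-counting their parent's signal), and normalize to percent.
Ecological summaries sum contributions over the major-mutualist /
minor-mutualist / opportunist groupings of the default 30-probe
annotation; cluster IX is grouped with the major mutualists per the probe
annotation table.

## Problem sizes in the test-bench

The synthetic study system is 10 target groups of 4 members × 240 nt,
a 47-ZipCode single-subarray layout, 6-template mixes over 0.7–75 fmol,
8-sample cohorts, and 200-replicate null/power simulations — sizes chosen
so the whole suite and the acceptance run complete in well under a minute
each while leaving every statistical check fully powered (e.g. the 200
null simulations bound the per-probe false-present rate at the nominal
0.01 with zero observed false calls).

## Known limitations

- The Tm model is one defensible choice among several; absolute Tm values
  shift by ~1–2 °C under other published parameter sets or salt
  corrections, which changes which candidates fall in the 68 ± 1 window
  but not the pipeline's structure.
- Negative-set discrimination is sequence-exact; thermodynamic
  cross-hybridization (partial-duplex stability of mismatched products) is
  out of scope.
- The linear yield model ignores ligase saturation at high template
  amounts; relative contributions are therefore proportional to template
  amounts by construction in simulation, which is the idealization the
  parameter-recovery test quantifies.
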