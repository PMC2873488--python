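# ldrua

A toolkit for designing, simulating and analysing **Ligase Detection
Reaction – Universal Array (LDR-UA)** experiments for high-taxonomic-level
16S rRNA fingerprinting of microbial communities, such as the human
intestinal microbiota.

## The problem and the approach

Phylogenetic microarrays based on direct hybridization struggle to
discriminate the single-base 16S rRNA differences that separate related
bacterial lineages. The LDR-UA approach sidesteps this: for each taxonomic
target group a pair of adjacent oligonucleotides is designed on the group's
consensus sequence — a 5'-fluorescently-labelled **Discriminating Probe
(DS)** whose 3'-terminal base sits on the discriminating position, and a
5'-phosphorylated **Common Probe (CP)** starting one base downstream and
carrying a cZipCode tail. A thermostable DNA ligase joins the two probes
only on a perfectly matching template, so a single mismatch under the DS
3' end suppresses product formation. The ligation product is addressed by
its cZipCode to a fixed spot on a generic **Universal Array** of ZipCode
oligos, decoupling assay chemistry from array content.

This package implements the complete computational side of such a platform:

- **`ldrua.consensus`** — aligned group parsing and IUPAC consensus
  extraction (75% base-calling cutoff; minority bases ≥ a 5% floor coded as
  ambiguity symbols).
- **`ldrua.design`** — exhaustive DS/CP candidate enumeration under the
  design constraints (25–60 nt per oligo, Tm 68 ± 1 °C, ≤ 4 degenerate
  bases), nearest-neighbor thermodynamics (`ldrua.thermo`), and the
  specificity filter: perfect match of every positive-set sequence over the
  DS+CP footprint, at least one mismatch against the entire negative set.
- **`ldrua.array`** — ZipCode pools and the multi-subarray layout
  (default: 47 ZipCodes in quadruplicate + 8 hybridization controls,
  6 ligation controls, 6 blanks = 208 spots per subarray, 8 subarrays).
- **`ldrua.simulate`** — an in-silico LDR-UA experiment: linear ligation
  yield per fmol of matching template, lognormal multiplicative spot noise,
  per-spot pixel SD, and seeded, bit-reproducible spot-intensity tables.
- **`ldrua.calling`** — presence/absence statistics: the null distribution
  is the blank-spot population with +2 pixel-SD added per spot
  (conservative), replicates below 2.5× the null mean are discarded as
  outliers, and retained replicates are tested with a one-sided Welch
  t-test (H₀: μ_test = μ_null, H₁: μ_test > μ_null; α = 0.01, relaxed to
  0.05 for sensitivity tests). Per-probe SNR is mean probe intensity over
  the raw blank mean.
- **`ldrua.fingerprint`** — binary fingerprints, relative IF contributions
  (percent of total intensity, sub-probes excluded), Euclidean/Ward
  hierarchical clustering with newick export, replicate reproducibility,
  and ecological-group summaries (major/minor mutualists, opportunists).

## Worked example

```python
from ldrua.array import assign_zipcodes, build_layout, default_zipcode_pool
from ldrua.calling import call_spots, compute_snr
from ldrua.datasets import (design_synthetic_probe_set, group_templates,
                            make_mix, synthetic_group_alignments)
from ldrua.design import probe_set_summary
from ldrua.simulate import NoiseParams, simulate_experiment

# ten divergent 16S-like target groups, one designed probe pair each
groups = synthetic_group_alignments(n_groups=10, seed=1)
probes = design_synthetic_probe_set(groups)
s = probe_set_summary(probes)
print(f"designed {int(s['n_pairs'])} probe pairs: "
      f"Tm {s['tm_mean']:.1f} +/- {s['tm_sd']:.1f} C, "
      f"length {s['length_mean']:.1f} +/- {s['length_sd']:.1f} nt")

pool = default_zipcode_pool(47)
assignment = assign_zipcodes(probes, pool)
layout = build_layout(pool, n_subarrays=1,
                      assigned_zip_ids=list(assignment.values()))
print(f"layout: {layout.spots_per_subarray} spots per subarray")

# artificial mix: six of the ten targets at 50 fmol each
templates = group_templates(groups)
in_mix = list(templates)[:6]
mix = make_mix(templates, {t: (50.0 if t in in_mix else 0.0)
                           for t in templates}, label="artificial_mix")
spots = simulate_experiment(probes, layout, mix, NoiseParams(seed=42),
                            assignment=assignment)
calls = call_spots(spots, assignment)
present = sorted(calls.loc[calls.present, "probe_id"])
print(f"present ({len(present)}/10): {', '.join(present)}")
_, snr_s, snr_ns = compute_snr(spots, in_mix, assignment)
print(f"SNR specific {snr_s:.1f}, non-specific {snr_ns:.2f}")
```

Output:

```
designed 10 probe pairs: Tm 68.0 +/- 0.5 C, length 37.5 +/- 8.2 nt
layout: 208 spots per subarray
present (6/10): group01, group02, group03, group04, group05, group06
SNR specific 224.8, non-specific 1.10
```

Exactly the six targets present in the mix are called (p < 0.01 against
the conservative blank null), the four absent targets stay silent, and the
specific-to-non-specific SNR separation is over two orders of magnitude —
the qualitative behaviour expected of the wet platform.

A `ldrua` console script exposes the same pipeline as `design`, `layout`,
`simulate`, `call` and `fingerprint` subcommands; see `ldrua --help`.

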