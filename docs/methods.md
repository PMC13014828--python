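# Methods

## The analysis in one paragraph

`modmet` re-implements a genome-resolved *modular metabolic analysis* of a
deep-groundwater microbial community. Carbon-fixation and nitrogen-acquisition
pathways are decomposed into short modules (P1–P83 for carbon metabolism and
intermediate-compound transport, PN1–PN7 for nitrogen acquisition), each
defined by KEGG Orthology (KO) requirement groups and anchored at an
exchangeable intermediate compound (formate, acetate, malate, 2-oxoglutarate,
…). Presence/absence of every module is called per genome from eggNOG-mapper
KO assignments, normalized prevalence is computed across GC-content and
genome-size bins, TPM-based abundance and Shannon–Wiener diversity are
summarized per borehole, a sugar–acid preference score is computed per genome,
and compound-mediated cross-feeding networks are inferred per borehole from
genome complementarity.

## Module calling

A module is *present* when every KO group is satisfied, and a group is
satisfied by any one member (isoenzymes or alternative subunits). This is the
strict all-of reading that the nitrogenase module makes explicit (nifH, nifD
and nifK must all be found); by default every KO in a module forms its own
group unless the catalog row marks alternatives. Calls are boolean — no
fractional module-completeness scores — and never use abundance: a genome
detected in zero samples still receives calls.

The reductive-TCA classification uses three slots: fumarate reductase (P35),
a 2-oxoglutarate:ferredoxin oxidoreductase (P37 or P42, alternatives), and
ATP-citrate lyase (P40). All three slots present → `complete` (the full cycle
can run in the carbon-fixing direction), exactly two → `partial` (genuine
truncation or bin incompleteness; such genomes can still fix carbon up to
citrate), otherwise `absent`. Partiality is counted on slots, not raw
modules, for consistency with the completeness rule; because "two of three"
could also be read as specifically {P35, P37}, both counts can be derived
from the role table.

The truncated-TCA consumer flag ("carrying modules P25 to P33") is ambiguous
between any-of and all-of; it is a policy parameter `min_ttca` (default 1)
so the sensitivity to this reading (1, 3, 9) can be swept explicitly.

## The packaged catalog

The catalog file `data/catalog_fsgd_synthetic.tsv` is a synthetic
reconstruction: its category tallies — 58 carbon-fixation modules containing
168 KOs, 25 intermediate-compound transporters encoded by 39 KOs, and 5
nitrogen-acquisition modules of 10 KOs (plus 2 nitrogen transporters of 10
KOs) — and all module identifiers with a documented role (the rTCA slots,
PAT-ACK, the formate channel P60, the promiscuous dicarboxylate importers
P64/P65, the acid transporters P74/P78/P79/P80/P82/P83, PN1–PN7, …) are
faithful to the published survey, while the KO membership of modules whose
exact gene content was never printed is a plausible stand-in. KO identifiers
the survey names explicitly (K02586/K02588/K02591 for nitrogenase, K00645 for
fabD, K03320 for the ammonium transporter) are used verbatim. Two role flags
(L-serine deaminase, glycine reductase) have no published module number; the
reconstruction assigns them the otherwise-unnamed slots P14 and P17. The
hydroxypropionate–hydroxybutyrate pathway is absent by design (its KOs were
not detected in the source dataset). A 16-module hand-written catalog
(`data/catalog_mini.tsv`) backs tests that should not depend on the full
reconstruction.

## Genome architecture

Estimated genome size is the completeness-corrected assembly size,
`EGS = size × (1 − contamination/100) / (completeness/100)`. Both
conventions (with and without the contamination numerator) exist in the
literature; the contamination correction is on by default as the more
conservative estimator and can be switched off
(`correct_contamination=False`). The quality filter keeps genomes with
≥ 50 % completeness and ≤ 5 % contamination; genomes missing from the
quality table are dropped with a warning, never defaulted. The noncoding
fraction treats input gene intervals as 1-based inclusive (GFF3), merges
overlaps before summation, and ignores strand; which feature types count as
coding (default CDS + tRNA + rRNA) is a filter option, since the operational
definition was never published.

## Prevalence binning

Equal-width bins, left-closed right-open with the final bin right-closed;
values outside the range go to an explicit overflow category so genome
counts conserve. Defaults reproduce the survey's normalization: GC 25–75 %
in five intervals, EGS 0.6–10.3 Mb in ten; figure-style genome-size
categories use ten 1-Mb intervals starting at 0.6 Mb (so 0.66 Mb → category
0, 3.7 Mb → category 3, 10.34 Mb → category 9). Bin prevalence is
carriers/total within the bin; an empty bin is NA, never 0 — a zero would
fabricate signal. The genome-count-weighted mean of bin prevalences is
exactly the overall prevalence, which the tests assert to 1e-12.
Correlations report raw two-sided p-values (a Benjamini–Hochberg helper
exists but is off by default, matching the source analysis).

## Abundance and diversity

TPM is consumed, never recomputed; a strict-mode check warns when a sample
column deviates from 10⁶ by > 1 %. A genome is a member of a borehole's
community when its TPM is nonzero in at least one of the borehole's samples.
Population size is the mean of log10 of the nonzero TPM values across those
samples, undefined (not zero) for absent genomes. Shannon–Wiener diversity
uses natural log; its input proportions derive from each member's mean
nonzero linear TPM by default — the published legend's "nonzero log10" is
read as a presence filter, since linear abundances are the conventional
Shannon input — with `weight_scale="log10"` available (it refuses to run
when log weights go non-positive rather than fabricate proportions).
Interval abundance pools all nonzero genome × sample TPM cells of a
genome-size category across the borehole's samples and averages on the
linear scale (cells pooled, not sample-averaged first).

## Sugar–acid preference

`SAP = tanh(s·S + a·A)` with fixed published coefficients s = 60.76 and
a = −20.21; S and A are counts of sugar-/acid-list gene matches (with
multiplicity, matched case-insensitively by identifier) divided by the
genome's total predicted gene count. +1 is an extreme sugar specialist,
−1 an extreme acid specialist. The curated gene lists belong to an external
supplement, so the packaged list (`data/sap_genes_synthetic.tsv`) is a
synthetic stand-in and any user list can be supplied. The normalizing
denominator is total predicted genes by default (switchable to annotated
genes via the `n_genes` argument).

## Cross-feeding networks

Per borehole, a typed multigraph over member genomes and public-goods
compounds (default set: formate, acetate, lactate, malate, citrate,
aspartate, fatty acids). Metabolic modules contribute `produce`
(genome→compound) and `consume` (compound→genome) edges; transporters
contribute `import`/`export` edges according to their direction. Export
transporters do not make their carrier a *producer* — production is
metabolic — and formate is additionally allowed to leave producers by
passive diffusion (an `export` edge flagged `mechanism=diffusion`),
the only compound with that default. Every edge records the justifying
module and borehole, is re-audited against the presence matrix on every
build, and carries `evidence=genomic_potential`: edges mean *could
exchange*, never *does exchange*. Reciprocal pairs are unordered genome
pairs with exchange chains in both directions where the two directions
differ in compound or supporting modules; one representative record per
pair (lexicographically smallest compound pair) is reported. The
phylum-collapsed view is always derived from the genome-level graph, never
built directly.

## Synthetic community generator

The generator encodes the study conditions the analysis assumes, so the
pipeline is testable end to end without external data:

* **GC** — trimodal mixture via three archetypes: streamlined symbionts
  (55 %, GC 40 ± 5), mid generalists (30 %, GC 57 ± 3), high-GC generalists
  (15 %, GC 63 ± 3), truncated to 25–75 %.
* **EGS** — per archetype, `egs_mean + 0.05 Mb/GC-point × (GC − gc_mean)`
  plus Gaussian noise, truncated to 0.6–10.3 Mb (archetype means 1.4 / 3.0
  / 4.2 Mb), giving the positive GC–EGS coupling.
* **Modules** — designated carbon-fixation/nitrogen modules are logistic in
  GC (probability 0.5 at GC 50, slope 0.15 logit units per GC point); all
  other modules have archetype-specific per-pathway base probabilities
  (symbionts transporter-heavy with truncated central metabolism,
  generalists broad). KO sets emit one member per required group, plus
  Poisson(25) decoy KOs absent from the catalog so tests exercise the
  calling's robustness to irrelevant annotations.
* **Degradation** — 10 % of genomes lose one KO group of one carried module,
  with the intended truth recorded, mimicking bin incompleteness and
  exercising the difference between genomic truth and observed calls.
* **Abundance** — per cell, log10 TPM = archetype baseline + depth response
  × (depth − 200 m) + Gaussian noise (σ = 0.35); archetype-specific dropout
  (0.3–0.5) creates sparsity; each sample column is rescaled to sum to 10⁶.
  The symbiont archetype's depth response is negative (−0.004 per m),
  encoding the decline of interaction-dependent lineages with depth. Four
  boreholes at 70/250/420/530 m below surface with three samples each.

Genome sizes, completeness (55–100 %) and contamination (0–5 %) are drawn so
every genome passes the quality filter by construction. Sugar/acid gene
rates per archetype (symbionts 2.0 %/0.4 %, high-GC generalists 0.6 %/4.0 %)
make SAP decline with GC, as observed.

What the generator does **not** emulate: phylogenetically structured trait
evolution, sequence-level artifacts (chimerism, strain heterogeneity),
co-occurrence structure between modules beyond GC, or realistic
rank-abundance shapes. Passing tests therefore demonstrate correctness of
the computations under the encoded statistical structure, not that real
communities satisfy it.

## Numerical and reproducibility choices

All randomness flows through one integer seed into `numpy.random.default_rng`
with a fixed sampling order, so identical seeds give identical communities on
any platform. Pipeline outputs carry no timestamps, all orderings are sorted,
and floats are written with a fixed format, so identical configs produce
byte-identical reports (asserted by checksum in the tests). Empty bins,
absent genomes, and empty exchange pools are NaN/undefined, never zero.
Zero-variance inputs to correlation return NaN with the n reported.
Problem sizes in the test-suite recovery experiments (1000 genomes × 100
seeds for the GC-slope check, 400 × 100 for the depth check) were chosen as
the smallest sizes at which the generative effects are unambiguous.

## Known limitations

* The full catalog's KO memberships are reconstructions wherever the
  published record names only the module; analyses that depend on exact KO
  identity (rather than module structure) should supply a user catalog.
* Boolean module calls ignore partial pathway completeness; a genome missing
  one subunit of a 9-group module scores identically to one missing all.
* Cross-feeding edges are genomic potential; no thermodynamics, flux, or
  abundance weighting.
* The Shannon weighting of the source legend is ambiguous; both readings are
  implemented but only one can be the default.
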