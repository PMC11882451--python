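# Methods

## The assay being modelled

A sort-seq deep mutational scan measures, in one pooled experiment, how
every member of a variant library affects a fluorescence phenotype.  Here
the phenotype is degradation of a GFP-tagged substrate driven by variants
of a short E3-ligase loop: cells expressing an efficacious variant lose
GFP signal, so variants enriched among the dimmest sorted cells (GFP−)
and depleted among the brightest (GFP+) are degradation-promoting.  The
package implements the four computational stages of such a screen —
library design, read counting, enrichment scoring and motif analytics —
plus a generative simulator that provides ground truth for all of them.

## Library enumeration semantics

The mutational window is a short protein sequence (default `GISIPRR`,
window positions 1–7 ↔ residues 307–313).  Categories:

* **Deletions**: every contiguous span of 1..L−1 residues (default 1–6);
  the full-window deletion is excluded by construction.
* **Single substitutions**: each position to each of the 19 non-wild-type
  residues.
* **Double substitutions**: both members of each adjacent position pair,
  19 × 19 non-wild-type choices per pair.
* **Single / double insertions**: each residue (or ordered residue pair)
  after each window position s ∈ {1..L}.  The before-position-1 site is
  not part of the design.
* **Scramble controls**: seeded random residue-order permutations of the
  window, all distinct and never equal to the wild-type order.  The exact
  wild-type entry is always emitted alongside as the normalization
  reference.
* **Named indels**: `delins` nomenclature (`<ref><pos>delins<new>`, full
  protein numbering); an indel whose product is already generated by an
  enabled category is absorbed, since it is not a new library member.

Deduplication is exact at the protein level and **per category**: two
edits of the same category producing the same protein collapse into one
variant that records all originating edits (`merged_edits`), while
identical proteins arising in different categories remain separate
because each category is amplified from its own barcoded subpool and is
therefore distinguishable at the DNA level.  For any window,
`|double insertions| = 400·L − 20·(L−1)`: at each internal boundary the
20 pairs that straddle a repeated flanking residue collapse.  Ordering is
deterministic (by length/position, then residue), so library files are
byte-identical across runs at a fixed seed.

The reported library size counts mutant members only; the wild-type
reference is carried in the library but tallied separately, which is the
convention that makes the default `GISIPRR` configuration total
25 + 133 + 2,166 + 134 + 2,680 + 100 + 2 = 5,240.

Nucleotide designs keep the reference codons at unchanged positions and
encode edited or inserted residues with a fixed one-codon-per-amino-acid
table (most-used human codons); scramble designs permute the reference
codons along with the residues.  This mirrors homology-arm oligo design
while keeping designs deterministic.  Codon optimisation and
vendor-specific synthesis constraints are out of scope; real designs can
be supplied instead of the generated ones.  An optional extra category
(GGG/GSG triple insertions) is available but excluded from the default
total.

## Read counting

Counting is exact-match only: both anchor strings (defaults: the 5' and
3' homology arms) must occur in the read, the intervening sequence must
equal a library design, and residual ambiguity between categories is
resolved by the subpool forward barcode upstream of the 5' anchor.  A
read failing any step is unassigned; assigned + unassigned always equals
reads processed.  There is no quality filtering, fuzzy matching or
paired-end merging — robustness to sequencing error is explicitly not a
goal of the counter, and the simulator's error-injection option exists to
document that limitation (a 5% per-base error rate visibly inflates the
unassigned tally).  Reverse-complement scanning is available but off by
default.

## Enrichment score

Per sample: counts → reads per million over the sample's **assigned**
total (the library defines the quantified universe) → add pseudocount 1 →
log2.  Per sorted sample: subtract the log2 value of the unsorted sample
of the same replicate.  Replicates are averaged after this subtraction,
never pooled before it.  Finally the replicate mean of the wild-type
entry is subtracted, pinning WT at exactly 0.  The score is linear in
per-sample log2 shifts and invariant to variant order and to sequencing
depth at fixed composition; these identities are asserted in the test
suite.  The wild-type entry (not the scramble-control mean) is the
normalization reference; scrambles are summarized as their own control
category.

## Position probability matrices and information content

Within one category all mutant windows share a length (7 for
substitutions, 8/9 for single/double insertions on a 7-residue window),
so positions align without gaps.  Per replicate, a variant's frequency is
its count over the category total in that sample; frequencies are
averaged across replicates and tallied into P(position, amino acid).  The
per-letter information content against a background PPM (the unsorted
population) is the Kullback–Leibler term

    IC(N, a) = P(N, a) · log2( P(N, a) / B(N, a) )

with P = 0 terms defined as 0 by continuity.  Background zeros under
positive foreground mass are floored at ε = 1/(10 × background category
reads) — finite IC, ranking preserved — and logged.  Per-position sums
are the relative-entropy logo heights; they are non-negative for proper
distributions (Gibbs' inequality, property-tested on random matrices).
The foreground population is a required argument: sorted-population
choice is a scientific decision, not a default.  Logo heights are emitted
as TSV consumable by standard logo tools, with a small built-in
matplotlib letter-stack renderer.

## Heatmaps, adjacency correlation, pattern slices

Heatmap matrices map every unmasked cell to exactly one variant: singles
are residues × positions/sites (wild-type identity cells masked), doubles
are ordered residue pairs × adjacent-pair positions or insertion sites.
Merged variants are broadcast to all their source cells, so equivalent
cells carry identical values by construction.  The single-vs-double
correlation pairs each single mutant (position n, residue X) with the
mean enrichment of the doubles containing exactly that change plus one
change at an adjacent position; for insertions, where "adjacent" is not
well defined by position, the doubles at the same site containing X as
either member of the pair are used.  Pearson r, the two-sided p-value and
the least-squares line are computed with scipy.  Pattern slices match
mutant windows against exact-length wildcard patterns, which is the
mechanism for site- or sequence-restricted views of the insertion
categories.

## Simulator

Generative model per replicate, all streams spawned from one seed:

1. variant frequencies f ~ Dirichlet(α·1), α = `frequency_concentration`;
2. cell pool ~ Multinomial(`n_cells`, f);
3. per-cell GFP intensity = (1 − θ_v) + Normal(0, `intensity_noise_sd`);
4. GFP− gate = lowest `gate_fraction` of cells, GFP+ = highest, unsorted
   = the whole pool (all simulated cells are transduced; the mCherry
   transduction marker is abstracted away);
5. reads per sample ~ Dirichlet-multinomial over the gate composition
   with concentration mass `sequencing_dispersion` (PCR jackpotting
   without a full PCR model); reads are the exact oligo sequences,
   optionally with per-base errors.

Default conditions, chosen once as the study design the pipeline targets:
5×10⁶ cells, 10⁶ reads per sample (≈190× coverage of a 5,240-member
library; the simulator enforces a configurable 150× floor), 3 replicates,
10% gates, intensity noise SD 0.25 (a realistic FACS spread that keeps
gate probabilities away from hard saturation), Dirichlet precision 5×10⁴
(≈20-fold variance inflation over multinomial at 10⁶ reads), read error
rate 0.  The default effect model plants screen-like structure: Beta(6,2)
efficacies for substitutions/insertions introducing a basic or aromatic
residue at mid-loop positions 3–5 and for the named clinical indels,
Beta(1.5,6) for other substitutions/insertions, Beta(1.2,12) for
deletions and Beta(1.2,20) for wild type and scrambles.  Efficacies are
drawn per variant (not per class), so rank recovery is a meaningful test;
an explicit per-variant efficacy vector can be passed instead, e.g. for
null screens.

Under these defaults the pipeline recovers the planted ranking with
Spearman ρ ≈ 0.93 and reproduces the GFP−/GFP+ anticorrelation at
Pearson ≈ −0.94 (asserted at ≥ 0.9 and ≤ −0.8 respectively in the
acceptance tests; stable across seeds).  What this does and does not
show: the simulator validates the pipeline's arithmetic, gating logic
and rank recovery under a known model; it does not emulate lentiviral
MOI, growth dropout during culture, PCR chimeras, index hopping or
read-quality structure, so passing tests are not evidence about those
failure modes in real data.

## Pipeline

One YAML config drives design → simulate (or a real-sample manifest) →
count → enrich → motif products.  Each stochastic stage derives its
sub-seed as `blake2b(master_seed:stage_name) mod 2³¹`, so adding a stage
never perturbs earlier stages' randomness.  Outputs are byte-identical
across reruns at fixed config and seed (gzip members are written with a
zeroed timestamp); the summary records per-category counts taken directly
from the library object (no re-derivation), output checksums, wild-type
enrichment, top/bottom variants and recovery statistics when simulated.
Missing analyses (e.g. a disabled category) are skipped with explicit
notices, never silently.

## Numerical conventions and degenerate inputs

* Window coordinates are 1-based in the public API and in edit
  nomenclature; full-protein numbering is used only in `delins` strings.
* Pseudocount is added after RPM conversion and before log2, in that
  order exactly.
* Percentile gates take exactly ⌊N·fraction⌉ cells via argpartition;
  ties at the threshold are resolved arbitrarily but deterministically.
* Homopolymer windows: scramble generation raises a capacity error when
  fewer distinct non-identity permutations exist than requested.
* Zero assigned reads in a sample, zero category reads in a replicate,
  empty gates, missing unsorted replicates and barcode collisions are
  hard errors naming the offending sample/replicate/subpool; empty FASTQ
  files produce a zero row with a warning.

## Known limitations

Exact-match counting discards any read with a sequencing error in the
variant region; the enrichment model has no variance shrinkage or
hit-calling layer (a deliberate non-goal); PPM frames assume one length
per category and therefore exclude deletions and mixed-length named
indels from logo analytics; the scramble-control semantics are
residue-order permutations (synonymous-codon scrambles of the wild-type
protein would be an alternative reading and can be supplied as a custom
category); and the adjacency definition for insertion doubles (same-site
pair membership) is one of several defensible choices.
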