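# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the underlying procedure left
room.

## Staged HGT screen (`potworm.hgt`)

The screen treats horizontal transfer as a claim requiring three
independent kinds of evidence, applied in order:

1. **Homology asymmetry.** Per gene, the best bitscore is taken over each
   taxon compartment of the hit tables. The h-score is the best
   non-metazoan bitscore minus the best metazoan bitscore; a compartment
   with no hits contributes 0, so h is always defined (a gene with no
   metazoan hit has h equal to its non-metazoan bitscore — 0 is the
   natural lower bound for a "best score over an empty set" here).
   Candidates require `h ≥ 30` and non-metazoan bitscore `≥ 100`, both
   boundaries inclusive. Annelid-database hits are tracked separately and
   count as metazoan: annelids are the focal lineage's own clade, so a
   strong annelid hit is evidence of vertical inheritance, not of a donor.
   The `annelida_nonmetazoan` flag inverts this for sensitivity analysis.
2. **Physical anchoring.** A real resident gene should be linked to the
   recipient genome; a contaminant scaffold will not be. "Native
   neighbour" is read strictly: the gene at rank ±1 in the per-scaffold
   gene order (ascending start) that is protein-coding and not itself a
   candidate. Linkage requires one read interval overlapping both the
   candidate span and that neighbour's span by at least `min_overlap_bp`
   (default 100 bp — large enough that a chance 1-bp touch never counts,
   small relative to any long-read alignment). The report distinguishes
   the two failure modes (`no_native_neighbor` vs `no_bridging_read`) but
   counts them as one rejection stage.
3. **Confirmation.** Anchored candidates with best metazoan bitscore
   strictly below 50 are confirmed directly — such a gene has essentially
   no metazoan homolog, so a tree would be uninformative. Otherwise the
   gene's tree is consulted: the smallest clade containing the candidate
   is its parent node's subtree, and the candidate is confirmed when that
   clade contains no metazoan leaf. Trees are used as rooted as parsed;
   support values are parsed but not thresholded. Candidates that need a
   tree but have none supplied are reported `phylo_missing` and never
   confirmed. Origin is the taxon group of the best non-metazoan hit,
   with ties broken by lower e-value then subject id; percentages are
   rounded half-away-from-zero to one decimal.

Stage counts obey two conservation identities, asserted in the report
object itself: candidates = linkage-rejected + bitscore-confirmed +
phylogenetically tested, and tested = confirmed + rejected + missing.

GO-term enrichment over a confirmed set is a one-sided hypergeometric
test per term present in the foreground, with Benjamini–Hochberg
correction applied separately per GO namespace and a q ≤ 0.05 report
threshold. The enrichment method is a package choice; nothing upstream
prescribes one.

## Family z-scores (`potworm.genefam`)

For each orthogroup, every species' count is standardised against the
mean and standard deviation of the counts of **all** species in the
matrix (zeros included). Two deliberate choices:

- **Sample sd (n−1)** is the default. With n species this bounds
  `|z| ≤ (n−1)/√n` — e.g. 2.67 at n = 9 — which makes the ±2 call
  conservative and impossible below 6 species; the population-sd
  alternative is available via `sd_mode="population"` and is pinned by a
  test where the two modes disagree.
- **Eligibility** requires the focal species present (count ≥ 1) and at
  least `min_other_species = 3` other species present. Ineligible
  families keep their z values but are never called expanded or
  contracted; zero-variance families are reported `undefined_sd`.
  A `representing_only` flag restricts the mean/sd to species with
  count ≥ 1, for comparison.

Lineage-specific families are rows private to the focal species; shared
families require count ≥ 1 in every species of a subset, with an
`exclusive` flag giving Venn-region semantics (absent everywhere else).
Expansions are ranked by focal gene count, ties by z then orthogroup id.
Collinear blocks (consumed, not detected) are classified inter-scaffold /
palindrome / tandem from the scaffold pair and the strand relation of the
anchor gene pairs.

## Assembly statistics (`potworm.stats`)

N50/L50 use the cumulative ≥ total/2 tie rule (the de facto standard; the
quantity has no universal boundary convention, so it is stated here).
GC excludes ambiguity codes from both numerator and denominator, so
N-padding does not dilute it, while total assembly size still counts all
bases. Genome fractions are computed on interval unions (overlaps counted
once); introns are the gene-span union minus the exon union, which
presumes single-transcript (pre-collapsed) gene models — the GFF3 reader
merges isoform exons per gene for the same reason.

The mitochondrial-fragment screen is an exact canonical k-mer containment
test: the mitochondrial genome is circularised (wrap-around k-mers
included), and a scaffold is flagged when at least `threshold = 0.5` of
its k-mer positions (k = 31) occur in the mitochondrial set on either
strand. k = 31 is long enough that chance matches are negligible
(4^31 ≫ genome size) yet short enough to tolerate scattered differences;
0.5 operationalises "a scaffold that is mostly mitochondrial copy".
Whether flagged scaffolds are excluded from nuclear statistics is a
caller decision (`exclude_ids`), defaulting to exclusion in the CLI
workflow since a mitochondrial genome is reported separately.

## Synthetic generators (`potworm.simulate`)

The generators emulate the *decision-relevant structure* of real inputs —
per-gene best bitscores with controllable margins around the thresholds,
scaffold gene neighbourhoods, reads that do or do not bridge adjacent
genes, trees with planted clade compositions, count matrices with planted
expansions — and nothing else. They do not simulate sequence evolution,
read errors, or e-value statistics beyond rank consistency with
bitscores. Passing tests therefore demonstrate that the *decision logic*
is correct under unambiguous inputs, not that the screen is robust to
noisy real alignments near the thresholds; boundary behaviour at the
exact threshold values is tested separately with exact numbers.

Key contracts:

- One `SeedSequence` per fixture, spawned into sub-streams per output
  kind, so outputs are byte-stable per seed and adding an output kind
  does not shift existing ones.
- Bitscores sit at least `bitscore_margin` (default 5) score units from
  every threshold, so planted stage labels are unambiguous; the
  generator/pipeline adjointness property (stage counts == class sizes)
  holds for any margin ≥ 1.
- The `paper-stages` preset encodes the latent class sizes of the
  published *E. crypticus* screen (33/5/27/40, i.e. 105 candidates and 32
  confirmed) and the donor composition 19/8/4/1 — the unique 4-part
  composition of 32 whose one-decimal percentages are 59.4/25.0/12.5/3.1.
  The preset adds 45 background genes by default.
- Planted family expansions/contractions are single-outlier rows (equal
  counts in all non-focal species), whose focal z is exactly
  ±(n−1)/√n; the fixture-spec constructor refuses to plant them when that
  bound is below 2. Contracted rows keep a focal count ≥ 1 so they stay
  eligible. Neutral rows are i.i.d. Poisson(3) counts, redrawn until they
  trigger no call.
- Genome fixtures default to 20 scaffolds of 3–30 kb at GC 0.35 with a
  15 kb mitochondrial genome and two planted fragment scaffolds carrying
  a verbatim mitochondrial substring over 60–90% of their length —
  loosely mirroring the scale relations of a real screen while staying
  desk-sized.

## Problem sizes and numerical notes

The test suite runs the oracle comparisons at these sizes: 1,000 random
length multisets for N50/L50; all 32,054 rooted two-label tree/labelling
combinations up to 6 leaves for the clade test; 10,000 random count
vectors for the z-bound; 100 random fixture specifications each for the
HGT and family planted-truth recovery. These sizes make every property
check exhaustive or heavily sampled while keeping the default suite in
tens of seconds.

Floating point: z-scores at an exact analytic boundary (e.g. population
sd with a single outlier over five species, exactly 2) can land a few ulp
below the threshold; thresholds are applied as written, without epsilon
adjustment, and tests avoid asserting calls at exactly representable
boundaries. Percentage rounding is half-away-from-zero, implemented
directly rather than via banker's rounding.

## Known limitations

- The screen operates at the unit of the hit tables' query ids; callers
  must pre-collapse transcript isoforms to genes.
- The native-neighbour rule is the strictest reading computable from a
  GFF3 alone (rank ±1); a gene whose only neighbours are non-coding fails
  linkage even if a coding gene lies two ranks away.
- Orthogroup inference, tree building, read mapping, repeat discovery and
  BLAST itself are upstream of this package: matrices, trees, intervals
  and hit tables are consumed, never produced.
- Statistics that depend on external databases (shared-family totals,
  GO-term counts) are functions of the inputs supplied and carry no
  expected values here; the properties and planted-truth tests cover the
  operations instead.
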