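# Methods

## Presence calling and the phylogenetic profile

A genome is called positive for a family iff it has at least one domain
hit to that family passing the presence policy. The default policy is
e-value ≤ 1e-5 with no bit-score floor — ordinary Pfam-screen practice —
and both thresholds are explicit, configurable, and written to the run
log, because presence calls are the single most consequential upstream
choice in this kind of screen. Multiple hits per genome collapse to one
call: presence is a genome-level property, matching how "family-positive
genomes" are counted downstream.

Family accessions are compared after stripping the release-version suffix
(`PF18330.5` → `PF18330`) and upper-casing, so hit tables produced against
different Pfam/TIGRFAM releases collate. An alias group (e.g.
`{PF18330, TIGR01209} → PF18330`) is unioned into a single matrix column
and the member columns are dropped, so a family represented by two
overlapping models is neither split nor double-counted in the screen.
Whether a published screen unioned such models is usually unstated; the
union is this package's default and is configurable.

Coordinates are 1-based inclusive (the GFF3 convention) on the public
`GeneFeature` type; the single conversion point to half-open 0-based
intervals is `GeneFeature.interval()`, used by the BED export. The GFF
reader keeps CDS features by default — domain hits address protein-coding
genes — with the type filter configurable.

## The exact test and its conventions

The enrichment screen conditions on both margins of each 2×2 table and
uses the exact hypergeometric distribution of the a-cell. The two-sided
p-value is the sum of probabilities of all tables with the observed
margins whose probability is ≤ the observed table's — the conventional
"as or more extreme" rule, stated here explicitly because two-sided
conventions differ between implementations. Probabilities are computed in
log-space via log-factorials (`gammaln`) so tables with tens of thousands
of genomes per margin remain stable. Two numerical choices:

- **Tie slack.** Mathematically tied probabilities (symmetric margins)
  computed through `gammaln` differ by a few ulps, so the inclusion rule
  allows an absolute slack of 1e-9 on the log scale. This is narrower than
  the 1 + 1e-7 relative slack some libraries use; the test suite verifies
  exact agreement (≤ 1e-12) with brute-force rational-arithmetic
  enumeration over every table with n ≤ 60.
- **Underflow.** Associations strong enough to drive p below the smallest
  positive double are reported at 5e-324 so p stays in (0, 1] and ranking
  and FDR adjustment remain well-defined.

A table with an empty row or column margin admits exactly one
configuration; p = 1.0 by convention, logged. The sample odds ratio
(ad)/(bc) is reported as-is (inf when bc = 0 with ad > 0); a
Haldane–Anscombe corrected value (+0.5 to all cells) is carried in a
separate field because the headline use case has c = 0 and an infinite
sample odds ratio.

Multiple testing is controlled by Benjamini–Hochberg step-up FDR at
α = 0.05 (configurable), delegated to statsmodels. Results are ranked by
q-value, then |log corrected odds ratio|. Direction (over/under) is
assigned from the sample odds ratio at q ≤ α; both directions are
reported, since a screen like this is as interested in what anchor-positive
genomes lack as in what they carry.

Conditional co-occurrence percentages are stored as exact fractions;
one-decimal and integer-rounded renderings are derived views, because
published prose typically prints coarse roundings ("89%", "a third") and
the exact fraction is the reproducible contract.

## Distance and orientation

The intergenic distance is the boundary-to-boundary gap,
max(0, right.start − left.end − 1) with genes ordered by position;
overlapping or abutting genes score 0, which makes "abutting" co-localized
under any positive threshold. Co-localization is strict: gap < 5,000 bp
by default (a pair at exactly 5,000 bp is not co-localized). Whether a
published distance was boundary gap or start-to-start is often unstated;
the boundary gap is this package's definition and is applied uniformly.

Orientation: same strand → tandem; opposite strands with the left gene on
the reverse strand → divergent (head-to-head promoters, the arrangement
often called "bidirectional"); the remaining case → convergent.
Convergent is tracked as its own class even where a study reports only
"bidirectional" and "tandem", so the three tallies are exhaustive and sum
to the co-localized count. Both distance and orientation are invariant
under argument order; coordinate ties break deterministically by
(start, end, gene id).

Each dual-positive genome contributes exactly one pair — the same-contig
pair with the minimal gap, ties broken by (anchor start, partner start) —
because the analysis counts genomes, not gene copies. If the two families
share no contig the pair is reported with `same_contig = False` and no
distance. Replicons are treated as linear by default; an optional circular
mode takes the smaller of the linear gap and the wraparound gap
(contig length − right.end + left.start − 1).

## The synthetic generator

The generator emulates the statistical skeleton the analysis assumes, and
nothing more: anchor presence ~ Bernoulli(p_anchor); partner presence
conditional on anchor status; background families mutually independent of
everything; taxon structure limited to an archaea/bacteria label plus
flavor taxon names. Defaults mirror the conditional structure of the
motivating two-family screen at desk scale: n_genomes = 1,000, a rare
anchor (p_anchor = 0.05), P(partner | anchor) = 0.89 and
P(partner | no anchor) = 0 (the partner's profile nested inside the
anchor's), 200 background families at prevalence 0.3, co-localization in
44% of dual-positive genomes, and an orientation mixture of 0.90
divergent / 0.05 convergent / 0.05 tandem.

Genes are laid left to right on one contig per genome: lengths uniform in
[300, 1500] bp, inter-gene gaps exponential (mean 500 bp) truncated at
5 kb. The truncation bounds the worst-case span, so infeasible
contig-length/gene-count combinations are rejected before any file is
written. In dual-positive genomes the anchor and partner occupy adjacent
slots (left/right at random) and the gap between them is drawn from the
co-localization law (uniform on [0, 4999] bp) or the far law (uniform on
[5000, 50000] bp); because they are adjacent, the planted gap *is* the
realized minimal intergenic distance, which is what lets the manifest act
as an exact—not statistical—oracle for re-ingestion tests. Non-co-localized
partners can instead be placed on a second contig with probability
`p_far_second_contig` (default 0).

One `SeedSequence` per collection spawns per-genome substreams, so
generation is reproducible (identical seed → byte-identical files) and
order-independent. Emitted files are plain GFF3, a five-column hits TSV, a
metadata TSV, and a JSON manifest.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation among genomes (the
screen here treats genomes as independent trials, as does the analysis it
supports; no independent-contrasts correction is attempted), multi-copy
families, fragmented assemblies, annotation errors, and any sequence-level
signal. `fixture_from_counts` is the deterministic companion: it builds a
matrix and pair list realizing requested per-domain counts exactly, which
turns published summary tables into testable worked examples.

## Problem sizes

The test-suite and acceptance-script studies run at sizes chosen to give
the statistical checks comfortable power on a desk machine: the exact-test
sweep is exhaustive over all 2×2 tables with n ≤ 60 against a
rational-arithmetic oracle; null calibration uses 200 background families
× 500 genomes across 50 (suite) or 20 (script) replicates; planted-truth
recovery uses 2,000-genome (suite) or 1,000-genome (script) collections.
The 99% binomial intervals used for parameter-recovery checks are allowed
one miss in twenty seeds, matching their nominal coverage.

## Known limitations

- Presence calls trust the hit table; there is no domain-architecture or
  overlap resolution between competing families.
- The enrichment screen is not phylogenetically corrected; lineage-driven
  co-occurrence will look enriched, by design (the profile comparison is
  descriptive, not causal).
- The iToL export targets the `DATASET_BINARY` flat-file dialect with a
  comma separator; other iToL dataset types are out of scope.
- Tree inference is out of scope; Newick input is validated and pruned to
  the genome set, nothing more.
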