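# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Preprocessing

Reads are adapter-ligated: 5′ adapter + insert + 3′ adapter. The 5′ adapter
is required as a full-length prefix with at most `adapter_max_mismatch`
substitutions (default 1); the 3′ adapter is located as the left-most
occurrence of its prefix with the fewest mismatches, allowing 3′ truncation
down to `adapter_min_overlap` bases (default 8). Reads missing either
adapter are discarded and counted (`no5`, `no3`), never raised, and the
identity `raw = kept + no5 + no3` is asserted in tests. Both adapters are
required because the insert is defined as the sequence *between* them; a
read with no 3′ adapter has an undefined insert boundary. Inserts are then
kept if 18–30 nt inclusive and collapsed to unique sequences with counts.
Sequences are stored in the DNA alphabet internally and rendered as RNA in
reports, since reference sets mix both conventions.

## Hierarchical annotation

Each unique read receives exactly one category, the highest-precedence one
in which it has a hit: ncRNA > miRBase > mRNA > repeats > genome, with
no-hit reads counted as unclassified. This makes the category table an
exact partition — category sums equal library totals as integers, which is
the property the summary renderer's computed `Total` row relies on.

Matching rules: ncRNA and mRNA references are transcripts, searched
sense-strand only for exact substrings; repeats and genome are searched on
both strands. Known-miRNA matching is ungapped and end-to-end with at most
2 substitutions and ±2 nt length slack, reflecting how conserved-family
members differ by one or two nucleotides across species. These tolerances
are declared package defaults (`mirna_max_mismatch` etc.) — the analysis
convention in this field rarely publishes them, so they are configuration,
not constants. Family names are parsed from miRBase-style ids
(`ath-miR156a` → `miR156`); the nearly-identical miR165/166 and miR170/171
pairs can optionally be merged. Ties in family assignment break by fewest
mismatches, then smallest length difference, then lexicographically
smallest reference id, so assignment is deterministic.

Exact-substring membership is implemented as C-speed scans over
separator-joined reference concatenations rather than a seeded heuristic
aligner: inputs at this scale make bit-exact matching both feasible and
preferable for testability.

## Abundance

tpm = count / library_total × 10⁶, with the preprocessed (18–30 nt) library
total as denominator — the only denominator defined for every category.
Σ tpm over all unique reads is 10⁶ by construction (checked to 10⁻⁶
relative). Tiers: abundant strictly above 1000 tpm, moderate in [100,
1000], low below 100; the boundary assignment (1000 → moderate) is a
documented convention since prose descriptions of the tiers are ambiguous
at the exact thresholds. Cross-library fold changes replace zero tpm cells
with a 0.5 pseudo-tpm so ratios stay finite while preserving order.

## Folding and the hairpin screen

The folder maximizes base-pair count over {A:U, G:C, G:U} with minimum
hairpin loop 3 and no pseudoknots (Nussinov dynamic programming). Maximum
pairing alone is massively degenerate — a random 180-mer admits many
structures with the same pair count, most of them scattered long-range
pairings — so the objective is lexicographic: maximize pairs, then maximize
the number of stacked pair adjacencies. Both terms are exact (the fill
optimizes `pairs·B + stacks` with `B` larger than any stack count);
remaining ties resolve by a deterministic traceback that prefers closing
pairs and 5′-most decompositions. The paired-base count is therefore
identical to plain maximum pairing and is verified against an independent
O(n³) reference recursion; the stacking tie-break is what lets the folder
recover a clean engineered stem inside a 180-nt window instead of an
equally-paired tangle. A thermodynamic folder can be substituted: the
hairpin module accepts any callable returning a fold result.

Novel-miRNA candidates are unique reads that (a) classified `genome`
(unannotated above it), (b) are 20–24 nt, and (c) map to 1–10 genomic loci
— more than 10 loci indicates repeat-derived sequence. For each locus two
windows are folded: read + 160 nt downstream, and 160 nt upstream + read
(on the locus strand, clipped at contig ends; 160 nt covers typical plant
precursor arms and is configurable). The read passes if, in either window:

* ≥ 16 of its bases are paired and ≤ 6 are unpaired;
* all partners lie on one side of the read (one arm; partners on both
  sides or inside the read mean it straddles the terminal loop);
* the opposing arm is compact — its span may exceed the read length by at
  most 4 nt, which admits the small bulges real precursors carry while
  rejecting diffuse pairings.

The ≥ 16 / ≤ 6 thresholds follow community plant-miRNA annotation
practice; the arm-span slack of 4 is this package's own compactness
criterion. With these settings, shuffled precursor decoys pass at well
under 10% while engineered hairpins with up to 2 bulges all pass. A
miRNA* (passenger strand) requirement is off by default — low-depth
libraries rarely recover stars — but the structural metrics needed for a
strict mode are reported for every candidate.

Passing candidates are retained as putative novel miRNAs only when their
exact sequence is present in libraries of ≥ 2 distinct genera (the genus
map is a configuration input, since species-vs-genus granularity is a
study-level decision). Cross-species recovery is the main guard against
single-library folding artifacts.

## TAS3 loci and tasiRNA phasing

Trigger-complementarity is scored with the duplex penalty (mismatch 1.0,
G:U 0.5) with penalties doubled at trigger positions 2–13; sites score
≤ 6.0 by default. A site is *cleavable* when trigger positions 9–12 pair
perfectly (no wobble). A TAS locus is a 5′/3′ site pair with 200–300 nt
strictly between the site intervals, a cleavable 3′ site, and is flagged
canonical when the 5′ site is additionally non-cleavable — the
configuration in which only the 3′ cut sets the phase.

Coordinates: with a trigger of length L aligned antisense to a site
starting at s, trigger position p faces transcript position s + L − p.
Cleavage falls between the bases facing trigger positions 10 and 11, so
the phase origin is o = s + L − 10 (the first base of the 3′ fragment):

```
transcript 5' ── [site5] ── spacer ── [ s ... s+L-11 | s+L-10 ... ] ── 3'
trigger                        3' ──  [ L   ...   11 | 10   ...  1 ] ── 5'
                                                 cut ^ = origin o
```

Register Dk(+) is the 21-nt window whose 5′ end lies 21·(k−1) nt upstream
of o; a read starting 147 nt upstream is D8(+), and D1(+) begins at the
origin itself, on the cleaved 3′ fragment, so spacer-derived tasiRNAs
populate D2(+) and up. A read is in phase when its 5′ end falls exactly on
a register boundary (tolerance 0); off-by-one starts are reported
separately as near-phase variants. The in-phase fraction is count-weighted
over all locus-overlapping reads: 1.0 for perfectly phased simulations,
≈ 1/21 for uniform placement. Trigger/tasiRNA co-expression across ≥ 3
libraries is summarized by a Spearman rank correlation of (trigger-family
tpm, summed in-phase tasiRNA tpm).

## Target prediction

Flat ungapped duplex penalty — mismatch 1.0, G:U 0.5, no position
weighting, no bulges — over every transcript window, reported at penalty
≤ 3.5 (so 3 mismatches + 1 wobble is the boundary case that passes and 4
mismatches fails). Windows are fixed at the miRNA length; no 3′-overhang
trimming. The best site per (miRNA, transcript) pair is flagged.
Annotation is a join against a user-supplied description table; missing
entries become "unknown protein" (no external homology search).

## qPCR expression

Relative expression is 2^−(Ct_target − Ct_reference) (delta-Ct against a
reference gene such as actin). Group comparisons use the classic
equal-variance two-sided Student's t-test (a Welch flag is provided);
stars: `*` p < 0.05, `**` p < 0.01. Zero pooled variance is handled
explicitly (equal means → p = 1; unequal → p = 0, flagged degenerate).
Replicate means are reported with standard deviations. The test's type-I
error is calibrated empirically in the acceptance suite: at n = 3 vs 3
over 10,000 null replicates the rejection rate at α = 0.05 must lie in
[0.04, 0.06].

## The synthetic study generator

`srna.simulate` builds one 60-kb genome containing: 8 conserved miRNA
families (1–2 members each; miR390 keeps its real mature sequence, all
other sequences are random), 10 novel precursor hairpins, one TAS3 locus
(dual sites 250 nt apart, tandem 21-nt repeats laid on the cleavage phase,
a 5′ site engineered with 2 mismatches + 1 wobble at positions 9–12), 4
tRNA and 2 rRNA decoys, 12 copies of a 150-nt repeat, and 6 mRNAs (two
carrying engineered miR156/miR159 target sites at penalties 0 and 3.5).
Precursors are validated *in genomic context* at construction — the mature
must pass the hairpin screen within its actual flank windows, which are
reserved against later feature placements — so embedded features are
detectable by construction and recovery tests measure the pipeline, not
placement luck.

Reads are drawn multinomially over feature classes, uniformly within a
class (mature miRNAs optionally weighted by family), and emitted as 5′
adapter + insert + 3′ adapter with the 3′ adapter truncated to ≥ 8 nt in
30% of reads. Class length conventions: matures 20–22 nt with occasional
3′-templated ±1 variants; tRNA reads are exact 19-nt 5′ fragments of only
four decoys (the highly redundant 19-nt class); repeat/rRNA reads are
24-mers; background siRNAs are 22–24-mers (mostly 24) drawn from a
per-library pool of 100 discrete feature-free loci, emulating discrete
siRNA-producing loci; each species' pool comes from a disjoint slice of
the genome. Every read carries a truth row (class, source feature, exact
insert), and features are written as GFF3 (1-based) plus TSV (0-based
half-open).

The default four-library preset (~10,000–11,500 reads each) reproduces
the qualitative contrasts the pipeline must resolve: 24-nt modal size
class with a redundant 19-nt secondary peak, one family (miR166) near 75%
of miRNA reads in three libraries with a ~50× miR156 boost in the fourth,
four cross-genus novel matures among the ten embedded (the other six stay
within one genus), and tasiRNA output co-monotone with miR390 abundance
across libraries. Problem sizes were chosen so a full end-to-end run
finishes in about three minutes on one CPU.

What the generator does **not** emulate: sequencing errors and quality
variation, multi-contig genomes, transcript isoforms, expression noise
beyond multinomial sampling, degradation products, and genuine
thermodynamic folding of decoy sequence. Passing the recovery tests
therefore demonstrates correctness of the pipeline's logic and scoring on
clean signals with realistic redundancy structure — not its robustness to
sequencing artifacts or to the fuzzier hairpins of real genomes.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed gives byte-identical FASTA/FASTQ/GFF3/TSV outputs.
* Penalty comparisons against cutoffs use a 10⁻⁹ slack to keep half-unit
  arithmetic exact in floating point.
* Fold input is capped at 1000 nt (flank windows are ~180 nt); non-ACGT/U
  characters raise immediately.
* Empty inputs: collapsing an empty read list yields an empty library with
  total 0; a zero library total makes tpm undefined and raises; an
  abundance-model class with no corresponding features is a configuration
  error.
* Spacing is measured as nucleotides strictly between the two site
  intervals, matching the "separated by N nt" convention; the boundary
  behavior is pinned by tests at 200/300.

## Known limitations

* Maximum-base-pairing is not a thermodynamic model: stems with many G:U
  pairs score as well as G:C stems, and loop entropies are ignored. The
  folder hook exists precisely so a free-energy folder can replace it.
* Exact-substring annotation cannot absorb sequencing errors; real
  libraries would need an error-tolerant mapper in front of the same
  category logic.
* The cross-genus filter uses exact sequence identity by default; a
  1-mismatch variant mode exists but is off because it inflates candidate
  linking on low-complexity sequences.
* Only TAS3-type biogenesis (dual 21-nt trigger sites, 3′ cleavage) is
  modeled; single-site 22-nt-trigger TAS1/TAS2 loci and genome-wide
  phasing statistics (p-values) are out of scope.
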