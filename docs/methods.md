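# Methods

This note records the models, conventions and numerical choices behind
`lineagediv`, the places where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Scope and data model

The package analyses one gene subfamily whose members fall into exactly two
lineages. It consumes a *pre-aligned* protein FASTA plus the matching coding
sequences; it never aligns, on the grounds that alignment choice (program,
version, parameters) dominates column-level results and should stay under the
user's control. The codon alignment is constructed by back-translation: every
residue column maps to its source codon, every protein gap to `---`, and the
translation of each ungapped codon row is checked against the protein row
before any statistic is computed.

Alignment columns are reported 1-based. After column filtering the surviving
columns keep their original coordinates (`original_columns`), so a site
number means the same thing in every report regardless of filtering.

## Gap handling

* **Partial deletion** (default coverage 0.95): a column is kept when the
  fraction of non-gap sequences is at least the coverage cutoff; codon
  columns are atomic (a codon containing any gap counts as a gap). Ambiguous
  residues/bases count as non-gap for coverage but are never counted as
  states in any statistic. The filter is idempotent and monotone in the
  cutoff.
* **Pair statistics** (distances, Nei–Gojobori): pairwise deletion — a column
  is skipped only for pairs in which either sequence is unusable there
  (gap, stop, or ambiguity).
* **Tajima's D**: complete deletion — any column containing a gap or
  ambiguity anywhere is dropped before S and k̄ are counted. This is the
  conventional default for that statistic; a pairwise-deletion variant exists
  behind the `deletion` argument.

## Pairwise identity and family clustering

Identity comes from a global protein alignment (BLOSUM62, gap open 10,
extend 0.5 — configurable), as 100 × matches / aligned columns after
stripping terminal-gap overhangs; a flag switches the denominator to the
shorter sequence length. Ambiguous residues never match. Because co-optimal
alignments can differ, the input pair is canonicalized (sorted) before
aligning, making identity exactly symmetric.

Families are connected components of the graph with edges where identity
strictly exceeds 40 %; subfamilies are components at >60 % within each
family, so subfamilies refine families by construction. Single linkage is
the weakest reading consistent with the pairwise nomenclature rule and is
deterministic; curated nomenclatures built on local-alignment (BLAST)
identities may group differently, which is why the identity matrix used is
returned alongside the clusters. Cluster ids are ordered by smallest member
id, so input order never matters.

## Site classification

A column is parsimony-informative when at least two distinct unambiguous
states each occur in at least two sequences. The site screen classifies, by
default, only informative columns (singleton variants say little about
lineage fixation); `sites="all"` overrides. Categories compare the two
lineages' residue sets at a column: any shared residue ⇒ *overlapping*;
disjoint sets with both lineages fixed ⇒ *strictly dimorphic*; disjoint with
one lineage fixed ⇒ *fixed/variable* (the fixed lineage is named); disjoint
with both variable ⇒ *disjoint*. A lineage with no unambiguous residue at a
column makes the contrast undefined (*non-informative*, with a warning).
Residue sets print most-frequent-first with alphabetical tie-breaks — a fixed
deterministic rule, since published tables rarely state one.

Residue numbers within an isoform are the count of non-gap characters up to
the column, so a site can be quoted as e.g. "Y465 in one isoform, F464 in
another" even though both sit in the same alignment column.

## Selection statistics

* **Nei–Gojobori counting.** Synonymous sites per codon position are the
  fraction of non-stop single-base changes that preserve the amino acid
  (stop-codon mutations are excluded from the denominator); S + N = 3 ×
  compared codons holds to 1e-9 for every pair. Multi-hit codons average
  syn/nonsyn step counts over all minimal mutational pathways, excluding
  pathways through stops; in the rare case that every pathway is blocked,
  all pathways are used (stop-crossing steps counted as nonsynonymous) so
  that S_d + N_d always equals the raw difference count.
* **Distances.** "Nucleotide divergence" defaults to the p-distance;
  published divergence tables often leave the model unstated, so the model
  used here is always recorded in the output. Jukes–Cantor is available and is undefined
  (flagged, NaN) at p ≥ 0.75.
* **Z-test.** Means of dS and dN are taken over within-lineage pairs when a
  partition is supplied (all pairs otherwise). Variances come from a
  1000-replicate (configurable, ≥100) seeded multinomial bootstrap over codon
  columns; Z = (d̄_S − d̄_N)/√(Var d̄_S + Var d̄_N) with a one-tailed normal
  p-value for directional alternatives. An alignment with no variation is
  flagged and returns p = 1 rather than a spurious statistic.
* **Per-site dN/dS** sums pairwise Nei–Gojobori counts per codon column and
  takes ratio = (N_d/N)/(S_d/S). This is a counting approximation, not a
  maximum-likelihood site model: columns with S_d = 0 are *undefined* (no
  synonymous yardstick), not evidence of positive selection, and the split
  of columns into >1 / <1 / undefined should be read as descriptive.
* **Tajima's D** uses the standard coefficients (a₁, a₂, b₁, b₂, c₁, c₂,
  e₁, e₂); θ_W and π are reported per site, D is computed from the raw S and
  k̄. S = 0 flags D as undefined. sign(D) = sign(π − θ_W) holds on every
  input with S > 0 and is property-tested.

## Composition and codon usage

Frequencies are computed per sequence (so a group mean carries a standard
error and supports a t-test across sequences), restricted by default to
parsimony-informative columns — nucleotide-level for the codon-position
table, residue-level for the amino-acid table. Gaps are excluded from both
numerator and denominator; each per-sequence vector sums to 100 % within its
codon position (or across the 20 amino acids). Group spread is reported as
SE = SD/√n with the SD retained, and cells are contrasted with a
pooled-variance Student's t (Welch is deliberately not the default, matching
the named test; degenerate zero-variance cases return t = 0, p = 1 or a
flagged infinite t). The significance convention highlights p < 0.001.
Whether such tables should use per-sequence means or pooled counts is
genuinely ambiguous; per-sequence means were chosen because pooled counts
admit no between-sequence variance and hence no t-test. A test verifies the
two routes agree exactly on gap-free equal-length input.

RSCU excludes stop codons and single-codon families (Met, Trp); an
unobserved family yields NaN entries and is listed in `zero_families`
rather than silently becoming 0/0.

## The simulator

Two lineages share a root coding sequence and evolve independently: a split
branch to each lineage ancestor, then a star phylogeny of tips. This is
deliberately not a coalescent — it is the minimal shape that produces
within-lineage variation and between-lineage divergence, which is all the
downstream statistics consume.

Substitution is a uniformized Markov chain per codon: events arrive at a
constant rate and either self-loop or apply a single-base change drawn with
weight 1 for synonymous changes, ω for nonsynonymous ones, zero for changes
creating stops, and third-position changes additionally scaled by the
lineage's GC3 preference for the *target* base. Because a move's weight
depends only on its target, the chain satisfies detailed balance against a
stationary distribution proportional to that GC weight — realized GC3
converges on the target (property-tested to ±0.05 at 500 codons), and the
synonymous/nonsynonymous flux ratio tracks ω (mean pairwise dN/dS recovers
ω = 0.2 within ±0.1). Depth parameters are expected *realized* substitutions
per codon; ω shapes the composition of events, not their number. At the
lineage split, third positions are additionally re-drawn synonymously under
the lineage's GC3 target, representing the mutational pressure accumulated
since divergence; a zero-length split branch skips this, so a zero-depth
simulation returns sequences identical to the ancestor.

Diagnostic sites are injected last by overwriting whole columns: strictly
dimorphic sites fix a different residue (one codon) in each lineage;
fixed-variable sites fix one lineage and give the other 2–4 disjoint
residues assigned cyclically so every drawn residue is realized. Injection
after evolution guarantees the truth labels are exact.

Defaults mirror the targeted study conditions: 8 + 15 sequences, 423 codons,
ω = 0.1, GC3 targets 0.41 and 0.87 (AT-rich dicot-like vs GC-rich
monocot-like third positions), one strictly dimorphic plus three
fixed-variable sites. Branch depths (split 0.75, tip 0.6 substitutions per
codon) were set by inverting the Jukes–Cantor saturation curve so that
uniform-rate expectations land near within-lineage ≈ 0.3 and between-lineage
≈ 0.5 p-distance; because purifying selection concentrates change at third
positions, realized distances saturate somewhat lower (≈ 0.24 within, ≈ 0.42
between), which is accepted rather than tuned away.

What the simulator does **not** model: indels (gap handling is tested on
hand-built fixtures), rate variation across sites, codon-model likelihoods
(GY94/MG94), within-lineage tree structure, and recombination. Passing tests
therefore demonstrate the correctness of the counting and the detectability
of lineage-fixed sites under the stated generative model — not robustness to
alignment error or deep coalescent structure in real data.

## Calibration and recovery checks

With ω = 1 the purifying Z-test's rejection rate at α = 0.05 stays within
[0.01, 0.10] over 200 seeded replicates (6 sequences × 200 codons each) —
the bootstrap variance is approximately calibrated, slightly conservative
because Var(d̄_S) + Var(d̄_N) ignores their (small) covariance. Noise-free
simulations with injected sites are recovered with precision = recall = 1.
Problem sizes in the test suite and the acceptance script (hundreds of
codons, tens of sequences, 200–1000 bootstrap or replicate counts) were
chosen as the smallest sizes at which these stochastic properties are stable
across seeds.

## Known limitations

* Identity-threshold clustering reproduces curated family nomenclature only
  up to the identity definition; local-alignment identities can merge or
  split borderline families.
* Per-site dN/dS categories are pairwise counts, not a site model; the
  undefined category absorbs both invariant columns and purely
  nonsynonymous ones.
* The Z-test's normal approximation is poor for very short alignments
  (< ~100 codons) or ≤ 3 sequences.
* Tajima's D here has no attached p-value; the usual beta-distribution
  approximation was left out as the statistic is used descriptively.
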