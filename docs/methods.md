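# Methods

## The classification model

The classifier treats a metagenomic read set as a bag of fixed-length
nucleotide fragments. Each read is cut into non-overlapping k-mers
(k = 50 by default; the trailing remainder is dropped, pairing is
ignored), identical fragment sequences are merged with summed
multiplicity, and each distinct fragment is aligned against a reference
index with a substitution-only mismatch budget (3 by default). The model
therefore assumes:

- substitution errors only — indel-containing fragments simply fail to
  match, which at short k and low error rates loses little sensitivity;
- unstranded input — every fragment is matched against both strands via
  canonical k-mers (lexicographic minimum of a window and its reverse
  complement);
- a reference curated to species rank: strain and sub-species labels are
  collapsed into their parent species, sequences resolvable only to genus
  or above — or flagged "environmental" — are removed before indexing.

A fragment whose hit set contains exactly one taxon at the evaluated rank
is a *signature* fragment. For genus-rank analysis, species hits are
mapped to their genus ancestor **before** uniqueness is evaluated, so a
fragment shared by two congeneric species is still genus-signature.
Per-taxon bookkeeping keeps the total/unique duality throughout: "total"
counts weight fragments by multiplicity, "unique" counts each distinct
fragment sequence once.

### Index realization

The lookup contract — all taxa owning a reference window within Hamming
distance d of a query, either strand — is honoured with hash postings
over canonical k-mers plus pigeonhole seeding: the query is split into
d + 1 contiguous blocks, candidate reference k-mers are gathered from
per-block exact maps, and each candidate is verified with a full Hamming
comparison. This is exact (any window within distance d must match at
least one block exactly) and fast at the scales this package targets
(up to a few hundred Mb of reference on one core). A full-text index
would honour the same contract; nothing downstream depends on the choice.
Windows containing N are excluded from the index and from queries so the
mismatch budget is never consumed by no-calls; fragments containing
non-ACGT characters are skipped with a warning and not counted as
queries.

## Confidence scoring

Present organisms should produce signature hits in the proportion their
references predict. For taxon T:

- **expected SR**: n = 100,000 fragments are drawn uniformly (with
  replacement, error-free) from T's own curated references and classified
  against the full index; expected SR is the fraction of signature
  fragments among those that hit anything. An exhaustive enumeration over
  every reference window is also provided and is the estimator's n → ∞
  limit.
- **observed SR**: T's signature / total hits in the sample.
- one-sample proportion test with the *expected* proportion in the
  variance, z = (SR̂ − SR)/√(SR(1 − SR)/n), two-sided normal p-value. The
  trial count n defaults to the expected-SR estimation count (100,000),
  overridable.
- Cohen's h = |2 arcsin √SR̂ − 2 arcsin √SR| (the standard
  arcsine-difference effect size; the absolute value makes it a distance).
- ratio = SR̂ / SR, deliberately *not* folded to max(r, 1/r): ratios below
  one (fewer signature hits than expected) still qualify for the
  confident tiers and are visible in the output for transparency.

Tier rules, first match wins: very_high (≥ 300 unique signature hits,
h < 0.4, ratio < 2.5), high (≥ 300, h < 0.5, ratio < 2.5), medium
(≥ 300, ratio < 4), else low; low-tier records are discarded from
summaries but written to an audit table.

Degenerate cases, reachable on toy references: expected SR = 1 gives a
zero-variance test; the z/p fields are left unset and the record is
tiered on its (well-defined) ratio and h — a taxon with all-signature
references and all-signature observations tiers very_high with h = 0,
ratio = 1. Expected SR = 0 leaves the ratio undefined; such records
cannot satisfy any ratio bound and tier low, flagged `degenerate`.

No multiple-testing correction is applied across taxa; the tier rules,
not the p-value, make the call.

## Accumulation curves

Sequencing sufficiency is judged by subsampling *reads* (not fragments),
then fragmenting and classifying each subsample and counting species
with at least one species-level signature hit. Fractions run 10%–90% in
10% steps with 10 replicates, plus the full sample once: 20 samples
yield 20 × 10 × 9 = 1,800 classification runs.

Within one replicate the fractions are **nested**: a single permutation
of the reads is drawn per (master seed, sample, replicate) and fraction
f takes its first round(f·N) entries. Nesting makes the species count
non-decreasing in f within every replicate by construction — the defining
property of a rarefaction-style curve — whereas independent per-fraction
draws leave the mean curve monotone only in expectation, with visible
violations at 10 replicates. Any cell is still independently
reproducible from its replicate seed.

## Consensus comparison

Profiles from other classifiers are ingested in their native formats
(Kraken-style report, MetaPhlAn-style clade table) alongside this
package's confidence TSV, rank-filtered, and name-harmonised (rank
prefixes trimmed, underscores to spaces, plus a user-editable synonym
table for renamed taxa such as Cutibacterium/Propionibacterium).
Presence is abundance > 0 for external tools and tier ≥ medium for the
signature classifier. A *call* is a (taxon, sample) pair present in ≥ 1
method; the agreement matrix counts methods per call and the overlap
summary partitions calls by agreement level, summing to the total call
count by construction. Abundances are never averaged across methods —
counts and relative abundances are not commensurable.

## KO functional profiling

A KO library pools gene sequences per KEGG Orthology identifier,
de-duplicated by sequence text across contributing species; its index is
the same canonical-k-mer structure with KO labels. The identical
fragment multiset from taxonomic classification is re-used. Fragments
matching exactly one KO count toward it; multi-KO and no-hit fragments
are discarded but accounted, so assigned + multi + no-hit = total always.

RPKM = (count / (aggregate unique gene length / 1000)) /
(total fragments / 10⁶), with total fragments counting classified and
unclassified alike (a flag switches to classified-only). Per sample the
top-500 KOs by RPKM (ties broken by KO id) are unioned; Bray-Curtis
dissimilarity over that KO set is ordinated by classical scaling (PCoA).
Bray-Curtis is non-Euclidean, so "principal components" on it are
computed as principal coordinates; negative eigenvalues are dropped with
a warning and axis variance fractions are reported over the positive
spectrum.

## Scaffold taxonomy

Scaffolds ≥ 1 kb (inclusive) enter the analysis. Per scaffold, the top
BLAST hit is selected by bit score, ties broken by lower e-value then
input order — deterministic under any row shuffling. The top hit is
retained when coverage ≥ 0.25, identity ≥ 80% and e-value ≤ 1e-7, all
boundaries inclusive. Coverage is alignment length / query length — the
reproducible reading of "alignment covered X% of the query" from
tabular output; a qstart/qend-based definition differs when gaps are
asymmetric and is available via flag. Only the single top hit per
scaffold contributes to organism fractions (summing all retained hits
would double-count), alignment lengths are capped at scaffold length,
and the remainder is reported as unassigned so fractions sum to one.
Because the conventional denominators for "scaffolds without
high-quality hits" percentages are ambiguous in practice, the summary
emits both candidates (share of all scaffolds and share of annotated
scaffolds).

## The synthetic generator: what a green test establishes

Genomes are uniform-random over A/C/G/T with shared blocks copied
*verbatim* between taxon pairs at stated fractions, placed in disjoint
regions per genome so no unintended three-way sharing arises — the
signature status of every window is therefore exactly enumerable. Reads
are drawn uniformly with random strand and independent per-base
substitutions. KO gene sets plant verbatim cross-KO blocks the same way;
BLAST fixtures plant full-length passing hits plus rows straddling every
filter boundary and a bit-score tie.

Defaults are the package's stated world: 5 taxa × 20 kb genomes, 10⁴
reads of 150 bp at 1% substitution error; the default fixture adds a
sixth "ghost" species sharing 0.9 of its genome with the least-abundant
present species and contributing zero reads. All generation is
deterministic under its seeds.

What this does **not** emulate: quality-dependent or indel errors, GC
and coverage bias, mosaic homology (real shared sequence diverges rather
than matching verbatim), plasmid/chromosome structure, or databases with
mislabelled references. A green composition-recovery test therefore
establishes the counting and scoring machinery, not robustness to real
reference noise.

## Parameter defaults

| parameter | default | meaning |
| --- | --- | --- |
| k | 50 nt | fragment length |
| max_mm | 3 | Hamming mismatch budget per fragment |
| n | 100,000 | trials for expected-SR estimation (and z by default) |
| tier thresholds | 300 / 0.4 / 0.5 / 2.5 / 4 | unique-signature floor, h bounds, ratio bounds |
| fractions, n_reps | 0.1–0.9, 10 | accumulation design |
| top_n | 500 | per-sample KO set size |
| min_len | 1,000 b | scaffold length floor |
| min_cov / min_ident / max_e | 0.25 / 80% / 1e-7 | scaffold hit quality filters |

## Known limitations

- The mismatch search is exact but in-memory; references beyond a few
  hundred Mb per core call for the disk-backed full-text index the
  contract was written to allow.
- Expected-SR estimation samples error-free fragments; at elevated
  sequencing error the observed ratio drifts from it, inflating the
  ratio statistic slightly before the tier bounds absorb it.
- Genus-rank handling maps species without a genus ancestor to
  themselves (logged) rather than dropping them.
- The consensus module harmonises names lexically; taxonomies that
  disagree structurally (merged/split genera) need explicit synonym
  entries.
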