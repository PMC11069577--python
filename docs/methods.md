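# Methods

This note documents the models, the synthetic data they are tested on, the
numerical conventions, and the design choices that were genuinely open.

## Site windows

Both predictors consume a cytosine with 15 nt of upstream and 10 nt of
downstream context (a 26-nt window). Coordinates are 1-based on the coding
sequence, matching HGVS `c.` numbering. The internal alphabet is RNA
({A,C,G,U}); DNA input is converted on read and ambiguity codes are
rejected outright rather than silently handled.

Sites within 15 nt of the 5' end or 10 nt of the 3' end of a sequence are
retained, padded with U, and flagged (`SiteWindow.padded`) so callers can
exclude them. U is the neutral choice: it encodes as the all-zero bit pair
in the classifier's feature map, and the stem-loop search never pairs
against padding (padded positions read as "no residue", so stems simply
stop at the true sequence boundary). Keeping edge sites makes genome-wide
scans total functions of the input; the flag preserves the caller's right
to be stricter.

## Rules-based stem-loop scorer

A hairpin is a 3- or 4-nt loop closed by a stem of Watson–Crick pairs.
The scored cytosine is fixed at one loop terminus. Which terminus is a
configuration enum (`LoopTerminus`), because the two natural readings of
the substrate geometry disagree; the default is the 3' end of the loop,
matching the orientation of the canonical substrate diagrams (and the
package's own worked examples), with the 5'-end convention fully
implemented and tested under the same oracle.

For each loop length the stem extends pairwise outward from the loop
boundary. G:C and A:U pairs score 3 and 1; G:U wobble pairs score nothing
and, like any other mismatch, end the stem — the scoring formula names only
the two canonical pairs, so the search recognises only them. One
imperfection is tolerated per structure: at the position two nucleotides 5'
of the scored C, counted along the primary sequence, the search branches
into (a) an unscored mismatch pair, (b) a one-nt bulge on the 5' arm, (c) a
one-nt bulge on the 3' arm, each continued as a separate candidate
structure. Counting the offset in sequence space keeps the rule well
defined under both loop conventions; under the default 3'-end convention
the offset lands inside the loop, so the allowance is effectively inactive
there (this is a property of the convention, not a special case in the
code). Stem length is capped at 15 pairs — unreachable inside a 26-nt
window, so the cap only bounds pathological configurations.

The site total is the maximum over all candidate structures of
`3·n_GC + n_AU + bonus`, where the bonus is +2 (awarded once) if a uracil
occurs among the non-C loop residues *or* the residue immediately 5' of the
C is a purine, and −2 if a guanine occurs among the non-C loop residues;
both clauses can apply, netting 0. The scored C itself is a fixed loop
residue and never counts as evidence. A site is called when the total is
strictly greater than 9. Sites with no qualifying hairpin (at least one
scored pair) carry a sentinel that ranks below every reachable integer
total in threshold sweeps — this is what caps the rules model's maximum
recall in ROC analysis, since no threshold can recover a no-structure site.

Ties between equal-scoring structures prefer loop length 3, then the longer
stem, then the 5'-most loop start. This affects only which structure is
*reported*, never the score.

The scorer is verified against an independent brute-force oracle
(generate-and-test over every loop placement, stem length and imperfection
option) on 10⁴ random windows per convention, padded and unpadded.

## Random-forest classifier

Each window's 25 context nucleotides are encoded position-major, two bits
per position, `isPurine` before `pairsGC`: A→(1,0), G→(1,1), C→(0,1),
U→(0,0). The code is bijective on {A,C,G,U}, so unpadded windows decode
exactly; padding encodes as (0,0), indistinguishable from U by design. Bit
order is fixed and documented here because any consistent order works —
forests are insensitive to feature permutation — but reproducibility
requires picking one.

Training-set construction is where the class imbalance is handled. All
positives are kept. Negatives are sampled without replacement to
`neg_pos_ratio` per positive (default 3), and a fraction of them (default
0.5) is drawn from "hard" negatives whose rules total is at least 6. The
threshold 6 is a declared default for "scores highly but is not edited",
exposed in `TrainingConfig`; when the hard pool is smaller than requested
the sampler falls back to random negatives with a logged warning (on
rejection-sampled synthetic data this is common, since the generator
actively suppresses high-scoring negatives). SMOTE-style oversampling —
interpolation between minority samples and their k nearest minority
neighbours — is implemented in-house (a dozen lines on a dense matrix) and
off by default: downsampling plus hard negatives is the primary strategy,
SMOTE an alternative worth keeping testable.

The forest itself is scikit-learn's `RandomForestClassifier` with 500
trees, unlimited depth, √p features per split, and a mandatory seed. These
hyperparameters are declared defaults, not tuned values; they are exposed
in `TrainingConfig`. A site is called when the predicted probability is
strictly over 0.5.

## Consensus and benchmarking

Union and intersection operate on boolean calls, purely set-theoretically.
On any labeled set, union recall ≥ each primary's recall ≥ intersection
recall, and the reverse ordering tends to hold for precision; the test
suite asserts the recall chain.

Evaluation uses two sets. The testing set is the held-out 30% of a
stratified split (1:3 editing:non-editing). The proportional set keeps the
same positives and tops negatives up to 1:468 with a seeded global sample
from a disjoint pool (per-gene sampling would be an alternative; global is
simpler and the choice is recorded here). Because positives are shared,
recall is identical across the two sets for any fixed classifier — a
structural fact the tests verify. A leakage check refuses pool negatives
that overlap the training set, keyed by (gene, position); synthetic gene
ids embed the generator seed so independently drawn fixtures never collide.

Point metrics come from closed forms with explicit NaN on zero
denominators — never 0, which would silently flatter a model that calls
nothing. AUROC is trapezoidal (equal to the normalized Mann–Whitney U
statistic, cross-checked against scipy), AUPRC is step-wise average
precision (non-interpolated), and the AUPRC baseline is the positive
prevalence. The redundancy audit computes pairwise identity over the 25
context nucleotides and reports the fraction of pairs above 75% (≥19
matching positions) and above 30% identity, in blocks to bound memory.

## Synthetic data

The generators encode the study conditions; they are inputs to the tests,
not knobs to turn afterwards.

*Sites.* Positives embed a hairpin with `stem_len` pairs (default 5), each
G:C with probability `gc_fraction` (default 0.8), closing a loop of length
3 (default) or 4 with the C at the configured terminus and, by default, a
planted uracil among the free loop residues (which are drawn from {A,C,U} —
a guanine would penalise the very motif being planted). Background is
uniform 25% per base. Negatives are background around a C,
rejection-sampled (cap 50 draws, then warn and emit) until the rules model
does not call them. Benchmarks of `n_pos` positives at ratio 1:3 or 1:468
reproduce the testing and proportional shapes; at 1:468 the prevalence is
1/469 ≈ 0.00213 by construction.

What this emulates: the structural separation between substrate and
background. What it does not: real editing data has no oracle that
guarantees negatives score below threshold, shares sequence between sites
in the same gene, and carries base composition far from uniform. So a
perfect rules-model score on synthetic benchmarks demonstrates internal
consistency (the generator and scorer agree about the motif), not field
performance; the forest's AUROC on held-out synthetic data is the
meaningful recovery statistic, and published benchmark numbers on curated
sites are not reproducible from synthetic data at all.

*Variant tables.* `make_variant_table` writes a ClinVar-dialect TSV plus
matching CCDS-style FASTA from a `VariantTableSpec` of marginal counts.
Each retained variant owns a 20-codon slot of a synthetic gene, so site
windows never interact. Variants that must be predicted get the fixed
hairpin `GGGGUC·UUC·GACCCC` planted around a CGA→UGA (Arg→Ter) cytosine:
16 stem points + 2 bonus = 18 > 9 whatever the flanks, so the rules call is
guaranteed. Non-predicted C>U variants use ACG→AUG (Thr→Met, plus strand)
or CAA→UAA (Gln→Ter written as the minus-strand G>A record, default 30% of
the remainder), with slot background re-drawn until the site is
rules-negative. Non-C>U exonic rows use GAA→AAA (Glu→Lys). Decoy rows
exercise every filter: non-SNV type, GRCh37 duplicates, like-to-like and
non-specific alleles, missing and synonymous protein changes, a gene with
no coding sequence, and a duplicate allele id. Because the rules model is
deterministic, the fixture guarantees its downstream marginals exactly
*under the rules model*; a trained forest cannot be forced per-site by
construction, so exact round-trips pin `model="rules"` (the union model
remains available for analysis use).

The bundled `PAPER_SCALE_SPEC` (617,363 exonic / 101,565 C>U / 4,600
predicted, with bins 19,285/9,459/72,821 and 1,046/422/3,132) is the
printed-scale study. `REDUCED_SCALE_SPEC` (121,212 / 20,000 / 900, bins
3,800/1,860/14,340 and 204/83/613) was solved as the smallest integer
configuration whose half-up rounded percentages equal the printed-scale
ones at every reported figure; naive 1/100 scaling cannot achieve this —
with only 46 predicted sites the percentage granularity is about 2 points,
so no integer split rounds to 22.7/68.1/9.2. Tests use the reduced spec
(about 10 s end to end); the acceptance script runs the full printed scale
(about 50 s).

*Hierarchy.* `make_mesh_fixture` builds a complete b-ary tree of dotted
tree numbers with known top/third-level structure and a condition→term
mapping with a configurable unmapped fraction.

## Variant pipeline conventions

Filters apply in a fixed order (SNV type, GRCh38, specific alleles, not
like-to-like, non-synonymous protein change present, duplicates collapsed
by allele id keeping the first), each stage logged. Assembly filtering
precedes duplicate collapse deliberately: GRCh37/GRCh38 companion records
share an allele id, and collapsing first could keep the wrong assembly.

C>U inference is codon-driven: enumerate the ≤9 single-base substitutions
of the reference codon, keep those translating to the recorded alternate
amino acid, and intersect with the genomic ref/alt pair read on both
strands (plus: ref→alt; minus: complement(ref)→complement(alt)). A unique
survivor gives the mRNA change; no survivor drops the record as
inconsistent; multiple survivors (e.g. UGG→Ter via G>A, where both UAG and
UGA are stops) mark the record ambiguous and exclude it from the C>U set
with a log line — excluding rather than guessing may undercount slightly,
and the log makes the volume auditable.

Significance binning is a case-insensitive whole-word match, "pathogenic"
before "benign", else unspecified. Word boundaries matter: "Conflicting
interpretations of pathogenicity" contains the substring but not the word
"pathogenic" and bins as unspecified.

Summary percentages are always recomputed from counts (never accumulated)
and rounded half-up to one decimal via `decimal.Decimal` — Python's
built-in banker's rounding would turn e.g. 2.25% into 2.2%.

## MeSH-style rollup conventions

The condition→term mapping is an input artifact, reflecting manual
curation; the module validates and consumes it, never infers it. A
non-empty qualifier column demotes a mapping to "Not found", which is a
reserved top-level pseudo-heading. Multi-tree descriptors count once per
top-level heading reached (consistent with per-heading tallies). Top-level
headings are counted at most once per variant regardless of how many of
its conditions roll up to them. Third-level terms are the absolute depth-3
tree numbers under the queried root; a term is covered by editing if any
predicted site's term maps to it or to a descendant, and covered by C>U
only if C>U terms (but no predicted term) do. Terms shallower than depth 3
that receive mappings directly do not create phantom coverage.

## Problem sizes and runtime

The default test suite runs in well under a minute on one CPU: 10⁴ windows
per convention for oracle equivalence, 10⁴ windows for encoding
bijectivity, 200 positives for classifier recovery (evaluated at 1:468,
about 28k sites), the reduced-scale variant spec for the exact round-trip,
and exhaustive confusion tables with counts ≤ 6 for the metric closed
forms. The acceptance script uses the full printed-scale variant spec and
the same benchmark sizes.

## Known limitations

- The stem-loop search is combinatorial, not thermodynamic: no folding
  energies, no pseudoknots, no multiloops, no G:U pairing.
- The pipeline works on concatenated coding sequences only — no genomic
  coordinates, splice structure, or liftover, and no indels/MNVs.
- Synthetic training data cannot stand in for curated editing sites;
  models trained here demonstrate machinery, not transferable weights.
- The hard-negative threshold (rules ≥ 6), forest hyperparameters and the
  downsampling ratio are declared defaults, exposed in configuration.
- Window padding at sequence edges is a documented convention (U, flagged),
  one of several defensible choices.
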