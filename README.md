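# cueditscan

Prediction of APOBEC3A/G-mediated C-to-U RNA editing sites in human coding
sequences, with an imbalance-aware benchmarking harness, a ClinVar-style
disease-variant pipeline, and a MeSH-style condition rollup.

## The problem

The cytidine deaminases APOBEC3A and APOBEC3G edit cytosine to uracil in
mRNA, transiently creating protein variants that never appear in the
genome. Their preferred substrate is a cytosine presented at the terminus
of the loop of an RNA hairpin: a 3–4 nt loop closed by a base-paired stem.
Editing sites are rare — roughly one per 468 cytosines in curated data —
so both prediction and evaluation must take the class imbalance seriously.

`cueditscan` is for computational biologists who want to (a) scan coding
sequences for candidate editing sites, (b) train and honestly benchmark
sequence classifiers at realistic prevalence, and (c) ask which known
disease variants could equally arise from transient RNA editing.

## The models

**Rules-based stem-loop scorer.** Around each cytosine (15 nt upstream,
10 nt downstream of context) candidate hairpins with loop length 3 or 4 are
enumerated, with the C fixed at a loop terminus (3' end by default; the 5'
end convention is available). The stem extends pairwise outward; one
mismatch or single-nucleotide bulge is tolerated at the position two
nucleotides 5' of the C. The score is

```
total = 3·(# G:C pairs) + 1·(# A:U pairs)
        + 2  if a uracil is in the loop or a purine is immediately 5' of the C
        − 2  if a guanine is in the loop
```

maximised over all candidate structures; a site is called when
`total > 9`. G:U wobble pairs are not scored and terminate the stem.

**Random forest.** The 25 context nucleotides are encoded position-major
with two bits each (`isPurine`, `pairsGC`: A→10, G→11, C→01, U→00), giving
a 50-bit vector fed to a scikit-learn `RandomForestClassifier` (500 trees,
seeded). Training downsamples non-editing sites to 3 per editing site,
drawing half of them from "hard" negatives the rules scorer rates ≥ 6;
SMOTE-style minority oversampling is available but off by default. A site
is called when P(editing) > 0.5.

**Consensus.** The union model calls a site if either primary model does
(highest recall); the intersection model only if both do (highest
precision).

**Benchmarking.** A stratified 70–30 split yields the 1:3 testing set; the
proportional set adds negatives up to 1:468, the realistic prevalence.
Recall, precision, F1 and MCC are computed from confusion counts (NaN, not
0, when undefined), AUROC/AUPRC by threshold sweep with the AUPRC baseline
equal to prevalence (1/469 ≈ 0.00213), and a pairwise 25-nt
sequence-identity audit guards against redundancy between site windows.

**Variant pipeline.** From a ClinVar `variant_summary`-style TSV: keep
GRCh38 non-synonymous SNVs with specific, unlike alleles; validate each
record's reference amino acid against the CCDS codon; infer the single-base
mRNA substitution consistent with the protein change and the genomic
alleles read on both strands; scan C>U sites with a chosen model; bin
clinical significance (pathogenic / benign / unspecified, whole-word
match); and report proportions over the nested exonic ⊇ C>U ⊇ predicted
sets. A MeSH-style rollup maps variant conditions through a curated table
to hierarchy terms, tallies top-level headings once per variant, and
measures third-level ("individual disease") coverage.

All inputs can be generated synthetically (`cueditscan.synthetic`): planted
stem-loop positives, rejection-sampled negatives, ClinVar-dialect variant
tables whose downstream marginals are known by construction, and toy
hierarchies.

## Worked example

`python examples/score_hairpin_sites.py` scans a 36-nt demo sequence
containing one planted hairpin (4 G:C pairs closing a `UUC` loop):

```
c_pos score  gc  au bonus call
   12    --   -   -     - no
   14     2   0   2     0 no
   17    14   4   0     2 YES
   19    --   -   -     - no
   21    --   -   -     - no
   29     5   1   0     2 no
   30    --   -   -     - no
```

The C at position 17 sits at the 3' end of the loop: 4 G:C pairs give 12
stem points, the loop uracils add +2, and 14 > 9 calls the site. `--`
marks cytosines with no qualifying hairpin at all (they rank below every
scored site in threshold sweeps).

`python examples/train_and_benchmark.py` trains the forest on 200 planted
positives at 1:3 and evaluates all four models at 1:468:

```
proportional set: 60 editing / 28080 non-editing sites (prevalence 0.00213)
         rules: recall 100.0%  precision 100.0%  F1 1.00  MCC 1.00
 random forest: recall  81.7%  precision  20.3%  F1 0.33  MCC 0.41
         union: recall 100.0%  precision  23.8%  F1 0.38  MCC 0.49
  intersection: recall  81.7%  precision 100.0%  F1 0.90  MCC 0.90
random forest AUROC 0.990, AUPRC 0.550 (baseline AUPRC = prevalence = 0.00213)
```

Union recall is the upper envelope of the primary models and intersection
precision the highest of the four — the ordering that makes the union model
the surveying tool and the intersection model the validation tool. (The
rules model is perfect *on this synthetic data* because the generator
rejection-samples negatives below its threshold; see `docs/methods.md` for
what that does and does not show.)

`examples/variant_pipeline_demo.py` and `examples/mesh_rollup_demo.py`
walk the variant pipeline and the hierarchy rollup the same way.

## Command line

```bash
cueditscan simulate --kind sites --n-pos 50 --ratio 468 --seed 7 --out sim/
cueditscan scan     --fasta sim/seqs.fa --model rules --out scan/
cueditscan train    --sites sim/sites.tsv --fasta sim/seqs.fa --seed 7 --out model/
cueditscan benchmark --sites sim/sites.tsv --fasta sim/seqs.fa \
                     --model-file model/model.joblib --out bench/
cueditscan pipeline --variants variant_summary.tsv --ccds-dir ccds.fa \
                    --model union --model-file model/model.joblib --out pipe/
cueditscan mesh     --hierarchy hierarchy.tsv --map mapping.tsv \
                    --annotated pipe/annotated_variants.tsv --out mesh/
```

Every subcommand is seeded and writes a run manifest; rerunning with the
same inputs and seed reproduces outputs byte for byte.

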