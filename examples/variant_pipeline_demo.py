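"""Run the ClinVar-style variant pipeline on a generated fixture.

The fixture writes a ``variant_summary``-dialect table (with decoy rows the
filters must drop) and matching coding sequences.  The pipeline keeps
GRCh38 non-synonymous SNVs, validates each record's reference amino acid
against its codon, infers the mRNA-level substitution from the protein
change and the genomic alleles read on both strands, scans every C>U site
with the rules model, and summarizes pathogenicity proportions over the
nested exonic / C>U / predicted sets.
"""

import tempfile

from cueditscan import synthetic, variants

spec = synthetic.VariantTableSpec(
    n_exonic=2000, n_c2u=330, n_pathogenic=63, n_benign=31,
    n_unspecified=236, n_predicted=15, n_predicted_pathogenic=4,
    n_predicted_benign=1, n_predicted_unspecified=10, n_genes=10,
    conditions=(("hereditary anemia", 40), ("cardiomyopathy", 25)))

with tempfile.TemporaryDirectory() as tmp:
    manifest = synthetic.make_variant_table(spec, seed=5, out_dir=tmp)
    result = variants.run_pipeline(manifest["variants"], manifest["ccds"],
                                   model="rules")

print("filter stages:", result["filter_log"])
s = result["summary"]
print(f"exonic SNPs: {s['exonic']['n']}")
print(f"C>U SNPs:    {s['c2u']['n']} ({s['c2u']['pct_of_exonic']}% of exonic)")
print(f"predicted:   {s['predicted']['n']} "
      f"({s['predicted']['pct_of_c2u']}% of C>U)")
for b in ("pathogenic", "benign", "unspecified"):
    print(f"  {b:>12}: C>U {s['c2u'][b]['pct']:>5}%   "
          f"predicted {s['predicted'][b]['pct']:>5}%   "
          f"predicted-within-bin {s['predicted']['pct_within_bin'][b]}%")

# Percentages are recomputed from counts and rounded half-up to one
# decimal; the generator guarantees the marginals, so the pipeline output
# equals the spec exactly -- the round-trip the test suite relies on.
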