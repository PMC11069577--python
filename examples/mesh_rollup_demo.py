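"""Roll variant conditions up a toy MeSH-like hierarchy.

Conditions map (via a curated table) to hierarchy terms; each variant's
terms roll up to top-level headings, counted at most once per variant.
Third-level terms (grandchildren of the roots) proxy individual diseases:
a term is covered when a predicted editing site, or failing that a C>U
SNP, maps to it or to any descendant.
"""

from cueditscan import mesh, synthetic

fix = synthetic.make_mesh_fixture(depth=4, branching=3, n_conditions=20,
                                  seed=2)
h = mesh.load_hierarchy(fix["hierarchy"])
mapping = mesh.load_mapping(fix["mapping"])

# three variants with overlapping condition annotations
variant_conditions = {
    "snp1": ("condition 0000", "condition 0001"),
    "snp2": ("condition 0001",),
    "snp3": ("condition 0002", "never curated"),
}
counts = mesh.count_headings(variant_conditions, mapping, h)
print("top-level heading counts (deduplicated per variant):")
for term, n in sorted(counts.items(), key=lambda kv: -kv[1]):
    print(f"  {h.names.get(term, term):>18}: {n}")

pred_terms = {mapping["condition 0000"]}
c2u_terms = {mapping[c] for c in ("condition 0000", "condition 0001",
                                  "condition 0002")}
for root in [t for t in h.tree_numbers if h.level(t) == 1]:
    cov = mesh.third_level_coverage(h, c2u_terms, pred_terms, root)
    print(f"{h.names[root]}: {cov['n_terms']} third-level terms, "
          f"{cov['pct_predicted']:.0f}% with a predicted site, "
          f"{cov['pct_c2u_only']:.0f}% with only a C>U SNP")

# "Not found" absorbs conditions without a curated heading and counts as
# its own top-level heading.
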