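"""Variant parsing, filtering, codon validation, C>U inference and
summary proportions."""

import pandas as pd
import pytest

from cueditscan import synthetic, variants
from cueditscan.seqio import NucSequence
from cueditscan.variants import (MrnaChange, SchemaError, bin_significance,
                                 filter_variants, infer_mrna_change,
                                 parse_variant_summary, round_half_up,
                                 summarize, validate_against_ccds)


def _table(rows):
    cols = ["#AlleleID", "Type", "Name", "GeneSymbol",
            "ClinicalSignificance", "RS# (dbSNP)", "PhenotypeList",
            "Assembly", "ReferenceAlleleVCF", "AlternateAlleleVCF"]
    return pd.DataFrame(rows, columns=cols)


def _row(allele=1, type_="single nucleotide variant", assembly="GRCh38",
         ref="C", alt="T", name="NM_1.1(G1):c.1C>T (p.Arg1Ter)", gene="G1",
         sig="Pathogenic", pheno="not provided"):
    return [allele, type_, name, gene, sig, 10, pheno, assembly, ref, alt]


class TestParsing:
    def test_protein_change_extracted(self, tmp_path):
        p = tmp_path / "v.tsv"
        _table([_row(name="NM_1.1(G1):c.743G>A (p.Arg248Gln)")]).to_csv(
            p, sep="\t", index=False)
        df = parse_variant_summary(p)
        assert df.loc[0, "ref_aa"] == "Arg"
        assert df.loc[0, "aa_pos"] == 248
        assert df.loc[0, "alt_aa"] == "Gln"

    def test_stop_and_synonymous_notation(self, tmp_path):
        p = tmp_path / "v.tsv"
        _table([
            _row(allele=1, name="NM_1.1(G1):c.1C>T (p.Arg1*)"),
            _row(allele=2, name="NM_1.1(G1):c.6C>T (p.Leu2=)"),
        ]).to_csv(p, sep="\t", index=False)
        df = parse_variant_summary(p)
        assert df.loc[0, "alt_aa"] == "Ter"
        assert df.loc[1, "alt_aa"] == df.loc[1, "ref_aa"] == "Leu"

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "v.tsv"
        _table([_row()]).drop(columns=["Assembly"]).to_csv(p, sep="\t",
                                                           index=False)
        with pytest.raises(SchemaError, match="Assembly"):
            parse_variant_summary(p)


class TestFilters:
    def _parse(self, tmp_path, rows):
        p = tmp_path / "v.tsv"
        _table(rows).to_csv(p, sep="\t", index=False)
        return parse_variant_summary(p)

    def test_each_exclusion_clause(self, tmp_path):
        rows = [
            _row(allele=1),                                   # retained
            _row(allele=2, type_="Deletion"),                 # not an SNV
            _row(allele=3, assembly="GRCh37"),                # old assembly
            _row(allele=4, ref="A", alt="A"),                 # like-to-like
            _row(allele=5, ref="A", alt="X"),                 # non-specific
            _row(allele=6, name="NM_1.1(G1):c.9G>A"),         # no aa change
            _row(allele=7, name="NM_1.1(G1):c.9G>A (p.Leu3=)"),  # synonymous
            _row(allele=1),                                   # duplicate
        ]
        df, log = filter_variants(self._parse(tmp_path, rows))
        assert len(df) == 1
        assert log["input"] == 8
        assert log["snv_type"] == 7
        assert log["grch38"] == 6
        assert log["specific_alleles"] == 5
        assert log["not_like_to_like"] == 4
        assert log["nonsynonymous_change"] == 2
        assert log["unique_alleles"] == 1

    def test_filter_chain_is_monotone(self, tmp_path):
        rows = [_row(allele=i) for i in range(10)]
        rows += [_row(allele=99, type_="Indel")]
        _, log = filter_variants(self._parse(tmp_path, rows))
        stages = list(log.values())
        assert all(a >= b for a, b in zip(stages, stages[1:]))


class TestCcdsValidation:
    def test_codon_matches_record(self):
        cds = NucSequence(id="G1", residues="AUGCGA")
        assert validate_against_ccds("Arg", 2, cds)
        assert not validate_against_ccds("Gly", 2, cds)

    def test_position_beyond_cds_invalid(self):
        cds = NucSequence(id="G1", residues="AUGCGA")
        assert not validate_against_ccds("Arg", 5, cds)


class TestInferMrnaChange:
    def test_plus_strand_nonsense(self):
        # CGA (Arg) -> UGA (Ter) forced by genomic C>T
        cds = NucSequence(id="G1", residues="AUGCGA")
        ch = infer_mrna_change("G1", "Arg", 2, "Ter", "C", "T", cds)
        assert ch == MrnaChange(gene="G1", cds_pos=4, ref_base="C",
                                alt_base="U", is_c2u=True)

    def test_plus_strand_not_c2u(self):
        # GAA (Glu) -> AAA (Lys) via genomic G>A
        cds = NucSequence(id="G1", residues="GAA")
        ch = infer_mrna_change("G1", "Glu", 1, "Lys", "G", "A", cds)
        assert ch.is_c2u is False
        assert (ch.ref_base, ch.alt_base) == ("G", "A")

    def test_minus_strand_c2u(self):
        # CAA (Gln) -> UAA (Ter); record carries the minus strand G>A
        cds = NucSequence(id="G1", residues="CAA")
        ch = infer_mrna_change("G1", "Gln", 1, "Ter", "G", "A", cds)
        assert ch.cds_pos == 1
        assert ch.is_c2u is True and not ch.ambiguous

    def test_strand_symmetry(self):
        """Complementing both genomic alleles leaves the inference
        unchanged (the other strand reading covers it)."""
        cds = NucSequence(id="G1", residues="CAA")
        a = infer_mrna_change("G1", "Gln", 1, "Ter", "G", "A", cds)
        b = infer_mrna_change("G1", "Gln", 1, "Ter", "C", "T", cds)
        assert a == b

    def test_inconsistent_record_returns_none(self):
        # alleles cannot produce the claimed change
        cds = NucSequence(id="G1", residues="CGA")
        assert infer_mrna_change("G1", "Arg", 1, "Ter", "A", "G", cds) is None

    def test_two_survivors_marks_ambiguous(self):
        # UGG (Trp) -> Ter with genomic G>A: UAG (position 2) and UGA
        # (position 3) are both stops reachable by the same G>A reading,
        # so the record is ambiguous and excluded from the C>U set
        cds = NucSequence(id="G2", residues="UGG")
        ch = infer_mrna_change("G2", "Trp", 1, "Ter", "G", "A", cds)
        assert ch is not None and ch.ambiguous

    def test_symmetric_alleles_resolved_by_codon(self):
        # UUA (Leu) -> Ter, genomic T>A: only position 2 yields a stop
        # (UAA); the minus-strand reading (A>U) finds nothing
        cds = NucSequence(id="G1", residues="UUA")
        ch = infer_mrna_change("G1", "Leu", 1, "Ter", "T", "A", cds)
        assert ch is not None and not ch.ambiguous
        assert (ch.cds_pos, ch.alt_base) == (2, "A")


class TestBinSignificance:
    @pytest.mark.parametrize("tag,expected", [
        ("Pathogenic", "pathogenic"),
        ("Pathogenic/Likely pathogenic", "pathogenic"),
        ("Likely benign", "benign"),
        ("Benign", "benign"),
        ("Uncertain significance", "unspecified"),
        ("not provided", "unspecified"),
        # word-boundary match: "pathogenicity" is not the word "pathogenic"
        ("Conflicting interpretations of pathogenicity", "unspecified"),
        ("likely PATHOGENIC", "pathogenic"),
    ])
    def test_binning(self, tag, expected):
        assert bin_significance(tag) == expected


class TestSummarize:
    def test_half_up_rounding(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(2.24, 1) == 2.2
        assert round_half_up(18.996, 1) == 19.0

    def test_percentages_recomputed_from_counts(self):
        df = pd.DataFrame({
            "bin": ["pathogenic"] * 19 + ["benign"] * 9 + ["unspecified"] * 72,
            "is_c2u": [True] * 100,
            "predicted": [True] * 5 + [False] * 95,
        })
        s = summarize(df)
        assert s["c2u"]["pathogenic"]["pct"] == 19.0
        assert s["predicted"]["pct_of_c2u"] == 5.0

    def test_empty_predicted_set_gives_none(self):
        df = pd.DataFrame({"bin": ["benign"], "is_c2u": [False],
                           "predicted": [False]})
        s = summarize(df)
        assert s["predicted"]["pathogenic"]["pct"] is None
        assert s["predicted"]["pct_of_c2u"] is None

    def test_set_nesting_invariant(self, tmp_path):
        spec = synthetic.VariantTableSpec(
            n_exonic=80, n_c2u=30, n_pathogenic=10, n_benign=5,
            n_unspecified=15, n_predicted=6, n_predicted_pathogenic=2,
            n_predicted_benign=1, n_predicted_unspecified=3, n_genes=3)
        man = synthetic.make_variant_table(spec, seed=8, out_dir=tmp_path)
        res = variants.run_pipeline(man["variants"], man["ccds"],
                                    model="rules")
        t = res["table"]
        assert t[t["predicted"]]["is_c2u"].all()
        for scope in ("exonic", "c2u", "predicted"):
            s = res["summary"][scope]
            assert (s["pathogenic"]["n"] + s["benign"]["n"]
                    + s["unspecified"]["n"]) == s["n"]
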