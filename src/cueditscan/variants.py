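"""ClinVar-style variant filtering, codon validation and C>U inference.

The pipeline mirrors a disease-variant survey: start from a
``variant_summary``-dialect table, keep GRCh38 single-nucleotide variants
with specific, unlike alleles and a non-synonymous protein change, validate
each record's reference amino acid against the gene's coding sequence,
work out which single-base mRNA substitution explains the protein change
(considering both strand readings of the genomic alleles), keep the C>U
subset, scan each edited cytosine with the editing-site predictors, bin the
clinical-significance strings three ways (pathogenic / benign /
unspecified), and summarize the nested sets.

Percentages in the summary are recomputed from counts and rounded half-up
to one decimal, matching how such surveys print proportions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import ml, rules
from .consensus import SitePrediction
from .seqio import (AA3_TO_AA1, NucSequence, codon_at, extract_window,
                    gene_of, normalize, read_fasta, translate)

__all__ = [
    "VariantRecord",
    "MrnaChange",
    "parse_variant_summary",
    "filter_variants",
    "load_ccds",
    "validate_against_ccds",
    "infer_mrna_change",
    "bin_significance",
    "predict_c2u_sites",
    "summarize",
    "run_pipeline",
    "round_half_up",
    "SchemaError",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ["Type", "Name", "GeneSymbol", "ClinicalSignificance",
                     "Assembly", "ReferenceAlleleVCF", "AlternateAlleleVCF",
                     "PhenotypeList"]

_PROTEIN_RE = re.compile(
    r"\(p\.([A-Z][a-z]{2})(\d+)(?:(=)|([A-Z][a-z]{2}|\*))\)")

_PATHOGENIC_RE = re.compile(r"\bpathogenic\b", re.IGNORECASE)
_BENIGN_RE = re.compile(r"\bbenign\b", re.IGNORECASE)

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class SchemaError(ValueError):
    """The variant table lacks a mandatory column."""


@dataclass(frozen=True)
class VariantRecord:
    """One parsed variant row (post-filter invariants documented in the
    pipeline, not enforced here)."""

    gene: str
    allele_id: str
    rsid: str
    variant_type: str
    assembly: str
    ref_allele: str
    alt_allele: str
    ref_aa: str | None
    aa_pos: int | None
    alt_aa: str | None
    significance_raw: str
    conditions: tuple[str, ...]


@dataclass(frozen=True)
class MrnaChange:
    """A single-base mRNA substitution explaining a protein change."""

    gene: str
    cds_pos: int
    ref_base: str
    alt_base: str
    is_c2u: bool
    ambiguous: bool = False


def parse_variant_summary(path) -> pd.DataFrame:
    """Read a ``variant_summary``-dialect TSV.

    The protein change is parsed out of the HGVS ``Name`` field into
    ``ref_aa`` / ``aa_pos`` / ``alt_aa`` columns (three-letter codes, ``=``
    marking a synonymous record); rows without a recognisable change get
    nulls there.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table is missing mandatory column(s): "
                          f"{missing}")
    if "#AlleleID" in df.columns:
        df = df.rename(columns={"#AlleleID": "AlleleID"})
    if "AlleleID" not in df.columns:
        df["AlleleID"] = np.arange(len(df)).astype(str)

    extracted = df["Name"].str.extract(_PROTEIN_RE)
    df["ref_aa"] = extracted[0]
    df["aa_pos"] = pd.to_numeric(extracted[1], errors="coerce").astype("Int64")
    # "=" (or identical 3-letter codes) means synonymous
    df["alt_aa"] = extracted[3].where(extracted[2].isna(), df["ref_aa"])
    df.loc[df["alt_aa"] == "*", "alt_aa"] = "Ter"
    return df


def filter_variants(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the inclusion filters in order, logging stage counts.

    Stages: single-nucleotide-variant type; GRCh38 assembly; specific
    alleles (single A/C/G/T characters); not like-to-like; a protein change
    present and non-synonymous; duplicate rows for the same allele collapsed
    keeping the first.
    """
    log: dict[str, int] = {"input": len(df)}
    df = df[df["Type"] == "single nucleotide variant"]
    log["snv_type"] = len(df)
    df = df[df["Assembly"] == "GRCh38"]
    log["grch38"] = len(df)
    ok = (df["ReferenceAlleleVCF"].isin(list("ACGT"))
          & df["AlternateAlleleVCF"].isin(list("ACGT")))
    df = df[ok]
    log["specific_alleles"] = len(df)
    df = df[df["ReferenceAlleleVCF"] != df["AlternateAlleleVCF"]]
    log["not_like_to_like"] = len(df)
    has_change = df["ref_aa"].notna() & df["alt_aa"].notna() & df["aa_pos"].notna()
    df = df[has_change & (df["ref_aa"] != df["alt_aa"])]
    log["nonsynonymous_change"] = len(df)
    before = len(df)
    df = df.drop_duplicates(subset="AlleleID", keep="first")
    log["unique_alleles"] = len(df)
    if before != len(df):
        logger.info("collapsed %d duplicate allele rows", before - len(df))
    for stage, count in log.items():
        logger.info("filter %-20s %d rows", stage, count)
    return df.copy(), log


def load_ccds(path) -> dict[str, NucSequence]:
    """Coding sequences keyed by gene symbol.

    ``path`` may be one FASTA file or a directory of them; gene symbols come
    from the last |-field of CCDS-dialect headers (or the whole id).
    """
    from pathlib import Path
    p = Path(path)
    files = sorted(p.glob("*.fa")) + sorted(p.glob("*.fasta")) if p.is_dir() else [p]
    out: dict[str, NucSequence] = {}
    for f in files:
        for seq in read_fasta(f):
            out[gene_of(seq.id)] = seq
    return out


def validate_against_ccds(ref_aa: str, aa_pos: int, cds: NucSequence) -> bool:
    """True iff the coding sequence codes the recorded reference amino acid
    at the recorded position."""
    try:
        return translate(codon_at(cds, int(aa_pos))) == ref_aa
    except IndexError:
        return False


def infer_mrna_change(gene: str, ref_aa: str, aa_pos: int, alt_aa: str,
                      ref_allele: str, alt_allele: str,
                      cds: NucSequence) -> MrnaChange | None:
    """Work out which single-base mRNA substitution explains the protein
    change.

    All single-base substitutions of the reference codon whose translation
    equals the recorded alternate amino acid are enumerated and intersected
    with the genomic ref/alt pair read on both strands (plus: ref->alt;
    minus: complement(ref)->complement(alt)).  A unique survivor yields the
    change; several survivors mark the record ambiguous; none returns None
    (an inconsistent record, dropped by the pipeline).
    """
    codon = codon_at(cds, int(aa_pos))
    r = normalize(ref_allele)
    a = normalize(alt_allele)
    readings = {(r, a), (_COMPLEMENT[r], _COMPLEMENT[a])}
    survivors = []
    for i in range(3):
        for b in "ACGU":
            if b == codon.bases[i]:
                continue
            mutated = codon.bases[:i] + b + codon.bases[i + 1:]
            if translate(mutated) != alt_aa:
                continue
            if (codon.bases[i], b) in readings:
                survivors.append((i, codon.bases[i], b))
    if not survivors:
        return None
    if len(set(survivors)) > 1:
        i, rb, ab = survivors[0]
        return MrnaChange(gene=gene, cds_pos=3 * (int(aa_pos) - 1) + i + 1,
                          ref_base=rb, alt_base=ab,
                          is_c2u=(rb == "C" and ab == "U"), ambiguous=True)
    i, rb, ab = survivors[0]
    return MrnaChange(gene=gene, cds_pos=3 * (int(aa_pos) - 1) + i + 1,
                      ref_base=rb, alt_base=ab,
                      is_c2u=(rb == "C" and ab == "U"))


def bin_significance(tag: str) -> str:
    """Three-way collapse of a clinical-significance string.

    Case-insensitive whole-word match: "pathogenic" wins, else "benign",
    else unspecified.  Word boundaries keep e.g. "Conflicting
    interpretations of pathogenicity" out of the pathogenic bin.
    """
    if _PATHOGENIC_RE.search(tag):
        return "pathogenic"
    if _BENIGN_RE.search(tag):
        return "benign"
    return "unspecified"


def predict_c2u_sites(changes: list[MrnaChange], ccds: dict[str, NucSequence],
                      model: str = "union", rf_model=None,
                      rules_cfg: rules.RulesConfig = rules.DEFAULT_CONFIG,
                      ) -> list[SitePrediction]:
    """Score every C>U site with the editing-site predictors.

    ``model`` selects which call the pipeline treats as "predicted":
    ``rules``, ``rf``, ``union`` or ``intersection``.  A fitted forest is
    required for any mode involving the random forest.
    """
    if model not in ("rules", "rf", "union", "intersection"):
        raise ValueError(f"unknown model {model!r}")
    needs_rf = model in ("rf", "union", "intersection")
    if needs_rf and rf_model is None:
        raise ValueError(f"model {model!r} needs a trained random forest")
    preds = []
    windows = []
    metas = []
    for ch in changes:
        if not ch.is_c2u or ch.ambiguous:
            continue
        cds = ccds[ch.gene]
        if cds.residues[ch.cds_pos - 1] != "C":
            raise ValueError(f"{ch.gene}:{ch.cds_pos} is not a C in the "
                             "coding sequence")
        w = extract_window(cds, ch.cds_pos, gene=ch.gene)
        windows.append(w)
        metas.append(ch)
    probs = (ml.predict_prob_many(rf_model, windows)
             if needs_rf and windows else np.zeros(len(windows)))
    for w, ch, p in zip(windows, metas, probs):
        rs = rules.rules_score(w, rules_cfg)
        preds.append(SitePrediction(
            gene=ch.gene, c_pos=ch.cds_pos,
            rules_score=rs.total, rules_call=rules.rules_classify(rs),
            rf_prob=float(p), rf_call=ml.ml_classify(float(p)),
        ))
    return preds


def _model_call(pred: SitePrediction, model: str) -> bool:
    return {"rules": pred.rules_call, "rf": pred.rf_call,
            "union": pred.union_call,
            "intersection": pred.intersection_call}[model]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one digit), matching how
    the summary percentages are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_BINS = ("pathogenic", "benign", "unspecified")


def _set_summary(bins: pd.Series) -> dict:
    n = int(len(bins))
    out: dict = {"n": n}
    for b in _BINS:
        nb = int((bins == b).sum())
        out[b] = {"n": nb,
                  "pct": round_half_up(100.0 * nb / n) if n else None}
    return out


def summarize(df: pd.DataFrame) -> dict:
    """Proportions over the nested exonic / C>U / predicted sets.

    ``df`` needs columns ``bin`` (pathogenic/benign/unspecified), ``is_c2u``
    and ``predicted`` (booleans).  Percentages are recomputed from counts
    and rounded half-up to one decimal; empty sets report None.
    """
    c2u = df[df["is_c2u"]]
    pred = df[df["predicted"]]
    out = {
        "exonic": _set_summary(df["bin"]),
        "c2u": _set_summary(c2u["bin"]),
        "predicted": _set_summary(pred["bin"]),
    }
    out["c2u"]["pct_of_exonic"] = (
        round_half_up(100.0 * len(c2u) / len(df)) if len(df) else None)
    out["predicted"]["pct_of_c2u"] = (
        round_half_up(100.0 * len(pred) / len(c2u)) if len(c2u) else None)
    within = {}
    for b in _BINS:
        nb = int((c2u["bin"] == b).sum())
        npb = int((pred["bin"] == b).sum())
        within[b] = round_half_up(100.0 * npb / nb) if nb else None
    out["predicted"]["pct_within_bin"] = within
    return out


def run_pipeline(variants_path, ccds_path, model: str = "union",
                 rf_model=None,
                 rules_cfg: rules.RulesConfig = rules.DEFAULT_CONFIG,
                 ) -> dict:
    """End-to-end run: parse, filter, validate, infer, predict, summarize.

    Returns a dict with the annotated exonic table (``table``), per-site
    predictions (``predictions``), the stage-count ``filter_log`` and the
    ``summary`` proportions.
    """
    raw = parse_variant_summary(variants_path)
    df, log = filter_variants(raw)
    ccds = load_ccds(ccds_path)

    known = df["GeneSymbol"].isin(ccds.keys())
    n_missing = int((~known).sum())
    if n_missing:
        missing_genes = sorted(df.loc[~known, "GeneSymbol"].unique())
        logger.info("excluding %d variants in %d genes without a usable "
                    "coding sequence (e.g. %s)", n_missing,
                    len(missing_genes), missing_genes[:3])
    df = df[known].copy()
    log["with_ccds"] = len(df)

    keep = []
    changes: list[MrnaChange | None] = []
    n_invalid = n_inconsistent = n_ambiguous = 0
    for row in df.itertuples(index=False):
        cds = ccds[row.GeneSymbol]
        if not validate_against_ccds(row.ref_aa, row.aa_pos, cds):
            n_invalid += 1
            keep.append(False)
            changes.append(None)
            continue
        ch = infer_mrna_change(row.GeneSymbol, row.ref_aa, int(row.aa_pos),
                               row.alt_aa, row.ReferenceAlleleVCF,
                               row.AlternateAlleleVCF, cds)
        if ch is None:
            n_inconsistent += 1
            keep.append(False)
            changes.append(None)
            continue
        if ch.ambiguous:
            n_ambiguous += 1
        keep.append(True)
        changes.append(ch)
    if n_invalid:
        logger.info("excluded %d records whose reference amino acid "
                    "mismatches the coding sequence", n_invalid)
    if n_inconsistent:
        logger.info("excluded %d records with no consistent single-base "
                    "substitution", n_inconsistent)
    if n_ambiguous:
        logger.info("%d records had multiple consistent substitutions; "
                    "excluded from the C>U set", n_ambiguous)
    df = df[np.asarray(keep, dtype=bool)].copy()
    good = [c for c in changes if c is not None]
    log["validated"] = len(df)

    df["cds_pos"] = [c.cds_pos for c in good]
    df["is_c2u"] = [c.is_c2u and not c.ambiguous for c in good]
    df["bin"] = df["ClinicalSignificance"].map(bin_significance)

    preds = predict_c2u_sites(good, ccds, model=model, rf_model=rf_model,
                              rules_cfg=rules_cfg)
    called = {(p.gene, p.c_pos) for p in preds if _model_call(p, model)}
    df["predicted"] = [
        bool(c2u) and (g, pos) in called
        for g, pos, c2u in zip(df["GeneSymbol"], df["cds_pos"], df["is_c2u"])
    ]
    return {
        "table": df,
        "predictions": preds,
        "filter_log": log,
        "summary": summarize(df),
    }
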