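"""Seeded synthetic inputs for every stage of the package.

Three generators live here:

* **Planted-motif sites** (:func:`make_site`, :func:`make_benchmark`):
  positive sites are cytosines at the terminus of a 3-4 nt loop closed by a
  GC-rich stem, optionally with a uracil planted in the loop -- the substrate
  APOBEC3A/G prefer.  Negatives are background sequence around a cytosine,
  optionally rejection-sampled until the rules scorer stays below its call
  threshold.  Class ratio is configurable from the balanced 1:3 testing shape
  up to the realistic 1:468 prevalence.

* **ClinVar-style variant tables** (:func:`make_variant_table`): a
  ``variant_summary``-dialect TSV plus matching coding sequences constructed
  so that the variant pipeline's filters, codon validation, C>U inference and
  editing-site scan reproduce the marginal counts of a
  :class:`VariantTableSpec` exactly.  Decoy rows (non-SNV, GRCh37,
  like-to-like, non-specific alleles, missing/synonymous protein change,
  genes without coding sequence, duplicate alleles) exercise every filter.

* **A toy MeSH-like hierarchy** (:func:`make_mesh_fixture`) with known
  top/third-level structure and a condition-to-term mapping table.

Background composition is uniform (25% per base).  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rules
from .ml import LabeledSite
from .benchmark import BenchmarkSet
from .seqio import (DOWNSTREAM_LEN, UPSTREAM_LEN, NucSequence, SiteWindow,
                    extract_window)

__all__ = [
    "MotifParams",
    "VariantTableSpec",
    "make_site",
    "make_benchmark",
    "make_variant_table",
    "make_mesh_fixture",
    "PAPER_SCALE_SPEC",
    "REDUCED_SCALE_SPEC",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))
_REJECTION_CAP = 50


@dataclass(frozen=True)
class MotifParams:
    """Shape of the planted editing-site motif.

    Defaults emulate the curated substrate: a 5-pair stem at 80% G:C
    closing a triloop with a planted uracil, the scored C at the loop 3'
    end, embedded in uniform background.  Negatives are rejection-sampled
    below the rules call threshold so labels and structure agree.
    """

    stem_len: int = 5
    gc_fraction: float = 0.8
    loop_len: int = 3
    plant_u_in_loop: bool = True
    background_gc: float = 0.5
    reject_high_score_negatives: bool = True
    loop_terminus: rules.LoopTerminus = rules.LoopTerminus.THREE_PRIME

    def __post_init__(self) -> None:
        if self.stem_len < 3:
            raise ValueError("stem_len must be >= 3")
        if self.loop_len not in (3, 4):
            raise ValueError("loop_len must be 3 or 4")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[idx])


def _hairpin(params: MotifParams, rng: np.random.Generator) -> tuple[str, int]:
    """A stem-loop with the C at the configured loop terminus.

    Returns (sequence, 0-based index of the scored C within it).
    """
    arm5 = []
    arm3 = []
    for _ in range(params.stem_len):
        if rng.random() < params.gc_fraction:
            b5, b3 = ("G", "C") if rng.random() < 0.5 else ("C", "G")
        else:
            b5, b3 = ("A", "U") if rng.random() < 0.5 else ("U", "A")
        # pairs are generated from the loop outward: prepend on the 5' arm,
        # append on the 3' arm, so arm5[-1] pairs arm3[0]
        arm5.insert(0, b5)
        arm3.append(b3)
    n_free = params.loop_len - 1
    free = list(rng.choice(["A", "C", "U"], size=n_free))
    if params.plant_u_in_loop and "U" not in free:
        free[int(rng.integers(0, n_free))] = "U"
    if params.loop_terminus is rules.LoopTerminus.THREE_PRIME:
        loop = "".join(free) + "C"
        c_in_loop = n_free
    else:
        loop = "C" + "".join(free)
        c_in_loop = 0
    seq = "".join(arm5) + loop + "".join(arm3)
    return seq, params.stem_len + c_in_loop


def make_site(label: int, params: MotifParams, rng: np.random.Generator,
              gene: str = "synthetic") -> tuple[LabeledSite, NucSequence]:
    """One labeled site embedded in a 26-nt sequence (C at position 16).

    Positives carry the planted hairpin with the C at the loop terminus;
    negatives are background around a C, re-drawn (up to a cap) until the
    rules scorer stays at or below its threshold when rejection is on.
    """
    cfg = rules.RulesConfig(loop_terminus=params.loop_terminus)
    total_len = UPSTREAM_LEN + 1 + DOWNSTREAM_LEN
    if label == 1:
        hp, c_idx = _hairpin(params, rng)
        left = UPSTREAM_LEN - c_idx
        right = total_len - left - len(hp)
        if left < 0 or right < 0:
            raise ValueError("motif too large for the site window")
        seq = (_random_bases(rng, left, params.background_gc) + hp
               + _random_bases(rng, right, params.background_gc))
    else:
        for attempt in range(_REJECTION_CAP):
            seq = (_random_bases(rng, UPSTREAM_LEN, params.background_gc)
                   + "C"
                   + _random_bases(rng, DOWNSTREAM_LEN, params.background_gc))
            if not params.reject_high_score_negatives:
                break
            nseq = NucSequence(id=gene, residues=seq)
            w = extract_window(nseq, UPSTREAM_LEN + 1, gene=gene)
            if not rules.rules_classify(rules.rules_score(w, cfg)):
                break
        else:
            logger.warning("negative rejection cap (%d) exceeded for %s; "
                           "emitting last draw", _REJECTION_CAP, gene)
    nseq = NucSequence(id=gene, residues=seq)
    window = extract_window(nseq, UPSTREAM_LEN + 1, gene=gene)
    return LabeledSite(window=window, label=label, provenance="synthetic"), nseq


def make_benchmark(n_pos: int, ratio: int, params: MotifParams,
                   seed: int = 0) -> tuple[BenchmarkSet, list[NucSequence]]:
    """``n_pos`` positives plus ``ratio * n_pos`` negatives, shuffled.

    ``ratio=3`` gives the testing-set shape, ``ratio=468`` the proportional
    (realistic-prevalence) shape with prevalence 1/469.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    rng = np.random.default_rng(seed)
    sites: list[LabeledSite] = []
    seqs: list[NucSequence] = []
    # seed is part of the gene id so sites from different draws never share
    # a (gene, position) identity
    for i in range(n_pos):
        s, q = make_site(1, params, rng, gene=f"S{seed}POS{i:06d}")
        sites.append(s)
        seqs.append(q)
    for i in range(ratio * n_pos):
        s, q = make_site(0, params, rng, gene=f"S{seed}NEG{i:06d}")
        sites.append(s)
        seqs.append(q)
    order = rng.permutation(len(sites))
    return (BenchmarkSet(sites=tuple(sites[i] for i in order),
                         ratio=float(ratio), name=f"synthetic_1to{ratio}"),
            [seqs[i] for i in order])


# --------------------------------------------------------------------------
# ClinVar-style variant tables
# --------------------------------------------------------------------------

#: hairpin planted at predicted C>U sites: 6-pair stem (5 G:C + 1 A:U),
#: loop UUC with the C at its 3' end; rules total 16 + 2 = 18, so the site
#: is called regardless of flanking background
_PLANT_HAIRPIN = "GGGGUCUUCGACCCC"
_PLANT_C_IDX = 8  # 0-based C position within _PLANT_HAIRPIN

_SLOT_CODONS = 20
_SLOT_LEN = 3 * _SLOT_CODONS
_VAR_CODON = 10  # 0-based codon index of the variant codon within its slot

_SIG_STRINGS = {
    "pathogenic": ["Pathogenic", "Likely pathogenic",
                   "Pathogenic/Likely pathogenic"],
    "benign": ["Benign", "Likely benign", "Benign/Likely benign"],
    "unspecified": ["Uncertain significance", "not provided",
                    "Conflicting interpretations of pathogenicity"],
}


@dataclass(frozen=True)
class VariantTableSpec:
    """Marginal counts the generated table must reproduce downstream.

    ``n_exonic`` counts retained exonic non-synonymous SNPs; the C>U subset
    splits into pathogenicity bins, and the predicted subset (sites the
    rules scorer calls) splits likewise, nested inside the C>U bins.
    ``minus_strand_fraction`` of non-predicted C>U rows are written as
    minus-strand genes (genomic G>A carrying an mRNA C>U).
    """

    n_exonic: int
    n_c2u: int
    n_pathogenic: int
    n_benign: int
    n_unspecified: int
    n_predicted: int
    n_predicted_pathogenic: int
    n_predicted_benign: int
    n_predicted_unspecified: int
    n_genes: int = 20
    minus_strand_fraction: float = 0.3
    conditions: tuple[tuple[str, int], ...] = ()
    include_decoys: bool = True

    def __post_init__(self) -> None:
        if self.n_c2u > self.n_exonic:
            raise ValueError("n_c2u cannot exceed n_exonic")
        if self.n_pathogenic + self.n_benign + self.n_unspecified != self.n_c2u:
            raise ValueError("C>U pathogenicity bins must sum to n_c2u")
        pred_sum = (self.n_predicted_pathogenic + self.n_predicted_benign
                    + self.n_predicted_unspecified)
        if pred_sum != self.n_predicted:
            raise ValueError("predicted bins must sum to n_predicted")
        for pred, parent, name in [
            (self.n_predicted_pathogenic, self.n_pathogenic, "pathogenic"),
            (self.n_predicted_benign, self.n_benign, "benign"),
            (self.n_predicted_unspecified, self.n_unspecified, "unspecified"),
        ]:
            if pred > parent:
                raise ValueError(f"predicted {name} exceeds C>U {name}")
        total_cond = sum(c for _, c in self.conditions)
        if total_cond and total_cond > 0 and self.n_c2u == 0:
            raise ValueError("conditions given but no C>U variants")


#: the printed-scale study: 617,363 exonic SNPs, 101,565 C>U
#: (19,285 / 9,459 / 72,821 pathogenic / benign / unspecified), 4,600
#: predicted (1,046 / 422 / 3,132)
PAPER_SCALE_SPEC = VariantTableSpec(
    n_exonic=617_363,
    n_c2u=101_565,
    n_pathogenic=19_285,
    n_benign=9_459,
    n_unspecified=72_821,
    n_predicted=4_600,
    n_predicted_pathogenic=1_046,
    n_predicted_benign=422,
    n_predicted_unspecified=3_132,
    n_genes=120,
)

#: the smallest solved spec whose half-up rounded percentages equal the
#: printed-scale ones at every reported figure
REDUCED_SCALE_SPEC = VariantTableSpec(
    n_exonic=121_212,
    n_c2u=20_000,
    n_pathogenic=3_800,
    n_benign=1_860,
    n_unspecified=14_340,
    n_predicted=900,
    n_predicted_pathogenic=204,
    n_predicted_benign=83,
    n_predicted_unspecified=613,
    n_genes=60,
)

_COLUMNS = ["#AlleleID", "Type", "Name", "GeneSymbol", "ClinicalSignificance",
            "RS# (dbSNP)", "PhenotypeList", "Assembly",
            "ReferenceAlleleVCF", "AlternateAlleleVCF"]


def _variant_kinds(spec: VariantTableSpec, rng: np.random.Generator):
    """Per-variant plan: (kind, bin) rows; kind in
    {predicted, c2u_plus, c2u_minus, background}."""
    plan: list[tuple[str, str]] = []
    for bin_name, n_pred, n_tot in [
        ("pathogenic", spec.n_predicted_pathogenic, spec.n_pathogenic),
        ("benign", spec.n_predicted_benign, spec.n_benign),
        ("unspecified", spec.n_predicted_unspecified, spec.n_unspecified),
    ]:
        plan.extend([("predicted", bin_name)] * n_pred)
        n_rest = n_tot - n_pred
        n_minus = int(round(spec.minus_strand_fraction * n_rest))
        plan.extend([("c2u_minus", bin_name)] * n_minus)
        plan.extend([("c2u_plus", bin_name)] * (n_rest - n_minus))
    plan.extend([("background", "unspecified")] * (spec.n_exonic - spec.n_c2u))
    order = rng.permutation(len(plan))
    return [plan[i] for i in order]


def _window_at(seq_arr: np.ndarray, c_idx: int) -> SiteWindow:
    up = "".join(seq_arr[c_idx - UPSTREAM_LEN:c_idx])
    down = "".join(seq_arr[c_idx + 1:c_idx + 1 + DOWNSTREAM_LEN])
    return SiteWindow(gene="fixture", c_pos=c_idx + 1,
                      upstream=up, downstream=down)


def make_variant_table(spec: VariantTableSpec, seed: int, out_dir) -> dict:
    """Write a ClinVar-dialect variant TSV and matching CCDS-style FASTA.

    Each retained variant occupies its own 20-codon slot of a synthetic
    gene, so site windows never interact.  Rules-predicted C>U variants get
    a strong planted hairpin around the edited C; the rest are
    rejection-sampled below the call threshold.  Returns a manifest dict
    (also written as JSON) with the file paths and expected downstream
    counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plan = _variant_kinds(spec, rng)

    n = len(plan)
    genes = [f"SYNG{g:04d}" for g in range(spec.n_genes)]
    slot_of = np.arange(n) // spec.n_genes  # slot index within its gene
    gene_of_var = np.arange(n) % spec.n_genes
    slots_per_gene = np.bincount(gene_of_var, minlength=spec.n_genes)

    cfg = rules.DEFAULT_CONFIG
    gene_seqs: dict[str, np.ndarray] = {}
    for g, gname in enumerate(genes):
        glen = int(slots_per_gene[g]) * _SLOT_LEN
        if glen == 0:
            glen = _SLOT_LEN  # keep every declared gene non-empty
        gene_seqs[gname] = _BASES[rng.integers(0, 4, size=glen)].copy()

    condition_pool: list[str] = []
    for cond, count in spec.conditions:
        condition_pool.extend([cond] * count)

    sig_cyclers = {b: 0 for b in _SIG_STRINGS}

    rows = []
    cond_i = 0
    for i, (kind, bin_name) in enumerate(plan):
        gname = genes[gene_of_var[i]]
        arr = gene_seqs[gname]
        slot0 = int(slot_of[i]) * _SLOT_LEN
        codon0 = slot0 + 3 * _VAR_CODON  # first nt of the variant codon
        aa_pos = codon0 // 3 + 1

        if kind == "predicted":
            # plant the hairpin so its C is the codon's first base (CGA)
            start = codon0 - _PLANT_C_IDX
            arr[start:start + len(_PLANT_HAIRPIN)] = list(_PLANT_HAIRPIN)
            c_idx = codon0
            cds_pos = codon0 + 1
            ref_aa, alt_aa = "Arg", "Ter"
            ref, alt = "C", "T"
            cds_ref, cds_alt = "C", "T"
        elif kind == "c2u_plus":
            # ACG (Thr) -> AUG (Met), edited C at codon position 2
            arr[codon0:codon0 + 3] = list("ACG")
            c_idx = codon0 + 1
            cds_pos = codon0 + 2
            ref_aa, alt_aa = "Thr", "Met"
            ref, alt = "C", "T"
            cds_ref, cds_alt = "C", "T"
        elif kind == "c2u_minus":
            # CAA (Gln) -> UAA (Ter); genomic record is the minus strand G>A
            arr[codon0:codon0 + 3] = list("CAA")
            c_idx = codon0
            cds_pos = codon0 + 1
            ref_aa, alt_aa = "Gln", "Ter"
            ref, alt = "G", "A"
            cds_ref, cds_alt = "C", "T"
        else:
            # GAA (Glu) -> AAA (Lys): exonic but not C>U on the mRNA
            arr[codon0:codon0 + 3] = list("GAA")
            c_idx = None
            cds_pos = codon0 + 1
            ref_aa, alt_aa = "Glu", "Lys"
            ref, alt = "G", "A"
            cds_ref, cds_alt = "G", "A"

        if kind in ("c2u_plus", "c2u_minus"):
            # re-draw the slot background until the site is rules-negative
            fixed = set(range(codon0, codon0 + 3))
            for attempt in range(_REJECTION_CAP):
                w = _window_at(arr, c_idx)
                if not rules.rules_classify(rules.rules_score(w, cfg)):
                    break
                for j in range(slot0, slot0 + _SLOT_LEN):
                    if j not in fixed:
                        arr[j] = _BASES[rng.integers(0, 4)]
            else:
                logger.warning("rejection cap exceeded for %s slot %d",
                               gname, slot_of[i])

        sig_list = _SIG_STRINGS[bin_name]
        sig = sig_list[sig_cyclers[bin_name] % len(sig_list)]
        sig_cyclers[bin_name] += 1

        phenotype = "not provided"
        if kind != "background" and cond_i < len(condition_pool):
            phenotype = condition_pool[cond_i]
            cond_i += 1

        rows.append({
            "#AlleleID": 100000 + i,
            "Type": "single nucleotide variant",
            "Name": (f"NM_{gene_of_var[i]:06d}.1({gname}):c.{cds_pos}"
                     f"{cds_ref}>{cds_alt} (p.{ref_aa}{aa_pos}{alt_aa})"),
            "GeneSymbol": gname,
            "ClinicalSignificance": sig,
            "RS# (dbSNP)": 5_000_000 + i,
            "PhenotypeList": phenotype,
            "Assembly": "GRCh38",
            "ReferenceAlleleVCF": ref,
            "AlternateAlleleVCF": alt,
        })

    n_decoys = 0
    if spec.include_decoys:
        decoys = []
        # GRCh37 companion records for a sample of retained rows
        for r in rows[:min(25, len(rows))]:
            d = dict(r)
            d["Assembly"] = "GRCh37"
            decoys.append(d)
        base = dict(rows[0])

        def decoy(**kw):
            d = dict(base)
            d["#AlleleID"] = 900000 + len(decoys)
            d.update(kw)
            decoys.append(d)

        decoy(Type="Deletion", Name="NM_000001.1(SYNG0000):c.5del")
        decoy(ReferenceAlleleVCF="A", AlternateAlleleVCF="A")
        decoy(ReferenceAlleleVCF="A", AlternateAlleleVCF="X")
        decoy(Name=f"NM_000001.1({base['GeneSymbol']}):c.77G>A")  # no p. change
        decoy(Name=f"NM_000001.1({base['GeneSymbol']}):c.78G>A (p.Leu26Leu)")
        decoy(GeneSymbol="NOCDSGENE",
              Name="NM_999999.1(NOCDSGENE):c.3G>A (p.Glu1Lys)")
        # duplicate submission for an existing allele id
        dup = dict(rows[1])
        decoys.append(dup)
        rows.extend(decoys)
        n_decoys = len(decoys)

    df = pd.DataFrame(rows, columns=_COLUMNS)
    variants_path = out_dir / "variant_summary.tsv"
    df.to_csv(variants_path, sep="\t", index=False)

    fasta_path = out_dir / "ccds.fa"
    with open(fasta_path, "w") as fh:
        for g, gname in enumerate(genes):
            dna = "".join(gene_seqs[gname]).replace("U", "T")
            fh.write(f">CCDS{g + 1}.1|Hs38|{gname}\n")
            for k in range(0, len(dna), 70):
                fh.write(dna[k:k + 70] + "\n")

    manifest = {
        "variants": str(variants_path),
        "ccds": str(fasta_path),
        "seed": seed,
        "n_rows_written": len(rows),
        "n_decoys": n_decoys,
        "prediction_model": "rules",
        "expected": {
            "n_exonic": spec.n_exonic,
            "n_c2u": spec.n_c2u,
            "c2u_bins": {"pathogenic": spec.n_pathogenic,
                         "benign": spec.n_benign,
                         "unspecified": spec.n_unspecified},
            "n_predicted": spec.n_predicted,
            "predicted_bins": {"pathogenic": spec.n_predicted_pathogenic,
                               "benign": spec.n_predicted_benign,
                               "unspecified": spec.n_predicted_unspecified},
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --------------------------------------------------------------------------
# Toy MeSH-like hierarchy
# --------------------------------------------------------------------------

def make_mesh_fixture(depth: int = 3, branching: int = 2,
                      n_conditions: int = 12, seed: int = 0,
                      unmapped_fraction: float = 0.2) -> dict:
    """A complete ``branching``-ary hierarchy of the given depth plus a
    condition-to-term mapping table.

    Terms carry dotted tree numbers (top level ``C01`` .. ``C0b``); each
    deeper level appends ``.NNN``.  Conditions are mapped cyclically onto
    the deepest terms, with a fraction left unmapped (they resolve to the
    reserved "Not found" pseudo-heading).  Returns DataFrames under keys
    ``hierarchy`` and ``mapping``.
    """
    if depth < 3:
        raise ValueError("depth must be >= 3")
    rng = np.random.default_rng(seed)
    terms = []  # (term_id, name, tree_number)
    counter = 1

    def grow(prefix: str, level: int):
        nonlocal counter
        for j in range(branching):
            tn = (f"C{j + 1:02d}" if level == 1
                  else f"{prefix}.{100 * (j + 1):03d}")
            terms.append((f"D{counter:06d}", f"term level{level} {tn}", tn))
            counter += 1
            if level < depth:
                grow(tn, level + 1)

    grow("", 1)
    hierarchy = pd.DataFrame(terms, columns=["term_id", "name", "tree_numbers"])

    leaves = [t for t in terms if t[2].count(".") == depth - 1]
    mapping_rows = []
    for i in range(n_conditions):
        cond = f"condition {i:04d}"
        if rng.random() < unmapped_fraction:
            mapping_rows.append((cond, "Not found", ""))
        else:
            term_id = leaves[i % len(leaves)][0]
            mapping_rows.append((cond, term_id, ""))
    mapping = pd.DataFrame(mapping_rows,
                           columns=["condition", "term_id", "qualifier"])
    return {"hierarchy": hierarchy, "mapping": mapping}
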