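"""Sequence input and per-cytosine window extraction.

Coding sequences (CCDS-style FASTA) are read with Biopython and normalized to
the RNA alphabet ``{A, C, G, U}``.  All positions reported by this package are
1-based on the coding sequence, matching HGVS ``c.`` numbering.

The unit consumed by both editing-site predictors is the :class:`SiteWindow`:
a cytosine with 15 nucleotides of upstream and 10 nucleotides of downstream
context.  Windows that run off a sequence end are padded with ``U`` (the
neutral residue: it encodes as all-zero bits in the classifier feature map)
and flagged so callers can exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import standard_rna_table

__all__ = [
    "NucSequence",
    "SiteWindow",
    "Codon",
    "UPSTREAM_LEN",
    "DOWNSTREAM_LEN",
    "read_fasta",
    "normalize",
    "extract_window",
    "iter_cytosines",
    "codon_at",
    "translate",
    "SequenceError",
    "NotACytosineError",
]

logger = logging.getLogger(__name__)

#: context taken on each side of the scored cytosine
UPSTREAM_LEN = 15
DOWNSTREAM_LEN = 10

_RNA_ALPHABET = frozenset("ACGU")

#: three-letter amino-acid codes keyed by one-letter code; stop is "Ter"
_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}
AA1_TO_AA3 = dict(_AA3)
AA3_TO_AA1 = {v: k for k, v in _AA3.items()}

_CODON_TABLE: dict[str, str] = dict(standard_rna_table.forward_table)
for _stop in standard_rna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


class SequenceError(ValueError):
    """Malformed or unusable sequence input."""


class NotACytosineError(SequenceError):
    """A window was requested at a position that does not hold a C."""


@dataclass(frozen=True)
class NucSequence:
    """An RNA-normalized nucleotide sequence.

    ``residues`` is uppercase over ``{A, C, G, U}``; DNA input has had T
    mapped to U on read, recorded in ``source_alphabet``.
    """

    id: str
    residues: str
    source_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-ACGU residues after "
                f"normalization: {sorted(bad)} (ambiguity codes are rejected)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteWindow:
    """A cytosine and its sequence context.

    ``upstream`` is exactly 15 nt (5'->3', immediately preceding the C) and
    ``downstream`` exactly 10 nt (immediately following), padded with U where
    the source sequence ends inside the window.  ``n_pad_up``/``n_pad_down``
    record how many leading/trailing residues are padding; ``padded`` is true
    if either is nonzero.
    """

    gene: str
    c_pos: int  # 1-based position of the C in the coding sequence
    upstream: str
    downstream: str
    n_pad_up: int = 0
    n_pad_down: int = 0

    def __post_init__(self) -> None:
        if len(self.upstream) != UPSTREAM_LEN:
            raise SequenceError(
                f"upstream must be {UPSTREAM_LEN} nt, got {len(self.upstream)}"
            )
        if len(self.downstream) != DOWNSTREAM_LEN:
            raise SequenceError(
                f"downstream must be {DOWNSTREAM_LEN} nt, got {len(self.downstream)}"
            )

    @property
    def padded(self) -> bool:
        return self.n_pad_up > 0 or self.n_pad_down > 0

    @property
    def sequence(self) -> str:
        """The full 26-nt window, C included."""
        return self.upstream + "C" + self.downstream

    @property
    def context25(self) -> str:
        """The 25 context nucleotides (C excluded) used by the classifier
        and by the pairwise identity audit."""
        return self.upstream + self.downstream

    def residue(self, offset: int) -> str | None:
        """Residue at a C-relative offset (negative = upstream, positive =
        downstream, 0 = the C).  Returns None outside the window or where
        the window is padding rather than real sequence."""
        if offset == 0:
            return "C"
        if offset < 0:
            idx = UPSTREAM_LEN + offset
            if idx < self.n_pad_up or idx < 0:
                return None
            return self.upstream[idx]
        idx = offset - 1
        if idx >= DOWNSTREAM_LEN - self.n_pad_down or idx >= DOWNSTREAM_LEN:
            return None
        return self.downstream[idx]


@dataclass(frozen=True)
class Codon:
    """One codon of a coding sequence, 1-based amino-acid index."""

    bases: str
    aa_index: int

    def __post_init__(self) -> None:
        if len(self.bases) != 3 or set(self.bases) - _RNA_ALPHABET:
            raise SequenceError(f"invalid codon {self.bases!r}")
        if self.aa_index < 1:
            raise SequenceError("aa_index must be >= 1")


def normalize(residues: str) -> str:
    """Uppercase and map DNA T to RNA U.  Idempotent; length-preserving."""
    return residues.upper().replace("T", "U")


def read_fasta(path) -> list[NucSequence]:
    """Read a FASTA file into RNA-normalized sequences.

    Record ids are taken from the header up to the first whitespace (the full
    token, so CCDS-dialect ids like ``CCDS30547.1|Hs110|SAMD11`` survive
    intact).  DNA T is converted to U; ambiguity codes are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise SequenceError(f"record {rec.id!r} has a header but no sequence")
        alphabet = "DNA" if ("T" in raw.upper() or "t" in raw) else "RNA"
        records.append(NucSequence(id=rec.id, residues=normalize(raw),
                                   source_alphabet=alphabet))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def gene_of(seq_id: str) -> str:
    """Gene symbol from a FASTA id: last |-separated field of a CCDS-dialect
    header, else the id itself."""
    return seq_id.rsplit("|", 1)[-1] if "|" in seq_id else seq_id


def extract_window(seq: NucSequence, c_pos: int, gene: str | None = None) -> SiteWindow:
    """Extract the 15+1+10 window around the cytosine at ``c_pos`` (1-based).

    Sides truncated by the sequence ends are padded with U and flagged.
    Raises :class:`NotACytosineError` if the residue there is not C, and an
    IndexError for out-of-range positions.
    """
    if not 1 <= c_pos <= len(seq):
        raise IndexError(f"position {c_pos} outside sequence {seq.id!r} "
                         f"(length {len(seq)})")
    if seq.residues[c_pos - 1] != "C":
        raise NotACytosineError(
            f"residue at {seq.id}:{c_pos} is {seq.residues[c_pos - 1]}, not C"
        )
    up_start = max(0, c_pos - 1 - UPSTREAM_LEN)
    up = seq.residues[up_start:c_pos - 1]
    down = seq.residues[c_pos:c_pos + DOWNSTREAM_LEN]
    n_pad_up = UPSTREAM_LEN - len(up)
    n_pad_down = DOWNSTREAM_LEN - len(down)
    return SiteWindow(
        gene=gene if gene is not None else gene_of(seq.id),
        c_pos=c_pos,
        upstream="U" * n_pad_up + up,
        downstream=down + "U" * n_pad_down,
        n_pad_up=n_pad_up,
        n_pad_down=n_pad_down,
    )


def iter_cytosines(seq: NucSequence):
    """Yield a SiteWindow for every C in the sequence."""
    for i, base in enumerate(seq.residues, start=1):
        if base == "C":
            yield extract_window(seq, i)


def codon_at(seq: NucSequence, aa_index: int) -> Codon:
    """The codon coding for amino acid ``aa_index`` (1-based)."""
    if aa_index < 1:
        raise IndexError("aa_index must be >= 1")
    start = 3 * (aa_index - 1)
    if start + 3 > len(seq):
        raise IndexError(
            f"aa_index {aa_index} beyond sequence {seq.id!r} ({len(seq)} nt)"
        )
    if len(seq) % 3 != 0:
        logger.warning("sequence %s length %d not divisible by 3; trailing "
                       "bases ignored", seq.id, len(seq))
    return Codon(bases=seq.residues[start:start + 3], aa_index=aa_index)


def translate(codon: Codon | str) -> str:
    """Three-letter amino-acid code of a codon under the standard genetic
    code; stop codons translate to ``Ter``."""
    bases = codon.bases if isinstance(codon, Codon) else normalize(codon)
    try:
        one = _CODON_TABLE[bases]
    except KeyError:
        raise SequenceError(f"cannot translate codon {bases!r}") from None
    return _AA3[one]
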