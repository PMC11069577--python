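"""Rules-based stem-loop scorer for APOBEC3A/G C-to-U editing sites.

APOBEC3A and APOBEC3G preferentially deaminate cytosines presented at the
terminus of the loop of an RNA hairpin: a 3-4 nt loop closed by a base-paired
stem.  This module detects qualifying hairpins around a candidate cytosine
and scores them:

    stem points  = 3 * (# G:C pairs) + 1 * (# A:U pairs)
    bonus        = +2 if a uracil occurs in the loop OR the residue
                    immediately 5' of the C is a purine (awarded once)
                   -2 if a guanine occurs in the loop
    total        = stem points + bonus

A site is called an editing site when its best total is strictly greater
than 9 (equivalently, a score threshold of >= 10 on integer totals).

The scored cytosine sits at a fixed terminus of the loop.  The literature
describes the substrate with the C at the loop 3' end, which is the default
convention here; the 5'-end convention is also implemented
(:class:`LoopTerminus`).  One stem imperfection -- a mismatched pair or a
one-nucleotide bulge on either arm -- is tolerated at the position two
nucleotides 5' of the scored cytosine, counted along the primary sequence.
Under the 3'-end convention that position lies inside the loop, so the
allowance only takes effect under the 5'-end convention.

G:U wobble pairs are not scored and terminate stem extension, as the scoring
formula recognises only G:C and A:U pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .seqio import SiteWindow

__all__ = [
    "LoopTerminus",
    "RulesConfig",
    "StemLoopCall",
    "RulesScore",
    "NO_STRUCTURE",
    "find_stem_loops",
    "score_stem",
    "sequence_bonus",
    "rules_score",
    "rules_classify",
    "SENTINEL_RANK",
]

#: decision threshold: call positive iff total > RULES_THRESHOLD
RULES_THRESHOLD = 9

#: rank assigned to no-structure sites when sweeping score thresholds; sorts
#: below every reachable integer total (minimum reachable total is -1)
SENTINEL_RANK = -(10 ** 6)

_PAIRS = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_GC = {("G", "C"), ("C", "G")}


class LoopTerminus(str, Enum):
    """Which end of the loop holds the scored cytosine."""

    THREE_PRIME = "three_prime"
    FIVE_PRIME = "five_prime"


@dataclass(frozen=True)
class RulesConfig:
    loop_terminus: LoopTerminus = LoopTerminus.THREE_PRIME
    #: offset of the tolerated mismatch/bulge, in primary-sequence space,
    #: relative to the scored C (negative = 5')
    mismatch_offset: int = -2
    max_stem_pairs: int = 15

    def __post_init__(self) -> None:
        if self.max_stem_pairs < 1:
            raise ValueError("max_stem_pairs must be >= 1")


DEFAULT_CONFIG = RulesConfig()


@dataclass(frozen=True)
class StemLoopCall:
    """One candidate hairpin placing the scored C at a loop terminus.

    Offsets are C-relative primary-sequence positions (negative = 5').
    ``pairs`` lists the stem pairs from the loop outward as
    ``(offset5, offset3, kind)`` with kind in {"GC", "AU", "mismatch"}.
    ``bulge`` records a skipped (unpaired) arm position as
    ``("bulge5"|"bulge3", offset)``; at most one of a mismatch pair or a
    bulge is present, and only at the permitted offset.
    """

    loop_offsets: tuple[int, ...]
    loop_len: int
    pairs: tuple[tuple[int, int, str], ...]
    bulge: tuple[str, int] | None = None
    n_gc: int = 0
    n_au: int = 0

    @property
    def n_pairs(self) -> int:
        return self.n_gc + self.n_au

    @property
    def loop_start(self) -> int:
        return self.loop_offsets[0]


@dataclass(frozen=True)
class RulesScore:
    """Best rules score for a site; ``best_call`` is None when no stem-loop
    with at least one scored pair exists (the no-structure sentinel)."""

    stem_points: int
    bonus: int
    total: int | None
    best_call: StemLoopCall | None

    @property
    def has_structure(self) -> bool:
        return self.best_call is not None

    @property
    def rank(self) -> int:
        """Total usable in threshold sweeps; sentinel ranks below all
        reachable totals."""
        return self.total if self.total is not None else SENTINEL_RANK


NO_STRUCTURE = RulesScore(stem_points=0, bonus=0, total=None, best_call=None)


def _pair_kind(b5: str, b3: str) -> str:
    if (b5, b3) in _GC:
        return "GC"
    if (b5, b3) in _PAIRS:
        return "AU"
    return "mismatch"


def _loop_offsets(loop_len: int, terminus: LoopTerminus) -> tuple[int, ...]:
    if terminus is LoopTerminus.THREE_PRIME:
        return tuple(range(-(loop_len - 1), 1))
    return tuple(range(0, loop_len))


def _extend(window: SiteWindow, i5: int, i3: int, cfg: RulesConfig,
            disruption_used: bool, pairs: list, bulge, out: list,
            loop_offsets: tuple[int, ...]) -> None:
    """Greedy outward stem extension from arm positions (i5, i3), branching
    once at the permitted disruption offset.  Every maximal viable extension
    is emitted as a distinct call."""
    while len(pairs) + (1 if bulge else 0) < cfg.max_stem_pairs:
        b5 = window.residue(i5)
        b3 = window.residue(i3)
        if b5 is None or b3 is None:
            break
        kind = _pair_kind(b5, b3)
        at_allowed = (not disruption_used) and i5 == cfg.mismatch_offset
        if kind != "mismatch":
            if at_allowed:
                # a WC pair at the permitted offset: besides pairing through,
                # each one-nt bulge is a distinct viable continuation
                _extend(window, i5 - 1, i3, cfg, True, list(pairs),
                        ("bulge5", i5), out, loop_offsets)
                _extend(window, i5, i3 + 1, cfg, True, list(pairs),
                        ("bulge3", i3), out, loop_offsets)
            pairs.append((i5, i3, kind))
            i5 -= 1
            i3 += 1
            continue
        if at_allowed:
            # branch: tolerate as a mismatched pair, or bulge either arm
            _extend(window, i5 - 1, i3 + 1, cfg, True,
                    pairs + [(i5, i3, "mismatch")], None, out, loop_offsets)
            _extend(window, i5 - 1, i3, cfg, True, list(pairs),
                    ("bulge5", i5), out, loop_offsets)
            _extend(window, i5, i3 + 1, cfg, True, list(pairs),
                    ("bulge3", i3), out, loop_offsets)
        break
    n_gc = sum(1 for p in pairs if p[2] == "GC")
    n_au = sum(1 for p in pairs if p[2] == "AU")
    if n_gc + n_au >= 1:
        out.append(StemLoopCall(
            loop_offsets=loop_offsets,
            loop_len=len(loop_offsets),
            pairs=tuple(pairs),
            bulge=bulge,
            n_gc=n_gc,
            n_au=n_au,
        ))


def find_stem_loops(window: SiteWindow,
                    cfg: RulesConfig = DEFAULT_CONFIG) -> list[StemLoopCall]:
    """Enumerate candidate hairpins with the C at the configured loop
    terminus.

    For each loop length (3 then 4) the stem is extended pairwise outward
    from the loop boundary, stopping at the first disallowed mismatch; at the
    single permitted imperfection offset the search branches into a mismatch
    pair and a one-nt bulge on either arm.  Calls are ordered by loop length
    ascending, then stem length descending, then 5'-most loop start; the
    empty list means no hairpin with at least one scored pair exists.
    """
    calls: list[StemLoopCall] = []
    for loop_len in (3, 4):
        offsets = _loop_offsets(loop_len, cfg.loop_terminus)
        out: list[StemLoopCall] = []
        _extend(window, offsets[0] - 1, offsets[-1] + 1, cfg,
                disruption_used=False, pairs=[], bulge=None, out=out,
                loop_offsets=offsets)
        out.sort(key=lambda c: -c.n_pairs)
        calls.extend(out)
    return calls


def score_stem(call: StemLoopCall) -> int:
    """Stem strength: 3 per G:C pair plus 1 per A:U pair; mismatches and
    bulges contribute nothing."""
    return 3 * call.n_gc + call.n_au


def sequence_bonus(call: StemLoopCall, window: SiteWindow) -> int:
    """Sequence-feature bonus for one hairpin call.

    +2 (once) if a U occurs among the loop residues other than the scored C,
    or if the residue immediately 5' of the C is a purine; -2 if a G occurs
    among the non-C loop residues.  Both may apply, netting 0.
    """
    loop_res = [window.residue(o) for o in call.loop_offsets if o != 0]
    bonus = 0
    neighbour = window.residue(-1)
    if "U" in loop_res or neighbour in ("A", "G"):
        bonus += 2
    if "G" in loop_res:
        bonus -= 2
    return bonus


def rules_score(window: SiteWindow,
                cfg: RulesConfig = DEFAULT_CONFIG) -> RulesScore:
    """Best total over all candidate hairpins for this site.

    Ties prefer loop length 3, then the longer stem, then the 5'-most loop
    start (this affects only which structure is reported, never the score).
    Returns the no-structure sentinel when no hairpin qualifies.
    """
    best: tuple[int, StemLoopCall] | None = None
    for call in find_stem_loops(window, cfg):
        total = score_stem(call) + sequence_bonus(call, window)
        if best is None or total > best[0]:
            best = (total, call)
        elif total == best[0]:
            cur = best[1]
            key_new = (call.loop_len, -call.n_pairs, call.loop_start)
            key_old = (cur.loop_len, -cur.n_pairs, cur.loop_start)
            if key_new < key_old:
                best = (total, call)
    if best is None:
        return NO_STRUCTURE
    total, call = best
    return RulesScore(
        stem_points=score_stem(call),
        bonus=sequence_bonus(call, window),
        total=total,
        best_call=call,
    )


def rules_classify(score: RulesScore | int | None,
                   threshold: int = RULES_THRESHOLD) -> bool:
    """True iff the site's total is defined and strictly greater than the
    threshold (default: > 9, i.e. >= 10 on integers)."""
    if isinstance(score, RulesScore):
        total = score.total
    else:
        total = score
    return total is not None and total > threshold
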