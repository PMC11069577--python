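"""Independent brute-force oracle for the stem-loop rules score.

Generate-and-test enumeration: every loop placement, every stem length, and
every placement of the single tolerated imperfection (mismatch pair, 5'-arm
bulge, 3'-arm bulge, all anchored at the permitted 5'-sequence offset) is
constructed explicitly as a list of pair positions and checked against the
window.  No greedy extension, no early stopping -- deliberately different
machinery from the implementation it cross-checks.
"""

from __future__ import annotations

from cueditscan import rules
from cueditscan.seqio import SiteWindow

_WC = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_GC = {("G", "C"), ("C", "G")}


def _loop_offsets(loop_len, terminus):
    if terminus is rules.LoopTerminus.THREE_PRIME:
        return list(range(-(loop_len - 1), 1))
    return list(range(0, loop_len))


def _bonus(window: SiteWindow, loop_offsets) -> int:
    loop_res = [window.residue(o) for o in loop_offsets if o != 0]
    b = 0
    if "U" in loop_res or window.residue(-1) in ("A", "G"):
        b += 2
    if "G" in loop_res:
        b -= 2
    return b


def _score_pairs(window, pair_positions, mismatch_register):
    """Score an explicit pairing, or None if it is not viable."""
    n_gc = n_au = 0
    for k, (x, y) in enumerate(pair_positions):
        bx, by = window.residue(x), window.residue(y)
        if bx is None or by is None:
            return None
        if k == mismatch_register:
            continue  # unscored imperfection, any residues allowed
        if (bx, by) in _GC:
            n_gc += 1
        elif (bx, by) in _WC:
            n_au += 1
        else:
            return None
    if n_gc + n_au < 1:
        return None
    return 3 * n_gc + n_au


def oracle_rules_total(window: SiteWindow,
                       cfg: rules.RulesConfig = rules.DEFAULT_CONFIG):
    """Best total over all structures, or None for no structure."""
    best = None
    off = cfg.mismatch_offset
    for loop_len in (3, 4):
        loop = _loop_offsets(loop_len, cfg.loop_terminus)
        x0, y0 = loop[0] - 1, loop[-1] + 1
        bonus = _bonus(window, loop)
        candidates = []
        for n in range(1, cfg.max_stem_pairs + 1):
            # perfect stem
            plain = [(x0 - k, y0 + k) for k in range(n)]
            candidates.append((plain, None))
            # one mismatch pair at the permitted offset
            for k in range(n):
                if x0 - k == off:
                    candidates.append((plain, k))
            # one-nt bulge on either arm, anchored where the 5' side
            # reaches the permitted offset
            for m in range(n + 1):
                if x0 - m != off:
                    continue
                if n + 1 <= cfg.max_stem_pairs:  # bulge counts toward the cap
                    b5 = [(x0 - k - (1 if k >= m else 0), y0 + k)
                          for k in range(n)]
                    b3 = [(x0 - k, y0 + k + (1 if k >= m else 0))
                          for k in range(n)]
                    candidates.append((b5, None))
                    candidates.append((b3, None))
        for positions, mm in candidates:
            stem = _score_pairs(window, positions, mm)
            if stem is None:
                continue
            total = stem + bonus
            if best is None or total > best:
                best = total
    return best
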