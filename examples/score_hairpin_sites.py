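"""Score every cytosine of a short coding sequence with the rules model.

The sequence below carries one strong planted hairpin: a 4-pair G:C stem
closing a UUC triloop, with the candidate C at the loop 3' end.  The rules
model gives 3 points per G:C pair and 1 per A:U pair, +2 for a uracil in
the loop or a purine 5' of the C, -2 for a guanine in the loop, and calls
a site when the total exceeds 9.
"""

from cueditscan import rules
from cueditscan.seqio import NucSequence, iter_cytosines

seq = NucSequence(id="DEMO", residues="AUGAAAGAAAGCGCUUCGCGCAAAGAAACCAAAUAG")

print(f"{'c_pos':>5} {'score':>5} {'gc':>3} {'au':>3} {'bonus':>5} call")
for window in iter_cytosines(seq):
    rs = rules.rules_score(window)
    call = rules.rules_classify(rs)
    if rs.has_structure:
        print(f"{window.c_pos:>5} {rs.total:>5} {rs.best_call.n_gc:>3} "
              f"{rs.best_call.n_au:>3} {rs.bonus:>5} {'YES' if call else 'no'}")
    else:
        print(f"{window.c_pos:>5} {'--':>5} {'-':>3} {'-':>3} {'-':>5} no")

# The C at position 17 closes the planted UUC loop behind four G:C pairs:
# stem 12 + U-in-loop bonus 2 = 14 > 9, so it is the only called site.
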