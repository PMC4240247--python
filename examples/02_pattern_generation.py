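"""Turn a conserved motif into stringent PROSITE patterns.

Shows the filter cascade on a hand-built motif: positions with more than
three residue preferences collapse to the wildcard 'x', double-wildcard
runs split the pattern, wildcard ends are trimmed, and anything shorter
than 3 positions is discarded.  Every surviving pattern matches the
source query at its reported position.
"""

from mqsearch import filter_cascade, motif_to_elements, pattern_matches, to_prosite
from mqsearch.motifs import Motif

# a 12-column motif: per-column residue sets of sizes 1,1,2,4,4,1,3,1,1,5,1,1
columns = [
    "G", "D", "AS", "KREQ", "ILMV", "W", "DEN", "C", "H", "FYWIL", "P", "T",
]
n_seqs = 5
stretches = tuple(
    (f"seq{i+1}", "".join(col[min(i, len(col) - 1)] for col in columns))
    for i in range(n_seqs)
)
motif = Motif(start_col=0, end_col=len(columns) - 1,
              per_sequence_stretches=stretches, query_anchor=1)

elements = motif_to_elements(motif)
print("element kinds: ", " ".join(e.kind[0] for e in elements), "(f=fixed c=choice w=wildcard)")

fragments = filter_cascade(elements)
query = stretches[0][1]
print(f"{len(fragments)} compliant pattern(s) after the cascade:")
for frag in fragments:
    pro = to_prosite(frag)
    hits = pattern_matches(frag, query)
    print(f"  {pro:<30} length {len(frag):>2}  matches query at {hits}")

# The double wildcard at columns 3-4 split the motif; both fragments obey
# every rule at once: length 3-15, <=3 residues per position, no wildcard
# at either end, no two consecutive wildcards.
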