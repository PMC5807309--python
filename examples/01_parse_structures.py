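"""Parse candidate structures, including pseudoknots, and query motifs.

Builds a small candidate set from dot-bracket strings (the format emitted by
thermodynamic samplers), deduplicates it, and asks whether candidates contain
a helix motif.
"""

import splandscape as sp

seq, hairpin5, hairpin3 = sp.bistable_example()

# a pseudoknotted fold: bracket layers beyond () encode crossing helices
pk = sp.parse_dotbracket(
    "..[[[..((((...]]]....))))........." , seq, id="pseudoknot"
)
print("pseudoknot pairs (5'->3'):", sorted(pk.pairs_display))

cands = sp.CandidateSet(structures=[hairpin5, hairpin3])
cands = cands.spike_in([pk])  # appended, tagged 'spiked', deduplicated
print("candidate ids:", [s.id for s in cands])

# does a candidate realize at least 60% of the 5' hairpin's helix?
for s in cands:
    print(f"  {s.id:10s} contains 5'-helix motif:",
          sp.motif_contains(s, hairpin5.pairs, min_fraction=0.6))

# Expected: the 5' hairpin matches its own motif; the 3' hairpin and the
# pseudoknot (which pairs different sites) do not.
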