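"""Build a per-patient clonal tree from biopsy-presence patterns.

Mutations shared by every biopsy form the trunk; partially shared and
private mutations form internal and leaf edges.  Conflicting patterns are
resolved greedily by mutation count before construction.
"""

from mrith.phylogeny import PresencePattern, build_tree, resolve_conflicts

# biopsies A, B, C: 10 clonal, 4 shared by A+B, private 3/2/5
patterns = [
    PresencePattern(0b111, 10),
    PresencePattern(0b011, 4),
    PresencePattern(0b001, 3),
    PresencePattern(0b010, 2),
    PresencePattern(0b100, 5),
]
tree = build_tree(patterns, ["A", "B", "C"])
print("newick:", tree.to_newick())
print("total mutations on tree:", tree.total_length())
# ((A:3,B:2):4,C:5):10; -- the trunk carries the 10 clonal mutations.

# An incompatible pattern (B+C overlaps A+B without nesting) is dropped:
conflicted = patterns + [PresencePattern(0b110, 2)]
kept, dropped = resolve_conflicts(conflicted)
print("dropped patterns:", [(f"{p.mask:03b}", p.mutation_count) for p in dropped])
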