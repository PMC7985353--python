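"""Count walks that traverse multiple node classes.

Uses the two-population fixture (a source alternately driving a "V" and a
"D" group, with cross-coupling) to count, for each k-subset of classes,
how many walks contain at least one node of every class in the subset.
"""

from tseqnet import class_interaction_counts, extract_tseqs
from tseqnet import fixtures as fx

fixture = fx.make_two_population(n_steps=60)
log = fixture.run()
X = extract_tseqs(log, fixture.start_node, fixture.end_nodes)
class_map = fixture.network.class_label

print(f"{len(X)} walks from {fixture.start_node} to the labeled groups")
for k in (1, 2):
    counts = class_interaction_counts(X, class_map, ["V", "D"], k=k)
    for subset, count in sorted(counts.items(), key=lambda kv: sorted(kv[0])):
        print(f"  k={k}  {{{','.join(sorted(subset))}}}: {count} walks")
print(
    "-> a walk counts toward a subset only if it touches every class in "
    "it; walks spanning both classes exist because of the V->D "
    "cross-coupling edges."
)
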