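"""Build a bidirected scaffold graph from a handful of paired-read
alignments and find the heterozygous bubble in it.

Four contigs — two flanking homotigs c1, c2 and a candidate homolotig pair
a, b — are linked by innie pairs; each pair nominates one contig end per
mate (forward hit -> 3' end, reverse hit -> 5' end) and suggests a gap of
insert - tail1 - tail2."""

from hapscaffold import ReadAlignment, build_graph, find_perfect_bubbles, pair_to_edge

lengths = {"c1": 1000, "a": 300, "b": 300, "c2": 1000}

# one pair linking c1 -> a: read1 forward near c1's 3' end, read2 reverse near a's 5' end
a1 = ReadAlignment("p0/1", "c1", 850, 925, "+")   # tail = 1000 - 850 = 150
a2 = ReadAlignment("p0/2", "a", 75, 150, "-")     # tail = 150
link = pair_to_edge(a1, a2, mean_insert=400, contig_lengths=lengths)
print(f"pair p0 links {link.end_a} to {link.end_b} with gap {link.gap:.0f} bp")

alns = []
for i, (left, right) in enumerate([("c1", "a"), ("c1", "a"), ("c1", "b"), ("c1", "b"),
                                   ("a", "c2"), ("a", "c2"), ("b", "c2"), ("b", "c2")]):
    L = lengths[left]
    alns.append(ReadAlignment(f"p{i}/1", left, L - 150, L - 75, "+"))
    alns.append(ReadAlignment(f"p{i}/2", right, 75, 150, "-"))

graph, statuses = build_graph(alns, mean_insert=400, contig_lengths=lengths)
for edge in graph.all_edges():
    print(f"edge {edge.key}: weight {edge.weight}, gap {edge.gap_estimate:.0f} bp")

bubbles = find_perfect_bubbles(graph)
print(f"perfect bubbles: {len(bubbles)}")
b = bubbles[0]
print(f"  ({b.c1}) = {b.a} | {b.b} = ({b.c2})  "
      "-- a homolotig pair flanked by common homotigs on both sides")
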