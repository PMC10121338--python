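"""Downstream summaries of a mined result set.

Builds the global view (union graph of all result patterns), gene
co-occurrence tables, and flags hubs against a toy protein-interaction list.
"""

from wigamine import build_global_view, cooccurrence_frequencies, flag_hubs
from wigamine.wiga import Pattern

patterns = [
    Pattern.make([("RPL5", "RPL11"), ("RPL11", "SRP14")]),
    Pattern.make([("RPL5", "RPL11"), ("RPL5", "RPS3")]),
    Pattern.make([("RPL5", "RPL11")]),
    Pattern.make([("HSPB1", "POU3F1")]),
]

view = build_global_view(patterns)
print("global view edges (weight = number of containing patterns):")
print(view.to_edge_table().to_string(index=False))
print(f"components: {list(view.component_sizes)}; "
      f"{len(view.small_components())} at or below the size-4 analysis threshold")

print("\ngene pair co-occurrence across patterns:")
print(cooccurrence_frequencies(patterns, 2).head(5).to_string(index=False))

ppi = [("RPL5", f"P{i}") for i in range(12)] + [("RPL11", "RPL5"), ("HSPB1", "P1")]
genes = sorted({g for p in patterns for g in p.nodes})
print("\nhub flags (PPI degree >= 10):")
print(flag_hubs(ppi, genes, degree_threshold=10).to_string(index=False))
print("\nRecurrent edges mark 'building blocks' shared by many patterns, and")
print("hub genes are those whose proteins are highly connected in the PPI net.")
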