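"""Contiguity structure of a small irregular lattice.

Builds an adjacency graph from an explicit border-sharing edge list, derives
the first- and second-order neighbor sets used as spatial lags, and prints
the row-standardized weight matrix row of one unit.
"""

from noiselag import build_adjacency, neighbor_orders, weight_matrix

edges = [
    ("center", "north"), ("center", "south"), ("center", "east"),
    ("center", "west"), ("north", "east"), ("south", "west"),
    ("west", "outskirt"),
]
graph = build_adjacency(edges)
orders = neighbor_orders(graph)
weights = weight_matrix(graph)

print("unit      order-1 neighbors        order-2 neighbors")
for unit in graph.unit_ids:
    print(
        f"{unit:9s} {', '.join(sorted(orders.order1[unit])) or '-':24s} "
        f"{', '.join(sorted(orders.order2[unit])) or '-'}"
    )

row = weights.row("center")
print("\nweight row of 'center':", dict(zip(graph.unit_ids, row.round(2))))
print(
    "Each of the 4 border-sharing neighbors receives weight 1/4, so the row"
    " sums to 1; 'outskirt' is two borders away and enters only the"
    " second-order neighborhood."
)
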