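"""Rank and filter spines by weighted morpho-functional similarity.

Generates a 200-spine synthetic feature table, then runs both query modes:
a cell-distribution query (where does each spine sit in the cell-wide
Volume/Length ranking?) and a spine-comparison query (which spines most
resemble a chosen query spine?).  Scores are always in [0, 1]; the range
filter keeps the top of the distribution.
"""

from spinekit import (
    DatasetSpec,
    QuerySpec,
    RangeFilter,
    cell_distribution_query,
    generate_feature_dataset,
    histogram,
    range_filter,
    spine_comparison_query,
)

table = generate_feature_dataset(
    DatasetSpec(n_spines=200, seed=42, include_potential=False)
)

dist = cell_distribution_query(
    table,
    QuerySpec(mode="cell_distribution", weights={"Volume": 1.0, "Length": -0.5}),
)
print("cell distribution (large volume, short length):")
print(f"  top 3: {dist.ranking[:3]}  scores "
      f"{[round(dist.scores[i], 3) for i in dist.ranking[:3]]}")
top = range_filter(dist, RangeFilter(lo=0.9, hi=1.0))
print(f"  {len(top)} spines score >= 0.9 of {len(dist.scores)} scored")
print(f"  10-bin histogram: {histogram(dist, n_bins=10).tolist()}")

query_id = dist.ranking[0]
comp = spine_comparison_query(
    table,
    QuerySpec(
        mode="spine_comparison",
        weights={"Volume": 1.0, "MaxDiameter": 1.0},
        query_ids=(query_id,),
    ),
)
print(f"spine comparison against {query_id}:")
print(f"  self-score {comp.scores[query_id]:.3f} (rank "
      f"{comp.ranking.index(query_id) + 1}); nearest neighbours "
      f"{comp.ranking[1:4]}")
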