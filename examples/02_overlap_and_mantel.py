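"""Dietary overlap between populations and its relation to distance.

Builds the overlap_extremes scenario (one identical-diet population pair,
one disjoint pair), computes Schoener and Pianka overlap matrices, then
runs a Mantel test of overlap against great-circle distance.
"""

from dietscope import (
    haversine_matrix,
    mantel_test,
    overlap_matrix,
    pool_counts,
    two_triangle_table,
)
from dietscope.synthetic import generate_records, generate_sites, get_preset

scenario = get_preset("overlap_extremes", seed=7)
sites = generate_sites(scenario)
records = generate_records(scenario, sites)
matrix = pool_counts(records)

schoener = overlap_matrix(matrix, "schoener", threshold=0.6)
pianka = overlap_matrix(matrix, "pianka", threshold=0.6)
print("two-triangle overlap (Pianka below diagonal, Schoener above):")
print(two_triangle_table(schoener, pianka).round(3).to_string())
print("\nP1-P2 share a diet template (overlap 1); P3-P4 use disjoint prey")
print("(overlap 0). Cells > 0.6 count as biologically significant overlap:")
print(f"significant Schoener pairs: "
      f"{int(schoener.significance_mask.to_numpy().sum() // 2)}")

dist = haversine_matrix(sites)
res = mantel_test(dist, schoener.matrix, n_permutations=10_000, seed=7)
print(f"\nMantel (distance vs. overlap): r = {res.r:.3f}, p = {res.p_value:.3f} "
      f"[{res.method}, {res.n_permutations} relabelings]")
print("negative r would mean nearer populations eat more similarly; with")
print("4 sites the test enumerates all 24 relabelings, so p is exact.")
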