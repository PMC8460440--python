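"""Orthogroup expansion/contraction z-scores on a tiny count matrix.

Builds a 4-family x 9-species matrix by hand, computes per-species
z-scores, and prints the focal species' calls. A single-outlier family
over 9 species has |z| = 8/3 ~ 2.67, so the LINE-like row is called
expanded, while the bound (n-1)/sqrt(n) makes |z| >= 2 unreachable with
few species.
"""

import pandas as pd

from potworm.genefam import family_zscores, lineage_specific_families, rank_expansions
from potworm.io import OrthogroupCounts

species = ["E_crypticus"] + [f"sp{i}" for i in range(1, 9)]
table = pd.DataFrame.from_dict(
    {
        "OG_LINE": [129, 1, 1, 1, 1, 1, 1, 1, 1],   # strong expansion
        "OG_P450": [44, 2, 2, 2, 2, 2, 2, 2, 2],    # expansion
        "OG_flat": [3, 3, 4, 2, 3, 3, 4, 2, 3],     # nothing going on
        "OG_zf":   [7, 0, 0, 0, 0, 0, 0, 0, 0],     # lineage-specific
    },
    orient="index",
    columns=species,
)
counts = OrthogroupCounts(table, focal_species="E_crypticus")

records = family_zscores(counts)
print("focal-species calls:")
for r in records:
    if r.species_id == "E_crypticus":
        z = "undefined" if r.z is None else f"{r.z:6.3f}"
        print(f"  {r.orthogroup_id:8s} count={r.count:4d}  z={z}  status={r.status}")

print("\nlargest expansions (by focal gene count):")
for og, count, z in rank_expansions(records, counts):
    print(f"  {og}: {count} genes (z = {z:.2f})")

print(f"\nlineage-specific families: {lineage_specific_families(counts)}")
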