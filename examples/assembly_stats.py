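"""Assembly summary statistics and the mitochondrial-fragment screen.

Simulates a 20-scaffold assembly in which two scaffolds are mostly
verbatim copies of a circular mitochondrial genome, then prints the
N50/L50/GC summary and the k-mer containment screen. The two planted
fragment scaffolds are the only ones above the 0.5 containment threshold.
"""

from potworm.simulate import generate_genome_fixture
from potworm.stats import compute_assembly_stats, screen_mito_fragments

fx = generate_genome_fixture(n_scaffolds=20, n_mito_fragment_scaffolds=2, seed=7)

s = compute_assembly_stats(fx.scaffolds, min_len_bp=1000)
print(f"scaffolds >= 1 kb : {s.n_scaffolds}")
print(f"total size        : {s.total_bp:,} bp")
print(f"largest / smallest: {s.largest_bp:,} / {s.smallest_bp:,} bp")
print(f"N50 / L50         : {s.n50_bp:,} bp / {s.l50}")
print(f"GC                : {s.gc_percent:.2f} %")

print("\nmitochondrial 31-mer containment screen:")
for r in screen_mito_fragments(fx.scaffolds, fx.mito.sequence):
    mark = "  <- flagged (planted fragment)" if r.flagged else ""
    if r.flagged or r.containment > 0.01:
        print(f"  {r.scaffold_id}: containment {r.containment:.3f}{mark}")
planted = sorted(sid for sid, frag in fx.truth.items() if frag)
print(f"planted fragment scaffolds: {planted}")
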