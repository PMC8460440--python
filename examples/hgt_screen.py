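"""Run the staged HGT screen end to end on a small planted fixture.

Generates homology hits, gene models, long-read intervals and gene trees
for a handful of genes with known stage labels, runs the pipeline, and
prints the per-stage counts plus the donor composition of the confirmed
set. With a margin around every threshold, the reported counts equal the
planted class sizes exactly.
"""

from potworm.hgt import run_hgt_pipeline
from potworm.simulate import HgtFixtureSpec, generate_hgt_fixture

spec = HgtFixtureSpec(
    class_sizes={
        "rejected_no_linkage": 3,
        "confirmed_bitscore": 2,
        "phylo_confirmed": 4,
        "phylo_rejected": 2,
    },
    n_background=10,
    origin_distribution={"bacteria": 4, "fungi": 2},
    seed=42,
)
fixture = generate_hgt_fixture(spec)
decisions, report = run_hgt_pipeline(
    fixture.hits, fixture.genes, fixture.reads, fixture.trees
)

print(f"genes screened        : {len(decisions)}")
print(f"candidates (h>=30 & non-metazoan bitscore>=100): {report.n_candidates}")
print(f"rejected at linkage   : {report.n_rejected_linkage}")
print(f"confirmed (metazoan bitscore < 50)             : {report.n_confirmed_bitscore}")
print(f"sent to phylogeny     : {report.n_phylo_tested}")
print(f"confirmed by clade test                        : {report.n_phylo_confirmed}")
print(f"total confirmed HGT   : {report.n_confirmed_total}")
print("origin of confirmed genes:")
for group, pct in report.origin_percentages.items():
    print(f"  {group:10s} {pct:5.1f} %")
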