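"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately avoid the library's own code paths:
N50/L50 by definition-level search, clade membership by enumerating every
ancestor clade on a nested-tuple tree representation.
"""

from __future__ import annotations

import pytest

from potworm.io import GeneModel, HomologyHit


# ---------------------------------------------------------------------------
# N50 / L50 oracle


def n50_l50_oracle(lengths: list[int]) -> tuple[int, int]:
    """Definition-level N50/L50: try every rank in descending order and take
    the first whose cumulative sum reaches half the total."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    for rank in range(1, len(ls) + 1):
        if sum(ls[:rank]) >= total / 2:
            return ls[rank - 1], rank
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Exhaustive rooted-binary-tree enumeration (nested tuples; leaf = str)


def all_rooted_topologies(leaves: list[str]):
    """All rooted binary tree shapes over the given labeled leaves,
    built by inserting each leaf on every edge (incl. above the root)."""

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert_everywhere(left, leaf):
                yield (sub, right)
            for sub in insert_everywhere(right, leaf):
                yield (left, sub)

    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, leaf)]
    return trees


def tuple_to_newick(tree) -> str:
    def rec(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(rec(c) for c in t) + ")"

    return rec(tree) + ";"


def leafset(tree) -> frozenset:
    if isinstance(tree, str):
        return frozenset([tree])
    return leafset(tree[0]) | leafset(tree[1])


def ancestor_clades(tree, leaf: str):
    """Leaf sets of every clade on the path from the root to ``leaf``,
    excluding the leaf itself."""
    if isinstance(tree, str):
        return [] if tree == leaf else None
    for child in tree:
        below = ancestor_clades(child, leaf)
        if below is not None:
            return [leafset(tree)] + below
    return None


def clade_oracle(tree, candidate: str, is_metazoan) -> bool:
    """A candidate is horizontally acquired per the smallest-clade rule iff
    some ancestor clade of it contains no metazoan leaf."""
    clades = ancestor_clades(tree, candidate)
    assert clades is not None
    return any(
        not any(is_metazoan(l) for l in clade if l != candidate) for clade in clades
    )


# ---------------------------------------------------------------------------
# Tiny builders


def mk_hit(query: str, group: str, bitscore: float, subject: str = "s1",
           evalue: float = 1e-20) -> HomologyHit:
    return HomologyHit(
        query_id=query, subject_id=subject, percent_identity=50.0,
        alignment_length=100, mismatches=40, gap_opens=2,
        qstart=1, qend=100, sstart=1, send=100,
        evalue=evalue, bitscore=bitscore, taxon_group=group,
    )


def mk_gene(gid: str, scaffold: str, start: int, end: int, strand: str = "+",
            order: int | None = None, biotype: str = "protein_coding") -> GeneModel:
    return GeneModel(gid, scaffold, start, end, strand, biotype, order_index=order)


@pytest.fixture()
def micro_counts_tsv(tmp_path):
    """A 5x3 orthogroup count table with 2 focal-only rows."""
    text = (
        "Orthogroup\tecry\tspA\tspB\n"
        "OG1\t4\t0\t0\n"
        "OG2\t2\t3\t1\n"
        "OG3\t1\t0\t0\n"
        "OG4\t0\t0\t0\n"
        "OG5\t5\t5\t5\n"
    )
    p = tmp_path / "counts.tsv"
    p.write_text(text)
    return p
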