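"""Orthogroup gene-family statistics.

The central quantity is the per-species expansion z-score of an orthogroup:

    z_s = (n_s - mean(n)) / sd(n)

where ``n`` are the gene counts of the family across all species in the
matrix. Families with z >= 2 in the focal species are called expanded,
z <= -2 contracted. A family enters the analysis only when it is
represented (count >= 1) in the focal species and in at least
``min_other_species`` others, so the standardisation is not driven by a
single genome.

With the sample standard deviation over n species, |z| is bounded by
(n - 1) / sqrt(n); a two-unit threshold is therefore unreachable with
fewer than six species, which callers planting synthetic expansions must
respect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import GeneModel, OrthogroupCounts

__all__ = [
    "FamilyZScore",
    "CollinearBlock",
    "family_zscores",
    "lineage_specific_families",
    "shared_families",
    "rank_expansions",
    "classify_collinear_block",
    "max_abs_zscore",
]

STATUSES = ("expanded", "contracted", "neither", "ineligible", "undefined_sd")


@dataclass(frozen=True)
class FamilyZScore:
    """Z-score of one species' gene count within one orthogroup."""

    orthogroup_id: str
    species_id: str
    count: int
    z: float | None
    eligible: bool
    status: str


@dataclass
class CollinearBlock:
    """A duplicated (collinear) gene block: anchor gene pairs between two
    scaffold copies (possibly the same scaffold)."""

    block_id: str
    gene_pairs: list[tuple[str, str]]
    scaffolds: tuple[str, str]
    orientation: str = "same"


def max_abs_zscore(n_species: int) -> float:
    """Analytic maximum of |z| under the sample-sd rule: (n-1)/sqrt(n)."""
    return (n_species - 1) / math.sqrt(n_species)


def family_zscores(
    counts: OrthogroupCounts,
    min_other_species: int = 3,
    sd_mode: str = "sample",
    representing_only: bool = False,
) -> list[FamilyZScore]:
    """Per-family, per-species expansion/contraction z-scores.

    Parameters
    ----------
    counts
        Orthogroup x species matrix with a focal species set.
    min_other_species
        A family is eligible when the focal species has count >= 1 and at
        least this many non-focal species have count >= 1.
    sd_mode
        "sample" (denominator n-1, default) or "population" (n).
    representing_only
        When True, the mean/sd of a family are taken over the species with
        count >= 1 only instead of all species.

    Returns one record per (family, species). ``z`` is None when the family
    standard deviation is zero. Status semantics: expanded/contracted only
    for eligible family-species with |z| >= 2; ineligible families keep any
    defined z but are never called.
    """
    if sd_mode not in {"sample", "population"}:
        raise ValueError("sd_mode must be 'sample' or 'population'")
    species = counts.species_ids
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    ddof = 1 if sd_mode == "sample" else 0
    focal = counts.focal_species

    out: list[FamilyZScore] = []
    for og, row in counts.table.iterrows():
        vals = row.to_numpy(dtype=float)
        n_other = int(sum(1 for sp in species if sp != focal and row[sp] >= 1))
        eligible = row[focal] >= 1 and n_other >= min_other_species
        pool = vals[vals >= 1] if representing_only else vals
        mean = float(pool.mean()) if pool.size else 0.0
        sd = float(pool.std(ddof=ddof)) if pool.size > ddof else 0.0
        for sp in species:
            c = int(row[sp])
            if sd == 0.0:
                z = None
                status = "undefined_sd" if eligible else "ineligible"
            else:
                z = (c - mean) / sd
                if not eligible:
                    status = "ineligible"
                elif sp == focal and z >= 2.0:
                    status = "expanded"
                elif sp == focal and z <= -2.0:
                    status = "contracted"
                else:
                    status = "neither"
            out.append(FamilyZScore(str(og), sp, c, z, bool(eligible), status))
    return out


def lineage_specific_families(counts: OrthogroupCounts) -> list[str]:
    """Orthogroups private to the focal species (focal count >= 1, every
    other species 0)."""
    t = counts.table
    focal = counts.focal_species
    others = [s for s in t.columns if s != focal]
    mask = (t[focal] >= 1) & (t[others].sum(axis=1) == 0)
    return [str(i) for i in t.index[mask]]


def shared_families(
    counts: OrthogroupCounts,
    species_subset: Sequence[str],
    exclusive: bool = False,
) -> tuple[int, list[str]]:
    """Families represented (count >= 1) in every species of the subset.

    With ``exclusive=True`` the Venn-region semantics apply: the family must
    additionally be absent (count 0) from every species outside the subset.
    """
    if not species_subset:
        raise ValueError("species subset must be non-empty")
    unknown = set(species_subset) - set(counts.species_ids)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    t = counts.table
    mask = (t[list(species_subset)] >= 1).all(axis=1)
    if exclusive:
        outside = [s for s in t.columns if s not in set(species_subset)]
        if outside:
            mask &= (t[outside] == 0).all(axis=1)
    ids = [str(i) for i in t.index[mask]]
    return len(ids), ids


def rank_expansions(
    zscores: Sequence[FamilyZScore],
    counts: OrthogroupCounts,
    top_n: int = 10,
) -> list[tuple[str, int, float]]:
    """Expanded families ranked by focal gene count (descending), ties by z
    descending then orthogroup id. Returns (orthogroup, focal count, z)."""
    focal = counts.focal_species
    expanded = [
        r for r in zscores if r.species_id == focal and r.status == "expanded"
    ]
    expanded.sort(key=lambda r: (-r.count, -(r.z or 0.0), r.orthogroup_id))
    return [(r.orthogroup_id, r.count, float(r.z)) for r in expanded[:top_n]]


def classify_collinear_block(
    block: CollinearBlock, genes: Mapping[str, GeneModel] | Sequence[GeneModel]
) -> str:
    """Classify a duplicated block as ``inter_scaffold``, ``palindrome``
    (intra-scaffold, copies on opposite strands) or ``tandem``
    (intra-scaffold, same strand).

    The call is made on the strand relation of the anchor gene pairs; mixed
    strand relations within one intra-scaffold block are rejected.
    """
    gene_map = (
        dict(genes) if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    )
    if block.scaffolds[0] != block.scaffolds[1]:
        return "inter_scaffold"
    if not block.gene_pairs:
        raise ValueError(f"block {block.block_id} has no gene pairs")
    relations = set()
    for a, b in block.gene_pairs:
        for gid in (a, b):
            if gid not in gene_map:
                raise KeyError(f"unknown gene {gid!r} in block {block.block_id}")
        relations.add(gene_map[a].strand == gene_map[b].strand)
    if len(relations) > 1:
        raise ValueError(
            f"block {block.block_id}: inconsistent strand relations across pairs"
        )
    return "tandem" if relations.pop() else "palindrome"
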