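"""Staged horizontal-gene-transfer (HGT) screen.

A candidate forms where a gene's best non-metazoan homology bitscore
exceeds its best metazoan bitscore by at least ``h_min`` (the h-score) and
reaches at least ``nonmet_min`` in absolute terms. Candidates must then be
physically anchored in the focal genome: an immediately neighbouring native
(non-candidate, protein-coding) gene on the same scaffold, with at least one
long read spanning both gene bodies — evidence against assembly
contamination. Anchored candidates with a best metazoan bitscore below
``confirm_below`` are confirmed outright; the rest go to a phylogenetic
test, confirmed when the smallest clade containing the candidate in its
gene tree (the candidate's parent subtree) holds no metazoan sequence.

Annelid-database hits are metazoan for the purposes of the clade test and
are excluded from the non-metazoan best hit; they represent vertical
inheritance in the focal lineage. ``annelida_nonmetazoan=True`` inverts
this for sensitivity analysis.

All stage thresholds default to the screen's published operating point
(h >= 30, non-metazoan bitscore >= 100, metazoan bitscore < 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import (
    METAZOAN_GROUPS,
    NONMETAZOAN_GROUPS,
    GeneModel,
    GeneTree,
    HomologyHit,
    ReadInterval,
    gene_span0,
)

__all__ = [
    "BestHitSummary",
    "HgtConfig",
    "HgtDecision",
    "HgtReport",
    "EnrichmentResult",
    "STAGES",
    "summarize_best_hits",
    "filter_candidates",
    "check_context_linkage",
    "classify_by_bitscore",
    "clade_test",
    "attribute_origin",
    "enrich_go",
    "run_hgt_pipeline",
]

STAGES = (
    "not_candidate",
    "rejected_no_linkage",
    "confirmed_bitscore",
    "phylo_confirmed",
    "phylo_rejected",
    "phylo_missing",
)


@dataclass(frozen=True)
class BestHitSummary:
    """Per-gene best bitscores by taxon compartment and the derived h-score
    (best non-metazoan minus best metazoan; missing compartments score 0)."""

    gene_id: str
    best_metazoan_bitscore: float = 0.0
    best_annelid_bitscore: float = 0.0
    best_nonmetazoan_bitscore: float = 0.0
    best_nonmetazoan_group: str | None = None

    @property
    def h_score(self) -> float:
        return self.best_nonmetazoan_bitscore - self.best_metazoan_bitscore


@dataclass
class HgtConfig:
    """Thresholds and flags of the staged screen."""

    h_min: float = 30.0
    nonmet_min: float = 100.0
    confirm_below: float = 50.0
    min_overlap_bp: int = 100
    annelida_nonmetazoan: bool = False

    def __post_init__(self) -> None:
        if min(self.h_min, self.nonmet_min, self.confirm_below) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_overlap_bp < 0:
            raise ValueError("min_overlap_bp must be >= 0")


@dataclass
class HgtDecision:
    gene_id: str
    stage: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class HgtReport:
    """Per-stage counts of one pipeline run plus origin percentages of the
    confirmed set."""

    n_candidates: int
    n_rejected_linkage: int
    n_confirmed_bitscore: int
    n_phylo_tested: int
    n_phylo_confirmed: int
    n_phylo_rejected: int
    n_phylo_missing: int
    n_confirmed_total: int
    origin_percentages: dict[str, float]

    def __post_init__(self) -> None:
        assert self.n_candidates == (
            self.n_rejected_linkage + self.n_confirmed_bitscore + self.n_phylo_tested
        )
        assert self.n_phylo_tested == (
            self.n_phylo_confirmed + self.n_phylo_rejected + self.n_phylo_missing
        )
        assert self.n_confirmed_total == self.n_confirmed_bitscore + self.n_phylo_confirmed
        if self.origin_percentages:
            assert abs(sum(self.origin_percentages.values()) - 100.0) <= 0.2


@dataclass(frozen=True)
class EnrichmentResult:
    go_term: str
    namespace: str
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# Stage 1: best-hit summaries and the h-score


def summarize_best_hits(
    hits: Iterable[HomologyHit],
    gene_universe: set[str],
    annelida_nonmetazoan: bool = False,
) -> dict[str, BestHitSummary]:
    """Collapse a hit list to per-gene best bitscores per compartment.

    Every gene of the universe gets a summary; compartments without hits
    score 0, so the h-score is always defined. The donor group of the best
    non-metazoan hit breaks ties by lower e-value, then subject id.
    """
    best_met: dict[str, float] = {}
    best_ann: dict[str, float] = {}
    # gene -> (bitscore, -evalue?, ...) keep full tuple for tie-breaks
    best_non: dict[str, tuple[float, float, str, str]] = {}

    nonmet = set(NONMETAZOAN_GROUPS)
    if annelida_nonmetazoan:
        nonmet = nonmet | {"annelida"}

    for h in hits:
        if h.query_id not in gene_universe:
            raise ValueError(f"hit for unknown gene {h.query_id!r}")
        if h.taxon_group == "metazoa_excl_annelida":
            best_met[h.query_id] = max(best_met.get(h.query_id, 0.0), h.bitscore)
        if h.taxon_group == "annelida":
            best_ann[h.query_id] = max(best_ann.get(h.query_id, 0.0), h.bitscore)
        if h.taxon_group in nonmet:
            # rank: higher bitscore, then lower evalue, then subject id
            key = (h.bitscore, -h.evalue, h.subject_id, h.taxon_group)
            cur = best_non.get(h.query_id)
            if cur is None or (key[0], key[1]) > (cur[0], cur[1]) or (
                (key[0], key[1]) == (cur[0], cur[1]) and key[2] < cur[2]
            ):
                best_non[h.query_id] = key

    out: dict[str, BestHitSummary] = {}
    for gid in sorted(gene_universe):
        non = best_non.get(gid)
        out[gid] = BestHitSummary(
            gene_id=gid,
            best_metazoan_bitscore=best_met.get(gid, 0.0),
            best_annelid_bitscore=best_ann.get(gid, 0.0),
            best_nonmetazoan_bitscore=non[0] if non else 0.0,
            best_nonmetazoan_group=non[3] if non else None,
        )
    return out


def filter_candidates(
    summaries: Mapping[str, BestHitSummary],
    h_min: float = 30.0,
    nonmet_min: float = 100.0,
) -> set[str]:
    """Genes with h-score >= h_min and best non-metazoan bitscore >=
    nonmet_min (both boundaries inclusive)."""
    return {
        gid
        for gid, s in summaries.items()
        if s.h_score >= h_min and s.best_nonmetazoan_bitscore >= nonmet_min
    }


# ---------------------------------------------------------------------------
# Stage 2: genomic-context / long-read linkage


def _overlap_bp(iv: ReadInterval, span0: tuple[int, int]) -> int:
    return max(0, min(iv.end, span0[1]) - max(iv.start, span0[0]))


def check_context_linkage(
    candidate: str,
    genes: Sequence[GeneModel],
    candidates: set[str],
    reads: Sequence[ReadInterval],
    min_overlap_bp: int = 100,
) -> tuple[bool, dict]:
    """Native-neighbour plus long-read linkage test for one candidate.

    Passes when an immediately adjacent gene (gene-order rank +/- 1 on the
    same scaffold) is protein-coding and not itself a candidate, and at
    least one read interval overlaps both the candidate span and that
    neighbour's span by ``min_overlap_bp`` each. Evidence distinguishes the
    two failure sub-reasons (``no_native_neighbor`` / ``no_bridging_read``).
    """
    by_id = {g.gene_id: g for g in genes}
    if candidate not in by_id:
        raise KeyError(f"candidate {candidate!r} absent from gene set")
    cand = by_id[candidate]
    neighbors = [
        g
        for g in genes
        if g.scaffold_id == cand.scaffold_id
        and g.order_index is not None
        and cand.order_index is not None
        and abs(g.order_index - cand.order_index) == 1
        and g.biotype == "protein_coding"
        and g.gene_id not in candidates
    ]
    if not neighbors:
        return False, {"reason": "no_native_neighbor"}

    cand_span = gene_span0(cand)
    scaffold_reads = [r for r in reads if r.scaffold_id == cand.scaffold_id]
    for nb in sorted(neighbors, key=lambda g: g.gene_id):
        nb_span = gene_span0(nb)
        for r in scaffold_reads:
            if (
                _overlap_bp(r, cand_span) >= min_overlap_bp
                and _overlap_bp(r, nb_span) >= min_overlap_bp
            ):
                return True, {"neighbor": nb.gene_id, "read": r.read_id}
    return False, {
        "reason": "no_bridging_read",
        "neighbors": [nb.gene_id for nb in sorted(neighbors, key=lambda g: g.gene_id)],
    }


# ---------------------------------------------------------------------------
# Stage 3: metazoan-bitscore confirmation


def classify_by_bitscore(summary: BestHitSummary, confirm_below: float = 50.0) -> str:
    """``confirmed`` when the best metazoan bitscore is strictly below the
    cutoff, else ``needs_phylo`` (the boundary value goes to phylogeny)."""
    return "confirmed" if summary.best_metazoan_bitscore < confirm_below else "needs_phylo"


# ---------------------------------------------------------------------------
# Stage 4: smallest-clade phylogenetic test


def clade_test(
    tree: GeneTree,
    candidate_leaf: str,
    metazoan_groups: frozenset[str] | set[str] = METAZOAN_GROUPS,
) -> tuple[bool, list[str]]:
    """Smallest-clade test: the candidate is confirmed when its parent
    subtree (the smallest clade containing it) holds no metazoan leaf.

    Returns (confirmed, labels of the clade's leaves). A tree in which the
    candidate has no siblings (a single-leaf clade equal to the whole tree)
    is invalid.
    """
    leaf = tree.find_leaf(candidate_leaf)
    parent = leaf.parent_node
    if parent is None:
        raise ValueError("candidate leaf is the tree root")
    labels = [
        lf.taxon.label for lf in parent.leaf_iter() if lf.taxon is not None
    ]
    others = [l for l in labels if l != candidate_leaf]
    if not others:
        raise ValueError("candidate's smallest clade contains no other sequence")
    confirmed = not any(
        GeneTree.taxon_group_of(l) in metazoan_groups for l in others
    )
    return confirmed, sorted(labels)


# ---------------------------------------------------------------------------
# Origin attribution and GO enrichment


def _round_half_away(x: float, digits: int = 1) -> float:
    scale = 10**digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def attribute_origin(
    confirmed: set[str], summaries: Mapping[str, BestHitSummary]
) -> dict[str, tuple[int, float]]:
    """Donor-group composition of the confirmed set.

    Origin of a gene is the taxon group of its best non-metazoan hit.
    Percentages are rounded half-away-from-zero to one decimal.
    """
    missing = confirmed - set(summaries)
    if missing:
        raise ValueError(f"confirmed genes without summaries: {sorted(missing)}")
    if not confirmed:
        return {}
    counts: dict[str, int] = {}
    for gid in sorted(confirmed):
        group = summaries[gid].best_nonmetazoan_group
        assert group is not None, f"confirmed gene {gid} has no non-metazoan hit"
        counts[group] = counts.get(group, 0) + 1
    total = len(confirmed)
    return {
        grp: (n, _round_half_away(100.0 * n / total))
        for grp, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def enrich_go(
    foreground: set[str],
    background: set[str],
    annotations: Mapping[str, set[str]],
    namespaces: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric GO-term over-representation test.

    Terms are tested when present in the foreground; Benjamini–Hochberg
    correction is applied separately per namespace (``namespaces`` maps a
    term to BP/MF/CC; unmapped terms default to BP). Terms with q <= alpha
    are returned, ordered by (namespace, q, p, term).
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    ns_of = namespaces or {}
    n_bg = len(background)
    n_fg = len(foreground)

    term_fg: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1

    tested: dict[str, list] = {}
    for term, k_fg in sorted(term_fg.items()):
        k_bg = term_bg[term]
        p = float(hypergeom.sf(k_fg - 1, n_bg, k_bg, n_fg))
        tested.setdefault(ns_of.get(term, "BP"), []).append(
            [term, k_fg, k_bg, min(1.0, p)]
        )

    results: list[EnrichmentResult] = []
    for ns, rows in tested.items():
        pvals = [r[3] for r in rows]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (term, k_fg, k_bg, p), q in zip(rows, qvals):
            if q <= alpha:
                results.append(
                    EnrichmentResult(term, ns, k_fg, n_fg, k_bg, n_bg, p, float(q))
                )
    results.sort(key=lambda r: (r.namespace, r.q_value, r.p_value, r.go_term))
    return results


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_hgt_pipeline(
    hits: Iterable[HomologyHit],
    genes: Sequence[GeneModel],
    reads: Sequence[ReadInterval],
    trees: Mapping[str, GeneTree],
    config: HgtConfig | None = None,
) -> tuple[list[HgtDecision], HgtReport]:
    """Run the full staged screen and return per-gene decisions plus the
    stage-count report.

    Stages in order: best-hit summaries -> h-score/bitscore candidate filter
    -> native-neighbour/long-read linkage -> metazoan-bitscore confirmation
    -> smallest-clade test for the remainder. Genes needing phylogeny
    without a supplied tree are reported ``phylo_missing`` and are not
    confirmed. Iteration order (hence output order) is by gene id.
    """
    cfg = config or HgtConfig()
    gene_universe = {g.gene_id for g in genes}
    summaries = summarize_best_hits(
        hits, gene_universe, annelida_nonmetazoan=cfg.annelida_nonmetazoan
    )
    candidates = filter_candidates(summaries, cfg.h_min, cfg.nonmet_min)

    decisions: list[HgtDecision] = []
    n_rej = n_bit = n_pc = n_pr = n_pm = 0
    confirmed: set[str] = set()

    for gid in sorted(gene_universe):
        if gid not in candidates:
            decisions.append(HgtDecision(gid, "not_candidate"))
            continue
        linked, evidence = check_context_linkage(
            gid, genes, candidates, reads, cfg.min_overlap_bp
        )
        if not linked:
            n_rej += 1
            decisions.append(HgtDecision(gid, "rejected_no_linkage", evidence))
            continue
        if classify_by_bitscore(summaries[gid], cfg.confirm_below) == "confirmed":
            n_bit += 1
            confirmed.add(gid)
            decisions.append(HgtDecision(gid, "confirmed_bitscore", evidence))
            continue
        tree = trees.get(gid)
        if tree is None:
            n_pm += 1
            decisions.append(
                HgtDecision(gid, "phylo_missing", {**evidence, "tree": None})
            )
            continue
        metaz = (
            METAZOAN_GROUPS - {"annelida"}
            if cfg.annelida_nonmetazoan
            else METAZOAN_GROUPS
        )
        ok, clade = clade_test(tree, gid, metaz)
        if ok:
            n_pc += 1
            confirmed.add(gid)
            decisions.append(
                HgtDecision(gid, "phylo_confirmed", {**evidence, "clade": clade})
            )
        else:
            n_pr += 1
            decisions.append(
                HgtDecision(gid, "phylo_rejected", {**evidence, "clade": clade})
            )

    origin = attribute_origin(confirmed, summaries)
    report = HgtReport(
        n_candidates=len(candidates),
        n_rejected_linkage=n_rej,
        n_confirmed_bitscore=n_bit,
        n_phylo_tested=n_pc + n_pr + n_pm,
        n_phylo_confirmed=n_pc,
        n_phylo_rejected=n_pr,
        n_phylo_missing=n_pm,
        n_confirmed_total=n_bit + n_pc,
        origin_percentages={g: pct for g, (n, pct) in origin.items()},
    )
    return decisions, report
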