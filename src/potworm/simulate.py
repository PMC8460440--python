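"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (which gene belongs to which
screen stage, which orthogroup row is expanded, which scaffold is a
mitochondrial fragment) and returns it alongside the data, so every stage
of the analysis is testable without any external download. Fixtures are
deterministic per seed; independent RNG sub-streams per output kind keep
existing outputs stable when new kinds are added.

Bitscores are drawn inside class-specific intervals kept at least
``bitscore_margin`` score units away from every decision threshold
(30 h-score / 100 non-metazoan / 50 metazoan), so planted stage labels are
unambiguous; threshold boundary behaviour is exercised separately with
exact values in the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genefam as _genefam
from .io import (
    NONMETAZOAN_GROUPS,
    GeneModel,
    GeneTree,
    HomologyHit,
    OrthogroupCounts,
    ReadInterval,
    Scaffold,
    write_counts_matrix,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_paf,
)

__all__ = [
    "HgtFixtureSpec",
    "HgtFixture",
    "FamilyFixtureSpec",
    "FamilyFixture",
    "GenomeFixture",
    "PAPER_STAGES_CLASS_SIZES",
    "PAPER_STAGES_ORIGINS",
    "paper_stages_spec",
    "generate_hgt_fixture",
    "generate_family_counts_fixture",
    "generate_genome_fixture",
]

# Latent per-stage composition of the staged HGT screen reported for the
# E. crypticus genome: 105 candidates = 33 linkage-rejected + 5 confirmed on
# low metazoan bitscore + 67 sent to phylogeny, of which 27 were confirmed,
# for 32 confirmed in total.
PAPER_STAGES_CLASS_SIZES: dict[str, int] = {
    "rejected_no_linkage": 33,
    "confirmed_bitscore": 5,
    "phylo_confirmed": 27,
    "phylo_rejected": 40,
}

# Donor composition of the 32 confirmed genes. 19/8/4/1 is the unique
# 4-part composition of 32 whose one-decimal percentages round to the
# reported 59.4 / 25.0 / 12.5 / 3.1.
PAPER_STAGES_ORIGINS: dict[str, int] = {
    "bacteria": 19,
    "plants": 8,
    "fungi": 4,
    "archaea": 1,
}

_PLANTED_CLASSES = (
    "rejected_no_linkage",
    "confirmed_bitscore",
    "phylo_confirmed",
    "phylo_rejected",
)


@dataclass
class HgtFixtureSpec:
    """Recipe for a synthetic HGT-screen input set with planted stages."""

    class_sizes: dict[str, int] = field(default_factory=dict)
    n_background: int = 45
    origin_distribution: dict[str, int] | None = None
    bitscore_margin: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.class_sizes.items():
            if cls not in _PLANTED_CLASSES and cls != "not_candidate":
                raise ValueError(f"unknown stage class {cls!r}")
            if n < 0:
                raise ValueError(f"negative size for class {cls!r}")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.bitscore_margin < 1:
            raise ValueError("bitscore_margin must be >= 1")
        n_confirmed = self.class_sizes.get("confirmed_bitscore", 0) + self.class_sizes.get(
            "phylo_confirmed", 0
        )
        if self.origin_distribution is not None:
            bad = set(self.origin_distribution) - NONMETAZOAN_GROUPS
            if bad:
                raise ValueError(f"origin groups must be non-metazoan: {sorted(bad)}")
            if sum(self.origin_distribution.values()) != n_confirmed:
                raise ValueError(
                    "origin_distribution must sum to the number of confirmed genes "
                    f"({n_confirmed})"
                )


@dataclass
class HgtFixture:
    """Generated inputs plus the planted truth table (gene id -> stage)."""

    hits: list[HomologyHit]
    genes: list[GeneModel]
    reads: list[ReadInterval]
    trees: dict[str, GeneTree]
    truth: dict[str, dict[str, str | None]]

    def write(self, outdir: str | Path) -> None:
        """Emit the fixture as standard files: per-group 12-column hit
        tables, GFF3 gene models, PAF read intervals, Newick trees and a
        truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        groups = sorted({h.taxon_group for h in self.hits})
        for grp in groups:
            write_hit_table(
                [h for h in self.hits if h.taxon_group == grp],
                outdir / f"hits.{grp}.tsv",
            )
        write_gff3(self.genes, outdir / "genes.gff3")
        write_paf(self.reads, outdir / "reads.paf")
        tree_dir = outdir / "trees"
        tree_dir.mkdir(exist_ok=True)
        for gid, tree in sorted(self.trees.items()):
            (tree_dir / f"{gid}.nwk").write_text(tree.as_newick() + "\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("gene_id\tplanted_stage\torigin_group\n")
            for gid in sorted(self.truth):
                row = self.truth[gid]
                fh.write(f"{gid}\t{row['stage']}\t{row['origin'] or ''}\n")


def paper_stages_spec(
    seed: int = 1234, n_background: int = 45, bitscore_margin: float = 5.0
) -> HgtFixtureSpec:
    """The ``paper-stages`` preset: class sizes and donor composition of the
    published E. crypticus screen (see module constants)."""
    return HgtFixtureSpec(
        class_sizes=dict(PAPER_STAGES_CLASS_SIZES),
        n_background=n_background,
        origin_distribution=dict(PAPER_STAGES_ORIGINS),
        bitscore_margin=bitscore_margin,
        seed=seed,
    )


def _mk_hit(
    rng: np.random.Generator, query: str, group: str, bitscore: float, subject: str
) -> HomologyHit:
    aln = int(rng.integers(80, 400))
    mism = int(rng.integers(0, aln // 3))
    evalue = float(10.0 ** -(bitscore / 4.0 + rng.uniform(0, 2)))
    return HomologyHit(
        query_id=query,
        subject_id=subject,
        percent_identity=float(np.round(rng.uniform(35, 95), 2)),
        alignment_length=aln,
        mismatches=mism,
        gap_opens=int(rng.integers(0, 5)),
        qstart=1,
        qend=aln,
        sstart=1,
        send=aln,
        evalue=max(evalue, 1e-180),
        bitscore=float(np.round(bitscore, 1)),
        taxon_group=group,
    )


def _jittered_tree(
    rng: np.random.Generator, gid: str, donor: str, confirmed: bool
) -> GeneTree:
    def bl() -> str:
        return f"{rng.uniform(0.02, 0.5):.3f}"

    if confirmed:
        # candidate sisters a donor sequence; metazoans only outside the clade
        nwk = (
            f"(({gid}:{bl()},{donor}|p1:{bl()})0.96:{bl()},"
            f"({donor}|p2:{bl()},metazoa_excl_annelida|m1:{bl()})0.88:{bl()});"
        )
    else:
        nwk = (
            f"(({gid}:{bl()},metazoa_excl_annelida|m1:{bl()})0.93:{bl()},"
            f"({donor}|p1:{bl()},{donor}|p2:{bl()})0.85:{bl()});"
        )
    return GeneTree.from_newick(nwk)


def generate_hgt_fixture(spec: HgtFixtureSpec) -> HgtFixture:
    """Generate hit tables, gene models, read intervals and gene trees whose
    pipeline stage labels are planted per ``spec.class_sizes``.

    Layout: every planted candidate sits on its own scaffold; linkage-pass
    classes get a native protein-coding neighbour plus one long read
    spanning both gene bodies; linkage-fail genes get either no neighbour
    or reads that bridge nothing. Background genes live one per scaffold
    with hit profiles safely outside the candidate thresholds.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_coord, rng_score, rng_tree, rng_misc = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    m = spec.bitscore_margin

    hits: list[HomologyHit] = []
    genes: list[GeneModel] = []
    reads: list[ReadInterval] = []
    trees: dict[str, GeneTree] = {}
    truth: dict[str, dict[str, str | None]] = {}

    # expand classes into an ordered gene roster
    roster: list[str] = []
    for cls in _PLANTED_CLASSES:
        roster += [cls] * spec.class_sizes.get(cls, 0)
    n_bg = spec.n_background + spec.class_sizes.get("not_candidate", 0)

    # donor groups for the confirmed classes, in roster order
    confirmed_classes = {"confirmed_bitscore", "phylo_confirmed"}
    if spec.origin_distribution is not None:
        donor_pool = [g for g, n in sorted(spec.origin_distribution.items()) for _ in range(n)]
        donor_pool = [str(g) for g in rng_misc.permutation(donor_pool)]
    else:
        donor_pool = None
    nonmet_sorted = sorted(NONMETAZOAN_GROUPS)

    subj_counter = 0

    def subject(group: str) -> str:
        nonlocal subj_counter
        subj_counter += 1
        return f"{group}_prot{subj_counter:05d}"

    for i, cls in enumerate(roster):
        gid = f"g{i:04d}"
        scaf = f"scf{i:04d}"
        # candidate gene and (usually) a native neighbour
        cand_start = int(2001 + rng_coord.integers(0, 500))
        cand_len = int(rng_coord.integers(1500, 2500))
        cand_end = cand_start + cand_len - 1
        nb_start = cand_end + int(rng_coord.integers(600, 1500))
        nb_end = nb_start + int(rng_coord.integers(1500, 2500)) - 1
        strand = "+" if rng_coord.random() < 0.5 else "-"
        genes.append(GeneModel(gid, scaf, cand_start, cand_end, strand))

        no_neighbor = cls == "rejected_no_linkage" and rng_coord.random() < 0.5
        if not no_neighbor:
            genes.append(GeneModel(f"{gid}n", scaf, nb_start, nb_end, "+"))

        if cls == "rejected_no_linkage":
            if not no_neighbor:
                # a read touching only the candidate: bridges nothing
                reads.append(
                    ReadInterval(f"read_{gid}a", scaf, cand_start - 1, cand_start + 399)
                )
        else:
            reads.append(
                ReadInterval(f"read_{gid}", scaf, cand_end - 300, nb_start - 1 + 300)
            )

        # donor group
        if cls in confirmed_classes and donor_pool is not None:
            donor = donor_pool.pop()
        else:
            donor = nonmet_sorted[int(rng_misc.integers(len(nonmet_sorted)))]

        # bitscores, kept >= margin away from every threshold
        if cls == "confirmed_bitscore":
            met = 0.0 if rng_score.random() < 0.3 else float(
                rng_score.uniform(m, 50.0 - m)
            )
        elif cls in {"phylo_confirmed", "phylo_rejected"}:
            met = float(rng_score.uniform(50.0 + m, 150.0))
        else:  # rejected_no_linkage: any side of the confirmation cutoff
            met = float(
                rng_score.uniform(0.0, 50.0 - m)
                if rng_score.random() < 0.5
                else rng_score.uniform(50.0 + m, 150.0)
            )
        nonmet = max(100.0 + m, met + 30.0 + m) + float(rng_score.uniform(0.0, 100.0))

        hits.append(_mk_hit(rng_score, gid, donor, nonmet, subject(donor)))
        if met > 0:
            hits.append(
                _mk_hit(rng_score, gid, "metazoa_excl_annelida", met, subject("metazoa"))
            )
            if rng_score.random() < 0.5:
                hits.append(
                    _mk_hit(
                        rng_score, gid, "annelida", met * 0.9, subject("annelida")
                    )
                )
        # lower-scoring decoy hits in other donor groups
        for grp in rng_misc.permutation(nonmet_sorted)[: int(rng_misc.integers(0, 3))]:
            if grp == donor:
                continue
            decoy = nonmet - float(rng_score.uniform(m, 40.0))
            if decoy > 0:
                hits.append(_mk_hit(rng_score, gid, str(grp), decoy, subject(str(grp))))

        if cls in {"phylo_confirmed", "phylo_rejected"}:
            trees[gid] = _jittered_tree(rng_tree, gid, donor, cls == "phylo_confirmed")

        truth[gid] = {"stage": cls, "origin": donor}
        if not no_neighbor:
            truth[f"{gid}n"] = {"stage": "not_candidate", "origin": None}

    # background genes: never candidates, margins respected
    for j in range(n_bg):
        gid = f"b{j:04d}"
        scaf = f"bgscf{j:04d}"
        start = int(1001 + rng_coord.integers(0, 1000))
        end = start + int(rng_coord.integers(1000, 3000)) - 1
        genes.append(GeneModel(gid, scaf, start, end, "+"))
        mode = int(rng_misc.integers(0, 3))
        if mode == 1:  # metazoan-only profile
            met = float(rng_score.uniform(60.0, 300.0))
            hits.append(
                _mk_hit(rng_score, gid, "metazoa_excl_annelida", met, subject("metazoa"))
            )
        elif mode == 2:  # weak non-metazoan hit: h fine but bitscore < 100
            grp = nonmet_sorted[int(rng_misc.integers(len(nonmet_sorted)))]
            nm = float(rng_score.uniform(20.0, 100.0 - m))
            hits.append(_mk_hit(rng_score, gid, grp, nm, subject(grp)))
        # mode 0: no hits at all
        truth[gid] = {"stage": "not_candidate", "origin": None}

    # assign gene-order indices per scaffold, as the GFF3 reader would
    genes.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    rank: dict[str, int] = {}
    for g in genes:
        g.order_index = rank.get(g.scaffold_id, 0)
        rank[g.scaffold_id] = g.order_index + 1

    return HgtFixture(hits=hits, genes=genes, reads=reads, trees=trees, truth=truth)


# ---------------------------------------------------------------------------
# Orthogroup count fixtures


@dataclass
class FamilyFixtureSpec:
    """Recipe for a synthetic orthogroup count matrix with planted rows.

    ``planted`` maps each orthogroup id to one of expanded / contracted /
    lineage_specific / neutral. Expansions and contractions are planted as
    single-outlier rows, whose |z| is exactly (n-1)/sqrt(n); requesting one
    with too few species for that bound to reach 2 is an error.
    """

    n_species: int = 9
    planted: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        allowed = {"expanded", "contracted", "lineage_specific", "neutral"}
        bad = {c for c in self.planted.values() if c not in allowed}
        if bad:
            raise ValueError(f"unknown planted classes: {sorted(bad)}")
        needs_z = {"expanded", "contracted"}
        if any(c in needs_z for c in self.planted.values()):
            if _genefam.max_abs_zscore(self.n_species) < 2.0:
                raise ValueError(
                    f"single-outlier |z| bound (n-1)/sqrt(n) = "
                    f"{_genefam.max_abs_zscore(self.n_species):.3f} < 2 for "
                    f"n_species={self.n_species}; expansion/contraction infeasible"
                )

    @classmethod
    def from_class_counts(
        cls,
        n_expanded: int = 0,
        n_contracted: int = 0,
        n_lineage_specific: int = 0,
        n_neutral: int = 0,
        n_species: int = 9,
        seed: int = 0,
    ) -> "FamilyFixtureSpec":
        classes = (
            ["expanded"] * n_expanded
            + ["contracted"] * n_contracted
            + ["lineage_specific"] * n_lineage_specific
            + ["neutral"] * n_neutral
        )
        order = np.random.default_rng(seed).permutation(len(classes))
        planted = {f"OG{i:07d}": classes[order[i]] for i in range(len(classes))}
        return cls(n_species=n_species, planted=planted, seed=seed)


@dataclass
class FamilyFixture:
    counts: OrthogroupCounts
    truth: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts_matrix(self.counts, outdir / "gene_counts.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("orthogroup_id\tplanted_class\n")
            for og in sorted(self.truth):
                fh.write(f"{og}\t{self.truth[og]}\n")


def _focal_status(row: np.ndarray) -> str:
    """Sample-sd focal status of a count row (focal first), mirroring the
    default z-score rule; used for rejection-sampling neutral rows."""
    focal, others = row[0], row[1:]
    if focal >= 1 and (others == 0).all():
        return "lineage_specific"
    if not (focal >= 1 and (others >= 1).sum() >= 3):
        return "neutral"
    sd = row.std(ddof=1)
    if sd == 0:
        return "neutral"
    z = (focal - row.mean()) / sd
    if z >= 2:
        return "expanded"
    if z <= -2:
        return "contracted"
    return "neutral"


def generate_family_counts_fixture(spec: FamilyFixtureSpec) -> FamilyFixture:
    """Build an orthogroup x species count matrix realising ``spec.planted``.

    The focal species is the first column. Every planted expansion or
    contraction is verified against the sample-sd z-score rule before the
    matrix is returned; neutral rows are redrawn until they trigger no call.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_species
    species = ["focal"] + [f"sp{i:02d}" for i in range(1, n)]
    rows: dict[str, np.ndarray] = {}
    for og in sorted(spec.planted):
        cls = spec.planted[og]
        if cls == "expanded":
            b = int(rng.integers(1, 4))
            row = np.full(n, b)
            row[0] = b + int(rng.integers(5, 51))
        elif cls == "contracted":
            b = int(rng.integers(5, 16))
            row = np.full(n, b)
            row[0] = int(rng.integers(1, min(3, b)))
        elif cls == "lineage_specific":
            row = np.zeros(n, dtype=int)
            row[0] = int(rng.integers(1, 9))
        else:
            while True:
                row = rng.poisson(3.0, n)
                if _focal_status(row) == "neutral":
                    break
        status = _focal_status(row)
        if cls in {"expanded", "contracted", "lineage_specific"} and status != cls:
            raise AssertionError(f"planted {cls} row for {og} realised as {status}")
        rows[og] = row.astype(int)

    table = pd.DataFrame.from_dict(rows, orient="index", columns=species).astype(int)
    counts = OrthogroupCounts(table, focal_species="focal")
    return FamilyFixture(counts=counts, truth=dict(spec.planted))


# ---------------------------------------------------------------------------
# Genome fixtures (assembly stats + mito screen)


@dataclass
class GenomeFixture:
    scaffolds: dict[str, Scaffold]
    genes: list[GeneModel]
    mito: Scaffold
    truth: dict[str, bool]  # scaffold id -> is a planted mito fragment

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds.values(), outdir / "assembly.fasta")
        write_fasta([self.mito], outdir / "mito.fasta")
        write_gff3(self.genes, outdir / "genes.gff3")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("scaffold_id\tis_mito_fragment\n")
            for sid in sorted(self.truth):
                fh.write(f"{sid}\t{int(self.truth[sid])}\n")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.35) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=length, p=probs).tobytes().decode()


def generate_genome_fixture(
    n_scaffolds: int = 20,
    scaffold_lengths: list[int] | None = None,
    gene_density_per_kbp: float = 0.15,
    mito_length: int = 15000,
    n_mito_fragment_scaffolds: int = 2,
    gc: float = 0.35,
    seed: int = 0,
) -> GenomeFixture:
    """Random assembly with genes, a mitochondrial genome, and a planted set
    of scaffolds that are mostly verbatim (circular) mitochondrial sequence.

    Fragment scaffolds carry a mitochondrial substring covering 60-90% of
    their length, comfortably above the default 0.5 containment threshold of
    the screen; all other sequence is i.i.d. at the requested GC.
    """
    if n_mito_fragment_scaffolds > n_scaffolds:
        raise ValueError("more fragment scaffolds than scaffolds")
    if mito_length < 100:
        raise ValueError("mito_length too small")
    ss = np.random.SeedSequence(seed)
    rng_seq, rng_gene, rng_misc = (np.random.default_rng(c) for c in ss.spawn(3))

    mito = Scaffold("MT", _random_seq(rng_seq, mito_length, gc))
    circ = mito.sequence + mito.sequence

    if scaffold_lengths is None:
        lengths = [int(rng_misc.integers(3000, 30001)) for _ in range(n_scaffolds)]
    else:
        if len(scaffold_lengths) != n_scaffolds:
            raise ValueError("scaffold_lengths length mismatch")
        lengths = list(scaffold_lengths)

    frag_idx = set(
        int(i) for i in rng_misc.choice(n_scaffolds, n_mito_fragment_scaffolds, replace=False)
    )
    scaffolds: dict[str, Scaffold] = {}
    truth: dict[str, bool] = {}
    for i, L in enumerate(lengths):
        sid = f"scaffold_{i + 1:03d}"
        if i in frag_idx:
            L = min(L, int(mito_length / 0.95))
            frac = float(rng_misc.uniform(0.6, 0.9))
            frag_len = min(int(frac * L), mito_length)
            off = int(rng_misc.integers(0, mito_length))
            seq = circ[off : off + frag_len] + _random_seq(rng_seq, L - frag_len, gc)
            truth[sid] = True
        else:
            seq = _random_seq(rng_seq, L, gc)
            truth[sid] = False
        scaffolds[sid] = Scaffold(sid, seq)

    genes: list[GeneModel] = []
    gi = 0
    for sid, sc in scaffolds.items():
        n_genes = int(round(gene_density_per_kbp * sc.length / 1000))
        pos = 200
        for _ in range(n_genes):
            glen = int(rng_gene.integers(800, 3001))
            if pos + glen + 200 > sc.length:
                break
            start, end = pos + 1, pos + glen
            n_ex = int(rng_gene.integers(1, 4))
            bounds = sorted(
                {start - 1, end}
                | {int(rng_gene.integers(start, end)) for _ in range(2 * (n_ex - 1))}
            )
            exons = []
            # alternate exon/intron segments across the span
            for k in range(0, len(bounds) - 1, 2):
                exons.append((bounds[k] + 1, bounds[k + 1]))
            gi += 1
            genes.append(
                GeneModel(
                    f"gene_{gi:05d}",
                    sid,
                    start,
                    end,
                    "+" if rng_gene.random() < 0.5 else "-",
                    exons=exons or [(start, end)],
                )
            )
            pos = end + int(rng_gene.integers(300, 1500))

    genes.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    rank: dict[str, int] = {}
    for g in genes:
        g.order_index = rank.get(g.scaffold_id, 0)
        rank[g.scaffold_id] = g.order_index + 1
    return GenomeFixture(scaffolds=scaffolds, genes=genes, mito=mito, truth=truth)
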