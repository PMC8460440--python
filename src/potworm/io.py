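"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Gene models keep GFF3 coordinates: 1-based, inclusive on both ends.
Read intervals (PAF / BED) keep the 0-based half-open convention those
formats use. All overlap arithmetic elsewhere in the package converts gene
spans to 0-based half-open through :func:`gene_span0`, so the two
conventions never mix inside a computation.

Validation is strict by design: a malformed record raises
:class:`FormatError` carrying the offending line number, rather than being
silently skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "FormatError",
    "Scaffold",
    "GeneModel",
    "HomologyHit",
    "GeneTree",
    "ReadInterval",
    "OrthogroupCounts",
    "TAXON_GROUPS",
    "METAZOAN_GROUPS",
    "NONMETAZOAN_GROUPS",
    "gene_span0",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_tree",
    "read_read_intervals",
    "write_paf",
    "write_bed",
    "read_counts_matrix",
    "write_counts_matrix",
]

#: Database labels a homology hit can carry. ``metazoa_excl_annelida`` and
#: ``annelida`` together represent vertical (metazoan) inheritance; the rest
#: are candidate horizontal donors.
TAXON_GROUPS = frozenset(
    {
        "metazoa_excl_annelida",
        "annelida",
        "plants",
        "bacteria",
        "archaea",
        "protists",
        "fungi",
    }
)
METAZOAN_GROUPS = frozenset({"metazoa_excl_annelida", "annelida"})
NONMETAZOAN_GROUPS = frozenset(TAXON_GROUPS - METAZOAN_GROUPS)

# IUPAC nucleotide codes, including U and ambiguity codes.
_IUPAC = frozenset("ACGTUNRYSWKMBDHV")

BIOTYPES = ("protein_coding", "rRNA", "tRNA", "tRNA_pseudogene", "other")


class FormatError(ValueError):
    """A file violated its format contract.

    Carries the path and 1-based line number of the offending record when
    known, so callers can point users at the exact spot.
    """

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        self.path = str(path) if path is not None else None
        self.line = line
        loc = ""
        if self.path is not None:
            loc = f" [{self.path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


@dataclass(frozen=True)
class Scaffold:
    """One assembly scaffold: an id and its nucleotide sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with its scaffold placement (GFF3 1-based inclusive span).

    ``order_index`` is the gene's rank on its scaffold by ascending start
    (0-based); it is assigned by :func:`read_gene_models` and is what the
    HGT linkage rule means by "neighboring" (rank +/- 1).
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)
    order_index: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def gene_span0(gene: GeneModel) -> tuple[int, int]:
    """Gene span as a 0-based half-open interval (for overlap arithmetic)."""
    return gene.start - 1, gene.end


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular homology search, stamped with the
    taxon-group database it was searched against."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    taxon_group: str

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class ReadInterval:
    """A long-read alignment interval on a scaffold, 0-based half-open."""

    read_id: str
    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.read_id}: invalid interval [{self.start},{self.end})"
            )


class GeneTree:
    """A rooted gene tree whose leaves carry taxon-group labels.

    Leaf labels follow the ``group|sequence_id`` convention for database
    sequences; any label that does not start with a known taxon group is an
    unlabelled sequence (typically the focal-genome candidate). Backed by a
    :class:`dendropy.Tree`.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"invalid Newick: {exc}") from None
        gt = cls(tree)
        if not gt.leaf_labels():
            raise FormatError("tree has no labelled leaves")
        return gt

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon]

    @staticmethod
    def taxon_group_of(label: str) -> str | None:
        """Taxon group encoded in a leaf label, or None for focal sequences."""
        head = label.split("|", 1)[0]
        return head if head in TAXON_GROUPS else None

    def find_leaf(self, label: str):
        matches = [
            lf for lf in self.tree.leaf_node_iter() if lf.taxon and lf.taxon.label == label
        ]
        if not matches:
            raise KeyError(f"leaf {label!r} not in tree")
        if len(matches) > 1:
            raise ValueError(f"leaf {label!r} occurs {len(matches)} times")
        return matches[0]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class OrthogroupCounts:
    """Orthogroup x species gene-count matrix with a designated focal species.

    Wraps a pandas DataFrame (index: orthogroup ids, columns: species ids,
    values: non-negative integers).
    """

    table: pd.DataFrame
    focal_species: str

    def __post_init__(self) -> None:
        if self.focal_species not in self.table.columns:
            raise ValueError(
                f"focal species {self.focal_species!r} not among species "
                f"{list(self.table.columns)}"
            )
        if (self.table.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def other_species(self) -> list[str]:
        return [s for s in self.species_ids if s != self.focal_species]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, Scaffold]:
    """Parse a FASTA file into scaffolds keyed by id (input order preserved).

    Ids are truncated at the first whitespace. Wrapped sequence lines are
    concatenated. Empty records, duplicate ids and non-IUPAC characters are
    format errors naming the offending line.
    """
    scaffolds: dict[str, Scaffold] = {}
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {cur_id!r} has no sequence", path, cur_line)
        scaffolds[cur_id] = Scaffold(cur_id, seq)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                new_id = line[1:].split()[0] if line[1:].split() else ""
                if not new_id:
                    raise FormatError("empty FASTA header", path, lineno)
                if new_id in seen:
                    raise FormatError(f"duplicate scaffold id {new_id!r}", path, lineno)
                seen.add(new_id)
                _flush()
                cur_id = new_id
                cur_line = lineno
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError("sequence before first '>' header", path, lineno)
                bad = set(line.upper()) - _IUPAC
                if bad:
                    raise FormatError(
                        f"non-IUPAC character(s) {sorted(bad)} in record {cur_id!r}",
                        path,
                        lineno,
                    )
                chunks.append(line.upper())
        _flush()
    if not scaffolds:
        raise FormatError("no FASTA records found", path)
    return scaffolds


def write_fasta(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id}\n")
            for i in range(0, len(sc.sequence), width):
                fh.write(sc.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_GENE_TYPES = {"gene"}
_GFF_RNA_TYPES = {"mRNA", "rRNA", "tRNA", "tRNA_pseudogene", "pseudogenic_tRNA"}


def _gff_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merged and sorted."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def read_gene_models(
    path: str | Path, assembly: Mapping[str, Scaffold] | None = None
) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon plus rRNA/tRNA features).

    One :class:`GeneModel` per ``gene`` feature; exon intervals are attached
    through their mRNA parents and unioned per gene (isoform exons merged).
    Gene-order indices are assigned per scaffold by ascending start. When an
    ``assembly`` is supplied, genes on unknown scaffolds (or extending past
    the scaffold end) are errors.
    """
    genes: dict[str, GeneModel] = {}
    gene_lines: dict[str, int] = {}
    rna_parent: dict[str, str] = {}  # mRNA id -> gene id
    exons: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"expected 9 tab-separated columns, got {len(cols)}", path, lineno
                )
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer coordinate", path, lineno) from None
            if end < start:
                raise FormatError(f"end < start ({start_s}..{end_s})", path, lineno)
            attrs = _gff_attributes(attrs_s)
            if ftype in _GFF_GENE_TYPES:
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError("gene feature without ID", path, lineno)
                if gid in genes:
                    raise FormatError(f"duplicate gene id {gid!r}", path, lineno)
                if assembly is not None:
                    if seqid not in assembly:
                        raise FormatError(f"unknown scaffold {seqid!r}", path, lineno)
                    if end > assembly[seqid].length:
                        raise FormatError(
                            f"gene {gid!r} extends past scaffold end", path, lineno
                        )
                biotype = attrs.get("gene_biotype", attrs.get("biotype", "protein_coding"))
                if biotype not in BIOTYPES:
                    biotype = "other"
                genes[gid] = GeneModel(gid, seqid, start, end, strand, biotype)
                gene_lines[gid] = lineno
            elif ftype in _GFF_RNA_TYPES:
                rid, parent = attrs.get("ID"), attrs.get("Parent")
                if rid and parent:
                    rna_parent[rid] = parent
                if ftype != "mRNA" and parent in genes and genes[parent].biotype == "protein_coding":
                    # infer biotype for genes whose transcript is non-coding
                    bt = "tRNA_pseudogene" if ftype == "pseudogenic_tRNA" else ftype
                    genes[parent].biotype = bt if bt in BIOTYPES else "other"
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError("exon without Parent", path, lineno)
                gid = rna_parent.get(parent, parent)
                exons.setdefault(gid, []).append((start, end))

    for gid, ivals in exons.items():
        if gid not in genes:
            continue
        g = genes[gid]
        merged = _merge_intervals(ivals)
        for s, e in merged:
            if s < g.start or e > g.end:
                raise FormatError(
                    f"exon {s}..{e} outside gene {gid!r} span {g.start}..{g.end}",
                    path,
                    gene_lines[gid],
                )
        g.exons = merged

    out = sorted(genes.values(), key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    rank: dict[str, int] = {}
    for g in out:
        idx = rank.get(g.scaffold_id, 0)
        g.order_index = idx
        rank[g.scaffold_id] = idx + 1
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with one mRNA per protein-coding gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};gene_biotype={g.biotype}"
            fh.write(
                f"{g.scaffold_id}\tpotworm\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            if g.biotype == "protein_coding":
                mid = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.scaffold_id}\tpotworm\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={mid};Parent={g.gene_id}\n"
                )
                for s, e in g.exons or [(g.start, g.end)]:
                    fh.write(
                        f"{g.scaffold_id}\tpotworm\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_HIT_COLS = 12


def read_hit_table(path: str | Path, taxon_group: str) -> list[HomologyHit]:
    """Parse a 12-column BLAST tabular file, stamping every row with
    ``taxon_group``. No deduplication or filtering is applied on read."""
    if taxon_group not in TAXON_GROUPS:
        raise ValueError(f"unknown taxon group {taxon_group!r}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_COLS:
                raise FormatError(
                    f"expected {_HIT_COLS} columns, got {len(cols)}", path, lineno
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                        taxon_group=taxon_group,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"unparsable field: {exc}", path, lineno) from None
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick


def read_tree(path: str | Path) -> GeneTree:
    """Read a single rooted Newick tree (must be ';'-terminated)."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise FormatError("Newick string not terminated by ';'", path)
    try:
        return GeneTree.from_newick(text)
    except FormatError as exc:
        raise FormatError(str(exc), path) from None


# ---------------------------------------------------------------------------
# Read intervals (PAF / BED)


def read_read_intervals(path: str | Path, dialect: str) -> list[ReadInterval]:
    """Parse long-read alignment intervals from PAF or BED3+.

    Both dialects are 0-based half-open on the target; PAF target fields are
    columns 6-9 (name, length, start, end).
    """
    if dialect not in {"paf", "bed"}:
        raise ValueError("dialect must be 'paf' or 'bed'")
    out: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "paf":
                    if len(cols) < 12:
                        raise FormatError("PAF needs >= 12 columns", path, lineno)
                    read_id, scaf = cols[0], cols[5]
                    start, end = int(cols[7]), int(cols[8])
                else:
                    if len(cols) < 3:
                        raise FormatError("BED needs >= 3 columns", path, lineno)
                    scaf = cols[0]
                    start, end = int(cols[1]), int(cols[2])
                    read_id = cols[3] if len(cols) > 3 else f"interval{lineno}"
                if end <= start:
                    raise FormatError(f"end <= start ({start}, {end})", path, lineno)
                out.append(ReadInterval(read_id, scaf, start, end))
            except ValueError:
                raise FormatError("non-integer coordinate", path, lineno) from None
    return out


def write_paf(intervals: Iterable[ReadInterval], path: str | Path) -> None:
    """Write intervals as minimal 12-column PAF records."""
    with open(path, "w") as fh:
        for iv in intervals:
            span = iv.end - iv.start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iv.read_id, span, 0, span, "+",
                        iv.scaffold_id, iv.end, iv.start, iv.end,
                        span, span, 60,
                    )
                )
                + "\n"
            )


def write_bed(intervals: Iterable[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{iv.read_id}\n")


# ---------------------------------------------------------------------------
# Orthogroup count matrices


def read_counts_matrix(path: str | Path, focal_species: str) -> OrthogroupCounts:
    """Read an orthogroup gene-count TSV (species in header, one row per
    orthogroup; a trailing ``Total`` column is dropped by name)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"unreadable counts table: {exc}", path) from None
    if "Total" in df.columns:
        df = df.drop(columns=["Total"])
    if focal_species not in df.columns:
        raise FormatError(
            f"focal species {focal_species!r} absent from header "
            f"{list(df.columns)}", path
        )
    for col in df.columns if len(df) else []:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals):
            raise FormatError(f"non-numeric counts in column {col!r}", path)
        if (vals % 1 != 0).any():
            raise FormatError(f"non-integer count in column {col!r}", path)
        if (vals < 0).any():
            raise FormatError(f"negative count in column {col!r}", path)
    df = df.astype(int)
    df.index = df.index.astype(str)
    return OrthogroupCounts(df, focal_species)


def write_counts_matrix(counts: OrthogroupCounts, path: str | Path) -> None:
    counts.table.rename_axis("Orthogroup").to_csv(path, sep="\t")
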