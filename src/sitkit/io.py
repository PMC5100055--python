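"""Readers and writers for the interchange formats used across the toolkit.

All other modules consume only the record types defined here.  Project
labels travel inside sequence identifiers as ``project|contig`` so that
every interchange file is self-describing; coordinates are 1-based
inclusive throughout, matching the 12-column tabular output convention
of standard local aligners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DataError",
    "ContigRecord",
    "ProteinRecord",
    "Hit",
    "ExpressionRecord",
    "read_fasta",
    "write_fasta",
    "split_seqid",
    "join_seqid",
    "read_hits_table",
    "write_hits_table",
    "read_counts_table",
    "write_counts_table",
    "parse_newick",
    "write_newick",
    "write_report_tsv",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

COUNTS_TOTAL_MARKER = "*"  # contig_id of the per-project total-reads row


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide contig; lowercase positions are soft-masked."""

    project: str
    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def seqid(self) -> str:
        return join_seqid(self.project, self.contig_id)

    def validate(self) -> None:
        bad = set(self.sequence.upper()) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c.upper() in bad
            )
            raise DataError(
                f"illegal nucleotide character {self.sequence[pos]!r} at "
                f"position {pos + 1} in {self.seqid}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein linked back to its source contig."""

    project: str
    protein_id: str
    contig_id: str
    sequence: str

    @property
    def seqid(self) -> str:
        return join_seqid(self.project, self.protein_id)

    def validate(self) -> None:
        if not self.sequence:
            raise DataError(f"empty protein sequence for {self.seqid}")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c.upper() in bad
            )
            raise DataError(
                f"illegal amino-acid character {self.sequence[pos]!r} at "
                f"position {pos + 1} in {self.seqid}"
            )


@dataclass(frozen=True)
class Hit:
    """One pairwise local alignment between contigs of different projects.

    Coordinates are 1-based inclusive on the forward strand of each
    contig; ``strand`` records the orientation of the subject.
    """

    q_project: str
    q_contig: str
    s_project: str
    s_contig: str
    pident: float
    aln_len: int
    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_project == self.s_project:
            raise DataError(
                "within-project hit "
                f"{self.q_project}|{self.q_contig} vs "
                f"{self.s_project}|{self.s_contig}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise DataError(f"pident {self.pident} outside [0, 100]")
        if self.aln_len < 1:
            raise DataError(f"alignment length {self.aln_len} < 1")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.q_project, self.s_project))

    @property
    def contig_pair(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            ((self.q_project, self.q_contig), (self.s_project, self.s_contig))
        )


@dataclass
class ExpressionRecord:
    """Per-contig mapped read count with its project library size."""

    project: str
    contig_id: str
    read_count: int
    project_total_reads: int
    rpkm: float | None = None


@dataclass(frozen=True)
class FastaRecord:
    """A raw FASTA entry (id and sequence, case preserved)."""

    id: str
    sequence: str


def split_seqid(seqid: str) -> tuple[str, str]:
    """Split a ``project|contig`` identifier."""
    if "|" not in seqid:
        raise DataError(f"sequence id {seqid!r} lacks a 'project|' prefix")
    project, _, contig = seqid.partition("|")
    if not project or not contig:
        raise DataError(f"sequence id {seqid!r} has an empty component")
    return project, contig


def join_seqid(project: str, contig_id: str) -> str:
    return f"{project}|{contig_id}"


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[FastaRecord]:
    """Read a FASTA file, preserving case and order.

    Duplicate ids and characters outside the chosen alphabet raise
    :class:`DataError`; an empty file yields an empty list with a warning.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        bad = set(seq.upper()) - allowed
        if bad:
            pos = next(i for i, c in enumerate(seq) if c.upper() in bad)
            raise DataError(
                f"illegal character {seq[pos]!r} at position {pos + 1} "
                f"of sequence {rec.id!r} in {path}"
            )
        records.append(FastaRecord(rec.id, seq))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with ``.seqid``/``.id`` and ``.sequence``)."""
    out = []
    for rec in records:
        seqid = getattr(rec, "seqid", None) or getattr(rec, "id")
        out.append(SeqRecord(Seq(rec.sequence), id=seqid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


def contigs_from_fasta(path: str | Path, project: str | None = None) -> list[ContigRecord]:
    """Load contigs, taking the project label from the ``project|`` id prefix.

    If ids carry no prefix, ``project`` must be supplied.
    """
    contigs = []
    for rec in read_fasta(path, "nucleotide"):
        if "|" in rec.id:
            proj, cid = split_seqid(rec.id)
            if project is not None and proj != project:
                raise DataError(
                    f"sequence {rec.id!r} in {path} does not belong to "
                    f"project {project!r}"
                )
        elif project is not None:
            proj, cid = project, rec.id
        else:
            raise DataError(
                f"sequence id {rec.id!r} lacks a project prefix and no "
                "project label was given"
            )
        contig = ContigRecord(proj, cid, rec.sequence)
        contig.validate()
        contigs.append(contig)
    return contigs


def proteins_from_fasta(path: str | Path, project: str | None = None) -> list[ProteinRecord]:
    """Load proteins; ids are ``project|protein`` and the source contig is
    taken to be the protein id with any trailing ``.pN`` ORF suffix removed."""
    proteins = []
    for rec in read_fasta(path, "protein"):
        if "|" in rec.id:
            proj, pid = split_seqid(rec.id)
        elif project is not None:
            proj, pid = project, rec.id
        else:
            raise DataError(
                f"sequence id {rec.id!r} lacks a project prefix and no "
                "project label was given"
            )
        contig_id = pid.rsplit(".p", 1)[0] if ".p" in pid else pid
        protein = ProteinRecord(proj, pid, contig_id, rec.sequence)
        protein.validate()
        proteins.append(protein)
    return proteins


# ---------------------------------------------------------------------------
# 12-column tabular hit files (qseqid sseqid pident length mismatch gapopen
# qstart qend sstart send evalue bitscore)
# ---------------------------------------------------------------------------

def read_hits_table(path: str | Path) -> tuple[list[Hit], int]:
    """Parse a 12-column tabular hit file.

    Rows whose query and subject belong to the same project are dropped
    (the procedure compares sequencing projects, never a project against
    itself); the number of dropped rows is returned alongside the hits.
    Subject strand is inferred from ``sstart > send``.
    """
    hits: list[Hit] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise DataError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                q_project, q_contig = split_seqid(fields[0])
                s_project, s_contig = split_seqid(fields[1])
                pident = float(fields[2])
                aln_len = int(fields[3])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
                score = float(fields[11])
            except (ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            if q_project == s_project:
                n_dropped += 1
                continue
            strand = "+"
            if s_start > s_end:
                strand = "-"
                s_start, s_end = s_end, s_start
            hits.append(
                Hit(
                    q_project, q_contig, s_project, s_contig,
                    pident=pident, aln_len=aln_len, score=score,
                    q_start=q_start, q_end=q_end,
                    s_start=s_start, s_end=s_end, strand=strand,
                )
            )
    return hits, n_dropped


def write_hits_table(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            s_start, s_end = h.s_start, h.s_end
            if h.strand == "-":
                s_start, s_end = s_end, s_start
            mismatch = round(h.aln_len * (1.0 - h.pident / 100.0))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        join_seqid(h.q_project, h.q_contig),
                        join_seqid(h.s_project, h.s_contig),
                        f"{h.pident:.2f}", h.aln_len, mismatch, 0,
                        h.q_start, h.q_end, s_start, s_end,
                        "0.0", f"{h.score:g}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count tables: TSV of (project, contig_id, read_count); a row whose
# contig_id is "*" carries the project's total mapped reads.
# ---------------------------------------------------------------------------

def read_counts_table(path: str | Path) -> tuple[list[ExpressionRecord], dict[str, int]]:
    """Read per-contig mapped read counts plus per-project totals.

    Returns the expression records (RPKM left unset) and a mapping of
    project label to total mapped reads.  A contig whose project has no
    total row, or a negative count, is an error.
    """
    rows: list[tuple[str, str, int]] = []
    totals: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise DataError(
                    f"{path}:{lineno}: expected 3 columns "
                    "(project, contig_id, read_count)"
                )
            project, contig_id, count_s = fields
            try:
                count = int(count_s)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad count {count_s!r}") from exc
            if count < 0:
                raise DataError(f"{path}:{lineno}: negative read count {count}")
            if contig_id == COUNTS_TOTAL_MARKER:
                if count < 1:
                    raise DataError(
                        f"{path}:{lineno}: project total for {project} must be >= 1"
                    )
                totals[project] = count
            else:
                rows.append((project, contig_id, count))
    records = []
    for project, contig_id, count in rows:
        if project not in totals:
            raise DataError(
                f"{path}: no total-reads row (contig_id '*') for project {project}"
            )
        records.append(ExpressionRecord(project, contig_id, count, totals[project]))
    return records, totals


def write_counts_table(
    records: Iterable[ExpressionRecord], totals: dict[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for project in sorted(totals):
            fh.write(f"{project}\t{COUNTS_TOTAL_MARKER}\t{totals[project]}\n")
        for r in records:
            fh.write(f"{r.project}\t{r.contig_id}\t{r.read_count}\n")


# ---------------------------------------------------------------------------
# Newick trees with numeric internal-node support labels
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; numeric internal labels become ``node.support``.

    Unbalanced parentheses raise :class:`DataError` with the character
    offset of the first imbalance.
    """
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise DataError(
                    f"unbalanced ')' at character offset {offset} in newick string"
                )
    if depth != 0:
        raise DataError(
            f"unbalanced '(' in newick string: {depth} unclosed at end "
            f"(offset {len(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise DataError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise DataError(f"duplicate leaf labels in tree: {dup}")
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                continue
            if not (0.0 <= support <= 100.0):
                raise DataError(f"support value {support} outside [0, 100]")
            node.support = support
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            sup = getattr(node, "support", None)
            node.label = None if sup is None else f"{sup:g}"
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


# ---------------------------------------------------------------------------
# Report TSVs
# ---------------------------------------------------------------------------

def write_report_tsv(
    path: str | Path,
    header: list[str],
    rows: Iterable[Iterable],
    meta: dict | None = None,
) -> None:
    """Write a TSV report with a commented metadata line."""
    from . import __version__

    with open(path, "w") as fh:
        parts = [f"sitkit v{__version__}"]
        for key, value in (meta or {}).items():
            parts.append(f"{key}={value}")
        fh.write("# " + " ".join(parts) + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
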