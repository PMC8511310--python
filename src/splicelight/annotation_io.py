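"""Transcript models and GFF3 input/output.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` on a named
chromosome and strand, the convention of BED and most Python genomics code.
GFF3 files use 1-based closed coordinates; the conversion happens only at
the file boundary (:func:`read_gff3` / :func:`write_gff3`).

The reference isoform of a gene is its longest isoform measured in spliced
(exonic) nucleotides; ties go to the lexicographically smallest transcript
id so the choice is deterministic and independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "AnnotationError",
    "GFF3ParseError",
    "read_gff3",
    "write_gff3",
    "spliced_length",
    "select_ref_isoform",
    "intron_chain",
    "transcript_span",
]


class AnnotationError(ValueError):
    """A transcript/gene model violates a structural invariant."""


class GFF3ParseError(ValueError):
    """The GFF3 file itself is malformed (bad linkage, bad columns)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_strictly(self, other: "GenomicInterval") -> bool:
        """True if *other* lies strictly inside this interval (no shared ends)."""
        return self.start < other.start and other.end < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def shift(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta, self.strand)


@dataclass
class TranscriptModel:
    """An isoform: ordered, non-overlapping exons on one chromosome strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes {chroms}"
            )
        if len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or abut "
                    f"({a.start},{a.end}) / ({b.start},{b.end}); introns need length >= 1"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class GeneModel:
    """All isoforms of one gene plus the designated reference isoform."""

    gene_id: str
    transcripts: list[TranscriptModel]
    ref_transcript_id: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if self.ref_transcript_id not in ids:
            raise AnnotationError(
                f"gene {self.gene_id}: ref transcript {self.ref_transcript_id!r} "
                "is not a member"
            )
        if len({t.chrom for t in self.transcripts}) > 1 or len(
            {t.strand for t in self.transcripts}
        ) > 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts disagree on chromosome/strand"
            )

    @property
    def ref_transcript(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.ref_transcript_id:
                return t
        raise AssertionError("unreachable: validated in __post_init__")

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class AnnotationSet:
    """A collection of gene models, e.g. one tissue's isoform set."""

    genes: dict[str, GeneModel]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id in seen:
                    raise AnnotationError(
                        f"duplicate transcript id {t.transcript_id!r} across the set"
                    )
                seen.add(t.transcript_id)

    def transcripts(self):
        for g in self.genes.values():
            yield from g.transcripts

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def spliced_length(t: TranscriptModel) -> int:
    """Total exonic length of a transcript in nucleotides."""
    return sum(e.length for e in t.exons)


def transcript_span(t: TranscriptModel) -> GenomicInterval:
    """Genomic extent from the first exon start to the last exon end."""
    return GenomicInterval(t.chrom, t.exons[0].start, t.exons[-1].end, t.strand)


def select_ref_isoform(g: GeneModel) -> str:
    """Longest-isoform rule: id of the transcript maximizing spliced length.

    Ties break to the lexicographically smallest transcript id, so the
    result does not depend on the order transcripts were listed.
    """
    return min(
        g.transcripts, key=lambda t: (-spliced_length(t), t.transcript_id)
    ).transcript_id


def intron_chain(t: TranscriptModel) -> tuple[GenomicInterval, ...]:
    """Gaps between consecutive exons, 0-based half-open; empty if monoexonic."""
    return tuple(
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    )


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_SOURCE_LABEL_DIRECTIVE = "#!source-label"


def _prescan_linkage(path: str) -> None:
    """Check that every Parent attribute refers to a declared ID.

    GFF3 permits forward references, so IDs are collected in a first pass and
    Parent references verified in a second; errors name the offending line.
    """
    ids: set[str] = set()
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            attrs = cols[8]
            for fld in attrs.split(";"):
                if fld.startswith("ID="):
                    ids.add(fld[3:])
            rows.append((lineno, attrs))
    for lineno, attrs in rows:
        for fld in attrs.split(";"):
            if fld.startswith("Parent="):
                for parent in fld[7:].split(","):
                    if parent and parent not in ids:
                        raise GFF3ParseError(
                            f"{path}:{lineno}: Parent={parent} refers to an undeclared ID"
                        )


def _clean_attributes(feature) -> dict:
    """gffutils attributes minus structural keys, values as tuples."""
    out = {}
    for key, values in feature.attributes.items():
        if key in ("ID", "Parent"):
            continue
        out[key] = tuple(values)
    return out


def read_gff3(path: str) -> AnnotationSet:
    """Read a gene/mRNA/exon GFF3 file into an :class:`AnnotationSet`.

    GFF3 1-based closed coordinates are converted to internal 0-based
    half-open intervals. The reference isoform of every gene is assigned by
    the longest-isoform rule. Transcripts without exon children are dropped
    with a warning; a gene losing all transcripts is dropped too.
    """
    _prescan_linkage(path)
    source_label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith(_SOURCE_LABEL_DIRECTIVE):
                source_label = line[len(_SOURCE_LABEL_DIRECTIVE):].strip()
            elif not line.startswith("#"):
                break
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
            sort_attribute_values=False,
        )
    except gffutils.exceptions.EmptyInputError:
        return AnnotationSet(genes={}, source_label=source_label)
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, level=1, order_by="start"):
            if mrna.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = [
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
                for ex in db.children(mrna, featuretype="exon", order_by="start")
            ]
            if not exons:
                warnings.warn(
                    f"transcript {mrna.id} has no exon children; rejected",
                    stacklevel=2,
                )
                continue
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene.id,
                    exons=tuple(exons),
                    attributes=_clean_attributes(mrna),
                )
            )
        if not transcripts:
            continue
        ref_id = min(
            transcripts, key=lambda t: (-spliced_length(t), t.transcript_id)
        ).transcript_id
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            transcripts=transcripts,
            ref_transcript_id=ref_id,
            attributes=_clean_attributes(gene),
        )
    return AnnotationSet(genes=genes, source_label=source_label)


_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09"}


def _escape(value: str) -> str:
    for raw, enc in _ESCAPES.items():
        value = value.replace(raw, enc)
    return value


def _format_attrs(pairs: list[tuple[str, str]], extra: dict) -> str:
    parts = [f"{k}={_escape(v)}" for k, v in pairs]
    for key, values in extra.items():
        parts.append(f"{_escape(key)}={','.join(_escape(v) for v in values)}")
    return ";".join(parts)


def write_gff3(ann: AnnotationSet, path: str) -> None:
    """Write an :class:`AnnotationSet` as GFF3 (1-based closed coordinates).

    Output ordering is deterministic: genes by id, transcripts by id, exons
    by start. Attributes beyond ID/Parent are carried through opaquely, so
    ``read_gff3(write_gff3(ann))`` round-trips the model exactly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if ann.source_label:
            fh.write(f"{_SOURCE_LABEL_DIRECTIVE} {ann.source_label}\n")
        for gene_id in sorted(ann.genes):
            g = ann.genes[gene_id]
            chrom = g.transcripts[0].chrom
            strand = g.transcripts[0].strand
            gstart = min(t.exons[0].start for t in g.transcripts)
            gend = max(t.exons[-1].end for t in g.transcripts)
            fh.write(
                "\t".join(
                    [
                        chrom,
                        "splicelight",
                        "gene",
                        str(gstart + 1),
                        str(gend),
                        ".",
                        strand,
                        ".",
                        _format_attrs([("ID", gene_id)], g.attributes),
                    ]
                )
                + "\n"
            )
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                fh.write(
                    "\t".join(
                        [
                            chrom,
                            "splicelight",
                            "mRNA",
                            str(t.exons[0].start + 1),
                            str(t.exons[-1].end),
                            ".",
                            strand,
                            ".",
                            _format_attrs(
                                [("ID", t.transcript_id), ("Parent", gene_id)],
                                t.attributes,
                            ),
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                chrom,
                                "splicelight",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                strand,
                                ".",
                                f"Parent={_escape(t.transcript_id)}",
                            ]
                        )
                        + "\n"
                    )
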