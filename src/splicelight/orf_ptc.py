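"""Premature-termination-codon assessment for intron-retention isoforms.

A retained intron inserts genomic sequence into the mature transcript. If
that insertion carries an in-frame stop, or shifts the reading frame so a
downstream stop appears before the position where the reference isoform
terminates, the isoform carries a premature termination codon (PTC) and may
produce a truncated protein. PTC-bearing transcripts whose stop lies more
than 50 nt upstream of the last exon-exon junction are flagged as
candidates for nonsense-mediated decay (NMD), the canonical 50-nt rule.

No CDS annotation is consumed: the reference reading frame is taken to be
the longest ATG-initiated open reading frame of the reference isoform's
spliced sequence (ties going to the 5'-most start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .annotation_io import GenomicInterval, TranscriptModel, spliced_length
from .as_classify import ASEvent, EventType

__all__ = [
    "OrfAnnotation",
    "CodingAssessment",
    "extract_spliced_sequence",
    "find_reference_orf",
    "assess_ptc",
    "transcript_to_genomic",
    "genomic_to_transcript",
]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame in transcript coordinates, stop included."""

    start: int
    stop_end: int  # exclusive end of the stop codon

    def __post_init__(self) -> None:
        if (self.stop_end - self.start) % 3 != 0 or self.stop_end - self.start < 6:
            raise ValueError("ORF length must be >= 6 and divisible by 3")

    @property
    def length(self) -> int:
        return self.stop_end - self.start


@dataclass
class CodingAssessment:
    """PTC/NMD verdict for one intron-retaining isoform."""

    alt_id: str
    has_ptc: bool
    ptc_transcript_pos: int | None
    ptc_in_retained_intron: bool
    nmd_candidate: bool
    truncation_note: str

    def __post_init__(self) -> None:
        if not self.has_ptc:
            assert self.ptc_transcript_pos is None
            assert not self.ptc_in_retained_intron and not self.nmd_candidate


def extract_spliced_sequence(genome: Mapping, t: TranscriptModel) -> str:
    """Concatenate exon sequences 5'->3' in transcript orientation.

    *genome* maps chromosome name to a sliceable sequence (a dict of
    strings, or a ``pyfaidx.Fasta``). Minus-strand transcripts are
    reverse-complemented.
    """
    try:
        chrom_seq = genome[t.chrom]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome {t.chrom!r}") from exc
    chrom_len = len(chrom_seq)
    parts = []
    for e in t.exons:
        if e.end > chrom_len:
            raise ValueError(
                f"{t.transcript_id}: exon [{e.start},{e.end}) exceeds "
                f"{t.chrom} length {chrom_len}"
            )
        parts.append(str(chrom_seq[e.start : e.end]))
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def find_reference_orf(seq: str) -> OrfAnnotation | None:
    """Longest ATG-initiated ORF ending in a stop codon; None if noncoding.

    Ties on length break to the smallest (5'-most) start position.
    """
    seq = seq.upper()
    best: OrfAnnotation | None = None
    # first stop position per frame, computed left-to-right once per frame
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG" and not open_starts:
                open_starts.append(pos)
            elif codon in STOP_CODONS and open_starts:
                cand = OrfAnnotation(start=open_starts[0], stop_end=pos + 3)
                if best is None or (cand.length, -cand.start) > (best.length, -best.start):
                    best = cand
                open_starts.clear()
    return best


def transcript_to_genomic(t: TranscriptModel, pos: int) -> int:
    """Genomic coordinate of transcript position *pos* (0-based, strand-aware)."""
    n = spliced_length(t)
    if not 0 <= pos < n:
        raise IndexError(f"transcript position {pos} outside [0, {n})")
    if t.strand == "-":
        pos = n - 1 - pos
    for e in t.exons:
        if pos < e.length:
            return e.start + pos
        pos -= e.length
    raise AssertionError("unreachable")


def genomic_to_transcript(t: TranscriptModel, gpos: int) -> int | None:
    """Transcript coordinate of genomic base *gpos*, or None if intronic/outside."""
    offset = 0
    plus_pos = None
    for e in t.exons:
        if e.start <= gpos < e.end:
            plus_pos = offset + (gpos - e.start)
            break
        offset += e.length
    if plus_pos is None:
        return None
    if t.strand == "-":
        return spliced_length(t) - 1 - plus_pos
    return plus_pos


def _retained_segments(alt: TranscriptModel, events: list[ASEvent]) -> list[tuple[int, int]]:
    """Transcript-coordinate intervals of introns retained in *alt*."""
    segs = []
    for e in events:
        if e.type is not EventType.IR or e.retained_in != "alt":
            continue
        lo = genomic_to_transcript(alt, e.region.start)
        hi = genomic_to_transcript(alt, e.region.end - 1)
        if lo is None or hi is None:
            continue
        a, b = sorted((lo, hi))
        segs.append((a, b + 1))
    return segs


def assess_ptc(
    genome: Mapping,
    ref: TranscriptModel,
    alt: TranscriptModel,
    events: list[ASEvent],
) -> CodingAssessment:
    """Decide whether the retained intron(s) of *alt* introduce a PTC.

    The reference ORF start is projected through shared exonic sequence
    into *alt* (the genomic base of the reference ATG must be exonic in
    *alt*); translation then proceeds codon by codon. ``has_ptc`` is true
    iff an in-frame stop occurs strictly before the position corresponding
    to the reference stop codon. ``nmd_candidate`` applies the 50-nt
    last-junction rule.
    """

    def _not_assessable(note: str) -> CodingAssessment:
        return CodingAssessment(
            alt_id=alt.transcript_id,
            has_ptc=False,
            ptc_transcript_pos=None,
            ptc_in_retained_intron=False,
            nmd_candidate=False,
            truncation_note=note,
        )

    ref_seq = extract_spliced_sequence(genome, ref)
    orf = find_reference_orf(ref_seq)
    if orf is None:
        return _not_assessable("not assessable: reference isoform noncoding")

    start_g = transcript_to_genomic(ref, orf.start)
    alt_start = genomic_to_transcript(alt, start_g)
    if alt_start is None:
        return _not_assessable("not assessable: reference start codon not exonic in isoform")

    alt_seq = extract_spliced_sequence(genome, alt)
    if alt_seq[alt_start : alt_start + 3] != "ATG":
        return _not_assessable("not assessable: projected start is not ATG in isoform")

    # position in alt corresponding to the reference stop codon's first base
    ref_stop_g = transcript_to_genomic(ref, orf.stop_end - 3)
    alt_ref_stop = genomic_to_transcript(alt, ref_stop_g)

    first_stop = None
    for pos in range(alt_start, len(alt_seq) - 2, 3):
        if alt_seq[pos : pos + 3] in STOP_CODONS:
            first_stop = pos
            break

    retained = _retained_segments(alt, events)
    retained_len = sum(b - a for a, b in retained)
    in_frame_insertion = retained_len % 3 == 0

    if first_stop is None:
        return _not_assessable("no stop codon reached in isoform (read-through)")

    is_premature = alt_ref_stop is None or first_stop < alt_ref_stop
    if not is_premature:
        note = (
            "in-frame insertion"
            if in_frame_insertion
            else "stop at reference position"
        )
        return _not_assessable(note)

    in_retained = any(
        first_stop < b and a < first_stop + 3 for a, b in retained
    )
    # last exon-exon junction position in transcript coordinates
    if len(alt.exons) >= 2:
        if alt.strand == "+":
            last_junction = spliced_length(alt) - alt.exons[-1].length
        else:
            last_junction = spliced_length(alt) - alt.exons[0].length
        nmd = last_junction - (first_stop + 3) > 50
    else:
        nmd = False

    note = "frameshift truncation" if retained_len % 3 else "in-frame premature stop"
    return CodingAssessment(
        alt_id=alt.transcript_id,
        has_ptc=True,
        ptc_transcript_pos=first_stop,
        ptc_in_retained_intron=in_retained,
        nmd_candidate=nmd,
        truncation_note=note,
    )
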