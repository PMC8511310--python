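"""Alternative-splicing event classification against a reference isoform.

Each non-reference isoform of a gene is compared with the gene's reference
(longest) isoform and the local differences between their intron chains are
typed into five categories:

``IR``
    intron retention — an intron of one isoform is exonic in the other;
``ES``
    exon skipping — an internal reference exon spanned by a single
    alternative intron whose outer splice sites match the reference;
``AA`` / ``AD``
    alternative 3'/5' splice site — two introns share exactly one boundary
    and the moving boundary is nearer the transcript 3' (AA) or 5' (AD)
    end, judged strand-aware;
``OTHER``
    any remaining intron-chain difference (mutually exclusive exons,
    complex nests), one event per maximal differing region.

Differences confined to the genomic endpoints of the first/last exon (an
alternative transcription start or end with an identical intron chain) are
not splicing events and yield nothing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    intron_chain,
    spliced_length,
)

__all__ = [
    "EventType",
    "ASEvent",
    "IsoformClassification",
    "ASSummary",
    "classify_pair",
    "classify_annotation",
    "merge_across_sources",
    "summarize",
    "events_to_frame",
]


class EventType(str, enum.Enum):
    IR = "IR"
    AA = "AA"
    AD = "AD"
    ES = "ES"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ASEvent:
    """One typed local difference between an isoform and its reference."""

    type: EventType
    gene_id: str
    ref_id: str
    alt_id: str
    region: GenomicInterval
    retained_in: str = "n/a"  # {"alt", "ref", "n/a"}

    def __post_init__(self) -> None:
        if self.type is EventType.IR and self.retained_in not in ("alt", "ref"):
            raise ValueError("IR events must set retained_in to 'alt' or 'ref'")


@dataclass
class IsoformClassification:
    """All events of one non-reference isoform, plus its source labels."""

    alt_id: str
    gene_id: str
    events: list[ASEvent]
    sources: set[str]
    alt_model: TranscriptModel | None = field(default=None, compare=False, repr=False)
    ref_model: TranscriptModel | None = field(default=None, compare=False, repr=False)

    @property
    def is_as(self) -> bool:
        return len(self.events) > 0

    @property
    def event_types(self) -> frozenset[EventType]:
        return frozenset(e.type for e in self.events)


@dataclass
class ASSummary:
    """Dataset-level counts in the shape of the usual AS survey tables."""

    n_as_genes: int
    n_ir_genes: int
    n_as_isoforms: int
    n_ir_isoforms: int
    n_events: int
    events_by_type: dict[EventType, int]
    event_type_proportions: dict[EventType, float]  # % of events, 2 decimals
    isoform_type_proportions: dict[EventType, float]  # % of AS isoforms carrying type
    isoforms_per_gene_histogram: dict[int, int]
    type_combination_counts: dict[frozenset, int]
    source_overlap_counts: dict[frozenset, int]


def _validate_pair(ref: TranscriptModel, alt: TranscriptModel) -> None:
    if ref.gene_id != alt.gene_id:
        raise ValueError(f"gene mismatch: {ref.gene_id} vs {alt.gene_id}")
    if ref.chrom != alt.chrom or ref.strand != alt.strand:
        raise ValueError(
            f"{ref.transcript_id}/{alt.transcript_id}: chromosome/strand mismatch"
        )


def _contains_complete_exon(
    lo: int, hi: int, *transcripts: TranscriptModel
) -> bool:
    return any(
        lo <= e.start and e.end <= hi for t in transcripts for e in t.exons
    )


def classify_pair(ref: TranscriptModel, alt: TranscriptModel) -> list[ASEvent]:
    """Type the splicing differences between *alt* and its reference *ref*.

    The calculus is purely coordinate-based on the two intron chains; see
    the module docstring for the five categories. The result is ordered by
    region start and deterministic.
    """
    _validate_pair(ref, alt)
    strand = ref.strand
    I_ref = list(intron_chain(ref))
    I_alt = list(intron_chain(alt))
    ref_coords = {(i.start, i.end) for i in I_ref}
    alt_coords = {(i.start, i.end) for i in I_alt}
    shared = ref_coords & alt_coords
    rem_ref = [i for i in I_ref if (i.start, i.end) not in shared]
    rem_alt = [j for j in I_alt if (j.start, j.end) not in shared]

    events: list[ASEvent] = []

    def _mk(type_: EventType, region: GenomicInterval, retained: str = "n/a") -> ASEvent:
        return ASEvent(
            type=type_,
            gene_id=ref.gene_id,
            ref_id=ref.transcript_id,
            alt_id=alt.transcript_id,
            region=region,
            retained_in=retained,
        )

    # (a) intron retention: an intron of one isoform strictly inside a
    # single exon of the other (both flanking splice sites unused there).
    still_ref: list[GenomicInterval] = []
    for i in rem_ref:
        if any(e.contains_strictly(i) for e in alt.exons):
            events.append(_mk(EventType.IR, i, retained="alt"))
        else:
            still_ref.append(i)
    rem_ref = still_ref
    still_alt: list[GenomicInterval] = []
    for j in rem_alt:
        if any(e.contains_strictly(j) for e in ref.exons):
            events.append(_mk(EventType.IR, j, retained="ref"))
        else:
            still_alt.append(j)
    rem_alt = still_alt

    # (b) exon skipping: internal ref exon spanned by one alt intron whose
    # outer splice sites coincide with the flanking ref introns' outer sites.
    consumed_ref: set[tuple[int, int]] = set()
    consumed_alt: set[tuple[int, int]] = set()
    rem_ref_coords = {(i.start, i.end) for i in rem_ref}
    for k in range(1, len(ref.exons) - 1):
        x = ref.exons[k]
        left = (ref.exons[k - 1].end, x.start)
        right = (x.end, ref.exons[k + 1].start)
        spanning = (left[0], right[1])
        if (
            left in rem_ref_coords
            and right in rem_ref_coords
            and any((j.start, j.end) == spanning for j in rem_alt)
        ):
            events.append(_mk(EventType.ES, x))
            consumed_ref.update((left, right))
            consumed_alt.add(spanning)
    rem_ref = [i for i in rem_ref if (i.start, i.end) not in consumed_ref]
    rem_alt = [j for j in rem_alt if (j.start, j.end) not in consumed_alt]

    # (c) alternative 5'/3' splice sites: a mutually unique boundary-sharing
    # intron pair whose differing interval swallows no complete exon.
    def _sharers(i: GenomicInterval, pool: list[GenomicInterval]) -> list[GenomicInterval]:
        return [
            j
            for j in pool
            if (i.start == j.start) != (i.end == j.end)  # exactly one boundary
        ]

    pair_ref: set[tuple[int, int]] = set()
    pair_alt: set[tuple[int, int]] = set()
    for i in rem_ref:
        cands = _sharers(i, rem_alt)
        if len(cands) != 1:
            continue
        j = cands[0]
        if len(_sharers(j, rem_ref)) != 1:
            continue
        if i.start == j.start:
            lo, hi = min(i.end, j.end), max(i.end, j.end)
            moving_is_genomic_right = True
        else:
            lo, hi = min(i.start, j.start), max(i.start, j.start)
            moving_is_genomic_right = False
        if _contains_complete_exon(lo, hi, ref, alt):
            continue
        # genomic-right intron boundary = transcript-3' splice site on "+"
        if moving_is_genomic_right:
            type_ = EventType.AA if strand == "+" else EventType.AD
        else:
            type_ = EventType.AD if strand == "+" else EventType.AA
        events.append(_mk(type_, GenomicInterval(ref.chrom, lo, hi, strand)))
        pair_ref.add((i.start, i.end))
        pair_alt.add((j.start, j.end))
    rem_ref = [i for i in rem_ref if (i.start, i.end) not in pair_ref]
    rem_alt = [j for j in rem_alt if (j.start, j.end) not in pair_alt]

    # (d) everything left: cluster remaining introns of both isoforms by
    # genomic overlap; one OTHER event per maximal differing region.
    leftovers = sorted(rem_ref + rem_alt, key=lambda iv: (iv.start, iv.end))
    cluster_lo = cluster_hi = None
    for iv in leftovers:
        if cluster_lo is None:
            cluster_lo, cluster_hi = iv.start, iv.end
        elif iv.start < cluster_hi:
            cluster_hi = max(cluster_hi, iv.end)
        else:
            events.append(
                _mk(EventType.OTHER, GenomicInterval(ref.chrom, cluster_lo, cluster_hi, strand))
            )
            cluster_lo, cluster_hi = iv.start, iv.end
    if cluster_lo is not None:
        events.append(
            _mk(EventType.OTHER, GenomicInterval(ref.chrom, cluster_lo, cluster_hi, strand))
        )

    events.sort(key=lambda e: (e.region.start, e.region.end, e.type.value))
    return events


def classify_annotation(ann: AnnotationSet) -> list[IsoformClassification]:
    """Classify every non-reference isoform of every gene in *ann*.

    A gene is an *AS gene* iff at least one of its isoforms carries at
    least one event; an *IR gene* iff at least one event is IR.
    """
    out: list[IsoformClassification] = []
    for gene_id in sorted(ann.genes):
        g = ann.genes[gene_id]
        ref = g.ref_transcript
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            if t.transcript_id == g.ref_transcript_id:
                continue
            out.append(
                IsoformClassification(
                    alt_id=t.transcript_id,
                    gene_id=gene_id,
                    events=classify_pair(ref, t),
                    sources={ann.source_label} if ann.source_label else set(),
                    alt_model=t,
                    ref_model=ref,
                )
            )
    return out


def merge_across_sources(
    sets: list[tuple[str, list[IsoformClassification]]],
) -> list[IsoformClassification]:
    """Unify isoforms seen in several sources (tissues and/or the prior set).

    Isoform identity across sources is the pair ``(gene_id, intron chain)``
    — terminal exon ends vary with read evidence and do not split identity.
    The longest representative supplies the terminal ends, sources are
    unioned, and events are recomputed once against the reference. The
    operation is idempotent and order-invariant.
    """
    buckets: dict[tuple, list[tuple[str, IsoformClassification]]] = {}
    order: list[tuple] = []
    for label, classifications in sets:
        for c in classifications:
            if c.alt_model is None or c.ref_model is None:
                raise ValueError(
                    f"{c.alt_id}: merge requires transcript models on the classification"
                )
            chain = tuple((i.start, i.end) for i in intron_chain(c.alt_model))
            key = (c.gene_id, c.alt_model.chrom, chain)
            if any(
                prev.alt_model.strand != c.alt_model.strand
                for _, prev in buckets.get(key, [])
            ):
                raise ValueError(f"{c.alt_id}: conflicting strand for identity key {key}")
            if key not in buckets:
                order.append(key)
            buckets.setdefault(key, []).append((label, c))

    merged: list[IsoformClassification] = []
    for key in order:
        members = buckets[key]
        rep = min(
            (c for _, c in members),
            key=lambda c: (-spliced_length(c.alt_model), c.alt_id),
        )
        sources: set[str] = set()
        for label, c in members:
            sources |= c.sources
            if label:
                sources.add(label)
        merged.append(
            IsoformClassification(
                alt_id=rep.alt_id,
                gene_id=rep.gene_id,
                events=classify_pair(rep.ref_model, rep.alt_model),
                sources=sources,
                alt_model=rep.alt_model,
                ref_model=rep.ref_model,
            )
        )
    merged.sort(key=lambda c: (c.gene_id, c.alt_id))
    return merged


def summarize(cls: list[IsoformClassification], ann: AnnotationSet) -> ASSummary:
    """Dataset-level AS statistics (gene/isoform/event counts, proportions)."""
    as_isoforms = [c for c in cls if c.is_as]
    as_genes = {c.gene_id for c in as_isoforms}
    ir_isoforms = [c for c in as_isoforms if EventType.IR in c.event_types]
    ir_genes = {c.gene_id for c in ir_isoforms}

    events_by_type: dict[EventType, int] = {t: 0 for t in EventType}
    for c in as_isoforms:
        for e in c.events:
            events_by_type[e.type] += 1
    n_events = sum(events_by_type.values())

    event_type_proportions = {
        t: round(100.0 * n / n_events, 2) if n_events else 0.0
        for t, n in events_by_type.items()
    }
    isoform_type_proportions = {
        t: (
            round(
                100.0 * sum(1 for c in as_isoforms if t in c.event_types) / len(as_isoforms),
                2,
            )
            if as_isoforms
            else 0.0
        )
        for t in EventType
    }

    histogram: dict[int, int] = {}
    for g in ann.genes.values():
        k = len(g.transcripts)
        if k >= 2:
            histogram[k] = histogram.get(k, 0) + 1

    type_combination_counts: dict[frozenset, int] = {}
    source_overlap_counts: dict[frozenset, int] = {}
    for c in as_isoforms:
        combo = c.event_types
        type_combination_counts[combo] = type_combination_counts.get(combo, 0) + 1
        src = frozenset(c.sources)
        source_overlap_counts[src] = source_overlap_counts.get(src, 0) + 1

    return ASSummary(
        n_as_genes=len(as_genes),
        n_ir_genes=len(ir_genes),
        n_as_isoforms=len(as_isoforms),
        n_ir_isoforms=len(ir_isoforms),
        n_events=n_events,
        events_by_type=events_by_type,
        event_type_proportions=event_type_proportions,
        isoform_type_proportions=isoform_type_proportions,
        isoforms_per_gene_histogram=dict(sorted(histogram.items())),
        type_combination_counts=type_combination_counts,
        source_overlap_counts=source_overlap_counts,
    )


def events_to_frame(cls: list[IsoformClassification]) -> pd.DataFrame:
    """Flatten classifications into the event-table layout used on disk."""
    rows = []
    for c in cls:
        for e in c.events:
            rows.append(
                {
                    "gene_id": e.gene_id,
                    "ref_id": e.ref_id,
                    "alt_id": e.alt_id,
                    "type": e.type.value,
                    "chrom": e.region.chrom,
                    "start": e.region.start,
                    "end": e.region.end,
                    "strand": e.region.strand,
                    "retained_in": e.retained_in,
                    "sources": ",".join(sorted(c.sources)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "ref_id",
            "alt_id",
            "type",
            "chrom",
            "start",
            "end",
            "strand",
            "retained_in",
            "sources",
        ],
    )
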