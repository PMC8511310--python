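"""Event calculus: typed classification of isoform pairs and set summaries."""

import numpy as np
import pytest

from splicelight.annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from splicelight.as_classify import (
    ASEvent,
    EventType,
    IsoformClassification,
    classify_annotation,
    classify_pair,
    merge_across_sources,
    summarize,
)
from splicelight.synthetic_data import (
    SimConfig,
    generate_annotation_with_events,
    per_source_annotations,
)

from conftest import impl_events_as_tuples, oracle_classify_pair, random_pair, random_transcript


def _tx(exon_coords, strand="+", tid="t", gid="g"):
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval("chr1", s, e, strand) for s, e in exon_coords)
    )


class TestClassifyPair:
    def test_intron_retention(self):
        ref = _tx([(0, 100), (200, 300)], tid="t.ref")
        alt = _tx([(0, 300)], tid="t.alt")
        events = classify_pair(ref, alt)
        assert impl_events_as_tuples(events) == [("IR", 100, 200, "alt")]

    def test_intron_retention_in_reference(self):
        ref = _tx([(0, 300)], tid="t.ref")
        alt = _tx([(0, 100), (200, 300)], tid="t.alt")
        assert impl_events_as_tuples(classify_pair(ref, alt)) == [("IR", 100, 200, "ref")]

    def test_identical_intron_chains_give_no_events(self):
        ref = _tx([(0, 100), (200, 300)], tid="t.ref")
        alt = _tx([(20, 100), (200, 280)], tid="t.alt")  # ends differ only
        assert classify_pair(ref, alt) == []

    def test_exon_skipping(self):
        ref = _tx([(0, 100), (200, 300), (400, 500)], tid="t.ref")
        alt = _tx([(0, 100), (400, 500)], tid="t.alt")
        assert impl_events_as_tuples(classify_pair(ref, alt)) == [("ES", 200, 300, "n/a")]

    @pytest.mark.parametrize("strand,expected", [("+", "AA"), ("-", "AD")])
    def test_shared_donor_moving_acceptor(self, strand, expected):
        ref = _tx([(0, 100), (200, 300)], strand=strand, tid="t.ref")
        alt = _tx([(0, 100), (250, 300)], strand=strand, tid="t.alt")
        assert impl_events_as_tuples(classify_pair(ref, alt)) == [
            (expected, 200, 250, "n/a")
        ]

    def test_mutually_exclusive_exons_are_other(self):
        ref = _tx([(0, 100), (200, 260), (400, 500)], tid="t.ref")
        alt = _tx([(0, 100), (300, 340), (400, 500)], tid="t.alt")
        assert impl_events_as_tuples(classify_pair(ref, alt)) == [
            ("OTHER", 100, 400, "n/a")
        ]

    def test_self_comparison_is_empty(self, rng):
        for _ in range(200):
            t = random_transcript(rng)
            assert classify_pair(t, t) == []

    def test_mismatched_strand_rejected(self):
        ref = _tx([(0, 100)], strand="+", tid="t.ref")
        alt = _tx([(0, 100)], strand="-", tid="t.alt")
        with pytest.raises(ValueError, match="strand"):
            classify_pair(ref, alt)

    def test_shift_equivariance(self, rng):
        for _ in range(100):
            ref, alt = random_pair(rng)
            delta = int(rng.integers(1, 500))
            shift = lambda t: TranscriptModel(  # noqa: E731
                t.transcript_id, t.gene_id, tuple(e.shift(delta) for e in t.exons)
            )
            base = impl_events_as_tuples(classify_pair(ref, alt))
            moved = impl_events_as_tuples(classify_pair(shift(ref), shift(alt)))
            assert moved == [(t, s + delta, e + delta, r) for t, s, e, r in base]

    def test_strand_relabel_swaps_aa_ad_and_mirror_flip_preserves(self, rng):
        """Relabelling the strand with fixed coordinates swaps the 5'/3'
        splice-site event polarity (AA <-> AD); mirroring the coordinates
        together with the strand flip describes the same molecule and
        preserves every event type."""
        L = 2000
        swap = {"AA": "AD", "AD": "AA", "IR": "IR", "ES": "ES", "OTHER": "OTHER"}
        for _ in range(100):
            ref, alt = random_pair(rng)
            other = "-" if ref.strand == "+" else "+"
            relabel = lambda t: TranscriptModel(  # noqa: E731
                t.transcript_id,
                t.gene_id,
                tuple(
                    GenomicInterval(e.chrom, e.start, e.end, other) for e in t.exons
                ),
            )
            mirror = lambda t: TranscriptModel(  # noqa: E731
                t.transcript_id,
                t.gene_id,
                tuple(
                    GenomicInterval(e.chrom, L - e.end, L - e.start, other)
                    for e in t.exons
                ),
            )
            base = impl_events_as_tuples(classify_pair(ref, alt))
            relabelled = impl_events_as_tuples(
                classify_pair(relabel(ref), relabel(alt))
            )
            assert relabelled == sorted((swap[t], s, e, r) for t, s, e, r in base)
            mirrored = impl_events_as_tuples(classify_pair(mirror(ref), mirror(alt)))
            assert mirrored == sorted((t, L - e, L - s, r) for t, s, e, r in base)

    def test_matches_brute_force_oracle(self, rng):
        """Interval-logic implementation agrees with the per-base enumeration
        oracle on random boundary-sharing pairs."""
        for _ in range(2000):
            ref, alt = random_pair(rng)
            assert impl_events_as_tuples(classify_pair(ref, alt)) == oracle_classify_pair(
                ref, alt
            )


class TestClassifyAnnotation:
    def test_single_isoform_genes_yield_nothing(self):
        genes = {
            f"g{i}": GeneModel(f"g{i}", [_tx([(0, 100)], tid=f"t{i}", gid=f"g{i}")], f"t{i}")
            for i in range(3)
        }
        assert classify_annotation(AnnotationSet(genes=genes)) == []

    def test_recovers_planted_truth(self):
        ann, truth = generate_annotation_with_events(SimConfig(n_genes=200), seed=42)
        by_alt = {c.alt_id: c for c in classify_annotation(ann)}
        assert set(by_alt) >= set(truth.events)
        for alt_id, planted in truth.events.items():
            got = impl_events_as_tuples(by_alt[alt_id].events)
            want = sorted((t, s, e, r) for t, _, s, e, r in planted)
            assert got == want

    def test_gene_with_two_ir_isoforms_counted_once(self):
        ref = _tx([(0, 300), (400, 700), (800, 1100)], tid="t.ref")
        alt1 = _tx([(100, 700), (800, 1000)], tid="t.a1")
        alt2 = _tx([(100, 300), (400, 1050)], tid="t.a2")
        ann = AnnotationSet(genes={"g": GeneModel("g", [ref, alt1, alt2], "t.ref")})
        cls = classify_annotation(ann)
        assert len(cls) == 2
        s = summarize(cls, ann)
        assert (s.n_as_genes, s.n_ir_genes) == (1, 1)
        assert (s.n_as_isoforms, s.n_ir_isoforms) == (2, 2)


class TestMerge:
    def test_same_isoform_in_four_tissues_unifies(self):
        cfg = SimConfig(n_genes=80)
        ann, truth = generate_annotation_with_events(cfg, seed=9)
        per_tissue = per_source_annotations(ann, truth)
        merged = merge_across_sources(
            [(t, classify_annotation(sub)) for t, sub in sorted(per_tissue.items())]
        )
        by_alt = {c.alt_id: c for c in merged}
        quad = [a for a, s in truth.sources.items() if len(s) == 4]
        assert quad, "overlap design should place isoforms in all four tissues"
        for alt_id in quad:
            assert by_alt[alt_id].sources == set(truth.sources[alt_id])
        # every merged isoform reports exactly its planted source set
        for alt_id, c in by_alt.items():
            assert c.sources == set(truth.sources[alt_id])

    def test_disjoint_sets_concatenate(self):
        ref1 = _tx([(0, 100), (200, 300)], tid="a.ref", gid="a")
        alt1 = _tx([(10, 300)], tid="a.alt", gid="a")
        ref2 = _tx([(0, 100), (200, 300)], tid="b.ref", gid="b")
        alt2 = _tx([(10, 300)], tid="b.alt", gid="b")
        mk = lambda r, a, src: [  # noqa: E731
            IsoformClassification(
                a.transcript_id,
                a.gene_id,
                classify_pair(r, a),
                {src},
                alt_model=a,
                ref_model=r,
            )
        ]
        merged = merge_across_sources(
            [("leaf", mk(ref1, alt1, "leaf")), ("root", mk(ref2, alt2, "root"))]
        )
        assert sorted(c.alt_id for c in merged) == ["a.alt", "b.alt"]

    def test_idempotent_and_order_invariant(self):
        ann, truth = generate_annotation_with_events(SimConfig(n_genes=40), seed=4)
        per_tissue = per_source_annotations(ann, truth)
        sets = [(t, classify_annotation(sub)) for t, sub in sorted(per_tissue.items())]
        merged = merge_across_sources(sets)
        again = merge_across_sources([("", merged)])
        assert [(c.alt_id, sorted(c.sources)) for c in merged] == [
            (c.alt_id, sorted(c.sources)) for c in again
        ]
        reversed_merge = merge_across_sources(sets[::-1])
        assert [(c.alt_id, sorted(c.sources), impl_events_as_tuples(c.events)) for c in merged] == [
            (c.alt_id, sorted(c.sources), impl_events_as_tuples(c.events))
            for c in reversed_merge
        ]


class TestSummarize:
    def test_empty_classifications(self):
        s = summarize([], AnnotationSet(genes={}))
        assert s.n_as_genes == s.n_as_isoforms == s.n_events == 0

    def test_planted_mix_proportions(self):
        mix = {"IR": 0.5, "ES": 0.3, "AA": 0.2, "AD": 0.0, "OTHER": 0.0}
        cfg = SimConfig(n_genes=100, as_gene_fraction=1.0, extra_isoform_p=0.0, event_mix=mix)
        ann, truth = generate_annotation_with_events(cfg, seed=13)
        cls = classify_annotation(ann)
        s = summarize(cls, ann)
        assert s.events_by_type[EventType.IR] == 50
        assert s.events_by_type[EventType.ES] == 30
        assert s.events_by_type[EventType.AA] == 20
        assert s.event_type_proportions[EventType.IR] == 50.00

    def test_multi_event_isoform_counts_one_combination(self):
        ref = _tx([(0, 100), (200, 300), (400, 500)], tid="t.ref")
        # retains intron 1 and shifts the acceptor of intron 2
        alt = _tx([(0, 300), (430, 500)], tid="t.alt")
        events = classify_pair(ref, alt)
        assert {e.type for e in events} == {EventType.IR, EventType.AA}
        ann = AnnotationSet(genes={"g": GeneModel("g", [ref, alt], "t.ref")})
        cls = [
            IsoformClassification("t.alt", "g", events, {"leaf"}, alt_model=alt, ref_model=ref)
        ]
        s = summarize(cls, ann)
        assert s.type_combination_counts[frozenset({EventType.IR, EventType.AA})] == 1

    def test_conservation_of_isoform_counts(self):
        ann, truth = generate_annotation_with_events(SimConfig(n_genes=150), seed=3)
        per_tissue = per_source_annotations(ann, truth)
        merged = merge_across_sources(
            [(t, classify_annotation(sub)) for t, sub in sorted(per_tissue.items())]
        )
        s = summarize(merged, ann)
        assert sum(s.type_combination_counts.values()) == s.n_as_isoforms
        assert sum(s.source_overlap_counts.values()) == s.n_as_isoforms
        assert sum(s.events_by_type.values()) == s.n_events
        assert s.n_ir_genes <= s.n_as_genes
        assert sum(s.isoforms_per_gene_histogram.values()) == sum(
            1 for g in ann.genes.values() if len(g.transcripts) >= 2
        )


def test_ir_event_requires_retained_side():
    with pytest.raises(ValueError):
        ASEvent(
            type=EventType.IR,
            gene_id="g",
            ref_id="r",
            alt_id="a",
            region=GenomicInterval("chr1", 0, 10, "+"),
            retained_in="n/a",
        )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
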