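"""Shared fixtures and independent oracles.

The oracles deliberately use different mechanics from the package
implementation: per-base occupancy arrays and exhaustive double loops for
event classification, explicit per-base coordinate lists plus Biopython
translation for PTC assessment, and direct combinatorial enumeration for
the hypergeometric tail.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicelight.annotation_io import GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# random model generators
# ---------------------------------------------------------------------------


def random_transcript(
    rng: np.random.Generator,
    chrom: str = "chr1",
    strand: str | None = None,
    max_exons: int = 6,
    span: int = 1000,
    gene_id: str = "G",
    transcript_id: str = "T",
) -> TranscriptModel:
    """A valid random transcript: distinct sorted breakpoints define exons."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n = int(rng.integers(1, max_exons + 1))
    pts = np.sort(rng.choice(np.arange(span), size=2 * n, replace=False))
    exons = tuple(
        GenomicInterval(chrom, int(pts[2 * i]), int(pts[2 * i + 1]), strand)
        for i in range(n)
    )
    return TranscriptModel(transcript_id, gene_id, exons)


def random_pair(
    rng: np.random.Generator, share_prob: float = 0.6, span: int = 1000
) -> tuple[TranscriptModel, TranscriptModel]:
    """Two transcripts of one gene that share some splice boundaries."""
    strand = "+" if rng.random() < 0.5 else "-"
    ref = random_transcript(rng, strand=strand, span=span, transcript_id="T.ref")
    ref_pts = [p for e in ref.exons for p in (e.start, e.end)]
    n = int(rng.integers(1, 7))
    pool = np.array(ref_pts + list(rng.integers(0, span, size=40)))
    pool = np.unique(pool)
    # bias toward reusing reference boundaries
    weights = np.where(np.isin(pool, ref_pts), share_prob, 1 - share_prob)
    weights = weights / weights.sum()
    k = min(2 * n, len(pool))
    if k % 2:
        k -= 1
    if k < 2:
        k = 2
    pts = np.sort(rng.choice(pool, size=k, replace=False, p=weights))
    exons = tuple(
        GenomicInterval("chr1", int(pts[2 * i]), int(pts[2 * i + 1]), strand)
        for i in range(k // 2)
    )
    alt = TranscriptModel("T.alt", "G", exons)
    return ref, alt


# ---------------------------------------------------------------------------
# brute-force classification oracle
# ---------------------------------------------------------------------------


def oracle_classify_pair(ref: TranscriptModel, alt: TranscriptModel):
    """Enumerate intron/exon containment and boundary-sharing relations
    directly over per-base occupancy arrays; returns (type, lo, hi,
    retained_in) tuples."""
    strand = ref.strand
    lo = min(ref.exons[0].start, alt.exons[0].start)
    hi = max(ref.exons[-1].end, alt.exons[-1].end)

    def intron_coords(t):
        return [(a.end, b.start) for a, b in zip(t.exons, t.exons[1:])]

    def exonic_array(t):
        arr = np.zeros(hi - lo, dtype=bool)
        for e in t.exons:
            arr[e.start - lo : e.end - lo] = True
        return arr

    I_ref, I_alt = intron_coords(ref), intron_coords(alt)
    shared = set(I_ref) & set(I_alt)
    rem_ref = [i for i in I_ref if i not in shared]
    rem_alt = [j for j in I_alt if j not in shared]
    exonic_ref, exonic_alt = exonic_array(ref), exonic_array(alt)
    events = []

    # IR: the intron and both flanking bases are exonic in the other isoform
    def retained(intron, arr):
        s, e = intron
        return bool(arr[s - 1 - lo : e + 1 - lo].all()) if s - 1 >= lo and e + 1 <= hi else False

    keep = []
    for i in rem_ref:
        if retained(i, exonic_alt):
            events.append(("IR", i[0], i[1], "alt"))
        else:
            keep.append(i)
    rem_ref = keep
    keep = []
    for j in rem_alt:
        if retained(j, exonic_ref):
            events.append(("IR", j[0], j[1], "ref"))
        else:
            keep.append(j)
    rem_alt = keep

    # ES: internal ref exon whose flanking introns' outer sites bound one alt intron
    es_ref, es_alt = set(), set()
    for k in range(1, len(ref.exons) - 1):
        x = ref.exons[k]
        left = (ref.exons[k - 1].end, x.start)
        right = (x.end, ref.exons[k + 1].start)
        for j in rem_alt:
            if j == (left[0], right[1]) and left in rem_ref and right in rem_ref:
                events.append(("ES", x.start, x.end, "n/a"))
                es_ref.update((left, right))
                es_alt.add(j)
    rem_ref = [i for i in rem_ref if i not in es_ref]
    rem_alt = [j for j in rem_alt if j not in es_alt]

    # AA/AD: mutually unique single-boundary-sharing pairs, no swallowed exon
    def one_boundary(i, j):
        return (i[0] == j[0]) != (i[1] == j[1])

    aa_ref, aa_alt = set(), set()
    for i in rem_ref:
        partners = [j for j in rem_alt if one_boundary(i, j)]
        if len(partners) != 1:
            continue
        j = partners[0]
        if len([i2 for i2 in rem_ref if one_boundary(i2, j)]) != 1:
            continue
        if i[0] == j[0]:
            a, b = sorted((i[1], j[1]))
            right_moves = True
        else:
            a, b = sorted((i[0], j[0]))
            right_moves = False
        if any(
            a <= e.start and e.end <= b for t in (ref, alt) for e in t.exons
        ):
            continue
        if right_moves:
            etype = "AA" if strand == "+" else "AD"
        else:
            etype = "AD" if strand == "+" else "AA"
        events.append((etype, a, b, "n/a"))
        aa_ref.add(i)
        aa_alt.add(j)
    rem_ref = [i for i in rem_ref if i not in aa_ref]
    rem_alt = [j for j in rem_alt if j not in aa_alt]

    # OTHER: connected components (by strict overlap) of leftover introns
    leftovers = rem_ref + rem_alt
    n = len(leftovers)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = leftovers[a], leftovers[b]
            if ia[0] < ib[1] and ib[0] < ia[1]:
                parent[find(a)] = find(b)
    comps = {}
    for idx in range(n):
        comps.setdefault(find(idx), []).append(leftovers[idx])
    for members in comps.values():
        events.append(
            ("OTHER", min(m[0] for m in members), max(m[1] for m in members), "n/a")
        )
    return sorted(events)


def impl_events_as_tuples(events):
    return sorted(
        (e.type.value, e.region.start, e.region.end, e.retained_in) for e in events
    )


# ---------------------------------------------------------------------------
# naive PTC oracle
# ---------------------------------------------------------------------------

_COMPL = str.maketrans("ACGT", "TGCA")


def _splice(genome, t):
    s = "".join(str(genome[t.chrom][e.start : e.end]) for e in t.exons).upper()
    return s.translate(_COMPL)[::-1] if t.strand == "-" else s


def _base_positions(t):
    """Genomic coordinate of every transcript base, 5'->3'."""
    pos = [p for e in t.exons for p in range(e.start, e.end)]
    return pos[::-1] if t.strand == "-" else pos


def _longest_orf_naive(seq):
    """Exhaustive scan over every ATG/stop pair; (start, stop_end) or None."""
    best = None
    for start in range(len(seq) - 5):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start, len(seq) - 2, 3):
            if seq[pos : pos + 3] in ("TAA", "TAG", "TGA"):
                cand = (start, pos + 3)
                if best is None or (
                    cand[1] - cand[0],
                    -cand[0],
                ) > (best[1] - best[0], -best[0]):
                    best = cand
                break
    return best


def oracle_assess_ptc(genome, ref, alt):
    """Naive verdict: translate the full alt sequence from the projected
    start with Biopython and scan the protein for the first stop.

    Returns (has_ptc, stop_pos_or_None, nmd_candidate) or None when the
    case is not assessable.
    """
    from Bio.Seq import Seq

    ref_seq = _splice(genome, ref)
    orf = _longest_orf_naive(ref_seq)
    if orf is None:
        return None
    ref_pos = _base_positions(ref)
    alt_pos = _base_positions(alt)
    start_g = ref_pos[orf[0]]
    if start_g not in alt_pos:
        return None
    alt_start = alt_pos.index(start_g)
    alt_seq = _splice(genome, alt)
    if alt_seq[alt_start : alt_start + 3] != "ATG":
        return None
    tail = alt_seq[alt_start:]
    protein = str(Seq(tail[: len(tail) - len(tail) % 3]).translate())
    stop_aa = protein.find("*")
    first_stop = None if stop_aa == -1 else alt_start + 3 * stop_aa

    stop_g = ref_pos[orf[1] - 3]
    alt_ref_stop = alt_pos.index(stop_g) if stop_g in alt_pos else None
    if first_stop is None:
        return (False, None, False)
    has_ptc = alt_ref_stop is None or first_stop < alt_ref_stop
    junctions = [
        i + 1
        for i in range(len(alt_pos) - 1)
        if abs(alt_pos[i + 1] - alt_pos[i]) != 1
    ]
    nmd = bool(
        has_ptc and junctions and junctions[-1] - (first_stop + 3) > 50
    )
    return (has_ptc, first_stop if has_ptc else None, nmd)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
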