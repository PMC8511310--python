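"""Synthetic genomes, annotations with planted AS events, and NB counts.

The generator emulates the study design the analysis modules target:

* multi-isoform gene models in which every alternative isoform carries
  planted splicing events of known type and coordinates (constructed by
  inverting the classification calculus: fuse two exons across an intron
  for IR, delete an internal exon for ES, move one intron boundary by
  3-60 nt for AA/AD, swap in a mutually exclusive exon for OTHER);
* per-tissue isoform subsets with a controlled overlap design over four
  tissues (leaf, flower, stem, root);
* negative-binomial count matrices over five light conditions (FR, R, B,
  WL, D) x 3 replicates with planted condition effects, including
  antagonistic regulation of a gene's reference vs IR isoform.

Event-type quotas are allocated by largest remainder, so the realized
event mix equals the configured mix exactly whenever the proportions are
representable at the requested size. All generators are deterministic
under a fixed seed; per-stage substreams are spawned from a single
``numpy`` SeedSequence.

To keep the planted truth stable through file round-trips, every
alternative isoform is built strictly shorter (in spliced length) than its
reference — an intron-retaining isoform would otherwise outrank the
reference under the longest-isoform rule, so its terminal exon ends are
trimmed, which is not a splicing event and leaves the planted events as
the only differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    spliced_length,
)
from .expression_de import CONDITIONS, ExpressionMatrix, counts_to_tpm, make_design

__all__ = [
    "TISSUES",
    "SimConfig",
    "EffectEntry",
    "SyntheticTruth",
    "generate_genome",
    "generate_annotation_with_events",
    "generate_coding_genome",
    "simulate_counts",
    "per_source_annotations",
    "generate_term_mapping",
    "default_effect_plan",
    "default_tissue_overlap",
]

TISSUES = ("leaf", "flower", "stem", "root")

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def default_tissue_overlap() -> dict[frozenset, float]:
    """Overlap design over the four tissues: mostly tissue-specific isoforms,
    some pairwise sharing, and a core found in all four."""
    return {
        frozenset({"leaf"}): 0.15,
        frozenset({"flower"}): 0.15,
        frozenset({"stem"}): 0.20,
        frozenset({"root"}): 0.15,
        frozenset({"leaf", "flower"}): 0.08,
        frozenset({"stem", "root"}): 0.07,
        frozenset({"leaf", "stem"}): 0.10,
        frozenset(TISSUES): 0.10,
    }


@dataclass(frozen=True)
class EffectEntry:
    """One planted differential-expression effect.

    Applies *log2fc* to the test condition of *contrast* for a random
    *fraction* of the features in *feature_class*.
    """

    feature_class: str
    contrast: tuple[str, str]
    log2fc: float
    fraction: float


def default_effect_plan() -> list[EffectEntry]:
    """Light-response effects echoing the study: IR isoforms respond to blue
    and red light more often than non-AS genes, and up-regulation dominates."""
    plan = []
    for test in ("B", "R"):
        plan += [
            EffectEntry("IR_isoform", (test, "D"), +2.0, 0.25),
            EffectEntry("IR_isoform", (test, "D"), -2.0, 0.12),
            EffectEntry("non_AS_gene", (test, "D"), +2.0, 0.19),
            EffectEntry("non_AS_gene", (test, "D"), -2.0, 0.09),
        ]
    return plan


@dataclass
class SimConfig:
    """Study-design parameters for all generators."""

    n_genes: int = 500
    as_gene_fraction: float = 0.5
    extra_isoform_p: float = 0.25  # chance an AS gene carries a second alt isoform
    exon_count_range: tuple[int, int] = (3, 8)
    internal_exon_len_range: tuple[int, int] = (80, 240)
    terminal_exon_len_range: tuple[int, int] = (250, 400)
    intron_len_range: tuple[int, int] = (60, 200)
    event_mix: dict = field(
        default_factory=lambda: {"IR": 0.49, "ES": 0.17, "AA": 0.17, "AD": 0.12, "OTHER": 0.05}
    )
    tissue_overlap: dict = field(default_factory=default_tissue_overlap)
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 3
    dispersion: float = 0.1
    baseline_log_mean: float = 4.0  # lognormal location of baseline mean counts
    baseline_log_sd: float = 1.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    effect_plan: list = field(default_factory=default_effect_plan)
    n_antagonistic_genes: int = 5
    antagonistic_log2fc: float = 3.0
    genes_per_chrom: int = 50
    intergenic_gap: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event mix proportions must sum to 1")
        if abs(sum(self.tissue_overlap.values()) - 1.0) > 1e-9:
            raise ValueError("tissue overlap proportions must sum to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the contract every recovery test checks against."""

    # alt_id -> list of (type, chrom, start, end, retained_in)
    events: dict[str, list[tuple[str, str, int, int, str]]] = field(default_factory=dict)
    sources: dict[str, frozenset] = field(default_factory=dict)
    ref_ids: dict[str, str] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)
    # (feature_id, "TEST_vs_BASE") -> log2fc
    lfc: dict[tuple[str, str], float] = field(default_factory=dict)
    antagonistic_genes: list[str] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _largest_remainder(proportions: Mapping, total: int) -> dict:
    """Integer quotas matching *proportions* exactly in expectation and sum."""
    keys = list(proportions)
    raw = [proportions[k] * total for k in keys]
    counts = [math.floor(x) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(keys)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts))


def generate_genome(
    chrom_lengths: Mapping[str, int], seed: int
) -> dict[str, str]:
    """Uniform-random ACGT chromosomes, deterministic under *seed*."""
    rng = _substream(seed, 0)
    genome = {}
    for chrom in chrom_lengths:
        n = int(chrom_lengths[chrom])
        genome[chrom] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    return genome


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------


def _plant_ir(exons, introns, rng):
    i = int(rng.integers(0, len(introns)))
    intr = introns[i]
    fused = GenomicInterval(
        exons[i].chrom, exons[i].start, exons[i + 1].end, exons[i].strand
    )
    alt = list(exons[: i]) + [fused] + list(exons[i + 2 :])
    trim = intr.length + int(rng.integers(1, 21))
    first = alt[0]
    alt[0] = GenomicInterval(first.chrom, first.start + trim, first.end, first.strand)
    region = (intr.start, intr.end)
    return alt, region, "alt"


def _plant_es(exons, introns, rng):
    j = int(rng.integers(1, len(exons) - 1))
    alt = list(exons[:j]) + list(exons[j + 1 :])
    return alt, (exons[j].start, exons[j].end), "n/a"


def _plant_splice_site_shift(exons, introns, rng, event_type, strand):
    i = int(rng.integers(0, len(introns)))
    intr = introns[i]
    d = 3 * int(rng.integers(1, 21))
    if rng.random() >= 0.5:  # half the shifts break frame
        d = min(60, d + int(rng.integers(1, 3)))
    move_right = (event_type == "AA") == (strand == "+")
    alt = list(exons)
    if move_right:
        # intron 3'-genomic end moves into the downstream exon
        nxt = exons[i + 1]
        alt[i + 1] = GenomicInterval(nxt.chrom, nxt.start + d, nxt.end, nxt.strand)
        region = (intr.end, intr.end + d)
    else:
        prev = exons[i]
        alt[i] = GenomicInterval(prev.chrom, prev.start, prev.end - d, prev.strand)
        region = (intr.start - d, intr.start)
    return alt, region, "n/a"


def _plant_other(exons, introns, rng):
    """Mutually exclusive exon: replace an internal exon with a novel exon
    placed inside the downstream intron, sharing no splice boundary."""
    j = int(rng.integers(1, len(exons) - 1))
    intr = introns[j]  # intron between exon j and j+1
    x = exons[j]
    max_len = min(intr.length - 10, x.length - 10)
    new_len = int(rng.integers(20, max(21, max_len + 1)))
    offset = int(rng.integers(1, intr.length - new_len))
    new_exon = GenomicInterval(
        x.chrom, intr.start + offset, intr.start + offset + new_len, x.strand
    )
    alt = list(exons[:j]) + [new_exon] + list(exons[j + 1 :])
    region = (exons[j - 1].end, exons[j + 1].start)
    return alt, region, "n/a"


_PLANTERS = {
    "IR": _plant_ir,
    "ES": _plant_es,
    "OTHER": _plant_other,
}


def generate_annotation_with_events(
    cfg: SimConfig, seed: int
) -> tuple[AnnotationSet, SyntheticTruth]:
    """Gene models with planted AS events of known type and coordinates.

    Every AS gene receives a reference isoform and one or two alternative
    isoforms, each carrying exactly one planted event; tissue source sets
    follow the configured overlap design.
    """
    rng = _substream(seed, 1)
    truth = SyntheticTruth(params={"seed": seed, "n_genes": cfg.n_genes})

    n_as = round(cfg.as_gene_fraction * cfg.n_genes)
    as_flags = np.zeros(cfg.n_genes, dtype=bool)
    as_flags[:n_as] = True
    rng.shuffle(as_flags)
    extra_flags = rng.random(cfg.n_genes) < cfg.extra_isoform_p
    n_alts = int(n_as + (as_flags & extra_flags).sum())

    quotas = _largest_remainder(cfg.event_mix, n_alts)
    event_types = [t for t, c in quotas.items() for _ in range(c)]
    rng.shuffle(event_types)
    source_quotas = _largest_remainder(cfg.tissue_overlap, n_alts)
    source_sets = [s for s, c in source_quotas.items() for _ in range(c)]
    rng.shuffle(source_sets)

    genes: dict[str, GeneModel] = {}
    cursor = 0
    chrom_idx = 1
    genes_on_chrom = 0
    chrom_lengths: dict[str, int] = {}
    alt_counter = 0
    ndigits = len(str(cfg.n_genes))

    for gi in range(cfg.n_genes):
        if genes_on_chrom >= cfg.genes_per_chrom:
            chrom_idx += 1
            genes_on_chrom = 0
            cursor = 0
        chrom = f"chr{chrom_idx}"
        gene_id = f"G{gi + 1:0{ndigits}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lo_exons = cfg.exon_count_range[0]
        if as_flags[gi] and extra_flags[gi]:
            # two alt isoforms need room for two distinct events (e.g. two
            # different skippable internal exons)
            lo_exons = max(lo_exons, 4)
        n_exons = int(rng.integers(lo_exons, max(lo_exons, cfg.exon_count_range[1]) + 1))

        exons = []
        pos = cursor + cfg.intergenic_gap
        for k in range(n_exons):
            lo, hi = (
                cfg.terminal_exon_len_range
                if k in (0, n_exons - 1)
                else cfg.internal_exon_len_range
            )
            elen = int(rng.integers(lo, hi + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            if k < n_exons - 1:
                pos += elen + int(rng.integers(*cfg.intron_len_range))
            else:
                pos += elen
        exons = tuple(exons)
        introns = tuple(
            GenomicInterval(chrom, a.end, b.start, strand)
            for a, b in zip(exons, exons[1:])
        )

        ref_id = f"{gene_id}.ref"
        transcripts = [TranscriptModel(ref_id, gene_id, exons)]
        truth.ref_ids[gene_id] = ref_id
        if as_flags[gi]:
            n_gene_alts = 2 if extra_flags[gi] else 1
            seen_chains = set()
            for a in range(n_gene_alts):
                etype = event_types[alt_counter]
                sources = source_sets[alt_counter]
                alt_counter += 1
                # sibling alt isoforms must have distinct intron chains or
                # they would be one isoform; resample with bounded retries
                for _ in range(50):
                    if etype in ("AA", "AD"):
                        alt_exons, region, retained = _plant_splice_site_shift(
                            exons, introns, rng, etype, strand
                        )
                    else:
                        alt_exons, region, retained = _PLANTERS[etype](exons, introns, rng)
                    chain = tuple(
                        (x.end, y.start) for x, y in zip(alt_exons, alt_exons[1:])
                    )
                    if chain not in seen_chains:
                        seen_chains.add(chain)
                        break
                else:  # pragma: no cover - geometry always leaves room
                    raise RuntimeError(f"{gene_id}: could not plant a distinct isoform")
                alt_id = f"{gene_id}.alt{a + 1}"
                transcripts.append(TranscriptModel(alt_id, gene_id, tuple(alt_exons)))
                truth.events[alt_id] = [(etype, chrom, region[0], region[1], retained)]
                truth.sources[alt_id] = frozenset(sources)
        genes[gene_id] = GeneModel(
            gene_id=gene_id, transcripts=transcripts, ref_transcript_id=ref_id
        )
        cursor = pos
        genes_on_chrom += 1
        chrom_lengths[chrom] = cursor + cfg.intergenic_gap

    truth.chrom_lengths = chrom_lengths
    return AnnotationSet(genes=genes, source_label="synthetic"), truth


def per_source_annotations(
    ann: AnnotationSet, truth: SyntheticTruth
) -> dict[str, AnnotationSet]:
    """Split one annotation into per-tissue sets per the planted source sets.

    Each tissue set keeps every gene's reference isoform plus the alt
    isoforms whose planted source set includes that tissue; genes with no
    alt in a tissue are dropped from that tissue's set.
    """
    tissues = sorted({t for s in truth.sources.values() for t in s})
    out = {}
    for tissue in tissues:
        genes = {}
        for gene_id, g in ann.genes.items():
            keep = [
                t
                for t in g.transcripts
                if t.transcript_id == g.ref_transcript_id
                or tissue in truth.sources.get(t.transcript_id, frozenset())
            ]
            if len(keep) >= 2:
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    transcripts=keep,
                    ref_transcript_id=g.ref_transcript_id,
                )
        out[tissue] = AnnotationSet(genes=genes, source_label=tissue)
    return out


# ---------------------------------------------------------------------------
# genome with controlled coding content
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=n)])


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_coding_genome(
    ann: AnnotationSet,
    seed: int,
    intron_mode: str = "random",
) -> dict[str, str]:
    """A genome in which every reference isoform carries a full-length ORF.

    The reference spliced sequence of each gene is written as ATG, a run of
    non-stop codons, and a terminal stop, so the longest-ORF rule recovers
    a reading frame spanning (almost) the whole transcript. Intron content
    is controlled by *intron_mode*:

    - ``"random"``: uniform ACGT (stops arise naturally);
    - ``"no_stop"``: T-free sequence, so no stop codon in any frame — the
      frame-preserving, stop-free retention case.
    """
    if intron_mode not in ("random", "no_stop"):
        raise ValueError(f"unknown intron_mode {intron_mode!r}")
    rng = _substream(seed, 2)
    chrom_lengths: dict[str, int] = {}
    for g in ann.genes.values():
        for t in g.transcripts:
            chrom_lengths[t.chrom] = max(
                chrom_lengths.get(t.chrom, 0), t.exons[-1].end + 10
            )
    genome = {c: bytearray(_random_seq(rng, n).encode()) for c, n in chrom_lengths.items()}

    for gene_id in sorted(ann.genes):
        g = ann.genes[gene_id]
        ref = g.ref_transcript
        L = spliced_length(ref)
        n_codons = L // 3
        body = [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)]
        spliced = "ATG" + "".join(body) + "TAA" + _random_seq(rng, L % 3, "ACG")
        if ref.strand == "-":
            spliced = _revcomp(spliced)
        # lay the spliced sequence across exons in genomic order
        offset = 0
        for e in ref.exons:
            genome[ref.chrom][e.start : e.end] = spliced[offset : offset + e.length].encode()
            offset += e.length
        # overwrite intron content per mode
        for a, b in zip(ref.exons, ref.exons[1:]):
            n = b.start - a.end
            seq = (
                _random_seq(rng, n)
                if intron_mode == "random"
                else _random_seq(rng, n, "ACG")
            )
            genome[ref.chrom][a.end : b.start] = seq.encode()
    return {c: bytes(b).decode() for c, b in genome.items()}


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _label_features(ann: AnnotationSet, truth: SyntheticTruth) -> dict[str, str]:
    labels: dict[str, str] = {}
    for g in ann.genes.values():
        if len(g.transcripts) == 1:
            labels[g.transcripts[0].transcript_id] = "non_AS_gene"
            continue
        for t in g.transcripts:
            if t.transcript_id == g.ref_transcript_id:
                labels[t.transcript_id] = "ref_isoform"
            else:
                planted = truth.events.get(t.transcript_id, [])
                labels[t.transcript_id] = (
                    "IR_isoform"
                    if any(e[0] == "IR" for e in planted)
                    else "other_AS_isoform"
                )
    return labels


def simulate_counts(
    ann: AnnotationSet,
    cfg: SimConfig,
    seed: int,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial counts (and derived TPM) with planted light effects.

    Baseline means are log-normal; each effect-plan entry multiplies the
    test condition's mean by ``2**log2fc`` for a random subset of its
    feature class; antagonistic gene pairs get opposite-sign effects on the
    reference vs the IR isoform in every light-vs-dark contrast. Counts are
    NB with the configured dispersion and per-sample library size factors.
    """
    rng = _substream(seed, 3)
    if truth is None:
        truth = SyntheticTruth()
        truth.ref_ids = {gid: g.ref_transcript_id for gid, g in ann.genes.items()}
    labels = truth.class_labels or _label_features(ann, truth)
    truth.class_labels = labels

    features = sorted(labels)
    design = make_design(cfg.conditions, cfg.n_replicates)
    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(features))
    # per-feature, per-condition multiplier
    mult = pd.DataFrame(1.0, index=features, columns=list(cfg.conditions))

    feat_by_class: dict[str, list[str]] = {}
    for f in features:
        feat_by_class.setdefault(labels[f], []).append(f)

    claimed: set[tuple[str, str]] = set()  # (feature, condition) already affected
    for entry in cfg.effect_plan:
        pool = feat_by_class.get(entry.feature_class, [])
        test = entry.contrast[0]
        free = [f for f in pool if (f, test) not in claimed]
        n_pick = round(entry.fraction * len(pool))
        picked = [str(f) for f in rng.choice(free, size=min(n_pick, len(free)), replace=False)]
        for f in picked:
            mult.loc[f, test] *= 2.0**entry.log2fc
            claimed.add((f, test))
            truth.lfc[(f, f"{test}_vs_{entry.contrast[1]}")] = entry.log2fc

    # antagonistic ref-down / IR-up gene pairs in every light-vs-dark contrast
    candidates = sorted(
        gid
        for gid, g in ann.genes.items()
        if any(labels.get(t.transcript_id) == "IR_isoform" for t in g.transcripts)
    )
    n_anta = min(cfg.n_antagonistic_genes, len(candidates))
    anta = (
        [str(g) for g in rng.choice(candidates, size=n_anta, replace=False)]
        if n_anta
        else []
    )
    truth.antagonistic_genes = sorted(anta)
    lights = [c for c in cfg.conditions if c != "D"]
    for gid in truth.antagonistic_genes:
        g = ann.genes[gid]
        ref_id = g.ref_transcript_id
        ir_ids = [
            t.transcript_id
            for t in g.transcripts
            if labels.get(t.transcript_id) == "IR_isoform"
        ]
        for cond in lights:
            mult.loc[ref_id, cond] = 2.0**-cfg.antagonistic_log2fc
            truth.lfc[(ref_id, f"{cond}_vs_D")] = -cfg.antagonistic_log2fc
            for ir_id in ir_ids:
                mult.loc[ir_id, cond] = 2.0**cfg.antagonistic_log2fc
                truth.lfc[(ir_id, f"{cond}_vs_D")] = cfg.antagonistic_log2fc

    sf = rng.uniform(*cfg.library_size_range, size=len(design))
    mu = (
        base[:, None]
        * mult[design["condition"]].to_numpy()
        * sf[None, :]
    )
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_em = ExpressionMatrix(
        values=pd.DataFrame(counts, index=features, columns=design.index),
        design=design,
        kind="counts",
    )
    lengths = {
        t.transcript_id: spliced_length(t)
        for t in ann.transcripts()
        if t.transcript_id in labels
    }
    tpm_em = counts_to_tpm(counts_em, lengths)
    truth.params.update(
        {
            "dispersion": cfg.dispersion,
            "size_factors": {s: float(v) for s, v in zip(design.index, sf)},
        }
    )
    return counts_em, tpm_em, truth


@dataclass
class PtcCase:
    """One randomized intron-retention coding case for PTC assessment.

    ``mode`` is the construction recipe: ``frameshift`` (intron length not
    divisible by 3), ``inframe_random`` (length divisible by 3, random
    content, stops arise naturally), or ``inframe_nostop`` (length
    divisible by 3, T-free content, codon-aligned insertion — provably no
    premature stop can appear).
    """

    genome: dict[str, str]
    ref: TranscriptModel
    alt: TranscriptModel
    events: list
    mode: str


def generate_ir_ptc_cases(
    n: int, seed: int, modes: Sequence[str] = ("frameshift", "inframe_random", "inframe_nostop")
) -> list[PtcCase]:
    """Randomized single-gene IR cases with controlled coding consequences.

    Each case is one gene whose reference isoform carries a long central
    ORF flanked by T-free (hence ATG- and stop-free) UTRs of >= 234 nt, and
    one alternative isoform retaining one intron. The alternative's first
    exon start is trimmed so the reference stays the longest isoform; the
    UTRs are long enough that the trim never removes the start or stop
    codon projection. For ``inframe_nostop`` cases the 5' UTR length is
    adjusted so the retained intron inserts at a codon boundary, which
    together with T-free intron content guarantees no premature stop.
    """
    from .as_classify import ASEvent, EventType  # local import to avoid a cycle

    rng = _substream(seed, 5)
    cases: list[PtcCase] = []
    for idx in range(n):
        mode = modes[int(rng.integers(0, len(modes)))]
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chrP{idx + 1}"
        n_exons = int(rng.integers(3, 6))
        exon_lens = [int(rng.integers(300, 401))] + [
            int(rng.integers(100, 241)) for _ in range(n_exons - 2)
        ] + [int(rng.integers(300, 401))]
        intron_lens = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]
        retained_idx = int(rng.integers(0, n_exons - 1))
        if mode.startswith("inframe"):
            intron_lens[retained_idx] -= intron_lens[retained_idx] % 3

        exons = []
        pos = 50
        for k, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if k < n_exons - 1:
                pos += intron_lens[k]
        exons = tuple(exons)
        L = sum(e.length for e in exons)

        # transcript-orientation position where the retained intron inserts
        if strand == "+":
            ins_tx = sum(e.length for e in exons[: retained_idx + 1])
        else:
            ins_tx = sum(e.length for e in exons[retained_idx + 1 :])
        utr5 = 234 + ((ins_tx - 234) % 3) if mode == "inframe_nostop" else 235
        utr3 = L - utr5 - 3 * ((L - utr5 - 234) // 3)
        orf_len = L - utr5 - utr3  # divisible by 3, >= 234

        body = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), orf_len // 3 - 2)
        )
        spliced = (
            _random_seq(rng, utr5, "ACG") + "ATG" + body + "TAA" + _random_seq(rng, utr3, "ACG")
        )
        genome_seq = spliced if strand == "+" else _revcomp(spliced)

        chrom_seq = bytearray(_random_seq(rng, pos + 50).encode())
        offset = 0
        for e in exons:
            chrom_seq[e.start : e.end] = genome_seq[offset : offset + e.length].encode()
            offset += e.length
        for k, (a, b) in enumerate(zip(exons, exons[1:])):
            ilen = b.start - a.end
            alphabet = "ACG" if (mode == "inframe_nostop" and k == retained_idx) else "ACGT"
            chrom_seq[a.end : b.start] = _random_seq(rng, ilen, alphabet).encode()
        genome = {chrom: bytes(chrom_seq).decode()}

        intron = GenomicInterval(
            chrom, exons[retained_idx].end, exons[retained_idx + 1].start, strand
        )
        fused = GenomicInterval(
            chrom, exons[retained_idx].start, exons[retained_idx + 1].end, strand
        )
        alt_exons = list(exons[:retained_idx]) + [fused] + list(exons[retained_idx + 2 :])
        trim = intron.length + int(rng.integers(1, 21))
        first = alt_exons[0]
        alt_exons[0] = GenomicInterval(chrom, first.start + trim, first.end, strand)

        gene_id = f"P{idx + 1}"
        ref = TranscriptModel(f"{gene_id}.ref", gene_id, exons)
        alt = TranscriptModel(f"{gene_id}.alt", gene_id, tuple(alt_exons))
        event = ASEvent(
            type=EventType.IR,
            gene_id=gene_id,
            ref_id=ref.transcript_id,
            alt_id=alt.transcript_id,
            region=intron,
            retained_in="alt",
        )
        cases.append(PtcCase(genome=genome, ref=ref, alt=alt, events=[event], mode=mode))
    return cases


def generate_term_mapping(
    genes: Sequence[str],
    seed: int,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (10, 80),
    planted: tuple[str, Sequence[str]] | None = None,
) -> dict[str, tuple[str, set[str]]]:
    """Random term-to-gene mapping, optionally with one planted gene set.

    *planted* is a (term_id, gene list) pair inserted verbatim, giving a
    term that is genuinely over-represented in any study set drawn from
    those genes.
    """
    rng = _substream(seed, 4)
    genes = list(genes)
    mapping: dict[str, tuple[str, set[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(genes))
        members = set(rng.choice(genes, size=size, replace=False))
        term_id = f"TERM:{i + 1:04d}"
        mapping[term_id] = (f"synthetic term {i + 1}", members)
    if planted is not None:
        term_id, members = planted
        mapping[term_id] = ("planted term", set(members))
    return mapping
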