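"""End-to-end orchestration: simulate -> classify -> ptc -> de -> enrich -> report.

The pipeline either consumes user-supplied inputs (GFF3 annotation, genome
FASTA, count/design tables, term mapping) or, when none are given,
generates a fully synthetic study with known ground truth. Every stage
logs its input/output row counts; the report bundle is a directory of
plain TSV tables plus a machine-readable run manifest. Reruns with the
same configuration and seed produce byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import AnnotationSet, read_gff3, spliced_length, write_gff3
from .as_classify import (
    EventType,
    classify_annotation,
    events_to_frame,
    merge_across_sources,
    summarize,
)
from .expression_de import (
    DEFAULT_CONTRASTS,
    ExpressionMatrix,
    compare_de_fraction,
    counts_to_tpm,
    de_summary,
    expression_summary,
    nb_wald_contrast,
    pathway_heatmap_matrix,
)
from .go_enrich import enrich, enrichment_to_frame, read_term_mapping
from .orf_ptc import assess_ptc
from .synthetic_data import (
    SimConfig,
    generate_annotation_with_events,
    generate_coding_genome,
    generate_term_mapping,
    per_source_annotations,
    simulate_counts,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "REPORT_FILES"]

logger = logging.getLogger("splicelight")

REPORT_FILES = (
    "as_summary.tsv",
    "event_types.tsv",
    "tissue_overlap.tsv",
    "events.tsv",
    "expression_summary.tsv",
    "de_summary.tsv",
    "de_fraction_test.tsv",
    "heatmap_matrix.tsv",
    "enrichment.tsv",
    "ptc_assessments.tsv",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths, thresholds and the contrast plan for one run."""

    out_dir: str
    seed: int = 0
    tpm_cutoff: float = 1.0
    alpha: float = 0.05
    min_term_size: int = 10
    contrasts: list = field(default_factory=lambda: [list(c) for c in DEFAULT_CONTRASTS])
    sim: SimConfig = field(default_factory=SimConfig)
    annotation_gff3: str | None = None
    novel_gff3s: list = field(default_factory=list)
    genome_fasta: str | None = None
    counts_tsv: str | None = None
    design_tsv: str | None = None
    term_mapping_tsv: str | None = None
    pathway_genes_txt: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tpm_cutoff < 0:
            raise ValueError("tpm_cutoff must be non-negative")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {})) if "sim" in raw else SimConfig()
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the analysis, not where it lands
        payload["sim"]["tissue_overlap"] = {
            "|".join(sorted(k)): v for k, v in payload["sim"]["tissue_overlap"].items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [
        h
        for h in logger.handlers
        if not isinstance(h, logging.FileHandler)
    ]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage in dependency order; return the report bundle paths.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    bundle: dict[str, Path] = {}

    def _stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                fn()
                logger.info("stage %s: done", name)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return deco

    state: dict = {}

    @_stage("simulate")
    def _simulate():
        if cfg.annotation_gff3:
            ann = read_gff3(cfg.annotation_gff3)
            novel = [(Path(p).stem, read_gff3(p)) for p in cfg.novel_gff3s]
            truth = None
            logger.info("loaded annotation: %d genes", ann.n_genes)
        else:
            ann, truth = generate_annotation_with_events(cfg.sim, cfg.seed)
            novel = [
                (label, sub)
                for label, sub in sorted(per_source_annotations(ann, truth).items())
            ]
            gff_path = out / "annotation.gff3"
            write_gff3(ann, str(gff_path))
            bundle["annotation.gff3"] = gff_path
            logger.info("simulated annotation: %d genes", ann.n_genes)
        state["ann"], state["truth"], state["novel"] = ann, truth, novel

        if cfg.counts_tsv and cfg.design_tsv:
            design = pd.read_csv(cfg.design_tsv, sep="\t").set_index("sample_id")
            values = pd.read_csv(cfg.counts_tsv, sep="\t", index_col=0)
            counts = ExpressionMatrix(values=values, design=design, kind="counts")
            lengths = {
                t.transcript_id: spliced_length(t) for t in state["ann"].transcripts()
            }
            tpm = counts_to_tpm(counts, lengths)
        else:
            counts, tpm, truth = simulate_counts(
                state["ann"], cfg.sim, cfg.seed, state["truth"]
            )
            state["truth"] = truth
            counts.values.to_csv(out / "counts.tsv", sep="\t")
            tpm.values.to_csv(out / "tpm.tsv", sep="\t", float_format="%.6f")
            counts.design.to_csv(out / "design.tsv", sep="\t")
        state["counts"], state["tpm"] = counts, tpm
        logger.info(
            "expression: %d features x %d samples", *counts.values.shape
        )

    @_stage("classify")
    def _classify():
        ann = state["ann"]
        if state["novel"]:
            per_source = [
                (label, classify_annotation(sub)) for label, sub in state["novel"]
            ]
            cls = merge_across_sources(per_source)
        else:
            cls = classify_annotation(ann)
        state["cls"] = cls
        summary = summarize(cls, ann)
        state["summary"] = summary
        ev = events_to_frame(cls)
        _write_tsv(ev, out / "events.tsv")
        bundle["events.tsv"] = out / "events.tsv"
        logger.info("classified %d isoforms, %d events", len(cls), len(ev))

        rows = [
            ("n_as_genes", summary.n_as_genes),
            ("n_ir_genes", summary.n_ir_genes),
            ("n_as_isoforms", summary.n_as_isoforms),
            ("n_ir_isoforms", summary.n_ir_isoforms),
            ("n_events", summary.n_events),
        ]
        _write_tsv(pd.DataFrame(rows, columns=["metric", "value"]), out / "as_summary.tsv")
        bundle["as_summary.tsv"] = out / "as_summary.tsv"

        et = pd.DataFrame(
            [
                {
                    "type": t.value,
                    "n_events": summary.events_by_type[t],
                    "pct_of_events": summary.event_type_proportions[t],
                    "pct_of_as_isoforms": summary.isoform_type_proportions[t],
                }
                for t in EventType
            ]
        )
        _write_tsv(et, out / "event_types.tsv")
        bundle["event_types.tsv"] = out / "event_types.tsv"

        ov = pd.DataFrame(
            sorted(
                (
                    {"sources": ",".join(sorted(k)), "n_isoforms": v}
                    for k, v in summary.source_overlap_counts.items()
                ),
                key=lambda r: r["sources"],
            )
        )
        _write_tsv(ov, out / "tissue_overlap.tsv")
        bundle["tissue_overlap.tsv"] = out / "tissue_overlap.tsv"

    @_stage("ptc")
    def _ptc():
        ann = state["ann"]
        if cfg.genome_fasta:
            import pyfaidx

            genome = pyfaidx.Fasta(cfg.genome_fasta)
        elif state["truth"] is not None:
            genome = generate_coding_genome(ann, cfg.seed)
        else:
            logger.info("no genome available; PTC stage writes an empty table")
            genome = None
        rows = []
        if genome is not None:
            for c in state["cls"]:
                if not any(
                    e.type is EventType.IR and e.retained_in == "alt" for e in c.events
                ):
                    continue
                a = assess_ptc(genome, c.ref_model, c.alt_model, c.events)
                rows.append(
                    {
                        "alt_id": a.alt_id,
                        "gene_id": c.gene_id,
                        "has_ptc": a.has_ptc,
                        "ptc_transcript_pos": (
                            "" if a.ptc_transcript_pos is None else a.ptc_transcript_pos
                        ),
                        "ptc_in_retained_intron": a.ptc_in_retained_intron,
                        "nmd_candidate": a.nmd_candidate,
                        "note": a.truncation_note,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=[
                "alt_id",
                "gene_id",
                "has_ptc",
                "ptc_transcript_pos",
                "ptc_in_retained_intron",
                "nmd_candidate",
                "note",
            ],
        )
        _write_tsv(df, out / "ptc_assessments.tsv")
        bundle["ptc_assessments.tsv"] = out / "ptc_assessments.tsv"
        logger.info("PTC assessed for %d IR isoforms", len(df))

    @_stage("de")
    def _de():
        counts, tpm = state["counts"], state["tpm"]
        labels = _feature_labels(state["ann"], state["cls"])
        state["labels"] = labels

        es = expression_summary(tpm, labels, cutoff=cfg.tpm_cutoff)
        _write_tsv(es, out / "expression_summary.tsv")
        bundle["expression_summary.tsv"] = out / "expression_summary.tsv"

        if not cfg.contrasts:
            logger.info("empty contrast plan; DE stage skipped")
            state["de"] = {}
            for name in ("de_summary.tsv", "de_fraction_test.tsv"):
                _write_tsv(pd.DataFrame(), out / name)
                bundle[name] = out / name
        else:
            results = {}
            for test, base in [tuple(c) for c in cfg.contrasts]:
                res = nb_wald_contrast(counts, (test, base), alpha=cfg.alpha)
                results[f"{test}_vs_{base}"] = res
                _write_tsv(res.reset_index(), out / f"de_{test}_vs_{base}.tsv")
            state["de"] = results
            summary = de_summary(results, labels)
            _write_tsv(summary, out / "de_summary.tsv")
            bundle["de_summary.tsv"] = out / "de_summary.tsv"

            frac_rows = []
            for contrast, res in results.items():
                lab = pd.Series(labels).reindex(res.index)
                ir = res[lab == "IR_isoform"]
                non = res[lab == "non_AS_gene"]
                if len(ir) and len(non):
                    chi2, p = compare_de_fraction(
                        int(ir["significant"].sum()),
                        len(ir),
                        int(non["significant"].sum()),
                        len(non),
                    )
                    frac_rows.append(
                        {
                            "contrast": contrast,
                            "ir_de": int(ir["significant"].sum()),
                            "ir_total": len(ir),
                            "non_as_de": int(non["significant"].sum()),
                            "non_as_total": len(non),
                            "chi2": chi2,
                            "p": p,
                        }
                    )
            _write_tsv(pd.DataFrame(frac_rows), out / "de_fraction_test.tsv")
            bundle["de_fraction_test.tsv"] = out / "de_fraction_test.tsv"
            logger.info("DE run for %d contrasts", len(results))

        pathway_genes = _pathway_genes(cfg, state)
        mat, annot = pathway_heatmap_matrix(tpm, pathway_genes, state["ann"])
        hm = mat.copy()
        hm.insert(0, "row", mat.index)
        _write_tsv(hm.merge(annot, on="row"), out / "heatmap_matrix.tsv")
        bundle["heatmap_matrix.tsv"] = out / "heatmap_matrix.tsv"

    @_stage("enrich")
    def _enrich():
        if not cfg.contrasts or not state.get("de"):
            logger.info("no DE results; enrichment stage skipped")
            _write_tsv(pd.DataFrame(), out / "enrichment.tsv")
            bundle["enrichment.tsv"] = out / "enrichment.tsv"
            return
        ann = state["ann"]
        universe = sorted(ann.genes)
        gene_of = {
            t.transcript_id: g.gene_id
            for g in ann.genes.values()
            for t in g.transcripts
        }
        if cfg.term_mapping_tsv:
            mapping = read_term_mapping(cfg.term_mapping_tsv)
        else:
            mapping = generate_term_mapping(universe, cfg.seed)
        labels = state["labels"]
        frames = []
        for contrast, res in state["de"].items():
            lab = pd.Series(labels).reindex(res.index)
            de_ir = res[(lab == "IR_isoform") & res["significant"]]
            study = sorted({gene_of[f] for f in de_ir.index})
            if not study:
                continue
            rows = enrich(
                study, universe, mapping, min_term_size=cfg.min_term_size, alpha=cfg.alpha
            )
            df = enrichment_to_frame(rows)
            df.insert(0, "contrast", contrast)
            frames.append(df)
        enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        _write_tsv(enr, out / "enrichment.tsv")
        bundle["enrichment.tsv"] = out / "enrichment.tsv"
        logger.info("enrichment rows: %d", len(enr))

    @_stage("report")
    def _report():
        manifest = {
            "tool": "splicelight",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "report_files": sorted(name for name in bundle),
            "row_counts": {
                name: sum(1 for _ in open(path)) - 1
                for name, path in sorted(bundle.items())
                if str(path).endswith(".tsv")
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        bundle["manifest.json"] = out / "manifest.json"

    return bundle


def _feature_labels(ann: AnnotationSet, cls) -> dict[str, str]:
    """Partition features: IR isoform / other AS isoform / ref isoform / non-AS gene."""
    by_alt = {c.alt_id: c for c in cls}
    labels: dict[str, str] = {}
    for g in ann.genes.values():
        if len(g.transcripts) == 1:
            labels[g.transcripts[0].transcript_id] = "non_AS_gene"
            continue
        for t in g.transcripts:
            if t.transcript_id == g.ref_transcript_id:
                labels[t.transcript_id] = "ref_isoform"
            else:
                c = by_alt.get(t.transcript_id)
                if c is not None and any(e.type is EventType.IR for e in c.events):
                    labels[t.transcript_id] = "IR_isoform"
                else:
                    labels[t.transcript_id] = "other_AS_isoform"
    return labels


def _pathway_genes(cfg: PipelineConfig, state: dict) -> list[str]:
    if cfg.pathway_genes_txt:
        with open(cfg.pathway_genes_txt) as fh:
            return [line.strip() for line in fh if line.strip()]
    truth = state.get("truth")
    if truth is not None and truth.antagonistic_genes:
        return list(truth.antagonistic_genes)
    # fall back to the first few genes carrying IR isoforms
    ir_genes = sorted(
        {
            c.gene_id
            for c in state["cls"]
            if any(e.type is EventType.IR for e in c.events)
        }
    )
    return ir_genes[:10]
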