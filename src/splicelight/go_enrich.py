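"""Hypergeometric over-representation analysis of gene sets.

Given a study set (e.g. the differentially expressed intron-retention
isoforms' genes), a background universe, and a term-to-gene mapping, each
term is tested with the hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the term's background members, n the study
size and k the study members carrying the term. P-values are adjusted by
Benjamini-Hochberg across the tested terms. GeneRatio (k/n) and BgRatio
(K/N) are serialized with thousands separators in the style of published
enrichment tables.

The mapping is consumed as-is: no ontology DAG propagation is performed,
so annotations must already be propagated to ancestor terms if that
semantics is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression_de import bh_adjust

__all__ = [
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "enrich",
    "read_term_mapping",
    "enrichment_to_frame",
]

DEFAULT_MIN_TERM_SIZE = 10


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    k: int  # study genes with the term
    n: int  # study genes total
    K: int  # background genes with the term
    N: int  # background genes total
    p: float
    padj: float
    significant: bool

    @property
    def gene_ratio(self) -> str:
        return f"{self.k:,}/{self.n:,}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K:,}/{self.N:,}"


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), computed in log space.

    *N* population size, *K* marked members, *n* draws, *k* marked draws.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P[X >= k]; scipy parameterization (M, n, N) = (pop, marked, draws)
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


def enrich(
    study: Iterable[str],
    universe: Iterable[str],
    mapping: Mapping[str, tuple[str, set[str]]],
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test every sufficiently large term for over-representation in *study*.

    *mapping* maps term id to (description, gene set); gene sets are
    restricted to the universe before counting, and only terms with at
    least *min_term_size* background members are tested. Rows are sorted
    by adjusted p then term id. Results do not depend on input ordering.
    """
    universe_set = set(universe)
    study_set = set(study)
    if not study_set <= universe_set:
        raise ValueError("study set must be a subset of the universe")
    if not study_set:
        warnings.warn("empty study set; no enrichment computed", stacklevel=2)
        return []
    N = len(universe_set)
    n = len(study_set)
    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(mapping):
        description, genes = mapping[term_id]
        K = len(set(genes) & universe_set)
        if K < min_term_size:
            continue
        k = len(set(genes) & study_set)
        tested.append((term_id, description, k, K))
    if not tested:
        return []
    pvals = [hypergeom_upper_tail(k, n, K, N) for _, _, k, K in tested]
    padj = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term_id=term_id,
            description=description,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            padj=float(q),
            significant=bool(q < alpha),
        )
        for (term_id, description, k, K), p, q in zip(tested, pvals, padj)
    ]
    rows.sort(key=lambda r: (r.padj, r.term_id))
    return rows


def read_term_mapping(path: str) -> dict[str, tuple[str, set[str]]]:
    """Read a term mapping TSV (term_id, description, gene_id per line)."""
    mapping: dict[str, tuple[str, set[str]]] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["term_id", "description", "gene_id"], dtype=str
    )
    for term_id, grp in df.groupby("term_id", sort=True):
        mapping[str(term_id)] = (str(grp["description"].iloc[0]), set(grp["gene_id"]))
    return mapping


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a table with GeneRatio/BgRatio string columns."""
    return pd.DataFrame(
        [
            {
                "ID": r.term_id,
                "Description": r.description,
                "GeneRatio": r.gene_ratio,
                "BgRatio": r.bg_ratio,
                "pvalue": r.p,
                "p.adjust": r.padj,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=["ID", "Description", "GeneRatio", "BgRatio", "pvalue", "p.adjust", "significant"],
    )
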