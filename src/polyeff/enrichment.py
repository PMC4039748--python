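"""Fisher's exact test machinery for motif and GO-term overrepresentation.

Two applications share the same 2x2 machinery:

* TOP-motif occurrence per regulation group versus the remaining groups
  (two-sided by default, following the odds-ratio null);
* classic gene-count GO-term overrepresentation of each group against a
  reference gene list (one-sided 'greater' by default), using true-path
  propagated annotations and no multiple-testing adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RegulationClassification, group_name
from .datamodel import GeneOntology

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact",
    "top_enrichment",
    "go_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in-group & has-feature, b = in-group & lacks,
    c = out-group & has, d = out-group & lacks."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def odds_ratio(self) -> float:
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one overrepresentation test."""

    unit_id: str
    table: ContingencyTable
    p_value: float
    significant: bool


def fisher_exact(table: ContingencyTable, sided: str = "two_sided") -> float:
    """Exact hypergeometric p for a 2x2 table.

    ``two_sided`` sums the probabilities of all tables with the observed
    margins that are no more likely than the observed one; ``greater`` is
    the upper tail of a.
    """
    if sided not in ("two_sided", "greater"):
        raise ValueError("sided must be 'two_sided' or 'greater'")
    alternative = "two-sided" if sided == "two_sided" else "greater"
    return float(stats.fisher_exact(table.as_array(), alternative=alternative)[1])


def top_enrichment(
    classification: RegulationClassification,
    motif_status: Mapping[str, bool],
    sided: str = "two_sided",
    alpha: float = 0.05,
    groups: Sequence[int] = tuple(range(1, 9)),
) -> list[EnrichmentResult]:
    """Test TOP-motif occurrence in each regulation group vs the rest.

    ``motif_status`` maps gene id -> TOP-bearing flag; classified genes with
    no motif status (no UTR available) are excluded and their count logged.
    Significance is called at p < alpha.
    """
    per_gene = classification.per_gene
    in_scope = per_gene[per_gene["group_id"].isin(groups)]
    known = in_scope["gene_id"].map(lambda g: g in motif_status)
    excluded = int((~known).sum())
    if excluded:
        logger.info("%d classified gene(s) without UTR excluded from TOP test", excluded)
    scoped = in_scope[known.to_numpy()]
    bearing = scoped["gene_id"].map(motif_status).to_numpy(dtype=bool)
    gids = scoped["group_id"].to_numpy()

    results = []
    for g in groups:
        mask = gids == g
        a = int((bearing & mask).sum())
        b = int((~bearing & mask).sum())
        c = int((bearing & ~mask).sum())
        d = int((~bearing & ~mask).sum())
        if a + b == 0:
            logger.warning("group %s has zero genes with motif status", group_name(g))
            table = ContingencyTable(a, b, c, d)
            results.append(EnrichmentResult(group_name(g), table, 1.0, False))
            continue
        table = ContingencyTable(a, b, c, d)
        p = fisher_exact(table, sided=sided)
        results.append(EnrichmentResult(group_name(g), table, p, p < alpha))
    return results


def go_enrichment(
    genes_by_group: Mapping[int, Sequence[str]],
    ontology: GeneOntology,
    universe: Sequence[str] | None = None,
    namespace: str = "BP",
    sided: str = "greater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classic gene-count GO overrepresentation per term per group.

    The universe (reference gene list) defaults to the grouped genes that
    carry at least one annotation in the namespace.  Per term t with >= 1
    annotated universe gene: a = |group ∩ genes(t)|, etc.; raw one-sided
    Fisher p, significant at p <= alpha, no multiplicity adjustment.
    Output is sorted by (group, p, term id).
    """
    grouped_genes = {g for genes in genes_by_group.values() for g in genes}
    annotated = ontology.annotated_genes(namespace)
    if universe is None:
        uni = sorted(grouped_genes & annotated)
    else:
        uni = sorted(set(universe))
    if not uni:
        raise ValueError("empty reference gene list (universe)")
    uni_set = set(uni)

    rows = []
    for gid, genes in sorted(genes_by_group.items()):
        group = set(genes) & uni_set
        n_group = len(group)
        for tid in ontology.terms_in_namespace(namespace):
            term_genes = set(ontology.propagated.get(tid, frozenset())) & uni_set
            if not term_genes:
                continue
            a = len(group & term_genes)
            b = n_group - a
            c = len(term_genes) - a
            d = len(uni_set) - a - b - c
            table = ContingencyTable(a, b, c, d)
            p = fisher_exact(table, sided=sided)
            term = ontology.terms[tid]
            rows.append(
                {
                    "group_id": gid,
                    "group_name": group_name(gid),
                    "term_id": tid,
                    "term_name": term.name,
                    "namespace": namespace,
                    "annotated": len(term_genes),
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": table.odds_ratio,
                    "p_value": p,
                    "significant": p <= alpha,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "group_id", "group_name", "term_id", "term_name", "namespace",
            "annotated", "a", "b", "c", "d", "odds_ratio", "p_value",
            "significant",
        ],
    )
    if len(frame):
        frame = frame.sort_values(
            ["group_id", "p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    return frame
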