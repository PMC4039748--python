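"""Core domain containers shared by every stage of the pipeline.

The experimental design is a two-fraction (polysomal / non-polysomal) by
two-timepoint (0 h / 6 h) log2-intensity layout with replicate arrays.
Containers here validate that structure once, so downstream statistics can
assume a well-formed dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

FRACTIONS = ("polysomal", "nonpolysomal")
TIMEPOINTS = (0, 6)
NAMESPACES = ("BP", "MF")


class FormatError(ValueError):
    """A file or in-memory object violates the expected format."""


class OntologyStructureError(ValueError):
    """The is_a graph is not a DAG or references unresolvable terms."""


@dataclass(frozen=True)
class SampleDescriptor:
    """One array: which fraction, which timepoint, which replicate."""

    sample_id: str
    fraction: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise FormatError(
                f"sample {self.sample_id!r}: fraction must be one of "
                f"{FRACTIONS}, got {self.fraction!r}"
            )
        if self.time_h not in TIMEPOINTS:
            raise FormatError(
                f"sample {self.sample_id!r}: time_h must be one of "
                f"{TIMEPOINTS}, got {self.time_h!r}"
            )
        if int(self.replicate) < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )

    @property
    def cell(self) -> tuple[str, int]:
        """Design cell key (fraction, time_h)."""
        return (self.fraction, self.time_h)


@dataclass
class ExpressionDataset:
    """Log2 intensity matrix (genes x samples) plus design metadata.

    ``spikein`` flags control probes of constant true abundance; they anchor
    between-array normalization.
    """

    genes: list[str]
    samples: list[SampleDescriptor]
    values: np.ndarray
    spikein: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spikein = np.asarray(self.spikein, dtype=bool)
        n_genes, n_samples = len(self.genes), len(self.samples)
        if self.values.shape != (n_genes, n_samples):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if self.spikein.shape != (n_genes,):
            raise FormatError("spike-in flag vector length must equal gene count")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        if len(set(self.genes)) != n_genes:
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != n_samples:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cell_columns(self) -> dict[tuple[str, int], list[int]]:
        """Column indices of every populated (fraction, time_h) design cell."""
        cells: dict[tuple[str, int], list[int]] = {}
        for j, s in enumerate(self.samples):
            cells.setdefault(s.cell, []).append(j)
        return cells

    def validate_design(self, min_replicates: int = 2) -> None:
        """Require all four design cells with at least ``min_replicates`` arrays."""
        cells = self.cell_columns()
        for fraction in FRACTIONS:
            for time_h in TIMEPOINTS:
                n = len(cells.get((fraction, time_h), []))
                if n < min_replicates:
                    raise FormatError(
                        f"design cell ({fraction}, {time_h} h) has {n} "
                        f"replicates; need >= {min_replicates}"
                    )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            genes=list(self.genes),
            samples=list(self.samples),
            values=self.values.copy(),
            spikein=self.spikein.copy(),
        )


@dataclass(frozen=True)
class UtrRecord:
    """A 5'UTR sequence, 5'->3', position 1 = the 5' terminus (cap-adjacent)."""

    gene_id: str
    refseq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.refseq_id}: empty 5'UTR sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise FormatError(
                f"{self.refseq_id}: sequence contains characters outside "
                f"A/C/G/T: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TermRecord:
    """One ontology term with its direct is_a parents."""

    term_id: str
    name: str
    namespace: str
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise FormatError(
                f"term {self.term_id}: namespace must be BP or MF, "
                f"got {self.namespace!r}"
            )


@dataclass
class GeneOntology:
    """An is_a DAG over terms plus gene annotations.

    ``annotations`` holds the direct gene -> term links; ``propagated`` maps
    each term to the genes annotated to it or to any of its descendants
    (true-path rule: annotation to a term implies annotation to all its
    ancestors).
    """

    terms: dict[str, TermRecord]
    annotations: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)
    dropped_annotations: int = 0

    def __post_init__(self) -> None:
        for t in self.terms.values():
            unresolved = t.parents - self.terms.keys()
            if unresolved:
                raise OntologyStructureError(
                    f"term {t.term_id}: unresolved is_a parents {sorted(unresolved)}"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(f"is_a graph contains a cycle: {cycle}")
        for gene, tids in self.annotations.items():
            unknown = tids - self.terms.keys()
            if unknown:
                raise OntologyStructureError(
                    f"gene {gene} annotated to unknown terms {sorted(unknown)}"
                )
        if not self.propagated:
            self.propagated = self._propagate()

    def graph(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges along is_a."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.term_id, p)
        return g

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via is_a (excluding itself)."""
        return frozenset(nx.descendants(self.graph(), term_id))

    def _propagate(self) -> dict[str, frozenset[str]]:
        g = self.graph()
        acc: dict[str, set[str]] = {t: set() for t in self.terms}
        for gene, tids in self.annotations.items():
            for tid in tids:
                acc[tid].add(gene)
                for anc in nx.descendants(g, tid):
                    acc[anc].add(gene)
        return {t: frozenset(genes) for t, genes in acc.items()}

    def propagate(self) -> "GeneOntology":
        """Recompute propagated gene sets (idempotent)."""
        return dataclasses.replace(self, propagated=self._propagate())

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(
            t.term_id for t in self.terms.values() if t.namespace == namespace
        )

    def annotated_genes(self, namespace: str) -> frozenset[str]:
        """Genes directly annotated to at least one term of the namespace."""
        ns_terms = set(self.terms_in_namespace(namespace))
        return frozenset(
            gene for gene, tids in self.annotations.items() if tids & ns_terms
        )


def as_metadata_mapping(samples: list[SampleDescriptor]) -> Mapping[str, SampleDescriptor]:
    return {s.sample_id: s for s in samples}
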