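"""Readers and writers for the tabular, FASTA and OBO formats the pipeline touches.

All TSV outputs carry a header row; comment lines starting with '#' are
ignored on input so provenance headers survive a round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ExpressionDataset,
    FormatError,
    GeneOntology,
    OntologyStructureError,
    SampleDescriptor,
    TermRecord,
    UtrRecord,
)

logger = logging.getLogger(__name__)

_NAMESPACE_MAP = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "BP": "BP",
    "MF": "MF",
}


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path: str | Path,
    metadata_path: str | Path,
    spikein_path: str | Path | None = None,
) -> ExpressionDataset:
    """Load a genes x samples log2 TSV plus sample metadata.

    The expression TSV has a ``gene_id`` first column, one column per sample
    and optionally a ``spikein`` 0/1 column.  Alternatively spike-in gene ids
    can be listed one-per-line in ``spikein_path``.
    """
    expr = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if expr.columns[0] != "gene_id":
        raise FormatError(
            f"{path}: first column must be 'gene_id', got {expr.columns[0]!r}"
        )
    genes = expr["gene_id"].tolist()
    if len(set(genes)) != len(genes):
        dupes = expr["gene_id"][expr["gene_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate gene ids {sorted(set(dupes))[:5]}")

    spike = np.zeros(len(genes), dtype=bool)
    value_cols = [c for c in expr.columns[1:] if c != "spikein"]
    if "spikein" in expr.columns:
        spike = expr["spikein"].astype(int).to_numpy().astype(bool)
    if spikein_path is not None:
        listed = {
            line.strip()
            for line in Path(spikein_path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        spike = np.array([g in listed for g in genes], dtype=bool)

    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "fraction", "time_h", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FormatError(f"{metadata_path}: missing columns {sorted(missing_cols)}")
    by_id = {}
    for _, row in meta.iterrows():
        by_id[str(row["sample_id"])] = SampleDescriptor(
            sample_id=str(row["sample_id"]),
            fraction=str(row["fraction"]),
            time_h=int(row["time_h"]),
            replicate=int(row["replicate"]),
        )

    samples = []
    for col in value_cols:
        if col not in by_id:
            raise FormatError(
                f"sample {col!r} present in {path} but missing from metadata "
                f"{metadata_path}"
            )
        samples.append(by_id[col])

    values = np.empty((len(genes), len(value_cols)), dtype=float)
    for j, col in enumerate(value_cols):
        converted = pd.to_numeric(expr[col], errors="coerce")
        bad = converted.isna() & expr[col].notna()
        if bad.any() or converted.isna().any():
            i = int(np.flatnonzero(converted.isna())[0])
            raise FormatError(
                f"{path}: non-numeric value {expr[col].iloc[i]!r} at "
                f"gene {genes[i]!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()

    return ExpressionDataset(genes=genes, samples=samples, values=values, spikein=spike)


def write_expression_table(
    data: ExpressionDataset,
    path: str | Path,
    metadata_path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write the dataset back to the expression + metadata TSV pair."""
    frame = pd.DataFrame(
        data.values, columns=[s.sample_id for s in data.samples]
    )
    frame.insert(0, "gene_id", data.genes)
    frame["spikein"] = data.spikein.astype(int)
    _write_tsv(frame, path, header_comments)

    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in data.samples],
            "fraction": [s.fraction for s in data.samples],
            "time_h": [s.time_h for s in data.samples],
            "replicate": [s.replicate for s in data.samples],
        }
    )
    _write_tsv(meta, metadata_path, header_comments)


def _write_tsv(
    frame: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


write_table = _write_tsv


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[UtrRecord]:
    """Parse 5'UTR records; header = refseq id, optional ``gene=`` tag.

    Sequences are upper-cased and U is mapped to T; any other non-ACGT
    character is rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        refseq_id = rec.id
        gene_id = refseq_id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence under header {refseq_id!r}")
        bad = set(seq) - set("ACGT")
        if bad:
            raise FormatError(
                f"{path}: sequence {refseq_id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        records.append(UtrRecord(gene_id=gene_id, refseq_id=refseq_id, sequence=seq))
    return records


def write_fasta(records: Iterable[UtrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.refseq_id} gene={rec.gene_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# ontology


def read_ontology(
    obo_path: str | Path, annotation_path: str | Path
) -> GeneOntology:
    """Load an OBO term DAG and a two-column gene->term annotation TSV.

    Obsolete terms and terms outside BP/MF are dropped; annotations pointing
    at unknown terms are dropped with a logged count (available as
    ``dropped_annotations``).  A cycle in the is_a graph is a structural error.
    """
    graph = obonet.read_obo(str(obo_path), ignore_obsolete=True)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyStructureError(f"{obo_path}: is_a cycle {cycle}")

    terms: dict[str, TermRecord] = {}
    kept_ids = set()
    for tid, attrs in graph.nodes(data=True):
        ns = _NAMESPACE_MAP.get(attrs.get("namespace", ""))
        if ns is None:
            continue
        kept_ids.add(tid)
    for tid, attrs in graph.nodes(data=True):
        if tid not in kept_ids:
            continue
        ns = _NAMESPACE_MAP[attrs.get("namespace")]
        parents = frozenset(
            p for _, p, key in graph.out_edges(tid, keys=True)
            if key == "is_a" and p in kept_ids
        )
        terms[tid] = TermRecord(
            term_id=tid, name=attrs.get("name", tid), namespace=ns, parents=parents
        )

    ann = pd.read_csv(
        annotation_path, sep="\t", comment="#", header=None,
        names=["gene_id", "term_id"], dtype=str,
    )
    if len(ann) and tuple(ann.iloc[0]) == ("gene_id", "term_id"):
        ann = ann.iloc[1:]

    annotations: dict[str, set[str]] = {}
    dropped = 0
    for gene, tid in ann.itertuples(index=False):
        if tid not in terms:
            dropped += 1
            continue
        annotations.setdefault(gene, set()).add(tid)
    if dropped:
        logger.warning(
            "%d annotation(s) referenced unknown/obsolete terms and were dropped",
            dropped,
        )
    return GeneOntology(
        terms=terms,
        annotations={g: frozenset(t) for g, t in annotations.items()},
        dropped_annotations=dropped,
    )


def write_obo(ontology: GeneOntology, path: str | Path) -> None:
    """Serialize the term DAG as a minimal OBO 1.2 document."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go-subset\n")
        for tid in sorted(ontology.terms):
            t = ontology.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.term_id}\n")
            fh.write(f"name: {t.name}\n")
            fh.write(f"namespace: {ns_long[t.namespace]}\n")
            for p in sorted(t.parents):
                fh.write(f"is_a: {p} ! {ontology.terms[p].name}\n")


def write_annotations(ontology: GeneOntology, path: str | Path) -> None:
    rows = [
        {"gene_id": gene, "term_id": tid}
        for gene in sorted(ontology.annotations)
        for tid in sorted(ontology.annotations[gene])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path)
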