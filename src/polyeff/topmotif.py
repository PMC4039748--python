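"""5' terminal oligopyrimidine (TOP) motif scanning.

A TOP motif here is a cap-adjacent C followed by an uninterrupted pyrimidine
(C/T) run of at least ``min_pyrimidines`` bases, terminated by a G.  The scan
is anchored at position 1 and continues immediately after each hit, so
consecutive motifs (as seen for Rpl30 and Polr2h) are reported as separate,
contiguous hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import UtrRecord

__all__ = ["TopMotifHit", "scan_top", "scan_all"]

_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class TopMotifHit:
    """One motif occurrence; start/end are 1-based inclusive."""

    refseq_id: str
    gene_id: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.matched[0] != "C" or self.matched[-1] != "G":
            raise ValueError("a TOP motif must start with C and end with G")
        interior = self.matched[1:-1]
        if not interior or any(c not in _PYRIMIDINES for c in interior):
            raise ValueError("motif interior must be a nonempty pyrimidine run")
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("coordinates inconsistent with matched sequence")


def _scan_sequence(seq: str, min_pyrimidines: int, anchor: int) -> list[tuple[int, int]]:
    """Chain of (start, end) 0-based-exclusive hits beginning at ``anchor``."""
    hits: list[tuple[int, int]] = []
    q = anchor
    n = len(seq)
    while q < n and seq[q] == "C":
        j = q + 1
        while j < n and seq[j] in _PYRIMIDINES:
            j += 1
        run = j - q - 1
        if run >= min_pyrimidines and j < n and seq[j] == "G":
            hits.append((q, j + 1))
            q = j + 1
        else:
            break
    return hits


def scan_top(
    utr: UtrRecord | str,
    min_pyrimidines: int = 3,
    internal: bool = False,
) -> list[TopMotifHit]:
    """Scan one 5'UTR for TOP motifs.

    By default only the motif chain anchored at position 1 is reported.
    With ``internal=True`` chains starting at any downstream C are also
    scanned (non-overlapping, left to right).
    """
    if isinstance(utr, str):
        if not utr:
            return []
        utr = UtrRecord(gene_id="", refseq_id="", sequence=utr.upper().replace("U", "T"))
    seq = utr.sequence
    spans = _scan_sequence(seq, min_pyrimidines, 0)
    if internal:
        q = spans[-1][1] if spans else 1
        while q < len(seq):
            more = _scan_sequence(seq, min_pyrimidines, q)
            if more:
                spans.extend(more)
                q = more[-1][1]
            else:
                q += 1
    return [
        TopMotifHit(
            refseq_id=utr.refseq_id,
            gene_id=utr.gene_id,
            start=a + 1,
            end=b,
            matched=seq[a:b],
        )
        for a, b in spans
    ]


def scan_all(
    utrs: list[UtrRecord], min_pyrimidines: int = 3, internal: bool = False
) -> pd.DataFrame:
    """Per-gene motif summary over a set of UTRs.

    Returns one row per gene with columns gene_id, n_hits, top_bearing
    (>= 1 hit on any of the gene's UTRs), consecutive (>= 2 contiguous hits
    on a single UTR) and the hit list flattened as a table attribute
    ``hits`` (refseq_id, gene_id, sequence_length, start, end, matched).
    """
    hit_rows = []
    per_gene: dict[str, dict] = {}
    for utr in utrs:
        hits = scan_top(utr, min_pyrimidines=min_pyrimidines, internal=internal)
        rec = per_gene.setdefault(
            utr.gene_id, {"gene_id": utr.gene_id, "n_hits": 0, "consecutive": False}
        )
        rec["n_hits"] += len(hits)
        if len(hits) >= 2:
            rec["consecutive"] = True
        for h in hits:
            hit_rows.append(
                {
                    "refseq_id": h.refseq_id,
                    "gene_id": h.gene_id,
                    "sequence_length": utr.length,
                    "start": h.start,
                    "end": h.end,
                    "matched": h.matched,
                }
            )
    summary = pd.DataFrame(
        [
            {
                "gene_id": rec["gene_id"],
                "n_hits": rec["n_hits"],
                "top_bearing": rec["n_hits"] >= 1,
                "consecutive": rec["consecutive"],
            }
            for rec in per_gene.values()
        ],
        columns=["gene_id", "n_hits", "top_bearing", "consecutive"],
    )
    summary.attrs["hits"] = pd.DataFrame(
        hit_rows,
        columns=["refseq_id", "gene_id", "sequence_length", "start", "end", "matched"],
    )
    return summary
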