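"""Shared fixtures: published motif coordinates and small seeded datasets."""

from __future__ import annotations

import numpy as np
import pytest

import polyeff as pe

# Published 5'TOP motif table for the TC:up/TL:up group: per gene the RefSeq
# id, the 5'UTR length, and the printed (start, end, matched) motif chain.
# Genes with two entries carry two consecutive motifs.
TABLE2_MOTIFS: dict[str, tuple[str, int, list[tuple[int, int, str]]]] = {
    "Prei4": ("NM_001042672", 205, [(1, 6, "CCTTCG")]),
    "Dpm1": ("NM_010072", 26, [(1, 6, "CTTCCG")]),
    "Rps21": ("NM_025587", 82, [(1, 6, "CTCCTG")]),
    "Rpl35": ("NM_025592", 45, [(1, 12, "CTCTTTCTCTCG")]),
    "Rps27": ("NM_027015", 33, [(1, 8, "CCTTTCCG")]),
    "Dph5": ("NM_027193", 118, [(1, 5, "CTCTG")]),
    "Rps6": ("NM_009096", 41, [(1, 10, "CTCTTTTTCG")]),
    "Rps20": ("NM_026147", 114, [(1, 8, "CCTTTCTG")]),
    "Tpst2": ("NM_009419", 168, [(1, 5, "CCTCG")]),
    "Rpl32": ("NM_172086", 51, [(1, 11, "CTTCTTCCTCG")]),
    "Rpl28": ("NM_009081", 42, [(1, 9, "CTCTTTCCG")]),
    "Rplp2": ("NM_026020", 59, [(1, 7, "CCTTTCG")]),
    "Rps15a": ("NM_170669", 17, [(1, 9, "CTTCCCTCG")]),
    "Gatad2a": ("NM_145596", 540, [(1, 6, "CCCTCG")]),
    "Rpl14": ("NM_025974", 22, [(1, 7, "CTTCTCG")]),
    "Acsl4": ("NM_207625", 460, [(1, 8, "CTTTTCCG")]),
    "Atp5d": ("NM_025313", 151, [(1, 6, "CCTTCG")]),
    "Nrn1": ("NM_153529", 164, [(1, 8, "CTTCCTCG")]),
    "E430028B21Rik": ("NM_178668", 294, [(1, 6, "CCCTCG")]),
    "Rpl30": (
        "NM_009083", 180,
        [(1, 12, "CTTCCTTTCTCG"), (13, 19, "CTCCCCG")],
    ),
    "Bop1": ("NM_013481", 48, [(1, 6, "CTCCCG")]),
    "Polr2h": ("NM_145632", 96, [(1, 5, "CTCTG"), (6, 10, "CCCTG")]),
    "Rps28": ("NM_016844", 26, [(1, 10, "CTCCTCTCCG")]),
}

# Published nine-group sizes (group id 1..9).
TABLE1_SIZES = {1: 813, 2: 754, 3: 25, 4: 660, 5: 10, 6: 87, 7: 358, 8: 37, 9: 2536}


@pytest.fixture(scope="session")
def table2_utrs() -> list[pe.UtrRecord]:
    """UTR records whose 5' ends are the printed per-gene motif chains,
    padded with a motif-free tail up to the printed sequence length."""
    rng = np.random.default_rng(20140518)
    records = []
    for gene, (refseq, length, hits) in TABLE2_MOTIFS.items():
        prefix = "".join(m for _, _, m in hits)
        tail_len = max(0, length - len(prefix))
        # tail opens with A so it cannot extend the motif chain
        tail = "A" + "".join(rng.choice(list("ACGT"), size=max(0, tail_len - 1)))
        records.append(
            pe.UtrRecord(gene_id=gene, refseq_id=refseq, sequence=prefix + tail)
        )
    return records


@pytest.fixture(scope="session")
def small_dataset() -> tuple[pe.ExpressionDataset, pe.GroundTruth]:
    cfg = pe.SimulationConfig(n_genes=300, n_spikeins=10, seed=11)
    return pe.simulate_expression(cfg)


def make_dataset(values, spikein=None, r=None):
    """Build an ExpressionDataset from a (genes x samples) array laid out as
    [p0 x r, p6 x r, np0 x r, np6 x r]."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if r is None:
        r = n_samples // 4
    samples = []
    for fraction, time_h, tag in (
        ("polysomal", 0, "p0"),
        ("polysomal", 6, "p6"),
        ("nonpolysomal", 0, "np0"),
        ("nonpolysomal", 6, "np6"),
    ):
        for rep in range(1, r + 1):
            samples.append(
                pe.SampleDescriptor(f"{tag}_r{rep}", fraction, time_h, rep)
            )
    if spikein is None:
        spikein = np.zeros(n_genes, dtype=bool)
    return pe.ExpressionDataset(
        genes=[f"g{i}" for i in range(n_genes)],
        samples=samples,
        values=values,
        spikein=np.asarray(spikein, dtype=bool),
    )
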