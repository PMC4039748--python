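"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-fraction x two-timepoint log2-intensity design:
gene-wise variances follow a scaled inverse-chi-square prior (the conjugate
form assumed by the moderated t-test), planted TC/TL effects follow the
nine-group taxonomy, per-array additive offsets hit every probe including
spike-ins (so spike-in normalization can remove them exactly), TOP motifs
are planted at the 5' terminus of flagged genes, and a toy GO DAG carries
planted term enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import GROUP_TABLE, group_name
from .datamodel import (
    ExpressionDataset,
    GeneOntology,
    SampleDescriptor,
    TermRecord,
    UtrRecord,
)
from .topmotif import scan_top

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_utrs",
    "simulate_ontology",
]

# Relative group sizes of the published classification (groups 1..9); used as
# the default composition of the simulated transcriptome.
_DEFAULT_PROPORTIONS = np.array(
    [813, 754, 25, 660, 10, 87, 358, 37, 2536], dtype=float
)
_DEFAULT_PROPORTIONS /= _DEFAULT_PROPORTIONS.sum()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Effects are log2 units; the default 1.25-3.0 magnitude range straddles
    the |log2FC| > 1 significance rule.  ``d0``/``s0_sq`` parameterize the
    scaled inverse-chi-square variance prior; ``array_offset_sd`` is the SD
    of the per-array additive offset removable via spike-ins.
    """

    n_genes: int = 2000
    n_spikeins: int = 20
    replicates: int = 3
    group_proportions: np.ndarray = field(
        default_factory=lambda: _DEFAULT_PROPORTIONS.copy()
    )
    effect_low: float = 1.25
    effect_high: float = 3.0
    d0: float = 4.0
    s0_sq: float = 0.05
    array_offset_sd: float = 0.25
    top_probability_by_group: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.5, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]
        )
    )
    baseline_low: float = 6.0
    baseline_high: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_proportions = np.asarray(self.group_proportions, dtype=float)
        self.top_probability_by_group = np.asarray(
            self.top_probability_by_group, dtype=float
        )
        if self.n_genes < 1 or self.n_spikeins < 0 or self.replicates < 2:
            raise ValueError("counts must be positive (replicates >= 2)")
        if self.group_proportions.shape != (9,) or np.any(self.group_proportions < 0):
            raise ValueError("group_proportions must be 9 nonnegative weights")
        if abs(self.group_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if not (0 <= self.effect_low <= self.effect_high):
            raise ValueError("need 0 <= effect_low <= effect_high")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ValueError("d0 and s0_sq must be positive")
        if self.top_probability_by_group.shape != (9,):
            raise ValueError("top_probability_by_group must have 9 entries")


@dataclass
class GroundTruth:
    """Planted per-gene parameters of a simulated dataset."""

    gene_ids: list[str]
    tc: np.ndarray
    tl: np.ndarray
    group_id: np.ndarray
    sigma_sq: np.ndarray
    top_flag: np.ndarray
    spikein: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "true_TC": self.tc,
                "true_TL": self.tl,
                "true_group_id": self.group_id,
                "true_group_name": [group_name(int(g)) for g in self.group_id],
                "sigma_sq": self.sigma_sq,
                "top_flag": self.top_flag.astype(int),
                "spikein": self.spikein.astype(int),
            }
        )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainder."""
    quotas = weights * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a seeded dataset with planted TC/TL effects.

    Condition means are built so the population contrasts equal the drawn
    effects: both 0 h cells sit at the gene baseline; the polysomal 6 h cell
    adds TC + TL/2 and the non-polysomal 6 h cell adds TC - TL/2.
    """
    rng = np.random.default_rng(config.seed)
    n, r = config.n_genes, config.replicates
    gene_ids = [f"g{i:05d}" for i in range(n)]
    spike_ids = [f"spike{i:03d}" for i in range(config.n_spikeins)]
    all_ids = gene_ids + spike_ids
    n_all = len(all_ids)
    spikein = np.array([False] * n + [True] * config.n_spikeins)

    counts = _largest_remainder(config.group_proportions, n)
    group_id = np.concatenate(
        [np.full(c, gid) for gid, c in zip(GROUP_TABLE, counts)]
    )
    rng.shuffle(group_id)
    group_id = np.concatenate([group_id, np.full(config.n_spikeins, 9)])

    def signed_effect(status: np.ndarray) -> np.ndarray:
        mag = rng.uniform(config.effect_low, config.effect_high, size=n_all)
        sign = np.where(status == "up", 1.0, np.where(status == "down", -1.0, 0.0))
        return mag * sign

    tc_status = np.array([GROUP_TABLE[int(g)][0] for g in group_id])
    tl_status = np.array([GROUP_TABLE[int(g)][1] for g in group_id])
    tc = signed_effect(tc_status)
    tl = signed_effect(tl_status)
    tc[spikein] = 0.0
    tl[spikein] = 0.0

    sigma_sq = config.s0_sq * config.d0 / rng.chisquare(config.d0, size=n_all)
    baseline = rng.uniform(config.baseline_low, config.baseline_high, size=n_all)

    samples = []
    cell_offsets = {
        ("polysomal", 0): np.zeros(n_all),
        ("polysomal", 6): tc + tl / 2.0,
        ("nonpolysomal", 0): np.zeros(n_all),
        ("nonpolysomal", 6): tc - tl / 2.0,
    }
    columns = []
    for fraction in ("polysomal", "nonpolysomal"):
        for time_h in (0, 6):
            for rep in range(1, r + 1):
                tag = "p" if fraction == "polysomal" else "np"
                samples.append(
                    SampleDescriptor(
                        sample_id=f"{tag}{time_h}_r{rep}",
                        fraction=fraction,
                        time_h=time_h,
                        replicate=rep,
                    )
                )
                mu = baseline + cell_offsets[(fraction, time_h)]
                noise = rng.normal(0.0, np.sqrt(sigma_sq))
                array_offset = rng.normal(0.0, config.array_offset_sd)
                columns.append(mu + noise + array_offset)

    values = np.column_stack(columns)
    data = ExpressionDataset(
        genes=all_ids, samples=samples, values=values, spikein=spikein
    )
    top_p = config.top_probability_by_group[group_id.astype(int) - 1]
    top_flag = rng.random(n_all) < top_p
    top_flag[spikein] = False
    truth = GroundTruth(
        gene_ids=all_ids,
        tc=tc,
        tl=tl,
        group_id=group_id.astype(int),
        sigma_sq=sigma_sq,
        top_flag=top_flag,
        spikein=spikein,
    )
    return data, truth


def _random_tail(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_utrs(truth: GroundTruth, seed: int = 0) -> list[UtrRecord]:
    """One 5'UTR per non-spike-in gene; TOP-flagged genes open with a motif.

    Flagged genes get C + 3-12 pyrimidines + G + a 20-200 nt random tail;
    unflagged genes get a random sequence redrawn until position 1 does not
    open a TOP motif.
    """
    rng = np.random.default_rng(seed)
    records = []
    for gene, flagged, spike in zip(truth.gene_ids, truth.top_flag, truth.spikein):
        if spike:
            continue
        if flagged:
            n_pyr = int(rng.integers(3, 13))
            interior = "".join(rng.choice(list("CT"), size=n_pyr))
            seq = "C" + interior + "G" + _random_tail(rng, int(rng.integers(20, 201)))
        else:
            while True:
                seq = _random_tail(rng, int(rng.integers(20, 201)))
                if not scan_top(UtrRecord(gene_id=gene, refseq_id=gene, sequence=seq)):
                    break
        records.append(UtrRecord(gene_id=gene, refseq_id=f"SYN_{gene}", sequence=seq))
    return records


def simulate_ontology(
    genes: list[str],
    n_terms: int = 30,
    enriched_term_fraction: float = 0.1,
    target_group_genes: list[str] | None = None,
    background_p: float = 0.05,
    enriched_p: float = 0.25,
    namespace: str = "BP",
    seed: int = 0,
) -> tuple[GeneOntology, list[str]]:
    """Random rooted is_a DAG with planted term enrichment.

    Each non-root term picks 1-2 parents among earlier terms (guaranteeing
    acyclicity).  Designated enriched terms annotate ``target_group_genes``
    with probability ``enriched_p`` instead of ``background_p``.  Returns
    the ontology and the list of enriched term ids.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if n_terms < 2:
        raise ValueError("need at least two terms")
    rng = np.random.default_rng(seed)
    target = set(target_group_genes or [])

    term_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    terms: dict[str, TermRecord] = {
        term_ids[0]: TermRecord(term_ids[0], "root", namespace, frozenset())
    }
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(2, i) + 1))
        parents = frozenset(
            rng.choice(term_ids[:i], size=k, replace=False).tolist()
        )
        terms[term_ids[i]] = TermRecord(
            term_ids[i], f"term {i}", namespace, parents
        )

    n_enriched = max(1, int(round(enriched_term_fraction * (n_terms - 1))))
    # enrich leaf-ward terms (skip the root, which annotates everything)
    enriched = rng.choice(term_ids[1:], size=n_enriched, replace=False).tolist()
    enriched_set = set(enriched)

    annotations: dict[str, set[str]] = {}
    for tid in term_ids[1:]:
        for gene in genes:
            p = (
                enriched_p
                if (tid in enriched_set and gene in target)
                else background_p
            )
            if rng.random() < p:
                annotations.setdefault(gene, set()).add(tid)
    ontology = GeneOntology(
        terms=terms,
        annotations={g: frozenset(t) for g, t in annotations.items()},
    )
    return ontology, sorted(enriched)
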