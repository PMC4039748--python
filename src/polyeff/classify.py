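"""Nine-way TC x TL regulation grouping and summary marginals.

A gene's transcription (TC) and translation (TL) status is called up, down
or unchanged from the moderated-test fdr and the effect size; the cross of
the two statuses yields nine regulation groups.  The net-effect score
(TC + TL) summarizes the combined influence on protein output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_TABLE",
    "SignificanceRule",
    "RegulationClassification",
    "classify",
    "marginals",
    "net_effect",
]

# group id -> (tc_status, tl_status); the canonical numbering
GROUP_TABLE: dict[int, tuple[str, str]] = {
    1: ("up", "up"),
    2: ("up", "unchanged"),
    3: ("up", "down"),
    4: ("unchanged", "up"),
    5: ("unchanged", "down"),
    6: ("down", "up"),
    7: ("down", "unchanged"),
    8: ("down", "down"),
    9: ("unchanged", "unchanged"),
}
_GROUP_ID = {v: k for k, v in GROUP_TABLE.items()}


def group_name(group_id: int) -> str:
    tc, tl = GROUP_TABLE[group_id]
    return f"TC:{tc}/TL:{tl}"


@dataclass(frozen=True)
class SignificanceRule:
    """Thresholds for calling an effect significant.

    ``apply_lfc_to`` controls which contrasts additionally require
    |effect| > lfc_min on top of fdr < fdr_max: 'both' (default),
    'TC_only', or 'neither'.
    """

    fdr_max: float = 0.05
    lfc_min: float = 1.0
    apply_lfc_to: str = "both"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.apply_lfc_to not in ("both", "TC_only", "neither"):
            raise ValueError("apply_lfc_to must be 'both', 'TC_only' or 'neither'")

    def _lfc_applies(self, which: str) -> bool:
        if self.apply_lfc_to == "both":
            return True
        if self.apply_lfc_to == "TC_only":
            return which == "TC"
        return False

    def status(self, effect: float, fdr: float, which: str) -> str:
        """'up', 'down' or 'unchanged' for one contrast (strict inequalities)."""
        significant = fdr < self.fdr_max
        if self._lfc_applies(which):
            significant = significant and abs(effect) > self.lfc_min
        if not significant or effect == 0:
            return "unchanged"
        return "up" if effect > 0 else "down"


@dataclass
class RegulationClassification:
    """Per-gene group labels plus the group-size summary."""

    per_gene: pd.DataFrame  # gene_id, tc_status, tl_status, group_id, group_name, net_effect
    group_sizes: dict[int, int]

    def __post_init__(self) -> None:
        n = len(self.per_gene)
        if sum(self.group_sizes.values()) != n:
            raise ValueError("group sizes do not partition the gene list")
        for gid, (tc, tl) in GROUP_TABLE.items():
            self.group_sizes.setdefault(gid, 0)

    @classmethod
    def from_statuses(
        cls,
        gene_ids: Sequence[str],
        tc_status: Sequence[str],
        tl_status: Sequence[str],
        tc: Sequence[float] | None = None,
        tl: Sequence[float] | None = None,
    ) -> "RegulationClassification":
        tc = np.zeros(len(gene_ids)) if tc is None else np.asarray(tc, float)
        tl = np.zeros(len(gene_ids)) if tl is None else np.asarray(tl, float)
        gids = [_GROUP_ID[(a, b)] for a, b in zip(tc_status, tl_status)]
        per_gene = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "tc_status": list(tc_status),
                "tl_status": list(tl_status),
                "group_id": gids,
                "group_name": [group_name(g) for g in gids],
                "net_effect": net_effect(tc, tl),
            }
        )
        sizes = {gid: 0 for gid in GROUP_TABLE}
        for g in gids:
            sizes[g] += 1
        return cls(per_gene=per_gene, group_sizes=sizes)

    def genes_in_group(self, group_id: int) -> list[str]:
        mask = self.per_gene["group_id"] == group_id
        return self.per_gene.loc[mask, "gene_id"].tolist()

    def genes_by_group(self, groups: Iterable[int] = range(1, 9)) -> dict[int, list[str]]:
        return {g: self.genes_in_group(g) for g in groups}


def classify(
    records: pd.DataFrame, rule: SignificanceRule | None = None
) -> RegulationClassification:
    """Assign each gene a TC and TL status and the resulting group.

    ``records`` is the per-gene efficiency table with columns gene_id, TC,
    TL, fdr_TC, fdr_TL.
    """
    rule = rule or SignificanceRule()
    tc_status = [
        rule.status(e, f, "TC")
        for e, f in zip(records["TC"], records["fdr_TC"])
    ]
    tl_status = [
        rule.status(e, f, "TL")
        for e, f in zip(records["TL"], records["fdr_TL"])
    ]
    return RegulationClassification.from_statuses(
        records["gene_id"].tolist(), tc_status, tl_status,
        tc=records["TC"].to_numpy(), tl=records["TL"].to_numpy(),
    )


def marginals(classification: RegulationClassification) -> dict[str, int]:
    """Marginal counts over the nine groups.

    'only transcriptional' = TC significant while TL unchanged (groups 2, 7);
    'only translational' = TL significant while TC unchanged (groups 4, 5).
    """
    s = classification.group_sizes
    return {
        "tc_up": s[1] + s[2] + s[3],
        "tc_down": s[6] + s[7] + s[8],
        "tl_up": s[1] + s[4] + s[6],
        "tl_down": s[3] + s[5] + s[8],
        "only_transcriptional": s[2] + s[7],
        "only_translational": s[4] + s[5],
    }


def net_effect(tc: np.ndarray | float, tl: np.ndarray | float) -> np.ndarray | float:
    """Combined transcription + translation score, (TC + TL)_total."""
    return np.asarray(tc, float) + np.asarray(tl, float)
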