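"""End-to-end orchestration: simulate -> normalize -> analyze -> classify ->
scan-top -> enrich-top -> enrich-go, with seeded determinism and a plain-text
summary report.

Every output TSV carries a provenance header (tool version, config hash,
seed) as '#' comment lines; readers in :mod:`polyeff.io` skip them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import SignificanceRule, classify, group_name, marginals
from .enrichment import go_enrichment, top_enrichment
from .io import (
    read_expression_table,
    read_fasta,
    read_ontology,
    write_annotations,
    write_expression_table,
    write_fasta,
    write_obo,
    write_table,
)
from .normalization import normalize_spikein
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_ontology,
    simulate_utrs,
)
from .stats import analyze
from .topmotif import scan_all

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "normalize",
    "analyze",
    "classify",
    "scan-top",
    "enrich-top",
    "enrich-go",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run (key = value file or kwargs)."""

    out_dir: str = "polyeff_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # input paths (ignored by stages that are skipped or when simulating)
    expression: str | None = None
    metadata: str | None = None
    fasta: str | None = None
    obo: str | None = None
    annotations: str | None = None
    # analysis options
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    apply_lfc_to: str = "both"
    min_pyrimidines: int = 3
    top_sided: str = "two_sided"
    go_sided: str = "greater"
    go_namespaces: tuple[str, ...] = ("BP", "MF")
    # simulation options
    n_genes: int = 2000
    n_spikeins: int = 20
    replicates: int = 3

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config; kwargs override."""
        values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        for key in ("seed", "min_pyrimidines", "n_genes", "n_spikeins", "replicates"):
            if key in values:
                values[key] = int(values[key])
        for key in ("fdr_max", "lfc_min"):
            if key in values:
                values[key] = float(values[key])
        for key in ("stages", "go_namespaces"):
            if key in values:
                values[key] = tuple(s.strip() for s in values[key].split(",") if s.strip())
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def config_hash(self) -> str:
        # hash analysis-relevant settings only, not filesystem locations
        payload = asdict(self)
        for key in ("out_dir", "expression", "metadata", "fasta", "obo", "annotations"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def header(self) -> list[str]:
        return [
            f"polyeff {__version__}",
            f"config_hash={self.config_hash()}",
            f"seed={self.seed}",
        ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return a summary dict (also written
    to ``report.txt``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()
    report: dict = {"seed": config.seed, "stages": []}
    state: dict = {}

    def stage(name: str):
        return name in config.stages

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise PipelineError(name, exc) from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        report["stages"].append(name)

    # ---- simulate -------------------------------------------------------
    def _simulate():
        sim = SimulationConfig(
            n_genes=config.n_genes,
            n_spikeins=config.n_spikeins,
            replicates=config.replicates,
            seed=config.seed,
        )
        data, truth = simulate_expression(sim)
        write_expression_table(
            data, out / "expression.tsv", out / "metadata.tsv", header
        )
        write_table(truth.to_frame(), out / "truth.tsv", header)
        utrs = simulate_utrs(truth, seed=config.seed + 1)
        write_fasta(utrs, out / "utrs.fasta")
        non_spike = [g for g, s in zip(truth.gene_ids, truth.spikein) if not s]
        target = [
            g for g, gid, s in zip(truth.gene_ids, truth.group_id, truth.spikein)
            if gid == 1 and not s
        ]
        ontology, enriched = simulate_ontology(
            non_spike, target_group_genes=target, seed=config.seed + 2
        )
        write_obo(ontology, out / "ontology.obo")
        write_annotations(ontology, out / "annotations.tsv")
        (out / "enriched_terms.txt").write_text("\n".join(enriched) + "\n")
        state.update(data=data, truth=truth, utrs=utrs, ontology=ontology)
        config.expression = str(out / "expression.tsv")
        config.metadata = str(out / "metadata.tsv")
        config.fasta = str(out / "utrs.fasta")
        config.obo = str(out / "ontology.obo")
        config.annotations = str(out / "annotations.tsv")
        for path in ("expression.tsv", "metadata.tsv", "truth.tsv", "utrs.fasta",
                     "ontology.obo", "annotations.tsv"):
            logger.info("wrote %s", out / path)

    if stage("simulate"):
        run_stage("simulate", _simulate)

    # ---- normalize ------------------------------------------------------
    def _normalize():
        data = state.get("data")
        if data is None:
            data = read_expression_table(config.expression, config.metadata)
        normalized, norm_report = normalize_spikein(data)
        state["data"] = normalized
        write_expression_table(
            normalized, out / "expression_normalized.tsv",
            out / "metadata_normalized.tsv", header,
        )
        write_table(norm_report.to_frame(), out / "normalization_report.tsv", header)

    if stage("normalize"):
        run_stage("normalize", _normalize)

    # ---- analyze --------------------------------------------------------
    def _analyze():
        data = state.get("data")
        if data is None:
            data = read_expression_table(config.expression, config.metadata)
            state["data"] = data
        records = analyze(data)
        state["records"] = records
        write_table(records, out / "efficiency.tsv", header)

    if stage("analyze"):
        run_stage("analyze", _analyze)

    # ---- classify -------------------------------------------------------
    def _classify():
        records = state.get("records")
        if records is None:
            records = pd.read_csv(out / "efficiency.tsv", sep="\t", comment="#")
        rule = SignificanceRule(
            fdr_max=config.fdr_max,
            lfc_min=config.lfc_min,
            apply_lfc_to=config.apply_lfc_to,
        )
        cls = classify(records, rule)
        state["classification"] = cls
        write_table(cls.per_gene, out / "classification.tsv", header)
        sizes = pd.DataFrame(
            {
                "group_id": sorted(cls.group_sizes),
                "group_name": [group_name(g) for g in sorted(cls.group_sizes)],
                "n_genes": [cls.group_sizes[g] for g in sorted(cls.group_sizes)],
            }
        )
        marg = marginals(cls)
        write_table(sizes, out / "group_sizes.tsv", header)
        write_table(
            pd.DataFrame([marg]), out / "marginals.tsv", header
        )
        report["group_sizes"] = {group_name(g): int(n) for g, n in sorted(cls.group_sizes.items())}
        report["marginals"] = marg

    if stage("classify"):
        run_stage("classify", _classify)

    # ---- scan-top -------------------------------------------------------
    have_fasta = config.fasta is not None or "utrs" in state
    if stage("scan-top") and not have_fasta:
        logger.info("no FASTA configured; skipping TOP stages")

    def _scan_top():
        utrs = state.get("utrs")
        if utrs is None:
            utrs = read_fasta(config.fasta)
            state["utrs"] = utrs
        summary = scan_all(utrs, min_pyrimidines=config.min_pyrimidines)
        state["motifs"] = summary
        write_table(summary.attrs["hits"], out / "top_hits.tsv", header)
        write_table(summary, out / "top_summary.tsv", header)
        report["top_bearing_genes"] = int(summary["top_bearing"].sum())

    if stage("scan-top") and have_fasta:
        run_stage("scan-top", _scan_top)

    # ---- enrich-top -----------------------------------------------------
    def _enrich_top():
        cls = state["classification"]
        summary = state["motifs"]
        status = dict(zip(summary["gene_id"], summary["top_bearing"]))
        results = top_enrichment(cls, status, sided=config.top_sided)
        frame = pd.DataFrame(
            {
                "group_name": [r.unit_id for r in results],
                "a": [r.table.a for r in results],
                "b": [r.table.b for r in results],
                "c": [r.table.c for r in results],
                "d": [r.table.d for r in results],
                "odds_ratio": [r.table.odds_ratio for r in results],
                "p_value": [r.p_value for r in results],
                "significant": [r.significant for r in results],
            }
        )
        write_table(frame, out / "top_enrichment.tsv", header)
        report["top_enrichment"] = {
            r.unit_id: {"p": r.p_value, "significant": r.significant}
            for r in results
        }
        report["top_bearing_by_group"] = {
            r.unit_id: r.table.a for r in results
        }

    if stage("enrich-top") and have_fasta and "classification" in state:
        run_stage("enrich-top", _enrich_top)

    # ---- enrich-go ------------------------------------------------------
    have_ontology = config.obo is not None or "ontology" in state

    def _enrich_go():
        ontology = state.get("ontology")
        if ontology is None:
            ontology = read_ontology(config.obo, config.annotations)
        cls = state["classification"]
        frames = []
        for ns in config.go_namespaces:
            if not ontology.terms_in_namespace(ns):
                continue
            frames.append(
                go_enrichment(
                    cls.genes_by_group(), ontology, namespace=ns,
                    sided=config.go_sided,
                )
            )
        frame = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame()
        )
        write_table(frame, out / "go_enrichment.tsv", header)
        top_terms = {}
        for gid, sub in frame.groupby("group_id"):
            best = sub.nsmallest(3, "p_value")
            top_terms[group_name(int(gid))] = [
                f"{t} (p={p:.3g})"
                for t, p in zip(best["term_id"], best["p_value"])
            ]
        report["top_go_terms"] = top_terms

    if stage("enrich-go") and have_ontology and "classification" in state:
        run_stage("enrich-go", _enrich_go)

    _write_report(report, out / "report.txt", header)
    return report


def _write_report(report: dict, path: Path, header: list[str]) -> None:
    lines = [f"# {h}" for h in header]
    lines.append(f"stages run: {', '.join(report['stages'])}")
    if "group_sizes" in report:
        lines.append("")
        lines.append("group sizes:")
        for name, n in report["group_sizes"].items():
            lines.append(f"  {name}: {n}")
        lines.append("marginals:")
        for key, n in report["marginals"].items():
            lines.append(f"  {key}: {n}")
    if "top_bearing_genes" in report:
        lines.append("")
        lines.append(f"TOP-bearing genes: {report['top_bearing_genes']}")
    if "top_enrichment" in report:
        lines.append("TOP enrichment (p, significant):")
        for name, res in report["top_enrichment"].items():
            lines.append(
                f"  {name}: p={res['p']:.4g} significant={res['significant']}"
            )
    if "top_go_terms" in report:
        lines.append("top GO terms per group:")
        for name, terms in report["top_go_terms"].items():
            lines.append(f"  {name}: {'; '.join(terms)}")
    path.write_text("\n".join(lines) + "\n")
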