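"""End-to-end orchestration: counts -> DE screen -> global + two-state
networks -> modules -> centralities -> key genes -> enrichment.

Every run resolves an :class:`AnalysisConfig`, embeds its hash in each output
file name-independent header, and writes a ``run_report.json`` with the
record counts of every stage.  When a ground-truth file from the synthetic
generator is supplied, the report additionally carries recovery metrics
(module adjusted Rand index, key-gene precision/recall).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import centrality as centrality_mod
from . import modules as modules_mod
from .enrichment import AnnotationMap, fisher_enrichment
from .keygenes import identify_key_genes, summarize_report
from .network import (
    CoexpressionNetwork,
    build_network,
    correlation_matrix,
    network_properties,
    soft_threshold_scan,
)
from .preprocess import (
    CountDataset,
    filter_low_expression,
    normalize,
    size_factors,
    wald_de_screen,
)
from .simulate import SyntheticTruth

logger = logging.getLogger("coexkey")

__all__ = ["AnalysisConfig", "RunReport", "run_all", "recovery_metrics"]

STATE_GLOBAL, STATE_NORMAL, STATE_SALINITY = "global", "normal", "salinity"


@dataclass
class AnalysisConfig:
    """All stage parameters with the pipeline's standard defaults."""

    zero_fraction: float = 0.8
    de_alpha: float = 0.05
    stress_condition: str = "salt"
    control_condition: str = "control"
    powers: tuple[int, ...] = tuple(range(1, 21))
    fit_threshold: float = 0.90
    n_bins: int = 10
    edge_min: float = 0.1
    fallback_beta: int = 6
    min_mean_connectivity: float = 1.0
    min_module_size: int = 30
    cut_height: float = 0.90
    merge_cut: float = 0.25
    kme_threshold: float = 0.65
    mtr_r_cut: float = 0.50
    mtr_p_cut: float = 0.05
    mtr_include_controls: bool = True
    salinity_top_fraction: float = 0.10
    normal_max_percentile: float = 0.50
    enrichment_q_cut: float = 0.05
    size_factor_fallback: str = "error"  # or "pseudocount"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "powers" in d:
            d["powers"] = tuple(int(p) for p in d["powers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage record counts and the three network property panels."""

    config_hash: str
    seed: int
    n_samples: int
    n_genes_raw: int
    n_genes_filtered: int
    n_de_genes: int
    chosen_beta: float
    beta_from_scan: bool
    network_properties: dict  # state -> property dict
    n_modules: int
    module_sizes: dict
    significant_modules: list
    n_key_genes: int
    key_gene_summary: dict
    recovery: dict | None = None
    enrichment_files: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def recovery_metrics(
    truth: SyntheticTruth,
    module_result,
    key_report,
    de_genes,
) -> dict:
    """Compare pipeline output to planted ground truth.

    Module recovery is the adjusted Rand index between the detected
    assignment and the planted membership, over the genes that entered
    module detection.  Key-gene recovery is precision/recall of
    flagged-by-any-measure against the planted key set.
    """
    genes = list(module_result.assignment.index)
    detected = module_result.assignment.to_numpy()
    planted = np.array([truth.module_membership.get(g, "null") for g in genes])
    ari = float(adjusted_rand_score(planted, detected))

    flagged = set(key_report.flagged_genes)
    true_keys = set(truth.key_genes)
    tp = len(flagged & true_keys)
    precision = tp / len(flagged) if flagged else 0.0
    recall = tp / len(true_keys) if true_keys else 0.0
    de_called = set(de_genes)
    de_true = set(truth.de_genes)
    n_true_null = max(1, len(truth.module_membership) - len(de_true))
    return {
        "module_ari": ari,
        "key_gene_precision": precision,
        "key_gene_recall": recall,
        "n_flagged": len(flagged),
        "n_true_keys": len(true_keys),
        "de_recall": len(de_called & de_true) / len(de_true) if de_true else 0.0,
        "de_false_positive_rate": len(de_called - de_true) / n_true_null,
    }


def _write_network(net: CoexpressionNetwork, props, outdir: Path, tag: str) -> None:
    edges = nx_edge_frame(net)
    edges.to_csv(outdir / f"network_{tag}_edges.tsv", sep="\t", index=False)
    pd.Series(sorted(net.graph.nodes), name="gene").to_csv(
        outdir / f"network_{tag}_nodes.tsv", sep="\t", index=False
    )
    (outdir / f"network_{tag}_properties.json").write_text(
        json.dumps(props.to_dict(), indent=1)
    )


def nx_edge_frame(net: CoexpressionNetwork) -> pd.DataFrame:
    rows = [
        (a, b, w) for a, b, w in net.graph.edges(data="weight")
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).sort_values(
        ["gene_a", "gene_b"]
    )


def run_all(
    config: AnalysisConfig,
    data: CountDataset,
    outdir,
    annotation: AnnotationMap | None = None,
    truth: SyntheticTruth | None = None,
) -> RunReport:
    """Execute every stage in order and write all outputs under ``outdir``.

    Returns the :class:`RunReport`; intermediate tables (filtered counts,
    size factors, DE table, soft-threshold scan, edge lists, module
    assignment, eigengenes, MTR table, centralities, key genes, enrichment)
    are written as TSV/JSON files.  Stage failures raise with the failing
    stage named; files written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    stage = "preprocess"
    try:
        logger.info("[%s] %d genes x %d samples", stage, *data.counts.shape)
        filtered = filter_low_expression(data, config.zero_fraction)
        factors = size_factors(filtered, on_no_reference=config.size_factor_fallback)
        norm = normalize(filtered, factors)
        de = wald_de_screen(
            norm,
            filtered,
            alpha=config.de_alpha,
            stress_condition=config.stress_condition,
            control_condition=config.control_condition,
        )
        de_genes = de.significant_genes
        logger.info("[%s] %d genes kept, %d DE", stage, filtered.counts.shape[0], len(de_genes))
        filtered.counts.to_csv(outdir / "counts_filtered.tsv", sep="\t", index_label="gene")
        factors.to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample")
        de.table.to_csv(outdir / "de_table.tsv", sep="\t", index_label="gene")
        if len(de_genes) < 3:
            raise RuntimeError("fewer than 3 DE genes; nothing to network")

        stage = "network"
        log_expr = norm.log_expression.loc[de_genes]
        design = filtered.design
        cor_global = correlation_matrix(log_expr)
        scan = soft_threshold_scan(
            cor_global, powers=config.powers, fit_threshold=config.fit_threshold,
            n_bins=config.n_bins, min_mean_connectivity=config.min_mean_connectivity,
        )
        scan.table.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
        if scan.chosen_beta is not None:
            beta, from_scan = scan.chosen_beta, True
        else:
            beta = int(config.fallback_beta)
            from_scan = False
            warnings.warn(
                f"no power reached scale-free R^2 >= {config.fit_threshold}; "
                f"falling back to the default unsigned power {beta}",
                stacklevel=2,
            )
        nets, props = {}, {}
        samples_by_state = {
            STATE_GLOBAL: list(design.index),
            STATE_NORMAL: list(design.index[design["condition"] == config.control_condition]),
            STATE_SALINITY: list(design.index[design["condition"] == config.stress_condition]),
        }
        for state, samp in samples_by_state.items():
            cor = cor_global if state == STATE_GLOBAL else correlation_matrix(log_expr[samp])
            nets[state] = build_network(cor, beta, config.edge_min, state_label=state)
            props[state] = network_properties(nets[state], n_bins=config.n_bins)
            _write_network(nets[state], props[state], outdir, state)
            logger.info(
                "[%s] %s: %d nodes, %d edges", stage, state,
                props[state].n_nodes, props[state].n_edges,
            )

        stage = "modules"
        tom = modules_mod.topological_overlap(nets[STATE_GLOBAL])
        module_result = modules_mod.detect_modules(
            tom,
            log_expr,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cut=config.merge_cut,
            kme_threshold=config.kme_threshold,
        )
        traits = modules_mod.salt_time_traits(
            design, config.stress_condition, include_controls=config.mtr_include_controls
        )
        if len(module_result.eigengenes):
            mtr = modules_mod.module_trait_relationships(
                module_result.eigengenes.loc[:, traits.index],
                traits,
                r_cut=config.mtr_r_cut,
                p_cut=config.mtr_p_cut,
            )
        else:
            mtr = modules_mod.module_trait_relationships(
                pd.DataFrame(columns=traits.index), traits,
                r_cut=config.mtr_r_cut, p_cut=config.mtr_p_cut,
            )
        significant_modules = mtr.significant_modules
        module_result.assignment.rename("module").to_csv(
            outdir / "module_assignment.tsv", sep="\t", index_label="gene"
        )
        module_result.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
        mtr.table.to_csv(outdir / "module_trait_relationships.tsv", sep="\t", index=False)
        logger.info(
            "[%s] %d modules, %d significant", stage,
            len(module_result.modules), len(significant_modules),
        )

        stage = "centrality"
        tables = {}
        for state in (STATE_NORMAL, STATE_SALINITY):
            tables[state] = centrality_mod.centrality_table(nets[state])
            tables[state].table.to_csv(
                outdir / f"centrality_{state}.tsv", sep="\t", index_label="gene"
            )

        stage = "key_genes"
        report = identify_key_genes(
            tables[STATE_NORMAL],
            tables[STATE_SALINITY],
            module_result,
            significant_modules,
            salinity_top_fraction=config.salinity_top_fraction,
            normal_max_percentile=config.normal_max_percentile,
        )
        summary = summarize_report(report)
        header = (
            f"# config={config.config_hash} salinity_top_fraction="
            f"{config.salinity_top_fraction} normal_max_percentile="
            f"{config.normal_max_percentile}\n"
        )
        with open(outdir / "key_genes.tsv", "w") as fh:
            fh.write(header)
            report.rows.to_csv(fh, sep="\t", index=False)
        (outdir / "key_gene_summary.json").write_text(json.dumps(summary, indent=1))
        logger.info("[%s] %d key genes", stage, summary["n_key_genes"])

        stage = "enrichment"
        enrichment_files = []
        if annotation is not None:
            for module in significant_modules:
                res = fisher_enrichment(
                    set(module_result.members(module)), annotation,
                    q_cut=config.enrichment_q_cut,
                )
                fname = f"enrichment_{module}.tsv"
                res.table.to_csv(outdir / fname, sep="\t", index=False)
                enrichment_files.append(fname)
            if report.flagged_genes:
                res = fisher_enrichment(
                    report.flagged_genes, annotation, q_cut=config.enrichment_q_cut
                )
                res.table.to_csv(outdir / "enrichment_key_genes.tsv", sep="\t", index=False)
                enrichment_files.append("enrichment_key_genes.tsv")

        recovery = None
        if truth is not None:
            stage = "recovery"
            recovery = recovery_metrics(truth, module_result, report, de_genes)
            (outdir / "recovery.json").write_text(json.dumps(recovery, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_report = RunReport(
        config_hash=config.config_hash,
        seed=config.seed,
        n_samples=data.counts.shape[1],
        n_genes_raw=data.counts.shape[0],
        n_genes_filtered=filtered.counts.shape[0],
        n_de_genes=len(de_genes),
        chosen_beta=float(beta),
        beta_from_scan=from_scan,
        network_properties={s: p.to_dict() for s, p in props.items()},
        n_modules=len(module_result.modules),
        module_sizes={k: int(v) for k, v in module_result.module_sizes.items()},
        significant_modules=list(significant_modules),
        n_key_genes=summary["n_key_genes"],
        key_gene_summary=summary,
        recovery=recovery,
        enrichment_files=enrichment_files,
    )
    (outdir / "run_report.json").write_text(json.dumps(run_report.to_dict(), indent=1))
    return run_report
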