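"""Key-gene calls from the two-state centrality comparison.

A key gene is one that is unimportant in the normal-state network but gains
importance in the salinity-state network.  The qualitative rule is made
operational per module and per centrality measure: within a module's gene
set, a gene is flagged by a measure when its salinity-state percentile is in
the top ``salinity_top_fraction`` (default 10%) and its normal-state
percentile is at or below ``normal_max_percentile`` (default the median).
Genes flagged by more than one measure carry a multi-measure flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .centrality import MEASURES, CentralityTable, percentile_ranks
from .modules import ModuleResult

__all__ = ["KeyGeneReport", "identify_key_genes", "summarize_report"]

REPORT_COLUMNS = [
    "gene",
    "module",
    "measure",
    "normal_value",
    "salinity_value",
    "normal_pct",
    "salinity_pct",
]


@dataclass
class KeyGeneReport:
    """Flagged (gene, module, measure) rows plus per-gene summaries."""

    rows: pd.DataFrame  # REPORT_COLUMNS, one row per flagged gene x measure
    detecting_measures: dict[str, set]  # gene -> measures that flagged it
    salinity_top_fraction: float = 0.10
    normal_max_percentile: float = 0.50

    @property
    def flagged_genes(self) -> set:
        return set(self.detecting_measures)

    @property
    def multi_measure_genes(self) -> set:
        return {g for g, ms in self.detecting_measures.items() if len(ms) >= 2}


def _module_percentiles(
    table: CentralityTable, members: list[str], measure: str
) -> tuple[pd.Series, pd.Series]:
    """Values and within-module percentiles for one measure and state.

    Present genes are ranked against the whole module gene set, with genes
    absent from the state's graph entering the ranking as zeros; absent
    genes themselves are forced to percentile 0.
    """
    present = [g for g in members if g in table.table.index]
    values = pd.Series(0.0, index=members)
    if present:
        values.loc[present] = table.table.loc[present, measure].astype(float)
    pct = percentile_ranks(values)
    pct.loc[[g for g in members if g not in table.table.index]] = 0.0
    return values, pct


def identify_key_genes(
    normal: CentralityTable,
    salinity: CentralityTable,
    modules: ModuleResult,
    significant_modules,
    salinity_top_fraction: float = 0.10,
    normal_max_percentile: float = 0.50,
) -> KeyGeneReport:
    """Flag genes whose centrality rank jumps from normal to salinity state.

    Percentiles are computed within each module's gene set, separately per
    state; a gene missing from one state's graph counts as percentile 0
    there.  A row is emitted for every (gene, measure) pair satisfying
    salinity_pct >= 1 - salinity_top_fraction and
    normal_pct <= normal_max_percentile; the report is sorted by module then
    gene.
    """
    if not 0 < salinity_top_fraction <= 1:
        raise ValueError("salinity_top_fraction must be in (0, 1]")
    rows = []
    detecting: dict[str, set] = {}
    for module in sorted(significant_modules):
        members = sorted(modules.members(module))
        if not members:
            continue
        in_normal = [g for g in members if g in normal.table.index]
        in_salinity = [g for g in members if g in salinity.table.index]
        if not in_normal:
            warnings.warn(
                f"module {module!r} absent from the normal-state network; "
                "treating its genes as percentile 0 there",
                stacklevel=2,
            )
        if not in_salinity:
            warnings.warn(
                f"module {module!r} absent from the salinity-state network; "
                "treating its genes as percentile 0 there",
                stacklevel=2,
            )
        for measure in MEASURES:
            n_val, n_pct = _module_percentiles(normal, members, measure)
            s_val, s_pct = _module_percentiles(salinity, members, measure)
            hit = (s_pct >= 1.0 - salinity_top_fraction) & (
                n_pct <= normal_max_percentile
            )
            for gene in n_pct.index[hit]:
                rows.append(
                    (
                        gene,
                        module,
                        measure,
                        n_val[gene],
                        s_val[gene],
                        n_pct[gene],
                        s_pct[gene],
                    )
                )
                detecting.setdefault(gene, set()).add(measure)
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame = frame.sort_values(["module", "gene", "measure"]).reset_index(drop=True)
    return KeyGeneReport(
        rows=frame,
        detecting_measures=detecting,
        salinity_top_fraction=salinity_top_fraction,
        normal_max_percentile=normal_max_percentile,
    )


def summarize_report(report: KeyGeneReport) -> dict:
    """Per-module flag counts by measure, plus the multi-measure gene lists."""
    summary: dict = {
        "n_key_genes": len(report.flagged_genes),
        "per_module": {},
        "multi_measure_genes": {},
    }
    if len(report.rows):
        for module, block in report.rows.groupby("module"):
            counts = {m: int((block["measure"] == m).sum()) for m in MEASURES}
            genes = sorted(set(block["gene"]))
            multi = sorted(
                g for g in genes if len(report.detecting_measures[g]) >= 2
            )
            summary["per_module"][module] = {
                "n_genes": len(genes),
                "by_measure": counts,
            }
            summary["multi_measure_genes"][module] = multi
    return summary
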