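"""Module detection on the topological overlap matrix, module eigengenes, and
module--trait relationships.

TOM_ij combines the direct adjacency of two genes with the weight of their
shared neighbourhood; 1 - TOM is the clustering dissimilarity.  Modules are
branches of an average-linkage dendrogram under a static dissimilarity cut,
with small branches sent to the reserved "grey" label, near-identical
modules merged through their eigengenes, and left-over genes adopted by
module membership (kME).  The static cut stands in for dynamic tree
cutting: the target is recovery of genuinely distinct co-expression groups,
not label-for-label agreement with any particular tree-cut heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .network import CoexpressionNetwork

__all__ = [
    "TOMMatrix",
    "ModuleResult",
    "MTRTable",
    "GREY",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_relationships",
    "salt_time_traits",
]

GREY = "grey"

# WGCNA-style module colours, assigned in decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class TOMMatrix:
    """Topological overlap similarity (unit diagonal) and its dissimilarity."""

    genes: list[str]
    tom: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def topological_overlap(net: CoexpressionNetwork) -> TOMMatrix:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Computed on the weighted adjacency before edge thresholding; the
    diagonal is 1 by definition.
    """
    a = net.adjacency
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(genes=list(net.genes), tom=tom)


@dataclass
class ModuleResult:
    """Gene -> module assignment with eigengenes and the merge history."""

    assignment: pd.Series  # gene -> label; GREY = unassigned
    module_sizes: dict[str, int]
    eigengenes: pd.DataFrame  # module x sample
    merge_log: list[str] = field(default_factory=list)

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes if m != GREY]


def module_eigengene(log_expr: pd.DataFrame, member_genes) -> pd.Series:
    """First principal component of the z-scored member expression.

    Returned per sample with unit variance, sign-oriented so the mean
    correlation with the member genes is positive.  Constant genes are
    excluded; at least 2 varying members are required.
    """
    member_genes = list(member_genes)
    if len(member_genes) < 2:
        raise ValueError("need at least 2 member genes for an eigengene")
    x = log_expr.loc[member_genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    varying = sd > 0
    if varying.sum() < 2:
        raise ValueError("fewer than 2 non-constant member genes")
    x = x[varying]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    pc = pc / pc.std()
    mean_cor = np.mean([np.corrcoef(row, pc)[0, 1] for row in z])
    if mean_cor < 0:
        pc = -pc
    return pd.Series(pc, index=log_expr.columns, name="eigengene")


def _label_by_size(groups: dict[int, list[str]]) -> dict[int, str]:
    order = sorted(groups, key=lambda c: (-len(groups[c]), c))
    labels = {}
    for i, c in enumerate(order):
        labels[c] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    return labels


def detect_modules(
    tom: TOMMatrix,
    log_expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.90,
    merge_cut: float = 0.25,
    kme_threshold: float = 0.65,
) -> ModuleResult:
    """Average-linkage clustering of 1 - TOM into size-ordered colour modules.

    The dendrogram is cut at the absolute dissimilarity ``cut_height``
    (static-cut convention: merges at 1 - TOM above the cut are not applied,
    so genes that share essentially no topological overlap stay apart);
    branches smaller than ``min_module_size`` become grey.  Modules whose
    eigengenes correlate above ``1 - merge_cut`` are merged iteratively
    (largest pairwise correlation first, eigengenes recomputed after every
    merge).  Grey genes whose module membership |kME| (correlation with a
    module eigengene) reaches ``kme_threshold`` are then adopted by their
    best-matching module — this recovers genes co-expressed with a module in
    only part of the samples (e.g. one condition), which tree branches
    routinely miss.  Module labels are WGCNA-style colours in decreasing
    size order.
    """
    genes = tom.genes
    if len(genes) < min_module_size:
        raise ValueError("fewer genes than min_module_size")
    d = tom.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=float(cut_height), criterion="distance")

    groups: dict[int, list[str]] = {}
    for gene, c in zip(genes, flat):
        groups.setdefault(int(c), []).append(gene)
    groups = {c: g for c, g in groups.items() if len(g) >= min_module_size}
    if not groups:
        warnings.warn("no module reached min_module_size; all genes grey", stacklevel=2)
        assignment = pd.Series(GREY, index=genes)
        return ModuleResult(
            assignment=assignment,
            module_sizes={GREY: len(genes)},
            eigengenes=pd.DataFrame(columns=log_expr.columns),
        )

    merge_log: list[str] = []
    members: list[list[str]] = list(groups.values())
    while True:
        if len(members) < 2:
            break
        eig = np.vstack([module_eigengene(log_expr, m).to_numpy() for m in members])
        cor = np.corrcoef(eig)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_cut:
            break
        merge_log.append(
            f"merged clusters of sizes {len(members[i])} and {len(members[j])} "
            f"(eigengene r = {cor[i, j]:.3f})"
        )
        members[i] = members[i] + members[j]
        del members[j]

    # kME adoption of grey genes
    if kme_threshold < 1.0 and members:
        eig = np.vstack([module_eigengene(log_expr, m).to_numpy() for m in members])
        assigned = set().union(*map(set, members))
        grey_genes = [g for g in genes if g not in assigned]
        if grey_genes:
            x = log_expr.loc[grey_genes].to_numpy(dtype=float)
            sd = x.std(axis=1)
            ok = sd > 0
            xz = np.where(ok[:, None], (x - x.mean(1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None], 0.0)
            ez = (eig - eig.mean(1, keepdims=True)) / eig.std(1, keepdims=True)
            kme = xz @ ez.T / x.shape[1]  # gene x module correlations
            best = np.abs(kme).argmax(axis=1)
            adopt = (np.abs(kme).max(axis=1) >= kme_threshold) & ok
            for gi in np.nonzero(adopt)[0]:
                members[best[gi]].append(grey_genes[gi])

    labels = _label_by_size({i: m for i, m in enumerate(members)})
    assignment = pd.Series(GREY, index=genes, dtype=object)
    for i, m in enumerate(members):
        assignment.loc[m] = labels[i]
    sizes = assignment.value_counts().to_dict()
    eigengenes = pd.DataFrame(
        {
            labels[i]: module_eigengene(log_expr, m)
            for i, m in enumerate(members)
        }
    ).T
    eigengenes = eigengenes.loc[sorted(eigengenes.index, key=lambda c: -sizes[c])]
    return ModuleResult(
        assignment=assignment,
        module_sizes=sizes,
        eigengenes=eigengenes,
        merge_log=merge_log,
    )


@dataclass
class MTRTable:
    """Module--trait correlations with significance flags."""

    table: pd.DataFrame  # columns: module, trait, r, p, significant
    r_cut: float = 0.50
    p_cut: float = 0.05

    @property
    def significant_modules(self) -> list[str]:
        sig = self.table.loc[self.table["significant"], "module"]
        return sorted(set(sig))


def salt_time_traits(
    design: pd.DataFrame,
    stress_condition: str = "salt",
    include_controls: bool = True,
) -> pd.DataFrame:
    """One indicator trait per stress time point.

    Trait ``salt_<t>h`` is 1 for stress samples taken at time t and 0 for
    every other sample; with ``include_controls=False`` control samples are
    dropped instead of coded 0.
    """
    design = design if include_controls else design[design["condition"] == stress_condition]
    is_stress = design["condition"] == stress_condition
    traits = {}
    for t in sorted(design.loc[is_stress, "time_h"].unique()):
        t_lab = int(t) if float(t).is_integer() else t
        traits[f"{stress_condition}_{t_lab}h"] = (
            (is_stress & (design["time_h"] == t)).astype(float)
        )
    return pd.DataFrame(traits)


def module_trait_relationships(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    r_cut: float = 0.50,
    p_cut: float = 0.05,
) -> MTRTable:
    """Pearson r of each eigengene with each trait; p from the t test with
    n - 2 degrees of freedom; significant iff |r| > r_cut and p < p_cut.

    Constant traits give NaN rows flagged non-significant.
    """
    rows = []
    traits = traits.loc[eigengenes.columns] if len(eigengenes.columns) else traits
    n = traits.shape[0]
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        for trait in traits.columns:
            tvec = traits[trait].to_numpy(dtype=float)
            if np.std(tvec) == 0 or np.std(e) == 0:
                rows.append((module, trait, np.nan, np.nan, False))
                continue
            r = float(np.corrcoef(e, tvec)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
                p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
            rows.append((module, trait, r, p, bool(abs(r) > r_cut and p < p_cut)))
    table = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "significant"])
    return MTRTable(table=table, r_cut=r_cut, p_cut=p_cut)
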