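"""Count filtering, median-of-ratios normalization and the NB Wald DE screen.

The preprocessing chain mirrors the standard bulk RNA-seq recipe for
co-expression studies: drop genes that are zero in most libraries, correct
library size and composition with median-of-ratios size factors, and screen
for genes that respond to the stress condition with a per-gene negative
binomial Wald test.  The screen is a gene-selection device (raw p < alpha),
not a publication-grade DE analysis: dispersions are per-gene method of
moments with a small floor and there is no shrinkage or independent
filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountDataset",
    "NormalizedDataset",
    "DEResult",
    "filter_low_expression",
    "size_factors",
    "normalize",
    "wald_de_screen",
]

DESIGN_COLUMNS = ("condition", "time_h", "replicate")


@dataclass
class CountDataset:
    """Gene x sample integer counts with a per-sample design table.

    ``counts`` is indexed by gene ID with one column per sample;
    ``design`` is indexed by sample ID with columns ``condition``,
    ``time_h`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene IDs in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in count matrix")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        if set(self.design.index) != set(self.counts.columns):
            raise ValueError("design table does not cover the sample set exactly")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")
        # keep design rows in sample-column order; normalize index names
        self.design = self.design.loc[self.counts.columns]
        self.counts.index.name = "gene"
        self.design.index.name = "sample"
        self.counts.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])


@dataclass
class NormalizedDataset:
    """Size-factor normalized expression.

    ``normalized[g, s] * size_factors[s] == counts[g, s]`` exactly;
    ``log_expression = log2(normalized + 1)``.
    """

    size_factors: pd.Series
    normalized: pd.DataFrame
    log_expression: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


@dataclass
class DEResult:
    """Per-gene Wald screen output: log2FC (stress vs control), statistic, p."""

    table: pd.DataFrame  # columns: log2_fc, stat, pvalue, significant
    alpha: float = 0.05

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def filter_low_expression(data: CountDataset, zero_fraction: float = 0.8) -> CountDataset:
    """Remove genes whose fraction of zero-count samples strictly exceeds ``zero_fraction``.

    Gene order is preserved; the sample set is unchanged.  Filtering is
    idempotent.
    """
    if not 0 < zero_fraction <= 1:
        raise ValueError("zero_fraction must be in (0, 1]")
    frac_zero = (data.counts == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction
    if not keep.any():
        warnings.warn("all genes removed by the zero-count filter", stacklevel=2)
    return CountDataset(counts=data.counts.loc[keep].copy(), design=data.design.copy())


def size_factors(data: CountDataset, on_no_reference: str = "error") -> pd.Series:
    """Median-of-ratios size factors.

    For each sample the factor is the median over reference genes of
    ``count / geometric-mean-across-samples``; the reference set is the genes
    with strictly positive counts in every sample.  ``on_no_reference``
    controls behaviour when no such gene exists: ``"error"`` raises,
    ``"pseudocount"`` adds 1 to every count for the purpose of the factor
    computation only.
    """
    counts = data.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        if on_no_reference == "pseudocount":
            counts = counts + 1.0
            all_positive = np.ones(counts.shape[0], dtype=bool)
        else:
            raise ValueError(
                "no gene has positive counts in every sample; filter more "
                "aggressively or pass on_no_reference='pseudocount'"
            )
    ref = counts[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor; check the count matrix")
    return pd.Series(factors, index=data.counts.columns, name="size_factor")


def normalize(data: CountDataset, factors: pd.Series) -> NormalizedDataset:
    """Divide each sample's counts by its size factor; add log2(x+1) expression."""
    if len(factors) != data.counts.shape[1]:
        raise ValueError("one size factor per sample required")
    factors = factors.loc[data.counts.columns]
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    normalized = data.counts / factors
    return NormalizedDataset(
        size_factors=factors.copy(),
        normalized=normalized,
        log_expression=np.log2(normalized + 1.0),
    )


def _nb_group_fit(
    y: np.ndarray, sf: np.ndarray, alpha_disp: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scoring iterations for a per-group NB intercept with offsets.

    Model: y[g, s] ~ NB(mean = sf[s] * exp(b[g]), dispersion alpha_disp[g]).
    Returns (b, fisher_information).  Genes with zero total count get
    b = -inf and information 0.
    """
    tot = y.sum(axis=1)
    with np.errstate(divide="ignore"):
        b = np.log(tot / sf.sum())
    ok = tot > 0
    bw = np.where(ok, b, 0.0)
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(bw)[:, None]
        w = 1.0 + alpha_disp[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        bw = bw + step
        if np.max(np.abs(step[ok])) < 1e-10:
            break
    mu = sf[None, :] * np.exp(bw)[:, None]
    info = (mu / (1.0 + alpha_disp[:, None] * mu)).sum(axis=1)
    b = np.where(ok, bw, -np.inf)
    info = np.where(ok, info, 0.0)
    return b, info


def moment_dispersions(
    norm: NormalizedDataset,
    data: CountDataset,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, pooled within condition.

    For each condition c: alpha_c = (var_c - mean_c) / mean_c^2 on normalized
    counts; the estimate is the df-weighted average over conditions, floored.
    Pooling within condition keeps a genuine condition effect from inflating
    the dispersion.
    """
    conditions = norm.normalized.columns.map(data.design["condition"])
    num = np.zeros(norm.normalized.shape[0])
    den = 0.0
    for cond in pd.unique(conditions):
        block = norm.normalized.loc[:, np.asarray(conditions == cond)].to_numpy()
        n_c = block.shape[1]
        if n_c < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        num += (n_c - 1) * a
        den += n_c - 1
    alpha = num / den if den > 0 else np.zeros_like(num)
    return pd.Series(np.maximum(alpha, floor), index=norm.normalized.index)


def wald_de_screen(
    norm: NormalizedDataset,
    data: CountDataset,
    alpha: float = 0.05,
    stress_condition: str = "salt",
    control_condition: str = "control",
) -> DEResult:
    """Screen for condition-responsive genes with a per-gene NB Wald test.

    Fits, per gene, a negative binomial GLM with a condition covariate and
    log size factors as offsets (equivalently: one NB intercept per
    condition on size-factor offsets), dispersion fixed at the pooled
    method-of-moments estimate.  The Wald statistic is the log fold change
    divided by its standard error from the Fisher information; two-sided p
    from a t reference with n - 2 degrees of freedom, which compensates for
    the estimated dispersion at these small group sizes.

    All time points are pooled within each condition (condition main
    effect).  Genes that are all-zero in both groups get p = 1.
    """
    cond = data.design["condition"]
    for label in (control_condition, stress_condition):
        if (cond == label).sum() < 2:
            raise ValueError(f"need >= 2 samples with condition {label!r}")
    y = data.counts.to_numpy(dtype=float)
    sf = norm.size_factors.loc[data.counts.columns].to_numpy()
    disp = moment_dispersions(norm, data).to_numpy()

    is_ctrl = (cond == control_condition).to_numpy()
    is_strs = (cond == stress_condition).to_numpy()
    b0, i0 = _nb_group_fit(y[:, is_ctrl], sf[is_ctrl], disp)
    b1, i1 = _nb_group_fit(y[:, is_strs], sf[is_strs], disp)

    with np.errstate(divide="ignore", invalid="ignore"):
        delta = b1 - b0
        se = np.sqrt(1.0 / i0 + 1.0 / i1)
        z = delta / se
    # all-zero in one or both groups: coefficient not estimable -> null call
    bad = ~np.isfinite(z)
    z = np.where(bad, 0.0, z)
    delta = np.where(np.isfinite(delta), delta, 0.0)
    df = int(is_ctrl.sum() + is_strs.sum() - 2)
    p = 2.0 * stats.t.sf(np.abs(z), df=df)
    table = pd.DataFrame(
        {
            "log2_fc": delta / np.log(2.0),
            "stat": z,
            "pvalue": p,
            "significant": p < alpha,
        },
        index=data.counts.index,
    )
    return DEResult(table=table, alpha=alpha)
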