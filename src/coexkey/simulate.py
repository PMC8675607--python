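"""Synthetic time-course count data with planted co-expression modules.

The generator emulates the study design the pipeline targets: two conditions
(control and salt stress) x six sampling times (0, 3, 6, 12, 24, 48 h) x
three replicates = 36 libraries.  Counts are negative binomial around a
log-linear mean:

    mu[g, s] = size_factor[s] * exp( baseline[g]
                                     + loading[g, s] * factor[m(g), s]
                                     - loading[g, s]^2 * V_state(s) / 2
                                     + sign[m(g)] * de_effect * ln2 * 1[salt] )

(the quadratic term removes the lognormal mean contribution of the factor,
so the planted condition fold change is exact for every loading).

Each planted module m has a latent per-sample factor
``factor[m, s] = activity_m(condition_s, time_s) + N(0, factor_noise_sd)``;
the default activity is flat under control and a single-time-point bump
under salt, with bump times rotating over the non-zero sampling times and
alternating sign (up- and down-regulated modules).  Ordinary module members
load on their factor in both conditions with per-gene loadings drawn from
``member_loading_range``; their control-sample loadings are scaled by
sqrt(var_salt_factor / var_control_factor) so that ordinary co-expression is
equally strong in the two states — the stress bump moves the module's mean
profile (and hence its trait correlation) without making every member a
stronger stress hub.  "Key" genes load only in salt samples, at the full
``within_module_loading`` — they are uncorrelated bystanders in the control
state but module hubs under stress, the condition-specific rewiring the
two-state comparison is designed to detect.  Null genes are independent NB
noise with no condition effect.

Draw order from the single seeded generator (fixed; determinism contract):
size factors, baselines, member loadings (module by module), module factors,
NB counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountDataset

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "write_truth",
    "read_truth",
    "write_dataset",
    "read_dataset",
]

NULL_LABEL = "null"


def default_activity_profiles(
    n_modules: int,
    timepoints_h: tuple[float, ...],
    amplitude: float = 2.2,
    conditions: tuple[str, ...] = ("control", "salt"),
) -> list[dict]:
    """Flat control activity; a single-time-point bump under stress.

    Bump times rotate over the non-zero sampling times and the bump sign
    alternates across modules (up, down, up, ...), so both induced and
    repressed modules are planted and per-sample totals stay roughly
    balanced between conditions.
    """
    control, stress = conditions
    bump_times = [t for t in timepoints_h if t > 0] or list(timepoints_h)
    profiles = []
    for m in range(n_modules):
        sign = 1.0 if m % 2 == 0 else -1.0
        bump_t = bump_times[m % len(bump_times)]
        profiles.append(
            {
                control: {float(t): 0.0 for t in timepoints_h},
                stress: {
                    float(t): sign * amplitude if t == bump_t else 0.0
                    for t in timepoints_h
                },
            }
        )
    return profiles


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters for the generator.

    Log-scale quantities (baselines, activities, loadings x factors) are in
    natural-log expression units; ``de_effect_log2fc`` is in log2 units.
    """

    n_genes: int = 8000
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (70, 60, 55, 50, 45)
    n_key_genes_per_module: int = 5
    n_null_genes: int = 7720
    conditions: tuple[str, ...] = ("control", "salt")
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0, 48.0)
    n_replicates: int = 3
    module_activity_profiles: list[dict] | None = None
    within_module_loading: float = 1.0
    member_loading_range: tuple[float, float] = (0.4, 0.6)
    factor_noise_sd: float = 0.85
    nb_dispersion: float = 0.2
    baseline_log_mean_range: tuple[float, float] = (5.0, 7.5)
    size_factor_log_sd: float = 0.3
    de_effect_log2fc: float = 1.3
    key_de_multiplier: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.conditions = tuple(self.conditions)
        self.timepoints_h = tuple(float(t) for t in self.timepoints_h)
        self.member_loading_range = tuple(self.member_loading_range)
        self.baseline_log_mean_range = tuple(self.baseline_log_mean_range)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if sum(self.module_sizes) + self.n_null_genes != self.n_genes:
            raise ValueError(
                "gene budget inconsistent: sum(module_sizes) + n_null_genes "
                f"= {sum(self.module_sizes) + self.n_null_genes} != n_genes = {self.n_genes}"
            )
        if any(self.n_key_genes_per_module > s for s in self.module_sizes):
            raise ValueError("n_key_genes_per_module exceeds a module size")
        if not 0 < self.within_module_loading <= 1:
            raise ValueError("within_module_loading must be in (0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions (control, stress) expected")

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * len(self.timepoints_h) * self.n_replicates

    def profiles(self) -> list[dict]:
        if self.module_activity_profiles is not None:
            return self.module_activity_profiles
        return default_activity_profiles(
            self.n_modules, self.timepoints_h, conditions=self.conditions
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["conditions"] = list(self.conditions)
        d["timepoints_h"] = list(self.timepoints_h)
        d["member_loading_range"] = list(self.member_loading_range)
        d["baseline_log_mean_range"] = list(self.baseline_log_mean_range)
        if d["module_activity_profiles"] is not None:
            d["module_activity_profiles"] = [
                {c: {str(t): a for t, a in prof.items()} for c, prof in p.items()}
                for p in d["module_activity_profiles"]
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("module_activity_profiles") is not None:
            d["module_activity_profiles"] = [
                {c: {float(t): float(a) for t, a in prof.items()} for c, prof in p.items()}
                for p in d["module_activity_profiles"]
            ]
        for key in ("module_sizes", "conditions", "timepoints_h",
                    "member_loading_range", "baseline_log_mean_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    module_membership: dict[str, str]  # gene -> module label ("M1".. / "null")
    key_genes: set[str]
    de_genes: set[str]
    size_factors: dict[str, float]
    module_factors: pd.DataFrame  # module x sample latent factor realizations
    config_echo: SimulationConfig

    def __post_init__(self) -> None:
        planted = {g for g, m in self.module_membership.items() if m != NULL_LABEL}
        if not self.key_genes <= planted:
            raise ValueError("key genes must be planted module genes")
        if any(v <= 0 for v in self.size_factors.values()):
            raise ValueError("size factors must be strictly positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.module_membership == other.module_membership
            and self.key_genes == other.key_genes
            and self.de_genes == other.de_genes
            and self.size_factors.keys() == other.size_factors.keys()
            and np.allclose(
                [self.size_factors[k] for k in self.size_factors],
                [other.size_factors[k] for k in self.size_factors],
            )
            and self.module_factors.shape == other.module_factors.shape
            and list(self.module_factors.index) == list(other.module_factors.index)
            and list(self.module_factors.columns) == list(other.module_factors.columns)
            and np.allclose(self.module_factors.values, other.module_factors.values)
            and self.config_echo == other.config_echo
        )


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for t in config.timepoints_h:
            for rep in range(1, config.n_replicates + 1):
                t_lab = int(t) if float(t).is_integer() else t
                rows.append(
                    {
                        "sample": f"{cond}_{t_lab:02}h_r{rep}",
                        "condition": cond,
                        "time_h": float(t),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def generate_dataset(config: SimulationConfig) -> tuple[CountDataset, SyntheticTruth]:
    """Draw a count dataset and its ground truth from ``config``.

    Deterministic given ``config.seed``: the same config yields identical
    counts on every run.
    """
    rng = np.random.default_rng(config.seed)
    design = _sample_table(config)
    n_samples = len(design)
    control, stress = config.conditions
    is_stress = (design["condition"] == stress).to_numpy()
    times = design["time_h"].to_numpy()

    # 1. size factors (geometric mean 1)
    log_sf = rng.normal(0.0, config.size_factor_log_sd, n_samples)
    log_sf -= log_sf.mean()
    sf = np.exp(log_sf)

    # 2. gene baselines (log-uniform means)
    lo, hi = config.baseline_log_mean_range
    baselines = rng.uniform(lo, hi, config.n_genes)

    # 3. gene bookkeeping + member loadings
    genes: list[str] = []
    membership: dict[str, str] = {}
    key_genes: set[str] = set()
    loadings = np.zeros(config.n_genes)
    module_of = np.full(config.n_genes, -1)
    idx = 0
    for m, size in enumerate(config.module_sizes):
        label = f"M{m + 1}"
        lo_l, hi_l = config.member_loading_range
        member_load = rng.uniform(lo_l, hi_l, size) * config.within_module_loading
        for j in range(size):
            name = f"{label}_G{j:03d}"
            genes.append(name)
            membership[name] = label
            module_of[idx] = m
            if j < config.n_key_genes_per_module:
                key_genes.add(name)
                loadings[idx] = config.within_module_loading
            else:
                loadings[idx] = member_load[j]
            idx += 1
    for j in range(config.n_null_genes):
        name = f"NULL_G{j:03d}"
        genes.append(name)
        membership[name] = NULL_LABEL
        idx += 1

    # 4. module latent factors: activity(condition, time) + noise
    profiles = config.profiles()
    activity = np.zeros((config.n_modules, n_samples))
    for m in range(config.n_modules):
        prof = profiles[m]
        for s in range(n_samples):
            cond = stress if is_stress[s] else control
            activity[m, s] = prof[cond].get(float(times[s]), 0.0)
    factors = activity + rng.normal(0.0, config.factor_noise_sd, activity.shape)

    # 5. log-mean matrix; the DE sign of a module follows its activity
    # direction (induced modules are up-regulated, repressed ones down).
    # Ordinary members' control loadings carry the variance-equalizing boost
    # so that within-module co-expression is equally strong in both states.
    log_mu = np.tile(baselines[:, None], (1, n_samples))
    de_signs = np.zeros(config.n_modules)
    control_boost = np.ones(config.n_modules)
    v_salt_arr = np.zeros(config.n_modules)
    v_ctrl_arr = np.zeros(config.n_modules)
    for m in range(config.n_modules):
        prof = profiles[m]
        shift = np.mean(list(prof[stress].values())) - np.mean(list(prof[control].values()))
        de_signs[m] = -1.0 if shift < 0 else 1.0
        # realized (not theoretical) factor variances: with 18 samples per
        # state the realized variance fluctuates enough to unbalance the two
        # states' co-expression strength if left uncorrected
        v_salt_arr[m] = np.var(factors[m, is_stress])
        v_ctrl_arr[m] = np.var(factors[m, ~is_stress])
        control_boost[m] = np.sqrt(v_salt_arr[m] / v_ctrl_arr[m])
    de_genes: set[str] = set()
    key_mask = np.array([g in key_genes for g in genes])
    for i in range(config.n_genes):
        m = module_of[i]
        if m < 0:
            continue
        if key_mask[i]:
            load = np.where(is_stress, loadings[i], 0.0)
        else:
            load = np.where(is_stress, loadings[i], loadings[i] * control_boost[m])
        # subtract the lognormal mean term so the planted condition fold
        # change is exact regardless of loading (keys load in one state only)
        v_state = np.where(is_stress, v_salt_arr[m], v_ctrl_arr[m])
        log_mu[i] += load * factors[m] - 0.5 * np.square(load) * v_state
        if config.de_effect_log2fc != 0.0:
            # stress-rewired hub genes are also the most strongly induced;
            # their larger fold change offsets the variance their salt-only
            # factor loading adds to the screen
            mult = config.key_de_multiplier if key_mask[i] else 1.0
            log_mu[i] += de_signs[m] * config.de_effect_log2fc * mult * np.log(2.0) * is_stress
            de_genes.add(genes[i])

    mu = sf[None, :] * np.exp(log_mu)

    # 6. NB counts (gamma-Poisson; Poisson when dispersion is 0)
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    dataset = CountDataset(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        design=design.copy(),
    )
    truth = SyntheticTruth(
        module_membership=membership,
        key_genes=key_genes,
        de_genes=de_genes,
        size_factors={s: float(v) for s, v in zip(design.index, sf)},
        module_factors=pd.DataFrame(
            factors,
            index=[f"M{m + 1}" for m in range(config.n_modules)],
            columns=design.index,
        ),
        config_echo=config,
    )
    return dataset, truth


# --- plumbing: TSV/JSON round-trips -----------------------------------------


def write_dataset(data: CountDataset, counts_path, metadata_path) -> None:
    """Counts as gene x sample TSV (first column gene ID); metadata TSV."""
    data.counts.to_csv(counts_path, sep="\t", index_label="gene")
    meta = data.design.reset_index().rename(columns={"index": "sample"})
    if "sample" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample"})
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_dataset(counts_path, metadata_path) -> CountDataset:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    design = pd.read_csv(metadata_path, sep="\t").set_index("sample")
    return CountDataset(counts=counts, design=design)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth to JSON; round-trips losslessly via read_truth."""
    payload = {
        "module_membership": truth.module_membership,
        "key_genes": sorted(truth.key_genes),
        "de_genes": sorted(truth.de_genes),
        "size_factors": truth.size_factors,
        "module_factors": {
            "index": list(truth.module_factors.index),
            "columns": list(truth.module_factors.columns),
            "values": truth.module_factors.values.tolist(),
        },
        "config": truth.config_echo.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    mf = payload["module_factors"]
    return SyntheticTruth(
        module_membership=payload["module_membership"],
        key_genes=set(payload["key_genes"]),
        de_genes=set(payload["de_genes"]),
        size_factors=payload["size_factors"],
        module_factors=pd.DataFrame(
            np.asarray(mf["values"], dtype=float), index=mf["index"], columns=mf["columns"]
        ),
        config_echo=SimulationConfig.from_dict(payload["config"]),
    )
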