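import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexkey import (
    SimulationConfig,
    build_network,
    correlation_matrix,
    detect_modules,
    generate_dataset,
    module_eigengene,
    module_trait_relationships,
    topological_overlap,
)
from coexkey.modules import GREY, salt_time_traits
from coexkey.network import CoexpressionNetwork, CorrelationMatrix
from oracles import bf_tom


def net_from_adjacency(a: np.ndarray) -> CoexpressionNetwork:
    genes = [f"g{i}" for i in range(a.shape[0])]
    import networkx as nx

    return CoexpressionNetwork(
        genes=genes, adjacency=a, beta=1.0, edge_min=0.1,
        graph=nx.Graph(), state_label="global",
    )


class TestTOM:
    def test_single_strong_pair(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = topological_overlap(net_from_adjacency(a))
        assert tom.tom[0, 1] == pytest.approx(1.0)  # (0 + 1)/(1 + 1 - 1)

    def test_disconnected_pair_is_zero(self):
        a = np.zeros((3, 3))
        a[0, 2] = a[2, 0] = 0.0
        tom = topological_overlap(net_from_adjacency(a))
        assert tom.tom[0, 1] == 0.0

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(net_from_adjacency(a))
        np.testing.assert_allclose(tom.tom, bf_tom(a), atol=1e-12)

    def test_unweighted_clique_is_all_ones(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        tom = topological_overlap(net_from_adjacency(a))
        np.testing.assert_allclose(tom.tom, 1.0)

    def test_dissimilarity_complements_tom(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0, 0.5, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(net_from_adjacency(a))
        np.testing.assert_allclose(tom.dissimilarity, 1.0 - tom.tom)


def block_expression(seed=0, block_sizes=(35, 32), n_noise=0, n_samples=24):
    """Two (or more) perfectly coherent expression blocks plus noise genes."""
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for b, size in enumerate(block_sizes):
        profile = rng.normal(0, 1, n_samples)
        for i in range(size):
            rows.append(profile * (1 + 0.01 * i) + rng.normal(0, 0.01, n_samples))
            names.append(f"b{b}_{i}")
    for i in range(n_noise):
        rows.append(rng.normal(0, 1, n_samples))
        names.append(f"noise_{i}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"s{j}" for j in range(n_samples)])


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        le = block_expression(seed=1)
        net = build_network(correlation_matrix(le), beta=6)
        res = detect_modules(topological_overlap(net), le)
        assert len(res.modules) == 2
        for b in (0, 1):
            members = [g for g in le.index if g.startswith(f"b{b}_")]
            labels = set(res.assignment.loc[members])
            assert len(labels) == 1 and GREY not in labels

    def test_pure_noise_goes_grey(self):
        rng = np.random.default_rng(2)
        le = pd.DataFrame(rng.normal(0, 1, size=(60, 20)),
                          index=[f"g{i}" for i in range(60)])
        net = build_network(correlation_matrix(le), beta=6)
        with pytest.warns(UserWarning):
            res = detect_modules(topological_overlap(net), le)
        assert (res.assignment == GREY).all()

    def test_labels_ordered_by_size(self):
        le = block_expression(seed=3, block_sizes=(45, 33))
        net = build_network(correlation_matrix(le), beta=6)
        res = detect_modules(topological_overlap(net), le)
        sizes = {m: res.module_sizes[m] for m in res.modules}
        assert sizes["turquoise"] >= sizes["blue"]

    def test_identical_blocks_are_merged(self):
        # two blocks sharing one underlying profile merge via their eigengenes
        rng = np.random.default_rng(4)
        profile = rng.normal(0, 1, 24)
        rows = [profile + rng.normal(0, 0.05, 24) for _ in range(70)]
        le = pd.DataFrame(rows, index=[f"g{i}" for i in range(70)])
        net = build_network(correlation_matrix(le), beta=6)
        res = detect_modules(topological_overlap(net), le)
        assert len(res.modules) == 1


class TestEigengene:
    def test_rank_one_module_recovers_profile(self):
        profile = np.array([1.0, 5.0, 2.0, 8.0, 4.0, 0.0])
        le = pd.DataFrame([profile, 2 * profile + 3, 0.5 * profile - 1],
                          index=["a", "b", "c"])
        e = module_eigengene(le, ["a", "b", "c"])
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(e.to_numpy(), z, atol=1e-10)

    def test_sign_orientation_follows_members(self):
        profile = np.array([1.0, 5.0, 2.0, 8.0, 4.0, 0.0])
        le = pd.DataFrame([profile, profile * 1.5], index=["a", "b"])
        e_pos = module_eigengene(le, ["a", "b"])
        le_neg = -le
        e_neg = module_eigengene(le_neg, ["a", "b"])
        assert np.corrcoef(le.loc["a"], e_pos)[0, 1] > 0
        assert np.corrcoef(le_neg.loc["a"], e_neg)[0, 1] > 0

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(5)
        le = pd.DataFrame(rng.normal(0, 1, size=(10, 14)),
                          index=[f"g{i}" for i in range(10)])
        e = module_eigengene(le, le.index)
        x = le.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        vals, vecs = np.linalg.eigh(z.T @ z)
        lead = vecs[:, -1]
        lead = lead / lead.std()
        r = abs(np.corrcoef(lead, e.to_numpy())[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_constant_members_rejected(self):
        le = pd.DataFrame(np.ones((3, 6)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            module_eigengene(le, ["a", "b", "c"])


class TestMTR:
    def _design36(self):
        from conftest import make_design

        rows = []
        for cond in ("control", "salt"):
            for t in (0, 3, 6, 12, 24, 48):
                for rep in (1, 2, 3):
                    rows.append({"sample": f"{cond}_{t}_{rep}", "condition": cond,
                                 "time_h": float(t), "replicate": rep})
        return pd.DataFrame(rows).set_index("sample")

    def test_indicator_eigengene_self_correlation(self):
        design = self._design36()
        traits = salt_time_traits(design)
        eig = pd.DataFrame([traits["salt_12h"].to_numpy()], index=["m1"],
                           columns=design.index)
        mtr = module_trait_relationships(eig, traits)
        row = mtr.table.query("module == 'm1' and trait == 'salt_12h'").iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-10
        assert row.significant

    def test_orthogonal_trait_uncorrelated(self):
        design = self._design36()
        traits = salt_time_traits(design)
        rng = np.random.default_rng(0)
        e = rng.normal(0, 1, len(design))
        e -= e.mean()
        tv = traits["salt_12h"].to_numpy() - traits["salt_12h"].mean()
        e -= tv * (e @ tv) / (tv @ tv)
        eig = pd.DataFrame([e], index=["m1"], columns=design.index)
        mtr = module_trait_relationships(eig, traits)
        row = mtr.table.query("module == 'm1' and trait == 'salt_12h'").iloc[0]
        assert row.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_t_distribution_formula(self):
        design = self._design36()
        traits = salt_time_traits(design)
        rng = np.random.default_rng(6)
        eig = pd.DataFrame(rng.normal(0, 1, size=(3, 36)),
                           index=["m1", "m2", "m3"], columns=design.index)
        mtr = module_trait_relationships(eig, traits)
        n = 36
        for _, row in mtr.table.iterrows():
            r = np.corrcoef(eig.loc[row.module], traits[row.trait])[0, 1]
            tstat = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            p = 2 * stats.t.sf(abs(tstat), df=n - 2)
            assert row.r == pytest.approx(r, abs=1e-12)
            assert row.p == pytest.approx(p, rel=1e-10)

    def test_constant_trait_marked_na(self):
        design = self._design36()
        traits = salt_time_traits(design)
        traits["flat"] = 1.0
        rng = np.random.default_rng(7)
        eig = pd.DataFrame([rng.normal(0, 1, 36)], index=["m1"],
                           columns=design.index)
        mtr = module_trait_relationships(eig, traits)
        row = mtr.table.query("trait == 'flat'").iloc[0]
        assert np.isnan(row.r) and not row.significant


def test_planted_modules_peak_at_their_activity_time():
    """Each planted module's strongest trait correlation lands on its planted
    stress time point in most seeds (time-localized responses)."""
    from coexkey import filter_low_expression, normalize, size_factors

    hits = trials = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed)
        data, truth = generate_dataset(cfg)
        filt = filter_low_expression(data)
        norm = normalize(filt, size_factors(filt))
        traits = salt_time_traits(filt.design)
        profiles = cfg.profiles()
        bump_time = {
            f"M{m + 1}": max(profiles[m]["salt"], key=lambda t: abs(profiles[m]["salt"][t]))
            for m in range(cfg.n_modules)
        }
        eig = {}
        for m in range(cfg.n_modules):
            label = f"M{m + 1}"
            members = [g for g, mm in truth.module_membership.items()
                       if mm == label and g in norm.log_expression.index
                       and g not in truth.key_genes]
            eig[label] = module_eigengene(norm.log_expression, members)
        mtr = module_trait_relationships(pd.DataFrame(eig).T, traits)
        for label, t in bump_time.items():
            sub = mtr.table[mtr.table.module == label]
            best = sub.loc[sub.r.abs().idxmax(), "trait"]
            t_lab = int(t) if float(t).is_integer() else t
            trials += 1
            hits += best == f"salt_{t_lab}h"
    assert hits >= 0.8 * trials
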