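"""Coexpression network: TOM exactness, module recovery, drivers, permutation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysnet import modulenet as mn
from dysnet import synthio
from dysnet.degflow import run_deg_pipeline


def _tom_oracle(a):
    """Brute-force double-loop evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_hand_computed_three_gene_oracle(self):
        # pairwise correlations 0.9, 0.6, 0.3 at beta=2
        a = np.array([[1.0, 0.81, 0.36], [0.81, 1.0, 0.09], [0.36, 0.09, 1.0]])
        tom = mn.tom_from_adjacency(a)
        expected = np.array(
            [
                [1.0, 0.8424 / 1.09, 0.4329 / 1.09],
                [0.8424 / 1.09, 1.0, 0.3816 / 1.36],
                [0.4329 / 1.09, 0.3816 / 1.36, 1.0],
            ]
        )
        np.testing.assert_allclose(tom, expected, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            c = rng.uniform(-1, 1, (15, 15))
            a = np.abs((c + c.T) / 2) ** 3
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(
                mn.tom_from_adjacency(a), _tom_oracle(a), atol=1e-10
            )

    def test_symmetric_unit_interval(self, planted_network):
        tom = planted_network["network"].tom
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)

    def test_identical_genes_have_unit_overlap(self, rng):
        x = rng.normal(0, 1, 30)
        # exactly 1 when the pair is alone; near 1 alongside other genes,
        # where fractional shared adjacency enters the normalization
        pair = pd.DataFrame([x, x], index=["a", "b"],
                            columns=[f"s{i}" for i in range(30)])
        assert mn.build_tom(pair, beta=6).tom[0, 1] == pytest.approx(1.0)
        expr = pd.DataFrame(
            [x, x, rng.normal(0, 1, 30)], index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(30)],
        )
        net = mn.build_tom(expr, beta=6)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.tom[0, 1] > 0.99

    def test_independent_genes_vanishing_overlap(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (10, 2000)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(2000)],
        )
        net = mn.build_tom(expr, beta=6)
        off = net.tom[~np.eye(10, dtype=bool)]
        assert off.max() < 0.01

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (5, 20)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(20)],
        )
        expr.loc["g0"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            net = mn.build_tom(expr, beta=2)
        assert "g0" not in net.genes


class TestSoftPower:
    def test_mean_connectivity_decreases_with_power(self, planted_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, diag = mn.pick_soft_power(planted_sim["expr"].values)
        assert diag["mean_k"].is_monotonic_decreasing

    def test_planted_modules_reach_scale_free_target(self, planted_sim, planted_network):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, diag = mn.pick_soft_power(planted_sim["expr"].values)
        assert diag.loc[beta, "fit_r2"] >= 0.8
        assert beta == planted_network["beta"]

    def test_white_noise_falls_back_with_warning(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (60, 10)), index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="plateau"):
            mn.pick_soft_power(expr, candidates=range(1, 8), fit_target=0.99)

    def test_too_few_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            mn.pick_soft_power(expr)


class TestDetectModules:
    def test_planted_modules_recovered(self, planted_sim, planted_network):
        from sklearn.metrics import adjusted_rand_score

        assignment = planted_network["assignment"]
        truth_labels = (
            pd.Series(planted_sim["truth"].module_map)
            .reindex(assignment.index)
            .fillna("none")
        )
        assert adjusted_rand_score(truth_labels, assignment) >= 0.7
        # planted trait directions survive detection (up and down modules)
        stats_ = mn.module_trait_stats(
            planted_network["eigengenes"], planted_sim["meta"], covariates=("trait",)
        )
        assert {np.sign(r) for r in stats_["r"]} == {1.0, -1.0}

    def test_noise_mostly_unassigned(self):
        cfg = synthio.SimConfig(n_genes=600, de_fraction=0.0, seed=13)
        counts, meta, _ = synthio.simulate_bulk_counts(cfg)
        _, expr, _ = run_deg_pipeline(counts, meta, drop_outliers=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, _ = mn.pick_soft_power(expr.values)
            assignment, _ = mn.detect_modules(mn.build_tom(expr.values, beta))
        assert (assignment == mn.UNASSIGNED).mean() >= 0.8

    def test_min_size_above_planted_structure_suppresses_it(self, planted_network):
        assignment, _ = mn.detect_modules(planted_network["network"], min_size=400)
        assert set(assignment.unique()) == {mn.UNASSIGNED}

    def test_every_gene_labeled_once(self, planted_network):
        assignment = planted_network["assignment"]
        assert len(assignment) == len(planted_network["network"].genes)
        assert not assignment.isna().any()


class TestEigengenes:
    def test_unit_norm_and_positive_orientation(self, planted_sim, planted_network):
        eig = planted_network["eigengenes"]
        norms = np.linalg.norm(eig.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0)
        expr = planted_sim["expr"].values
        assignment = planted_network["assignment"]
        for label in eig.index:
            genes = assignment.index[assignment == label]
            cors = [
                np.corrcoef(expr.loc[g], eig.loc[label])[0, 1] for g in genes
            ]
            assert np.mean(cors) >= 0

    def test_sign_flip_flips_eigengene_only(self, planted_sim, planted_network):
        expr = planted_sim["expr"].values
        assignment = planted_network["assignment"]
        eig = mn.module_eigengenes(expr, assignment)
        flipped = mn.module_eigengenes(-expr, assignment)
        meta = planted_sim["meta"]
        r1 = mn.module_trait_stats(eig, meta, covariates=("trait",))
        r2 = mn.module_trait_stats(flipped, meta, covariates=("trait",))
        np.testing.assert_allclose(np.abs(r1["r"]), np.abs(r2["r"]), atol=1e-9)


class TestModuleTraitStats:
    def test_eigengene_equal_to_trait_gives_unit_correlation(self):
        trait = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        eig = pd.DataFrame([trait], index=["m1"], columns=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(6)], "trait": list("AAABBB")}
        )
        out = mn.module_trait_stats(eig, meta, covariates=("trait",))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_eigengene_gives_zero(self):
        # zero-mean eigengene orthogonal to the 0/0/0/1/1/1 trait encoding
        eig = pd.DataFrame(
            [[1, -1, 0, 0, 1, -1]], index=["m1"], columns=[f"s{i}" for i in range(6)]
        )
        meta = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(6)], "trait": list("AAABBB")}
        )
        out = mn.module_trait_stats(eig, meta, covariates=("trait",))
        assert abs(out["r"].iloc[0]) < 1e-12

    def test_zero_variance_trait_rejected(self):
        eig = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["m"], columns=list("abcd"))
        meta = pd.DataFrame({"sample": list("abcd"), "trait": ["X"] * 4})
        with pytest.raises(ValueError, match="variance"):
            mn.module_trait_stats(eig, meta, covariates=("trait",))

    def test_p_matches_t_transform(self, planted_sim, planted_network):
        out = mn.module_trait_stats(planted_network["eigengenes"], planted_sim["meta"])
        n = planted_network["eigengenes"].shape[1]
        for _, row in out.iterrows():
            t = abs(row["r"]) * np.sqrt((n - 2) / (1 - row["r"] ** 2))
            assert row["p"] == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-6)


class TestGeneStats:
    def test_self_eigengene_and_trait_extremes(self):
        samples = [f"s{i}" for i in range(8)]
        trait_vec = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        eig_vec = trait_vec - trait_vec.mean()
        eig_vec /= np.linalg.norm(eig_vec)
        expr = pd.DataFrame(
            [eig_vec, trait_vec], index=["ge", "gt"], columns=samples
        )
        eig = pd.DataFrame([eig_vec], index=["m1"], columns=samples)
        assignment = pd.Series(["m1", "m1"], index=["ge", "gt"])
        meta = pd.DataFrame({"sample": samples, "trait": list("AAAABBBB")})
        per_gene, _ = mn.gene_module_stats(expr, eig, assignment, meta)
        assert per_gene.loc["ge", "MM"] == pytest.approx(1.0)
        assert abs(per_gene.loc["gt", "GS"]) == pytest.approx(1.0)

    def test_trait_linked_module_couples_gs_and_mm(self, planted_sim, planted_network):
        per_gene, summary = mn.gene_module_stats(
            planted_sim["expr"].values,
            planted_network["eigengenes"],
            planted_network["assignment"],
            planted_sim["meta"],
        )
        assert (summary["gs_mm_r"] > 0.4).all()
        assert (summary["gs_mm_p"] < 0.01).all()
        assert per_gene["MM"].abs().max() <= 1.0 + 1e-9


class TestDrivers:
    def test_distinct_scores_yield_exact_top_five(self):
        mm = np.linspace(0.01, 1.0, 100)
        per_gene = pd.DataFrame(
            {"module": "m1", "MM": mm, "GS": mm}, index=[f"g{i}" for i in range(100)]
        )
        drivers = mn.select_drivers(per_gene, percentile=95)
        assert sorted(drivers["m1"]) == sorted(f"g{i}" for i in range(95, 100))

    def test_ties_at_cutoff_all_included(self):
        mm = np.array([0.1] * 90 + [0.9] * 10)
        per_gene = pd.DataFrame(
            {"module": "m1", "MM": mm, "GS": mm}, index=[f"g{i}" for i in range(100)]
        )
        drivers = mn.select_drivers(per_gene, percentile=95)
        assert len(drivers["m1"]) == 10  # all tied top scores survive

    def test_percentile_zero_selects_everyone(self):
        per_gene = pd.DataFrame(
            {"module": "m1", "MM": np.linspace(0, 1, 30), "GS": 0.0},
            index=[f"g{i}" for i in range(30)],
        )
        drivers = mn.select_drivers(per_gene, percentile=0)
        assert len(drivers["m1"]) == 30

    def test_small_module_warns(self):
        per_gene = pd.DataFrame(
            {"module": "tiny", "MM": np.linspace(0, 1, 10), "GS": 0.0},
            index=[f"g{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="coarse"):
            mn.select_drivers(per_gene)


class TestPermutationValidation:
    def test_zero_permutations_rejected(self, planted_sim, planted_network):
        with pytest.raises(ValueError):
            mn.permute_module_validation(
                planted_sim["expr"].values,
                planted_network["assignment"],
                planted_sim["meta"],
                n_perm=0,
            )

    def test_cloud_shape_and_flags(self, planted_sim, planted_network):
        summary = mn.permute_module_validation(
            planted_sim["expr"].values,
            planted_network["assignment"],
            planted_sim["meta"],
            n_perm=10,
            seed=1,
        )
        modules = list(planted_network["eigengenes"].index)
        assert len(summary.permuted) == 10 * len(modules)
        assert set(summary.exceeds_all.index) == set(modules)
        for module in modules:
            cloud = summary.permuted[summary.permuted["module"] == module]
            expected = bool(
                abs(summary.observed.loc[module, "r"]) > cloud["r"].abs().max()
                and summary.observed.loc[module, "p"] < cloud["p"].min()
            )
            assert summary.exceeds_all[module] == expected

    def test_rank_of_null_module_is_uniform(self, rng):
        """Exchangeability: for a trait-independent module the observed |r|
        rank among permuted values is uniform."""
        samples = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"sample": samples, "trait": ["a"] * 6 + ["b"] * 6})
        n_perm, reps = 19, 120
        ranks = []
        for rep in range(reps):
            expr = pd.DataFrame(
                rng.normal(0, 1, (60, 12)),
                index=[f"g{i}" for i in range(60)], columns=samples,
            )
            assignment = pd.Series(
                ["m1"] * 30 + [mn.UNASSIGNED] * 30, index=expr.index
            )
            s = mn.permute_module_validation(
                expr, assignment, meta, n_perm=n_perm, seed=rep
            )
            obs = abs(s.observed.loc["m1", "r"])
            perm = s.permuted["r"].abs().to_numpy()
            ranks.append(int((perm < obs).sum()))
        counts = np.bincount(ranks, minlength=n_perm + 1)
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestDriverDeletion:
    def test_no_drivers_returns_zero_statistic(self, planted_sim, planted_network):
        module = planted_network["eigengenes"].index[0]
        shift = mn.driver_deletion_shift(
            planted_network["network"], planted_network["assignment"], [], module
        )
        assert shift.statistic == 0.0 and shift.note

    def test_driver_deletion_shifts_weights_left(self, planted_sim, planted_network):
        network = planted_network["network"]
        assignment = planted_network["assignment"]
        per_gene, _ = mn.gene_module_stats(
            planted_sim["expr"].values, planted_network["eigengenes"],
            assignment, planted_sim["meta"],
        )
        drivers = mn.select_drivers(per_gene)
        module = max(drivers, key=lambda m: (assignment == m).sum())
        shift = mn.driver_deletion_shift(network, assignment, drivers[module], module)
        assert shift.direction == "left"
        assert shift.statistic > 0.1 and shift.pvalue < 0.01
        # matched random deletions shift far less
        members = [g for g in assignment.index
                   if assignment[g] == module and g not in set(drivers[module])]
        rng = np.random.default_rng(0)
        random_d = [
            mn.driver_deletion_shift(
                network, assignment,
                list(rng.choice(members, size=len(drivers[module]), replace=False)),
                module,
            ).statistic
            for _ in range(20)
        ]
        assert float(np.median(random_d)) < shift.statistic

    def test_adjacency_mode_and_unknown_weights(self, planted_network):
        module = planted_network["eigengenes"].index[0]
        assignment = planted_network["assignment"]
        members = list(assignment.index[assignment == module])
        shift = mn.driver_deletion_shift(
            planted_network["network"], assignment, members[:3], module,
            weights="adjacency",
        )
        assert 0 <= shift.statistic <= 1
        with pytest.raises(ValueError, match="weights"):
            mn.driver_deletion_shift(
                planted_network["network"], assignment, members[:3], module,
                weights="raw",
            )
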