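import dataclasses
import itertools

import numpy as np
import pytest

from ibcnet import AnalysisConfig, ExpressionMatrix, ksg_mi, mi_matrix
from ibcnet.network import (
    MIMatrix,
    MINetwork,
    Regulon,
    dpi_prune,
    extract_regulons,
    permutation_mi_threshold,
    threshold_mi_matrix,
)


def gaussian_pair(rho, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


class TestKSG:
    def test_independent_vectors_near_zero(self):
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            estimates.append(
                ksg_mi(rng.standard_normal(1000), rng.standard_normal(1000), k=3, seed=seed)
            )
        assert np.mean(estimates) < 0.05

    def test_correlated_gaussian_matches_closed_form(self):
        """Bivariate normal rho=0.9: MI = -0.5*ln(1-rho^2) ~ 0.830 nats."""
        true_mi = -0.5 * np.log(1 - 0.81)
        estimates = [
            ksg_mi(*gaussian_pair(0.9, 1000, seed), k=3, seed=seed)
            for seed in range(10)
        ]
        assert abs(np.mean(estimates) - true_mi) <= 0.1

    def test_near_identity_dependence_is_large(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        assert ksg_mi(x, x, k=3, noise_amplitude=1e-10, seed=1) > 2.0

    def test_symmetry_exact_without_jitter(self):
        x, y = gaussian_pair(0.5, 300, seed=4)
        assert ksg_mi(x, y, noise_amplitude=0.0) == ksg_mi(y, x, noise_amplitude=0.0)

    def test_consistency_improves_with_n(self):
        """Mean absolute error vs the Gaussian closed form shrinks from n=250 to n=1000."""
        true_mi = -0.5 * np.log(1 - 0.81)
        errors = {}
        for n in (250, 1000):
            est = [
                ksg_mi(*gaussian_pair(0.9, n, 100 + seed), k=3, seed=seed)
                for seed in range(10)
            ]
            errors[n] = abs(np.mean(est) - true_mi)
        assert errors[1000] <= errors[250]

    def test_matches_reference_knn_estimator(self):
        """Independent check against scikit-learn's k-NN MI implementation."""
        sklearn = pytest.importorskip("sklearn.feature_selection")
        diffs = []
        for seed in range(5):
            x, y = gaussian_pair(0.7, 800, seed)
            ours = ksg_mi(x, y, k=3, seed=seed)
            theirs = sklearn.mutual_info_regression(
                x[:, None], y, n_neighbors=3, random_state=seed
            )[0]
            diffs.append(ours - theirs)
        assert abs(np.mean(diffs)) < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ksg_mi([1.0, 2.0], [1.0, 2.0], k=3)
        with pytest.raises(ValueError):
            ksg_mi([1.0, np.nan, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0], k=1)


class TestMIMatrix:
    @pytest.fixture
    def matrix(self, rng):
        genes = [f"T{i}" for i in range(3)] + [f"G{i}" for i in range(7)]
        return ExpressionMatrix(
            genes, [f"S{j}" for j in range(120)], rng.standard_normal((10, 120))
        )

    def test_shape_and_self_exclusion(self, matrix, config):
        mim = mi_matrix(matrix, ["T0", "T1", "T2"], config)
        assert mim.mi.shape == (3, 10)
        for t, tf in enumerate(mim.tf_ids):
            assert np.isnan(mim.mi[t, mim.gene_ids.index(tf)])

    def test_tf_block_symmetric(self, matrix, config):
        mim = mi_matrix(matrix, ["T0", "T1", "T2"], config)
        cols = [mim.gene_ids.index(tf) for tf in mim.tf_ids]
        block = mim.mi[:, cols]
        np.testing.assert_array_equal(block[0, 1], block[1, 0])
        np.testing.assert_array_equal(block[0, 2], block[2, 0])

    def test_sample_permutation_invariance(self, matrix):
        config = AnalysisConfig(noise_amplitude=0.0, seed=0)
        perm = np.random.default_rng(5).permutation(matrix.n_samples)
        permuted = ExpressionMatrix(
            matrix.gene_ids,
            [matrix.sample_ids[j] for j in perm],
            matrix.values[:, perm],
        )
        a = mi_matrix(matrix, ["T0", "T1"], config)
        b = mi_matrix(permuted, ["T0", "T1"], config)
        np.testing.assert_allclose(a.mi, b.mi, atol=1e-9)

    def test_unknown_tf_rejected(self, matrix, config):
        with pytest.raises(KeyError):
            mi_matrix(matrix, ["NOPE"], config)

    def test_zero_coupling_tf_target_mi_like_background(self, config):
        """With coupling 0 the mean TF-target MI matches TF-background MI."""
        from ibcnet import GeneratorParams, generate_truth, simulate_expression

        tt, bg = [], []
        for seed in range(5):
            params = GeneratorParams(
                n_ibc=50, n_nibc=70, n_tfs=3, n_mr=0, regulon_size=8,
                n_background=40, coupling=0.0, seed=seed,
            )
            truth = generate_truth(params)
            X, _ = simulate_expression(truth, params)
            mim = mi_matrix(X, truth.tf_ids, dataclasses.replace(config, seed=seed))
            col = {g: j for j, g in enumerate(mim.gene_ids)}
            for t, tf in enumerate(truth.tf_ids):
                tt.extend(mim.mi[t, col[g]] for g in truth.regulons[tf])
                bg.extend(mim.mi[t, col[g]] for g in mim.gene_ids if g.startswith("BG"))
        assert abs(np.mean(tt) - np.mean(bg)) < 0.01


def dpi_oracle(mim: MIMatrix, eps: float) -> set:
    """Enumerate every fully estimated triple and cut the strictly weakest edge."""
    col = {g: j for j, g in enumerate(mim.gene_ids)}
    tf_set = set(mim.tf_ids)

    def mi(a, b):
        if a in tf_set and b in col:
            v = mim.mi[mim.tf_ids.index(a), col[b]]
            return None if np.isnan(v) else v
        return None

    removed = set()
    nodes = mim.gene_ids
    for t in mim.tf_ids:
        for g in nodes:
            v_tg = mi(t, g)
            if v_tg is None or v_tg <= 0:
                continue
            for u in mim.tf_ids:
                if u in (t, g):
                    continue
                v_tu, v_ug = mi(t, u), mi(u, g)
                if v_tu is None or v_ug is None:
                    continue
                if v_tg < min(v_tu, v_ug) - eps:
                    removed.add((t, g))
                    break
    return {
        (t, g, float(mim.mi[i, col[g]]))
        for i, t in enumerate(mim.tf_ids)
        for g in nodes
        if t != g and not np.isnan(mim.mi[i, col[g]]) and mim.mi[i, col[g]] > 0
        and (t, g) not in removed
    }


def random_mimatrix(rng, n=6):
    nodes = [f"N{i}" for i in range(n)]
    sym = rng.uniform(0, 1, size=(n, n))
    sym = (sym + sym.T) / 2
    np.fill_diagonal(sym, np.nan)
    return MIMatrix(tf_ids=nodes, gene_ids=nodes, mi=sym)


class TestDPI:
    def triangle(self, xy, yz, xz):
        mi = np.array(
            [
                [np.nan, xy, xz],
                [xy, np.nan, yz],
                [xz, yz, np.nan],
            ]
        )
        return MIMatrix(tf_ids=["X", "Y", "Z"], gene_ids=["X", "Y", "Z"], mi=mi)

    def test_weakest_edge_of_chain_removed(self):
        net = dpi_prune(self.triangle(0.8, 0.7, 0.3), eps=0.0)
        pairs = {(a, b) for a, b, _ in net.edges}
        assert ("X", "Z") not in pairs and ("Z", "X") not in pairs
        assert ("X", "Y") in pairs and ("Y", "Z") in pairs

    def test_large_tolerance_disables_pruning(self):
        net = dpi_prune(self.triangle(0.8, 0.7, 0.3), eps=0.4)
        assert len({(a, b) for a, b, _ in net.edges}) == 6  # both directions kept

    def test_equal_mi_never_removed(self):
        net = dpi_prune(self.triangle(0.5, 0.5, 0.5), eps=0.0)
        assert len(net.edges) == 6

    @pytest.mark.parametrize("eps", [0.0, 0.05])
    def test_matches_exhaustive_triple_oracle(self, eps):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mim = random_mimatrix(rng)
            assert dpi_prune(mim, eps).edges == dpi_oracle(mim, eps)

    def test_output_subset_of_input_and_idempotent(self):
        rng = np.random.default_rng(7)
        mim = random_mimatrix(rng, n=8)
        net = dpi_prune(mim, eps=0.0)
        all_pairs = {
            (t, g)
            for i, t in enumerate(mim.tf_ids)
            for g in mim.gene_ids
            if t != g
        }
        assert {(a, b) for a, b, _ in net.edges} <= all_pairs
        # rebuild a matrix containing only surviving edges and prune again
        col = {g: j for j, g in enumerate(mim.gene_ids)}
        pruned = np.full_like(mim.mi, 0.0)
        np.fill_diagonal(pruned, np.nan)
        for a, b, v in net.edges:
            pruned[mim.tf_ids.index(a), col[b]] = v
        again = dpi_prune(
            MIMatrix(tf_ids=mim.tf_ids, gene_ids=mim.gene_ids, mi=pruned), eps=0.0
        )
        assert again.edges == net.edges


class TestRegulons:
    def test_direct_neighborhood(self):
        net = MINetwork(edges={("T1", "A", 0.5), ("T1", "B", 0.4)})
        regs = extract_regulons(net, ["T1", "T2"])
        assert len(regs) == 1
        assert regs[0].tf_id == "T1" and regs[0].targets == {"A", "B"}

    def test_empty_network_gives_no_regulons(self):
        assert extract_regulons(MINetwork(edges=set()), ["T1"]) == []

    def test_tf_as_target_counts_as_neighbor(self):
        net = MINetwork(edges={("T1", "T2", 0.5)})
        regs = {r.tf_id: r.targets for r in extract_regulons(net, ["T1", "T2"])}
        assert regs == {"T1": {"T2"}, "T2": {"T1"}}

    def test_planted_targets_recovered(self, small_params, config):
        """Most planted regulon members survive MI + DPI at a modest cohort size."""
        from ibcnet import generate_truth, simulate_expression

        truth = generate_truth(small_params)
        X, _ = simulate_expression(truth, small_params)
        mim = mi_matrix(X, truth.tf_ids, config)
        regs = {r.tf_id: r.targets for r in extract_regulons(dpi_prune(mim), truth.tf_ids)}
        fractions = [
            len(truth.regulons[tf] & regs.get(tf, set())) / len(truth.regulons[tf])
            for tf in truth.tf_ids
        ]
        assert np.mean(fractions) >= 0.7


class TestPermutationThreshold:
    def test_threshold_separates_signal_from_noise(self, small_cohort, config):
        truth, X, labels = small_cohort
        thr = permutation_mi_threshold(X, truth.tf_ids, config, n_perm=50)
        assert thr >= 0
        mim = mi_matrix(X, truth.tf_ids, config)
        kept = threshold_mi_matrix(mim, thr)
        # planted TF-target MI should largely survive the null threshold
        col = {g: j for j, g in enumerate(kept.gene_ids)}
        tf = truth.tf_ids[0]
        surviving = [
            kept.mi[0, col[g]] > 0 for g in truth.regulons[tf]
        ]
        assert np.mean(surviving) >= 0.7
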