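import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import crossome as cx
from conftest import brute_force_tau_b


class TestKendallTauB:
    def test_perfect_concordance(self):
        tau, n = cx.kendall_tau_b([1, 2, 3, 4], [2, 4, 6, 8])
        assert tau == pytest.approx(1.0)
        assert n == 4

    def test_perfect_discordance(self):
        tau, _ = cx.kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_worked_example(self):
        # brute force over all 10 pairs: C=7, D=3 -> (7-3)/10 = 0.4
        tau, n = cx.kendall_tau_b([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert tau == pytest.approx(0.4, abs=1e-15)
        assert n == 5

    def test_constant_vector_is_missing(self):
        tau, _ = cx.kendall_tau_b([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(tau)

    def test_pairwise_complete_drops_missing(self):
        tau, n = cx.kendall_tau_b([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert n == 3
        assert tau == pytest.approx(1.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(cx.ValidationError):
            cx.kendall_tau_b([1, 2], [1, 2, 3])

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.data(),
        n=st.integers(3, 12),
    )
    def test_matches_brute_force_with_ties(self, data, n):
        # small integer support forces ties frequently
        ints = st.integers(0, 4)
        x = data.draw(st.lists(ints, min_size=n, max_size=n))
        y = data.draw(st.lists(ints, min_size=n, max_size=n))
        tau, _ = cx.kendall_tau_b(x, y)
        oracle, _ = brute_force_tau_b(x, y)
        if np.isnan(oracle):
            assert np.isnan(tau)
        else:
            assert tau == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_matches_scipy_on_random_vectors(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        tau, _ = cx.kendall_tau_b(x, y)
        ref = stats.kendalltau(x, y, variant="b").statistic
        if np.isnan(ref):
            assert np.isnan(tau)
        else:
            assert tau == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        t_xy, _ = cx.kendall_tau_b(x, y)
        t_yx, _ = cx.kendall_tau_b(y, x)
        assert t_xy == pytest.approx(t_yx, abs=1e-14)
        t_trans, _ = cx.kendall_tau_b(np.exp(2 * x) + 1, y)
        assert t_trans == pytest.approx(t_xy, abs=1e-14)

    def test_null_mean_within_monte_carlo_error(self):
        rng = np.random.default_rng(42)
        n, reps = 10, 1000
        taus = np.array(
            [cx.kendall_tau_b(rng.normal(size=n), rng.normal(size=n))[0] for _ in range(reps)]
        )
        se = taus.std(ddof=1) / np.sqrt(reps)
        assert abs(taus.mean()) < 3 * se


def _omics(values, features, samples, layer):
    return cx.OmicsMatrix(layer, pd.DataFrame(values, index=features, columns=samples))


class TestBuildCrossome:
    def _panel(self):
        samples = [f"S{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        prot = _omics(
            np.vstack([base, rng.normal(size=12)]), ["Psame", "Pother"], samples, "protein"
        )
        lip = _omics(
            np.vstack([base, -base]), ["Lsame", "Lneg"], samples, "lipid"
        )
        return prot, lip

    def test_identical_profile_gives_tau_one(self):
        prot, lip = self._panel()
        cm = cx.build_crossome(prot, lip, min_overlap=12)
        assert cm.tau.loc["Lsame", "Psame"] == pytest.approx(1.0)

    def test_negated_profile_gives_tau_minus_one(self):
        prot, lip = self._panel()
        cm = cx.build_crossome(prot, lip, min_overlap=12)
        assert cm.tau.loc["Lneg", "Psame"] == pytest.approx(-1.0)

    def test_matches_per_pair_oracle_with_missingness(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(15)]
        pv = rng.integers(0, 6, size=(6, 15)).astype(float)
        lv = rng.integers(0, 6, size=(4, 15)).astype(float)
        pv[rng.random(pv.shape) < 0.2] = np.nan
        lv[rng.random(lv.shape) < 0.2] = np.nan
        prot = _omics(pv, [f"P{i}" for i in range(6)], samples, "protein")
        lip = _omics(lv, [f"L{i}" for i in range(4)], samples, "lipid")
        cm = cx.build_crossome(prot, lip, min_overlap=2)
        for li in lip.feature_ids:
            for pi in prot.feature_ids:
                oracle, n = brute_force_tau_b(lip.data.loc[li], prot.data.loc[pi])
                got = cm.tau.loc[li, pi]
                assert cm.n_pairs.loc[li, pi] == n
                if np.isnan(oracle) or n < 2:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(oracle, abs=1e-12)

    def test_min_overlap_masks_cells(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(12)]
        pv = rng.normal(size=(1, 12))
        lv = rng.normal(size=(1, 12))
        lv[0, :6] = np.nan  # only 6 joint samples
        prot = _omics(pv, ["P0"], samples, "protein")
        lip = _omics(lv, ["L0"], samples, "lipid")
        cm = cx.build_crossome(prot, lip, min_overlap=7)
        assert np.isnan(cm.tau.loc["L0", "P0"])
        assert cm.n_pairs.loc["L0", "P0"] == 6

    def test_too_few_shared_samples_fatal(self):
        prot = _omics(np.ones((1, 3)), ["P0"], ["a", "b", "c"], "protein")
        lip = _omics(np.ones((1, 3)), ["L0"], ["a", "b", "c"], "lipid")
        with pytest.raises(cx.ValidationError):
            cx.build_crossome(prot, lip, min_overlap=12)

    def test_genotype_mean_mode_planted_module_zero_noise(self):
        cfg = cx.SimConfig(
            n_genotypes=12, n_proteins=60, n_lipids=30, n_modules=2,
            proteins_per_module=10, lipids_per_module=5, noise_sd=0.0,
            missing_random=0.0, mnar_strength=0.0, seed=2,
        )
        panel = cx.simulate_panel(cfg)
        cm = cx.build_crossome(
            panel.protein, panel.lipid, panel.metadata,
            mode="genotype_mean", min_overlap=13,
        )
        for mod in panel.truth.modules.values():
            block = cm.tau.loc[list(mod["lipid_members"]), list(mod["protein_members"])]
            # identical genotype-mean orderings force tau = 1 within a module
            assert np.allclose(block.to_numpy(), 1.0)


class TestFilterConnected:
    def _cm(self, tau):
        tau = pd.DataFrame(
            tau,
            index=[f"L{i}" for i in range(tau.shape[0])],
            columns=[f"P{j}" for j in range(tau.shape[1])],
        )
        n = pd.DataFrame(20, index=tau.index, columns=tau.columns)
        return cx.CrossomeMatrix(tau, n)

    def test_two_strong_partners_retained(self):
        cm = self._cm(np.array([[0.50, 0.45, 0.0], [0.1, 0.2, 0.3]]))
        out = cx.filter_connected(cm, cx.FilterConfig(0.4, 2, 2))
        assert out.lipid_ids == ["L0"]

    def test_single_strong_partner_dropped(self):
        cm = self._cm(np.array([[0.90, 0.0, 0.0]]))
        with pytest.warns(UserWarning):
            out = cx.filter_connected(cm, cx.FilterConfig(0.4, 2, 2))
        assert out.lipid_ids == []

    def test_boundary_is_strict(self):
        cm = self._cm(np.full((2, 3), 0.40))
        with pytest.warns(UserWarning):
            out = cx.filter_connected(cm, cx.FilterConfig(0.4, 2, 2))
        assert out.shape == (0, 0)

    def test_counting_is_single_pass_on_full_matrix(self):
        # L0 keeps P0/P1; P2's only strong partner row (L1) is dropped, but
        # counting on the full matrix still retains P2 via L1's taus
        tau = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 0.9]])
        cm = self._cm(tau)
        out = cx.filter_connected(cm, cx.FilterConfig(0.4, 1, 2))
        assert out.lipid_ids == ["L0", "L1"]
        assert out.protein_ids == ["P0", "P1", "P2"]

    def test_missing_cells_are_non_partners(self):
        tau = np.array([[0.5, np.nan, np.nan]])
        cm = self._cm(tau)
        with pytest.warns(UserWarning):
            out = cx.filter_connected(cm, cx.FilterConfig(0.4, 2, 2))
        assert out.shape == (0, 0)

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        tau = rng.uniform(-1, 1, size=(8, 10))
        cm = self._cm(tau)
        out = cx.filter_connected(cm, cx.FilterConfig(0.4, 2, 2))
        perm_rows = rng.permutation(cm.tau.index)
        perm_cols = rng.permutation(cm.tau.columns)
        cm2 = cx.CrossomeMatrix(
            cm.tau.loc[perm_rows, perm_cols], cm.n_pairs.loc[perm_rows, perm_cols]
        )
        out2 = cx.filter_connected(cm2, cx.FilterConfig(0.4, 2, 2))
        assert set(out.lipid_ids) == set(out2.lipid_ids)
        assert set(out.protein_ids) == set(out2.protein_ids)
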