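import numpy as np
import pandas as pd
import pytest

import crossome as cx


def _diff(values: dict, genotypes=None):
    """values: feature -> list of per-genotype log2fc."""
    fc = pd.DataFrame(values).T
    fc.columns = genotypes or [f"KO{i + 1:02d}" for i in range(fc.shape[1])]
    n = fc.notna().astype(int) * 2
    return cx.DifferentialMatrix(fc, n, n.where(n > 0, 2).astype(int))


def _cm(tau):
    tau = pd.DataFrame(
        tau,
        index=[f"L{i}" for i in range(tau.shape[0])],
        columns=[f"P{j}" for j in range(tau.shape[1])],
    )
    n = pd.DataFrame(20, index=tau.index, columns=tau.columns)
    return cx.CrossomeMatrix(tau, n)


class TestSetSignature:
    def test_sum_mode(self):
        diff = _diff({"A": [1.0], "B": [0.5]})
        prof = cx.set_signature(diff, ["A", "B"], mode="sum")
        assert prof.values.iloc[0] == pytest.approx(1.5)
        assert prof.n_members_used.iloc[0] == 2

    def test_mean_mode(self):
        diff = _diff({"A": [1.0], "B": [0.5]})
        prof = cx.set_signature(diff, ["A", "B"], mode="mean")
        assert prof.values.iloc[0] == pytest.approx(0.75)

    def test_all_members_missing_gives_missing_with_zero_count(self):
        diff = _diff({"A": [np.nan], "B": [np.nan], "C": [1.0]})
        prof = cx.set_signature(diff, ["A", "B"], mode="sum")
        assert np.isnan(prof.values.iloc[0])
        assert prof.n_members_used.iloc[0] == 0

    def test_empty_member_set_errors(self):
        diff = _diff({"A": [1.0]})
        with pytest.raises(cx.ValidationError):
            cx.set_signature(diff, [])

    def test_sum_additive_over_disjoint_union(self):
        rng = np.random.default_rng(0)
        feats = {f"F{i}": list(rng.normal(size=3)) for i in range(10)}
        diff = _diff(feats)
        left, right = list(feats)[:4], list(feats)[4:]
        s_all = cx.set_signature(diff, left + right, mode="sum").values
        s_sum = (
            cx.set_signature(diff, left, mode="sum").values
            + cx.set_signature(diff, right, mode="sum").values
        )
        np.testing.assert_allclose(s_all.to_numpy(), s_sum.to_numpy(), atol=1e-12)


class TestModuleSignatures:
    def test_disjoint_sets_independent(self):
        diff = _diff({"A": [1.0], "B": [3.0]})
        ann = cx.AnnotationSets.from_dict("protein", {"S1": ["A"], "S2": ["B"]})
        profs = cx.module_signatures(diff, ann, mode="mean")
        assert profs["S1"].values.iloc[0] == pytest.approx(1.0)
        assert profs["S2"].values.iloc[0] == pytest.approx(3.0)

    def test_grand_mean_when_set_is_everything(self):
        diff = _diff({"A": [1.0], "B": [3.0]})
        ann = cx.AnnotationSets.from_dict("protein", {"all": ["A", "B"]})
        profs = cx.module_signatures(diff, ann, mode="mean")
        assert profs["all"].values.iloc[0] == pytest.approx(2.0)

    def test_planted_effect_recovered_exactly_without_noise(self):
        cfg = cx.SimConfig(
            n_proteins=60, n_lipids=30, n_modules=2, proteins_per_module=10,
            lipids_per_module=5, noise_sd=0.0, missing_random=0.0,
            mnar_strength=0.0, seed=4,
        )
        panel = cx.simulate_panel(cfg)
        diff = cx.log2fc_vs_control(panel.protein, panel.metadata)
        mod = panel.truth.modules["module1"]
        prof = cx.set_signature(diff, mod["protein_members"], mode="mean")
        for g in mod["affected_genotypes"]:
            assert prof.values[g] == pytest.approx(cfg.effect_size, abs=1e-9)


class TestExtractNetwork:
    def test_seed_protein_collects_partners(self):
        cm = _cm(np.array([[0.5, 0.0], [0.6, 0.0], [-0.7, 0.0]]))
        g = cx.extract_network(cm, ["P0"], 0.4)
        assert g.number_of_edges() == 3
        assert g.nodes["P0"]["layer"] == "protein"

    def test_threshold_one_empty(self):
        cm = _cm(np.array([[0.9]]))
        g = cx.extract_network(cm, ["P0"], 1.0)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 0

    def test_seeds_on_both_layers_union_no_duplicates(self):
        cm = _cm(np.array([[0.5, 0.45], [0.0, 0.8]]))
        g = cx.extract_network(cm, ["L0", "P1"], 0.4)
        # L0-P0, L0-P1 from the lipid seed; L1-P1 from the protein seed
        assert g.number_of_edges() == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        cm = _cm(rng.uniform(-1, 1, size=(6, 6)))
        lo = cx.extract_network(cm, ["L0", "P0"], 0.3)
        hi = cx.extract_network(cm, ["L0", "P0"], 0.6)
        assert {frozenset(e) for e in hi.edges()} <= {frozenset(e) for e in lo.edges()}

    def test_unknown_seed_errors(self):
        cm = _cm(np.array([[0.5]]))
        with pytest.raises(cx.ValidationError):
            cx.extract_network(cm, ["nope"], 0.4)


class TestTopPartnerFrequency:
    def test_shared_top_three(self):
        tau = np.array([[0.9, 0.8, 0.7, 0.1], [0.85, 0.75, 0.65, 0.0]])
        cm = _cm(tau)
        out = cx.top_partner_frequency(cm, ["L0", "L1"], 3)
        assert dict(zip(out["protein_id"], out["frequency"])) == {
            "P0": 2, "P1": 2, "P2": 2,
        }

    def test_saturation_warns_and_takes_all(self):
        tau = np.array([[0.9, np.nan, np.nan]])
        cm = _cm(tau)
        with pytest.warns(UserWarning):
            out = cx.top_partner_frequency(cm, ["L0"], 5)
        assert out["frequency"].sum() == 1

    def test_category_conservation(self):
        rng = np.random.default_rng(1)
        cm = _cm(rng.uniform(-1, 1, size=(4, 8)))
        out = cx.top_partner_frequency(
            cm, cm.lipid_ids, 3, categories={p: "one" for p in cm.protein_ids}
        )
        assert out["frequency"].sum() == 4 * 3
        assert (out["category"] == "one").all()

    def test_tie_break_descending_tau_then_id(self):
        tau = np.array([[0.5, 0.5, 0.4]])
        cm = _cm(tau)
        out = cx.top_partner_frequency(cm, ["L0"], 2)
        assert set(out["protein_id"]) == {"P0", "P1"}

    def test_total_count_conservation(self):
        rng = np.random.default_rng(2)
        tau = rng.uniform(-1, 1, size=(5, 7))
        tau[rng.random(tau.shape) < 0.4] = np.nan
        cm = _cm(tau)
        n_top = 4
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cx.top_partner_frequency(cm, cm.lipid_ids, n_top)
        expected = sum(
            min(n_top, int(cm.tau.loc[l].notna().sum())) for l in cm.lipid_ids
        )
        assert out["frequency"].sum() == expected


class TestOutlierAnalysis:
    def test_single_extreme_genotype_flagged(self):
        diff = _diff({"F1": [-0.2, -0.1, 0.0, 0.1, 0.2, 3.0]})
        rep = cx.outlier_analysis(diff, z_cutoff=2.5, min_genotypes=5)
        flagged = rep[rep["flagged"]]
        assert list(flagged["genotype"]) == ["KO06"]
        # median 0.05, MAD 0.15 -> z = 2.95 / (1.4826 * 0.15) ~ 13.27
        assert flagged["robust_z"].iloc[0] == pytest.approx(2.95 / (1.4826 * 0.15), rel=1e-3)

    def test_degenerate_all_equal_no_flags(self):
        diff = _diff({"F1": [1.0] * 6})
        rep = cx.outlier_analysis(diff, z_cutoff=2.5, min_genotypes=5)
        assert not rep["flagged"].any()

    def test_sign_symmetry(self):
        # an exactly symmetric +/-v pair flags both genotypes or neither
        diff = _diff({"F1": [0.0, 0.05, -0.05, 0.1, -0.1, 4.0, -4.0]})
        rep = cx.outlier_analysis(diff, z_cutoff=2.5, min_genotypes=5)
        flagged = set(rep[rep["flagged"]]["genotype"])
        assert flagged == {"KO06", "KO07"}
        zs = rep.set_index("genotype")["robust_z"]
        assert zs["KO06"] == pytest.approx(-zs["KO07"], abs=1e-9)

    def test_location_invariance(self):
        vals = [-0.2, -0.1, 0.0, 0.1, 0.2, 3.0]
        a = cx.outlier_analysis(_diff({"F1": vals}), z_cutoff=2.5, min_genotypes=5)
        b = cx.outlier_analysis(
            _diff({"F1": [v + 17.0 for v in vals]}), z_cutoff=2.5, min_genotypes=5
        )
        pd.testing.assert_series_equal(a["flagged"], b["flagged"])
        np.testing.assert_allclose(a["robust_z"], b["robust_z"], atol=1e-9)

    def test_sparse_feature_skipped_with_warning(self):
        diff = _diff({"F1": [0.1, np.nan, np.nan, np.nan, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="skipped"):
            rep = cx.outlier_analysis(diff, min_genotypes=5)
        assert len(rep) == 0

    def test_similarity_ranking_excludes_query(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        vals = {}
        for i, f in enumerate([f"F{j}" for j in range(20)]):
            vals[f] = [base[i], base[i] + 0.01, rng.normal(), 0.0, 0.0, 0.0]
        # make F0 an outlier in genotype 6 by a large shift
        vals["F0"] = [0.0, 0.01, 0.02, -0.01, 0.03, 5.0]
        diff = _diff(vals)
        rep = cx.outlier_analysis(diff, z_cutoff=2.5, min_genotypes=5)
        flagged = rep[rep["flagged"]]
        assert len(flagged) >= 1
        assert (flagged["most_similar"] != flagged["genotype"]).all()
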