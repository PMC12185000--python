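"""Phenotype statistics: heritability, sensitivity, contrasts, growth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from f2map.pheno import (
    broad_sense_heritability,
    classify_ko_kd,
    delta_delta_ct,
    growth_analysis,
    pairwise_contrasts,
    trait_correlations,
    vernalization_sensitivity,
)
from f2map.simulate import simulate_replicated_lines


def lines_table(means, reps, noise_sd, seed=0, treatment="none"):
    rng = np.random.default_rng(seed)
    rows = []
    for i, m in enumerate(means):
        for r in range(reps):
            rows.append({"line": f"l{i}", "replicate": r, "treatment": treatment,
                         "DTF": m + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestHeritability:
    def test_no_within_variance_gives_one(self):
        t = lines_table([10, 20, 30], reps=3, noise_sd=0.0)
        assert broad_sense_heritability(t, "DTF") == 1.0

    def test_identical_line_means_gives_zero(self):
        t = lines_table([20, 20, 20, 20], reps=5, noise_sd=1.0, seed=1)
        assert broad_sense_heritability(t, "DTF") < 0.25

    def test_variance_component_recovery(self):
        rl = simulate_replicated_lines(60, 12, line_sd=3.0, residual_sd=1.0, seed=2)
        unv = rl.pheno[rl.pheno["treatment"] == "none"]
        h2 = broad_sense_heritability(unv, "DTF")
        assert abs(h2 - 0.9) < 0.03

    def test_single_line_rejected(self):
        t = lines_table([10], reps=4, noise_sd=1.0)
        with pytest.raises(ValueError):
            broad_sense_heritability(t, "DTF")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        t = lines_table([10, 14, 18, 25], reps=4, noise_sd=2.0, seed=3)
        h2 = broad_sense_heritability(t, "DTF")
        t2 = t.assign(DTF=t["DTF"] * scale + shift)
        assert broad_sense_heritability(t2, "DTF") == pytest.approx(h2, abs=1e-9)

    def test_unbalanced_design_handled(self):
        t = lines_table([10, 20, 30, 40], reps=6, noise_sd=1.0, seed=4)
        t = t.drop(t[(t["line"] == "l0") & (t["replicate"] > 2)].index)
        assert 0.0 <= broad_sense_heritability(t, "DTF") <= 1.0


class TestVernalizationSensitivity:
    def _table(self, unv, vern):
        a = lines_table(unv, reps=3, noise_sd=0.0, treatment="none")
        b = lines_table(vern, reps=3, noise_sd=0.0, treatment="vernalized")
        return pd.concat([a, b], ignore_index=True)

    def test_ratio_arithmetic(self):
        sens = vernalization_sensitivity(self._table([40.0], [10.0]), "DTF")
        assert sens["l0"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        sens = vernalization_sensitivity(self._table([25.0], [25.0]), "DTF")
        assert sens["l0"] == pytest.approx(0.0)

    def test_swapped_arms_negate(self):
        t = self._table([40.0, 33.0], [17.0, 21.0])
        sens = vernalization_sensitivity(t, "DTF")
        swapped = t.assign(treatment=t["treatment"].map({"none": "vernalized", "vernalized": "none"}))
        assert np.allclose(vernalization_sensitivity(swapped, "DTF"), -sens)

    def test_missing_arm_skipped(self):
        t = lines_table([40.0], reps=3, noise_sd=0.0, treatment="none")
        assert len(vernalization_sensitivity(t, "DTF")) == 0


class TestKoKdClassification:
    @pytest.mark.parametrize(
        "expr,label", [(4.9, "KO"), (5.0, "KD"), (0.0, "KO"), (11.7, "KD")]
    )
    def test_cutoff_rule(self, expr, label):
        t = pd.DataFrame({"line": ["m1"] * 3, "genotype_class": "mutant",
                          "flc_expression": [expr] * 3})
        assert classify_ko_kd(t)["m1"] == label

    def test_wildtype_rows_rejected(self):
        t = pd.DataFrame({"line": ["w"], "genotype_class": ["wildtype"], "flc_expression": [9.0]})
        with pytest.raises(ValueError):
            classify_ko_kd(t)


class TestTraitCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"line": [f"l{i}" for i in range(20)],
                          "DTF": rng.normal(30, 3, 20), "RLN": rng.normal(12, 2, 20)})
        res = trait_correlations(t, ["DTF", "RLN"])
        self_row = res[(res["trait1"] == "DTF") & (res["trait2"] == "DTF")]
        assert self_row["r"].iloc[0] == 1.0

    def test_perfect_inverse(self):
        t = pd.DataFrame({"line": [f"l{i}" for i in range(10)],
                          "DTF": np.arange(10.0), "RLN": -np.arange(10.0)})
        res = trait_correlations(t, ["DTF", "RLN"])
        pair = res[(res["trait1"] == "DTF") & (res["trait2"] == "RLN")]
        assert pair["r"].iloc[0] == pytest.approx(-1.0)
        assert pair["df"].iloc[0] == 8

    def test_bivariate_normal_within_fisher_band(self):
        rho, n = 0.8, 60
        inside = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            t = pd.DataFrame({"line": [f"l{i}" for i in range(n)], "a": x, "b": y})
            r = trait_correlations(t, ["a", "b"]).query("trait1=='a' and trait2=='b'")["r"].iloc[0]
            z, z0 = np.arctanh(r), np.arctanh(rho)
            inside += abs(z - z0) <= 1.96 / np.sqrt(n - 3)
        assert inside >= 9


class TestPairwiseContrasts:
    def _data(self, groups):
        rows = [{"line": g, "v": v} for g, vals in groups.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_rank_p_one(self):
        d = self._data({"m": [1, 2, 3], "w": [1, 2, 3]})
        res = pairwise_contrasts(d, [("m", "w")], "v", test="mann_whitney", correction="none")
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(6)
        groups = {}
        for i in range(4):
            groups[f"m{i}"] = rng.normal(0, 1, 5)
            groups[f"w{i}"] = rng.normal(0, 1, 5)
        d = self._data(groups)
        pairs = [(f"m{i}", f"w{i}") for i in range(4)]
        res = pairwise_contrasts(d, pairs, "v", correction="bonferroni")
        assert np.allclose(res["p_adj"], np.minimum(res["p_raw"] * 4, 1.0))

    def test_bh_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_zero_variance_degenerate_rules(self):
        equal = self._data({"m": [2.0, 2.0], "w": [2.0, 2.0]})
        res = pairwise_contrasts(equal, [("m", "w")], "v", correction="none")
        assert res["p_raw"].iloc[0] == 1.0
        diff = self._data({"m": [2.0, 2.0], "w": [3.0, 3.0]})
        with pytest.warns(UserWarning):
            res = pairwise_contrasts(diff, [("m", "w")], "v", correction="none")
        assert res["p_raw"].iloc[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_bh_monotone_and_above_raw(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()


class TestDeltaDeltaCt:
    def test_formula(self):
        ct = pd.DataFrame({"sample": ["cal", "s"], "ct_target": [24.0, 22.0],
                           "ct_reference": [20.0, 20.0]})
        out = delta_delta_ct(ct, calibrator="cal")
        assert out["cal"] == pytest.approx(1.0)
        assert out["s"] == pytest.approx(4.0)

    def test_batch_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        n = 10
        ct = pd.DataFrame({"sample": [f"s{i}" for i in range(n)],
                           "ct_target": rng.uniform(18, 30, n),
                           "ct_reference": rng.uniform(15, 22, n)})
        out = delta_delta_ct(ct, calibrator="s0")
        dct = ct["ct_target"] - ct["ct_reference"]
        oracle = 2.0 ** (-(dct - dct.iloc[0]))
        assert np.allclose(out.to_numpy(), oracle.to_numpy(), atol=1e-12)

    def test_missing_reference_skipped(self):
        ct = pd.DataFrame({"sample": ["cal", "s"], "ct_target": [24.0, 22.0],
                           "ct_reference": [20.0, np.nan]})
        out = delta_delta_ct(ct, calibrator="cal")
        assert "s" not in out.index


class TestGrowthAnalysis:
    def _exp_growth(self, line, rate, a0=6000.0, days=range(8, 21), reps=2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for rep in range(reps):
            for d in days:
                rows.append({"line": line, "replicate": rep, "day": d,
                             "area_px": a0 * np.exp(rate * d) * np.exp(rng.normal(0, noise))})
        return pd.DataFrame(rows)

    def test_exponential_growth_exact_rgr(self):
        t = pd.concat([self._exp_growth("m", 0.2), self._exp_growth("w", 0.2)])
        res = growth_analysis(t, [("m", "w")], n_clusters=1, min_late_px=0, min_any_px=0)
        assert np.allclose(res.rgr["rgr"], 0.2, atol=1e-12)

    def test_identical_mutant_no_signal(self):
        t = pd.concat([self._exp_growth("m", 0.2), self._exp_growth("w", 0.2)])
        res = growth_analysis(t, [("m", "w")], n_clusters=1, min_late_px=0, min_any_px=0)
        assert np.allclose(res.trajectories.loc["m"], 0.0, atol=1e-12)
        assert not res.daily_contrasts["significant"].any()

    def test_small_plants_excluded(self):
        ok = self._exp_growth("m", 0.2)
        tiny = self._exp_growth("tiny", 0.2, a0=100.0)
        t = pd.concat([ok, tiny, self._exp_growth("w", 0.2)])
        res = growth_analysis(t, [("m", "w")], min_any_px=500.0)
        assert (res.excluded["line"] == "tiny").all()
        assert len(res.excluded) == 2

    def test_three_archetypes_recovered(self):
        # always-larger / crossing / always-smaller trajectory shapes
        rng = np.random.default_rng(8)
        frames = [self._exp_growth("w", 0.2, reps=3)]
        pairs = []
        truth = {}
        days = np.arange(8, 21)
        for k, offset in enumerate([0.4, None, -0.4]):
            for i in range(10):
                line = f"m{k}_{i}"
                if offset is None:  # crossing: below early, above late
                    shift = 0.05 * (days - days.mean())
                else:
                    shift = np.full(len(days), offset)
                rows = []
                for rep in range(3):
                    for d, s in zip(days, shift):
                        area = 6000 * np.exp(0.2 * d) * 2**s * np.exp(rng.normal(0, 0.05))
                        rows.append({"line": line, "replicate": rep, "day": d, "area_px": area})
                frames.append(pd.DataFrame(rows))
                pairs.append((line, "w"))
                truth[line] = k
        t = pd.concat(frames, ignore_index=True)
        res = growth_analysis(t, pairs, n_clusters=3, min_late_px=0, min_any_px=0)
        from sklearn.metrics import adjusted_rand_score

        labels_true = [truth[m] for m in res.clusters.index]
        assert adjusted_rand_score(labels_true, res.clusters.to_numpy()) >= 0.9
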