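"""QTL scans: regression oracle, permutations, model selection, intervals."""

import numpy as np
import pandas as pd
import pytest

from f2map.cross import CrossObject, cross_from_truth
from f2map.scan import (
    HKScan,
    bayes_interval,
    hk_scan,
    qtl_effects,
    scan_two,
    stepwise_additive,
    window_lod_summary,
)
from f2map.simulate import QTL, QTLSpec, simulate_f2, simulate_phenotypes


def single_marker_cross(codes, y, trait="DTF"):
    ids = [f"i{k}" for k in range(len(codes))]
    geno = pd.DataFrame({"Chr1_500": codes}, index=ids)
    markers = pd.DataFrame({"chrom": ["Chr1"], "pos_bp": [500], "pos_cm": [0.002]},
                           index=["Chr1_500"])
    pheno = pd.DataFrame({trait: y}, index=ids)
    return CrossObject(geno, markers, pheno)


class TestHKScan:
    def test_constant_phenotype_gives_zero_lod(self, qtl_cross):
        cross = qtl_cross
        cross2 = CrossObject(
            cross.genotypes, cross.markers,
            pd.DataFrame({"flat": np.ones(cross.n_individuals)}, index=cross.genotypes.index),
            n_crossovers=cross.n_crossovers,
        )
        with pytest.warns(UserWarning):
            res = hk_scan(cross2, "flat")
        assert (res.lod == 0).all()

    def test_fully_informative_marker_matches_regression_oracle(self):
        codes = ["A", "A", "H", "H", "B", "B"]
        y = np.array([10.0, 10, 12, 12, 14, 14])
        cross = single_marker_cross(codes, y)
        res = HKScan(cross, "DTF", error_prob=0.0, min_individuals=2).fit()

        X = np.column_stack([np.ones(6), [-1, -1, 0, 0, 1, 1], [0, 0, 1, 1, 0, 0]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        tss = ((y - y.mean()) ** 2).sum()
        rss1 = max(((y - X @ beta) ** 2).sum(), 1e-12 * tss)
        oracle = (6 / 2) * np.log10(tss / rss1)
        assert res.lod[0] == pytest.approx(oracle, abs=1e-8)

    def test_noisy_marker_matches_regression_oracle(self):
        rng = np.random.default_rng(50)
        codes = list(rng.choice(["A", "H", "B"], 60, p=[0.25, 0.5, 0.25]))
        y = rng.normal(0, 1, 60) + 0.8 * np.array([{"A": -1, "H": 0, "B": 1}[c] for c in codes])
        cross = single_marker_cross(codes, y)
        res = HKScan(cross, "DTF", error_prob=0.0).fit()
        X = np.column_stack(
            [np.ones(60), [{"A": -1, "H": 0, "B": 1}[c] for c in codes],
             [1.0 if c == "H" else 0.0 for c in codes]]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        tss = ((y - y.mean()) ** 2).sum()
        oracle = 30 * np.log10(tss / ((y - X @ beta) ** 2).sum())
        assert res.lod[0] == pytest.approx(oracle, abs=1e-8)

    def test_planted_qtl_recovered_near_truth(self, genome):
        hits = 0
        for rep in range(5):
            truth = simulate_f2(genome, 200, seed=200 + rep)
            spec = QTLSpec(qtl=(QTL("Chr2", 8_000_000, float(np.sqrt(2)), 0.0),), residual_sd=1.0)
            pheno = simulate_phenotypes(truth, spec, seed=300 + rep).set_index("individual")
            cross = cross_from_truth(truth, genome, phenotypes=pheno)
            res = hk_scan(cross, "DTF")
            peak = res.peak()
            if peak["chrom"] == "Chr2" and abs(peak["pos_cm"] - genome.bp_to_cm(8_000_000)) <= 5:
                hits += 1
        assert hits >= 4

    def test_lod_nonnegative_everywhere(self, qtl_cross):
        res = hk_scan(qtl_cross, "DTF")
        assert (res.lod >= 0).all()


class TestPermutationThreshold:
    def test_alpha_one_is_minimum_of_null_distribution(self, qtl_cross):
        model = HKScan(qtl_cross, "DTF")
        thr, max_lods = model.permutation_threshold(20, alpha=1.0, seed=1)
        assert thr == pytest.approx(max_lods.min())

    def test_fixed_seed_is_deterministic(self, qtl_cross):
        model = HKScan(qtl_cross, "DTF")
        t1, _ = model.permutation_threshold(25, seed=7)
        t2, _ = model.permutation_threshold(25, seed=7)
        assert t1 == t2


class TestScanTwo:
    def test_additive_two_qtl_trait_no_interaction_and_no_diagonal(self, genome):
        truth = simulate_f2(genome, 200, seed=55)
        spec = QTLSpec(
            qtl=(QTL("Chr1", 10_000_000, 1.0, 0.0), QTL("Chr3", 12_000_000, 1.0, 0.0)),
            residual_sd=1.0,
        )
        pheno = simulate_phenotypes(truth, spec, seed=56).set_index("individual")
        cross = cross_from_truth(truth, genome, phenotypes=pheno)
        res = scan_two(cross, "DTF", step_cm=10.0, n_perm=25, seed=2)
        assert len(res.interactions) == 0
        assert (np.diag(res.lod_int) == 0).all()
        assert (np.diag(res.lod_full) == 0).all()

    def test_planted_epistasis_detected(self, genome):
        rng = np.random.default_rng(60)
        truth = simulate_f2(genome, 300, seed=61)
        s1 = np.array([t.state_at("Chr1", 10_000_000) for t in truth]) - 1
        s2 = np.array([t.state_at("Chr3", 12_000_000) for t in truth]) - 1
        y = 1.0 * s1 + 1.0 * s2 + 2.0 * (s1 * s2) + rng.normal(0, 1, 300)
        pheno = pd.DataFrame({"DTF": y}, index=[t.individual_id for t in truth])
        cross = cross_from_truth(truth, genome, phenotypes=pheno)
        res = scan_two(cross, "DTF", step_cm=10.0, n_perm=30, seed=62)
        assert len(res.interactions) >= 1
        top = res.interactions.sort_values("lod_int").iloc[-1]
        assert {top["chrom1"], top["chrom2"]} == {"Chr1", "Chr3"}


class TestStepwise:
    def test_null_trait_gives_empty_model(self, genome):
        truth = simulate_f2(genome, 150, seed=70)
        pheno = pd.DataFrame(
            {"DTF": np.random.default_rng(71).normal(30, 1, 150)},
            index=[t.individual_id for t in truth],
        )
        cross = cross_from_truth(truth, genome, phenotypes=pheno)
        res = stepwise_additive(cross, "DTF", penalty=4.0, max_qtl=4)
        assert res.n_qtl == 0 and res.plod == 0.0
        res = qtl_effects(cross, res)
        assert res.model_pev == 0.0

    def test_two_planted_qtl_recovered(self, genome):
        truth = simulate_f2(genome, 250, seed=72)
        spec = QTLSpec(
            qtl=(QTL("Chr1", 10_000_000, 1.2, 0.0), QTL("Chr4", 9_000_000, 1.2, 0.0)),
            residual_sd=1.0,
        )
        pheno = simulate_phenotypes(truth, spec, seed=73).set_index("individual")
        cross = cross_from_truth(truth, genome, phenotypes=pheno)
        res = stepwise_additive(cross, "DTF", penalty=3.5, max_qtl=5)
        assert res.n_qtl == 2
        assert set(res.qtl["chrom"]) == {"Chr1", "Chr4"}

    def test_collinear_duplicate_reduced_to_one(self, qtl_cross):
        # single planted QTL: greedy forward may try nearby positions, the
        # penalized backward pass must keep exactly one
        res = stepwise_additive(qtl_cross, "DTF", penalty=3.0, max_qtl=4)
        assert res.n_qtl == 1
        assert res.qtl["chrom"].iloc[0] == "Chr1"


class TestEffects:
    def test_noiseless_effect_sign_and_magnitude(self):
        codes = (["A"] * 10 + ["H"] * 20 + ["B"] * 10) * 1
        y = np.array([10.0] * 10 + [12.0] * 20 + [14.0] * 10)
        cross = single_marker_cross(codes, y)
        res = stepwise_additive(cross, "DTF", penalty=1.0, max_qtl=1, error_prob=0.0)
        res = qtl_effects(cross, res, early_parent="A")
        assert res.effects["effect_add"].iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert res.effects["effect_dom"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        res_b = stepwise_additive(cross, "DTF", penalty=1.0, max_qtl=1, error_prob=0.0)
        res_b = qtl_effects(cross, res_b, early_parent="B")
        assert res_b.effects["effect_add"].iloc[0] == pytest.approx(-2.0, abs=1e-6)

    def test_pev_recovery(self, qtl_cross):
        res = stepwise_additive(qtl_cross, "DTF", penalty=3.0)
        res = qtl_effects(qtl_cross, res, early_parent="A")
        assert abs(res.effects["pev"].iloc[0] - 50.0) < 6.0
        assert abs(res.effects["effect_add"].iloc[0] - np.sqrt(2)) < 0.2
        assert 0 <= res.model_pev <= 100


class TestBayesInterval:
    def _scan(self, lods, n_pos=50):
        positions = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos_cm": np.linspace(0, 100, n_pos),
                "pos_bp": np.linspace(0, 25e6, n_pos),
                "is_marker": True,
            }
        )
        from f2map.scan import ScanResult

        return ScanResult("DTF", positions, np.asarray(lods, dtype=float), 100)

    def test_single_spike_collapses(self):
        lods = np.zeros(50)
        lods[20] = 10.0
        scan = self._scan(lods)
        lo, hi = bayes_interval(scan, "Chr1")
        bp = np.linspace(0, 25e6, 50)
        assert lo >= bp[19] and hi <= bp[21]

    def test_flat_profile_spans_chromosome(self):
        scan = self._scan(np.ones(50) * 2.0)
        with pytest.warns(UserWarning):
            lo, hi = bayes_interval(scan, "Chr1")
        assert lo == 0.0 and hi == 25e6

    def test_simulated_interval_covers_truth(self, qtl_cross):
        res = hk_scan(qtl_cross, "DTF")
        lo, hi = bayes_interval(res, "Chr1")
        assert lo <= 24_675_000 <= hi


class TestWindowSummary:
    def test_zero_scan_sums_to_zero(self, qtl_cross):
        res = hk_scan(qtl_cross, "DTF")
        res.lod = np.zeros_like(res.lod)
        win = window_lod_summary([res])
        assert (win["summed_lod"] == 0).all()

    def test_sum_and_center_arithmetic(self):
        positions = pd.DataFrame(
            {"chrom": "Chr1", "pos_cm": [98.6], "pos_bp": [24_650_000.0], "is_marker": True}
        )
        from f2map.scan import ScanResult

        scans = [ScanResult("DTF", positions, np.array([3.0]), 100) for _ in range(2)]
        win = window_lod_summary(scans, window_bp=100_000)
        hit = win[win["summed_lod"] > 0]
        assert len(hit) == 1
        assert hit["window_start"].iloc[0] == 24_600_000
        assert hit["center_bp"].iloc[0] == 24_650_000
        assert hit["summed_lod"].iloc[0] == 6.0

    def test_total_lod_conserved(self, qtl_cross):
        res = hk_scan(qtl_cross, "DTF")
        win = window_lod_summary([res])
        assert win["summed_lod"].sum() == pytest.approx(res.lod.sum(), rel=1e-12)
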