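"""Stepwise cofactor selection, flanking probabilities, EM scan, QTL calls."""

import numpy as np
import pandas as pd
import pytest

import grainqtl as gq
from grainqtl.containers import GeneticMap, GenotypeMatrix, line_means
from grainqtl.icim import CofactorModel, adjust_phenotype, stepwise_select
from grainqtl.simulate import PlantedQTL, SimConfig, TraitModel


def matrix_from_codes(codes: np.ndarray) -> GenotypeMatrix:
    n, p = codes.shape
    return GenotypeMatrix([f"L{i}" for i in range(n)],
                          [f"M{j}" for j in range(p)], codes.astype(np.int8))


def test_encode_genotypes():
    codes = np.array([[1, -1, 0], [1, 1, -1]])
    X = gq.encode_genotypes(matrix_from_codes(codes))
    assert X.dtype == float
    assert (X == codes).all()


class TestStepwiseSelect:
    def test_exact_signal_recovered(self, rng):
        X = rng.choice([1.0, -1.0], size=(60, 10))
        y = 2.0 * X[:, 4]
        model = stepwise_select(y, X, [f"M{j}" for j in range(10)])
        assert model.markers == ["M4"]
        assert model.coefficients["M4"] == pytest.approx(2.0, abs=1e-9)

    def test_duplicate_column_selected_once(self, rng):
        X = rng.choice([1.0, -1.0], size=(80, 6))
        X[:, 3] = X[:, 1]
        y = 1.5 * X[:, 1] + rng.normal(0, 0.1, 80)
        model = stepwise_select(y, X, [f"M{j}" for j in range(6)])
        assert ("M1" in model.markers) != ("M3" in model.markers)

    def test_null_selects_almost_nothing(self, rng):
        hits = 0
        for _ in range(20):
            X = rng.choice([1.0, -1.0], size=(100, 30))
            y = rng.normal(size=100)
            hits += len(stepwise_select(y, X, [f"M{j}" for j in range(30)]).markers)
        # expected entries ~ 0.001 * 30 per replicate
        assert hits <= 3

    def test_entry_exceeding_removal_rejected(self, rng):
        X = rng.choice([1.0, -1.0], size=(30, 3))
        with pytest.raises(ValueError):
            stepwise_select(rng.normal(size=30), X, ["a", "b", "c"],
                            p_entry=0.01, p_removal=0.001)


class TestAdjustPhenotype:
    def test_empty_model_identity(self, rng):
        y = rng.normal(size=20)
        X = rng.choice([1.0, -1.0], size=(20, 4))
        model = CofactorModel([], {}, 0.0, 0.001, 0.002)
        assert np.allclose(adjust_phenotype(y, model, X, list("abcd")), y)

    def test_flank_cofactors_excluded(self, rng):
        y = rng.normal(size=20)
        X = rng.choice([1.0, -1.0], size=(20, 4))
        model = CofactorModel(["a", "c"], {"a": 0.5, "c": -0.3}, 0.0, 0.001, 0.002)
        dy = adjust_phenotype(y, model, X, list("abcd"), exclude=("a", "c"))
        assert np.allclose(dy, y)
        dy2 = adjust_phenotype(y, model, X, list("abcd"), exclude=("a",))
        assert np.allclose(dy2, y + 0.3 * X[:, 2])


class TestQtlGenotypeProbs:
    def test_at_marker_position(self):
        pa, pb = gq.qtl_genotype_probs(1, -1, 0.0, 0.2, 0.2)
        assert pa == 1.0 and pb == 0.0

    def test_midpoint_symmetry(self):
        pa, pb = gq.qtl_genotype_probs(1, -1, 0.1, 0.1, 0.18)
        assert pa == pytest.approx(0.5, abs=1e-12)

    def test_both_missing_uninformative(self):
        pa, pb = gq.qtl_genotype_probs(0, 0, 0.1, 0.1, 0.18)
        assert pa == pb == 0.5

    def test_single_flank_conditioning(self):
        pa, _ = gq.qtl_genotype_probs(1, 0, 0.1, 0.1, 0.18)
        assert pa == pytest.approx(0.9, abs=1e-12)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            gq.qtl_genotype_probs(1, -1, 0.1, 0.1, 0.45)

    def test_forward_simulation_frequencies(self):
        """Empirical QTL-class frequencies given flank classes match the
        Markov conditioning within Monte-Carlo error (10 cM interval,
        locus at midpoint)."""
        gmap = GeneticMap(pd.DataFrame(
            [("L", "1", 0.0), ("R", "1", 10.0)],
            columns=["marker", "chromosome", "cm"]))
        g = gq.simulate_ril_genotypes(
            gmap, 40_000, seed=13, extra_loci=[("1", 5.0, "Q")]
        )
        lcol, qcol, rcol = g.column("L"), g.column("Q"), g.column("R")
        r5 = gq.inverse_map_distance(5.0, "haldane")
        R5 = 2 * r5 / (1 + 2 * r5)
        for lcall, rcall in [(1, 1), (1, -1), (-1, 1)]:
            mask = (lcol == lcall) & (rcol == rcall) & (qcol != 0)
            expected_pa, _ = gq.qtl_genotype_probs(lcall, rcall, R5, R5,
                                                   2 * R5 * (1 - R5) + 0.0)
            observed = (qcol[mask] == 1).mean()
            assert observed == pytest.approx(expected_pa, abs=0.02)


class TestEmScan:
    def test_constant_phenotype_zero_lod(self, rng):
        dy = np.full((3, 50), 1.7)
        pa = rng.uniform(0.2, 0.8, size=(3, 50))
        out = gq.em_scan(dy, pa, 1 - pa, s2y=1.0)
        assert (out["lod"] == 0).all()

    def test_complete_separation_recovers_class_means(self, rng):
        y = np.concatenate([rng.normal(2.0, 0.3, 40), rng.normal(-1.0, 0.3, 40)])
        pa = np.concatenate([np.ones(40), np.zeros(40)])[None, :]
        out = gq.em_scan(y[None, :], pa, 1 - pa, s2y=float(np.var(y, ddof=1)))
        mu_a, mu_b = y[:40].mean(), y[40:].mean()
        assert out.loc[0, "add"] == pytest.approx((mu_b - mu_a) / 2, abs=1e-6)
        assert out.loc[0, "lod"] > 10

    def test_minimum_lines_enforced(self):
        with pytest.raises(ValueError):
            gq.em_scan(np.zeros((1, 5)), np.full((1, 5), 0.5),
                       np.full((1, 5), 0.5), 1.0)


@pytest.fixture(scope="module")
def single_qtl_sim():
    """One 0.4-effect QTL on a 2-chromosome genome; line means, one env."""
    rows = [(f"C{c}M{j:02d}", str(c), float(j * 10)) for c in (1, 2)
            for j in range(8)]
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]))
    cfg = SimConfig(
        gmap=gmap, n_lines=200, n_envs=1, n_reps=2,
        traits={"T": TraitModel(mean=0.0, env_effects=(0.0,), var_ge=0.0,
                                var_rep=0.0, var_resid=0.16,
                                qtl=(PlantedQTL("1", 35.0, 0.4),))},
        derive_shape_traits=False,
    )
    sim = gq.simulate_study(cfg, seed=17)
    y = line_means(sim.phenotypes, "T").loc[sim.genotypes.lines].to_numpy()
    return sim, y


class TestIcimScan:
    def test_peak_at_planted_qtl_with_correct_sign(self, single_qtl_sim):
        sim, y = single_qtl_sim
        prof = gq.icim_scan(y, sim.genotypes, sim.gmap)
        peak = prof.loc[prof["lod"].idxmax()]
        assert peak["chromosome"] == "1"
        assert abs(peak["cm"] - 35.0) <= 5.0
        assert peak["add"] > 0  # B allele planted to increase the trait
        assert peak["pve"] == pytest.approx(
            100 * 0.16 / np.var(y, ddof=1), rel=0.35
        )

    def test_lod_scale_and_shift_invariance(self, single_qtl_sim):
        sim, y = single_qtl_sim
        a = gq.icim_scan(y, sim.genotypes, sim.gmap)
        b = gq.icim_scan(3.0 * y + 2.0, sim.genotypes, sim.gmap)
        assert np.allclose(a["lod"], b["lod"], atol=0.05)
        assert np.allclose(3.0 * a["add"], b["add"], atol=1e-3)
        assert np.allclose(a["pve"], b["pve"], atol=0.2)

    def test_reduces_to_simple_interval_mapping_without_cofactors(
        self, single_qtl_sim
    ):
        """With no cofactors selected, the profile at the QTL interval agrees
        with plain interval mapping (no background adjustment) within LOD 0.2."""
        sim, y = single_qtl_sim
        empty = CofactorModel([], {}, 0.0, 0.001, 0.002)
        icim = gq.icim_scan(y, sim.genotypes, sim.gmap)
        simple = gq.icim_scan(y, sim.genotypes, sim.gmap, model=empty)
        at_qtl = (icim["chromosome"] == "1") & (icim["left_marker"] == "C1M03")
        assert np.allclose(icim.loc[at_qtl, "lod"],
                           simple.loc[at_qtl, "lod"], atol=0.2)

    def test_background_adjustment_removes_distal_signal(self, small_map, rng):
        """Adjusting for a selected distal-QTL cofactor strips its LOD signal
        from the rest of the genome."""
        cfg = SimConfig(
            gmap=small_map, n_lines=250, n_envs=1, n_reps=1,
            traits={"T": TraitModel(mean=0.0, env_effects=(0.0,),
                                    var_resid=0.04,
                                    qtl=(PlantedQTL("1", 45.0, 0.5),))},
            derive_shape_traits=False,
        )
        sim = gq.simulate_study(cfg, seed=23)
        y = line_means(sim.phenotypes, "T").loc[sim.genotypes.lines].to_numpy()
        empty = CofactorModel([], {}, 0.0, 0.001, 0.002)
        icim = gq.icim_scan(y, sim.genotypes, sim.gmap)
        simple = gq.icim_scan(y, sim.genotypes, sim.gmap, model=empty)
        off = icim["chromosome"] != "1"
        # ghost signal on other chromosomes is purged by the cofactors
        assert icim.loc[off, "lod"].max() < simple.loc[off, "lod"].max() + 0.5
        assert icim.loc[off, "lod"].max() < 2.0


class TestPermutationThreshold:
    def test_quantile_monotone_and_reproducible(self, single_qtl_sim):
        sim, y = single_qtl_sim
        thr, maxima = gq.permutation_threshold(
            y, sim.genotypes, sim.gmap, n_perm=100, seed=5, return_maxima=True
        )
        q10 = np.quantile(maxima, 0.90, method="higher")
        assert q10 <= thr
        thr2 = gq.permutation_threshold(y, sim.genotypes, sim.gmap,
                                        n_perm=100, seed=5)
        assert thr == thr2
        assert 1.0 < thr < 5.0

    def test_minimum_permutations_enforced(self, single_qtl_sim):
        sim, y = single_qtl_sim
        with pytest.raises(ValueError):
            gq.permutation_threshold(y, sim.genotypes, sim.gmap, n_perm=10)


def synthetic_profile(chrom, cms, lods, left, right):
    return pd.DataFrame({
        "chromosome": chrom, "cm": cms, "interval": 0,
        "left_marker": left, "right_marker": right,
        "lod": lods, "add": 0.1, "pve": 5.0,
    })


class TestCallQtl:
    def test_no_peaks_above_threshold(self):
        prof = synthetic_profile("1", [0, 1, 2], [0.5, 1.0, 0.4], "A", "B")
        out = gq.call_qtl({"E1": prof}, threshold=2.65, trait="GL")
        assert len(out) == 0

    def test_one_significant_env_carries_all_envs(self):
        """A peak over threshold in one environment declares the QTL; the
        record keeps every environment's own peak, sub-threshold included."""
        lods = {"E1": 2.78, "E2": 6.31, "E3": 5.20, "E4": 2.40}
        profiles = {
            env: synthetic_profile("2", [85, 87, 89], [1.0, peak, 1.2], "RM29",
                                   "RM262")
            for env, peak in lods.items()
        }
        out = gq.call_qtl(profiles, threshold=2.65, trait="GL")
        assert out["qtl"].unique().tolist() == ["qGL2"]
        assert len(out) == 4
        sig = out.set_index("env")["significant"]
        assert sig["E1"] and sig["E2"] and sig["E3"] and not sig["E4"]

    def test_two_qtl_get_ordinal_suffixes(self):
        """Two deep-valley-separated peaks on one chromosome yield -1/-2
        names ordered by position."""
        prof = pd.DataFrame({
            "chromosome": "2",
            "cm": [10, 20, 30, 40, 50, 60, 70],
            "interval": [0, 0, 1, 1, 2, 2, 3],
            "left_marker": ["A", "A", "B", "B", "C", "C", "D"],
            "right_marker": ["B", "B", "C", "C", "D", "D", "E"],
            "lod": [1.0, 5.0, 1.0, 0.2, 1.0, 8.0, 1.0],
            "add": 0.1, "pve": 5.0,
        })
        out = gq.call_qtl({"E1": prof}, threshold=2.65, trait="GL")
        assert sorted(out["qtl"].unique()) == ["qGL2-1", "qGL2-2"]
        pos = out.set_index("qtl")["pos_cm"]
        assert pos["qGL2-1"] == 20 and pos["qGL2-2"] == 60

    def test_shallow_valley_peaks_merge_to_one(self):
        """Twin peaks separated by a dip of < 1 LOD (a marker-straddling
        artifact) are reported as a single QTL at the higher peak."""
        prof = pd.DataFrame({
            "chromosome": "2",
            "cm": [10, 20, 30, 40, 50],
            "interval": [0, 0, 0, 1, 1],
            "left_marker": ["A", "A", "A", "B", "B"],
            "right_marker": ["B", "B", "B", "C", "C"],
            "lod": [1.0, 6.0, 5.5, 6.2, 1.0],
            "add": 0.1, "pve": 5.0,
        })
        out = gq.call_qtl({"E1": prof}, threshold=2.65, trait="GL")
        assert out["qtl"].unique().tolist() == ["qGL2"]
        assert out["pos_cm"].iloc[0] == 40


class TestConsolidate:
    def test_single_record_single_cluster(self):
        prof = synthetic_profile("1", [0, 1, 2], [1.0, 3.0, 1.0], "A", "B")
        rec = gq.call_qtl({"E1": prof}, 2.65, "GL")
        clusters = gq.consolidate_qtl(rec)
        assert len(clusters) == 1
        assert clusters.loc[0, "n_qtl"] == 1

    def test_shared_interval_merges_traits(self):
        prof_gl = synthetic_profile("3", [110, 112, 114], [2.0, 28.0, 3.0],
                                    "RM411", "RM7097")
        prof_gw = synthetic_profile("3", [110, 112, 114], [1.0, 4.1, 0.5],
                                    "RM411", "RM7097")
        rec = pd.concat([
            gq.call_qtl({"E1": prof_gl}, 2.65, "GL"),
            gq.call_qtl({"E1": prof_gw}, 2.65, "GW"),
        ], ignore_index=True)
        clusters = gq.consolidate_qtl(rec)
        assert len(clusters) == 1
        assert clusters.loc[0, "n_qtl"] == 2
        assert "qGL3" in clusters.loc[0, "E1"] and "qGW3" in clusters.loc[0, "E1"]

    def test_different_chromosomes_never_merge(self):
        rec = pd.concat([
            gq.call_qtl({"E1": synthetic_profile("1", [0, 1, 2], [1, 3, 1],
                                                 "A", "B")}, 2.65, "GL"),
            gq.call_qtl({"E1": synthetic_profile("2", [0, 1, 2], [1, 3, 1],
                                                 "A", "B")}, 2.65, "GW"),
        ], ignore_index=True)
        assert len(gq.consolidate_qtl(rec)) == 2

    def test_empty_records(self):
        assert len(gq.consolidate_qtl(pd.DataFrame(
            columns=["qtl", "trait", "chromosome", "left_marker", "right_marker",
                     "env", "pos_cm", "lod", "pve", "add", "significant"]
        ))) == 0
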