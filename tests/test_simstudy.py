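import numpy as np
import pandas as pd
import pytest

from megwas import (
    draw_frequencies,
    estimate_power,
    fit_logistic,
    make_scenario,
    run_replicates,
    simulate_background_genotypes,
    simulate_causal_replicate,
)
from megwas.geno_io import ValidationError
from megwas.simstudy import (
    ADMIXED,
    POPULATIONS,
    Background,
    case_genotype_probs,
    control_genotype_probs,
    scenario_from_dict,
)

SMALL = dict(pop_size=120, n_background_snps=150)


class TestDrawFrequencies:
    def test_zero_f_is_exact(self, rng):
        f = draw_frequencies(0.37, [0.0, 0.0, 0.0], rng)
        assert np.allclose(f, 0.37)

    def test_beta_moments(self, rng):
        # Balding-Nichols: mean p, variance F p (1-p)
        p, F, n = 0.3, 0.1, 10000
        draws = np.array([draw_frequencies(p, [F], rng)[0] for _ in range(n)])
        var = F * p * (1 - p)
        se_mean = np.sqrt(var / n)
        assert abs(draws.mean() - p) < 3 * se_mean
        # SE of a variance estimate ~ var * sqrt(2/n) for near-normal; allow 4x
        assert abs(draws.var() - var) < 4 * var * np.sqrt(2 / n)

    def test_clip_floor(self, rng):
        f = draw_frequencies(0.005, [0.0, 0.3], rng)
        assert (f >= 0.01).all()

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValidationError):
            draw_frequencies(0.0, [0.1], rng)
        with pytest.raises(ValidationError):
            draw_frequencies(0.5, [1.0], rng)


class TestScenario:
    def test_african_specific_has_four_nonzero(self):
        sc = make_scenario("african_specific", "none", 0.3)
        nonzero = [p for p, b in sc.log_ors.items() if b != 0]
        assert sorted(nonzero) == ["ASW", "LWK", "MKK", "YRI"]
        assert all(b == 0.3 for p, b in sc.log_ors.items() if p in nonzero)

    def test_extreme_structure_no_african_cases(self):
        sc = make_scenario("null", "extreme")
        for pop, anc in POPULATIONS:
            if anc == "African":
                assert sc.case_fractions[pop] == 0.0
            else:
                assert sc.case_fractions[pop] > 0.5

    def test_null_model_all_zero(self):
        for structure in ("none", "moderate", "extreme"):
            sc = make_scenario("null", structure)
            assert all(b == 0.0 for b in sc.log_ors.values())

    def test_opposing_blocks_equal_magnitude(self):
        sc = make_scenario("african_vs_others", "none", 0.25)
        for pop, anc in POPULATIONS:
            assert sc.log_ors[pop] == (0.25 if anc == "African" else -0.25)
        sc = make_scenario("eastasian_vs_others", "none", 0.25)
        for pop, anc in POPULATIONS:
            expected = {"EastAsian": 0.25, "African": 0.0}.get(anc, -0.25)
            assert sc.log_ors[pop] == expected

    def test_total_sample_and_case_count_fixed_across_structure(self):
        totals = set()
        cases = set()
        for structure in ("none", "moderate", "extreme"):
            sc = make_scenario("null", structure)
            totals.add(sc.n_total)
            cases.add(sum(sc.n_cases(p) for p in sc.pop_names))
        assert totals == {20000}
        assert max(cases) - min(cases) <= 2  # rounding of 5/6 fractions

    def test_phenotype_matches_case_counts(self):
        sc = make_scenario("null", "moderate", **SMALL)
        y = sc.phenotype()
        labels = sc.labels()
        for pop in sc.pop_names:
            assert y[labels == pop].sum() == sc.n_cases(pop)

    def test_from_dict_roundtrip(self):
        sc = scenario_from_dict(
            {"model": "homogeneous", "structure": "moderate",
             "effect_size": 0.2, "pop_size": 100, "n_replicates": 10}
        )
        assert sc.model == "homogeneous" and sc.pop_size == 100
        assert sc.log_ors["CEU"] == 0.2


class TestRetrospectiveSampling:
    def test_null_case_equals_control_distribution(self):
        np.testing.assert_allclose(
            case_genotype_probs(0.3, 0.0), control_genotype_probs(0.3, 0.0)
        )

    def test_or_two_at_half_frequency(self):
        # HWE (0.25, 0.5, 0.25) tilted by OR^g = (1,2,4): (1/9, 4/9, 4/9)
        np.testing.assert_allclose(
            case_genotype_probs(0.5, np.log(2.0)), [1 / 9, 4 / 9, 4 / 9]
        )

    def test_exact_prevalence_reduces_to_hwe_under_null(self):
        np.testing.assert_allclose(
            control_genotype_probs(0.3, 0.0, prevalence=0.1),
            [0.49, 0.42, 0.09],
        )

    def test_sampler_recovers_log_odds_ratio(self, rng):
        # one large population: retrospective draws analysed prospectively
        beta = 0.3
        f, n_case, n_ctl = 0.4, 50000, 50000
        pc = case_genotype_probs(f, beta)
        p0 = control_genotype_probs(f, beta)
        g = np.r_[
            rng.choice(3, n_case, p=pc), rng.choice(3, n_ctl, p=p0)
        ].astype(float)
        y = np.r_[np.ones(n_case), np.zeros(n_ctl)]
        fit = fit_logistic(y, np.column_stack([np.ones(len(y)), g]))
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.params[1] - beta) < 3 * se

    def test_replicate_shapes_and_fixed_phenotype(self, rng):
        sc = make_scenario("homogeneous", "extreme", 0.2, **SMALL)
        g, y, labels = simulate_causal_replicate(sc, rng)
        assert g.shape == y.shape == labels.shape == (sc.n_total,)
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}
        np.testing.assert_array_equal(y, sc.phenotype())


class TestBackgroundGenotypes:
    def test_per_population_frequency_tracks_draws(self, rng):
        sc = make_scenario("null", "none", pop_size=400, n_background_snps=60)
        gm, labels, _ = simulate_background_genotypes(sc, 60, rng)
        # homogeneous populations: sample alt frequency within 4 binomial SE
        # of a plausible (0.01, 0.99) frequency — sanity of scale
        for pop in ("CEU", "YRI", "CHD"):
            freq = gm.dosage[labels == pop].mean(axis=0) / 2
            assert ((freq >= 0) & (freq <= 1)).all()
        assert gm.n_samples == 4000 and gm.n_variants == 60

    def test_no_differentiation_gives_no_structure(self, rng):
        from megwas.simstudy import FrequencyModel
        from megwas import compute_agv_from_genotypes

        fm = FrequencyModel(
            F_block={b: 0.0 for b in
                     ("African", "EastAsian", "SouthAsian", "Hispanic",
                      "European")},
            F_within=0.0,
        )
        sc = make_scenario("null", "none", pop_size=100,
                           n_background_snps=300, freq=fm)
        gm, labels, _ = simulate_background_genotypes(sc, 300, rng)
        agv = compute_agv_from_genotypes(gm, 5)
        # without structure the spectrum is flat: top eigenvalue near the
        # Marchenko-Pastur edge (1 + sqrt(n/M))^2, far below a spiked value
        n, M = 1000, 300
        edge = (1 + np.sqrt(n / M)) ** 2
        assert agv.eigenvalues[0] < 1.3 * edge

    def test_ancestry_blocks_separate_in_agv_space(self, rng):
        from sklearn.metrics import silhouette_score
        from megwas import compute_agv_from_genotypes

        sc = make_scenario("null", "none", pop_size=100, n_background_snps=400)
        gm, labels, _ = simulate_background_genotypes(sc, 400, rng)
        agv = compute_agv_from_genotypes(gm, 4)
        anc = np.array([dict(POPULATIONS)[p] for p in labels])
        # the three non-admixed continental groups separate cleanly
        keep = np.isin(anc, ["EastAsian", "European"]) | (
            np.isin(labels, ["YRI"])
        )
        score = silhouette_score(agv.axes[keep][:, :2], anc[keep])
        assert score > 0.5


class TestEstimatePower:
    def test_all_below(self):
        assert estimate_power(np.zeros(10) + 1e-9, 0.05) == (1.0, 0.0)

    def test_none_below(self):
        assert estimate_power(np.ones(10), 0.05) == (0.0, 0.0)

    def test_binomial_se(self):
        p = np.r_[np.zeros(500), np.ones(500)]
        power, se = estimate_power(p, 0.5)
        assert power == 0.5
        assert se == pytest.approx(np.sqrt(0.25 / 1000))

    def test_nan_counts_as_non_rejection(self):
        p = np.array([np.nan, 0.001, 0.001, 0.001])
        power, _ = estimate_power(p, 0.05)
        assert power == 0.75


class TestRunReplicates:
    def test_same_seed_bit_identical(self):
        sc = make_scenario("null", "moderate", **SMALL)
        pt1 = run_replicates(sc, seed=42, n_replicates=8)
        pt2 = run_replicates(sc, seed=42, n_replicates=8)
        pd.testing.assert_frame_equal(pt1.table, pt2.table)
        for a in pt1.pvalues:
            np.testing.assert_array_equal(pt1.pvalues[a], pt2.pvalues[a])

    def test_different_seed_differs(self):
        sc = make_scenario("null", "moderate", **SMALL)
        pt1 = run_replicates(sc, analyses=("glm_unadjusted",), seed=1,
                             n_replicates=8)
        pt2 = run_replicates(sc, analyses=("glm_unadjusted",), seed=2,
                             n_replicates=8)
        assert not np.array_equal(
            pt1.pvalues["glm_unadjusted"], pt2.pvalues["glm_unadjusted"]
        )

    def test_unknown_analysis_rejected(self):
        sc = make_scenario("null", "none", **SMALL)
        with pytest.raises(ValidationError):
            run_replicates(sc, analyses=("bogus",), n_replicates=2)

    def test_background_reuse_matches_rebuild(self):
        sc = make_scenario("null", "none", **SMALL)
        children = np.random.SeedSequence(7).spawn(3)
        bg = Background.build(sc, np.random.default_rng(children[0]))
        pt1 = run_replicates(sc, analyses=("glm_agv",), seed=7,
                             n_replicates=5, background=bg)
        pt2 = run_replicates(sc, analyses=("glm_agv",), seed=7, n_replicates=5)
        np.testing.assert_array_equal(
            pt1.pvalues["glm_agv"], pt2.pvalues["glm_agv"]
        )

    def test_power_table_written_with_sidecar(self, tmp_path):
        sc = make_scenario("homogeneous", "none", 0.3, **SMALL)
        pt = run_replicates(sc, analyses=("glm_unadjusted",), seed=3,
                            n_replicates=6)
        out = tmp_path / "power.tsv"
        pt.to_tsv(out, sidecar=str(tmp_path / "prov.json"))
        df = pd.read_csv(out, sep="\t")
        assert set(df.columns) >= {"analysis", "threshold", "power", "mc_se"}
        assert (tmp_path / "prov.json").exists()

    def test_admixture_dict_covers_admixed_pops(self, rng):
        sc = make_scenario("null", "none", **SMALL)
        _, _, admix = simulate_background_genotypes(sc, 50, rng)
        assert set(admix) == set(ADMIXED)
        for a in admix.values():
            assert ((a >= 0) & (a <= 1)).all() and len(a) == sc.pop_size
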