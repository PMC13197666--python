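import numpy as np
import pytest
from scipy.linalg import expm

from lbamix import likelihood_ml as ml
from lbamix import simulate as sim
from lbamix import substitution_models as sm
from lbamix import trees_io as T
from lbamix.benchmark import UndefinedZError


@pytest.fixture(scope="module")
def toy_tree():
    return T.read_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.0);")


@pytest.fixture(scope="module")
def toy_alignment():
    codes = np.array([[0, 5], [2, 5], [0, 7], [1, 5]], dtype=np.uint8)
    return T.Alignment(["A", "B", "C", "D"], codes)


def brute_force_loglik(aln, model, lengths):
    """Exhaustive enumeration over the two internal states (oracle)."""
    pi = model.mixture.profiles[0].freqs
    Q = sm.build_rate_matrix(model.exchangeabilities, model.mixture.profiles[0])
    rates = model.rates
    out = []
    for site in range(aln.n_sites):
        s = aln.codes[:, site]
        total = 0.0
        for g in range(rates.ncat):
            P = {k: expm(Q * t * rates.rates[g]) for k, t in lengths.items()}
            acc = 0.0
            for x in range(20):
                for y in range(20):
                    for r in range(20):
                        acc += (
                            pi[r]
                            * P["X"][r, x]
                            * P["Y"][r, y]
                            * P["A"][x, s[0]]
                            * P["B"][x, s[1]]
                            * P["C"][y, s[2]]
                            * P["D"][y, s[3]]
                        )
            total += rates.probs[g] * acc
        out.append(np.log(total))
    return np.array(out)


class TestSiteLogLikelihoods:
    def test_matches_brute_force_enumeration(self, toy_tree, toy_alignment):
        model = sm.SubstitutionModel.homogeneous("WAG", alpha=0.6, ncat=2)
        got = ml.site_log_likelihoods(toy_alignment, toy_tree, model)
        lengths = {"A": 0.1, "B": 0.3, "C": 0.15, "D": 0.4, "X": 0.2, "Y": 0.0}
        oracle = brute_force_loglik(toy_alignment, model, lengths)
        assert np.abs(got - oracle).max() < 1e-10

    def test_degenerate_weights_reduce_to_component(self, toy_tree, toy_alignment):
        hom = sm.SubstitutionModel.homogeneous("WAG")
        p2 = sm.FrequencyProfile(sm.smooth_profile(np.linspace(1, 3, 20)))
        mix = sm.SubstitutionModel(
            hom.exchangeabilities,
            sm.ProfileMixture(
                (hom.mixture.profiles[0], p2), np.array([1.0, 0.0])
            ),
            hom.rates,
        )
        a = ml.site_log_likelihoods(toy_alignment, toy_tree, hom)
        b = ml.site_log_likelihoods(toy_alignment, toy_tree, mix)
        assert np.abs(a - b).max() < 1e-12

    def test_identical_patterns_identical_values(self, toy_tree):
        codes = np.array(
            [[0, 3, 0], [2, 3, 2], [0, 3, 0], [1, 3, 1]], dtype=np.uint8
        )
        aln = T.Alignment(["A", "B", "C", "D"], codes)
        model = sm.SubstitutionModel.homogeneous("WAG")
        ll = ml.site_log_likelihoods(aln, toy_tree, model)
        assert ll[0] == ll[2]

    def test_leaf_reorder_invariance(self, toy_tree, toy_alignment):
        model = sm.SubstitutionModel.homogeneous("WAG")
        a = ml.site_log_likelihoods(toy_alignment, toy_tree, model).sum()
        perm = [2, 0, 3, 1]
        shuffled = T.Alignment(
            [toy_alignment.taxa[i] for i in perm], toy_alignment.codes[perm]
        )
        b = ml.site_log_likelihoods(shuffled, toy_tree, model).sum()
        assert a == pytest.approx(b, abs=1e-10)

    def test_rerooting_invariance(self, toy_alignment):
        """The unrooted likelihood does not depend on root placement."""
        model = sm.SubstitutionModel.homogeneous("WAG")
        t1 = T.read_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.0);")
        t2 = T.read_newick("(A:0.1,B:0.3,(C:0.15,D:0.4):0.2);")  # rooted on X
        a = ml.site_log_likelihoods(toy_alignment, t1, model).sum()
        b = ml.site_log_likelihoods(toy_alignment, t2, model).sum()
        assert a == pytest.approx(b, abs=1e-9)

    def test_gap_marginalization(self, toy_tree):
        codes = np.array([[0], [20], [0], [1]], dtype=np.uint8)
        aln = T.Alignment(["A", "B", "C", "D"], codes)
        model = sm.SubstitutionModel.homogeneous("WAG", ncat=1)
        got = ml.site_log_likelihoods(aln, toy_tree, model)[0]
        # oracle: sum over the 20 possible states at the gap leaf
        total = 0.0
        for b_state in range(20):
            full = T.Alignment(
                ["A", "B", "C", "D"], np.array([[0], [b_state], [0], [1]], dtype=np.uint8)
            )
            total += np.exp(ml.site_log_likelihoods(full, toy_tree, model)[0])
        assert got == pytest.approx(np.log(total), abs=1e-10)

    def test_taxon_mismatch_raises(self, toy_tree):
        aln = T.Alignment(["A", "B", "C", "Z"], np.zeros((4, 2), dtype=np.uint8))
        model = sm.SubstitutionModel.homogeneous("WAG")
        with pytest.raises(KeyError):
            ml.site_log_likelihoods(aln, toy_tree, model)

    def test_mixture_dominance_bound(self, toy_tree, toy_alignment):
        """lnL(mixture) >= lnL(component k) + log w_k for every component."""
        hom = sm.SubstitutionModel.homogeneous("WAG")
        mix = ml._wag_cxx_model("C10", 0.6, 4)
        total = ml.site_log_likelihoods(toy_alignment, toy_tree, mix).sum()
        for k, prof in enumerate(mix.mixture.profiles):
            single = sm.SubstitutionModel(
                mix.exchangeabilities, sm.ProfileMixture.single(prof), mix.rates
            )
            comp = ml.site_log_likelihoods(toy_alignment, toy_tree, single).sum()
            bound = comp + toy_alignment.n_sites * np.log(mix.mixture.weights[k])
            assert total >= bound - 1e-9


class TestFitModel:
    def test_parameter_recovery_light(self, felsenstein_tree, wag_homogeneous):
        aln = sim.simulate_alignment(
            felsenstein_tree, wag_homogeneous, 1500, np.random.default_rng(10)
        )
        fit = ml.fit_model(aln, felsenstein_tree, wag_homogeneous, ml.FitOptions())
        assert 0.45 < fit.alpha < 0.8  # true 0.6
        assert T.clade_branch_length(fit.tree, "EF") == pytest.approx(1.0, rel=0.25)
        assert fit.converged
        assert fit.site_log_likelihoods.sum() == pytest.approx(fit.log_likelihood)

    def test_em_single_component_weight_is_one(self, hom_alignment_1k, felsenstein_tree):
        model = sm.SubstitutionModel.homogeneous("WAG")
        fit = ml.fit_model(
            hom_alignment_1k,
            felsenstein_tree,
            model,
            ml.FitOptions(estimate_weights=True, optimize_branch_lengths=False,
                          optimize_alpha=False),
        )
        assert fit.weights.tolist() == [1.0]

    def test_monotone_lnl_across_em(self, felsenstein_tree, hom_alignment_1k):
        spec = ml._wag_cxx_model("C10", 0.6, 4)
        opts = ml.FitOptions(
            estimate_frequencies=True,
            estimate_weights=True,
            optimize_branch_lengths=False,
            optimize_alpha=False,
            max_outer=3,
        )
        fit = ml.fit_model(hom_alignment_1k, felsenstein_tree, spec, opts)
        hom_fit = ml.fit_model(
            hom_alignment_1k,
            felsenstein_tree,
            sm.SubstitutionModel.homogeneous("WAG"),
            ml.FitOptions(estimate_frequencies=True, optimize_branch_lengths=False,
                          optimize_alpha=False),
        )
        # weight EM can only improve on the equal-weight start; the fitted
        # mixture should not fall below the plain +F fit by more than noise
        assert fit.log_likelihood >= hom_fit.log_likelihood - 5.0

    def test_deterministic_given_seed(self, felsenstein_tree, hom_alignment_1k):
        opts = ml.FitOptions(n_restarts=2, seed=3)
        f1 = ml.fit_model(hom_alignment_1k, felsenstein_tree,
                          sm.SubstitutionModel.homogeneous("WAG"), opts)
        f2 = ml.fit_model(hom_alignment_1k, felsenstein_tree,
                          sm.SubstitutionModel.homogeneous("WAG"), opts)
        assert f1.log_likelihood == f2.log_likelihood


class TestBicSelect:
    def test_bic_arithmetic(self):
        assert ml.bic_score(-1000.0, 5, 100) == pytest.approx(2023.0258509299)

    def test_fewer_parameters_win_ties(self):
        assert ml.bic_score(-50.0, 5, 10) < ml.bic_score(-50.0, 10, 10)

    def test_wag_selected_on_wag_data(self, felsenstein_tree, wag_homogeneous):
        wins = 0
        for seed in (0, 1):
            aln = sim.simulate_alignment(
                felsenstein_tree, wag_homogeneous, 1200, np.random.default_rng(seed)
            )
            best, table = ml.bic_select(
                aln, felsenstein_tree, ml.mlho_candidates()
            )
            assert set(table.columns) == {"model", "lnL", "k", "BIC"}
            assert np.allclose(
                table["BIC"],
                -2 * table["lnL"] + table["k"] * np.log(aln.n_sites),
            )
            if best.name.startswith("WAG"):
                wins += 1
        assert wins == 2

    def test_empty_candidates_rejected(self, toy_alignment, toy_tree):
        with pytest.raises(ValueError):
            ml.bic_select(toy_alignment, toy_tree, [])


class TestSelectMlhe:
    def test_homogeneous_protocol_returns_c60(self, felsenstein_tree, hom_alignment_1k):
        opts = ml.FitOptions(
            estimate_frequencies=True,
            estimate_weights=True,
            optimize_branch_lengths=False,
            optimize_alpha=False,
        )
        fit, protocol = ml.select_mlhe(
            hom_alignment_1k, felsenstein_tree, is_homogeneous_protocol=True, options=opts
        )
        assert "C60" in fit.name and "C60" in protocol or "homogeneous" in protocol
        assert fit.weights is not None and len(fit.weights) == 61

    def test_heterogeneous_data_prefers_cxx(self, felsenstein_tree, het_alignment_1k):
        opts = ml.FitOptions(
            estimate_frequencies=True,
            estimate_weights=True,
            optimize_branch_lengths=False,
            optimize_alpha=False,
        )
        stage1 = ml.fit_model(
            het_alignment_1k,
            felsenstein_tree,
            sm.SubstitutionModel.homogeneous("WAG"),
            ml.FitOptions(estimate_frequencies=True),
        )
        fit, protocol = ml.select_mlhe(
            het_alignment_1k,
            stage1.tree,
            is_homogeneous_protocol=False,
            cxx_levels=("C10",),
            options=opts,
        )
        assert "C10" in fit.name  # mixture beats WAG+F+G on BIC


class TestEvaluateFocalSplit:
    def test_saturating_signal(self, quartet):
        tree = T.load_fixture_tree("farris")
        # stretch the focal internal branch so the signal saturates
        cands = T.focal_split_resolutions(tree, quartet)
        gen = cands["AB+EF"].copy()
        node = gen.find_clade_node(gen.clades["ABEF"])
        node.length = 1.0
        model = sm.SubstitutionModel.homogeneous("WAG")
        aln = sim.simulate_alignment(gen, model, 500, np.random.default_rng(0))
        call = ml.evaluate_focal_split(
            aln, cands, model, ml.FitOptions(), n_bootstrap=100,
            rng=np.random.default_rng(1),
        )
        assert call.best_label == "AB+EF"
        assert call.support == 100.0
        assert call.support_method == "bootstrap (RELL)"

    def test_no_bootstrap_still_calls(self, quartet, hom_alignment_1k):
        cands = T.focal_split_resolutions(T.load_fixture_tree("felsenstein"), quartet)
        model = sm.SubstitutionModel.homogeneous("WAG")
        small = hom_alignment_1k.subset_sites(np.arange(200))
        call = ml.evaluate_focal_split(
            small, cands, model, ml.FitOptions(), n_bootstrap=0
        )
        assert call.support is None
        assert call.best_label in cands

    def test_rell_close_to_full_refit(self, quartet):
        tree = T.load_fixture_tree("felsenstein")
        cands = T.focal_split_resolutions(tree, quartet)
        model = sm.SubstitutionModel.homogeneous("WAG")
        diffs = []
        for seed in (0, 1):
            aln = sim.simulate_alignment(tree, model, 150, np.random.default_rng(seed))
            rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
            rell = ml.evaluate_focal_split(
                aln, cands, model, ml.FitOptions(max_lbfgs_iter=40),
                n_bootstrap=20, rng=rng1, method="rell",
            )
            refit = ml.evaluate_focal_split(
                aln, cands, model, ml.FitOptions(max_lbfgs_iter=40),
                n_bootstrap=20, rng=rng2, method="refit",
            )
            assert rell.best_label == refit.best_label
            diffs.append(abs(rell.support - refit.support))
        assert np.mean(diffs) <= 15.0  # 20-replicate bootstrap granularity is 5 pts


class TestParametricBootstrap:
    def test_self_simulation_z_small(self, felsenstein_tree, wag_homogeneous):
        aln = sim.simulate_alignment(
            felsenstein_tree, wag_homogeneous, 1000, np.random.default_rng(20)
        )
        fit = ml.fit_model(aln, felsenstein_tree, wag_homogeneous, ml.FitOptions())
        res = ml.parametric_bootstrap_zscore(fit, 40, np.random.default_rng(21))
        assert abs(res.z_score) < 3.0
        assert res.mode == "pb"
        assert len(res.replicates) == 40

    def test_heterogeneous_data_fail_adequacy(self, felsenstein_tree, het_alignment_1k):
        fit = ml.fit_model(
            het_alignment_1k, felsenstein_tree,
            sm.SubstitutionModel.homogeneous("WAG"),
            ml.FitOptions(estimate_frequencies=True),
        )
        res = ml.parametric_bootstrap_zscore(fit, 30, np.random.default_rng(22))
        assert res.z_score > 2.0
        assert not res.fits

    def test_zero_spread_raises(self):
        tree = T.read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        model = sm.SubstitutionModel.homogeneous("WAG", ncat=1)
        aln = sim.simulate_alignment(tree, model, 50, np.random.default_rng(0))
        fit = ml.fit_model(
            aln, tree, model,
            ml.FitOptions(optimize_branch_lengths=False, optimize_alpha=False),
        )
        # zero-length fitted tree: every replicate has diversity exactly 1
        for node in fit.tree.postorder():
            node.length = 0.0
        with pytest.raises(UndefinedZError):
            ml.parametric_bootstrap_zscore(fit, 10, np.random.default_rng(1))


class TestPartitioned:
    def test_fit_and_sitewise_consistency(self, felsenstein_tree):
        rng = np.random.default_rng(0)
        base = sm.FrequencyProfile(np.full(20, 0.05))
        specs = [
            (sm.get_exchangeability("WAG"), sm.sample_profile_mixture(5, base, 1.0, 1.0, rng), 120),
            (sm.get_exchangeability("LG"), sm.sample_profile_mixture(5, base, 1.0, 1.0, rng), 120),
        ]
        aln, ranges = sim.simulate_multigene(felsenstein_tree, specs, rng)
        part = ml.PartitionedModel(
            ranges,
            [
                sm.SubstitutionModel.homogeneous("WAG"),
                sm.SubstitutionModel.homogeneous("LG"),
            ],
        )
        fit = ml.fit_partitioned(aln, felsenstein_tree, part, ml.FitOptions(max_lbfgs_iter=60))
        assert fit.rate_multipliers[0] == 1.0
        assert fit.site_log_likelihoods.shape == (240,)
        assert fit.site_log_likelihoods.sum() == pytest.approx(fit.log_likelihood, abs=1e-6)
        # joint fit should beat a deliberately perturbed branch-length vector
        worse = fit.tree.copy()
        for node in worse.postorder():
            node.length *= 1.7
        perturbed = ml.fit_partitioned(
            aln, worse, ml.PartitionedModel(fit.model.ranges, part.models),
            ml.FitOptions(max_lbfgs_iter=1),
        )
        assert fit.log_likelihood >= perturbed.log_likelihood - 1e-6

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            ml.PartitionedModel(
                [(0, 10), (12, 20)],
                [sm.SubstitutionModel.homogeneous("WAG")] * 2,
            )


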