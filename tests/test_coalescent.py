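"""Simulator calibration against closed forms and msprime cross-validation."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import ks_2samp, kstest

from isoscope import errors
from isoscope.coalescent import (
    DemographyModel,
    Genealogy,
    HkyParams,
    MutationSpec,
    PopulationConfig,
    SmmParams,
    apply_hky_mutations,
    apply_smm_mutations,
    build_demography,
    simulate_dataset,
    simulate_genealogy,
)
from isoscope.config import default_scenarios
from isoscope.scenarios import draw_scenario_parameters


def single_deme(ne, growth=0.0):
    return DemographyModel(
        [PopulationConfig("source", ne, growth)], np.zeros((1, 1)), []
    )


def two_tip_tree(total_separation):
    """Manual genealogy: two tips joined at total_separation / 2."""
    return Genealogy(
        node_time=np.array([0.0, 0.0, total_separation / 2.0]),
        node_parent=np.array([2, 2, -1]),
        tip_populations=["a", "b"],
    )


class TestGenealogySimulation:
    def test_pair_tmrca_mean_matches_constant_size_expectation(self):
        n_reps, ne = 2000, 400.0
        model = single_deme(ne)
        rng = np.random.default_rng(10)
        t = np.array(
            [simulate_genealogy(model, {"source": 2}, rng).tmrca() for _ in range(n_reps)]
        )
        se = t.std(ddof=1) / math.sqrt(n_reps)
        assert abs(t.mean() - ne) < 3 * se

    def test_pair_tmrca_under_growth_matches_time_rescaled_cdf(self):
        # Ne(t) = N exp(-g t): F(t) = 1 - exp(-(e^{g t} - 1) / (g N))
        ne, g, n_reps = 200.0, 0.05, 2000
        model = single_deme(ne, growth=g)
        rng = np.random.default_rng(11)
        t = np.array(
            [simulate_genealogy(model, {"source": 2}, rng).tmrca() for _ in range(n_reps)]
        )
        cdf = lambda x: 1.0 - np.exp(-(np.exp(g * np.asarray(x)) - 1.0) / (g * ne))
        assert kstest(t, cdf).pvalue > 0.01

    def test_disconnected_demes_raise(self):
        model = DemographyModel(
            [PopulationConfig("a", 100.0), PopulationConfig("b", 100.0)],
            np.zeros((2, 2)),
            [],
        )
        rng = np.random.default_rng(0)
        with pytest.raises(errors.ValidationError):
            simulate_genealogy(model, {"a": 2, "b": 2}, rng)

    def test_tips_are_contemporaneous_and_tree_is_binary(self):
        model = single_deme(300.0)
        rng = np.random.default_rng(12)
        g = simulate_genealogy(model, {"source": 7}, rng)
        assert g.n_tips == 7 and g.n_nodes == 13
        assert np.all(g.node_time[:7] == 0.0)
        assert np.all(g.branch_lengths()[np.arange(g.n_nodes) != g.root] > 0)


class TestHkyMutations:
    def test_zero_rate_gives_identical_tips(self):
        tree = two_tip_tree(1000.0)
        spec = MutationSpec("hky", hky=HkyParams(region_rate_per_year=0.0, length_bp=50))
        ds = apply_hky_mutations(tree, spec, np.random.default_rng(1))
        assert ds.records[0].sequence == ds.records[1].sequence

    def test_huge_kappa_yields_only_transitions(self):
        tree = two_tip_tree(4000.0)
        spec = MutationSpec(
            "hky",
            hky=HkyParams(region_rate_per_year=4e-3, kappa=1e7,
                          base_frequencies=(0.25, 0.25, 0.25, 0.25), length_bp=2000),
        )
        ds = apply_hky_mutations(tree, spec, np.random.default_rng(2),
                                 generation_years=25.0)
        transitions = {frozenset("AG"), frozenset("CT")}
        n_diff = 0
        for a, b in zip(ds.records[0].sequence, ds.records[1].sequence):
            if a != b:
                n_diff += 1
                assert frozenset((a, b)) in transitions
        assert n_diff > 50  # the check exercised many substitution events

    def test_pair_divergence_matches_matrix_exponential_oracle(self):
        # Two tips separated by total branch length T: expected differing
        # sites = L * sum_a pi_a (1 - P_aa(mu_site * T)), with P from an
        # independently constructed rate matrix exponentiated by scipy.
        kappa, freqs, L = 10.0, (0.3, 0.3, 0.15, 0.25), 333
        rate_year, gen_years, T = 5.2023e-5, 25.0, 3000.0
        pi = np.array(freqs)
        q = np.zeros((4, 4))
        transition = {0: 2, 1: 3, 2: 0, 3: 1}
        for a in range(4):
            for b in range(4):
                if a != b:
                    q[a, b] = pi[b] * (kappa if transition[a] == b else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        q /= -np.sum(pi * np.diag(q))
        mu_site = rate_year * gen_years / L
        p = expm(q * mu_site * T)
        expected = L * float(np.sum(pi * (1.0 - np.diag(p))))

        tree = two_tip_tree(T)
        spec = MutationSpec(
            "hky",
            hky=HkyParams(region_rate_per_year=rate_year, kappa=kappa,
                          base_frequencies=freqs, length_bp=L),
        )
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(2000):
            ds = apply_hky_mutations(tree, spec, rng, generation_years=gen_years)
            a, b = ds.records[0].sequence, ds.records[1].sequence
            diffs.append(sum(x != y for x, y in zip(a, b)))
        diffs = np.array(diffs, dtype=float)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean() - expected) < 3 * se


class TestSmmMutations:
    def test_zero_rate_gives_root_allele_everywhere(self):
        tree = two_tip_tree(500.0)
        spec = MutationSpec("smm", smm=SmmParams(("L1",), (0.0,), root_allele=15))
        ds = apply_smm_mutations(tree, spec, np.random.default_rng(1))
        assert all(r.repeats == (15,) for r in ds.records)

    def test_pair_difference_mean_and_variance_match_random_walk(self):
        # difference of two tips = net displacement of a +/-1 walk with
        # Poisson(mu T) steps: mean 0, variance mu T
        mu, T = 2.0e-3, 800.0
        tree = two_tip_tree(T)
        spec = MutationSpec("smm", smm=SmmParams(("L1",), (mu,), root_allele=30))
        rng = np.random.default_rng(4)
        d = []
        for _ in range(5000):
            ds = apply_smm_mutations(tree, spec, rng)
            d.append(ds.records[0].repeats[0] - ds.records[1].repeats[0])
        d = np.array(d, dtype=float)
        se_mean = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean()) < 3 * se_mean
        d2 = d**2
        se_var = d2.std(ddof=1) / math.sqrt(len(d2))
        assert abs(d2.mean() - mu * T) < 3 * se_var

    def test_alleles_never_drop_below_one(self):
        tree = two_tip_tree(2000.0)
        spec = MutationSpec("smm", smm=SmmParams(("L1",), (5e-3,), root_allele=1))
        rng = np.random.default_rng(5)
        for _ in range(200):
            ds = apply_smm_mutations(tree, spec, rng)
            assert min(r.repeats[0] for r in ds.records) >= 1


class TestScenarioDemography:
    def test_build_demography_structure(self):
        spec = default_scenarios(["mtdna"])[0]
        draw = {"sink_ne": 200.0, "sink_migration": 0.002,
                "split_times": [40.0, 40.0, 40.0]}
        model = build_demography(spec, draw)
        assert len(model.populations) == 4
        assert model.root == "source"
        sink = model.populations[1]
        assert sink.ne_at_sampling == 200.0
        # backward exponential shrink since the split
        assert sink.size_at(40.0) == pytest.approx(200.0 * math.exp(-0.017 * 40.0))
        # default conversion: forward source->sink flow 0.0001 becomes the
        # backward sink<-... tracing rates swapped
        assert model.migration[1, 0] == pytest.approx(spec.sink_to_source_m)
        assert model.migration[0, 1] == pytest.approx(spec.source_to_sink_m)
        assert model.migration[1, 2] == pytest.approx(0.002)

    def test_ystr_pairing_carries_halved_migration_into_model(self):
        spec = default_scenarios(["mtdna"])[0]
        draw = {"sink_ne": 200.0, "sink_migration": 0.002,
                "split_times": [40.0, 40.0, 40.0]}
        y_draw = dict(draw, sink_migration=0.001)
        model = build_demography(spec, draw)
        y_model = build_demography(spec.ystr_paired(), y_draw)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(y_model.migration[off], model.migration[off] / 2.0)

    def test_draw_outside_prior_rejected(self):
        spec = default_scenarios(["mtdna"])[0]
        with pytest.raises(errors.ValidationError):
            build_demography(
                spec,
                {"sink_ne": 1000.0, "sink_migration": 0.0,
                 "split_times": [40.0, 40.0, 40.0]},
            )

    def test_simulated_dataset_shapes_and_determinism(self):
        spec = default_scenarios(["mtdna"])[0]
        rng = np.random.default_rng(21)
        params = draw_scenario_parameters(spec, rng)
        ds1 = simulate_dataset(spec, params, np.random.default_rng(99))
        ds2 = simulate_dataset(spec, params, np.random.default_rng(99))
        assert len(ds1) == 150 and ds1.alignment_length == 333
        assert set(ds1.population_sizes().values()) == {50}
        assert [r.sequence for r in ds1.records] == [r.sequence for r in ds2.records]

        y_spec = default_scenarios(["ystr"])[0]
        y_params = draw_scenario_parameters(y_spec, rng)
        y_ds = simulate_dataset(y_spec, y_params, np.random.default_rng(7))
        assert len(y_ds) == 150 and y_ds.loci == list(y_spec.str_loci)


class TestMsprimeCrossValidation:
    """Distributional agreement with an independent coalescent simulator."""

    def _our_tmrcas(self, model, sample_sizes, n_reps, seed):
        rng = np.random.default_rng(seed)
        return np.array(
            [simulate_genealogy(model, sample_sizes, rng).tmrca() for _ in range(n_reps)]
        )

    def test_constant_size_tmrca_distribution(self):
        msprime = pytest.importorskip("msprime")
        ne, n, reps = 300.0, 10, 400
        ours = self._our_tmrcas(single_deme(ne), {"source": n}, reps, 31)
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples=n, ploidy=1, population_size=ne,
                    num_replicates=reps, random_seed=42,
                )
            ]
        )
        assert ks_2samp(ours, theirs).pvalue > 0.01

    def test_exponential_growth_tmrca_distribution(self):
        msprime = pytest.importorskip("msprime")
        ne, g, n, reps = 500.0, 0.02, 5, 400
        ours = self._our_tmrcas(single_deme(ne, growth=g), {"source": n}, reps, 32)
        demography = msprime.Demography()
        demography.add_population(name="source", initial_size=ne, growth_rate=g)
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples={"source": n}, ploidy=1, demography=demography,
                    num_replicates=reps, random_seed=43,
                )
            ]
        )
        assert ks_2samp(ours, theirs).pvalue > 0.01

    def test_two_deme_island_model_tmrca_distribution(self):
        msprime = pytest.importorskip("msprime")
        ne, m, n, reps = 300.0, 0.01, 5, 400
        model = DemographyModel(
            [PopulationConfig("a", ne), PopulationConfig("b", ne)],
            np.array([[0.0, m], [m, 0.0]]),
            [],
        )
        ours = self._our_tmrcas(model, {"a": n, "b": n}, reps, 33)
        demography = msprime.Demography()
        demography.add_population(name="a", initial_size=ne)
        demography.add_population(name="b", initial_size=ne)
        demography.set_symmetric_migration_rate(["a", "b"], m)
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples={"a": n, "b": n}, ploidy=1, demography=demography,
                    num_replicates=reps, random_seed=44,
                )
            ]
        )
        assert ks_2samp(ours, theirs).pvalue > 0.01

    def test_segregating_sites_distribution_in_jukes_cantor_limit(self):
        # kappa = 1 with equal frequencies reduces HKY to Jukes-Cantor, where
        # our substitution-rate convention coincides with msprime's
        # mutation-event rate (JC69 events are never silent). The kappa-biased
        # regime is checked against the matrix-exponential oracle above.
        msprime = pytest.importorskip("msprime")
        from isoscope.stats import segregating_sites

        ne, n, reps, L = 300.0, 8, 300, 333
        mu_site = 4e-6  # per site per generation
        spec = MutationSpec(
            "hky",
            hky=HkyParams(region_rate_per_year=mu_site * L, kappa=1.0,
                          base_frequencies=(0.25, 0.25, 0.25, 0.25), length_bp=L),
        )
        rng = np.random.default_rng(34)
        ours = []
        for _ in range(reps):
            tree = simulate_genealogy(single_deme(ne), {"source": n}, rng)
            ds = apply_hky_mutations(tree, spec, rng, generation_years=1.0)
            ours.append(segregating_sites(ds))
        theirs = []
        replicates = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=ne, sequence_length=L,
            num_replicates=reps, random_seed=45,
        )
        for i, ts in enumerate(replicates):
            mts = msprime.sim_mutations(
                ts, rate=mu_site, model=msprime.JC69(), random_seed=1000 + i
            )
            count = sum(
                1
                for var in mts.variants()
                if len({var.alleles[g] for g in var.genotypes}) >= 2
            )
            theirs.append(count)
        assert ks_2samp(np.array(ours), np.array(theirs)).pvalue > 0.01
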