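"""Random ecosystem generation: block structure, moments, determinism."""

import itertools

import numpy as np
import pytest

from microcrm import (
    Assumptions,
    make_consumer_matrix,
    make_initial_state,
    make_metabolic_matrix,
    make_params,
)
from microcrm.params import ModelParams


class TestAssumptions:
    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            Assumptions(M=10, T=3, M_A=[3, 3, 3])  # sums to 9
        with pytest.raises(ValueError):
            Assumptions(S_tot=10, F=2, S_A=[4, 4], S_gen=3)  # sums to 11
        with pytest.raises(ValueError):
            Assumptions(q=1.5)
        with pytest.raises(ValueError):
            Assumptions(s=0.0)
        with pytest.raises(ValueError):
            Assumptions(fw=0.6, fs=0.6)
        with pytest.raises(ValueError):
            Assumptions(S=20, S_tot=10)

    def test_layout_orders_resources_by_class_and_generalists_last(self):
        a = Assumptions(M=6, T=2, S_tot=5, F=1, S=2, S_A=[3], S_gen=2)
        assert list(a.resource_classes()) == [0, 0, 0, 1, 1, 1]
        assert list(a.species_families()) == [0, 0, 0, -1, -1]
        assert a.waste_class_index == a.T - 1

    def test_ledger_round_trip(self, small_assumptions, tmp_path):
        p = tmp_path / "assumptions.json"
        small_assumptions.to_json(p)
        assert Assumptions.from_file(p) == small_assumptions


class TestConsumerMatrix:
    def test_binary_generalist_uniform_uptake_probability(self):
        # generalists consume each resource with probability muc / (M c1)
        a = Assumptions(
            M=50, T=1, S_tot=400, F=1, S=10, S_A=[0], S_gen=400,
            muc=10.0, c1=1.0, c0=0.0, q=0.0, sampling_family="binary",
        )
        c = make_consumer_matrix(a, 7).to_numpy()
        p_hat = (c > 0.5).mean()
        p_exp = a.muc / (a.M * a.c1)
        se = np.sqrt(p_exp * (1 - p_exp) / c.size)
        assert abs(p_hat - p_exp) < 3 * se

    def test_binary_entries_take_only_two_levels(self, small_assumptions):
        a = small_assumptions
        c = make_consumer_matrix(a, 3).to_numpy()
        lo, hi = a.c0 / a.M, a.c0 / a.M + a.c1
        assert np.all(np.isclose(c, lo) | np.isclose(c, hi))

    def test_gaussian_pure_specialists_have_no_off_target_consumption(self):
        a = Assumptions(
            M=12, T=3, S_tot=9, F=3, S=3, S_A=[3, 3, 3], S_gen=0,
            q=1.0, sampling_family="gaussian",
        )
        c = make_consumer_matrix(a, 0).to_numpy()
        classes = a.resource_classes()
        fams = a.species_families()
        off = c[fams[:, None] != classes[None, :]]
        # off-class mean and variance are both zero at q = 1
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("family", ["gaussian", "gamma", "binary"])
    def test_row_sum_moment_recovery(self, family):
        # sampled consumption capacities recover the target row-sum moments
        a = Assumptions(
            M=100, T=1, S_tot=500, F=1, S=10, muc=10.0, sigc=3.0,
            c0=0.0, c1=1.0, q=0.0, sampling_family=family,
        )
        means, variances = [], []
        for seed in range(10):
            rs = make_consumer_matrix(a, seed).to_numpy().sum(axis=1)
            means.append(rs.mean())
            variances.append(rs.var(ddof=1))
        if family == "binary":
            p = a.muc / (a.M * a.c1)
            var_target = a.M * a.c1**2 * p * (1 - p)
        else:
            var_target = a.sigc**2
        n = 10 * a.S_tot
        se_mean = np.sqrt(var_target / n)
        assert abs(np.mean(means) - a.muc) < 3 * se_mean
        assert abs(np.mean(variances) - var_target) < 0.2 * var_target

    def test_gamma_rejects_zero_mean_and_is_positive(self):
        a = Assumptions(M=12, T=3, S_tot=6, F=3, S=2, S_A=[2, 2, 2],
                        q=1.0, sampling_family="gamma")
        with pytest.raises(ValueError, match="positive"):
            make_consumer_matrix(a, 0)
        a2 = Assumptions(M=12, T=3, S_tot=6, F=3, S=2, S_A=[2, 2, 2],
                         q=0.5, sampling_family="gamma")
        assert (make_consumer_matrix(a2, 0).to_numpy() > 0).all()

    def test_binary_rejects_probability_above_one(self):
        a = Assumptions(M=5, T=1, S_tot=4, F=1, S=2, muc=10.0, c1=1.0,
                        sampling_family="binary")
        with pytest.raises(ValueError, match="exceeds 1"):
            make_consumer_matrix(a, 0)

    def test_within_class_share_nondecreasing_in_q(self):
        # specialization monotonicity, averaged over a large sampled family
        shares = []
        for q in (0.0, 0.3, 0.6, 0.9):
            a = Assumptions(
                M=20, T=2, S_tot=300, F=2, S=10, S_A=[150, 150], q=q,
                muc=6.0, sigc=1.0, sampling_family="gamma",
            )
            c = make_consumer_matrix(a, 11).to_numpy()
            on = a.species_families()[:, None] == a.resource_classes()[None, :]
            shares.append((c * on).sum() / c.sum())
        assert all(b >= a - 1e-3 for a, b in itertools.pairwise(shares))

    def test_deterministic_given_seed(self, small_assumptions):
        c1 = make_consumer_matrix(small_assumptions, 5)
        c2 = make_consumer_matrix(small_assumptions, 5)
        assert c1.equals(c2)
        assert not c1.equals(make_consumer_matrix(small_assumptions, 6))


class TestMetabolicMatrix:
    @pytest.mark.parametrize("seed", range(5))
    def test_columns_sum_to_one(self, small_assumptions, seed):
        D = make_metabolic_matrix(small_assumptions, seed).to_numpy()
        assert np.abs(D.sum(axis=0) - 1.0).max() < 1e-12
        assert (D >= 0).all()

    def test_single_class_dense_limit_is_uniform(self):
        # T=1 (the class is its own waste class), s -> 0: symmetric Dirichlet
        # with huge concentration concentrates on the uniform column 1/M
        a = Assumptions(M=8, T=1, S_tot=4, F=1, S=2, s=1e-4)
        D = make_metabolic_matrix(a, 0).to_numpy()
        assert np.abs(D - 1.0 / a.M).max() < 0.01

    def test_tier_allocation_means(self):
        # mean allocation to waste / same-class tiers matches fw / fs
        a = Assumptions(M=30, T=3, S_tot=4, F=3, S=2, S_A=[2, 1, 1],
                        fw=0.49, fs=0.49, s=0.05)
        classes = a.resource_classes()
        wc = a.waste_class_index
        waste_alloc, same_alloc = [], []
        for seed in range(20):
            D = make_metabolic_matrix(a, seed).to_numpy()
            for beta in range(a.M):
                if classes[beta] == wc:
                    continue
                waste_alloc.append(D[classes == wc, beta].sum())
                same_alloc.append(D[classes == classes[beta], beta].sum())
        # Dirichlet total concentration is 1/s, so tier sums have
        # variance f(1-f)/(1/s + 1)
        n = len(waste_alloc)
        assert n >= 200
        se = np.sqrt(0.49 * 0.51 / (1 / a.s + 1) / n)
        assert abs(np.mean(waste_alloc) - a.fw) < 3 * se
        assert abs(np.mean(same_alloc) - a.fs) < 3 * se

    def test_sparsity_extremes(self):
        a_sparse = Assumptions(M=20, T=1, S_tot=4, F=1, S=2, s=1.0)
        D = make_metabolic_matrix(a_sparse, 2).to_numpy()
        # s = 1: columns concentrate on few entries
        assert (D.max(axis=0) > 0.5).mean() > 0.5

    def test_rejects_empty_waste_with_positive_fw(self):
        # make the waste class empty via a zero-size class partition
        a = Assumptions(M=6, T=2, S_tot=4, F=1, S=2, M_A=[6, 0], fw=0.3, fs=0.3)
        with pytest.raises(ValueError, match="waste"):
            make_metabolic_matrix(a, 0)


class TestMakeParams:
    def test_macarthur_limit_parameters(self, small_assumptions):
        a = Assumptions(**{**small_assumptions.to_dict(), "l": 0.0,
                           "response": "type1", "regulation": "off"})
        p = make_params(a, 0)
        assert np.all(p.l == 0.0)

    def test_requires_sigma_max_for_saturating_response(self, small_assumptions):
        a = Assumptions(**{**small_assumptions.to_dict(), "response": "type2"})
        with pytest.raises(ValueError, match="sigma_max"):
            make_params(a, 0)

    def test_round_trip_serialization(self, small_assumptions, tmp_path):
        p = make_params(small_assumptions, 4)
        path = tmp_path / "params.json"
        p.to_json(path)
        assert ModelParams.from_json(path) == p

    def test_single_carbon_source_supply_point(self, small_assumptions):
        p = make_params(small_assumptions, 0)
        a = small_assumptions
        assert p.R0[a.food] == a.R0_food
        assert np.count_nonzero(p.R0) == 1


class TestInitialState:
    def test_each_well_has_exactly_S_species_at_unit_abundance(
        self, small_assumptions
    ):
        st = make_initial_state(small_assumptions, n_wells=6, rng_seed=0)
        N = st.N.to_numpy()
        assert ((N > 0).sum(axis=0) == small_assumptions.S).all()
        assert np.all(N[N > 0] == 1.0)

    def test_full_pool_seeding(self):
        a = Assumptions(M=4, S_tot=6, S=6, T=1, F=1)
        st = make_initial_state(a, n_wells=2, rng_seed=1)
        assert (st.N.to_numpy() == 1.0).all()

    def test_subset_frequencies_match_enumeration(self):
        # S_tot=4, S=2: 6 equally likely subsets, so two independent draws
        # coincide with probability 1/6
        a = Assumptions(M=2, S_tot=4, S=2, T=1, F=1)
        matches = 0
        trials = 3000
        for k in range(trials):
            s1 = make_initial_state(a, 1, rng_seed=2 * k).N.to_numpy()[:, 0]
            s2 = make_initial_state(a, 1, rng_seed=2 * k + 1).N.to_numpy()[:, 0]
            matches += int(np.array_equal(s1, s2))
        p = 1.0 / 6.0
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(matches / trials - p) < 3.5 * se

    def test_same_seed_reproduces_wells(self, small_assumptions):
        s1 = make_initial_state(small_assumptions, 3, rng_seed=9)
        s2 = make_initial_state(small_assumptions, 3, rng_seed=9)
        assert s1.N.equals(s2.N) and s1.R.equals(s2.R)

    def test_per_well_food_override(self, small_assumptions):
        st = make_initial_state(
            small_assumptions, 2, 0, food=[0, 3], R0_food=[5.0, 7.0]
        )
        R = st.R.to_numpy()
        assert R[0, 0] == 5.0 and R[3, 1] == 7.0
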