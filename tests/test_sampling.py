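"""Unit and property tests for regional-pool sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micrm.sampling import (
    Environment,
    GlobalParameters,
    ResourceSchema,
    consumption_probabilities,
    emp_parameters,
    hmp_parameters,
    load_pool,
    make_supply,
    metabolic_concentrations,
    sample_consumer_matrix,
    sample_maintenance,
    sample_metabolic_matrix,
    sample_pool,
    save_pool,
)


def hmp_like(**overrides):
    base = dict(
        M=300, T=6, S_tot=120, F=6, S=60, mu_c=10.0, c0=0.0, c1=1.0,
        q=0.9, s=0.3, f_w=0.45, f_s=0.45, n_generalists=12,
    )
    base.update(overrides)
    return GlobalParameters(**base)


class TestConsumerMatrix:
    def test_structured_probabilities_match_closed_form(self):
        # M=300, T=6, M_A=50, q=0.9, mu_c=10, c1=1:
        # preferred class p = (10/300) (1 + (250/50) 0.9) = 0.18333...,
        # off-class p = (10/300) (1 - 0.9) = 0.003333...
        params = hmp_like()
        schema = ResourceSchema.from_params(params)
        p = consumption_probabilities(params, schema)
        fam0 = 0  # first species belongs to family A
        in_A = schema.class_of == 0
        assert np.allclose(p[fam0, in_A], (10 / 300) * (1 + 5 * 0.9))
        assert np.allclose(p[fam0, ~in_A], (10 / 300) * 0.1)
        # generalists are uniform
        assert np.allclose(p[-1], 10 / 300)

    def test_q_zero_uniformizes_specialists(self):
        params = hmp_like(q=0.0)
        schema = ResourceSchema.from_params(params)
        p = consumption_probabilities(params, schema)
        assert np.allclose(p, params.mu_c / (params.M * params.c1))

    def test_mean_row_sum_matches_mu_c(self):
        # unstructured pool: row sums are Binomial(M, mu_c/M); the
        # empirical mean over the pool should sit within 3 SE of mu_c
        params = emp_parameters()
        schema = ResourceSchema.from_params(params)
        c, _ = sample_consumer_matrix(params, schema, rng_seed=123)
        row_sums = c.sum(axis=1)
        p = params.mu_c / params.M
        se = np.sqrt(params.M * p * (1 - p) / params.S_tot)
        assert abs(row_sums.mean() - params.mu_c) < 3 * se

    def test_bernoulli_frequencies_match_probabilities(self):
        # many specialist rows share the same probabilities; pooled
        # frequencies must agree within binomial confidence bounds
        params = hmp_like(S_tot=1200, n_generalists=0, S=600)
        schema = ResourceSchema.from_params(params)
        c, fam = sample_consumer_matrix(params, schema, rng_seed=5)
        p = consumption_probabilities(params, schema)
        X = (c > params.c0 / params.M).astype(float)
        rows = fam == 0
        in_A = schema.class_of == 0
        n = rows.sum() * in_A.sum()
        p_true = p[np.flatnonzero(rows)[0], np.flatnonzero(in_A)[0]]
        assert abs(X[np.ix_(rows, in_A)].mean() - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)

    def test_probability_above_one_is_an_error(self):
        with pytest.raises(ValueError, match="probability exceeds 1"):
            params = hmp_like(M=30, S_tot=60, S=30, mu_c=10.0)
            consumption_probabilities(params, ResourceSchema.from_params(params))

    def test_more_families_than_classes_rejected(self):
        with pytest.raises(ValueError, match="families"):
            hmp_like(F=7)

    def test_unbalanced_classes_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            hmp_like(M=301)

    def test_family_sizes_partition_pool(self):
        params = hmp_like()
        _, fam = sample_consumer_matrix(params, ResourceSchema.from_params(params), 0)
        counts = np.bincount(fam[fam >= 0])
        assert np.all(counts == params.family_size)
        assert (fam == -1).sum() == params.n_generalists_effective


class TestMetabolicMatrix:
    def test_columns_sum_to_one(self):
        params = hmp_like()
        D = sample_metabolic_matrix(params, ResourceSchema.from_params(params), 7)
        assert np.allclose(D.sum(axis=0), 1.0, atol=1e-12)
        assert D.min() >= 0

    def test_tier_means_match_secretion_fractions(self):
        # Dirichlet mean of a tier = (tier concentration sum) * s; with
        # f_w = f_s = 0.45, a non-waste input sends on average 0.45 of
        # its secretion flux to the waste class and 0.45 to its own
        params = hmp_like()
        schema = ResourceSchema.from_params(params)
        rng = np.random.default_rng(0)
        d = metabolic_concentrations(params, schema)
        beta = 0  # class A input, not waste
        waste_rows = schema.class_of == schema.waste_class
        same_rows = schema.class_of == schema.class_of[beta]
        n = 10_000
        draws = rng.dirichlet(d[:, beta], size=n)
        waste_share = draws[:, waste_rows].sum(axis=1)
        same_share = draws[:, same_rows].sum(axis=1)
        assert abs(waste_share.mean() - 0.45) < 3 * waste_share.std() / np.sqrt(n)
        assert abs(same_share.mean() - 0.45) < 3 * same_share.std() / np.sqrt(n)

    def test_waste_input_merges_tiers(self):
        params = hmp_like()
        schema = ResourceSchema.from_params(params)
        d = metabolic_concentrations(params, schema)
        beta = schema.resources_in_class("F")[0]  # waste class input
        waste_rows = schema.class_of == schema.waste_class
        # mean share to waste = (f_w + f_s)
        assert np.isclose(d[waste_rows, beta].sum() * params.s, 0.9)

    def test_saturated_secretion_with_third_tier_rejected(self):
        params = hmp_like(f_w=0.5, f_s=0.5)
        with pytest.raises(ValueError, match="concentration"):
            metabolic_concentrations(params, ResourceSchema.from_params(params))

    def test_single_class_pool_is_uniform(self):
        params = emp_parameters()
        schema = ResourceSchema.from_params(params)
        d = metabolic_concentrations(params, schema)
        assert np.allclose(d, 1.0 / (params.s * params.M))


class TestMaintenance:
    def test_moments(self):
        params = hmp_like(S_tot=5000, S=100, n_generalists=200)
        m = sample_maintenance(params, 3)
        assert abs(m.mean() - 1.0) < 3 * 0.01 / np.sqrt(5000)

    def test_zero_sd_is_constant(self):
        m = sample_maintenance(hmp_like(m_sd=0.0), 3)
        assert np.all(m == 1.0)

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            sample_maintenance(hmp_like(m_mean=0.0, m_sd=1.0), 12)


@pytest.fixture(scope="module")
def schema():
    return ResourceSchema.from_params(hmp_like())


class TestSupply:

    def test_single(self, schema):
        kappa = make_supply("single", schema, 200.0, {"resource": 0})
        assert kappa[0] == 200.0 and kappa.sum() == 200.0

    @pytest.mark.parametrize("a,expect", [(0.0, (200.0, 0.0)), (1.0, (0.0, 200.0))])
    def test_pair_endpoints(self, schema, a, expect):
        kappa = make_supply("pair", schema, 200.0, {"resources": (3, 7), "a": a})
        assert (kappa[3], kappa[7]) == expect

    def test_pair_bad_fraction(self, schema):
        with pytest.raises(ValueError, match="outside"):
            make_supply("pair", schema, 1.0, {"resources": (0, 1), "a": 1.5})

    def test_class_uniform_total_and_support(self, schema):
        kappa = make_supply("class_uniform", schema, 1000.0, {"classes": ("A", "B")}, rng_seed=5)
        assert np.isclose(kappa.sum(), 1000.0)
        members = np.concatenate(
            [schema.resources_in_class("A"), schema.resources_in_class("B")]
        )
        outside = np.setdiff1d(np.arange(schema.M), members)
        assert np.all(kappa[outside] == 0) and np.all(kappa[members] > 0)

    def test_random_subset_size(self, schema):
        kappa = make_supply("random_subset", schema, 1000.0, {"n": 100}, rng_seed=1)
        assert (kappa > 0).sum() == 100 and np.isclose(kappa.sum(), 1000.0)


class TestPool:
    def test_replay_is_bit_identical(self):
        params = hmp_like()
        p1 = sample_pool(params, 99)
        p2 = sample_pool(params, 99)
        assert np.array_equal(p1.c, p2.c)
        assert np.array_equal(p1.D, p2.D)
        assert np.array_equal(p1.m_base, p2.m_base)

    def test_serialization_round_trip(self, tmp_path):
        pool = sample_pool(hmp_like(S_tot=24, M=12, S=12, n_generalists=6, mu_c=1.0), 4)
        save_pool(pool, tmp_path / "pool")
        back = load_pool(tmp_path / "pool")
        assert np.allclose(back.c, pool.c)
        assert np.allclose(back.D, pool.D, atol=1e-12)
        assert np.array_equal(back.family_of, pool.family_of)
        assert back.params == pool.params

    def test_structured_sampler_reduces_to_unstructured(self):
        # with one class and one family, q is irrelevant: first two
        # moments of the row sums match across q values
        base = emp_parameters(S_tot=2000)
        s1 = sample_consumer_matrix(base, ResourceSchema.from_params(base), 1)[0]
        qpar = emp_parameters(S_tot=2000, q=1.0)
        s2 = sample_consumer_matrix(qpar, ResourceSchema.from_params(qpar), 1)[0]
        r1, r2 = s1.sum(axis=1), s2.sum(axis=1)
        se = r1.std() / np.sqrt(r1.size)
        assert abs(r1.mean() - r2.mean()) < 4 * se
        assert abs(r1.std() - r2.std()) / r1.std() < 0.15

    def test_environment_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            Environment(kappa=np.array([-1.0, 2.0]))


@settings(max_examples=20, deadline=None)
@given(
    q=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**20),
)
def test_metabolic_columns_always_stochastic(q, seed):
    params = hmp_like(M=30, S_tot=24, S=12, n_generalists=6, q=q, mu_c=1.0)
    D = sample_metabolic_matrix(params, ResourceSchema.from_params(params), seed)
    assert np.allclose(D.sum(axis=0), 1.0, atol=1e-12)
    assert D.min() >= 0
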