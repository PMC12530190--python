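import numpy as np
import pytest

from pollinet.model_core import (
    DEFAULT_MEANS,
    ModelParams,
    SystemState,
    derivatives,
    initial_state,
    load_means,
    recruitment_fraction,
    sample_params,
    save_means,
    visit_quality,
    visitation_rates,
)
from pollinet.netgen import BipartiteNetwork


def make_params(net, **overrides):
    """Parameters pinned exactly at their means, with optional overrides."""
    P, A = net.n_plants, net.n_animals
    kw = dict(
        e=np.full(P, DEFAULT_MEANS["e"]),
        mu_p=np.full(P, DEFAULT_MEANS["mu_p"]),
        g=np.full(P, DEFAULT_MEANS["g"]),
        u=np.full(P, DEFAULT_MEANS["u"]),
        w=np.full(P, DEFAULT_MEANS["w"]),
        beta=np.full(P, DEFAULT_MEANS["beta"]),
        phi=np.full(P, DEFAULT_MEANS["phi"]),
        tau=np.full(A, DEFAULT_MEANS["tau"]),
        c=np.full(A, DEFAULT_MEANS["c"]),
        mu_a=np.full(A, DEFAULT_MEANS["mu_a"]),
        b=np.full(A, DEFAULT_MEANS["b"]),
        G=np.full(A, DEFAULT_MEANS["G"]),
    )
    kw.update(overrides)
    return ModelParams(**kw)


class TestSampleParams:
    def test_animal_params_exact(self, tiny_net):
        params = sample_params(tiny_net, rng=np.random.default_rng(0))
        assert (params.tau == 1.0).all()
        assert (params.c == 0.2).all()
        assert (params.mu_a == 0.001).all()
        assert (params.b == 0.4).all()
        assert (params.G == 2.0).all()

    def test_plant_params_within_ten_percent(self, ec_ensemble):
        net = ec_ensemble[0]
        params = sample_params(net, rng=np.random.default_rng(1))
        assert (params.beta >= 0.18).all() and (params.beta <= 0.22).all()
        assert (params.g >= 0.36).all() and (params.g <= 0.44).all()
        assert (params.w >= 1.08).all() and (params.w <= 1.32).all()

    def test_deterministic(self, tiny_net):
        p1 = sample_params(tiny_net, rng=np.random.default_rng(7))
        p2 = sample_params(tiny_net, rng=np.random.default_rng(7))
        assert np.array_equal(p1.beta, p2.beta)
        assert np.array_equal(p1.g, p2.g)

    def test_means_file_roundtrip(self, tiny_net, tmp_path):
        path = tmp_path / "means.txt"
        means = dict(DEFAULT_MEANS, beta=0.3)
        save_means(means, path)
        assert load_means(path)["beta"] == 0.3
        params = sample_params(tiny_net, rng=np.random.default_rng(0), means=load_means(path))
        assert (params.beta >= 0.27).all() and (params.beta <= 0.33).all()

    def test_validation(self, tiny_net):
        with pytest.raises(ValueError, match="phi"):
            make_params(tiny_net, phi=np.zeros(3))
        with pytest.raises(ValueError, match="non-negative"):
            make_params(tiny_net, u=np.full(3, -0.1))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            make_params(tiny_net, e=np.full(3, 1.5))


class TestInitialState:
    def test_densities(self, tiny_net):
        s = initial_state(tiny_net)
        assert (s.p == 0.5).all() and (s.a == 0.5).all() and (s.R == 0.5).all()

    def test_effort_is_inverse_diet_size(self):
        M = np.ones((4, 2), dtype=int)
        M[1:, 1] = 0
        M[1, 1] = 1  # animal 1 visits 2 plants
        net = BipartiteNetwork.from_matrix(M)
        s = initial_state(net)
        assert np.allclose(s.alpha[:, 0], 0.25)
        assert s.alpha[0, 1] == pytest.approx(0.5)

    def test_single_plant_animal_effort_one(self, tiny_net):
        s = initial_state(tiny_net)
        assert s.alpha[0, 2] == 1.0  # specialist animal

    def test_columns_sum_to_one(self, ec_ensemble):
        s = initial_state(ec_ensemble[0])
        assert np.allclose(s.alpha.sum(axis=0), 1.0)
        s.validate(ec_ensemble[0])


class TestVisitationRates:
    def test_initial_product(self, pair_net):
        params = make_params(pair_net)
        s = initial_state(pair_net)
        V = visitation_rates(s, params, pair_net)
        # alpha = 0.5, tau = 1, a = 0.5, p = 0.5
        assert np.allclose(V, 0.125)

    def test_degree_one_value(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        V = visitation_rates(s, params, tiny_net)
        assert V[0, 2] == pytest.approx(0.25)  # alpha=1, tau=1, a=0.5, p=0.5

    def test_extinct_visitor_column_zero(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.a[0] = 0.0
        V = visitation_rates(s, params, tiny_net)
        assert (V[:, 0] == 0).all()

    def test_linear_in_plant_density(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        V1 = visitation_rates(s, params, tiny_net)
        s.p[0] *= 2
        V2 = visitation_rates(s, params, tiny_net)
        assert np.allclose(V2[0], 2 * V1[0])
        assert np.allclose(V2[1:], V1[1:])


class TestVisitQuality:
    def test_specialist_quality_one(self, tiny_net):
        params = make_params(tiny_net)
        sigma = visit_quality(initial_state(tiny_net), params, tiny_net)
        assert sigma[0, 2] == pytest.approx(1.0)

    def test_equal_split(self, pair_net):
        params = make_params(pair_net)
        sigma = visit_quality(initial_state(pair_net), params, pair_net)
        assert np.allclose(sigma, 0.5)

    def test_unequal_densities(self):
        # two plants, alpha = (0.5, 0.5), p = (0.3, 0.1) -> sigma = (0.75, 0.25)
        net = BipartiteNetwork.from_matrix(np.ones((2, 2), dtype=int))
        params = make_params(net)
        s = initial_state(net)
        s.p = np.array([0.3, 0.1])
        sigma = visit_quality(s, params, net)
        assert np.allclose(sigma[:, 0], [0.75, 0.25])

    def test_invariant_to_animal_density_and_tau(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.p = np.array([0.7, 0.2, 0.4])
        sigma1 = visit_quality(s, params, tiny_net)
        s.a = np.array([3.0, 0.1, 9.9])
        params2 = make_params(tiny_net, tau=np.array([5.0, 0.2, 1.7]))
        sigma2 = visit_quality(s, params2, tiny_net)
        assert np.allclose(sigma1, sigma2)

    def test_columns_sum_to_one(self, ec_ensemble):
        net = ec_ensemble[0]
        params = sample_params(net, rng=np.random.default_rng(0))
        sigma = visit_quality(initial_state(net), params, net)
        assert np.allclose(sigma.sum(axis=0), 1.0)

    def test_zero_visits_column(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.a[:] = 0.0
        sigma = visit_quality(s, params, tiny_net)
        assert (sigma == 0).all()


class TestRecruitmentFraction:
    def test_no_competition_at_zero_density(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.p[:] = 0.0
        assert np.allclose(recruitment_fraction(s, params), params.g)

    def test_single_plant_plugin(self):
        net = BipartiteNetwork.from_matrix(np.ones((2, 2), dtype=int))
        params = make_params(net, u=np.zeros(2))
        s = initial_state(net)
        s.p = np.array([0.5, 0.0])
        gamma = recruitment_fraction(s, params)
        # g = 0.4, w = 1.2, p = 0.5 -> 0.4 * (1 - 0.6) = 0.16
        assert gamma[0] == pytest.approx(0.16)

    def test_clamped_at_zero(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.p[:] = 10.0
        assert (recruitment_fraction(s, params) == 0).all()


class TestDerivatives:
    def test_zero_state_absorbing(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.p[:] = 0.0
        s.a[:] = 0.0
        s.R[:] = 0.0
        s.alpha[:] = 0.0
        dp, da, dR, dal = derivatives(s, params, tiny_net, adaptive=True)
        assert not any(x.any() for x in (dp, da, dR, dal))

    def test_equal_rewards_replicator_fixed_point(self, pair_net):
        params = make_params(pair_net)
        s = initial_state(pair_net)
        s.R[:] = 0.3
        _, _, _, dal = derivatives(s, params, pair_net, adaptive=True)
        assert np.allclose(dal, 0.0)

    def test_effort_derivative_hand_example(self):
        # alpha = (0.5, 0.5), c=0.2, tau=1, b=0.4, G=2, R=(1,0) -> (+0.04, -0.04)
        net = BipartiteNetwork.from_matrix(np.ones((2, 2), dtype=int))
        params = make_params(net)
        s = initial_state(net)
        s.R = np.array([1.0, 0.0])
        _, _, _, dal = derivatives(s, params, net, adaptive=True)
        assert dal[0, 0] == pytest.approx(0.04)
        assert dal[1, 0] == pytest.approx(-0.04)

    def test_fixed_forager_alpha_frozen(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        _, _, _, dal = derivatives(s, params, tiny_net, adaptive=False)
        assert (dal == 0).all()

    def test_effort_conservation_identity(self, ec_ensemble):
        # sum_i dalpha_ij = 0 whenever sum_i alpha_ij = 1 (Eq. 4 identity)
        net = ec_ensemble[0]
        rng = np.random.default_rng(3)
        params = sample_params(net, rng=rng)
        s = initial_state(net)
        for _ in range(5):
            s.p = rng.uniform(0.01, 2, net.n_plants)
            s.a = rng.uniform(0.01, 2, net.n_animals)
            s.R = rng.uniform(0.0, 2, net.n_plants)
            raw = rng.uniform(0.1, 1, (net.n_plants, net.n_animals)) * net.incidence
            s.alpha = raw / raw.sum(axis=0, keepdims=True)
            _, _, _, dal = derivatives(s, params, net, adaptive=True)
            assert np.allclose(dal.sum(axis=0), 0.0, atol=1e-12)

    def test_nan_rejected(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.p[0] = np.nan
        with pytest.raises(ValueError, match="invalid state"):
            derivatives(s, params, tiny_net, adaptive=False)

    def test_negative_rejected(self, tiny_net):
        params = make_params(tiny_net)
        s = initial_state(tiny_net)
        s.a[0] = -0.5
        with pytest.raises(ValueError, match="invalid state"):
            derivatives(s, params, tiny_net, adaptive=False)

    def test_percapita_variant_differs(self, pair_net):
        params = make_params(pair_net)
        s = initial_state(pair_net)
        s.R = np.array([1.0, 0.2])
        s.p = np.array([0.5, 0.1])
        _, _, _, d1 = derivatives(s, params, pair_net, adaptive=True)
        _, _, _, d2 = derivatives(s, params, pair_net, adaptive=True, af_percapita_rewards=True)
        assert not np.allclose(d1, d2)
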