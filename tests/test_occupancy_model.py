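"""Model likelihood pieces, the Gibbs sampler, and diagnostics."""

import numpy as np
import pytest
from scipy.special import expit, logit

import msocc
from msocc.data import DetectionData
from msocc.occupancy_model import ModelConfig, SpeciesParams, _suff_stats

from conftest import pinned_config


def params_for(**kwargs):
    defaults = dict(u=0.0, a1=0.0, a2=0.0, v_yr1=0.0, v_yr2=0.0)
    defaults.update(kwargs)
    return SpeciesParams(**{k: np.atleast_1d(v) for k, v in defaults.items()})


class TestPsiMatrix:
    def test_null_parameters_give_half(self):
        psi = msocc.psi_matrix(params_for(), np.zeros(4), np.zeros(4))
        np.testing.assert_allclose(psi, 0.5)

    def test_direct_evaluation(self):
        psi = msocc.psi_matrix(
            params_for(u=0.5, a1=1.0, a2=-2.0), np.array([0.3]), np.array([0.1])
        )
        assert psi[0, 0] == pytest.approx(expit(0.6), abs=1e-9)
        assert psi[0, 0] == pytest.approx(0.64566, abs=1e-5)

    def test_monotone_in_width(self):
        width = np.linspace(-2, 2, 9)
        psi = msocc.psi_matrix(params_for(a1=1.5), width, np.zeros(9))
        assert (np.diff(psi[0]) > 0).all()

    def test_saturating_inverse_logit(self):
        psi = msocc.psi_matrix(params_for(u=1000.0), np.zeros(1), np.zeros(1))
        assert psi[0, 0] == 1.0


class TestDetectionProb:
    def test_year_flag_selects_parameter(self):
        p = msocc.detection_prob(
            params_for(v_yr1=-5.0, v_yr2=5.0), np.array([0, 1])
        )
        assert p[0, 0] == pytest.approx(0.00669, abs=1e-5)
        assert p[0, 1] == pytest.approx(1 - 0.00669, abs=1e-5)

    def test_direct_evaluation(self):
        p = msocc.detection_prob(params_for(v_yr2=1.5), np.array([1]))
        assert p[0, 0] == pytest.approx(0.81757, abs=1e-5)

    def test_zero_intercept_gives_half(self):
        p = msocc.detection_prob(params_for(), np.array([0]))
        assert p[0, 0] == 0.5

    def test_bad_flags_rejected(self):
        with pytest.raises(ValueError):
            msocc.detection_prob(params_for(), np.array([2]))


class TestConditionalZPosterior:
    def test_detection_forces_occupancy(self):
        assert msocc.conditional_z_posterior(0.3, [0.5, 0.5], [0, 1]) == 1.0

    def test_two_blank_replicates(self):
        assert msocc.conditional_z_posterior(0.5, [0.5, 0.5], [0, 0]) == pytest.approx(
            0.2, abs=1e-12
        )

    def test_certain_occupancy_survives_blanks(self):
        assert msocc.conditional_z_posterior(1.0, [0.9, 0.9], [0, 0]) == 1.0

    def test_more_blanks_lower_probability(self):
        probs = [
            msocc.conditional_z_posterior(0.6, [0.4] * k, [0] * k)
            for k in range(1, 7)
        ]
        assert (np.diff(probs) < 0).all()


class TestMarginalLoglik:
    def test_saturated_case_is_zero(self):
        data = DetectionData(
            y=np.ones((1, 2, 2), np.int8), year_flag=[1, 0]
        )
        ll = msocc.marginal_loglik(params_for(u=1000, v_yr1=1000, v_yr2=1000), data)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_detection_under_zero_psi_is_impossible(self):
        y = np.zeros((1, 1, 2), np.int8)
        y[0, 0, 0] = 1
        data = DetectionData(y=y, year_flag=[0, 0])
        assert msocc.marginal_loglik(params_for(u=-1000), data) == -np.inf

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_enumeration(self, seed):
        """Marginal likelihood equals the explicit sum over latent states."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, (2, 3, 2)).astype(np.int8)
        if seed % 2:
            y[0, 1, 0] = -1  # exercise a missing replicate
        data = DetectionData(
            y=y, year_flag=[1, 0],
            width=rng.normal(size=3), distance=rng.normal(size=3),
        )
        params = SpeciesParams(
            *[rng.normal(size=2) for _ in range(5)]
        )
        psi = msocc.psi_matrix(params, data.width, data.distance)
        p = msocc.detection_prob(params, data.year_flag)
        brute = 0.0
        for i in range(2):
            for j in range(3):
                cell = 0.0
                for z in (0, 1):
                    lik = psi[i, j] if z else 1 - psi[i, j]
                    for k in range(2):
                        if y[i, j, k] == -1:
                            continue
                        pk = p[i, k] * z
                        lik *= pk if y[i, j, k] == 1 else 1 - pk
                    cell += lik
                brute += np.log(cell)
        assert msocc.marginal_loglik(params, data) == pytest.approx(
            brute, abs=1e-9
        )


class TestSampler:
    def test_detected_cells_always_occupied(self, small_dataset):
        config = ModelConfig(n_chains=2, n_iter=400, burn_in=100, thin=5, seed=0)
        samples = msocc.sample_posterior(small_dataset.detections, config)
        detected = small_dataset.detections.detected_anywhere()
        assert (samples.z[:, :, detected] == 1).all()

    def test_identical_seeds_identical_draws(self, small_dataset):
        config = ModelConfig(n_chains=2, n_iter=300, burn_in=100, thin=2, seed=5)
        a = msocc.sample_posterior(small_dataset.detections, config)
        b = msocc.sample_posterior(small_dataset.detections, config)
        for fam in a.params:
            np.testing.assert_array_equal(a.params[fam], b.params[fam])
        np.testing.assert_array_equal(a.z, b.z)

    def test_z_frequency_matches_full_conditional(self):
        """With parameters pinned, latent-state draws are iid from the
        exact conditional, so empirical frequencies must match it."""
        rng = np.random.default_rng(8)
        y = np.zeros((2, 3, 4), np.int8)
        y[0, 0, 1] = 1  # one detected cell
        width = rng.normal(size=3)
        distance = rng.normal(size=3)
        data = DetectionData(
            y=y, year_flag=[1, 1, 0, 0], width=width, distance=distance
        )
        u0, a10, a20 = 0.4, 0.8, -0.6
        v1, v2 = logit(0.3), logit(0.5)
        n_draws = 4000
        config = pinned_config(
            u=u0, a1=a10, a2=a20,
            v1=np.full(2, v1), v2=np.full(2, v2),
            n_chains=1, n_iter=n_draws + 1, burn_in=1, thin=1, seed=2,
        )
        samples = msocc.sample_posterior(data, config)
        freq = samples.z.mean(axis=(0, 1))
        params = SpeciesParams(
            u=np.full(2, u0), a1=np.full(2, a10), a2=np.full(2, a20),
            v_yr1=np.full(2, v1), v_yr2=np.full(2, v2),
        )
        psi = msocc.psi_matrix(params, width, distance)
        p = msocc.detection_prob(params, data.year_flag)
        for i in range(2):
            for j in range(3):
                expected = msocc.conditional_z_posterior(
                    psi[i, j], p[i], y[i, j]
                )
                se = np.sqrt(max(expected * (1 - expected), 1e-12) / n_draws)
                assert abs(freq[i, j] - expected) <= 3 * se + 1e-6

    def test_posterior_matches_grid_integration(self):
        """Single species, known detection, spike-free prior on the
        intercept: the sampler must agree with numerical integration of
        the marginal likelihood over a fine grid."""
        p_true = 0.4
        ds = msocc.generate_dataset(
            msocc.CommunityHyperparams(
                mu_u=0.4, sigma_u=0, mu_a1=0, sigma_a1=0, mu_a2=0, sigma_a2=0,
                mu_v1=float(logit(p_true)), sigma_v1=0,
                mu_v2=float(logit(p_true)), sigma_v2=0,
            ),
            n_species=1, n_sites=50, seed=12,
        )
        data = DetectionData(
            y=ds.detections.y, year_flag=ds.detections.year_flag,
            width=np.zeros(50), distance=np.zeros(50),
        )
        prior_sd = 2.0
        config = msocc.ModelConfig(
            n_chains=2, n_iter=8000, burn_in=2000, thin=5, seed=3,
            fixed_hypers={
                "u": (0.0, prior_sd), "a1": (0.0, 1e-6), "a2": (0.0, 1e-6)
            },
            fixed_detection=(np.array([logit(p_true)]), np.array([logit(p_true)])),
        )
        samples = msocc.sample_posterior(data, config)
        psi_hat = msocc.occupancy_probability_matrix(samples, "marginal").iloc[0, 0]

        grid = np.linspace(-10, 10, 4001)
        log_post = np.array(
            [
                msocc.marginal_loglik(
                    SpeciesParams(
                        u=[g], a1=[0.0], a2=[0.0],
                        v_yr1=[logit(p_true)], v_yr2=[logit(p_true)],
                    ),
                    data,
                )
                - 0.5 * (g / prior_sd) ** 2
                for g in grid
            ]
        )
        w = np.exp(log_post - log_post.max())
        psi_grid = float(np.sum(expit(grid) * w) / np.sum(w))
        assert abs(psi_hat - psi_grid) < 0.05

    def test_all_missing_rejected(self):
        data = DetectionData(y=np.full((1, 2, 2), -1, np.int8), year_flag=[1, 0])
        with pytest.raises(ValueError, match="missing"):
            msocc.sample_posterior(data, ModelConfig(n_iter=100, burn_in=10, seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ModelConfig(thin=0)
        with pytest.raises(ValueError, match="unknown hyper"):
            ModelConfig(fixed_hypers={"nope": (0, 1)})

    def test_draw_count_contract(self):
        config = ModelConfig(n_chains=2, n_iter=30_000, burn_in=5_000, thin=25)
        assert config.n_draws == 1000

    def test_missing_replicates_are_ignored(self):
        """Padding a dataset with all-missing replicates changes nothing."""
        ds = msocc.generate_dataset(n_species=3, n_sites=6, seed=1)
        y_pad = np.concatenate(
            [ds.detections.y, np.full((3, 6, 2), -1, np.int8)], axis=2
        )
        padded = DetectionData(
            y=y_pad,
            year_flag=list(ds.detections.year_flag) + [1, 0],
            width=ds.detections.width, distance=ds.detections.distance,
        )
        config = ModelConfig(n_chains=2, n_iter=400, burn_in=100, thin=5, seed=9)
        a = msocc.sample_posterior(ds.detections, config)
        b = msocc.sample_posterior(padded, config)
        np.testing.assert_array_equal(a.params["u"], b.params["u"])
        np.testing.assert_array_equal(a.z, b.z)


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        r = msocc.rhat(rng.standard_normal((4, 5000)))
        assert 0.99 <= r <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 5.0
        assert msocc.rhat(chains) > 1.5

    def test_constant_chains_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(msocc.rhat(np.ones((2, 100))))

    def test_agrees_with_arviz(self):
        """Independent cross-check against the reference implementation."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 2000))
        def az_rhat(c):
            return float(az.rhat(az.convert_to_dataset(c[:, :, None]))["x"].item())

        ours = msocc.rhat(chains)
        assert abs(ours - az_rhat(chains)) < 0.01
        chains[0] += 4.0
        assert msocc.rhat(chains) > 1.3
        assert az_rhat(chains) > 1.3

    def test_convergence_report_covers_monitored_parameters(self, small_dataset):
        config = ModelConfig(n_chains=2, n_iter=600, burn_in=100, thin=5, seed=4)
        samples = msocc.sample_posterior(small_dataset.detections, config)
        report = msocc.convergence_report(samples)
        n_species = small_dataset.detections.n_species
        assert len(report) == 5 * n_species + 10
        assert {"parameter", "rhat", "flagged"} <= set(report.columns)


class TestOccupancyProbabilityMatrix:
    def test_detected_cell_is_certain(self, small_dataset):
        config = ModelConfig(n_chains=2, n_iter=400, burn_in=100, thin=5, seed=0)
        samples = msocc.sample_posterior(small_dataset.detections, config)
        P = msocc.occupancy_probability_matrix(samples, "conditional")
        detected = small_dataset.detections.detected_anywhere()
        assert (P.to_numpy()[detected] == 1.0).all()
        assert ((P.to_numpy() >= 0) & (P.to_numpy() <= 1)).all()

    def test_mean_of_draws(self, small_dataset):
        config = ModelConfig(n_chains=1, n_iter=60, burn_in=20, thin=10, seed=0)
        samples = msocc.sample_posterior(small_dataset.detections, config)
        P = msocc.occupancy_probability_matrix(samples, "conditional")
        np.testing.assert_allclose(
            P.to_numpy(), samples.z.mean(axis=(0, 1))
        )

    def test_unknown_mode_rejected(self, small_dataset):
        config = ModelConfig(n_chains=1, n_iter=60, burn_in=20, thin=10, seed=0)
        samples = msocc.sample_posterior(small_dataset.detections, config)
        with pytest.raises(ValueError):
            msocc.occupancy_probability_matrix(samples, "expected")


def test_suff_stats_split_by_year_group(toy_detection_data):
    st = _suff_stats(toy_detection_data)
    y = toy_detection_data.y
    # flag layout [1, 0]: replicate 0 belongs to group 1, replicate 1 to group 0
    np.testing.assert_array_equal(st["ntr1"], (y[:, :, 0] >= 0).astype(float))
    np.testing.assert_array_equal(st["det0"], (y[:, :, 1] == 1).astype(float))
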