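import math

import numpy as np
import pytest
from scipy.stats import lognorm

from adipowaves.distributions import make_log_grid
from adipowaves.evidence import (
    DEFAULT_ZERO_FLOOR,
    PriorSpec,
    PtConfig,
    accurate_pt_config,
    binwise_evidence_pt,
    binwise_evidence_quadrature,
    evidence_for_models,
    lognormal_loglik,
    model_evidence,
    prepare_observations,
)
from adipowaves.model_space import assign_bins, enumerate_models, null_model
from adipowaves.synthetic import GeneratorConfig, biopsy_schedule, sample_dataset

#: quick-but-valid settings for structure-level tests
TINY_PT = PtConfig(
    beta_ladder=(0.0, *np.geomspace(1e-5, 1.0, 10)),
    n_equilibration=300,
    n_samples=200,
    sampling_step_fraction=0.3,
    seed=0,
)


def _fixture_observations(seed=0, n_groups=3, n_obs=4):
    rng = np.random.default_rng(seed)
    return [np.exp(rng.normal(1.0, 0.3, n_obs)) for _ in range(n_groups)]


class TestLognormalLoglik:
    def test_standard_lognormal_at_one(self):
        assert lognormal_loglik(1.0, 0.0, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_at_exp_of_mu(self):
        assert lognormal_loglik(math.e, 1.0, 1.0) == pytest.approx(
            -1.0 - 0.5 * math.log(2 * math.pi)
        )

    def test_matches_scipy_density(self):
        expected = lognorm(s=0.3, scale=math.exp(0.5)).logpdf(2.0)
        assert lognormal_loglik(2.0, 0.5, 0.3) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("y,sigma", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0)])
    def test_invalid_inputs_rejected(self, y, sigma):
        with pytest.raises(ValueError):
            lognormal_loglik(y, 0.0, sigma)


class TestPrepareObservations:
    def test_null_model_pools_every_measurement(self):
        cfg = GeneratorConfig(grid=make_log_grid(5), seed=0)
        ds, _ = sample_dataset(cfg)
        groups = prepare_observations(ds, null_model(ds.days), cell_bin=2)
        assert len(groups) == 1 and len(groups[0]) == 64

    def test_best_56_day_model_group_sizes(self):
        # the printed assignment groups the 16 days as {0,162},{2,6,57},
        # {9,13,69},{23,134},{86,141},{33,150},{98,156}; 4 replicates each
        cfg = GeneratorConfig(grid=make_log_grid(5), seed=0)
        ds, _ = sample_dataset(cfg)
        models = [
            m
            for m in enumerate_models(ds.days).models
            if m.n_bins == 7 and m.assignment == assign_bins(ds.days, 7, 8, 7)
        ]
        groups = prepare_observations(ds, models[0], cell_bin=0)
        assert [len(g) for g in groups] == [8, 12, 12, 8, 8, 8, 8]

    def test_zero_values_floored_at_half_a_particle(self):
        cfg = GeneratorConfig(grid=make_log_grid(40), seed=1,
                              particles_per_measurement=50)
        ds, _ = sample_dataset(cfg)
        mat = ds.values_matrix()
        zero_bins = np.where((mat == 0).any(axis=0))[0]
        assert zero_bins.size, "fixture should contain empty bins"
        groups = prepare_observations(ds, null_model(ds.days), int(zero_bins[0]))
        assert DEFAULT_ZERO_FLOOR == pytest.approx(100 * 0.5 / 6000)
        assert min(groups[0]) == pytest.approx(DEFAULT_ZERO_FLOOR)


class TestQuadrature:
    def test_empty_group_has_unit_evidence(self):
        assert binwise_evidence_quadrature([np.array([])]) == 0.0

    def test_grid_refinement_self_consistency(self):
        obs = [np.array([2.5])]
        a = binwise_evidence_quadrature(obs, tol=1e-4)
        b = binwise_evidence_quadrature(obs, tol=1e-6)
        assert a == pytest.approx(b, abs=2e-4)

    def test_agrees_with_naive_monte_carlo(self):
        # importance-sample the evidence with 1e6 draws from the prior and
        # require agreement within three standard errors
        obs = _fixture_observations(seed=5, n_groups=1, n_obs=5)
        priors = PriorSpec()
        rng = np.random.default_rng(123)
        N = 1_000_000
        mu = rng.uniform(priors.mu_low, priors.mu_high, N)
        sigma = np.exp(
            rng.uniform(np.log(priors.sigma_low), np.log(priors.sigma_high), N)
        )
        ll = np.zeros(N)
        for y in obs[0]:
            ll += lognormal_loglik(float(y), mu, sigma)
        mx = ll.max()
        w = np.exp(ll - mx)
        logZ_mc = mx + np.log(w.mean())
        se = w.std() / (w.mean() * math.sqrt(N))
        assert binwise_evidence_quadrature(obs, priors) == pytest.approx(
            logZ_mc, abs=max(3 * se, 1e-3)
        )


class TestParallelTempering:
    def test_same_seed_gives_identical_evidence(self):
        obs = _fixture_observations()
        z1, _ = binwise_evidence_pt(obs, pt=TINY_PT)
        z2, _ = binwise_evidence_pt(obs, pt=TINY_PT)
        assert z1 == z2

    def test_matches_quadrature_oracle_on_small_fixture(self):
        obs = _fixture_observations(seed=17)
        q = binwise_evidence_quadrature(obs)
        z, _ = binwise_evidence_pt(obs, pt=accurate_pt_config(seed=17))
        assert z == pytest.approx(q, abs=0.1)

    def test_single_temperature_ladder_flagged_biased(self):
        obs = _fixture_observations()
        _, diag = binwise_evidence_pt(
            obs,
            pt=PtConfig(beta_ladder=(1.0,), n_equilibration=100, n_samples=100),
        )
        assert any("biased" in w for w in diag["warnings"])

    def test_duplication_moves_evidence_in_oracle_direction(self):
        obs = _fixture_observations(seed=3)
        dup = [np.concatenate([g, g]) for g in obs]
        dq = binwise_evidence_quadrature(dup) - binwise_evidence_quadrature(obs)
        pt = PtConfig(
            beta_ladder=(0.0, *np.geomspace(1e-7, 1.0, 64)),
            n_equilibration=4000, n_samples=4000,
            sampling_step_fraction=0.3, seed=3,
        )
        dz = binwise_evidence_pt(dup, pt=pt)[0] - binwise_evidence_pt(obs, pt=pt)[0]
        assert math.copysign(1, dz) == math.copysign(1, dq)
        assert abs(dq) > 1.0  # the effect is far above Monte Carlo noise

    def test_negative_observations_rejected(self):
        with pytest.raises(ValueError):
            binwise_evidence_pt([np.array([1.0, -2.0])], pt=TINY_PT)


class TestGroupingIdentity:
    def test_fixed_parameter_likelihood_independent_of_grouping(self):
        # with shared (mu, sigma), summing log-densities over any grouping of
        # the same observations gives the same total
        cfg = GeneratorConfig(grid=make_log_grid(5), seed=2)
        ds, _ = sample_dataset(cfg)
        periodic = enumerate_models(ds.days).models[0]
        mu, sigma = 1.3, 0.4
        null_groups = prepare_observations(ds, null_model(ds.days), 1)
        periodic_groups = prepare_observations(ds, periodic, 1)
        total_null = sum(
            lognormal_loglik(float(y), mu, sigma) for g in null_groups for y in g
        )
        total_periodic = sum(
            lognormal_loglik(float(y), mu, sigma) for g in periodic_groups for y in g
        )
        assert total_null == pytest.approx(total_periodic, rel=1e-12)


class TestModelEvidence:
    def test_all_but_one_cell_bin_included(self):
        cfg = GeneratorConfig(grid=make_log_grid(10), seed=0)
        ds, _ = sample_dataset(cfg)
        res = model_evidence(ds, null_model(ds.days), pt=TINY_PT)
        assert len(res.per_bin_logZ) == 9
        assert res.excluded_bin == 9
        assert res.total_logZ == pytest.approx(res.per_bin_logZ.sum())

    def test_two_bin_grid_gives_single_term(self):
        cfg = GeneratorConfig(grid=make_log_grid(2), seed=0)
        ds, _ = sample_dataset(cfg)
        res = model_evidence(ds, null_model(ds.days), pt=TINY_PT)
        assert len(res.per_bin_logZ) == 1

    def test_excluded_bin_choice_changes_total(self):
        cfg = GeneratorConfig(grid=make_log_grid(10), seed=0)
        ds, _ = sample_dataset(cfg)
        nm = null_model(ds.days)
        a = model_evidence(ds, nm, pt=TINY_PT, excluded_bin=0)
        b = model_evidence(ds, nm, pt=TINY_PT, excluded_bin=9)
        assert a.total_logZ != b.total_logZ

    def test_batch_scoring_covers_every_model(self):
        cfg = GeneratorConfig(grid=make_log_grid(5), seed=0)
        ds, _ = sample_dataset(cfg)
        models = enumerate_models(ds.days).models[:6] + [null_model(ds.days)]
        res = evidence_for_models(ds, models, pt=TINY_PT)
        assert [r.model for r in res] == models
        assert all(np.isfinite(r.total_logZ) for r in res)
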