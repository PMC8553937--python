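"""Likelihood correctness (against a brute-force oracle) and sampler behavior."""

import numpy as np
import pytest
from scipy import stats

from catiam.model import (
    McmcConfig,
    ModelConfig,
    SiteArrays,
    fit_iam,
    log_joint,
    summarize,
)
from catiam.preprocessing import SiteData
from catiam.synthetic import TruthConfig, simulate_sites


def brute_force_log_joint(params, sites, config):
    """Independent term-by-term reference: sums scipy log-densities.

    Written against the model description only; shares no code with
    ``log_joint``.
    """
    mu = params["mu"]
    beta = np.atleast_1d(np.asarray(params.get("beta", ()), dtype=float))
    sigma = params["sigma"]
    lam = np.asarray(params["lam"], dtype=float)
    z = np.asarray(params["z"], dtype=float)

    lp = stats.norm.logpdf(mu, 0, config.mu_sd)
    for b in beta:
        lp += stats.uniform.logpdf(b, -config.beta_bound, 2 * config.beta_bound)
    for m in (params["m_survey"], params["m_report"]):
        lp += stats.uniform.logpdf(m, 0, config.m_upper)
    lp += stats.uniform.logpdf(sigma, 0, config.sigma_upper)
    # p, omega ~ U(0,1): log density 0 inside support
    for i, s in enumerate(sites):
        x = np.array([s.covariates[n] for n in config.covariate_names])
        pred = mu + float(x @ beta) if beta.size else mu
        lp += stats.norm.logpdf(np.log(lam[i]), pred, sigma)
        lp += stats.bernoulli.logpmf(int(z[i]), params["omega"])
        N = z[i] * lam[i]
        for v in s.y:
            lp += stats.poisson.logpmf(round(v), N * params["p_survey"] + params["m_survey"])
        for v in s.u:
            lp += stats.poisson.logpmf(round(v), N * params["p_report"] + params["m_report"])
        if s.w is not None:
            lp += stats.poisson.logpmf(s.w, N)
    return float(lp)


def _random_instance(rng):
    """A random 3-site instance with all data configurations present."""
    config = ModelConfig(covariate_names=("imd", "popdens"))
    sites, lam, z = [], [], []
    for i in range(3):
        zi = int(rng.random() < 0.7) if i == 2 else 1
        w = None
        occ = "unknown"
        if i == 0:
            w = int(rng.poisson(3.0)) + 1
            occ = "present"
            zi = 1
        elif i == 1 and rng.random() < 0.5:
            w, occ, zi = 0, "absent", 0
        sites.append(
            SiteData(
                site_id=i,
                y=rng.poisson(2.0, size=rng.integers(1, 4)).astype(float),
                u=rng.poisson(1.0, size=rng.integers(0, 3)).astype(float),
                w=w,
                expert_occupancy=occ,
                covariates={"imd": float(rng.integers(1, 11)), "popdens": float(rng.normal())},
            )
        )
        lam.append(rng.lognormal(0.5, 0.8))
        z.append(zi)
    params = {
        "mu": rng.normal(0, 2),
        "beta": rng.uniform(-1, 1, size=2),
        "sigma": rng.uniform(0.2, 2.5),
        "p_survey": rng.uniform(0.05, 0.95),
        "p_report": rng.uniform(0.05, 0.95),
        "m_survey": rng.uniform(0.1, 4.5),
        "m_report": rng.uniform(0.1, 4.5),
        "omega": rng.uniform(0.1, 0.9),
        "lam": np.array(lam),
        "z": np.array(z, dtype=float),
    }
    return params, sites, config


class TestLogJoint:
    def test_single_poisson_term_closed_form(self):
        """Adding one y=1 observation at mean 1 changes the log joint by
        log Poisson(1; 1) = -1."""
        config = ModelConfig()
        common = dict(mu=0.5, beta=(), sigma=1.0, p_survey=0.5, p_report=0.3,
                      m_survey=0.0, m_report=0.5, omega=0.9,
                      lam=np.array([2.0]), z=np.array([1.0]))
        with_y = [SiteData(site_id=0, y=np.array([1.0]), u=np.array([]))]
        without_y = [SiteData(site_id=0, y=np.array([]), u=np.array([]))]
        delta = log_joint(common, with_y, config) - log_joint(common, without_y, config)
        assert delta == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            params, sites, config = _random_instance(rng)
            assert log_joint(params, sites, config) == pytest.approx(
                brute_force_log_joint(params, sites, config), abs=1e-10
            )

    def test_positive_expert_count_at_unoccupied_site_impossible(self):
        config = ModelConfig()
        sites = [SiteData(site_id=0, y=np.array([1.0]), u=np.array([]), w=2,
                          expert_occupancy="present")]
        params = dict(mu=0.0, beta=(), sigma=1.0, p_survey=0.5, p_report=0.5,
                      m_survey=1.0, m_report=1.0, omega=0.5,
                      lam=np.array([2.0]), z=np.array([0.0]))
        assert log_joint(params, sites, config) == -np.inf

    def test_outside_prior_support(self):
        config = ModelConfig()
        sites = [SiteData(site_id=0, y=np.array([1.0]), u=np.array([]))]
        base = dict(mu=0.0, beta=(), sigma=1.0, p_survey=0.5, p_report=0.5,
                    m_survey=1.0, m_report=1.0, omega=0.5,
                    lam=np.array([2.0]), z=np.array([1.0]))
        for key, bad in [("p_survey", 1.2), ("m_survey", 6.0), ("sigma", 3.5), ("omega", -0.1)]:
            assert log_joint({**base, key: bad}, sites, config) == -np.inf

    def test_nan_covariate_rejected(self):
        config = ModelConfig(covariate_names=("imd",))
        sites = [SiteData(site_id=0, y=np.array([1.0]), u=np.array([]),
                          covariates={"imd": float("nan")})]
        with pytest.raises(ValueError):
            SiteArrays(sites, config)

    def test_likelihood_modes_agree_on_integer_data(self):
        rng = np.random.default_rng(5)
        params, sites, _ = _random_instance(rng)
        a = log_joint(params, sites, ModelConfig(covariate_names=("imd", "popdens")))
        b = log_joint(
            params, sites,
            ModelConfig(covariate_names=("imd", "popdens"), likelihood_mode="continuous_gamma"),
        )
        assert a == pytest.approx(b, abs=1e-10)


class TestSummarize:
    def test_constant_draws(self):
        assert summarize(np.full(2000, 3.5)) == (3.5, 3.5, 3.5)

    def test_normal_quantiles(self, rng):
        draws = rng.standard_normal(10_000)
        mean, lo, hi = summarize(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_mean_is_arithmetic_average(self, rng):
        draws = rng.uniform(size=1500)
        assert summarize(draws)[0] == draws.mean()

    def test_unknown_parameter_rejected(self):
        data = simulate_sites(TruthConfig(n_sites=6, seed=1, beta=(), covariate_names=()))
        cfg = McmcConfig(n_chains=2, n_iterations=2_200, burn_in=1_100, seed=0)
        draws = fit_iam(data.sites, ModelConfig(), cfg)
        with pytest.raises(KeyError):
            summarize(draws, "nonexistent")


def _quick_fit(sites, names=(), seed=0, iters=3_000, burn=1_800):
    return fit_iam(
        sites,
        ModelConfig(covariate_names=names),
        McmcConfig(n_chains=2, n_iterations=iters, burn_in=burn, seed=seed),
    )


class TestSampler:
    def test_seeded_determinism(self):
        data = simulate_sites(TruthConfig(n_sites=8, seed=2, beta=(), covariate_names=()))
        a = _quick_fit(data.sites, seed=11)
        b = _quick_fit(data.sites, seed=11)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_expert_anchoring_poisson_conjugacy(self):
        """With detection ~1, negligible misidentification and expert counts
        everywhere, site intensities track the expert counts."""
        cfg = TruthConfig(
            n_sites=30, mu=1.5, sigma=0.5, beta=(), covariate_names=(),
            omega=1.0, p_survey=0.98, p_report=0.98, m_survey=0.02, m_report=0.02,
            expert_coverage=1.0, replicates_survey=(1, 1), replicates_report=(1, 1),
            seed=21,
        )
        data = simulate_sites(cfg)
        draws = _quick_fit(data.sites, seed=3)
        lam = draws.stacked("lam")
        w = np.array([s.w for s in data.sites], dtype=float)
        post_mean, post_sd = lam.mean(axis=0), lam.std(axis=0)
        within = np.abs(post_mean - w) <= 3 * post_sd + 0.5
        assert within.mean() >= 0.9
        assert stats.spearmanr(post_mean, w).statistic > 0.6

    def test_null_model_sigma_calibration(self):
        """95% CRIs for sigma cover the generating value in >= 90% of
        seeded covariate-free replicates."""
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = TruthConfig(n_sites=60, mu=1.8, sigma=0.8, beta=(), covariate_names=(),
                              omega=0.85, seed=100 + rep)
            data = simulate_sites(cfg)
            draws = _quick_fit(data.sites, seed=rep)
            _, lo, hi = summarize(draws, "sigma")
            covered += int(lo <= 0.8 <= hi)
        assert covered >= 0.9 * n_rep

    def test_prior_recovered_without_data(self):
        """With empty count data the sampler must reproduce the priors:
        detection draws are U(0,1) by Kolmogorov-Smirnov at alpha=0.01."""
        sites = [SiteData(site_id=i, y=np.empty(0), u=np.empty(0)) for i in range(2)]
        draws = fit_iam(
            sites,
            ModelConfig(),
            McmcConfig(n_chains=2, n_iterations=60_000, burn_in=10_000, thin=10, seed=4),
        )
        vals = draws.stacked("p_survey")
        assert vals.size == 10_000
        assert stats.kstest(vals, "uniform").pvalue > 0.01

    def test_removing_expert_data_inflates_detection_uncertainty(self):
        data = simulate_sites(TruthConfig(n_sites=50, seed=6, beta=(), covariate_names=(),
                                          sigma=0.8, expert_coverage=0.8))
        with_exp = _quick_fit(data.sites, seed=1)
        stripped = [
            SiteData(site_id=s.site_id, y=s.y, u=s.u, w=None, expert_occupancy="unknown",
                     covariates=dict(s.covariates), study_area=s.study_area)
            for s in data.sites
        ]
        without_exp = _quick_fit(stripped, seed=1)
        sd_with = with_exp.stacked("p_survey").std()
        sd_without = without_exp.stacked("p_survey").std()
        assert sd_without > 0.9 * sd_with  # never deflates beyond MC error

    def test_fixed_occupancy_never_changes(self):
        data = simulate_sites(TruthConfig(n_sites=20, seed=13, beta=(), covariate_names=(),
                                          expert_coverage=0.7))
        draws = _quick_fit(data.sites, seed=2)
        z = draws.stacked("z")
        for i, s in enumerate(data.sites):
            if s.expert_occupancy == "present":
                assert (z[:, i] == 1).all()
            elif s.expert_occupancy == "absent":
                assert (z[:, i] == 0).all()

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            fit_iam([SiteData(site_id=0, y=np.array([1.0]), u=np.empty(0))],
                    ModelConfig(), McmcConfig.reduced())

    def test_self_consistent_calibration_including_occupancy(self):
        """When expert presence/absence labels reflect the true occupancy
        (the inference model's own assumption), credible intervals are
        calibrated for omega and sigma too — isolating the bias of
        labelling occupied-but-empty-looking sites as absences."""
        hits = {"omega": 0, "sigma": 0, "mu": 0}
        n_rep = 8
        for rep in range(n_rep):
            cfg = TruthConfig(n_sites=80, mu=2.0, sigma=1.0, beta=(), covariate_names=(),
                              omega=0.8, expert_coverage=0.6, seed=300 + rep)
            data = simulate_sites(cfg)
            for i, s in enumerate(data.sites):
                if s.w is not None:
                    s.expert_occupancy = "present" if data.z[i] == 1 else "absent"
            draws = _quick_fit(data.sites, seed=rep)
            for name, truth in (("omega", 0.8), ("sigma", 1.0), ("mu", 2.0)):
                _, lo, hi = summarize(draws, name)
                hits[name] += int(lo <= truth <= hi)
        for name, h in hits.items():
            assert h >= n_rep - 2, f"{name} covered only {h}/{n_rep}"


class TestMcmcConfig:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=1_000, burn_in=1_000)

    def test_minimum_retained_draws(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=1_500, burn_in=1_000)

    def test_long_preset_retains_ten_thousand(self):
        cfg = McmcConfig.long()
        assert cfg.retained_per_chain == 10_000
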