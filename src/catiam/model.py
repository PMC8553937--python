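"""The Integrated Abundance Model (IAM) and its MCMC sampler.

Model
-----
Each site ``i`` holds a latent true abundance ``N_i = z_i * lambda_i``:
``z_i ~ Bernoulli(omega)`` is occupancy and ``lambda_i`` a positive
intensity with ``log lambda_i = mu + sum_j beta_j x_ij + eps_i``,
``eps_i ~ N(0, sigma^2)``.  Observations:

* survey replicates   ``y_ij ~ Poisson(N_i * p_survey + m_survey)``
* report replicates   ``u_ij ~ Poisson(N_i * p_report + m_report)``
* expert consensus    ``w_i  ~ Poisson(N_i)``  (subset of sites)

``p`` is the per-replicate detection probability of a truly present
unowned cat and ``m`` the expected number of owned cats misidentified as
unowned per replicate (a false-positive rate).  Expert data are treated
as exact at the presence/absence level, so where an expert consensus
exists ``z_i`` is fixed (present => 1, confirmed absence => 0).

Priors: p, omega ~ U(0,1); m ~ U(0,5); mu ~ N(0, 10^2); sigma ~ U(0,3);
beta_j ~ U(-5,5) (bound configurable for prior-sensitivity runs).

Sampler
-------
Adaptive Metropolis-within-Gibbs.  Because the replicate means are
constant within a site, the Poisson log-likelihood reduces to per-site
sufficient statistics (sum and count of replicates), making every full
likelihood evaluation O(n_sites).  mu and beta have exact conjugate
(truncated-)normal full conditionals given the site log-intensities and
are Gibbs-sampled — this matters because mu and the mean log-intensity
are nearly collinear and pure random-walk updates of mu mix poorly.
omega is Beta-conjugate given z.  p, m and sigma use adaptive random
walks on logit-transformed scales; the site log-intensities use a
vectorized per-site random walk (sites are conditionally independent);
free z_i are Gibbs-sampled from their Bernoulli full conditional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from catiam.preprocessing import SiteData

logger = logging.getLogger(__name__)

_LOGIT_PARAMS = ("p_survey", "p_report", "m_survey", "m_report", "sigma")


@dataclass(frozen=True)
class ModelConfig:
    """Structural and prior configuration of the IAM.

    ``covariate_names`` empty means the null (random-effects only) model.
    ``likelihood_mode`` controls how half-integer survey midpoints (1.5,
    3.5) enter the Poisson likelihood: ``round_half_up`` rounds them to
    the nearest integer for a proper pmf; ``continuous_gamma`` evaluates
    the Poisson density with the factorial replaced by the gamma
    function.
    """

    covariate_names: tuple[str, ...] = ()
    beta_bound: float = 5.0
    m_upper: float = 5.0
    sigma_upper: float = 3.0
    mu_sd: float = 10.0
    likelihood_mode: str = "round_half_up"

    def __post_init__(self) -> None:
        if self.likelihood_mode not in ("round_half_up", "continuous_gamma"):
            raise ValueError(f"bad likelihood_mode {self.likelihood_mode!r}")
        for name in ("beta_bound", "m_upper", "sigma_upper", "mu_sd"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run lengths and adaptation settings."""

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.retained_per_chain < 1_000:
            raise ValueError("need >= 1,000 retained draws per chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0) -> "McmcConfig":
        """Desk-scale preset used for the simulation-recovery battery."""
        return cls(n_chains=3, n_iterations=4_000, burn_in=2_000, seed=seed)

    @classmethod
    def long(cls, seed: int = 0) -> "McmcConfig":
        """Long thinned preset (used for slower-converging covariates,
        e.g. UK-adjusted deprivation quintiles)."""
        return cls(n_chains=3, n_iterations=100_000, burn_in=60_000, thin=4, seed=seed)


class SiteArrays:
    """Per-site sufficient statistics packed for vectorized likelihoods."""

    def __init__(self, sites: Sequence[SiteData], config: ModelConfig):
        n = len(sites)
        if n < 1:
            raise ValueError("no sites")
        self.n_sites = n
        self.site_ids = np.array([s.site_id for s in sites])
        self.study_area = np.array([s.study_area for s in sites])

        def process(vals: np.ndarray) -> np.ndarray:
            if config.likelihood_mode == "round_half_up":
                return np.floor(vals + 0.5)
            return vals

        self.S_y = np.array([process(s.y).sum() for s in sites])
        self.J_y = np.array([s.y.size for s in sites], dtype=float)
        self.S_u = np.array([process(s.u).sum() for s in sites])
        self.J_u = np.array([s.u.size for s in sites], dtype=float)
        # parameter-independent pmf constants (for full log densities)
        self.const = -sum(
            special.gammaln(np.concatenate([process(s.y), process(s.u)]) + 1).sum()
            for s in sites
        )
        self.w = np.array([float(s.w) if s.w is not None else np.nan for s in sites])
        self.has_w = ~np.isnan(self.w)
        self.const += -special.gammaln(self.w[self.has_w] + 1).sum()
        # occupancy: 1 fixed present, 0 fixed absent, -1 free
        occ = np.full(n, -1, dtype=int)
        for i, s in enumerate(sites):
            if s.expert_occupancy == "present":
                occ[i] = 1
            elif s.expert_occupancy == "absent":
                occ[i] = 0
        self.occ_fixed = occ
        self.free = occ < 0

        k = len(config.covariate_names)
        self.X = np.zeros((n, k))
        for j, name in enumerate(config.covariate_names):
            try:
                self.X[:, j] = [s.covariates[name] for s in sites]
            except KeyError as exc:
                raise ValueError(f"covariate {name!r} missing at some site") from exc
        if not np.all(np.isfinite(self.X)):
            raise ValueError("NaN/inf covariate values")


def _citizen_ll(S: np.ndarray, J: np.ndarray, mean: np.ndarray) -> float:
    """sum_i [S_i log mean_i - J_i mean_i], with 0*log(0) := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(S > 0, S * np.log(mean), 0.0) - J * mean
    if np.any(np.isnan(term)) or np.any((S > 0) & (mean <= 0)):
        return -np.inf
    return float(term.sum())


class _State:
    __slots__ = ("mu", "beta", "sigma", "p_s", "p_r", "m_s", "m_r", "omega", "eta", "z")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def log_joint(
    params: Mapping[str, object], sites: Sequence[SiteData] | SiteArrays, config: ModelConfig
) -> float:
    """Log prior + log likelihood of the full IAM at one parameter point.

    ``params`` carries scalars ``mu, sigma, p_survey, p_report, m_survey,
    m_report, omega``, vector ``beta`` (one per configured covariate) and
    per-site vectors ``lam`` (> 0) and ``z`` (0/1).  The density for the
    site intensities is taken with respect to ``log lambda`` (the sampled
    scale).  Returns ``-inf`` outside the prior support or at impossible
    data events (e.g. a positive expert count at an unoccupied site).
    """
    arr = sites if isinstance(sites, SiteArrays) else SiteArrays(sites, config)
    mu = float(params["mu"])
    beta = np.atleast_1d(np.asarray(params.get("beta", ()), dtype=float))
    sigma = float(params["sigma"])
    p_s, p_r = float(params["p_survey"]), float(params["p_report"])
    m_s, m_r = float(params["m_survey"]), float(params["m_report"])
    omega = float(params["omega"])
    lam = np.asarray(params["lam"], dtype=float)
    z = np.asarray(params["z"], dtype=float)

    if beta.size != arr.X.shape[1]:
        raise ValueError("beta length must match configured covariates")
    # prior support
    if not (0.0 <= p_s <= 1.0 and 0.0 <= p_r <= 1.0 and 0.0 <= omega <= 1.0):
        return -np.inf
    if not (0.0 <= m_s <= config.m_upper and 0.0 <= m_r <= config.m_upper):
        return -np.inf
    if not 0.0 < sigma <= config.sigma_upper:
        return -np.inf
    if np.any(np.abs(beta) > config.beta_bound):
        return -np.inf
    if np.any(lam <= 0) or not set(np.unique(z)).issubset({0.0, 1.0}):
        return -np.inf

    eta = np.log(lam)
    pred = mu + arr.X @ beta
    lp = (
        -0.5 * (mu / config.mu_sd) ** 2
        - np.log(config.mu_sd * np.sqrt(2 * np.pi))
        - beta.size * np.log(2 * config.beta_bound)
        - 2 * np.log(config.m_upper)
        - np.log(config.sigma_upper)
    )
    lp += float(
        -0.5 * ((eta - pred) / sigma) ** 2 @ np.ones_like(eta)
        - eta.size * np.log(sigma * np.sqrt(2 * np.pi))
    )
    with np.errstate(divide="ignore"):
        lp += float(np.sum(np.where(z == 1.0, np.log(omega), np.log1p(-omega))))
    if np.isnan(lp):
        return -np.inf

    N = z * lam
    ll = _citizen_ll(arr.S_y, arr.J_y, N * p_s + m_s)
    ll += _citizen_ll(arr.S_u, arr.J_u, N * p_r + m_r)
    # expert: w_i ~ Poisson(N_i); w>0 with N=0 is impossible
    wN = N[arr.has_w]
    wv = arr.w[arr.has_w]
    if np.any((wv > 0) & (wN <= 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ll += float(np.sum(np.where(wv > 0, wv * np.log(wN), 0.0) - wN))
    ll += arr.const
    return lp + ll


class PosteriorDraws:
    """Retained MCMC draws of all IAM parameters.

    Scalar parameters (and each ``beta_<name>``) are arrays of shape
    ``(n_chains, n_draws)``; ``lam`` and ``z`` have shape
    ``(n_chains, n_draws, n_sites)``.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        covariate_names: tuple[str, ...],
        site_ids: np.ndarray,
        accept_rates: dict[str, float],
        rhat: dict[str, float],
        seed: int,
    ):
        self.params = params
        self.covariate_names = covariate_names
        self.site_ids = site_ids
        self.accept_rates = accept_rates
        self.rhat = rhat
        self.seed = seed

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and all(v < 1.1 for v in self.rhat.values())

    @property
    def scalar_names(self) -> list[str]:
        return [k for k, v in self.params.items() if v.ndim == 2]

    def stacked(self, name: str) -> np.ndarray:
        """All chains' retained draws of one parameter, flattened."""
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        v = self.params[name]
        return v.reshape(-1) if v.ndim == 2 else v.reshape(-1, v.shape[-1])

    def site_abundance(self) -> np.ndarray:
        """Per-draw true abundances N_i = z_i lambda_i, flattened over chains."""
        return self.stacked("lam") * self.stacked("z")

    def to_dataframe(self):
        """Tidy (chain, iteration, parameter, value) frame of scalar draws."""
        import pandas as pd

        rows = []
        for name in self.scalar_names:
            v = self.params[name]
            for c in range(v.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(v.shape[1]),
                            "parameter": name,
                            "value": v[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_inference_data(self):
        """Export scalar draws to an ArviZ InferenceData object."""
        import arviz as az

        return az.from_dict({k: self.params[k] for k in self.scalar_names})


def summarize(draws: "PosteriorDraws | np.ndarray", parameter: str | None = None):
    """Posterior mean and equal-tailed 95% credible interval.

    Accepts either a :class:`PosteriorDraws` plus a parameter name, or a
    plain draw array.  Returns ``(mean, lower_2.5%, upper_97.5%)``.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        arr = draws.stacked(parameter)
    else:
        arr = np.asarray(draws, dtype=float).reshape(-1)
    if arr.ndim != 1:
        raise ValueError("summarize expects scalar-parameter draws")
    lo, hi = np.quantile(arr, [0.025, 0.975])
    return float(arr.mean()), float(lo), float(hi)


def _trunc_norm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Draw from N(mean, sd) truncated to (lo, hi), robust in the tails."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    Fa, Fb = special.ndtr(a), special.ndtr(b)
    if Fb - Fa > 1e-12:
        u = rng.uniform(Fa, Fb)
        x = mean + sd * special.ndtri(u)
        return float(np.clip(x, lo, hi))
    from scipy.stats import truncnorm  # far-tail fallback

    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _init_state(arr: SiteArrays, cfg: ModelConfig, rng: np.random.Generator) -> _State:
    # overdispersed chains around crude data-informed values
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (arr.S_y + arr.S_u) / np.maximum(arr.J_y + arr.J_u, 1.0)
    crude = np.where(arr.has_w, np.nan_to_num(arr.w), pooled)
    eta = np.log(np.maximum(crude, 0.3)) + rng.normal(0.0, 1.0, size=arr.n_sites)
    k = arr.X.shape[1]
    beta = rng.uniform(-0.5, 0.5, size=k)
    mu = float(np.mean(eta - arr.X @ beta)) + rng.normal(0.0, 1.0)
    z = np.where(arr.occ_fixed >= 0, arr.occ_fixed, 1).astype(int)
    return _State(
        mu=mu,
        beta=beta,
        sigma=float(rng.uniform(0.3, min(2.0, cfg.sigma_upper - 0.01))),
        p_s=float(rng.uniform(0.05, 0.6)),
        p_r=float(rng.uniform(0.05, 0.6)),
        m_s=float(rng.uniform(0.1, min(3.0, cfg.m_upper - 0.01))),
        m_r=float(rng.uniform(0.1, min(3.0, cfg.m_upper - 0.01))),
        omega=float(rng.uniform(0.3, 0.9)),
        eta=eta,
        z=z,
    )


def _run_chain(
    arr: SiteArrays, cfg: ModelConfig, mcmc: McmcConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    st = _init_state(arr, cfg, rng)
    n = arr.n_sites
    has_y = arr.J_y > 0
    has_u = arr.J_u > 0
    wmask = arr.has_w
    wvals = np.nan_to_num(arr.w)
    free = arr.free
    any_free = bool(free.any())

    def ll_y(p: float, m: float, N: np.ndarray) -> float:
        return _citizen_ll(arr.S_y[has_y], arr.J_y[has_y], (N * p + m)[has_y])

    def ll_u(p: float, m: float, N: np.ndarray) -> float:
        return _citizen_ll(arr.S_u[has_u], arr.J_u[has_u], (N * p + m)[has_u])

    # adaptive random-walk scales on transformed coordinates
    log_scales = {k: np.log(0.5) for k in _LOGIT_PARAMS}
    eta_log_scale = np.full(n, np.log(0.5))
    accepts = {k: 0 for k in _LOGIT_PARAMS}
    batch_accepts = {k: 0 for k in _LOGIT_PARAMS}
    eta_accepts = np.zeros(n)
    eta_batch = np.zeros(n)
    eta_proposals = 0

    def logit(x: float) -> float:
        return float(np.log(x) - np.log1p(-x))

    def mh_transformed(name: str, cur: float, upper: float, delta_ll) -> float:
        """One random-walk step for a uniform(0, upper) parameter on the
        logit(x/upper) scale; the Jacobian x(upper-x) enters the ratio."""
        t = logit(cur / upper)
        t_new = t + np.exp(log_scales[name]) * rng.standard_normal()
        new = upper * special.expit(t_new)
        if new <= 0.0 or new >= upper:  # numerically saturated
            return cur
        log_ratio = delta_ll(new) + np.log(new * (upper - new)) - np.log(cur * (upper - cur))
        if np.log(rng.random()) < log_ratio:
            accepts[name] += 1
            batch_accepts[name] += 1
            return new
        return cur

    total_updates = 0
    kept: dict[str, list] = {k: [] for k in ["mu", "sigma", "p_survey", "p_report", "m_survey", "m_report", "omega"]}
    for nm in cfg.covariate_names:
        kept[f"beta_{nm}"] = []
    kept["lam"], kept["z"] = [], []

    for it in range(mcmc.n_iterations):
        N = st.z * np.exp(st.eta)

        # detection / misidentification (citizen likelihood terms only)
        base_y = ll_y(st.p_s, st.m_s, N)
        st.p_s = mh_transformed("p_survey", st.p_s, 1.0, lambda v: ll_y(v, st.m_s, N) - base_y)
        base_y = ll_y(st.p_s, st.m_s, N)
        st.m_s = mh_transformed("m_survey", st.m_s, cfg.m_upper, lambda v: ll_y(st.p_s, v, N) - base_y)
        base_u = ll_u(st.p_r, st.m_r, N)
        st.p_r = mh_transformed("p_report", st.p_r, 1.0, lambda v: ll_u(v, st.m_r, N) - base_u)
        base_u = ll_u(st.p_r, st.m_r, N)
        st.m_r = mh_transformed("m_report", st.m_r, cfg.m_upper, lambda v: ll_u(st.p_r, v, N) - base_u)

        # sigma: normal likelihood of the log-intensity residuals
        resid = st.eta - st.mu - arr.X @ st.beta
        ss = float(resid @ resid)

        def d_sigma(v: float) -> float:
            return -0.5 * ss / v**2 - n * np.log(v) - (-0.5 * ss / st.sigma**2 - n * np.log(st.sigma))

        st.sigma = mh_transformed("sigma", st.sigma, cfg.sigma_upper, d_sigma)

        # mu: conjugate normal given eta, beta, sigma
        prec = n / st.sigma**2 + 1.0 / cfg.mu_sd**2
        mean = float((st.eta - arr.X @ st.beta).sum()) / st.sigma**2 / prec
        st.mu = mean + rng.standard_normal() / np.sqrt(prec)

        # beta_j: conjugate normal truncated to the uniform prior bounds
        for j in range(arr.X.shape[1]):
            xj = arr.X[:, j]
            r = st.eta - st.mu - arr.X @ st.beta + st.beta[j] * xj
            sxx = float(xj @ xj)
            bmean = float(xj @ r) / sxx
            bsd = st.sigma / np.sqrt(sxx)
            st.beta[j] = _trunc_norm(rng, bmean, bsd, -cfg.beta_bound, cfg.beta_bound)

        # omega: Beta conjugate given all z
        s1 = int(st.z.sum())
        st.omega = float(rng.beta(1 + s1, 1 + n - s1))

        # site log-intensities
        occ = st.z == 1
        pred = st.mu + arr.X @ st.beta
        if np.any(~occ):
            # unoccupied: likelihood-free, draw from the prior
            idx = ~occ
            st.eta[idx] = pred[idx] + st.sigma * rng.standard_normal(int(idx.sum()))
        if np.any(occ):
            eta_new = st.eta + np.exp(eta_log_scale) * rng.standard_normal(n)
            lam_o, lam_n = np.exp(st.eta), np.exp(eta_new)
            d = np.zeros(n)
            my_o, my_n = lam_o * st.p_s + st.m_s, lam_n * st.p_s + st.m_s
            mu_o, mu_n = lam_o * st.p_r + st.m_r, lam_n * st.p_r + st.m_r
            d += arr.S_y * (np.log(my_n) - np.log(my_o)) - arr.J_y * (my_n - my_o)
            d += arr.S_u * (np.log(mu_n) - np.log(mu_o)) - arr.J_u * (mu_n - mu_o)
            d += np.where(wmask, wvals * (eta_new - st.eta) - (lam_n - lam_o), 0.0)
            d += -0.5 * ((eta_new - pred) ** 2 - (st.eta - pred) ** 2) / st.sigma**2
            acc = occ & (np.log(rng.random(n)) < d)
            st.eta[acc] = eta_new[acc]
            eta_accepts[acc] += 1
            eta_batch[acc] += 1
            eta_proposals += 1

        # occupancy at sites without expert information: Bernoulli Gibbs
        if any_free:
            lam = np.exp(st.eta)
            a1 = np.log(st.omega)
            a0 = np.log1p(-st.omega)
            ly1 = np.where(arr.S_y > 0, arr.S_y * np.log(lam * st.p_s + st.m_s), 0.0) - arr.J_y * (lam * st.p_s + st.m_s)
            lu1 = np.where(arr.S_u > 0, arr.S_u * np.log(lam * st.p_r + st.m_r), 0.0) - arr.J_u * (lam * st.p_r + st.m_r)
            with np.errstate(divide="ignore", invalid="ignore"):
                ly0 = np.where(arr.S_y > 0, arr.S_y * np.log(st.m_s), 0.0) - arr.J_y * st.m_s
                lu0 = np.where(arr.S_u > 0, arr.S_u * np.log(st.m_r), 0.0) - arr.J_u * st.m_r
            logodds = (a1 + ly1 + lu1) - (a0 + ly0 + lu0)
            pz = special.expit(logodds)
            draw = (rng.random(n) < pz).astype(int)
            st.z = np.where(free, draw, st.z)

        total_updates += 1

        # batch adaptation during burn-in (frozen afterwards)
        if it < mcmc.burn_in and (it + 1) % mcmc.adapt_interval == 0:
            step = min(0.05, 1.0 / np.sqrt((it + 1) / mcmc.adapt_interval))
            for k in _LOGIT_PARAMS:
                rate = batch_accepts[k] / mcmc.adapt_interval
                log_scales[k] += step if rate > mcmc.target_accept else -step
                batch_accepts[k] = 0
            if eta_proposals:
                rates = eta_batch / eta_proposals
                eta_log_scale += np.where(rates > mcmc.target_accept, step, -step)
                eta_batch[:] = 0
                eta_proposals = 0

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            kept["mu"].append(st.mu)
            kept["sigma"].append(st.sigma)
            kept["p_survey"].append(st.p_s)
            kept["p_report"].append(st.p_r)
            kept["m_survey"].append(st.m_s)
            kept["m_report"].append(st.m_r)
            kept["omega"].append(st.omega)
            for j, nm in enumerate(cfg.covariate_names):
                kept[f"beta_{nm}"].append(st.beta[j])
            kept["lam"].append(np.exp(st.eta))
            kept["z"].append(st.z.copy())

    out = {k: np.asarray(v) for k, v in kept.items()}
    rates = {k: accepts[k] / total_updates for k in _LOGIT_PARAMS}
    rates["lam"] = float(eta_accepts.mean() / total_updates)
    return out, rates


def fit_iam(
    sites: Sequence[SiteData],
    model_config: ModelConfig | None = None,
    mcmc_config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Fit the IAM by MCMC and return retained draws from all chains.

    ``z_i`` is sampled only at sites whose expert occupancy is unknown;
    the site intensities are sampled on the log scale.  Convergence is
    checked with the Gelman-Rubin statistic on every scalar parameter;
    any value >= 1.1 flags the result (``draws.converged``) and logs a
    warning rather than failing.
    """
    cfg = model_config or ModelConfig()
    mcmc = mcmc_config or McmcConfig()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    arr = SiteArrays(sites, cfg)
    for j, name in enumerate(cfg.covariate_names):
        if np.unique(arr.X[:, j]).size < 2:
            raise ValueError(f"covariate {name!r} has < 2 distinct values")

    ss = np.random.SeedSequence(mcmc.seed)
    chains: list[dict[str, np.ndarray]] = []
    rate_acc: dict[str, float] = {}
    for c, child in enumerate(ss.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        out, rates = _run_chain(arr, cfg, mcmc, rng)
        chains.append(out)
        for k, v in rates.items():
            rate_acc[k] = rate_acc.get(k, 0.0) + v / mcmc.n_chains
        logger.debug("chain %d acceptance rates: %s", c, rates)

    params = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}

    from catiam.diagnostics import gelman_rubin

    rhat: dict[str, float] = {}
    if mcmc.n_chains >= 2:
        for k, v in params.items():
            if v.ndim == 2 and np.ptp(v) > 0:
                rhat[k] = gelman_rubin(v)
    else:
        logger.warning("single chain: Gelman-Rubin statistic cannot be computed")

    draws = PosteriorDraws(
        params=params,
        covariate_names=cfg.covariate_names,
        site_ids=arr.site_ids,
        accept_rates=rate_acc,
        rhat=rhat,
        seed=mcmc.seed,
    )
    if rhat and not draws.converged:
        worst = max(rhat, key=rhat.get)
        logger.warning(
            "non-convergence flagged: R-hat %.3f for %s (threshold 1.1)", rhat[worst], worst
        )
    return draws


def null_config(config: ModelConfig | None = None) -> ModelConfig:
    """The matching covariate-free (random effects only) model."""
    base = config or ModelConfig()
    return replace(base, covariate_names=())
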