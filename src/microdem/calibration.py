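"""Bayesian calibration: MCMC, convergence, DIC, nested-model selection.

The sampler is an adaptive random-scan block Metropolis: parameters are
grouped into small natural blocks (one fertility curve, one mortality
cluster, the relative-risk vector, ...), one block is perturbed per
iteration with a Gaussian proposal, and per-block step scales adapt
during burn-in toward a 20-40% acceptance rate.  Priors are vague
uniforms on the bounds declared by the variant spec, so the posterior
is the bounded likelihood surface.

Model selection uses the classic deviance information criterion
DIC = D_bar + p_D with p_D = D_bar - D(theta_bar), theta_bar the
posterior mean; differences larger than 10 points are flagged as
meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, VariantSpec, default_template
from .simulator import OutcomePlan, SimulationConfig, Trajectory, simulate
from .state import PopulationState
from .targets import TargetSet, deviance as deviance_of, log_likelihood

logger = logging.getLogger(__name__)


@dataclass
class McmcSettings:
    iterations: int = 20_000
    burn_in: int = 5_000
    n_chains: int = 4
    seed: int = 0
    proposal_scale: float = 0.05  # initial step, as a fraction of each bound width
    target_accept: float = 0.3
    adapt_interval: int = 25
    thin: int = 1
    init: str = "moment"  # "moment": moment-matched + polish + Gauss-Newton; "prior": uniform draws
    init_sweeps: int = 3  # block-polish sweep cap; sweeps stop early once converged
    init_jitter: float = 1.0  # start dispersion around the mode, x posterior sd
    map_maxfev: int = 6000  # Gauss-Newton refinement budget (function evaluations)

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class Chain:
    """Retained posterior draws with per-draw deviance."""

    draws: np.ndarray  # (n, d)
    deviance: np.ndarray  # (n,)
    names: list[str]
    accept_rate: float
    seed: int
    burn_in: int

    def __post_init__(self) -> None:
        if not 0.0 < self.accept_rate < 1.0:
            logger.warning("chain acceptance rate %.3f outside (0, 1)", self.accept_rate)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        df["deviance"] = self.deviance
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1, burn_in: int = 0, accept_rate: float = 0.5) -> "Chain":
        df = pd.read_csv(path)
        dev = df.pop("deviance").to_numpy(float)
        return cls(
            draws=df.to_numpy(float),
            deviance=dev,
            names=list(df.columns),
            accept_rate=accept_rate,
            seed=seed,
            burn_in=burn_in,
        )


@dataclass
class DICResult:
    mean_deviance: float
    deviance_at_posterior_mean: float
    p_d: float
    dic: float


class CalibrationProblem:
    """Posterior surface for one model variant against one TargetSet."""

    def __init__(
        self,
        variant: str,
        targets: TargetSet,
        initial_state: PopulationState,
        sim_config: SimulationConfig | None = None,
        template: ParameterSet | None = None,
    ):
        if sim_config is None:
            sim_config = SimulationConfig(start_year=initial_state.year)
        last_target_year = int(targets.df["year"].max()) if len(targets) else sim_config.end_year
        if sim_config.end_year > last_target_year:
            # the likelihood only needs the data window; projection past it
            # is wasted work inside MCMC
            sim_config = SimulationConfig(
                **{**sim_config.__dict__, "end_year": max(last_target_year, sim_config.start_year + 1)}
            )
        if sim_config.mode != "expected_value":
            # smooth deterministic likelihood inside MCMC; stochastic mode
            # is reserved for final uncertainty runs
            logger.info("calibration forces expected-value mode for a smooth likelihood")
            sim_config = SimulationConfig(
                **{**sim_config.__dict__, "mode": "expected_value"}
            )
        self.variant = variant
        self.spec = VariantSpec(variant)
        self.targets = targets
        self.initial_state = initial_state
        self.sim_config = sim_config
        self.template = (
            template.copy()
            if template is not None
            else default_template(variant, reference_year=sim_config.start_year)
        )
        self.plan = OutcomePlan(targets, sim_config.age_cap)
        self.n_evals = 0

    def params_of(self, theta: np.ndarray) -> ParameterSet:
        return self.spec.from_vector(theta, self.template)

    def simulate_theta(self, theta: np.ndarray) -> Trajectory:
        return simulate(self.params_of(theta), self.initial_state, self.sim_config)

    def log_likelihood_theta(self, theta: np.ndarray) -> float:
        self.n_evals += 1
        try:
            params = self.params_of(theta)
            traj = simulate(params, self.initial_state, self.sim_config)
            values = self.plan.evaluate(traj, params).values
        except (FloatingPointError, ValueError, OverflowError):
            return -math.inf
        if not np.all(np.isfinite(values)):
            return -math.inf
        return log_likelihood(values, self.targets)

    def deviance_theta(self, theta: np.ndarray) -> float:
        return deviance_of(self.log_likelihood_theta(theta))

    def residuals_theta(self, theta: np.ndarray) -> np.ndarray:
        """Standardized residuals over calibration rows.

        The Gaussian log-likelihood is, up to a constant,
        ``-0.5 * sum(residuals**2)``, so the posterior mode is a
        weighted least-squares solution.
        """
        self.n_evals += 1
        mask = self.targets.calibration_mask
        est = self.targets.df["estimate"].to_numpy(float)[mask]
        sig = self.targets.df["sigma"].to_numpy(float)[mask]
        try:
            params = self.params_of(theta)
            traj = simulate(params, self.initial_state, self.sim_config)
            values = self.plan.evaluate(traj, params).values[mask]
        except (FloatingPointError, ValueError, OverflowError):
            return np.full(mask.sum(), 1e6)
        r = (values - est) / sig
        return np.where(np.isfinite(r), r, 1e6)


def moment_init(problem: CalibrationProblem) -> np.ndarray:
    """Method-of-moments starting point read directly off the targets.

    Classic demographic estimators provide a cheap warm start in the
    right basin: the fertility quantum from the oldest children-ever-born
    band (with its trend from the across-wave slope), the median age and
    rise interval from where the cumulative curve crosses half / the
    5-95% span, Lee-Carter coefficients by regressing log death rates
    on calendar year and band mid-age per cluster, education trends
    from prevalence slopes across waves, and the migration rate from
    the 6-year lookback proportion divided by its window.  Relative
    risks start at 1.  Everything is clipped strictly inside the prior
    bounds.
    """
    df = problem.targets.df
    spec = problem.spec
    bounds = spec.bounds
    theta = {}

    fert = df[(df["class"] == "fertility") & df["calibration"]]
    tied = problem.variant == "v1"
    for res in ("urban", "rural"):
        edu_groups = [None] if tied else ("E0", "E1", "E2", "E3")
        for edu in edu_groups:
            sub = fert[fert["residence"] == res]
            if edu is not None:
                sub = sub[sub["education"] == edu]
            if len(sub) == 0:
                continue
            suffix = "" if tied else f"_{edu}"
            waves = sorted(sub["year"].unique())
            F_w, a_w, b_w = [], [], []
            for w in waves:
                s = sub[sub["year"] == w].sort_values("age_low")
                mids = (s["age_low"].to_numpy(float) + s["age_high"].to_numpy(float) + 1) / 2
                ceb = s["estimate"].to_numpy(float)
                F_hat = float(ceb[-1]) / 0.98  # oldest band is ~the completed quantum
                F_w.append(F_hat)
                a_w.append(float(np.interp(0.5 * F_hat, ceb, mids)))
                lo_age = np.interp(0.05 * F_hat, ceb, mids)
                hi_age = np.interp(0.95 * F_hat, ceb, mids)
                b_w.append(float(hi_age - lo_age))
            ref = problem.template.fertility.reference_year
            if len(waves) >= 2:
                slope, intercept = np.polyfit(np.asarray(waves) - ref, F_w, 1)
            else:
                slope, intercept = 0.0, F_w[0]
            theta[f"fert_F_{res}{suffix}"] = intercept
            theta[f"fert_trend_F_{res}{suffix}"] = slope
            theta[f"fert_a_{res}{suffix}"] = float(np.mean(a_w))
            theta[f"fert_b_{res}{suffix}"] = float(np.mean(b_w))

    mort = df[(df["class"] == "mortality") & df["calibration"]]
    ref_year = problem.template.lee_carter.reference_year
    ref_ages = problem.template.lee_carter.reference_ages
    for res in ("urban", "rural"):
        sub = mort[mort["residence"] == res]
        if len(sub) == 0:
            continue
        mids = (sub["age_low"].to_numpy(float) + sub["age_high"].to_numpy(float)) / 2
        q = np.clip(sub["estimate"].to_numpy(float), 1e-8, 1 - 1e-8)
        logmu = np.log(-np.log1p(-q))
        yr = sub["year"].to_numpy(float) - ref_year
        cl = np.where(mids < 1, 0, np.where(mids <= 10, 1, 2))
        for c_i, cname in enumerate(("infant", "child", "adult")):
            m = cl == c_i
            if not np.any(m):
                continue
            X = [np.ones(m.sum()), yr[m]]
            if c_i != 0:
                X.append(mids[m] - ref_ages[c_i])
            coef, *_ = np.linalg.lstsq(np.stack(X, axis=1), logmu[m], rcond=None)
            theta[f"lc_c_{res}_{cname}"] = coef[0]
            theta[f"lc_beta_year_{res}_{cname}"] = coef[1]
            if c_i != 0:
                theta[f"lc_beta_age_{res}_{cname}"] = coef[2]

    if problem.variant in ("v2", "v3"):
        edu_rows = df[(df["class"] == "education") & df["calibration"]]
        for res in ("urban", "rural"):
            for edu in ("E0", "E1", "E2", "E3"):
                sub = edu_rows[(edu_rows["residence"] == res) & (edu_rows["education"] == edu)]
                if len(sub) >= 2:
                    # prevalence at ages 20-24 reflects the birth cohort of
                    # ~22 years earlier; the calendar-year slope carries over
                    slope = np.polyfit(sub["year"].to_numpy(float), sub["estimate"].to_numpy(float), 1)[0]
                    theta[f"edutrend_{res}_{edu}"] = slope

    if problem.variant == "v3":
        mig = df[(df["class"] == "migration") & df["calibration"]]
        urb6 = mig[(mig["residence"] == "urban") & (mig["window"] == "6y")]
        for edu in ("E0", "E1", "E2", "E3"):
            sub = urb6[urb6["education"] == edu]
            if len(sub) == 0:
                continue
            # an urban resident's last move was rural-to-urban; the 6-year
            # window proportion approximates 6x the annual hazard scaled by
            # the odds of being urban
            rate = sub["estimate"].to_numpy(float) / 6.0
            urban_frac = 0.3
            rate = rate * urban_frac / max(1 - urban_frac, 1e-6)
            yrs = sub["year"].to_numpy(float)
            theta[f"mig_base_{edu}"] = float(np.mean(rate))
            if len(sub) >= 2:
                theta[f"mig_trend_{edu}"] = float(np.polyfit(yrs, rate, 1)[0])

    x0 = np.array(
        [theta.get(name, 0.5 * (lo + hi)) for name, (lo, hi) in zip(spec.names, bounds)]
    )
    # relative risks start neutral
    for i, name in enumerate(spec.names):
        if name.startswith("rr_"):
            x0[i] = 1.0
    width = bounds[:, 1] - bounds[:, 0]
    return np.clip(x0, bounds[:, 0] + 1e-3 * width, bounds[:, 1] - 1e-3 * width)


def block_polish(
    problem: CalibrationProblem,
    x0: np.ndarray,
    sweeps: int = 2,
    maxfev_per_block: int = 60,
) -> np.ndarray:
    """Cycle Nelder-Mead over parameter blocks to climb to the mode.

    Each block is a small (2-4 dimensional) subproblem, so coordinate
    polish converges quickly where full-dimensional optimizers stall on
    the ridge structure of the joint surface.
    """
    from scipy.optimize import minimize

    bounds = problem.spec.bounds
    x = x0.copy()
    current = -problem.log_likelihood_theta(x)
    for _ in range(sweeps):
        sweep_start = current
        for idx in problem.spec.blocks.values():
            def neg(sub, idx=idx):
                full = x.copy()
                full[idx] = sub
                if not np.all((full[idx] >= bounds[idx, 0]) & (full[idx] <= bounds[idx, 1])):
                    return np.inf
                return -problem.log_likelihood_theta(full)

            res = minimize(
                neg,
                x[idx],
                method="Nelder-Mead",
                options={"maxfev": maxfev_per_block, "xatol": 1e-6, "fatol": 1e-4},
            )
            if np.isfinite(res.fun) and res.fun < current:
                x[idx] = np.clip(res.x, bounds[idx, 0], bounds[idx, 1])
                current = res.fun
        if sweep_start - current < 0.5:  # log-likelihood units; converged
            break
    return x


def laplace_refine(
    problem: CalibrationProblem, x0: np.ndarray, maxfev: int = 6000
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Newton descent to the posterior mode plus a Laplace covariance.

    The Gaussian likelihood makes the mode a weighted least-squares
    problem; trust-region refinement resolves the cross-block ridges
    that coordinate polish cannot, and the Jacobian at the solution
    gives the curvature (J'J)^-1 used to scale MCMC proposals and
    overdisperse chain starts.
    """
    from scipy.optimize import least_squares

    bounds = problem.spec.bounds
    width = bounds[:, 1] - bounds[:, 0]
    res = least_squares(
        problem.residuals_theta,
        np.clip(x0, bounds[:, 0] + 1e-9 * width, bounds[:, 1] - 1e-9 * width),
        bounds=(bounds[:, 0], bounds[:, 1]),
        method="trf",
        x_scale=width,
        max_nfev=maxfev,
    )
    jtj = res.jac.T @ res.jac
    # regularize flat directions (e.g. parameters pinned at a bound)
    diag = np.diag(jtj).copy()
    floor = max(diag.max(), 1.0) * 1e-10
    cov = np.linalg.pinv(jtj + np.diag(np.maximum(1e-8 * diag, floor)))
    return res.x, cov


def _run_single_chain(
    logpost,
    x0: np.ndarray,
    bounds: np.ndarray,
    blocks: list[np.ndarray],
    settings: McmcSettings,
    seed: int,
    init_cov: np.ndarray | None = None,
) -> Chain:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    d = x0.size
    width = bounds[:, 1] - bounds[:, 0]
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log-posterior at the starting point")
    n_keep = (settings.iterations - settings.burn_in) // settings.thin
    draws = np.empty((n_keep, d))
    devs = np.empty(n_keep)
    n_blocks = len(blocks)
    # per-block proposal: scale factor x Cholesky of an adapted covariance
    # (Haario-style: the empirical burn-in covariance, regularized);
    # seeded from the Laplace curvature when available
    chol = []
    for idx in blocks:
        c = None
        if init_cov is not None:
            sub = (2.38**2 / idx.size) * init_cov[np.ix_(idx, idx)]
            sub = sub + np.diag((1e-9 * width[idx]) ** 2)
            try:
                c = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                c = None
        chol.append(c if c is not None else np.diag(settings.proposal_scale * width[idx]))
    log_scale = np.zeros(n_blocks)
    history: list[list[np.ndarray]] = [[] for _ in blocks]
    block_acc = np.zeros(n_blocks)
    block_try = np.zeros(n_blocks)
    accepted = 0
    kept = 0
    cov_interval = 10 * settings.adapt_interval
    for it in range(settings.iterations):
        bi = int(rng.integers(n_blocks))
        idx = blocks[bi]
        prop = x.copy()
        step = chol[bi] @ rng.standard_normal(idx.size)
        prop[idx] = x[idx] + math.exp(log_scale[bi]) * step
        block_try[bi] += 1
        if np.all(prop[idx] >= bounds[idx, 0]) and np.all(prop[idx] <= bounds[idx, 1]):
            lp_prop = logpost(prop)
            if math.log(rng.random() + 1e-300) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
                block_acc[bi] += 1
        if it < settings.burn_in:
            history[bi].append(x[idx].copy())
            if (it + 1) % settings.adapt_interval == 0:
                for b in range(n_blocks):
                    if block_try[b] > 0:
                        rate = block_acc[b] / block_try[b]
                        log_scale[b] += 0.5 * (rate - settings.target_accept)
                block_acc[:] = 0
                block_try[:] = 0
            if (it + 1) % cov_interval == 0:
                for b, idx_b in enumerate(blocks):
                    h = history[b]
                    if len(h) >= 20:
                        emp = np.cov(np.asarray(h[-500:]).T)
                        emp = np.atleast_2d(emp) + np.diag(1e-12 + (1e-6 * width[idx_b]) ** 2)
                        try:
                            chol[b] = np.linalg.cholesky((2.38**2 / idx_b.size) * emp)
                        except np.linalg.LinAlgError:
                            pass
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 and kept < n_keep:
            draws[kept] = x
            devs[kept] = -2.0 * lp
            kept += 1
    return Chain(
        draws=draws[:kept],
        deviance=devs[:kept],
        names=[],
        accept_rate=max(min(accepted / settings.iterations, 1 - 1e-9), 1e-9),
        seed=seed,
        burn_in=settings.burn_in,
    )


def run_chain(
    logpost,
    x0: np.ndarray,
    bounds: np.ndarray,
    settings: McmcSettings,
    seed: int,
    blocks: list[np.ndarray] | None = None,
) -> Chain:
    """Run one adaptive Metropolis chain on an arbitrary log-posterior.

    Useful for toy posteriors with known closed forms; the calibration
    entry point :func:`mcmc_run` builds on the same kernel.
    """
    if blocks is None:
        blocks = [np.arange(x0.size)]
    chain = _run_single_chain(logpost, np.asarray(x0, float), np.asarray(bounds, float), blocks, settings, seed)
    chain.names = [f"x{i}" for i in range(x0.size)]
    return chain


def mcmc_run(
    problem: CalibrationProblem,
    settings: McmcSettings,
    starts: np.ndarray | None = None,
) -> list[Chain]:
    """Run ``n_chains`` adaptive Metropolis chains.

    With the default ``moment`` initialization the mode is located once
    (method-of-moments estimate, block-coordinate polish, Gauss-Newton
    refinement) and chains start from seeded random draws of the
    Laplace approximation around it — random overdispersed starts in
    the posterior's own scale.  Full prior draws (``init='prior'``)
    need far longer burn-in than desk-scale budgets allow.  The whole
    run is deterministic given the settings seed.
    """
    bounds = problem.spec.bounds
    width = bounds[:, 1] - bounds[:, 0]
    blocks = list(problem.spec.blocks.values())
    mode_point = None
    laplace_cov = None
    post_sd = None
    if starts is None and settings.init == "moment":
        polished = block_polish(problem, moment_init(problem), sweeps=settings.init_sweeps)
        mode_point, laplace_cov = laplace_refine(problem, polished, maxfev=settings.map_maxfev)
        # flat (weakly identified) directions get huge Laplace sd; cap the
        # start dispersion at a modest fraction of the bound width
        post_sd = np.minimum(np.sqrt(np.clip(np.diag(laplace_cov), 0.0, None)), 0.05 * width)
    chains: list[Chain] = []
    for ci in range(settings.n_chains):
        chain_seed = (int(settings.seed) * 1000 + ci) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([chain_seed, 17]))
        if starts is not None:
            x0 = np.asarray(starts[ci], dtype=float)
        elif mode_point is not None:
            jitter = settings.init_jitter
            for _ in range(8):
                x0 = np.clip(
                    mode_point + jitter * post_sd * rng.standard_normal(width.size),
                    bounds[:, 0] + 1e-9 * width,
                    bounds[:, 1] - 1e-9 * width,
                )
                if np.isfinite(problem.log_likelihood_theta(x0)):
                    break
                jitter *= 0.5
            else:
                x0 = mode_point.copy()
        else:
            x0 = None
            for _ in range(50):
                cand = bounds[:, 0] + width * rng.random(bounds.shape[0])
                if np.isfinite(problem.log_likelihood_theta(cand)):
                    x0 = cand
                    break
            if x0 is None:
                raise RuntimeError("no finite-likelihood starting point found in 50 prior draws")
        chain = _run_single_chain(
            problem.log_likelihood_theta,
            x0,
            bounds,
            blocks,
            settings,
            chain_seed,
            init_cov=laplace_cov,
        )
        chain.names = problem.spec.names
        chains.append(chain)
    return chains


def gelman_rubin(chains: list[Chain] | list[np.ndarray]) -> np.ndarray:
    """Potential scale reduction factor (R-hat) per parameter.

    Requires at least two chains of equal retained length; values near
    1 indicate between-chain agreement.
    """
    arrays = [c.draws if isinstance(c, Chain) else np.atleast_2d(np.asarray(c, float).T).T for c in chains]
    if len(arrays) < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    arrays = [a.reshape(a.shape[0], -1) for a in arrays]
    n = arrays[0].shape[0]
    if n < 2:
        raise ValueError("chains must have at least two retained draws")
    if any(a.shape != arrays[0].shape for a in arrays):
        raise ValueError("chains must have equal retained lengths")
    m = len(arrays)
    stacked = np.stack(arrays)  # (m, n, d)
    chain_means = stacked.mean(axis=1)  # (m, d)
    chain_vars = stacked.var(axis=1, ddof=1)  # (m, d)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W > 0, rhat, np.where(B > 0, np.inf, 1.0))
    return rhat


def dic(chains: list[Chain], deviance_fn, bounds: np.ndarray | None = None, rhat_warn: float = 1.1) -> DICResult:
    """Spiegelhalter DIC from pooled post-burn-in draws.

    ``deviance_fn(theta_bar)`` re-evaluates the deviance at the pooled
    posterior mean (through the full simulator for a calibration
    problem); a posterior mean outside ``bounds`` is projected back in
    with a warning.
    """
    if not chains or any(len(c.deviance) == 0 for c in chains):
        raise ValueError("DIC requires non-empty chains")
    if len(chains) >= 2:
        try:
            rhat = gelman_rubin(chains)
            if np.any(rhat > rhat_warn):
                logger.warning(
                    "max R-hat %.3f exceeds %.2f; DIC computed on possibly unconverged chains",
                    float(np.nanmax(rhat)),
                    rhat_warn,
                )
        except ValueError:
            pass
    pooled_dev = np.concatenate([c.deviance for c in chains])
    pooled = np.concatenate([c.draws for c in chains], axis=0)
    mean_dev = float(pooled_dev.mean())
    theta_bar = pooled.mean(axis=0)
    if bounds is not None:
        clipped = np.clip(theta_bar, bounds[:, 0], bounds[:, 1])
        if not np.allclose(clipped, theta_bar):
            logger.warning("posterior mean outside bounds; projected for D(theta_bar)")
        theta_bar = clipped
    d_at_mean = float(deviance_fn(theta_bar))
    p_d = mean_dev - d_at_mean
    return DICResult(
        mean_deviance=mean_dev,
        deviance_at_posterior_mean=d_at_mean,
        p_d=p_d,
        dic=mean_dev + p_d,
    )


def dic_for_problem(chains: list[Chain], problem: CalibrationProblem) -> DICResult:
    return dic(chains, problem.deviance_theta, bounds=problem.spec.bounds)


MEANINGFUL_DIC_MARGIN = 10.0


def select_model(dic_results: dict[str, DICResult]) -> tuple[pd.DataFrame, str, bool]:
    """Compare nested variants by DIC.

    Returns the comparison table (ΔDIC versus the previous simpler
    variant and versus the best), the selected variant (lowest DIC,
    ties broken toward the simplest), and whether the selection margin
    over the runner-up exceeds the 10-point meaningfulness threshold.
    """
    if len(dic_results) < 2:
        raise ValueError("model selection needs at least two variants")
    names = list(dic_results)
    dics = np.array([dic_results[k].dic for k in names])
    best_idx = int(np.argmin(dics))  # argmin takes the first (simplest) on ties
    rows = []
    for i, name in enumerate(names):
        rows.append(
            {
                "variant": name,
                "dic": dics[i],
                "p_d": dic_results[name].p_d,
                "delta_vs_previous": np.nan if i == 0 else dics[i] - dics[i - 1],
                "delta_vs_best": dics[i] - dics[best_idx],
                "selected": i == best_idx,
            }
        )
    others = np.delete(dics, best_idx)
    meaningful = bool(others.min() - dics[best_idx] > MEANINGFUL_DIC_MARGIN)
    return pd.DataFrame(rows), names[best_idx], meaningful
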