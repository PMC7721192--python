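"""Posterior specification, MCMC sampling, diagnostics and model comparison.

The posterior couples four ingredients: the tagging multinomial likelihood,
the multinomial age-length-sample likelihood, the movement-configuration
prior, and independent uniform priors on the demographic parameters
(F ~ U(0,1) per region-year, M ~ U(0.2, 2), selectivity inflections
eta1/eta3 ~ U(1, 6) and slopes eta2/eta4 ~ U(0, 10)). Age compositions kappa
get a flat Dirichlet prior, realised by normalising Exponential(1) weights.

Sampling is adaptive random-walk Metropolis in parameter blocks on
transformed coordinates (log for positive, scaled logit for bounded), with
proposal covariances tuned during burn-in only, supplemented by periodic
univariate slice updates on the curved selectivity/mortality conditionals.
Any correct sampler satisfies the same contract; this one is
dependency-free and reproducible from a seed.

Model comparison reports DIC, WAIC (variance-form penalty) and PSIS-LOO, all
on the deviance (-2 log) scale so differences are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._params import Block, LogitTransform, LogTransform, ParameterSpace
from .age_key import kappa_conjugate_posterior, log_lik_age_sample
from .dynamics import recovery_probability_tensor, selectivity
from .likelihood import (
    LikelihoodResult,
    negative_log_likelihood,
    stratum_fate_probabilities,
)
from .movement import (
    MovementConfig,
    MovementParams,
    build_movement,
    log_prior_movement,
    sample_prior_movement,
)
from .tag_data import AgeLengthSample, ReportingRates, TagDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "TagReturnModel",
    "PosteriorRun",
    "run_mcmc",
    "gelman_rubin",
    "compute_dic",
    "compute_waic",
    "compute_psis_loo",
    "ComparisonResult",
    "compare_runs",
]


@dataclass(frozen=True)
class PriorSpec:
    """Bounds of the uniform priors on the demographic parameters."""

    F_bounds: tuple[float, float] = (0.0, 1.0)
    M_bounds: tuple[float, float] = (0.2, 2.0)
    eta_inflection_bounds: tuple[float, float] = (1.0, 6.0)
    eta_slope_bounds: tuple[float, float] = (0.0, 10.0)


class TagReturnModel:
    """Joint posterior of one movement configuration on one dataset.

    Parameters
    ----------
    dataset : validated releases/recoveries/at-large counts.
    reporting : fixed tag-reporting rates.
    age_sample : aged-fish counts; may be None (kappa then prior-only unless
        plugged in).
    config : movement configuration to fit.
    plugin_kappa : freeze the age compositions at their conjugate
        posterior means instead of sampling them (fast mode).
    pointwise : likelihood decomposition unit, "stratum" or "fish".
    """

    def __init__(
        self,
        dataset: TagDataset,
        reporting: ReportingRates,
        age_sample: AgeLengthSample | None,
        config: MovementConfig = MovementConfig("C"),
        priors: PriorSpec = PriorSpec(),
        plugin_kappa: bool = False,
        pointwise: str = "stratum",
    ):
        self.dataset = dataset
        self.reporting = reporting
        self.age_sample = age_sample
        self.config = config
        self.priors = priors
        self.plugin_kappa = plugin_kappa
        self.pointwise = pointwise
        self.frame = dataset.frame
        f = self.frame
        A, Y, K, L = f.n_ages, f.n_years, f.n_regions, f.n_lengths

        log, unit = LogTransform(), LogitTransform(0.0, 1.0)
        blocks = [Block("gamma", _movement_gamma_shape(config, f), log)]
        kind = config.kind
        if kind == "YR":
            blocks += [Block("psi", (K, K), log), Block("tau", (), unit)]
        elif kind == "AR":
            blocks += [Block("phi", (K, K), log), Block("omega", (), unit)]
        elif kind in ("AY", "AYc"):
            blocks += [
                Block("delta", (A, K, K), log),
                Block("phi", (K, K), log),
                Block("nu_a", (), unit),
                Block("nu_y", (), unit),
            ]
            if kind == "AYc":
                blocks += [Block("ratio", (), unit)]
        self._movement_block_names = [b.name for b in blocks]
        blocks += [
            Block("F", (K, Y), LogitTransform(*priors.F_bounds)),
            Block("M", (), LogitTransform(*priors.M_bounds)),
            Block("eta1", (), LogitTransform(*priors.eta_inflection_bounds)),
            Block("eta2", (), LogitTransform(*priors.eta_slope_bounds)),
            Block("eta3", (), LogitTransform(*priors.eta_inflection_bounds)),
            Block("eta4", (), LogitTransform(*priors.eta_slope_bounds)),
        ]
        if not plugin_kappa:
            blocks += [Block("g_kappa", (L, A), log)]
            self._kappa_fixed = None
        else:
            if age_sample is None:
                raise ValueError("plugin_kappa requires an age-length sample")
            conc = kappa_conjugate_posterior(age_sample)
            self._kappa_fixed = conc / conc.sum(axis=1, keepdims=True)
        self.space = ParameterSpace(blocks)

        # sampler update groups: hierarchical movement levels, F, demography,
        # and the age-key weights each get their own adapted proposal
        groups: dict[str, list[str]] = {"gamma": ["gamma"]}
        hyper = [n for n in self._movement_block_names if n != "gamma"]
        if hyper:
            groups["movement_hyper"] = hyper
        groups["F"] = ["F"]
        groups["demography"] = ["M", "eta1", "eta2", "eta3", "eta4"]
        if not plugin_kappa:
            groups["kappa"] = ["g_kappa"]
        self.update_groups = {
            name: np.concatenate(
                [np.arange(self.space.slices[b].start, self.space.slices[b].stop)
                 for b in names]
            )
            for name, names in groups.items()
        }
        # one joint proposal over everything picks up cross-block ridges
        # (e.g. M vs F, selectivity vs age key) that block moves cannot
        self.update_groups["joint"] = np.arange(self.space.size)
        # the dome-selectivity conditionals are strongly curved; univariate
        # slice updates traverse them where Gaussian proposals stall. Small
        # F blocks are included too — on compact frames F shares the slow
        # mortality ridge and the per-coordinate cost is modest.
        slice_coords = [
            self.space.slices[name].start
            for name in ("M", "eta1", "eta2", "eta3", "eta4")
        ]
        f_slice = self.space.slices["F"]
        if f_slice.stop - f_slice.start <= 8:
            slice_coords.extend(range(f_slice.start, f_slice.stop))
        self.slice_coords = np.array(slice_coords)

        # fixed index plans for the fused likelihood path
        ages0 = np.arange(A)
        self._prop_plan = [
            (np.arange(y + 1),
             np.minimum(ages0[None, :] + (y - np.arange(y + 1))[:, None], A - 1))
            for y in range(Y)
        ]
        self._eye_AKK = np.broadcast_to(np.eye(K), (A, K, K)).copy()
        self._strata = [tuple(i) for i in np.argwhere(dataset.releases > 0)]
        self._strata_flat = np.ravel_multi_index(
            np.array(self._strata).T, (Y, K, L)
        ) if self._strata else np.empty(0, dtype=int)

    # ------------------------------------------------------------------
    def movement_params(self, natural: dict[str, np.ndarray]) -> MovementParams:
        get = natural.get
        return MovementParams(
            gamma=natural["gamma"], psi=get("psi"), phi=get("phi"),
            delta=get("delta"), tau=get("tau"), omega=get("omega"),
            nu_a=get("nu_a"), nu_y=get("nu_y"), ratio=get("ratio"),
        )

    def kappa_of(self, natural: dict[str, np.ndarray]) -> np.ndarray:
        if self._kappa_fixed is not None:
            return self._kappa_fixed
        g = natural["g_kappa"]
        return g / g.sum(axis=1, keepdims=True)

    def fate_probabilities(self, natural: dict[str, np.ndarray],
                           validate: bool = True):
        """Stratum recovery/at-large probabilities at one parameter point."""
        f = self.frame
        mm = build_movement(self.movement_params(natural), self.config, f,
                            validate=validate)
        _, s = selectivity(
            float(natural["eta1"]), float(natural["eta2"]),
            float(natural["eta3"]), float(natural["eta4"]), f.ages,
        )
        sF = s[:, None, None] * np.asarray(natural["F"]).T[None, :, :]
        M = float(natural["M"])
        S = np.exp(-sF - M)
        u = sF / (sF + M) * (1.0 - S)
        P = recovery_probability_tensor(
            mm.pi, u, S, self.reporting.lam, f, pi_init=mm.pi_init
        )
        kappa = self.kappa_of(natural)
        return stratum_fate_probabilities(P, kappa, f, validate=validate)

    def _likelihood(self, natural: dict[str, np.ndarray]):
        """Tagging pointwise log-lik and age-sample log-lik at a point.

        Fused re-implementation of the public fate/NLL pipeline with cached
        index plans; agreement with the public path is covered by tests.
        """
        from scipy.special import xlogy

        if self.pointwise != "stratum":
            fate = self.fate_probabilities(natural, validate=False)
            res = negative_log_likelihood(self.dataset, fate,
                                          pointwise=self.pointwise)
            ll_age = 0.0
            if self.age_sample is not None and not self.plugin_kappa:
                ll_age = log_lik_age_sample(self.kappa_of(natural),
                                            self.age_sample)
            return res, ll_age

        f = self.frame
        A, Y, K = f.n_ages, f.n_years, f.n_regions
        # movement matrices (broadcast views; propagation copies as needed)
        mm = build_movement(self.movement_params(natural), self.config, f,
                            validate=False)
        pi, pi_init = mm.pi, mm.pi_init
        _, s = selectivity(
            float(natural["eta1"]), float(natural["eta2"]),
            float(natural["eta3"]), float(natural["eta4"]), f.ages,
        )
        sF = s[:, None, None] * np.asarray(natural["F"]).T[None, :, :]
        M = float(natural["M"])
        S = np.exp(-sF - M)
        u = sF / (sF + M) * (1.0 - S)
        lam = self.reporting.lam

        P = np.zeros((A, Y, K, Y, K))
        V = np.empty((Y, A, K, K))
        for y in range(Y):
            V[y] = self._eye_AKK
            t, acur = self._prop_plan[y]
            pim = pi[acur, y]
            if pi_init is not None:
                pim[y] = pi_init[np.arange(A), y]
            moved = np.einsum("task,takj->tasj", V[: y + 1], pim)
            w = u[acur, y] * lam[y]
            P[:, : y + 1, :, y, :] = (moved * w[:, :, None, :]).transpose(1, 0, 2, 3)
            V[: y + 1] = moved * S[acur, y][:, :, None, :]

        kappa = self.kappa_of(natural)
        pr_recap = np.einsum("la,atkfj->tklfj", kappa, P)
        pr_atlarge = 1.0 - pr_recap.sum(axis=(3, 4))
        with np.errstate(divide="ignore", invalid="ignore"):
            per_stratum = (
                xlogy(self.dataset.recoveries, pr_recap).sum(axis=(3, 4))
                + xlogy(self.dataset.at_large, pr_atlarge)
            )
        pw = per_stratum.ravel()[self._strata_flat]
        res = LikelihoodResult(nll=float(-pw.sum()), pointwise=pw,
                               strata=self._strata)
        ll_age = 0.0
        if self.age_sample is not None and not self.plugin_kappa:
            ll_age = log_lik_age_sample(kappa, self.age_sample)
        return res, ll_age

    def log_prior(self, natural: dict[str, np.ndarray]) -> float:
        """Natural-scale joint log prior (uniform constants dropped)."""
        lp = log_prior_movement(self.movement_params(natural), self.config)
        if not np.isfinite(lp):
            return -np.inf
        if self._kappa_fixed is None:
            lp += float(-natural["g_kappa"].sum())  # Exponential(1) weights
        return lp

    def log_posterior(self, x: np.ndarray) -> tuple[float, np.ndarray | None]:
        """Log posterior density on the sampling scale, plus pointwise log-lik.

        Returns ``(-inf, None)`` off support or on numerical failure.
        """
        natural = self.space.unpack(x)
        lp = self.log_prior(natural) + self.space.log_jacobian(x)
        if not np.isfinite(lp):
            return -np.inf, None
        try:
            res, ll_age = self._likelihood(natural)
        except (ValueError, FloatingPointError) as err:
            logger.warning("likelihood evaluation failed (%s); density set to 0", err)
            return -np.inf, None
        total = lp - res.nll + ll_age
        if not np.isfinite(total):
            return -np.inf, None
        return float(total), res.pointwise

    def pointwise_at(self, x: np.ndarray) -> np.ndarray:
        res, _ = self._likelihood(self.space.unpack(x))
        return res.pointwise

    def initial_point(self, rng: np.random.Generator, max_tries: int = 200
                      ) -> np.ndarray:
        """Overdispersed chain initialisation drawn from the prior."""
        for _ in range(max_tries):
            natural = self.sample_prior(rng)
            x = self.space.pack(natural)
            lp, _ = self.log_posterior(x)
            if np.isfinite(lp):
                return x
        raise RuntimeError("could not find a finite starting point from the prior")

    def sample_prior(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        f = self.frame
        mp = sample_prior_movement(self.config, f, rng)
        natural: dict[str, np.ndarray] = {"gamma": mp.gamma}
        for name in self._movement_block_names:
            if name != "gamma":
                natural[name] = getattr(mp, name)
        pr = self.priors
        natural["F"] = rng.uniform(*pr.F_bounds, (f.n_regions, f.n_years))
        natural["M"] = rng.uniform(*pr.M_bounds)
        natural["eta1"] = rng.uniform(*pr.eta_inflection_bounds)
        natural["eta2"] = rng.uniform(*pr.eta_slope_bounds)
        natural["eta3"] = rng.uniform(*pr.eta_inflection_bounds)
        natural["eta4"] = rng.uniform(*pr.eta_slope_bounds)
        if self._kappa_fixed is None:
            natural["g_kappa"] = rng.exponential(
                1.0, (f.n_lengths, f.n_ages)
            )
        return natural

    def n_observations(self) -> int:
        if self.pointwise == "stratum":
            return int((self.dataset.releases > 0).sum())
        return int(self.dataset.releases.sum())


def _movement_gamma_shape(config: MovementConfig, frame) -> tuple[int, ...]:
    A, Y, K = frame.n_ages, frame.n_years, frame.n_regions
    return {
        "C": (K, K), "YF": (Y, K, K), "YR": (Y, K, K),
        "AF": (A, K, K), "AR": (A, K, K),
        "AY": (A, Y, K, K), "AYc": (A, Y, K, K),
    }[config.kind]


# ---------------------------------------------------------------------------
# Adaptive block random-walk Metropolis
# ---------------------------------------------------------------------------

@dataclass
class PosteriorRun:
    """MCMC draws with diagnostics and everything model comparison needs.

    ``draws`` are on the sampling (transformed) scale, shape
    (chains, kept draws, n_params); ``natural`` is the same layout mapped
    back to the natural scale; ``pointwise`` holds per-draw log-likelihood
    contributions, shape (chains, kept draws, n_observations).
    """

    model: TagReturnModel
    draws: np.ndarray
    natural: np.ndarray
    pointwise: np.ndarray
    param_names: list[str]
    rhat: np.ndarray
    seed: int
    n_iter: int
    burn: int
    thin: int
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        finite = self.rhat[np.isfinite(self.rhat)]
        return bool((finite < 1.1).all()) if finite.size else True

    def stacked(self, scale: str = "natural") -> np.ndarray:
        arr = self.natural if scale == "natural" else self.draws
        return arr.reshape(-1, arr.shape[-1])

    def stacked_pointwise(self) -> np.ndarray:
        return self.pointwise.reshape(-1, self.pointwise.shape[-1])

    def posterior_mean_x(self) -> np.ndarray:
        return self.stacked("transformed").mean(axis=0)

    def summary(self) -> pd.DataFrame:
        flat = self.stacked()
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "median": np.median(flat, axis=0),
                "q2.5": np.quantile(flat, 0.025, axis=0),
                "q97.5": np.quantile(flat, 0.975, axis=0),
                "rhat": self.rhat,
            }
        )

    def draws_frame(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) natural-scale draws."""
        C, S, D = self.natural.shape
        rec = []
        for c in range(C):
            for s in range(S):
                rec.append(self.natural[c, s])
        df = pd.DataFrame(np.asarray(rec), columns=self.param_names)
        df.insert(0, "iteration", np.tile(np.arange(S), C))
        df.insert(0, "chain", np.repeat(np.arange(C), S))
        return df.melt(id_vars=["chain", "iteration"], var_name="parameter")

    def movement_probability_draws(self) -> np.ndarray:
        """Posterior draws of the movement matrix pi[a, y, k, k']."""
        f = self.model.frame
        flat = self.stacked("transformed")
        out = np.empty(
            (flat.shape[0], f.n_ages, f.n_years, f.n_regions, f.n_regions)
        )
        for i, x in enumerate(flat):
            natural = self.model.space.unpack(x)
            mm = build_movement(
                self.model.movement_params(natural), self.model.config, f
            )
            out[i] = mm.pi
        return out


class _BlockProposal:
    """Adaptive multivariate normal proposal for one update group.

    During burn-in the empirical covariance of the block is accumulated
    (Welford) and the proposal uses its Cholesky factor, rescaled by a
    Robbins-Monro-tuned global factor targeting the standard acceptance
    rates. After burn-in both covariance and scale are frozen.
    """

    REFRESH = 25  # iterations between Cholesky refreshes during burn-in

    def __init__(self, idx: np.ndarray):
        self.idx = idx
        d = idx.size
        self.target = 0.44 if d == 1 else 0.234
        self.log_scale = np.log(0.1 / np.sqrt(d))
        self.mean = np.zeros(d)
        self.cov = np.eye(d)
        self.chol = np.eye(d)
        self.count = 0
        self.tries = 0

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        prop = x.copy()
        step = self.chol @ rng.standard_normal(self.idx.size)
        prop[self.idx] = x[self.idx] + np.exp(self.log_scale) * step
        return prop

    def adapt(self, x: np.ndarray, accepted: bool) -> None:
        self.tries += 1
        rate = 1.0 / max(self.tries, 10) ** 0.6
        self.log_scale += rate * ((1.0 if accepted else 0.0) - self.target)
        v = x[self.idx]
        self.count += 1
        delta = v - self.mean
        self.mean += delta / self.count
        self.cov += (np.outer(delta, v - self.mean) - self.cov) / self.count
        if self.count >= 50 and self.count % self.REFRESH == 0:
            d = self.idx.size
            reg = self.cov + 1e-6 * np.eye(d) * max(np.trace(self.cov) / d, 1e-3)
            try:
                self.chol = np.linalg.cholesky(reg)
            except np.linalg.LinAlgError:
                pass


def _warm_start(model: TagReturnModel, x0: np.ndarray, maxfun: int) -> np.ndarray:
    """Climb from a prior draw toward the posterior mode (part of burn-in).

    A budgeted quasi-Newton ascent moves the chain out of the far prior
    tails so that covariance adaptation learns local posterior geometry
    rather than transit noise. Chains keep distinct prior starting points.
    """
    from scipy.optimize import minimize

    def neg(x):
        lp, _ = model.log_posterior(x)
        return -lp if np.isfinite(lp) else 1e12

    res = minimize(neg, x0, method="L-BFGS-B",
                   options={"maxfun": maxfun, "maxiter": maxfun})
    return res.x if np.isfinite(res.fun) and res.fun < 1e12 else x0


def _slice_update(model, x, lp, pw, coord, width, rng, max_steps=6):
    """Neal's stepping-out/shrinkage slice sampler on one coordinate."""
    logy = lp + np.log(rng.uniform())
    u = rng.uniform()
    lo = x[coord] - width * u
    hi = x[coord] + width * (1.0 - u)
    xt = x.copy()
    for _ in range(max_steps):
        xt[coord] = lo
        if model.log_posterior(xt)[0] <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        xt[coord] = hi
        if model.log_posterior(xt)[0] <= logy:
            break
        hi += width
    for _ in range(30):
        cand = rng.uniform(lo, hi)
        xt[coord] = cand
        lp_c, pw_c = model.log_posterior(xt)
        if lp_c > logy:
            return xt, lp_c, pw_c
        if cand < x[coord]:
            lo = cand
        else:
            hi = cand
    return x, lp, pw  # shrank to nothing; keep current point


def _run_chain(model: TagReturnModel, n_iter: int, burn: int, thin: int,
               rng: np.random.Generator, warm_start: int = 4000):
    x = model.initial_point(rng)
    if warm_start:
        x = _warm_start(model, x, warm_start)
    lp, pw = model.log_posterior(x)
    proposals = {g: _BlockProposal(idx) for g, idx in model.update_groups.items()}
    acc = {g: 0 for g in proposals}

    kept_x, kept_pw = [], []
    for it in range(n_iter):
        for gname, prop_dist in proposals.items():
            prop = prop_dist.propose(x, rng)
            lp_prop, pw_prop = model.log_posterior(prop)
            accepted = np.log(rng.uniform()) < lp_prop - lp
            if accepted:
                x, lp, pw = prop, lp_prop, pw_prop
            if it < burn:
                prop_dist.adapt(x, accepted)
            else:
                acc[gname] += int(accepted)
        if it % 10 == 0:  # periodic; the etas decorrelate in a few passes
            for coord in model.slice_coords:
                x, lp, pw = _slice_update(model, x, lp, pw, coord, 1.0, rng)
        if it >= burn and (it - burn) % thin == 0:
            kept_x.append(x.copy())
            kept_pw.append(pw.copy())
    rates = {g: acc[g] / max(n_iter - burn, 1) for g in proposals}
    return np.asarray(kept_x), np.asarray(kept_pw), rates


def run_mcmc(
    dataset: TagDataset,
    reporting: ReportingRates,
    age_sample: AgeLengthSample | None,
    config: MovementConfig = MovementConfig("C"),
    n_chains: int = 5,
    n_iter: int = 50_000,
    burn: int | None = None,
    thin: int = 10,
    seed: int | None = None,
    plugin_kappa: bool = False,
    pointwise: str = "stratum",
    priors: PriorSpec = PriorSpec(),
    warm_start: int = 4000,
) -> PosteriorRun:
    """Sample the posterior of one movement configuration.

    Defaults: 5 chains initialised from the prior, 50% burn-in, thinning 10.
    ``warm_start`` caps the quasi-Newton ascent (in posterior evaluations)
    that moves each prior-drawn start into the high-density region before
    adaptation begins; 0 disables it. A seed is required for
    reproducibility; two runs with identical inputs and seed produce
    identical draws. Non-convergence (any multi-chain Gelman-Rubin
    statistic >= 1.1) flags the run but does not discard it.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if n_chains < 2:
        logger.warning("fewer than 2 chains: Gelman-Rubin diagnostics undefined")
    if burn is None:
        burn = n_iter // 2
    model = TagReturnModel(
        dataset, reporting, age_sample, config,
        priors=priors, plugin_kappa=plugin_kappa, pointwise=pointwise,
    )
    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_x, all_pw, rates_acc = [], [], []
    for cs in child_seeds:
        kx, kpw, rates = _run_chain(
            model, n_iter, burn, thin, np.random.default_rng(cs),
            warm_start=warm_start,
        )
        all_x.append(kx)
        all_pw.append(kpw)
        rates_acc.append(rates)
    draws = np.asarray(all_x)  # (C, S, D)
    pointwise_ll = np.asarray(all_pw)
    rhat = gelman_rubin(draws) if n_chains >= 2 else np.full(draws.shape[-1], np.nan)
    natural = _natural_draws(model.space, draws)
    mean_rates = {
        g: float(np.mean([r[g] for r in rates_acc])) for g in rates_acc[0]
    }
    run = PosteriorRun(
        model=model, draws=draws, natural=natural, pointwise=pointwise_ll,
        param_names=model.space.flat_names(), rhat=rhat, seed=seed,
        n_iter=n_iter, burn=burn, thin=thin, accept_rates=mean_rates,
    )
    if not run.converged:
        logger.warning("run flagged: max rhat %.3f >= 1.1", np.nanmax(rhat))
    return run


def _natural_draws(space: ParameterSpace, draws: np.ndarray) -> np.ndarray:
    out = np.empty_like(draws)
    for b in space.blocks:
        sl = space.slices[b.name]
        seg = draws[..., sl]
        if isinstance(b.transform, LogTransform):
            out[..., sl] = np.exp(seg)
        else:
            t = b.transform
            out[..., sl] = t.lo + (t.hi - t.lo) / (1.0 + np.exp(-seg))
    return out


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per scalar parameter.

    ``draws`` has shape (chains, iterations, parameters) with equal-length
    chains. Parameters with zero within-chain variance get NaN (undefined).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("need draws shaped (>=2 chains, iterations, parameters)")
    m, n = draws.shape[0], draws.shape[1]
    chain_means = draws.mean(axis=1)  # (m, P)
    chain_vars = draws.var(axis=1, ddof=1)  # (m, P)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (n - 1) / n * W + B / n
        rhat = np.sqrt(var_plus / W)
    # constant (or numerically constant) parameters have no defined rhat
    scale = 1.0 + chain_means.mean(axis=0) ** 2
    rhat[W <= 1e-13 * scale] = np.nan
    return rhat


# ---------------------------------------------------------------------------
# Information criteria (all on the deviance scale; smaller is better)
# ---------------------------------------------------------------------------

@dataclass
class DICResult:
    dic: float
    dbar: float
    pd_dic: float


@dataclass
class WAICResult:
    waic: float
    lppd: float
    pd_waic: float


@dataclass
class LOOResult:
    loo: float
    elpd_loo: float
    pareto_k: np.ndarray

    @property
    def n_bad_k(self) -> int:
        return int((self.pareto_k > 0.7).sum())


def compute_dic(pointwise_loglik: np.ndarray,
                deviance_at_point_estimate: float) -> DICResult:
    """Deviance information criterion.

    ``pd = mean deviance - deviance at the posterior point estimate`` and
    ``DIC = mean deviance + pd``. A negative ``pd`` (a known DIC pathology)
    is reported with a warning, not an error.
    """
    ll = np.asarray(pointwise_loglik, dtype=float).reshape(
        -1, pointwise_loglik.shape[-1]
    )
    deviances = -2.0 * ll.sum(axis=1)
    dbar = float(deviances.mean())
    pd = dbar - float(deviance_at_point_estimate)
    if pd < 0:
        logger.warning("DIC effective parameter count negative (pd=%.3f)", pd)
    return DICResult(dic=dbar + pd, dbar=dbar, pd_dic=pd)


def compute_waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """Widely applicable information criterion with the variance penalty.

    ``lppd = sum_i log mean_s p(y_i | theta_s)``; ``pd = sum_i var_s log p``;
    ``WAIC = -2 (lppd - pd)``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float).reshape(
        -1, pointwise_loglik.shape[-1]
    )
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    S = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - np.log(S)).sum())
    pd = float(ll.var(axis=0, ddof=1).sum())
    return WAICResult(waic=-2.0 * (lppd - pd), lppd=lppd, pd_waic=pd)


def compute_psis_loo(pointwise_loglik: np.ndarray, reff: float = 1.0) -> LOOResult:
    """Leave-one-out predictive fit via Pareto-smoothed importance sampling.

    Raw importance ratios are the inverse pointwise likelihoods; their upper
    tail is stabilised by a generalized-Pareto fit (PSIS). Reported as
    ``LOO = -2 sum_i elpd_i`` to match the deviance scale of DIC/WAIC.
    Observations with Pareto k > 0.7 are unreliable and counted in
    ``n_bad_k``.
    """
    from arviz import psislw

    ll = np.asarray(pointwise_loglik, dtype=float).reshape(
        -1, pointwise_loglik.shape[-1]
    )
    if ll.shape[0] < 2:
        raise ValueError("PSIS-LOO needs at least two posterior draws")
    # psislw expects (..., n_samples) with observations leading
    lw, k = psislw(-ll.T, reff=reff)
    elpd_i = logsumexp(ll.T + lw, axis=1)
    elpd = float(elpd_i.sum())
    return LOOResult(loo=-2.0 * elpd, elpd_loo=elpd, pareto_k=np.asarray(k))


@dataclass
class ComparisonResult:
    """DIC/WAIC/LOO for a set of runs, with deltas to the best model."""

    table: pd.DataFrame

    def best(self, criterion: str = "loo") -> str:
        return str(self.table.sort_values(criterion).iloc[0]["model"])


def criteria_for_run(run: PosteriorRun) -> dict[str, float]:
    """All three criteria for one posterior run."""
    pw = run.stacked_pointwise()
    dev_hat = -2.0 * float(run.model.pointwise_at(run.posterior_mean_x()).sum())
    dic = compute_dic(pw, dev_hat)
    waic = compute_waic(pw)
    loo = compute_psis_loo(pw)
    return {
        "dic": dic.dic, "pd_dic": dic.pd_dic,
        "waic": waic.waic, "pd_waic": waic.pd_waic,
        "loo": loo.loo, "n_bad_pareto_k": loo.n_bad_k,
        "max_rhat": float(np.nanmax(run.rhat)) if run.rhat.size else np.nan,
    }


def compare_runs(runs: dict[str, PosteriorRun]) -> ComparisonResult:
    """Rank movement configurations fitted to the same dataset.

    The table carries DIC/WAIC/LOO plus deltas to the per-criterion minimum,
    ordered by increasing delta-LOO.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    datasets = {id(r.model.dataset) for r in runs.values()}
    if len(datasets) > 1:
        totals = {
            (r.model.dataset.total_releases, r.model.dataset.total_recoveries)
            for r in runs.values()
        }
        if len(totals) > 1:
            raise ValueError("runs were fitted to different datasets")
    rows = []
    for name, run in runs.items():
        rows.append({"model": name, **criteria_for_run(run)})
    df = pd.DataFrame(rows)
    for c in ("dic", "waic", "loo"):
        df[f"delta_{c}"] = df[c] - df[c].min()
    df = df.sort_values("delta_loo").reset_index(drop=True)
    cols = ["model", "dic", "delta_dic", "waic", "delta_waic",
            "loo", "delta_loo", "pd_dic", "pd_waic", "n_bad_pareto_k", "max_rhat"]
    return ComparisonResult(table=df[cols])
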