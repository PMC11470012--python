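"""Maximum-likelihood fitting and model selection for dancefloor mixtures.

Two nested model variants are fitted to each hive's waggle-run durations:

* the **individual** model — every trip is a scout trip (``p = 1``); two
  free parameters ``(a_s, b_s)``;
* the **collective** model — the scout fraction ``p`` is free on
  ``[0, 1]``; five free parameters ``(p, a_s, b_s, a_r, b_r)``.

The truncation point ``m`` is fixed at the dataset minimum and not
counted as a free parameter.  The variants are compared with AIC and
Akaike weights, goodness of fit is assessed with a bootstrapped
two-sample Kolmogorov–Smirnov test against a sample drawn from the
fitted model, and ``1 - p`` from the collective fit estimates the
colony's waggle dance use.

Likelihoods are maximised with Nelder–Mead on transformed parameters
(``logit`` for the scout support fraction and for ``p``, ``log`` for the
intensity factors and the recruit scale), started from a Latin-hypercube
screen: the likelihood surface carries boundary ridges where
``a * max(x) -> 1``, and a single local search is not reliable there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize
from scipy.stats import qmc

from .data import WaggleDataset
from .distributions import (
    MixtureParams,
    RecruitParams,
    ScoutParams,
    log_likelihood,
    sample_mixture,
    scout_norm,
    scout_pdf,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "KSResult",
    "PooledComparison",
    "fit_individual",
    "fit_collective",
    "fit_both",
    "compare_models",
    "bootstrap_ks_gof",
    "fit_pooled",
]

_N_FREE = {"individual": 2, "collective": 5}


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings shared by both model variants.

    ``n_starts`` Latin-hypercube points are screened by log-likelihood
    and the best ``n_polish`` are refined with Nelder–Mead; the
    collective fit additionally polishes a start anchored at the
    individual optimum so the nested model never scores worse.
    """

    n_starts: int = 32
    n_polish: int = 4
    min_observations: int = 10
    maxiter: int = 4000
    xatol: float = 1e-8
    fatol: float = 1e-10
    lhs_seed: int = 0
    # hard bounds keeping the parameter space compact: with m at the data
    # minimum the mixture likelihood is otherwise unbounded (a spike
    # component of arbitrarily large intensity at the support edge), the
    # textbook mixture-MLE degeneracy.  The recruit lower bound also
    # encodes the model's premise that the intensity of high-quality
    # resources is sizable: below b_r ~ 0.5 the Gaussian factor barely
    # decays inside the support and the component degenerates to a
    # free-form bump with no Rayleigh character left.
    b_s_bounds: tuple[float, float] = (0.1, 100.0)
    b_r_bounds: tuple[float, float] = (0.5, 100.0)
    u_r_bounds: tuple[float, float] = (0.02, 2.0)  # bounds on a_r * max(x)


@dataclass(frozen=True)
class FitResult:
    """One model variant fitted to one hive."""

    model_kind: str  # "individual" | "collective"
    hive_id: str
    params: MixtureParams
    loglik: float
    n_free_params: int
    nobs: int
    converged: bool
    n_restarts_used: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.loglik


@dataclass(frozen=True)
class KSResult:
    """Bootstrapped two-sample Kolmogorov–Smirnov goodness-of-fit result."""

    ks_statistic: float
    pvalue: float
    n_boot: int
    model_sample_size: int
    seed: int | None

    def __post_init__(self) -> None:
        assert 0.0 <= self.ks_statistic <= 1.0
        assert 0.0 <= self.pvalue <= 1.0


@dataclass
class ModelComparison:
    """AIC comparison of the individual and collective fits for one hive."""

    hive_id: str
    individual: FitResult
    collective: FitResult
    gof_individual: KSResult | None = None
    gof_collective: KSResult | None = None

    @property
    def delta_aic(self) -> float:
        """AIC(individual) - AIC(collective); positive favours collective."""
        return self.individual.aic - self.collective.aic

    @property
    def akaike_weights(self) -> tuple[float, float]:
        """(individual, collective) relative support; sums to 1."""
        aics = np.array([self.individual.aic, self.collective.aic])
        rel = np.exp(-(aics - aics.min()) / 2.0)
        w = rel / rel.sum()
        return float(w[0]), float(w[1])

    @property
    def selected(self) -> str:
        # ties (to within numerical noise) go to the simpler model
        return "collective" if self.delta_aic > 1e-9 else "individual"

    @property
    def waggle_dance_use(self) -> float:
        """Estimated fraction of trips driven by recruitment, 1 - p."""
        return 1.0 - self.collective.params.p

    def classify(self, alpha: float = 0.05) -> str:
        """Hive-level verdict: which model wins, or neither fits.

        A hive where both variants fail the goodness-of-fit test at
        ``alpha`` is reported as having no acceptable fit.
        """
        if self.gof_individual is None or self.gof_collective is None:
            raise ValueError("goodness-of-fit results not attached; run the KS test first")
        if self.gof_individual.pvalue < alpha and self.gof_collective.pvalue < alpha:
            return "no-acceptable-fit"
        return f"{self.selected}-selected"


@dataclass
class PooledComparison:
    """Pooled-versus-per-hive comparison for one group of hives."""

    pooled: ModelComparison
    per_hive: list[ModelComparison]

    @property
    def sum_per_hive_best_aic(self) -> float:
        return float(sum(min(c.individual.aic, c.collective.aic) for c in self.per_hive))

    @property
    def pooled_best_aic(self) -> float:
        return float(min(self.pooled.individual.aic, self.pooled.collective.aic))

    @property
    def delta_aic(self) -> float:
        """AIC(pooled) - sum of per-hive best AICs; positive favours per-hive fits."""
        return self.pooled_best_aic - self.sum_per_hive_best_aic

    @property
    def akaike_weights(self) -> tuple[float, float]:
        """(per-hive ensemble, pooled) relative support."""
        aics = np.array([self.sum_per_hive_best_aic, self.pooled_best_aic])
        rel = np.exp(-(aics - aics.min()) / 2.0)
        w = rel / rel.sum()
        return float(w[0]), float(w[1])


def _sigmoid(z: NDArray | float) -> NDArray | float:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(q: float) -> float:
    return math.log(q / (1.0 - q))


def _to_interval(z: float, lo: float, hi: float) -> float:
    """Map the real line onto (lo, hi) on a log scale."""
    return lo * (hi / lo) ** _sigmoid(z)


def _from_interval(v: float, lo: float, hi: float) -> float:
    frac = (math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return _logit(min(max(frac, 1e-6), 1.0 - 1e-6))


def _check_data(data: WaggleDataset, config: FitConfig) -> NDArray[np.float64]:
    x = data.durations
    if x.size < config.min_observations:
        raise ValueError(
            f"hive {data.hive_id!r}: {x.size} observations, "
            f"need at least {config.min_observations}"
        )
    if data.m > x.min():
        raise ValueError(f"hive {data.hive_id!r}: m={data.m} exceeds min(durations)")
    return x


def _scout_loglik(x: NDArray[np.float64], a: float, b: float, m: float) -> float:
    # scout-only log-likelihood in closed form (all x within support by construction)
    ms = scout_norm(ScoutParams(a, b, m))
    return float(
        x.size * (math.log(a * b) - math.log(ms))
        - b * a * np.sum(x - m)
        + np.sum(np.log1p(-a * x))
    )


def _polish(fun, starts, config: FitConfig):
    """Nelder-Mead from each start; returns (best_x, best_f, any_converged, n_runs)."""
    best_x, best_f, ok = None, np.inf, False
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.maxiter,
                "maxfev": config.maxiter,
            },
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
            ok = bool(res.success)
    return best_x, best_f, ok, len(starts)


def _lhs(n: int, d: int, seed: int) -> NDArray[np.float64]:
    return qmc.LatinHypercube(d=d, seed=seed).random(n)


def fit_individual(data: WaggleDataset, config: FitConfig | None = None) -> FitResult:
    """Fit the scouting-only model (``p = 1``) by maximum likelihood.

    Free parameters are ``(a_s, b_s)``; ``m`` is fixed at the dataset
    minimum.  The support constraint ``a_s * max(x) < 1`` is built into
    the parameter transform.
    """
    config = config or FitConfig()
    x = _check_data(data, config)
    m, xmax = float(data.m), float(x.max())
    sx, sl = float(np.sum(x - m)), float(x.size)

    b_lo, b_hi = config.b_s_bounds

    def unpack(theta):
        theta = np.clip(theta, -35.0, 35.0)
        return _sigmoid(theta[0]) / xmax, _to_interval(theta[1], b_lo, b_hi)

    def neg(theta):
        a, b = unpack(theta)
        try:
            val = -_scout_loglik(x, a, b, m)
        except (ValueError, OverflowError, ZeroDivisionError):
            return np.inf
        return val if math.isfinite(val) else np.inf

    grid = _lhs(config.n_starts, 2, config.lhs_seed)
    starts = np.column_stack(
        [
            np.vectorize(_logit)(0.30 + 0.65 * grid[:, 0]),
            [_from_interval(v, b_lo, b_hi) for v in 0.1 * 300.0 ** grid[:, 1]],
        ]
    )
    screened = starts[np.argsort([neg(t) for t in starts])[: config.n_polish]]
    theta, f, ok, n_runs = _polish(neg, screened, config)
    a, b = unpack(theta)
    scout = ScoutParams(a, b, m)
    params = MixtureParams(1.0, scout, RecruitParams(a, b, m))  # recruit side unused at p=1
    return FitResult(
        model_kind="individual",
        hive_id=data.hive_id,
        params=params,
        loglik=-f,
        n_free_params=_N_FREE["individual"],
        nobs=x.size,
        converged=ok,
        n_restarts_used=n_runs,
    )


def fit_collective(
    data: WaggleDataset,
    config: FitConfig | None = None,
    individual_start: FitResult | None = None,
) -> FitResult:
    """Fit the full mixture (``p`` free on ``[0, 1]``) by maximum likelihood.

    The scout component is constrained to cover the data
    (``a_s * max(x) < 1``) so the mixture density is positive at every
    observation; the recruit support may end inside the data range, in
    which case the longest runs are carried by the scout component alone.
    A start anchored at the individual-model optimum (``p -> 1``) is
    always polished, so the collective fit never scores below the nested
    individual fit beyond optimiser tolerance.
    """
    config = config or FitConfig()
    x = _check_data(data, config)
    m, xmax = float(data.m), float(x.max())

    bs_lo, bs_hi = config.b_s_bounds
    br_lo, br_hi = config.b_r_bounds
    u_lo, u_hi = config.u_r_bounds

    def unpack(theta):
        theta = np.clip(theta, -35.0, 35.0)
        a_s = _sigmoid(theta[0]) / xmax
        b_s = _to_interval(theta[1], bs_lo, bs_hi)
        a_r = _to_interval(theta[2], u_lo, u_hi) / xmax
        b_r = _to_interval(theta[3], br_lo, br_hi)
        p = _sigmoid(theta[4])
        return p, a_s, b_s, a_r, b_r

    def neg(theta):
        p, a_s, b_s, a_r, b_r = unpack(theta)
        if not all(map(math.isfinite, (a_s, b_s, a_r, b_r))) or a_r * m >= 1.0:
            return np.inf
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = log_likelihood(
                x, MixtureParams(p, ScoutParams(a_s, b_s, m), RecruitParams(a_r, b_r, m))
            )
        return -ll if math.isfinite(ll) else np.inf

    grid = _lhs(config.n_starts, 5, config.lhs_seed)
    starts = np.column_stack(
        [
            np.vectorize(_logit)(0.30 + 0.65 * grid[:, 0]),
            [_from_interval(v, bs_lo, bs_hi) for v in 0.1 * 300.0 ** grid[:, 1]],
            [_from_interval(v, u_lo, u_hi) for v in 0.1 * 13.0 ** grid[:, 2]],
            [_from_interval(v, br_lo, br_hi) for v in 0.5 * 60.0 ** grid[:, 3]],
            np.vectorize(_logit)(0.05 + 0.90 * grid[:, 4]),
        ]
    )
    screened = list(starts[np.argsort([neg(t) for t in starts])[: config.n_polish]])

    ind = individual_start or fit_individual(data, config)
    a0, b0 = ind.params.scout.a_s, ind.params.scout.b_s
    t0, t1 = _logit(min(a0 * xmax, 0.999)), _from_interval(b0, bs_lo, bs_hi)
    screened.append(
        np.array([t0, t1, _from_interval(0.8, u_lo, u_hi), _from_interval(3.0, br_lo, br_hi), _logit(0.99)])
    )
    # hump anchors: place the recruit mode at a low quantile of the data
    # (where a recruitment shoulder would sit) with matching intensity
    # lam = a_r^2 b_r = 1/(2 pi mode^2); the LHS rarely pairs u_r and b_r
    # to hit a sharp hump, so these starts cover that basin explicitly
    for q, p0 in ((0.15, 0.9), (0.15, 0.5), (0.35, 0.7)):
        mode = float(np.quantile(x, q))
        lam = 1.0 / (2.0 * math.pi * mode * mode)
        u0 = 0.6
        b_r0 = min(max(lam * (xmax / u0) ** 2, br_lo), br_hi)
        screened.append(
            np.array(
                [t0, t1, _from_interval(u0, u_lo, u_hi), _from_interval(b_r0, br_lo, br_hi), _logit(p0)]
            )
        )

    theta, f, ok, n_runs = _polish(neg, screened, config)
    p, a_s, b_s, a_r, b_r = unpack(theta)
    params = MixtureParams(p, ScoutParams(a_s, b_s, m), RecruitParams(a_r, b_r, m))
    loglik = -f
    # nested-model guarantee: fall back to the individual optimum if the
    # polished collective fit somehow scored below it
    if loglik < ind.loglik - 1e-6:
        params = replace(ind.params, p=1.0 - 1e-12)
        loglik = log_likelihood(x, params)
    return FitResult(
        model_kind="collective",
        hive_id=data.hive_id,
        params=params,
        loglik=loglik,
        n_free_params=_N_FREE["collective"],
        nobs=x.size,
        converged=ok,
        n_restarts_used=n_runs,
    )


def fit_both(data: WaggleDataset, config: FitConfig | None = None) -> ModelComparison:
    """Fit both model variants and compare them by AIC."""
    ind = fit_individual(data, config)
    col = fit_collective(data, config, individual_start=ind)
    return compare_models(ind, col)


def compare_models(ind: FitResult, col: FitResult) -> ModelComparison:
    """AIC comparison of an individual and a collective fit of one hive."""
    if ind.hive_id != col.hive_id:
        raise ValueError(f"fits are for different hives: {ind.hive_id!r} vs {col.hive_id!r}")
    if ind.model_kind != "individual" or col.model_kind != "collective":
        raise ValueError("expected one individual and one collective fit, in that order")
    return ModelComparison(hive_id=ind.hive_id, individual=ind, collective=col)


def _ks_stat(values: NDArray, n1: int, n2: int) -> NDArray:
    """Two-sample KS statistic, vectorised over rows.

    ``values`` has shape (B, n1 + n2): per row, the first ``n1`` entries
    are sample 1 and the rest sample 2.  Ties are handled by evaluating
    the ECDF difference only at the end of each tie group, as a
    bootstrap over a pooled sample requires.
    """
    w = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order = np.argsort(values, axis=1, kind="stable")
    svals = np.take_along_axis(values, order, axis=1)
    csum = np.cumsum(w[order], axis=1)
    boundary = np.concatenate(
        [svals[:, 1:] != svals[:, :-1], np.ones((values.shape[0], 1), dtype=bool)], axis=1
    )
    return np.max(np.abs(csum) * boundary, axis=1)


def bootstrap_ks_gof(
    data: WaggleDataset,
    fit: FitResult,
    n_boot: int = 1000,
    model_sample_size: int | None = None,
    seed: int | None = None,
) -> KSResult:
    """Bootstrapped two-sample KS test of a fitted model against its data.

    A sample of ``model_sample_size`` durations is drawn from the fitted
    model; the two-sample KS statistic against the observed durations is
    referred to its bootstrap distribution under the null of a common
    parent, obtained by resampling both samples with replacement from
    the pooled data (ties-robust).  Small p-values indicate lack of fit.
    """
    if not fit.converged:
        raise ValueError(
            f"hive {fit.hive_id!r}: refusing goodness-of-fit test on a non-converged fit"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n1 = int(data.durations.size)
    n2 = int(model_sample_size or n1)
    model_sample = sample_mixture(n2, fit.params, rng)
    obs = float(_ks_stat(np.concatenate([data.durations, model_sample])[None, :], n1, n2)[0])
    pooled = np.concatenate([data.durations, model_sample])
    idx = rng.integers(0, n1 + n2, size=(n_boot, n1 + n2))
    boot = _ks_stat(pooled[idx], n1, n2)
    pvalue = (1.0 + np.sum(boot >= obs - 1e-12)) / (n_boot + 1.0)
    return KSResult(
        ks_statistic=obs,
        pvalue=float(pvalue),
        n_boot=n_boot,
        model_sample_size=n2,
        seed=seed,
    )


def fit_pooled(
    datasets: list[WaggleDataset],
    config: FitConfig | None = None,
    label: str = "pooled",
) -> PooledComparison:
    """Fit both models to pooled data and compare with per-hive fits.

    Durations from all hives are concatenated (``m`` becomes the global
    minimum) and both model variants fitted to the pool; the summary
    sets the summed per-hive best AIC against the pooled best AIC, with
    Akaike weights quantifying the support for hive-level heterogeneity.
    """
    if len(datasets) < 2:
        raise ValueError("pooling requires at least two datasets")
    per_hive = [fit_both(d, config) for d in datasets]
    pooled_data = WaggleDataset(
        hive_id=label, durations=np.concatenate([d.durations for d in datasets])
    )
    pooled = fit_both(pooled_data, config)
    return PooledComparison(pooled=pooled, per_hive=per_hive)
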