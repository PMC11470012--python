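"""Scout/recruit mixture distributions for waggle-run durations.

The duration of a waggle run is linearly related to the distance of the
advertised forage site, so the distribution of durations on the dancefloor
mirrors the distribution of foraging distances.  Two processes generate
those distances:

* **Scout trips** — a bee searching independently along a roughly straight
  path encounters its first resource after an exponentially distributed
  distance (1-D nearest-neighbour).  Truncating below at the minimum
  recorded duration ``m`` and applying a linear taper ``(1 - a_s x)_+``
  (dances for the longest trips are under-represented) gives the scout
  density

  ``f_s(x) = a_s * M_s^{-1} * b_s * exp(-b_s a_s (x - m)) * (1 - a_s x)_+``

  on ``[m, 1/a_s)``, where ``1/a_s`` is the maximum scout waggle-run
  duration, ``a_s b_s`` the intensity of resources found by scouts, and

  ``M_s = (1 - a_s m) - (1/b_s) (1 - exp(-b_s (1 - a_s m)))``

  normalises the density.

* **Recruit trips** — dance-following bees converge on the nearest
  high-quality resource in the two-dimensional neighbourhood of the hive,
  whose distance follows a Rayleigh law.  With the same truncation and
  taper the recruit density is

  ``f_r(x) = M_r^{-1} * 2 pi a_r^2 b_r x * exp(-pi b_r (a_r x)^2) * (1 - a_r x)_+``

  on ``[m, 1/a_r)``, with ``a_r^2 b_r`` the intensity of high-quality
  resources and normaliser

  ``M_r = (1 - a_r m) exp(-pi b_r (a_r m)^2)
          + (erf(a_r m sqrt(pi b_r)) - erf(sqrt(pi b_r))) / (2 sqrt(b_r))``.

  (This erf argument, ``a_r * m * sqrt(pi b_r)``, is the one under which
  the density integrates to exactly 1; see docs/methods.md for the
  derivation.)

The dancefloor mixes the two: a fraction ``p`` of trips are scout trips,

  ``P(x) = p f_s(x) + (1 - p) f_r(x)``,

so ``1 - p`` — the fraction of recruit trips — measures how much of the
colony's foraging is driven by waggle-dance recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import erf

__all__ = [
    "ParameterError",
    "ScoutParams",
    "RecruitParams",
    "MixtureParams",
    "scout_norm",
    "recruit_norm",
    "scout_pdf",
    "recruit_pdf",
    "mixture_pdf",
    "scout_cdf",
    "recruit_cdf",
    "mixture_cdf",
    "log_likelihood",
    "sample_scout",
    "sample_recruit",
    "sample_mixture",
]


class ParameterError(ValueError):
    """A parameter set violates the domain of the mixture model."""


@dataclass(frozen=True)
class ScoutParams:
    """Parameters of the truncated, tapered exponential scout density.

    Parameters
    ----------
    a_s : float
        Inverse of the maximum scout waggle-run duration (1/s).
    b_s : float
        Dimensionless intensity factor; ``a_s * b_s`` is the encounter
        intensity of resources found by scouts.
    m : float
        Minimum recorded waggle-run duration (s); lower truncation point.
    """

    a_s: float
    b_s: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_s > 0 and self.b_s > 0):
            raise ParameterError(
                f"a_s and b_s must be positive (got a_s={self.a_s}, b_s={self.b_s})"
            )
        if self.m < 0 or self.a_s * self.m >= 1:
            raise ParameterError(
                f"need 0 <= m and a_s*m < 1 for a nonempty support "
                f"(got a_s={self.a_s}, m={self.m})"
            )

    @property
    def upper(self) -> float:
        """Upper end of the support, the maximum scout duration ``1/a_s``."""
        return 1.0 / self.a_s


@dataclass(frozen=True)
class RecruitParams:
    """Parameters of the truncated, tapered Rayleigh recruit density.

    ``a_r`` sets how fast dance repetition falls with distance for recruit
    trips; ``a_r**2 * b_r`` is the intensity of high-quality resources.
    """

    a_r: float
    b_r: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_r > 0 and self.b_r > 0):
            raise ParameterError(
                f"a_r and b_r must be positive (got a_r={self.a_r}, b_r={self.b_r})"
            )
        if self.m < 0 or self.a_r * self.m >= 1:
            raise ParameterError(
                f"need 0 <= m and a_r*m < 1 for a nonempty support "
                f"(got a_r={self.a_r}, m={self.m})"
            )

    @property
    def upper(self) -> float:
        return 1.0 / self.a_r


@dataclass(frozen=True)
class MixtureParams:
    """Full parameter set (p, a_s, b_s, a_r, b_r, m) of the dancefloor mixture.

    ``p`` is the fraction of scout trips; ``1 - p`` (the fraction of
    recruit trips) is the colony's *waggle dance use*.  Both components
    share the single dataset minimum ``m``.
    """

    p: float
    scout: ScoutParams
    recruit: RecruitParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"mixture weight p must lie in [0, 1] (got {self.p})")
        if self.scout.m != self.recruit.m:
            raise ParameterError(
                "scout and recruit components must share the same minimum m "
                f"(got {self.scout.m} and {self.recruit.m})"
            )

    @property
    def m(self) -> float:
        return self.scout.m

    @property
    def upper(self) -> float:
        """Upper end of the mixture support, ``max(1/a_s, 1/a_r)``."""
        if self.p == 0.0:
            return self.recruit.upper
        if self.p == 1.0:
            return self.scout.upper
        return max(self.scout.upper, self.recruit.upper)

    @classmethod
    def from_values(
        cls, p: float, a_s: float, b_s: float, a_r: float, b_r: float, m: float = 0.0
    ) -> "MixtureParams":
        return cls(p, ScoutParams(a_s, b_s, m), RecruitParams(a_r, b_r, m))

    def as_dict(self) -> dict[str, float]:
        return {
            "p": self.p,
            "a_s": self.scout.a_s,
            "b_s": self.scout.b_s,
            "a_r": self.recruit.a_r,
            "b_r": self.recruit.b_r,
            "m": self.m,
        }


def scout_norm(params: ScoutParams) -> float:
    """Normalising constant M_s of the scout density."""
    t = 1.0 - params.a_s * params.m
    return t - (1.0 - math.exp(-params.b_s * t)) / params.b_s


def recruit_norm(params: RecruitParams) -> float:
    """Normalising constant M_r of the recruit density.

    Closed form of the integral of the unnormalised Rayleigh-with-taper
    integrand over ``[m, 1/a_r]``; the erf argument is ``a_r m sqrt(pi b_r)``.
    """
    a, b, m = params.a_r, params.b_r, params.m
    u0 = a * m
    root = math.sqrt(math.pi * b)
    return (1.0 - u0) * math.exp(-math.pi * b * u0 * u0) + (
        erf(u0 * root) - erf(root)
    ) / (2.0 * math.sqrt(b))


def scout_pdf(x: ArrayLike, params: ScoutParams) -> NDArray[np.float64]:
    """Density of waggle-run durations reported from scout trips.

    Zero below ``m`` and at or above ``1/a_s``.
    """
    x = np.asarray(x, dtype=float)
    a, b, m = params.a_s, params.b_s, params.m
    hinge = np.maximum(1.0 - a * x, 0.0)
    core = a * b * np.exp(-b * a * (x - m)) * hinge / scout_norm(params)
    return np.where(x >= m, core, 0.0)


def recruit_pdf(x: ArrayLike, params: RecruitParams) -> NDArray[np.float64]:
    """Density of waggle-run durations reported from recruit trips.

    With ``m = 0`` and the taper removed this is the Rayleigh density
    ``2 pi lam x exp(-pi lam x^2)`` with intensity ``lam = a_r^2 b_r``.
    """
    x = np.asarray(x, dtype=float)
    a, b, m = params.a_r, params.b_r, params.m
    hinge = np.maximum(1.0 - a * x, 0.0)
    core = (
        2.0 * math.pi * a * a * b * x
        * np.exp(-math.pi * b * (a * x) ** 2)
        * hinge
        / recruit_norm(params)
    )
    return np.where(x >= m, core, 0.0)


def mixture_pdf(x: ArrayLike, params: MixtureParams) -> NDArray[np.float64]:
    """Dancefloor density ``p f_s + (1-p) f_r``."""
    p = params.p
    if p == 1.0:
        return scout_pdf(x, params.scout)
    if p == 0.0:
        return recruit_pdf(x, params.recruit)
    return p * scout_pdf(x, params.scout) + (1.0 - p) * recruit_pdf(x, params.recruit)


def _scout_cdf_unnorm(x: NDArray[np.float64], params: ScoutParams) -> NDArray[np.float64]:
    # integral of the unnormalised scout integrand from m to min(x, 1/a)
    a, b, m = params.a_s, params.b_s, params.m
    t = 1.0 - a * m
    s = np.clip(a * (x - m), 0.0, t)
    e = np.exp(-b * s)
    return t * (1.0 - e) + s * e - (1.0 - e) / b


def scout_cdf(x: ArrayLike, params: ScoutParams) -> NDArray[np.float64]:
    """Closed-form CDF of the scout density."""
    x = np.asarray(x, dtype=float)
    return _scout_cdf_unnorm(x, params) / scout_norm(params)


def _recruit_cdf_unnorm(
    x: NDArray[np.float64], params: RecruitParams
) -> NDArray[np.float64]:
    a, b, m = params.a_r, params.b_r, params.m
    u0 = a * m
    u1 = np.clip(a * x, u0, 1.0)
    c = math.pi * b
    root = math.sqrt(c)
    return (
        (1.0 - u0) * math.exp(-c * u0 * u0)
        - (1.0 - u1) * np.exp(-c * u1 * u1)
        + (erf(u0 * root) - erf(u1 * root)) / (2.0 * math.sqrt(b))
    )


def recruit_cdf(x: ArrayLike, params: RecruitParams) -> NDArray[np.float64]:
    """Closed-form CDF of the recruit density."""
    x = np.asarray(x, dtype=float)
    return _recruit_cdf_unnorm(x, params) / recruit_norm(params)


def mixture_cdf(x: ArrayLike, params: MixtureParams) -> NDArray[np.float64]:
    """Closed-form CDF of the dancefloor mixture.

    Monotone nondecreasing, 0 at ``x <= m`` and 1 at
    ``x >= max(1/a_s, 1/a_r)``; used for complementary-cumulative plots
    and for sampling.
    """
    p = params.p
    if p == 1.0:
        return scout_cdf(x, params.scout)
    if p == 0.0:
        return recruit_cdf(x, params.recruit)
    return p * scout_cdf(x, params.scout) + (1.0 - p) * recruit_cdf(x, params.recruit)


def log_likelihood(durations: ArrayLike, params: MixtureParams) -> float:
    """Log-likelihood of the mixture parameters given observed durations.

    Returns ``-inf`` if any observation falls where the mixture density is
    zero (outside ``[m, max(1/a_s, 1/a_r))``), so that optimisers reject
    parameter points whose support excludes part of the data.
    """
    x = np.asarray(durations, dtype=float)
    if x.size == 0:
        raise ValueError("log_likelihood requires at least one observation")
    dens = mixture_pdf(x, params)
    if np.any(dens <= 0.0):
        return -np.inf
    return float(np.sum(np.log(dens)))


def _rejection_sample(n, rng, propose, accept_prob):
    # draw from proposal until n accepted; both callables are vectorised
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        k = max(n - filled, 64)
        cand = propose(2 * k, rng)
        keep = cand[rng.random(cand.size) < accept_prob(cand)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_scout(
    n: int, params: ScoutParams, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Draw ``n`` scout durations by rejection from a truncated exponential."""
    a, b, m = params.a_s, params.b_s, params.m
    rate = a * b
    span = 1.0 / a - m
    # inverse-CDF truncated exponential proposal on [m, 1/a]
    cmax = -math.expm1(-rate * span)

    def propose(k, rng):
        return m - np.log1p(-rng.random(k) * cmax) / rate

    def accept(x):
        return (1.0 - a * x) / (1.0 - a * m)

    return _rejection_sample(n, rng, propose, accept)


def sample_recruit(
    n: int, params: RecruitParams, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Draw ``n`` recruit durations by rejection from a truncated Rayleigh."""
    a, b, m = params.a_r, params.b_r, params.m
    lam = a * a * b  # Rayleigh intensity: 2 pi lam x exp(-pi lam x^2)
    # Rayleigh CDF is 1 - exp(-pi lam x^2); invert a uniform restricted to
    # [F(m), F(1/a)] for an exact truncated proposal
    fm = -math.expm1(-math.pi * lam * m * m)
    fu = -math.expm1(-math.pi * lam / (a * a))

    def propose(k, rng):
        u = fm + rng.random(k) * (fu - fm)
        return np.sqrt(-np.log1p(-u) / (math.pi * lam))

    def accept(x):
        return (1.0 - a * x) / (1.0 - a * m)

    return _rejection_sample(n, rng, propose, accept)


def sample_mixture(
    n: int,
    params: MixtureParams,
    seed: int | np.random.Generator | None = None,
) -> NDArray[np.float64]:
    """Draw ``n`` i.i.d. waggle-run durations from the dancefloor mixture.

    Each draw picks its component with probability ``p`` (scout) versus
    ``1-p`` (recruit), then samples that component exactly by rejection
    from its truncated base distribution.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_scout = int(rng.binomial(n, params.p))
    out = np.empty(n, dtype=float)
    if n_scout:
        out[:n_scout] = sample_scout(n_scout, params.scout, rng)
    if n - n_scout:
        out[n_scout:] = sample_recruit(n - n_scout, params.recruit, rng)
    rng.shuffle(out)
    return out
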