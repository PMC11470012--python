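"""Model/results interface for fitting dancefloor mixtures to hive data.

Follows the familiar two-object pattern: :class:`WaggleRunMixture` is
built from one hive's decoded waggle-run durations and its ``fit``
method returns a :class:`WaggleMixtureResults` carrying the estimates,
fit statistics and diagnostics, with ``summary()`` for a readable table.

Example
-------
>>> import numpy as np
>>> from wagglemix import WaggleRunMixture, MixtureParams, sample_mixture
>>> truth = MixtureParams.from_values(p=0.3, a_s=0.2, b_s=1.5, a_r=0.3, b_r=3.0, m=0.5)
>>> x = sample_mixture(500, truth, seed=7)
>>> res = WaggleRunMixture(x, hive_id="H1").fit(kind="collective")
>>> 0.0 <= res.params.p <= 1.0
True
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .data import WaggleDataset
from .distributions import MixtureParams, log_likelihood, mixture_cdf, sample_mixture
from .fitting import (
    FitConfig,
    FitResult,
    KSResult,
    ModelComparison,
    bootstrap_ks_gof,
    fit_both,
    fit_collective,
    fit_individual,
)

__all__ = ["WaggleRunMixture", "WaggleMixtureResults"]


class WaggleRunMixture:
    """Scout/recruit mixture model for one hive's waggle-run durations.

    Parameters
    ----------
    durations : array-like of float
        Waggle-run durations in seconds.
    hive_id : str
        Label for the hive (used in reports).
    m : float, optional
        Truncation point; defaults to the smallest observed duration.
    site_class : str, optional
        Landscape category of the hive location.
    """

    def __init__(
        self,
        durations: ArrayLike,
        hive_id: str = "hive",
        m: float | None = None,
        site_class: str | None = None,
    ) -> None:
        self.data = WaggleDataset(
            hive_id=hive_id, durations=np.asarray(durations, float), m=m, site_class=site_class
        )

    @classmethod
    def from_dataset(cls, data: WaggleDataset) -> "WaggleRunMixture":
        obj = cls.__new__(cls)
        obj.data = data
        return obj

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str = "duration_s",
        hive_id: str = "hive",
        site_class: str | None = None,
    ) -> "WaggleRunMixture":
        """Build a model from a tidy DataFrame with one row per dance."""
        if duration_col not in df.columns:
            raise KeyError(f"column {duration_col!r} not found")
        return cls(df[duration_col].to_numpy(float), hive_id=hive_id, site_class=site_class)

    @property
    def nobs(self) -> int:
        return self.data.nobs

    def loglike(self, params: MixtureParams) -> float:
        """Log-likelihood of ``params`` given this hive's durations."""
        return log_likelihood(self.data.durations, params)

    def fit(
        self, kind: str = "collective", config: FitConfig | None = None
    ) -> "WaggleMixtureResults":
        """Fit one model variant ("collective" or "individual") by MLE."""
        if kind == "individual":
            raw = fit_individual(self.data, config)
        elif kind == "collective":
            raw = fit_collective(self.data, config)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        return WaggleMixtureResults(self, raw)

    def fit_compare(self, config: FitConfig | None = None) -> ModelComparison:
        """Fit both variants and return their AIC comparison."""
        return fit_both(self.data, config)


class WaggleMixtureResults:
    """Fitted dancefloor mixture for one hive.

    Attributes
    ----------
    params : MixtureParams
        Maximum-likelihood parameter estimates.
    llf : float
        Maximised log-likelihood (nats).
    aic : float
        ``2k - 2 llf`` with ``k`` the number of free parameters.
    """

    def __init__(self, model: WaggleRunMixture, raw: FitResult) -> None:
        self.model = model
        self._raw = raw

    # -- pass-throughs -------------------------------------------------
    @property
    def params(self) -> MixtureParams:
        return self._raw.params

    @property
    def model_kind(self) -> str:
        return self._raw.model_kind

    @property
    def llf(self) -> float:
        return self._raw.loglik

    @property
    def aic(self) -> float:
        return self._raw.aic

    @property
    def df_model(self) -> int:
        return self._raw.n_free_params

    @property
    def nobs(self) -> int:
        return self._raw.nobs

    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def waggle_dance_use(self) -> float:
        """Estimated fraction of trips driven by recruitment, ``1 - p``."""
        return 1.0 - self.params.p

    # -- diagnostics ---------------------------------------------------
    def ks_test(
        self, n_boot: int = 1000, model_sample_size: int | None = None, seed: int | None = None
    ) -> KSResult:
        """Bootstrapped two-sample KS goodness-of-fit test."""
        return bootstrap_ks_gof(
            self.model.data, self._raw, n_boot=n_boot, model_sample_size=model_sample_size, seed=seed
        )

    def sample(self, n: int, seed: int | None = None) -> NDArray[np.float64]:
        """Draw durations from the fitted mixture."""
        return sample_mixture(n, self.params, seed)

    def cdf(self, x: ArrayLike) -> NDArray[np.float64]:
        return mixture_cdf(x, self.params)

    def plot_ccdf(self, ax=None, **kwargs):
        """Complementary cumulative frequency of data with the fitted curve."""
        from .plotting import plot_ccdf

        return plot_ccdf(self.model.data.durations, params=self.params, ax=ax, **kwargs)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.params.as_dict()
        lines = [
            "Waggle-run duration mixture",
            "=" * 46,
            f"{'Hive:':<26}{self._raw.hive_id}",
            f"{'Model:':<26}{self.model_kind}",
            f"{'No. observations:':<26}{self.nobs}",
            f"{'Free parameters:':<26}{self.df_model}",
            f"{'Log-likelihood:':<26}{self.llf:.3f}",
            f"{'AIC:':<26}{self.aic:.3f}",
            f"{'Converged:':<26}{self.converged}",
            "-" * 46,
            f"{'p (scout fraction):':<26}{d['p']:.4f}",
            f"{'waggle dance use (1-p):':<26}{1 - d['p']:.4f}",
            f"{'a_s (1/s):':<26}{d['a_s']:.4f}",
            f"{'b_s:':<26}{d['b_s']:.4f}",
        ]
        if self.model_kind == "collective":
            lines += [
                f"{'a_r (1/s):':<26}{d['a_r']:.4f}",
                f"{'b_r:':<26}{d['b_r']:.4f}",
            ]
        lines += [f"{'m (s, fixed):':<26}{d['m']:.4f}", "=" * 46]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<WaggleMixtureResults {self.model_kind} hive={self._raw.hive_id!r} "
            f"llf={self.llf:.2f} aic={self.aic:.2f}>"
        )
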