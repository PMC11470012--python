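"""Container for one hive's decoded waggle-run durations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .distributions import MixtureParams

__all__ = ["WaggleDataset"]


@dataclass
class WaggleDataset:
    """Decoded waggle-run durations for a single observation hive.

    Parameters
    ----------
    hive_id : str
        Label identifying the hive.
    durations : array-like of float
        Waggle-run durations in seconds, one per decoded dance.
    m : float, optional
        Minimum duration considered (truncation point of the model).
        Defaults to ``min(durations)``.
    site_class : str, optional
        Landscape category of the hive location ("urban", "agri-rural", ...).
    ground_truth : MixtureParams, optional
        Generating parameters, attached by the synthetic-study generator
        so recovery can be scored.
    """

    hive_id: str
    durations: NDArray[np.float64]
    m: float | None = None
    site_class: str | None = None
    ground_truth: MixtureParams | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size < 1:
            raise ValueError(f"hive {self.hive_id!r}: need at least one duration")
        if np.any(self.durations <= 0):
            raise ValueError(f"hive {self.hive_id!r}: durations must be positive")
        if self.m is None:
            self.m = float(self.durations.min())

    def __len__(self) -> int:
        return int(self.durations.size)

    @property
    def nobs(self) -> int:
        return len(self)
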