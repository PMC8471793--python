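"""The sampled cumulative-release curve and replicate handling.

A :class:`ReleaseProfile` holds one dissolution measurement series: sampling
times in minutes and cumulative API release as a percentage of the total drug
load ``c_inf`` (the 100 % anchor).  Replicate vessels of the same design are
separate profiles sharing formulation label and SA/V; :func:`mean_profile`
averages them point-wise on their common schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DomainError, NonMonotoneWarning

__all__ = ["ReleaseProfile", "mean_profile"]


@dataclass
class ReleaseProfile:
    """Cumulative release curve sampled at strictly increasing times.

    Parameters
    ----------
    times : sampling times in minutes, strictly increasing, first >= 0.
    releases : cumulative release at each time, % of ``c_inf``.  Small
        negative values and overshoot (down to -0.5, up to 110) are allowed
        as measurement noise.
    c_inf : percent-scale anchor for complete release (default 100).
    replicate : vessel/replicate identifier, optional.
    formulation : formulation label, optional.
    sav : surface-area-to-volume ratio of the dosage form in mm^-1, optional.
    """

    times: np.ndarray
    releases: np.ndarray
    c_inf: float = 100.0
    replicate: int | None = None
    formulation: str | None = None
    sav: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.releases = np.asarray(self.releases, dtype=float)
        if self.times.ndim != 1 or self.releases.ndim != 1:
            raise DomainError("times and releases must be 1-D sequences")
        if self.times.size != self.releases.size:
            raise DomainError(
                f"times ({self.times.size}) and releases ({self.releases.size}) "
                "must have equal length"
            )
        if self.times.size < 2:
            raise DomainError("a release profile needs at least 2 points")
        if self.times[0] < 0:
            raise DomainError(f"first sampling time must be >= 0, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("sampling times must be strictly increasing")
        if self.releases.min() < -0.5 or self.releases.max() > 110.0:
            raise DomainError(
                "releases must lie within [-0.5, 110] % "
                f"(got range [{self.releases.min():.3g}, {self.releases.max():.3g}])"
            )
        if self.c_inf <= 0:
            raise DomainError(f"c_inf must be positive, got {self.c_inf}")
        if self.sav is not None and not self.sav > 0:
            raise DomainError(f"sav must be positive when present, got {self.sav}")
        backsteps = -np.diff(self.releases)
        if backsteps.size and backsteps.max() > 2.0:
            warnings.warn(
                f"profile {self.label()} steps backwards by "
                f"{backsteps.max():.2f} % between samples",
                NonMonotoneWarning,
                stacklevel=2,
            )

    def label(self) -> str:
        parts = [self.formulation or "profile"]
        if self.sav is not None:
            parts.append(f"SA/V={self.sav:g}")
        if self.replicate is not None:
            parts.append(f"rep={self.replicate}")
        return " ".join(parts)

    def __len__(self) -> int:
        return int(self.times.size)


def mean_profile(profiles: Sequence[ReleaseProfile]) -> ReleaseProfile:
    """Point-wise mean of replicate profiles on their common time grid.

    Times are intersected across replicates; at least 2 common points are
    required.  Metadata (formulation, SA/V) is taken from the first profile;
    the replicate id of the result is ``None``.
    """
    if not profiles:
        raise DomainError("mean_profile requires at least one profile")
    if len(profiles) == 1:
        p = profiles[0]
        return ReleaseProfile(
            p.times.copy(), p.releases.copy(), c_inf=p.c_inf,
            formulation=p.formulation, sav=p.sav,
        )
    common = profiles[0].times
    for p in profiles[1:]:
        common = np.intersect1d(common, p.times)
    if common.size < 2:
        raise DomainError("replicates share fewer than 2 common time points")
    stacked = []
    for p in profiles:
        idx = np.searchsorted(p.times, common)
        stacked.append(p.releases[idx])
    first = profiles[0]
    return ReleaseProfile(
        common,
        np.mean(stacked, axis=0),
        c_inf=first.c_inf,
        formulation=first.formulation,
        sav=first.sav,
    )
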