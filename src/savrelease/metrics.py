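"""Dissolution summary statistics: MDT, RMSEP and the f2 similarity factor.

The mean dissolution time (MDT) is the average residence time of a drug
molecule in the dosage form during dissolution, computed from the sampled
cumulative-release curve by the trapezoid-increment (area-between-curves)
rule

    MDT = sum_i (c_{i+1} - c_i) * (t_i + t_{i+1}) / 2 / c_inf .

RMSEP is the root mean square error between predicted and observed values.
The f2 similarity factor is the FDA-accepted log-transformed reciprocal
mean-squared-difference metric for comparing two dissolution profiles
(100 = identical, >= 50 = similar); point selection follows regulatory
practice — at most one point beyond 85 % release of the reference, and a
warning when fewer than 12 points remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, UndefinedMDTError, UnderSampledWarning
from .profiles import ReleaseProfile, mean_profile

__all__ = ["mdt", "mdt_of_replicates", "rmsep", "F2Points", "select_f2_points", "f2"]


def mdt(profile: ReleaseProfile) -> float:
    """Mean dissolution time in minutes.

    A (0 min, 0 %) point is prepended when the profile does not start at
    t = 0 (the trapezoid increments need the release onset).  Points are used
    only up to the first sample reaching ``c_inf`` — the area between the
    curves does not change afterwards — and that sample is clamped to
    ``c_inf`` exactly.  Backward steps from measurement noise enter with
    their sign.
    """
    t = profile.times
    c = profile.releases
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([0.0], c))
    complete = np.nonzero(c >= profile.c_inf)[0]
    if complete.size:
        stop = complete[0] + 1
        t = t[:stop]
        c = c[:stop].copy()
        c[-1] = profile.c_inf
    if np.all(c <= 0):
        raise UndefinedMDTError(
            f"profile {profile.label()} never releases API; MDT undefined"
        )
    increments = np.diff(c)
    midpoints = (t[:-1] + t[1:]) / 2.0
    return float(np.sum(increments * midpoints) / profile.c_inf)


def mdt_of_replicates(
    profiles: list[ReleaseProfile], per_replicate: bool = False
) -> float | list[float]:
    """MDT of a replicate set: on the replicate-mean profile by default.

    With ``per_replicate=True`` returns one MDT per replicate instead (for
    standard-deviation reporting).
    """
    if per_replicate:
        return [mdt(p) for p in profiles]
    return mdt(mean_profile(profiles))


def rmsep(predicted, observed) -> float:
    """Root mean square error of prediction, in the units of the inputs."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise DomainError(
            f"predicted ({predicted.shape}) and observed ({observed.shape}) "
            "must be 1-D sequences of equal length"
        )
    if predicted.size == 0:
        raise DomainError("rmsep requires at least one pair")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


@dataclass(frozen=True)
class F2Points:
    """Common measurement points selected for an f2 comparison."""

    times: np.ndarray
    reference: np.ndarray
    test: np.ndarray
    under_sampled: bool  # fewer than the recommended 12 points


def select_f2_points(reference: ReleaseProfile, test: ReleaseProfile) -> F2Points:
    """Common measurement points for f2, truncated after 85 % release.

    The t = 0 point is not a measurement and is excluded.  All common points
    up to and including the first at which the *reference* exceeds 85 % are
    kept; f2 is sensitive to the number of points, so only one point beyond
    85 % enters.  Fewer than 12 remaining points sets the under-sampled flag
    and emits a warning.
    """
    common = np.intersect1d(reference.times, test.times)
    common = common[common > 0]
    if common.size == 0:
        raise DomainError("profiles share no common measurement times")
    r = reference.releases[np.searchsorted(reference.times, common)]
    t = test.releases[np.searchsorted(test.times, common)]
    beyond = np.nonzero(r > 85.0)[0]
    if beyond.size:
        stop = beyond[0] + 1
        common, r, t = common[:stop], r[:stop], t[:stop]
    under = common.size < 12
    if under:
        warnings.warn(
            f"only {common.size} points available for f2 (12 recommended)",
            UnderSampledWarning,
            stacklevel=2,
        )
    return F2Points(times=common, reference=r, test=t, under_sampled=under)


def f2(reference: ReleaseProfile, test: ReleaseProfile) -> float:
    """Similarity factor f2 between two dissolution profiles.

    ``f2 = 50 * log10( (1 + mean((R_t - T_t)^2))^-0.5 * 100 )``; identical
    profiles give exactly 100, values >= 50 indicate curves differing by at
    most ~10 % on average.
    """
    pts = select_f2_points(reference, test)
    msd = float(np.mean((pts.reference - pts.test) ** 2))
    return float(50.0 * np.log10((1.0 + msd) ** -0.5 * 100.0))
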