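"""Log-log power-law correlations between SA/V and release descriptors.

MDT and the rate constants of the release equations vary with the
surface-area-to-volume ratio of the printed geometry as power laws,

    response = A * (SA/V)^p ,

which become straight lines after log-transforming both axes.  This module
fits such laws by ordinary least squares in log space, predicts scalars and
complete release profiles for arbitrary SA/V, and inverts the law to find
the SA/V required for a target response (the inverse-design step).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DomainError, ExcludedConstantWarning, ExtrapolationWarning, RankError
from .models import ModelFit, PeppasSahlin, Weibull, evaluate_release
from .profiles import ReleaseProfile

__all__ = [
    "PowerLaw",
    "ConstantCorrelations",
    "fit_power_law",
    "predict_scalar",
    "invert_power_law",
    "two_point_power_law",
    "build_constant_correlations",
    "predict_profile",
]


@dataclass(frozen=True)
class PowerLaw:
    """``response = coefficient * (SA/V)^exponent``.

    ``coefficient`` is the response at SA/V = 1 mm^-1 (units of the
    response); ``exponent`` is dimensionless (negative for MDT, which falls
    as SA/V grows).  ``r_squared`` is that of the log-log regression and is
    ``None`` for an exact two-point calibration.  ``domain`` records the
    SA/V range of the calibration data.
    """

    coefficient: float
    exponent: float
    r_squared: float | None
    n_points: int
    domain: tuple[float, float]

    def __post_init__(self):
        if self.coefficient <= 0:
            raise DomainError(f"coefficient must be positive, got {self.coefficient}")
        if self.n_points < 2:
            raise DomainError("a power law needs at least 2 calibration points")

    def __call__(self, sav: float) -> float:
        return predict_scalar(self, sav)


def fit_power_law(pairs: Iterable[tuple[float, float]]) -> PowerLaw:
    """OLS of ln(response) on ln(SA/V); A = exp(intercept), p = slope."""
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise DomainError("need at least 2 (sav, response) pairs")
    sav, resp = data[:, 0], data[:, 1]
    if np.any(sav <= 0) or np.any(resp <= 0):
        raise DomainError("SA/V values and responses must all be positive")
    if np.unique(sav).size < 2:
        raise RankError("at least 2 distinct SA/V values required")
    x, y = np.log(sav), np.log(resp)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((y - fitted) ** 2)) / sst
    return PowerLaw(
        coefficient=float(math.exp(intercept)),
        exponent=float(slope),
        r_squared=r2,
        n_points=int(sav.size),
        domain=(float(sav.min()), float(sav.max())),
    )


def predict_scalar(pl: PowerLaw, sav: float) -> float:
    """Evaluate the law at a SA/V ratio; warns outside the calibrated domain."""
    if sav <= 0:
        raise DomainError(f"SA/V must be positive, got {sav}")
    lo, hi = pl.domain
    if not (lo <= sav <= hi):
        warnings.warn(
            f"SA/V={sav:g} lies outside the calibrated domain [{lo:g}, {hi:g}]; "
            "extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return pl.coefficient * sav**pl.exponent


def invert_power_law(pl: PowerLaw, target_response: float) -> float:
    """SA/V ratio at which the law attains ``target_response``."""
    if target_response <= 0:
        raise DomainError(f"target response must be positive, got {target_response}")
    if pl.exponent == 0:
        raise DomainError("a flat power law (exponent 0) cannot be inverted")
    return (target_response / pl.coefficient) ** (1.0 / pl.exponent)


def two_point_power_law(
    low: tuple[float, float], high: tuple[float, float]
) -> PowerLaw:
    """Exact power law through two calibration points (order-insensitive)."""
    (s1, r1), (s2, r2) = low, high
    if min(s1, s2, r1, r2) <= 0:
        raise DomainError("SA/V values and responses must be positive")
    if s1 == s2:
        raise RankError("two-point calibration needs distinct SA/V values")
    p = (math.log(r2) - math.log(r1)) / (math.log(s2) - math.log(s1))
    a = r1 / s1**p
    return PowerLaw(
        coefficient=float(a),
        exponent=float(p),
        r_squared=None,
        n_points=2,
        domain=(float(min(s1, s2)), float(max(s1, s2))),
    )


# ---------------------------------------------------------------------------
# correlations of fitted model constants
# ---------------------------------------------------------------------------

#: constants correlated with SA/V per model family
_CONSTANT_NAMES: dict[str, tuple[str, ...]] = {
    "peppas_sahlin": ("k1", "k2"),
    "weibull": ("a", "b"),
}


@dataclass(frozen=True)
class ConstantCorrelations:
    """One power law per model constant, for profile prediction.

    For the Peppas–Sahlin family the laws cover k1 and k2 and ``n_bar`` is
    the shared diffusion exponent; for Weibull they cover the time-scale a
    and the shape b.
    """

    family: str
    laws: Mapping[str, PowerLaw]
    n_bar: float | None = None

    def __post_init__(self):
        if self.family not in _CONSTANT_NAMES:
            raise DomainError(
                f"constant correlations support {sorted(_CONSTANT_NAMES)}, "
                f"not {self.family!r}"
            )
        missing = set(_CONSTANT_NAMES[self.family]) - set(self.laws)
        if missing:
            raise DomainError(f"missing power law(s) for constant(s) {sorted(missing)}")
        if self.family == "peppas_sahlin" and self.n_bar is None:
            raise DomainError("peppas_sahlin correlations require n_bar")


def build_constant_correlations(
    fits_by_sav: Mapping[float, ModelFit],
    n_bar: float | None = None,
) -> ConstantCorrelations:
    """Power laws of the fitted constants across a SA/V series.

    ``fits_by_sav`` maps SA/V ratio to the :class:`~savrelease.models.ModelFit`
    obtained at that ratio (all of one family).  Non-positive constants —
    typically k2 at low SA/V — are excluded from that constant's regression
    with a warning.  For Peppas–Sahlin, ``n_bar`` defaults to the mean of the
    fitted exponents.
    """
    if len(fits_by_sav) < 2:
        raise DomainError("need fits at >= 2 SA/V ratios")
    families = {fit.family for fit in fits_by_sav.values()}
    if len(families) != 1:
        raise DomainError(f"fits mix model families: {sorted(families)}")
    family = families.pop()
    if family not in _CONSTANT_NAMES:
        raise DomainError(
            f"constant correlations support {sorted(_CONSTANT_NAMES)}, not {family!r}"
        )
    laws: dict[str, PowerLaw] = {}
    for name in _CONSTANT_NAMES[family]:
        pairs = []
        for sav, fit in sorted(fits_by_sav.items()):
            value = getattr(fit.model, name)
            if value <= 0:
                warnings.warn(
                    f"excluding non-positive {name}={value:g} at SA/V={sav:g} "
                    "from the log-log regression",
                    ExcludedConstantWarning,
                    stacklevel=2,
                )
                continue
            pairs.append((sav, value))
        if len(pairs) < 2:
            raise RankError(f"fewer than 2 usable values for constant {name}")
        laws[name] = fit_power_law(pairs)
    if family == "peppas_sahlin" and n_bar is None:
        n_bar = float(np.mean([fit.model.n for fit in fits_by_sav.values()]))
    return ConstantCorrelations(family=family, laws=laws, n_bar=n_bar)


def predict_profile(
    corr: ConstantCorrelations,
    sav: float,
    times: Sequence[float],
) -> ReleaseProfile:
    """Predicted release profile at a SA/V ratio.

    Each constant is evaluated from its power law, inserted into the model
    equation, and the curve evaluated at ``times`` (capped at 100 %, floored
    at 0).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0):
        raise DomainError("times must be a non-empty ascending sequence")
    if sav <= 0:
        raise DomainError(f"SA/V must be positive, got {sav}")
    if corr.family == "peppas_sahlin":
        model = PeppasSahlin(
            k1=predict_scalar(corr.laws["k1"], sav),
            k2=predict_scalar(corr.laws["k2"], sav),
            n=corr.n_bar,
        )
    else:
        model = Weibull(
            a=predict_scalar(corr.laws["a"], sav),
            b=predict_scalar(corr.laws["b"], sav),
            ti=0.0,
        )
    releases = evaluate_release(model, times, clamp=True)
    return ReleaseProfile(times=times, releases=releases, sav=sav)
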