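"""Release-kinetics equations: evaluation, fitting, ranking, classification.

Seven classical models of cumulative drug release (all on the 0–100 % scale,
time in minutes) are supported:

* Korsmeyer–Peppas power law          ``c(t) = k t^n``
* Peppas–Sahlin diffusion/relaxation  ``c(t) = k1 t^n + k2 t^{2n}``
* Higuchi square-root-of-time law     ``c(t) = kH sqrt(t)``
* Lapidus–Lordi (Higuchi with SA/V)   ``c(t) = 200 (SA/V) sqrt(D t / pi)``
* Hixson–Crowell cube-root law        ``c(t) = 100 (1 - (1 - k t / W0^{1/3})^3)``
* Hopfenberg erosion law              ``c(t) = 100 (1 - (1 - k0 t/(c0 a0))^n_shape)``
* Weibull curve                       ``c(t) = 100 (1 - exp(-((t - Ti)/a)^b))``

Only rate *ratios* are identifiable from a %-release curve for Higuchi,
Lapidus–Lordi, Hixson–Crowell and Hopfenberg, so fitting uses the collapsed
forms (the physical symbols remain available on the parameter classes).
The power-law models are valid only on the early part of the curve, so each
family carries a default fit cap: 60 % released for Korsmeyer–Peppas,
Higuchi and Lapidus–Lordi, 98 % for the rest.

Fitting is bounded nonlinear least squares seeded by log-linearisation, with
multi-starts; goodness of fit is R^2 over the fitted points only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar, nnls

from .exceptions import (
    ConvergenceError,
    DomainError,
    InsufficientDataError,
)
from .profiles import ReleaseProfile

__all__ = [
    "KorsmeyerPeppas",
    "PeppasSahlin",
    "Higuchi",
    "LapidusLordi",
    "HixsonCrowell",
    "Hopfenberg",
    "Weibull",
    "ModelFit",
    "MODEL_FAMILIES",
    "DEFAULT_FIT_CAPS",
    "evaluate_release",
    "fit_release",
    "shared_exponent_fit",
    "classify_transport",
    "select_model",
    "TRANSPORT_THRESHOLDS",
]


# ---------------------------------------------------------------------------
# parameter classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KorsmeyerPeppas:
    """Power law; k in %/min^n, diffusion exponent n dimensionless."""

    k: float
    n: float

    def __post_init__(self):
        if self.k < 0:
            raise DomainError(f"k must be >= 0, got {self.k}")
        if not (0 < self.n <= 2):
            raise DomainError(f"n must lie in (0, 2], got {self.n}")


@dataclass(frozen=True)
class PeppasSahlin:
    """Fickian (k1 t^n) plus relaxational (k2 t^2n) contributions."""

    k1: float
    k2: float
    n: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise DomainError("k1 and k2 must be >= 0")
        if not (0 < self.n <= 2):
            raise DomainError(f"n must lie in (0, 2], got {self.n}")


@dataclass(frozen=True)
class Higuchi:
    """Square-root-of-time law, collapsed constant kH in %/min^0.5.

    The physical form ``Q = sqrt(D (2 c0 - cs) cs t)`` collapses to
    ``kH sqrt(t)`` on the percent scale; D, c0 and cs are not individually
    identifiable from a release curve, so ``from_physical`` is provided for
    forward evaluation only.
    """

    kH: float

    def __post_init__(self):
        if self.kH < 0:
            raise DomainError(f"kH must be >= 0, got {self.kH}")

    @classmethod
    def from_physical(cls, D: float, c0: float, cs: float, q100: float) -> "Higuchi":
        """Collapse D (mm^2/min), c0, cs (mg/mm^3) and the amount-per-area
        corresponding to 100 % release (q100, mg/mm^2) into kH."""
        if min(D, c0, cs, q100) <= 0 or cs > c0:
            raise DomainError("need D, c0, cs, q100 > 0 and cs <= c0")
        return cls(kH=100.0 * math.sqrt(D * (2 * c0 - cs) * cs) / q100)


@dataclass(frozen=True)
class LapidusLordi:
    """Higuchi law for swellable matrices with SA/V explicit.

    ``c(t) = 100 * 2 (SA/V) sqrt(D t / pi)``; D in mm^2/min, sav in mm^-1.
    """

    D: float
    sav: float

    def __post_init__(self):
        if self.D < 0:
            raise DomainError(f"D must be >= 0, got {self.D}")
        if self.sav <= 0:
            raise DomainError(f"sav must be positive, got {self.sav}")


@dataclass(frozen=True)
class HixsonCrowell:
    """Cube-root (surface-erosion) law.

    ``W0^{1/3} - Wi^{1/3} = k t`` gives released % =
    ``100 (1 - (1 - k t / W0^{1/3})^3)``; only k / W0^{1/3} is identifiable,
    W0 is conventionally 100.  After complete erosion the release holds at
    100 %.
    """

    k: float
    w0: float = 100.0

    def __post_init__(self):
        if self.k < 0:
            raise DomainError(f"k must be >= 0, got {self.k}")
        if self.w0 <= 0:
            raise DomainError(f"w0 must be positive, got {self.w0}")

    @property
    def rate(self) -> float:
        """Collapsed erosion rate k / W0^{1/3} in 1/min."""
        return self.k / self.w0 ** (1.0 / 3.0)


@dataclass(frozen=True)
class Hopfenberg:
    """Erosion law for plates (n_shape=1), cylinders (2) and spheres (3).

    ``c(t) = 100 (1 - (1 - k0 t / (c0 a0))^n_shape)``; only the ratio
    ``k0 / (c0 a0)`` is identifiable from a release curve (fits return
    c0 = a0 = 1).  Release holds at 100 % after complete erosion.
    """

    k0: float
    c0: float
    a0: float
    n_shape: int

    def __post_init__(self):
        if self.k0 < 0:
            raise DomainError(f"k0 must be >= 0, got {self.k0}")
        if self.c0 <= 0 or self.a0 <= 0:
            raise DomainError("c0 and a0 must be positive")
        if self.n_shape not in (1, 2, 3):
            raise DomainError(f"n_shape must be 1, 2 or 3, got {self.n_shape}")

    @property
    def rate(self) -> float:
        """Collapsed erosion rate k0 / (c0 a0) in 1/min."""
        return self.k0 / (self.c0 * self.a0)


@dataclass(frozen=True)
class Weibull:
    """Empirical Weibull curve; a = time scale (min), b = shape, Ti = lag.

    b = 1 gives first-order release, b > 1 sigmoid, b < 1 parabolic curves.
    """

    a: float
    b: float
    ti: float = 0.0

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError(f"a must be positive, got {self.a}")
        if self.b <= 0:
            raise DomainError(f"b must be positive, got {self.b}")
        if self.ti < 0:
            raise DomainError(f"Ti must be >= 0, got {self.ti}")


ModelParams = (
    KorsmeyerPeppas
    | PeppasSahlin
    | Higuchi
    | LapidusLordi
    | HixsonCrowell
    | Hopfenberg
    | Weibull
)

MODEL_FAMILIES: dict[str, type] = {
    "korsmeyer_peppas": KorsmeyerPeppas,
    "peppas_sahlin": PeppasSahlin,
    "higuchi": Higuchi,
    "lapidus_lordi": LapidusLordi,
    "hixson_crowell": HixsonCrowell,
    "hopfenberg": Hopfenberg,
    "weibull": Weibull,
}

_FAMILY_OF = {cls: name for name, cls in MODEL_FAMILIES.items()}

#: default upper bound (% released) on points entering a fit
DEFAULT_FIT_CAPS: dict[str, float] = {
    "korsmeyer_peppas": 60.0,
    "higuchi": 60.0,
    "lapidus_lordi": 60.0,
    "peppas_sahlin": 98.0,
    "hixson_crowell": 98.0,
    "hopfenberg": 98.0,
    "weibull": 98.0,
}

#: continuous free parameters per family (as fitted)
_N_FREE: dict[str, int] = {
    "korsmeyer_peppas": 2,
    "peppas_sahlin": 3,
    "higuchi": 1,
    "lapidus_lordi": 1,
    "hixson_crowell": 1,
    "hopfenberg": 2,  # rate + shape index
    "weibull": 2,
}


def family_of(model: ModelParams) -> str:
    return _FAMILY_OF[type(model)]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_release(model: ModelParams, t, clamp: bool = False):
    """Cumulative release (% of total load) at time(s) t in minutes.

    Raw model values are returned by default (power-law models exceed 100 %
    at late times); ``clamp=True`` clips to [0, 100].  Scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")

    if isinstance(model, KorsmeyerPeppas):
        out = model.k * t_arr**model.n
    elif isinstance(model, PeppasSahlin):
        out = model.k1 * t_arr**model.n + model.k2 * t_arr ** (2 * model.n)
    elif isinstance(model, Higuchi):
        out = model.kH * np.sqrt(t_arr)
    elif isinstance(model, LapidusLordi):
        out = 100.0 * 2.0 * model.sav * np.sqrt(model.D * t_arr / math.pi)
    elif isinstance(model, HixsonCrowell):
        core = np.maximum(1.0 - model.rate * t_arr, 0.0)
        out = 100.0 * (1.0 - core**3)
    elif isinstance(model, Hopfenberg):
        core = np.maximum(1.0 - model.rate * t_arr, 0.0)
        out = 100.0 * (1.0 - core**model.n_shape)
    elif isinstance(model, Weibull):
        shifted = np.maximum(t_arr - model.ti, 0.0)
        out = 100.0 * (1.0 - np.exp(-((shifted / model.a) ** model.b)))
    else:
        raise DomainError(f"unknown model type {type(model).__name__}")

    if clamp:
        out = np.clip(out, 0.0, 100.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    """One fitted release equation with its goodness of fit."""

    model: ModelParams
    r_squared: float
    fit_cap: float
    n_points_used: int

    @property
    def family(self) -> str:
        return family_of(self.model)

    @property
    def n_free_params(self) -> int:
        return _N_FREE[self.family]


def _r_squared(model: ModelParams, t: np.ndarray, c: np.ndarray) -> float:
    pred = evaluate_release(model, t)
    ssr = float(np.sum((c - pred) ** 2))
    sst = float(np.sum((c - c.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if ssr < 1e-12 else -math.inf
    return 1.0 - ssr / sst


def _fit_points(
    profile: ReleaseProfile, fit_cap: float, n_free: int
) -> tuple[np.ndarray, np.ndarray]:
    mask = profile.releases <= fit_cap
    t, c = profile.times[mask], profile.releases[mask]
    if t.size < n_free + 1:
        raise InsufficientDataError(
            f"{t.size} points at or below {fit_cap} % released; "
            f"need at least {n_free + 1}"
        )
    return t, c


def _polish(residual, x0, bounds) -> np.ndarray | None:
    x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
    try:
        res = least_squares(
            residual, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=10_000,
        )
    except Exception:
        return None
    return res.x if res.success or np.isfinite(res.cost) else None


def _best_start(residual, starts, bounds) -> np.ndarray:
    best, best_ssr = None, math.inf
    for x0 in starts:
        x = _polish(residual, x0, bounds)
        if x is None:
            continue
        ssr = float(np.sum(residual(x) ** 2))
        if ssr < best_ssr:
            best, best_ssr = x, ssr
    if best is None:
        raise ConvergenceError(
            f"nonlinear fit failed to converge from {len(starts)} start(s)"
        )
    return best


def _loglin_kmp_seed(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    mask = (t > 0) & (c > 0)
    if mask.sum() < 2:
        return 1.0, 0.7
    slope, intercept = np.polyfit(np.log(t[mask]), np.log(c[mask]), 1)
    return math.exp(intercept), min(max(slope, 0.05), 2.0)


def _nnls_peppas_sahlin(t, c, n) -> tuple[float, float, float]:
    """k1, k2 >= 0 by non-negative least squares at a fixed exponent n."""
    design = np.column_stack([t**n, t ** (2 * n)])
    coef, rnorm = nnls(design, c)
    return float(coef[0]), float(coef[1]), float(rnorm**2)


def fit_release(
    profile: ReleaseProfile,
    family: str,
    fit_cap: float | None = None,
    fixed_n: float | None = None,
    sav: float | None = None,
) -> ModelFit:
    """Fit one release equation to a profile by bounded least squares.

    Only points with release <= ``fit_cap`` enter the fit (default cap per
    family, see :data:`DEFAULT_FIT_CAPS`); R^2 is computed strictly over the
    fitted points.  ``fixed_n`` pins the diffusion exponent of the
    Korsmeyer–Peppas or Peppas–Sahlin equation.  Lapidus–Lordi needs the
    SA/V ratio, taken from ``sav`` or the profile metadata.
    """
    if family not in MODEL_FAMILIES:
        raise DomainError(
            f"unknown model family {family!r}; expected one of {sorted(MODEL_FAMILIES)}"
        )
    cap = DEFAULT_FIT_CAPS[family] if fit_cap is None else float(fit_cap)
    n_free = _N_FREE[family]
    if fixed_n is not None and family in ("korsmeyer_peppas", "peppas_sahlin"):
        n_free -= 1
    t, c = _fit_points(profile, cap, n_free)

    if family == "korsmeyer_peppas":
        model = _fit_kmp(t, c, fixed_n)
    elif family == "peppas_sahlin":
        model = _fit_peppas_sahlin(t, c, fixed_n)
    elif family == "higuchi":
        model = _fit_higuchi(t, c)
    elif family == "lapidus_lordi":
        model = _fit_lapidus_lordi(t, c, sav if sav is not None else profile.sav)
    elif family == "hixson_crowell":
        model = _fit_hixson_crowell(t, c)
    elif family == "hopfenberg":
        model = _fit_hopfenberg(t, c)
    else:
        model = _fit_weibull(t, c)

    return ModelFit(
        model=model,
        r_squared=_r_squared(model, t, c),
        fit_cap=cap,
        n_points_used=int(t.size),
    )


def _fit_kmp(t, c, fixed_n) -> KorsmeyerPeppas:
    if fixed_n is not None:
        denom = float(np.sum(t ** (2 * fixed_n)))
        k = max(float(np.sum(c * t**fixed_n)) / denom, 0.0) if denom else 0.0
        return KorsmeyerPeppas(k=k, n=fixed_n)
    k0, n0 = _loglin_kmp_seed(t, c)

    def residual(x):
        return x[0] * t ** x[1] - c

    starts = [(k0, n0), (k0, 0.5), (k0, 1.0), (max(c) / max(t.max(), 1.0), 0.7)]
    x = _best_start(residual, starts, ([0.0, 1e-6], [np.inf, 2.0]))
    return KorsmeyerPeppas(k=float(x[0]), n=float(x[1]))


def _fit_peppas_sahlin(t, c, fixed_n) -> PeppasSahlin:
    if fixed_n is not None:
        k1, k2, _ = _nnls_peppas_sahlin(t, c, fixed_n)
        return PeppasSahlin(k1=k1, k2=k2, n=fixed_n)

    # profile over n: inner problem is linear, solved exactly by NNLS
    def ssr_of_n(n):
        return _nnls_peppas_sahlin(t, c, n)[2]

    grid = np.linspace(0.05, 2.0, 79)
    n_grid = grid[int(np.argmin([ssr_of_n(n) for n in grid]))]
    res = minimize_scalar(
        ssr_of_n,
        bounds=(max(n_grid - 0.05, 0.01), min(n_grid + 0.05, 2.0)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    n_hat = float(res.x)
    k1, k2, _ = _nnls_peppas_sahlin(t, c, n_hat)

    def residual(x):
        return x[0] * t ** x[2] + x[1] * t ** (2 * x[2]) - c

    x = _best_start(
        residual, [(k1, k2, n_hat)], ([0.0, 0.0, 1e-6], [np.inf, np.inf, 2.0])
    )
    return PeppasSahlin(k1=float(x[0]), k2=float(x[1]), n=float(x[2]))


def _fit_higuchi(t, c) -> Higuchi:
    denom = float(np.sum(t))
    kh = max(float(np.sum(c * np.sqrt(t))) / denom, 0.0) if denom else 0.0
    return Higuchi(kH=kh)


def _fit_lapidus_lordi(t, c, sav) -> LapidusLordi:
    if sav is None or sav <= 0:
        raise DomainError(
            "Lapidus-Lordi requires a positive SA/V ratio (profile metadata or sav=)"
        )
    kh = _fit_higuchi(t, c).kH
    return LapidusLordi(D=math.pi * (kh / (200.0 * sav)) ** 2, sav=float(sav))


def _erosion_rate_seed(t, c, n_shape) -> float:
    """Linearised seed for (1 - c/100)^(1/n_shape) = 1 - rate * t."""
    y = np.clip(1.0 - c / 100.0, 0.0, None) ** (1.0 / n_shape)
    denom = float(np.sum(t * t))
    if denom == 0:
        return 1e-3
    return max(float(np.sum(t * (1.0 - y))) / denom, 1e-9)


def _fit_hixson_crowell(t, c) -> HixsonCrowell:
    w0 = 100.0
    seed = _erosion_rate_seed(t, c, 3)

    def residual(x):
        core = np.maximum(1.0 - x[0] * t, 0.0)
        return 100.0 * (1.0 - core**3) - c

    x = _best_start(residual, [(seed,), (seed * 0.5,), (seed * 2,)], ([0.0], [np.inf]))
    return HixsonCrowell(k=float(x[0]) * w0 ** (1.0 / 3.0), w0=w0)


def _fit_hopfenberg(t, c) -> Hopfenberg:
    best: tuple[float, Hopfenberg] | None = None
    for n_shape in (1, 2, 3):
        seed = _erosion_rate_seed(t, c, n_shape)

        def residual(x, n_shape=n_shape):
            core = np.maximum(1.0 - x[0] * t, 0.0)
            return 100.0 * (1.0 - core**n_shape) - c

        try:
            x = _best_start(
                residual, [(seed,), (seed * 0.5,), (seed * 2,)], ([0.0], [np.inf])
            )
        except ConvergenceError:
            continue
        ssr = float(np.sum(residual(x) ** 2))
        model = Hopfenberg(k0=float(x[0]), c0=1.0, a0=1.0, n_shape=n_shape)
        if best is None or ssr < best[0]:
            best = (ssr, model)
    if best is None:
        raise ConvergenceError("Hopfenberg fit failed for all shape indices")
    return best[1]


def _fit_weibull(t, c, fit_lag: bool = False) -> Weibull:
    interior = (c > 0.0) & (c < 100.0) & (t > 0)
    if interior.sum() >= 2:
        y = np.log(-np.log(1.0 - c[interior] / 100.0))
        slope, intercept = np.polyfit(np.log(t[interior]), y, 1)
        b0 = min(max(slope, 0.05), 10.0)
        a0 = math.exp(-intercept / b0)
    else:
        a0, b0 = max(t.max(), 1.0) / 2.0, 1.0

    if not fit_lag:
        def residual(x):
            return 100.0 * (1.0 - np.exp(-((t / x[0]) ** x[1]))) - c

        x = _best_start(
            residual,
            [(a0, b0), (a0, 1.0), (a0 * 2, b0), (a0 / 2, b0)],
            ([1e-9, 1e-3], [np.inf, 10.0]),
        )
        return Weibull(a=float(x[0]), b=float(x[1]), ti=0.0)

    def residual(x):
        shifted = np.maximum(t - x[2], 0.0)
        return 100.0 * (1.0 - np.exp(-((shifted / x[0]) ** x[1]))) - c

    x = _best_start(
        residual,
        [(a0, b0, 0.0), (a0, b0, t[t > 0].min() if (t > 0).any() else 0.0)],
        ([1e-9, 1e-3, 0.0], [np.inf, 10.0, float(t.max())]),
    )
    return Weibull(a=float(x[0]), b=float(x[1]), ti=float(x[2]))


# ---------------------------------------------------------------------------
# shared diffusion exponent across a SA/V series
# ---------------------------------------------------------------------------

def shared_exponent_fit(
    profiles: Sequence[ReleaseProfile],
    family: str = "peppas_sahlin",
    fit_cap: float | None = None,
) -> tuple[float, list[ModelFit | None]]:
    """Two-pass fit of a SA/V series with one common diffusion exponent.

    Pass 1 fits the exponent n freely per profile; n_bar is their arithmetic
    mean.  Pass 2 refits the rate constants with n fixed to n_bar.  Profiles
    whose fit fails are reported as ``None`` in the output list (partial
    results) while the others proceed.
    """
    if family not in ("korsmeyer_peppas", "peppas_sahlin"):
        raise DomainError(f"shared exponent applies to power-law families, not {family}")
    if len(profiles) < 1:
        raise DomainError("shared_exponent_fit requires at least one profile")
    free_ns: list[float | None] = []
    for p in profiles:
        try:
            fit = fit_release(p, family, fit_cap=fit_cap)
            free_ns.append(fit.model.n)
        except (InsufficientDataError, ConvergenceError) as exc:
            warnings.warn(f"free-exponent fit failed for {p.label()}: {exc}", stacklevel=2)
            free_ns.append(None)
    usable = [n for n in free_ns if n is not None]
    if not usable:
        raise ConvergenceError("free-exponent pass failed for every profile")
    n_bar = float(np.mean(usable))
    fits: list[ModelFit | None] = []
    for p, n_i in zip(profiles, free_ns):
        if n_i is None:
            fits.append(None)
            continue
        try:
            fits.append(fit_release(p, family, fit_cap=fit_cap, fixed_n=n_bar))
        except (InsufficientDataError, ConvergenceError) as exc:
            warnings.warn(f"fixed-exponent refit failed for {p.label()}: {exc}", stacklevel=2)
            fits.append(None)
    return n_bar, fits


# ---------------------------------------------------------------------------
# transport classification
# ---------------------------------------------------------------------------

#: (Fickian threshold, Case-II threshold) of the diffusion exponent per geometry
TRANSPORT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "thin_film": (0.50, 1.00),
    "cylinder": (0.45, 0.89),
    "sphere": (0.43, 0.85),
}

_CLASSIFY_TOL = 0.005


def classify_transport(n: float, geometry_class: str) -> str:
    """Release-mechanism label from the diffusion exponent n.

    At the geometry's lower threshold (within 0.005): Fickian diffusion;
    at the upper: Case-II transport; strictly between: anomalous transport;
    below and above: sub-Fickian and super-Case-II respectively.
    """
    if geometry_class not in TRANSPORT_THRESHOLDS:
        raise DomainError(
            f"unknown geometry class {geometry_class!r}; "
            f"expected one of {sorted(TRANSPORT_THRESHOLDS)}"
        )
    if not n > 0:
        raise DomainError(f"diffusion exponent must be positive, got {n}")
    lo, hi = TRANSPORT_THRESHOLDS[geometry_class]
    if abs(n - lo) <= _CLASSIFY_TOL:
        return "Fickian diffusion"
    if abs(n - hi) <= _CLASSIFY_TOL:
        return "Case-II transport"
    if lo < n < hi:
        return "anomalous transport"
    return "sub-Fickian" if n < lo else "super-Case-II"


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_model(
    profile: ReleaseProfile,
    families: Sequence[str] | None = None,
    fit_caps: dict[str, float] | None = None,
    sav: float | None = None,
) -> list[ModelFit]:
    """Fit several families and rank them by R^2 (descending).

    Ties (difference below 1e-6) are broken in favour of fewer free
    parameters.  Families whose fit fails are skipped with a warning; if all
    fail a :class:`ConvergenceError` aggregates the causes.
    """
    families = list(families) if families is not None else list(MODEL_FAMILIES)
    fits: list[ModelFit] = []
    failures: list[str] = []
    for fam in families:
        cap = (fit_caps or {}).get(fam)
        try:
            fits.append(fit_release(profile, fam, fit_cap=cap, sav=sav))
        except (InsufficientDataError, ConvergenceError, DomainError) as exc:
            failures.append(f"{fam}: {exc}")
            warnings.warn(f"fit of {fam} failed: {exc}", stacklevel=2)
    if not fits:
        raise ConvergenceError("all model fits failed: " + "; ".join(failures))
    fits.sort(key=lambda f: (-round(f.r_squared / 1e-6), f.n_free_params))
    return fits
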