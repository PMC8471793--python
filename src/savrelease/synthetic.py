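"""Synthetic dissolution studies with the structure the analysis assumes.

The generator emulates an in-vitro dissolution experiment on FDM-printed
tablets: for an *archetype* formulation it evaluates the true release curve
from the archetype's model constants at the apparatus sampling schedule and
adds independent Gaussian replicate noise on the cumulative-% scale.

Archetype constants at the tabulated SA/V levels are the reference values
themselves; off-grid constants come from log-log interpolating laws fitted
here (a private regression), so the generator shares no code path with the
analysis-side :mod:`savrelease.correlation` — parameter-recovery tests
cannot self-confirm.

Defaults mirror the emulated study: three replicate vessels per design and
1.5 % (cumulative release) noise, a typical magnitude for basket-method
UV-Vis dissolution data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import reference
from .exceptions import DomainError
from .metrics import mdt
from .models import ModelParams, PeppasSahlin, Weibull, evaluate_release
from .profiles import ReleaseProfile

__all__ = [
    "Archetype",
    "ARCHETYPES",
    "SimulationConfig",
    "StudyDataset",
    "sampling_schedule",
    "simulate_profile",
    "simulate_study",
]


def sampling_schedule(t_end: float) -> np.ndarray:
    """Apparatus sampling times (min) for a run of duration ``t_end``.

    Zero, then every 5 min to 30 min, every 10 min to 120 min, every 20 min
    to 240 min and every 30 min thereafter, truncated at ``t_end``.
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be positive, got {t_end}")
    times = np.concatenate(
        [
            np.arange(0.0, 30.0 + 1e-9, 5.0),
            np.arange(40.0, 120.0 + 1e-9, 10.0),
            np.arange(140.0, 240.0 + 1e-9, 20.0),
            np.arange(270.0, t_end + 1e-9, 30.0),
        ]
    )
    return times[times <= t_end + 1e-9]


def _loglog_laws(table: dict[float, tuple[float, ...]]) -> list[tuple[float, float]]:
    """Private log-log interpolating law (A, p) per constant column."""
    sav = np.log(np.array(sorted(table)))
    laws = []
    n_cols = len(next(iter(table.values())))
    for j in range(n_cols):
        y = np.log(np.array([table[s][j] for s in sorted(table)]))
        slope, intercept = np.polyfit(sav, y, 1)
        laws.append((math.exp(intercept), slope))
    return laws


@dataclass(frozen=True)
class Archetype:
    """A benchmark formulation: model family plus constants keyed by SA/V."""

    name: str
    family: str  # "peppas_sahlin" or "weibull"
    constants: dict[float, tuple[float, ...]]
    n_bar: float | None = None

    def __post_init__(self):
        if self.family not in ("peppas_sahlin", "weibull"):
            raise DomainError(f"unsupported archetype family {self.family!r}")
        if self.family == "peppas_sahlin" and self.n_bar is None:
            raise DomainError("peppas_sahlin archetype requires n_bar")
        if any(min(v) <= 0 for v in self.constants.values()):
            raise DomainError("archetype constants must be positive")
        object.__setattr__(self, "_laws", _loglog_laws(self.constants))

    def constants_at(self, sav: float) -> tuple[float, ...]:
        """Constants at a SA/V ratio: tabulated if on-grid, else from the
        interpolating laws."""
        if sav <= 0:
            raise DomainError(f"SA/V must be positive, got {sav}")
        for key, values in self.constants.items():
            if abs(key - sav) < 1e-9:
                return values
        return tuple(a * sav**p for a, p in self._laws)

    def model_at(self, sav: float) -> ModelParams:
        values = self.constants_at(sav)
        if self.family == "peppas_sahlin":
            return PeppasSahlin(k1=values[0], k2=values[1], n=self.n_bar)
        return Weibull(a=values[0], b=values[1], ti=0.0)

    def true_curve(self, sav: float, times) -> np.ndarray:
        """Noise-free cumulative release (%) capped at 100."""
        return np.minimum(evaluate_release(self.model_at(sav), times), 100.0)

    def true_mdt(self, sav: float) -> float:
        """MDT of the noise-free curve, from a dense 0.05-min grid."""
        model = self.model_at(sav)
        if isinstance(model, Weibull):
            t_end = model.ti + model.a * math.log(1e5) ** (1.0 / model.b)
        else:
            # time at which the raw curve reaches 100 %
            t_end = (100.0 / model.k1) ** (1.0 / model.n)
            while evaluate_release(model, t_end) < 100.0:
                t_end *= 1.5
        t = np.arange(0.0, t_end + 0.05, 0.05)
        return mdt(ReleaseProfile(t, self.true_curve(sav, t), sav=sav))


ARCHETYPES: dict[str, Archetype] = {
    "PVA-PDM": Archetype(
        name="PVA-PDM",
        family="peppas_sahlin",
        constants=dict(reference.PEPPAS_SAHLIN_CONSTANTS["PVA-PDM"]),
        n_bar=reference.SHARED_EXPONENT["PVA-PDM"],
    ),
    "EVA-LD": Archetype(
        name="EVA-LD",
        family="peppas_sahlin",
        constants=dict(reference.PEPPAS_SAHLIN_CONSTANTS["EVA-LD"]),
        n_bar=reference.SHARED_EXPONENT["EVA-LD"],
    ),
    "PVA-PZQ": Archetype(
        name="PVA-PZQ",
        family="weibull",
        constants=dict(reference.WEIBULL_CONSTANTS["PVA-PZQ"]),
    ),
}


def _auto_t_end(archetype: Archetype, sav: float, cap: float = 600.0) -> float:
    """Shortest schedule-aligned duration covering ~99.5 % release."""
    times = sampling_schedule(cap)
    curve = archetype.true_curve(sav, times)
    done = np.nonzero(curve >= 99.5)[0]
    return float(times[done[0]]) if done.size else cap


def simulate_profile(
    archetype: Archetype | str,
    sav: float,
    noise_sd: float = 1.5,
    seed: int | None = 0,
    replicate_count: int = 3,
    t_end: float | None = None,
) -> list[ReleaseProfile]:
    """Replicate release profiles of one design.

    The truth curve is the archetype model evaluated on the sampling
    schedule (capped at 100 %); each replicate adds independent Gaussian
    noise of standard deviation ``noise_sd`` (% released) per point, clipped
    to [0, 102].  ``t_end=None`` extends the run until ~99.5 % is released.
    """
    if isinstance(archetype, str):
        if archetype not in ARCHETYPES:
            raise DomainError(
                f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
            )
        archetype = ARCHETYPES[archetype]
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    if replicate_count < 1:
        raise DomainError(f"replicate_count must be >= 1, got {replicate_count}")
    times = sampling_schedule(t_end if t_end is not None else _auto_t_end(archetype, sav))
    truth = archetype.true_curve(sav, times)
    rng = np.random.default_rng(seed)
    profiles = []
    for rep in range(1, replicate_count + 1):
        noisy = truth + rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd else truth.copy()
        noisy = np.clip(noisy, 0.0, 102.0)
        profiles.append(
            ReleaseProfile(
                times=times.copy(),
                releases=noisy,
                replicate=rep,
                formulation=archetype.name,
                sav=sav,
            )
        )
    return profiles


@dataclass(frozen=True)
class SimulationConfig:
    """Study design: archetype, SA/V grid, replication, noise and seed."""

    archetype: str
    sav_values: tuple[float, ...]
    replicates: int = 3
    noise_sd: float = 1.5  # % released, additive Gaussian per point
    seed: int = 0
    t_end: float | None = None

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise DomainError(
                f"unknown archetype {self.archetype!r}; expected one of {sorted(ARCHETYPES)}"
            )
        if not self.sav_values:
            raise DomainError("sav_values must be non-empty")
        if any(s <= 0 for s in self.sav_values):
            raise DomainError("all SA/V values must be positive")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


@dataclass(frozen=True)
class StudyDataset:
    """Simulated study: profiles plus the generating truth for recovery tests."""

    config: SimulationConfig
    profiles: list[ReleaseProfile]
    #: SA/V -> {"constants": tuple, "mdt": float} of the generating model
    truth: dict[float, dict]

    def profiles_at(self, sav: float) -> list[ReleaseProfile]:
        return [p for p in self.profiles if abs(p.sav - sav) < 1e-9]


def simulate_study(config: SimulationConfig) -> StudyDataset:
    """Profiles for each SA/V x replicate plus the generating truth record."""
    archetype = ARCHETYPES[config.archetype]
    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.generate_state(len(config.sav_values))
    profiles: list[ReleaseProfile] = []
    truth: dict[float, dict] = {}
    for sav, child in zip(config.sav_values, child_seeds):
        profiles.extend(
            simulate_profile(
                archetype,
                sav,
                noise_sd=config.noise_sd,
                seed=int(child),
                replicate_count=config.replicates,
                t_end=config.t_end,
            )
        )
        times = sampling_schedule(
            config.t_end if config.t_end is not None else _auto_t_end(archetype, sav)
        )
        truth[sav] = {
            "constants": archetype.constants_at(sav),
            "mdt": archetype.true_mdt(sav),
            # noise-free MDT under the same sampling operator as the analysis
            "mdt_sampled": mdt(
                ReleaseProfile(times, archetype.true_curve(sav, times), sav=sav)
            ),
        }
    return StudyDataset(config=config, profiles=profiles, truth=truth)
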